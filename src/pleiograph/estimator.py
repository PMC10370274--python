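"""Estimator interface for the annotation-aware MRF pleiotropy model.

:class:`PleiotropyMRF` follows the scikit-learn estimator contract
(constructor stores hyperparameters, ``fit`` learns, fitted attributes carry
a trailing underscore, ``get_params``/``set_params`` work with
:func:`sklearn.base.clone` and model-selection utilities).  ``X`` is the
T x n matrix of probit-transformed association statistics; annotations and a
prior phenotype graph enter as ``fit`` keyword arguments because they are
data, not hyperparameters.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_array

from .inference import (association_calls, decide_annotations, decide_graph,
                        pleiotropy_calls)
from .mrf import Hyperparameters
from .preprocess import AnnotationMatrix, PriorGraph, ZMatrix
from .sampler import MCMCConfig, run_mcmc

__all__ = ["PleiotropyMRF"]


class PleiotropyMRF(BaseEstimator):
    """Bayesian multi-trait association model with a latent phenotype graph.

    Parameters mirror :class:`~pleiograph.mrf.Hyperparameters` and
    :class:`~pleiograph.sampler.MCMCConfig`; see those classes for meanings
    and defaults.

    Attributes (after ``fit``)
    --------------------------
    summary_ : PosteriorSummary
        Full posterior accumulators and thinned traces.
    edge_prob_, beta_pos_prob_, beta_mean_ : ndarray (n, n)
        Posterior edge probabilities, sign probabilities, and coefficient
        means conditional on inclusion.
    alpha_mean_, mu_mean_, sigma_mean_ : ndarray (n,)
        Posterior means of the MRF intercepts and emission parameters.
    gamma_pos_prob_, gamma_mean_ : ndarray (n, M)
        Annotation-relevance probabilities and conditional coefficient means.
    marginal_prob_ : ndarray (T, n)
        Per-SNP posterior association probabilities.
    graph_ : ndarray (n, n)
        The decided phenotype graph at the default thresholds.
    """

    def __init__(self, n_iter: int = 10_000, n_burnin: int = 5_000, thin: int = 5,
                 random_state: int = 0, step_alpha: float = 0.1,
                 step_log_beta: float = 0.15, step_log_gamma: float = 0.15,
                 adapt: bool = True, target_accept: float = 0.4,
                 fit_annotation_effects: bool = True, n_max: int = 15,
                 pair_sets: tuple = (),
                 theta_mu: float = 0.0, tau2_mu: float = 1.0e4,
                 a_sigma: float = 0.5, b_sigma: float = 0.5,
                 theta_alpha: float = 0.0, tau2_alpha: float = 1.0e4,
                 a_beta: float = 4.0, b_beta: float = 2.0,
                 a_gamma: float = 4.0, b_gamma: float = 2.0,
                 prior_edge_prob_in: float = 0.8, prior_edge_prob_out: float = 0.2,
                 p_edge_cut: float = 0.5, p_sign_cut: float = 0.95):
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.random_state = random_state
        self.step_alpha = step_alpha
        self.step_log_beta = step_log_beta
        self.step_log_gamma = step_log_gamma
        self.adapt = adapt
        self.target_accept = target_accept
        self.fit_annotation_effects = fit_annotation_effects
        self.n_max = n_max
        self.pair_sets = pair_sets
        self.theta_mu = theta_mu
        self.tau2_mu = tau2_mu
        self.a_sigma = a_sigma
        self.b_sigma = b_sigma
        self.theta_alpha = theta_alpha
        self.tau2_alpha = tau2_alpha
        self.a_beta = a_beta
        self.b_beta = b_beta
        self.a_gamma = a_gamma
        self.b_gamma = b_gamma
        self.prior_edge_prob_in = prior_edge_prob_in
        self.prior_edge_prob_out = prior_edge_prob_out
        self.p_edge_cut = p_edge_cut
        self.p_sign_cut = p_sign_cut

    # -- sklearn plumbing --------------------------------------------------

    def _hyper(self) -> Hyperparameters:
        return Hyperparameters(
            theta_mu=self.theta_mu, tau2_mu=self.tau2_mu,
            a_sigma=self.a_sigma, b_sigma=self.b_sigma,
            theta_alpha=self.theta_alpha, tau2_alpha=self.tau2_alpha,
            a_beta=self.a_beta, b_beta=self.b_beta,
            a_gamma=self.a_gamma, b_gamma=self.b_gamma,
            prior_edge_prob_in=self.prior_edge_prob_in,
            prior_edge_prob_out=self.prior_edge_prob_out,
        )

    def _config(self) -> MCMCConfig:
        return MCMCConfig(
            n_iter=self.n_iter, n_burnin=self.n_burnin, thin=self.thin,
            seed=self.random_state, step_alpha=self.step_alpha,
            step_log_beta=self.step_log_beta, step_log_gamma=self.step_log_gamma,
            adapt=self.adapt, target_accept=self.target_accept,
            fit_annotation_effects=self.fit_annotation_effects,
            n_max=self.n_max, pair_sets=tuple(tuple(s) for s in self.pair_sets),
        )

    # -- API ---------------------------------------------------------------

    def fit(self, X, y=None, *, annotations=None, prior_graph: PriorGraph | None = None):
        """Run the MCMC on transformed statistics ``X`` (T SNPs x n phenotypes).

        ``annotations`` may be an AnnotationMatrix (aligned by SNP id when
        ``X`` is a ZMatrix) or a T x M binary array; ``prior_graph`` shifts
        the Bernoulli edge prior.
        """
        if isinstance(X, ZMatrix):
            data = X
        else:
            data = check_array(X, dtype=float, ensure_min_features=2,
                               ensure_all_finite=True)
        if annotations is not None and not isinstance(annotations, AnnotationMatrix):
            annotations = check_array(annotations, dtype=None, ensure_min_features=0)
        summary = run_mcmc(data, annotations=annotations, prior_graph=prior_graph,
                           hyper=self._hyper(), config=self._config())
        self.summary_ = summary
        self.n_features_in_ = len(summary.phenotype_names)
        self.phenotype_names_ = list(summary.phenotype_names)
        self.annotation_names_ = list(summary.annotation_names)
        self.edge_prob_ = summary.edge_prob
        self.beta_pos_prob_ = summary.beta_pos_prob
        self.beta_mean_ = summary.beta_mean
        self.gamma_pos_prob_ = summary.gamma_pos_prob
        self.gamma_mean_ = summary.gamma_mean
        self.alpha_mean_ = summary.traces["alpha"].mean(axis=0)
        self.mu_mean_ = summary.traces["mu"].mean(axis=0)
        self.sigma_mean_ = summary.traces["sigma"].mean(axis=0)
        self.marginal_prob_ = summary.marginal_prob
        self.pairwise_prob_ = summary.pairwise_prob
        self.acceptance_ = summary.acceptance
        self.graph_ = decide_graph(summary, self.p_edge_cut, self.p_sign_cut).adjacency
        return self

    def _check_fitted(self):
        if not hasattr(self, "summary_"):
            raise NotFittedError("this PleiotropyMRF instance is not fitted yet; "
                                 "call 'fit' first")

    def predict_proba(self, X=None):
        """Posterior association probabilities for the training SNPs (T x n)."""
        self._check_fitted()
        return self.marginal_prob_

    def decide_graph(self, p_edge_cut=None, p_sign_cut=None):
        self._check_fitted()
        return decide_graph(self.summary_,
                            self.p_edge_cut if p_edge_cut is None else p_edge_cut,
                            self.p_sign_cut if p_sign_cut is None else p_sign_cut)

    def decide_annotations(self, p_sign_cut=None):
        self._check_fitted()
        return decide_annotations(
            self.summary_, self.p_sign_cut if p_sign_cut is None else p_sign_cut)

    def association_calls(self, phenotype, levels=(0.05,)):
        self._check_fitted()
        return association_calls(self.summary_, phenotype, levels)

    def pleiotropy_calls(self, phenotype_set, levels=(0.05,)):
        self._check_fitted()
        return pleiotropy_calls(self.summary_, phenotype_set, levels)
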