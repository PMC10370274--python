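"""Exact probability computations for the latent auto-logistic Markov random field.

The model couples, for each SNP ``t``, a binary association vector
``e_t = (e_1t, ..., e_nt)`` over ``n`` phenotypes through an auto-logistic
(pairwise binary) Markov random field,

    p(e_t | alpha, gamma, beta, G, a_t)
        = exp( sum_i (alpha_i + sum_m gamma_im a_mt) e_it
               + sum_{i<j : E(i,j)=1} beta_ij e_it e_jt ) / C(a_t),

where ``a_t`` is the SNP's binary functional-annotation vector, and ties the
latent indicators to the transformed GWAS statistics ``y_it`` through a
lognormal/standard-normal emission mixture,

    y_it | e_it ~ e_it * LN(mu_i, sigma_i^2) + (1 - e_it) * N(0, 1).

The normalizing constant ``C`` is a sum over all 2^n binary vectors and is
evaluated exactly (in log space); it depends on the annotation vector only
through the effective intercepts ``alpha_i + sum_m gamma_im a_mt``, so SNPs
sharing an annotation pattern share one constant.

Everything here is deterministic and side-effect free; the MCMC machinery in
:mod:`pleiograph.sampler` and the generator in :mod:`pleiograph.simulate`
both call into this module, so the generating model and the fitted model are
structurally the same code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

__all__ = [
    "N_MAX_DEFAULT",
    "Hyperparameters",
    "MRFParameters",
    "AnnotationEffects",
    "EmissionParameters",
    "LatentAssociation",
    "ModelState",
    "enumerate_states",
    "emission_logdensity",
    "mrf_log_kernel",
    "log_normalizing_constant",
    "normalizing_constant",
    "conditional_logits",
    "conditional_association_odds",
    "edge_prior_matrix",
    "log_posterior_kernel",
]

#: Largest phenotype count for which the 2^n normalizing constant is enumerated.
N_MAX_DEFAULT = 15

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class Hyperparameters:
    """Top-level prior settings for the hierarchical model.

    Defaults are the weakly informative choices used throughout:
    flat normals for the emission location and MRF intercepts, IG(0.5, 0.5)
    for the emission variance, and Gamma(4, 2) slabs (shape/rate, mean 2)
    for both the edge coefficients ``beta`` and the annotation coefficients
    ``gamma`` so that included coefficients are a priori away from zero.

    ``prior_edge_prob_in`` / ``prior_edge_prob_out`` give the independent
    Bernoulli prior probability of an edge for pairs inside / outside a
    user-supplied prior phenotype graph; with no prior graph every pair gets
    0.5 (see :func:`edge_prior_matrix`).
    """

    theta_mu: float = 0.0
    tau2_mu: float = 1.0e4
    a_sigma: float = 0.5
    b_sigma: float = 0.5
    theta_alpha: float = 0.0
    tau2_alpha: float = 1.0e4
    a_beta: float = 4.0
    b_beta: float = 2.0
    a_gamma: float = 4.0
    b_gamma: float = 2.0
    prior_edge_prob_in: float = 0.8
    prior_edge_prob_out: float = 0.2

    def validate(self) -> None:
        for name in ("tau2_mu", "a_sigma", "b_sigma", "tau2_alpha",
                     "a_beta", "b_beta", "a_gamma", "b_gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"hyperparameter {name!r} must be strictly positive")
        for name in ("prior_edge_prob_in", "prior_edge_prob_out"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"hyperparameter {name!r} must lie in (0, 1)")


@dataclass
class MRFParameters:
    """Auto-logistic field parameters: intercepts, couplings and graph.

    ``beta`` is symmetric nonnegative with zeros off the graph; ``graph`` is
    a symmetric 0/1 adjacency with zero diagonal.  ``beta[i, j] > 0`` is
    allowed only where ``graph[i, j] == 1``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    graph: np.ndarray

    def validate(self) -> None:
        n = self.alpha.shape[0]
        if self.beta.shape != (n, n) or self.graph.shape != (n, n):
            raise ValueError("beta and graph must be n x n for n = len(alpha)")
        if not np.allclose(self.beta, self.beta.T):
            raise ValueError("beta must be symmetric")
        if not np.array_equal(self.graph, self.graph.T):
            raise ValueError("graph must be symmetric")
        if np.any(np.diag(self.graph) != 0):
            raise ValueError("graph must have a zero diagonal")
        if np.any(self.beta < 0):
            raise ValueError("beta entries must be nonnegative")
        if np.any((self.beta > 0) & (self.graph == 0)):
            raise ValueError("beta[i, j] > 0 requires graph[i, j] = 1 (spike-slab support)")
        if np.any((self.graph != 0) & (self.graph != 1)):
            raise ValueError("graph entries must be 0/1")


@dataclass
class AnnotationEffects:
    """Spike-slab annotation coefficients ``gamma`` with inclusion mask ``u``.

    ``gamma[i, m] > 0`` exactly where ``u[i, m] == 1``; ``p_u`` is the shared
    Bernoulli inclusion probability with a Beta(1, 1) hyperprior.
    """

    gamma: np.ndarray
    u: np.ndarray
    p_u: float = 0.5

    def validate(self) -> None:
        if self.gamma.shape != self.u.shape:
            raise ValueError("gamma and u must have identical shapes")
        if np.any(self.gamma < 0):
            raise ValueError("gamma entries must be nonnegative")
        if np.any((self.gamma > 0) != (self.u == 1)):
            raise ValueError("gamma[i, m] > 0 must hold exactly where u[i, m] = 1")
        if not 0.0 <= self.p_u <= 1.0:
            raise ValueError("p_u must lie in [0, 1]")


@dataclass
class EmissionParameters:
    """Lognormal emission parameters (location ``mu``, variance ``sigma2``)."""

    mu: np.ndarray
    sigma2: np.ndarray

    def validate(self) -> None:
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 must have identical shapes")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be strictly positive")


@dataclass
class LatentAssociation:
    """Binary T x n matrix of latent association indicators."""

    e: np.ndarray

    def validate(self, y: np.ndarray | None = None) -> None:
        if np.any((self.e != 0) & (self.e != 1)):
            raise ValueError("e entries must be 0/1")
        if y is not None:
            if y.shape != self.e.shape:
                raise ValueError("e must have the same shape as y")
            if np.any((self.e == 1) & (y <= 0)):
                raise ValueError("e_it = 1 requires y_it > 0 (lognormal support)")


@dataclass
class ModelState:
    """One full MCMC state of the hierarchical model."""

    latent: LatentAssociation
    mrf: MRFParameters
    annot: AnnotationEffects
    emission: EmissionParameters

    def validate(self, y: np.ndarray | None = None) -> None:
        self.latent.validate(y)
        self.mrf.validate()
        self.annot.validate()
        self.emission.validate()

    def copy(self) -> "ModelState":
        return ModelState(
            latent=LatentAssociation(self.latent.e.copy()),
            mrf=MRFParameters(self.mrf.alpha.copy(), self.mrf.beta.copy(),
                              self.mrf.graph.copy()),
            annot=AnnotationEffects(self.annot.gamma.copy(), self.annot.u.copy(),
                                    self.annot.p_u),
            emission=EmissionParameters(self.emission.mu.copy(),
                                        self.emission.sigma2.copy()),
        )


# ---------------------------------------------------------------------------
# Field computations
# ---------------------------------------------------------------------------


def enumerate_states(n: int, n_max: int = N_MAX_DEFAULT) -> np.ndarray:
    """All 2^n binary vectors as a float (2^n, n) array (counting order)."""
    if n > n_max:
        raise ValueError(
            f"exact enumeration over 2^n states is limited to n <= {n_max}; got n = {n}. "
            "Raise n_max explicitly if you really want this."
        )
    bits = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]
    return (bits & 1).astype(float)


def emission_logdensity(y, associated, mu: float, sigma2: float):
    """Log emission density of transformed statistics under one phenotype.

    Associated entries follow LN(mu, sigma2) (``-inf`` for y <= 0),
    null entries follow the standard normal.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be strictly positive")
    y = np.asarray(y, dtype=float)
    associated = np.asarray(associated, dtype=bool)
    out = np.where(associated, -np.inf, norm.logpdf(y))
    pos = associated & (y > 0)
    if np.any(pos):
        ly = np.log(y, where=y > 0, out=np.zeros_like(y))
        ln_pdf = -ly - 0.5 * np.log(sigma2) - _LOG_SQRT_2PI - (ly - mu) ** 2 / (2.0 * sigma2)
        out = np.where(pos, ln_pdf, out)
    return out if out.ndim else float(out)


def _effective_alpha(alpha: np.ndarray, gamma: np.ndarray | None,
                     a_vec: np.ndarray | None) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if gamma is None or a_vec is None or np.size(a_vec) == 0:
        return alpha
    gamma = np.asarray(gamma, dtype=float)
    a_vec = np.asarray(a_vec, dtype=float)
    if gamma.shape != (alpha.shape[0], a_vec.shape[-1]):
        raise ValueError(
            f"gamma must be (n, M) = {(alpha.shape[0], a_vec.shape[-1])}, got {gamma.shape}"
        )
    return alpha + a_vec @ gamma.T


def mrf_log_kernel(e_vec, alpha, beta, gamma=None, a_vec=None) -> float:
    """Log numerator of the auto-logistic mass function for one SNP.

    Returns ``sum_i (alpha_i + sum_m gamma_im a_m) e_i + sum_{i<j} beta_ij e_i e_j``.
    With ``gamma``/``a_vec`` omitted this is the annotation-free field.
    """
    e_vec = np.asarray(e_vec, dtype=float)
    alpha_eff = _effective_alpha(alpha, gamma, a_vec)
    beta = np.asarray(beta, dtype=float)
    if e_vec.shape[-1] != alpha_eff.shape[-1] or beta.shape != (e_vec.shape[-1],) * 2:
        raise ValueError("inconsistent dimensions between e, alpha and beta")
    return float(e_vec @ alpha_eff + 0.5 * e_vec @ beta @ e_vec)


def log_normalizing_constant(alpha_eff, beta, graph=None,
                             n_max: int = N_MAX_DEFAULT) -> float | np.ndarray:
    """Log of the exact normalizing constant of the auto-logistic field.

    ``alpha_eff`` may be a single length-n vector of effective intercepts or a
    (P, n) batch (one row per annotation pattern), in which case a length-P
    array of log constants is returned.  The sum over all 2^n states is done
    with the log-sum-exp trick.
    """
    alpha_eff = np.asarray(alpha_eff, dtype=float)
    batched = alpha_eff.ndim == 2
    alpha_eff = np.atleast_2d(alpha_eff)
    n = alpha_eff.shape[1]
    beta = np.asarray(beta, dtype=float)
    if graph is not None:
        beta = beta * (np.asarray(graph) != 0)
    states = enumerate_states(n, n_max=n_max)
    pair_term = 0.5 * np.einsum("si,ij,sj->s", states, beta, states)
    logits = states @ alpha_eff.T + pair_term[:, None]  # (2^n, P)
    out = logsumexp(logits, axis=0)
    return out if batched else float(out[0])


def normalizing_constant(alpha_eff, beta, graph=None,
                         n_max: int = N_MAX_DEFAULT) -> float | np.ndarray:
    """Exact normalizing constant ``C`` (see :func:`log_normalizing_constant`)."""
    return np.exp(log_normalizing_constant(alpha_eff, beta, graph, n_max=n_max))


def conditional_logits(e: np.ndarray, i: int, alpha_eff_col: np.ndarray,
                       beta: np.ndarray) -> np.ndarray:
    """Field part of the full-conditional logit of ``e[:, i]`` for all SNPs.

    ``alpha_eff_col`` is the length-T vector ``alpha_i + sum_m gamma_im a_mt``.
    The pairwise part sums coupling terms over current neighbor states; the
    normalizing constant cancels in the conditional, so none is needed.  The
    simulator and the Gibbs updates both use this routine.
    """
    return alpha_eff_col + e @ beta[:, i]


def conditional_association_odds(i: int, t: int, state: ModelState,
                                 y_it: float, a_t=None) -> float:
    """Posterior full-conditional odds that SNP ``t`` is associated with phenotype ``i``.

    odds = exp(alpha_i + sum_m gamma_im a_mt + sum_{j~i} beta_ij e_jt)
           * LN(y_it; mu_i, sigma_i^2) / N(y_it; 0, 1)

    Returns 0 for ``y_it <= 0`` (outside the lognormal support).  The Gibbs
    probability is ``odds / (1 + odds)``.
    """
    if y_it <= 0:
        return 0.0
    alpha_eff = _effective_alpha(state.mrf.alpha, state.annot.gamma, a_t)
    e_t = state.latent.e[t].astype(float).copy()
    e_t[i] = 0.0  # neighbor sum excludes the site itself (diagonal of beta is 0 anyway)
    field = alpha_eff[i] + float(e_t @ state.mrf.beta[:, i])
    llr = (emission_logdensity(y_it, True, state.emission.mu[i], state.emission.sigma2[i])
           - emission_logdensity(y_it, False, state.emission.mu[i], state.emission.sigma2[i]))
    return float(np.exp(field + llr))


# ---------------------------------------------------------------------------
# Priors and the joint kernel
# ---------------------------------------------------------------------------


def _normal_logpdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * np.log(2.0 * np.pi * var) - (x - mean) ** 2 / (2.0 * var)


def _gamma_logpdf(x, a, b):
    """Gamma(shape a, rate b) log density."""
    x = np.asarray(x, dtype=float)
    return a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(x) - b * x


def _invgamma_logpdf(x, a, b):
    """Inverse-gamma(shape a, rate b) log density: x^-(a+1) exp(-b/x)."""
    x = np.asarray(x, dtype=float)
    return a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x


def edge_prior_matrix(n: int, prior_edges=None, hyper: Hyperparameters | None = None,
                      phenotype_names=None) -> np.ndarray:
    """Bernoulli prior edge probabilities for every phenotype pair.

    With no prior graph every off-diagonal entry is 0.5.  With a prior graph
    (an iterable of index pairs, or of label pairs when ``phenotype_names`` is
    given), pairs in the graph get ``prior_edge_prob_in`` and the rest
    ``prior_edge_prob_out``.
    """
    hyper = hyper or Hyperparameters()
    if prior_edges is None:
        pi = np.full((n, n), 0.5)
    else:
        pi = np.full((n, n), hyper.prior_edge_prob_out)
        for i, j in prior_edges:
            if phenotype_names is not None:
                names = list(phenotype_names)
                i, j = names.index(i), names.index(j)
            if i == j:
                raise ValueError("prior graph must not contain self-edges")
            pi[i, j] = pi[j, i] = hyper.prior_edge_prob_in
    np.fill_diagonal(pi, 0.0)
    return pi


def annotation_patterns(annotations: np.ndarray):
    """Group SNPs by identical annotation rows.

    Returns ``(patterns, index, counts)`` with ``patterns`` a (P, M) array of
    the distinct rows, ``index`` mapping each SNP to its pattern, and
    ``counts`` the SNPs per pattern.  With M = 0 there is a single empty
    pattern covering all SNPs.
    """
    annotations = np.asarray(annotations)
    T = annotations.shape[0]
    if annotations.ndim != 2:
        raise ValueError("annotations must be a T x M matrix")
    if annotations.shape[1] == 0:
        return (np.zeros((1, 0)), np.zeros(T, dtype=np.intp),
                np.array([T], dtype=np.intp))
    patterns, index, counts = np.unique(annotations, axis=0,
                                        return_inverse=True, return_counts=True)
    return patterns.astype(float), index.astype(np.intp), counts


def log_posterior_kernel(y: np.ndarray, annotations: np.ndarray | None,
                         state: ModelState, hyper: Hyperparameters | None = None,
                         edge_prior: np.ndarray | None = None,
                         n_max: int = N_MAX_DEFAULT) -> float:
    """Log of the unnormalized joint posterior at one state.

    Sum of the emission log likelihood, the MRF log mass (kernel minus the
    per-pattern log normalizing constants), and all prior log densities
    (mu, sigma2, alpha, spike-slab beta | G, Bernoulli G, spike-slab
    gamma | u, Bernoulli u | p_u, flat Beta(1,1) on p_u).  Raises on any
    violated state invariant; with T = 0 only the priors remain.
    """
    hyper = hyper or Hyperparameters()
    hyper.validate()
    y = np.asarray(y, dtype=float)
    T, n = y.shape
    if annotations is None:
        annotations = np.zeros((T, 0))
    annotations = np.asarray(annotations, dtype=float)
    state.validate(y)
    e = state.latent.e.astype(float)
    alpha, beta, graph = state.mrf.alpha, state.mrf.beta, state.mrf.graph
    gamma, u, p_u = state.annot.gamma, state.annot.u, state.annot.p_u
    mu, sigma2 = state.emission.mu, state.emission.sigma2
    if edge_prior is None:
        edge_prior = edge_prior_matrix(n)

    total = 0.0
    # Emission likelihood.
    for i in range(n):
        total += float(np.sum(emission_logdensity(y[:, i], e[:, i] == 1,
                                                  mu[i], sigma2[i])))
    # MRF mass: singleton + pairwise kernel, minus pattern-grouped constants.
    alpha_eff = alpha[None, :] + annotations @ gamma.T  # (T, n)
    total += float(np.sum(alpha_eff * e))
    total += 0.5 * float(np.einsum("ti,ij,tj->", e, beta, e))
    patterns, _, counts = annotation_patterns(annotations)
    pat_alpha_eff = alpha[None, :] + patterns @ gamma.T
    logC = np.atleast_1d(log_normalizing_constant(pat_alpha_eff, beta, n_max=n_max))
    total -= float(counts @ logC)
    # Priors.
    total += float(np.sum(_normal_logpdf(mu, hyper.theta_mu, hyper.tau2_mu)))
    total += float(np.sum(_invgamma_logpdf(sigma2, hyper.a_sigma, hyper.b_sigma)))
    total += float(np.sum(_normal_logpdf(alpha, hyper.theta_alpha, hyper.tau2_alpha)))
    iu, ju = np.triu_indices(n, k=1)
    present = graph[iu, ju] == 1
    total += float(np.sum(np.log(edge_prior[iu, ju][present])))
    total += float(np.sum(np.log1p(-edge_prior[iu, ju][~present])))
    if np.any(present):
        total += float(np.sum(_gamma_logpdf(beta[iu, ju][present],
                                            hyper.a_beta, hyper.b_beta)))
    if gamma.size:
        inc = u == 1
        n_inc = int(np.sum(inc))
        if n_inc:
            total += float(np.sum(_gamma_logpdf(gamma[inc], hyper.a_gamma, hyper.b_gamma)))
        if p_u in (0.0, 1.0) and (n_inc != (u.size if p_u == 1.0 else 0)):
            return -np.inf
        if 0.0 < p_u < 1.0:
            total += n_inc * np.log(p_u) + (u.size - n_inc) * np.log1p(-p_u)
    return total
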