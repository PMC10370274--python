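"""Metropolis-within-Gibbs sampler for the annotation-aware MRF model.

One sweep updates, in order: the latent association indicators ``e`` (exact
Gibbs, vectorized over SNPs), the emission parameters ``mu, sigma2``
(conjugate), the MRF intercepts ``alpha`` (random-walk Metropolis), the edge
coefficients and graph ``(beta, G)`` (a 50/50 mixture of within-model
log-scale random walks and birth/death moves whose birth proposal is the
Gamma slab prior, so the proposal density cancels the slab in the acceptance
ratio), the annotation coefficients ``(gamma, u)`` (same scheme with
Bernoulli(p_u) inclusion odds), and ``p_u`` (conjugate Beta).

The exact per-pattern normalizing constants of the field are re-evaluated for
every Metropolis proposal that touches ``alpha``, ``beta`` or ``gamma``; SNPs
are grouped by distinct annotation pattern so each constant is computed once
per proposal regardless of T.

Step sizes adapt toward a target acceptance rate during burn-in only and are
frozen afterwards, preserving detailed balance for the retained samples.  A
single seeded generator drives the whole chain: identical seed and inputs
give a bitwise-identical result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .mrf import (
    N_MAX_DEFAULT,
    AnnotationEffects,
    EmissionParameters,
    Hyperparameters,
    LatentAssociation,
    ModelState,
    MRFParameters,
    annotation_patterns,
    edge_prior_matrix,
    enumerate_states,
)
from .preprocess import AnnotationMatrix, PriorGraph, ZMatrix, align_annotations

__all__ = ["MCMCConfig", "PosteriorSummary", "GibbsSampler", "run_mcmc"]

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class MCMCConfig:
    """Chain length, proposal scales and reproducibility settings."""

    n_iter: int = 10_000
    n_burnin: int = 5_000
    thin: int = 5
    seed: int = 0
    step_alpha: float = 0.1
    step_log_beta: float = 0.15
    step_log_gamma: float = 0.15
    adapt: bool = True
    target_accept: float = 0.4
    adapt_interval: int = 50
    fit_annotation_effects: bool = True
    n_max: int = N_MAX_DEFAULT
    pair_sets: tuple = ()  # extra phenotype index sets (size > 2) to accumulate
    check_invariants: bool = False

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be positive")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must satisfy 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be a positive integer")
        for name in ("step_alpha", "step_log_beta", "step_log_gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class PosteriorSummary:
    """Post-burn-in posterior accumulators and thinned traces.

    Probabilities are running means over every retained sweep; traces are the
    thinned parameter chains.  ``beta_mean`` and ``gamma_mean`` are posterior
    means conditional on inclusion (NaN where a coefficient was never
    included).  ``pairwise_prob[:, k]`` is p(e_i = e_j = 1 | Y) for
    ``pair_list[k]``; joint probabilities for larger requested sets are in
    ``set_prob``.
    """

    phenotype_names: list
    annotation_names: list
    snp_ids: list
    pair_list: list
    edge_prob: np.ndarray        # (n, n) p(E(i,j) | Y)
    beta_pos_prob: np.ndarray    # (n, n) p(beta_ij > 0 | Y)
    beta_mean: np.ndarray        # (n, n) E[beta_ij | beta_ij > 0, Y]
    gamma_pos_prob: np.ndarray   # (n, M) p(gamma_im > 0 | Y)
    gamma_mean: np.ndarray       # (n, M) E[gamma_im | gamma_im > 0, Y]
    marginal_prob: np.ndarray    # (T, n) p(e_it = 1 | Y)
    pairwise_prob: np.ndarray    # (T, n_pairs)
    set_prob: dict               # {tuple(indices): (T,) array}
    traces: dict                 # name -> (n_samples, ...) arrays
    acceptance: dict             # block -> acceptance rate(s)
    n_kept: int
    config: MCMCConfig
    hyper: Hyperparameters

    def _trace_samples(self, name, index, conditional):
        tr = self.traces[name]
        if index is not None and index != ():
            tr = tr[(slice(None),) + tuple(np.atleast_1d(index))]
        x = np.asarray(tr, dtype=float).ravel()
        return x[x > 0] if conditional else x

    def credible_interval(self, name: str, index=(), level: float = 0.95,
                          conditional: bool = False):
        """Equal-tailed posterior interval from the thinned trace.

        With ``conditional=True`` (spike-slab parameters) only strictly
        positive samples enter, i.e. the interval is conditional on inclusion.
        """
        x = self._trace_samples(name, index, conditional)
        if x.size == 0:
            return (np.nan, np.nan)
        lo = (1.0 - level) / 2.0
        return (float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo)))

    def posterior_mean(self, name: str, index=(), conditional: bool = False) -> float:
        x = self._trace_samples(name, index, conditional)
        return float(np.mean(x)) if x.size else float("nan")

    def pair_index(self, i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        return self.pair_list.index(key)


class GibbsSampler:
    """Stateful sampler bound to one dataset.

    Parameters are arrays: ``y`` (T x n transformed statistics),
    ``annotations`` (T x M binary, possibly M = 0) and an (n, n) matrix of
    prior edge probabilities.
    """

    def __init__(self, y: np.ndarray, annotations: np.ndarray | None,
                 hyper: Hyperparameters | None = None,
                 config: MCMCConfig | None = None,
                 edge_prior: np.ndarray | None = None,
                 phenotype_names=None, annotation_names=None, snp_ids=None):
        self.hyper = hyper or Hyperparameters()
        self.hyper.validate()
        self.config = config or MCMCConfig()
        self.config.validate()
        y = np.asarray(y, dtype=float)
        if y.ndim != 2:
            raise ValueError("y must be a T x n matrix")
        self.T, self.n = y.shape
        if self.n > self.config.n_max:
            raise ValueError(
                f"exact normalizing-constant enumeration is limited to "
                f"n <= {self.config.n_max} phenotypes; got n = {self.n}"
            )
        self.y = y
        if annotations is None or (hasattr(annotations, "shape")
                                   and annotations.shape[1] == 0):
            annotations = np.zeros((self.T, 0), dtype=np.int8)
        A = np.asarray(annotations)
        if A.shape[0] != self.T:
            raise ValueError("annotations must have one row per SNP")
        if A.size and not np.isin(A, (0, 1)).all():
            raise ValueError("annotations must be binary 0/1")
        # With annotation effects disabled gamma stays 0 and the annotation
        # values never enter any density, so collapse to one empty pattern;
        # this makes the chain bitwise-identical to an M = 0 fit.
        if not self.config.fit_annotation_effects:
            A = np.zeros((self.T, 0), dtype=np.int8)
        self.A = A.astype(np.int8)
        self.M = self.A.shape[1]
        self.patterns, self.pat_idx, self.pat_counts = annotation_patterns(self.A)
        self.phenotype_names = (list(phenotype_names) if phenotype_names is not None
                                else [f"P{i + 1}" for i in range(self.n)])
        self.annotation_names = (list(annotation_names) if annotation_names is not None
                                 else [f"A{m + 1}" for m in range(self.M)])
        self.snp_ids = (list(snp_ids) if snp_ids is not None
                        else [f"snp{t + 1}" for t in range(self.T)])
        self.edge_prior = (edge_prior if edge_prior is not None
                           else edge_prior_matrix(self.n))
        with np.errstate(divide="ignore"):
            self.edge_log_odds = np.log(self.edge_prior) - np.log1p(-self.edge_prior)

        # Precomputed data quantities.
        self.pos = y > 0
        self.logy = np.where(self.pos, np.log(np.where(self.pos, y, 1.0)), 0.0)
        self.log_null = norm.logpdf(y)
        self.iu, self.ju = np.triu_indices(self.n, k=1)
        self.pair_list = list(zip(self.iu.tolist(), self.ju.tolist()))
        self.S = enumerate_states(self.n, n_max=self.config.n_max)
        self.SS = self.S[:, self.iu] * self.S[:, self.ju]  # (2^n, n_pairs)
        for s in self.config.pair_sets:
            s = tuple(s)
            if len(s) < 3 or len(set(s)) != len(s) or max(s) >= self.n or min(s) < 0:
                raise ValueError(f"pair_sets entries must be distinct index sets "
                                 f"of size > 2 within range; got {s}")
        self.extra_sets = [tuple(sorted(s)) for s in self.config.pair_sets]

        self.rng = np.random.default_rng(self.config.seed)
        self._init_state()
        self._init_steps()
        self._init_accumulators()

    # -- initialization ----------------------------------------------------

    def _init_state(self) -> None:
        e = ((self.y > 2.0) & self.pos).astype(float)
        mu = np.empty(self.n)
        sigma2 = np.empty(self.n)
        for i in range(self.n):
            z = self.logy[e[:, i] > 0.5, i]
            mu[i] = float(np.mean(z)) if z.size > 3 else 1.0
            sigma2[i] = float(np.var(z) + 0.01) if z.size > 3 else 0.25
        frac = (np.clip(e.mean(axis=0), 1e-4, 0.5) if self.T
                else np.full(self.n, 1e-4))  # T = 0: prior-only chain
        self.e = e
        self.alpha = np.log(frac / (1.0 - frac))
        self.beta = np.zeros((self.n, self.n))
        self.graph = np.zeros((self.n, self.n), dtype=np.int8)
        self.gamma = np.zeros((self.n, self.M))
        self.u = np.zeros((self.n, self.M), dtype=np.int8)
        self.p_u = 0.5
        self.mu = mu
        self.sigma2 = sigma2
        self._refresh_llr()

    def _init_steps(self) -> None:
        c = self.config
        self.step_alpha = np.full(self.n, c.step_alpha)
        self.step_beta = np.full(len(self.pair_list), c.step_log_beta)
        self.step_gamma = np.full((self.n, self.M), c.step_log_gamma)
        self.acc = {k: np.zeros(2) for k in
                    ("alpha", "beta_within", "beta_jump", "gamma_within", "gamma_jump")}
        self._adapt_acc = {
            "alpha": np.zeros((self.n, 2)),
            "beta": np.zeros((len(self.pair_list), 2)),
            "gamma": np.zeros((self.n, self.M, 2)),
        }

    def _init_accumulators(self) -> None:
        n, M, T = self.n, self.M, self.T
        npair = len(self.pair_list)
        self.n_kept = 0
        self.sum_e = np.zeros((T, n))
        self.sum_pair = np.zeros((T, npair))
        self.sum_set = {s: np.zeros(T) for s in self.extra_sets}
        self.sum_edge = np.zeros(npair)
        self.sum_beta = np.zeros(npair)
        self.sum_u = np.zeros((n, M))
        self.sum_gamma = np.zeros((n, M))
        n_samples = (self.config.n_iter - self.config.n_burnin
                     + self.config.thin - 1) // self.config.thin
        self.trace = {
            "alpha": np.empty((n_samples, n)),
            "beta": np.empty((n_samples, npair)),
            "gamma": np.empty((n_samples, n, M)),
            "mu": np.empty((n_samples, n)),
            "sigma": np.empty((n_samples, n)),
            "p_u": np.empty(n_samples),
            "n_assoc": np.empty((n_samples, n)),
        }
        self._n_stored = 0

    # -- field helpers -----------------------------------------------------

    def _pat_gamma(self, gamma=None) -> np.ndarray:
        g = self.gamma if gamma is None else gamma
        return self.patterns @ g.T  # (P, n)

    def _logC_vec(self, alpha=None, beta=None, pat_gamma=None) -> np.ndarray:
        """Per-annotation-pattern log normalizing constants, shape (P,)."""
        alpha = self.alpha if alpha is None else alpha
        beta = self.beta if beta is None else beta
        pg = self._pat_gamma() if pat_gamma is None else pat_gamma
        q = self.SS @ beta[self.iu, self.ju]
        L = self.S @ (alpha[None, :] + pg).T + q[:, None]
        m = L.max(axis=0)
        return m + np.log(np.exp(L - m).sum(axis=0))

    def _refresh_llr(self) -> None:
        """Emission log-likelihood ratio LN/N per entry; -inf where y <= 0."""
        s2 = self.sigma2[None, :]
        log_ln = (-self.logy - 0.5 * np.log(s2) - _LOG_SQRT_2PI
                  - (self.logy - self.mu[None, :]) ** 2 / (2.0 * s2))
        self.llr = np.where(self.pos, log_ln - self.log_null, -np.inf)

    # -- update blocks -----------------------------------------------------

    def update_e(self) -> None:
        """Exact Gibbs resampling of every latent indicator.

        Phenotypes are visited sequentially; all SNPs are independent given
        the parameters so each column update is vectorized over SNPs.
        """
        Aterm = self._pat_gamma()[self.pat_idx]  # (T, n)
        U = self.rng.random((self.T, self.n))
        for i in range(self.n):
            logit = self.alpha[i] + Aterm[:, i] + self.e @ self.beta[:, i] \
                + self.llr[:, i]
            self.e[:, i] = (U[:, i] < expit(logit)).astype(float)

    def update_emission(self) -> None:
        """Conjugate draws of sigma2 (inverse-gamma) then mu (normal) per phenotype."""
        h = self.hyper
        for i in range(self.n):
            z = self.logy[self.e[:, i] > 0.5, i]
            k = z.size
            shape = h.a_sigma + 0.5 * k
            rate = h.b_sigma + 0.5 * float(np.sum((z - self.mu[i]) ** 2))
            self.sigma2[i] = rate / self.rng.gamma(shape)
            v = 1.0 / (1.0 / h.tau2_mu + k / self.sigma2[i])
            m = v * (h.theta_mu / h.tau2_mu + float(np.sum(z)) / self.sigma2[i])
            self.mu[i] = m + np.sqrt(v) * self.rng.standard_normal()
        self._refresh_llr()

    def update_alpha(self) -> None:
        """Random-walk Metropolis on each MRF intercept."""
        h = self.hyper
        n_assoc = self.e.sum(axis=0)
        pg = self._pat_gamma()
        logC = self._logC_vec(pat_gamma=pg)
        for i in range(self.n):
            prop = self.alpha.copy()
            prop[i] += self.step_alpha[i] * self.rng.standard_normal()
            logC_new = self._logC_vec(alpha=prop, pat_gamma=pg)
            dlp = ((prop[i] - self.alpha[i]) * n_assoc[i]
                   - float(self.pat_counts @ (logC_new - logC))
                   - ((prop[i] - h.theta_alpha) ** 2
                      - (self.alpha[i] - h.theta_alpha) ** 2) / (2.0 * h.tau2_alpha))
            acc = np.log(self.rng.random()) < dlp
            self._adapt_acc["alpha"][i] += (acc, 1)
            self.acc["alpha"] += (acc, 1)
            if acc:
                self.alpha = prop
                logC = logC_new

    def update_beta_graph(self) -> None:
        """Spike-slab update of every edge: within-model walk or birth/death.

        A fair coin picks the move type per pair.  Birth proposes the new
        coefficient from the Gamma slab so the acceptance ratio reduces to
        the likelihood change times the prior edge odds; death is the
        reverse.  Within-model moves are Gaussian walks on log beta.
        """
        h = self.hyper
        pg = self._pat_gamma()
        logC = self._logC_vec(pat_gamma=pg)
        Spair = self.e.T @ self.e
        for k, (i, j) in enumerate(self.pair_list):
            within = self.rng.random() < 0.5
            if within and self.graph[i, j] == 0:
                continue  # nothing to move within the spike
            beta_try = self.beta.copy()
            if within:
                b_old = self.beta[i, j]
                b_new = b_old * np.exp(self.step_beta[k] * self.rng.standard_normal())
                beta_try[i, j] = beta_try[j, i] = b_new
                logC_new = self._logC_vec(beta=beta_try, pat_gamma=pg)
                dlp = ((b_new - b_old) * Spair[i, j]
                       - float(self.pat_counts @ (logC_new - logC))
                       + h.a_beta * (np.log(b_new) - np.log(b_old))
                       - h.b_beta * (b_new - b_old))  # slab ratio + log-scale Jacobian
                bucket = "beta_within"
            elif self.graph[i, j] == 0:  # birth
                b_new = self.rng.gamma(h.a_beta, 1.0 / h.b_beta)
                beta_try[i, j] = beta_try[j, i] = b_new
                logC_new = self._logC_vec(beta=beta_try, pat_gamma=pg)
                dlp = (b_new * Spair[i, j]
                       - float(self.pat_counts @ (logC_new - logC))
                       + self.edge_log_odds[i, j])
                bucket = "beta_jump"
            else:  # death
                b_old = self.beta[i, j]
                beta_try[i, j] = beta_try[j, i] = 0.0
                logC_new = self._logC_vec(beta=beta_try, pat_gamma=pg)
                dlp = (-b_old * Spair[i, j]
                       - float(self.pat_counts @ (logC_new - logC))
                       - self.edge_log_odds[i, j])
                bucket = "beta_jump"
            acc = np.log(self.rng.random()) < dlp
            if bucket == "beta_within":
                self._adapt_acc["beta"][k] += (acc, 1)
            self.acc[bucket] += (acc, 1)
            if acc:
                self.beta = beta_try
                self.graph[i, j] = self.graph[j, i] = np.int8(self.beta[i, j] > 0)
                logC = logC_new

    def update_gamma_u(self) -> None:
        """Spike-slab update of every annotation coefficient, like the edges.

        Inclusion odds come from Bernoulli(p_u); within-model moves are
        log-scale walks keeping gamma > 0.
        """
        if self.M == 0:
            return
        h = self.hyper
        lo = np.log(self.p_u) - np.log1p(-self.p_u)
        AE = (self.A.T.astype(float) @ self.e)  # (M, n): sum_t a_mt e_it
        pg = self._pat_gamma()
        logC = self._logC_vec(pat_gamma=pg)
        for i in range(self.n):
            for m in range(self.M):
                within = self.rng.random() < 0.5
                if within and self.u[i, m] == 0:
                    continue
                gamma_try = self.gamma.copy()
                if within:
                    g_old = self.gamma[i, m]
                    g_new = g_old * np.exp(self.step_gamma[i, m]
                                           * self.rng.standard_normal())
                    gamma_try[i, m] = g_new
                    dlp_extra = (h.a_gamma * (np.log(g_new) - np.log(g_old))
                                 - h.b_gamma * (g_new - g_old))
                    delta = g_new - g_old
                    bucket = "gamma_within"
                elif self.u[i, m] == 0:  # birth
                    g_new = self.rng.gamma(h.a_gamma, 1.0 / h.b_gamma)
                    gamma_try[i, m] = g_new
                    dlp_extra = lo
                    delta = g_new
                    bucket = "gamma_jump"
                else:  # death
                    gamma_try[i, m] = 0.0
                    dlp_extra = -lo
                    delta = -self.gamma[i, m]
                    bucket = "gamma_jump"
                pg_try = pg.copy()
                pg_try[:, i] += (gamma_try[i, m] - self.gamma[i, m]) * self.patterns[:, m]
                logC_new = self._logC_vec(pat_gamma=pg_try)
                dlp = (delta * AE[m, i]
                       - float(self.pat_counts @ (logC_new - logC))
                       + dlp_extra)
                acc = np.log(self.rng.random()) < dlp
                if bucket == "gamma_within":
                    self._adapt_acc["gamma"][i, m] += (acc, 1)
                self.acc[bucket] += (acc, 1)
                if acc:
                    self.gamma = gamma_try
                    self.u[i, m] = np.int8(self.gamma[i, m] > 0)
                    pg, logC = pg_try, logC_new

    def update_pu(self) -> None:
        """Conjugate Beta(1 + sum u, 1 + nM - sum u) draw."""
        if self.M == 0:
            return
        s = float(self.u.sum())
        self.p_u = self.rng.beta(1.0 + s, 1.0 + self.n * self.M - s)

    # -- driver ------------------------------------------------------------

    def _adapt_steps(self) -> None:
        for name, steps in (("alpha", self.step_alpha), ("beta", self.step_beta),
                            ("gamma", self.step_gamma)):
            acc = self._adapt_acc[name]
            attempted = acc[..., 1] > 0
            rate = np.divide(acc[..., 0], acc[..., 1],
                             out=np.full(acc[..., 1].shape, self.config.target_accept),
                             where=attempted)
            steps *= np.exp(rate - self.config.target_accept)
            np.clip(steps, 1e-3, 10.0, out=steps)
            acc[...] = 0.0

    def _accumulate(self) -> None:
        self.n_kept += 1
        self.sum_e += self.e
        self.sum_pair += self.e[:, self.iu] * self.e[:, self.ju]
        for s, acc in self.sum_set.items():
            prod = self.e[:, s[0]].copy()
            for idx in s[1:]:
                prod *= self.e[:, idx]
            acc += prod
        bu = self.beta[self.iu, self.ju]
        self.sum_edge += self.graph[self.iu, self.ju]
        self.sum_beta += bu
        self.sum_u += self.u
        self.sum_gamma += self.gamma

    def _store_trace(self) -> None:
        t = self._n_stored
        self.trace["alpha"][t] = self.alpha
        self.trace["beta"][t] = self.beta[self.iu, self.ju]
        self.trace["gamma"][t] = self.gamma
        self.trace["mu"][t] = self.mu
        self.trace["sigma"][t] = np.sqrt(self.sigma2)
        self.trace["p_u"][t] = self.p_u
        self.trace["n_assoc"][t] = self.e.sum(axis=0)
        self._n_stored += 1

    def sweep(self) -> None:
        self.update_e()
        self.update_emission()
        self.update_alpha()
        self.update_beta_graph()
        if self.config.fit_annotation_effects:
            self.update_gamma_u()
            self.update_pu()

    def state(self) -> ModelState:
        return ModelState(
            latent=LatentAssociation(self.e.astype(np.int8)),
            mrf=MRFParameters(self.alpha.copy(), self.beta.copy(), self.graph.copy()),
            annot=AnnotationEffects(self.gamma.copy(), self.u.copy(), self.p_u),
            emission=EmissionParameters(self.mu.copy(), self.sigma2.copy()),
        )

    def run(self) -> PosteriorSummary:
        c = self.config
        for it in range(c.n_iter):
            self.sweep()
            if c.check_invariants:
                self.state().validate(self.y)
            if c.adapt and it < c.n_burnin and (it + 1) % c.adapt_interval == 0:
                self._adapt_steps()
            if it >= c.n_burnin:
                self._accumulate()
                if (it - c.n_burnin) % c.thin == 0:
                    self._store_trace()
            if (it + 1) % 1000 == 0:
                logger.info("sweep %d/%d: %d edges, mean assoc %.4f",
                            it + 1, c.n_iter, int(self.graph.sum() // 2),
                            float(self.e.mean()) if self.T else 0.0)
        return self._summary()

    def _summary(self) -> PosteriorSummary:
        nk = max(self.n_kept, 1)
        npair = len(self.pair_list)
        edge_prob = np.zeros((self.n, self.n))
        beta_pos = np.zeros((self.n, self.n))
        beta_mean = np.full((self.n, self.n), np.nan)
        bmean_pairs = np.where(self.sum_edge > 0,
                               self.sum_beta / np.maximum(self.sum_edge, 1), np.nan)
        edge_prob[self.iu, self.ju] = self.sum_edge / nk
        edge_prob += edge_prob.T
        beta_pos[self.iu, self.ju] = self.sum_edge / nk  # beta > 0 iff edge present
        beta_pos += beta_pos.T
        beta_mean[self.iu, self.ju] = bmean_pairs
        beta_mean[self.ju, self.iu] = bmean_pairs
        with np.errstate(invalid="ignore"):
            gamma_mean = np.where(self.sum_u > 0,
                                  self.sum_gamma / np.maximum(self.sum_u, 1), np.nan)
        acceptance = {k: (v[0] / v[1] if v[1] else np.nan)
                      for k, v in self.acc.items()}
        traces = {k: v[:self._n_stored] for k, v in self.trace.items()}
        return PosteriorSummary(
            phenotype_names=self.phenotype_names,
            annotation_names=self.annotation_names,
            snp_ids=self.snp_ids,
            pair_list=self.pair_list,
            edge_prob=edge_prob,
            beta_pos_prob=beta_pos,
            beta_mean=beta_mean,
            gamma_pos_prob=self.sum_u / nk,
            gamma_mean=gamma_mean,
            marginal_prob=self.sum_e / nk,
            pairwise_prob=self.sum_pair / nk,
            set_prob={s: acc / nk for s, acc in self.sum_set.items()},
            traces=traces,
            acceptance=acceptance,
            n_kept=self.n_kept,
            config=self.config,
            hyper=self.hyper,
        )


def run_mcmc(data, annotations=None, prior_graph: PriorGraph | None = None,
             hyper: Hyperparameters | None = None,
             config: MCMCConfig | None = None) -> PosteriorSummary:
    """Fit the model and return posterior summaries.

    ``data`` is a :class:`~pleiograph.preprocess.ZMatrix` or a T x n array;
    ``annotations`` a :class:`~pleiograph.preprocess.AnnotationMatrix`
    (aligned to the data by SNP identifier) or a T x M binary array, or None
    for the annotation-free model.  A ``prior_graph`` shifts the Bernoulli
    prior edge probabilities; without one every pair gets 0.5.
    """
    hyper = hyper or Hyperparameters()
    phen_names = snp_ids = None
    if isinstance(data, ZMatrix):
        phen_names, snp_ids = data.phenotype_names, data.snp_ids
        y = data.y
    else:
        y = np.asarray(data, dtype=float)
    ann_names = None
    if isinstance(annotations, AnnotationMatrix):
        if isinstance(data, ZMatrix):
            annotations = align_annotations(data, annotations)
        ann_names = annotations.annotation_names
        A = annotations.a
    else:
        A = annotations
    edge_prior = None
    if prior_graph is not None:
        if phen_names is None:
            phen_names = prior_graph.phenotype_names
        edge_prior = edge_prior_matrix(
            y.shape[1], prior_graph.edge_index_pairs(phen_names), hyper)
    sampler = GibbsSampler(y, A, hyper=hyper, config=config, edge_prior=edge_prior,
                           phenotype_names=phen_names, annotation_names=ann_names,
                           snp_ids=snp_ids)
    return sampler.run()
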