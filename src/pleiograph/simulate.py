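"""Synthetic multi-phenotype GWAS summary statistics with MRF structure.

The generator realizes the study conditions used to validate the model:
six phenotypes on a five-edge graph, five binary annotations each marking
10% of SNPs, annotation effects wired to two annotation columns, latent
association indicators drawn by single-site Gibbs from the annotation-aware
auto-logistic field, and observations from the lognormal/standard-normal
emission mixture.  The field and emission code is shared with
:mod:`pleiograph.mrf` and :mod:`pleiograph.sampler`, so generator and model
agree by construction.

Generating values (:func:`default_scenario`):

* ``alpha = (-4.7, -3.0, -5.5, -4.8, -3.6, -2.5)``
* edges {P1-P2, P1-P3, P2-P3, P3-P4, P4-P5} with
  ``beta = (4.0, 1.8, 2.3, 2.5, 5.0)``
* ``gamma_11 = gamma_21 = gamma_31 = 1`` and ``gamma_42 = gamma_52 = gamma_62 = 2``
* ``mu = (1.05, 0.9, 1.0, 1.0, 1.05, 0.95)``,
  ``sigma = (0.4, 0.3, 0.35, 0.3, 0.45, 0.4)``
* T = 200,000 SNPs, M = 5 annotations, 10% annotated per column,
  1,000 Gibbs sweeps for the latent draw.

Phenotype P6 carries an annotation effect but no graph edge: fitting without
annotations misattributes the annotation-induced co-association of P4, P5
and P6 to spurious edges, which is the behavior the robustness checks probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .mrf import conditional_logits
from .preprocess import AnnotationMatrix, SummaryStatsTable, ZMatrix

__all__ = [
    "SimulationScenario",
    "SimulationTruth",
    "default_scenario",
    "generate_annotations",
    "generate_latent",
    "generate_observations",
    "shuffle_annotations",
    "simulate",
]


@dataclass
class SimulationScenario:
    """Generating parameters for one synthetic dataset."""

    n: int
    T: int
    M: int
    edges: list                 # 0-based index pairs
    alpha: np.ndarray           # (n,)
    beta: np.ndarray            # (n, n) symmetric, zero off the edge set
    gamma: np.ndarray           # (n, M) nonnegative
    mu: np.ndarray              # (n,)
    sigma: np.ndarray           # (n,) emission standard deviations
    annotation_proportion: float = 0.1
    gibbs_iters: int = 1_000

    def validate(self) -> None:
        if self.alpha.shape != (self.n,) or self.mu.shape != (self.n,) \
                or self.sigma.shape != (self.n,):
            raise ValueError("alpha, mu, sigma must be length-n vectors")
        if self.beta.shape != (self.n, self.n) or not np.allclose(self.beta, self.beta.T):
            raise ValueError("beta must be a symmetric n x n matrix")
        if self.gamma.shape != (self.n, self.M):
            raise ValueError("gamma must be n x M")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if not 0.0 < self.annotation_proportion < 1.0:
            raise ValueError("annotation_proportion must lie in (0, 1)")
        support = {tuple(sorted(e)) for e in self.edges}
        iu, ju = np.triu_indices(self.n, k=1)
        for i, j in zip(iu, ju):
            if (self.beta[i, j] > 0) != ((int(i), int(j)) in support):
                raise ValueError("beta support must match the edge set")


@dataclass
class SimulationTruth:
    """A realized dataset together with everything needed for evaluation."""

    scenario: SimulationScenario
    e: np.ndarray               # (T, n) latent indicators
    annotations: AnnotationMatrix
    y: ZMatrix
    pvalues: SummaryStatsTable


def default_scenario() -> SimulationScenario:
    """The six-phenotype, five-edge, five-annotation reference scenario."""
    n, T, M = 6, 200_000, 5
    alpha = np.array([-4.7, -3.0, -5.5, -4.8, -3.6, -2.5])
    edges = [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]
    beta_values = [4.0, 1.8, 2.3, 2.5, 5.0]
    beta = np.zeros((n, n))
    for (i, j), b in zip(edges, beta_values):
        beta[i, j] = beta[j, i] = b
    gamma = np.zeros((n, M))
    gamma[0, 0] = gamma[1, 0] = gamma[2, 0] = 1.0
    gamma[3, 1] = gamma[4, 1] = gamma[5, 1] = 2.0
    mu = np.array([1.05, 0.9, 1.0, 1.0, 1.05, 0.95])
    sigma = np.array([0.4, 0.3, 0.35, 0.3, 0.45, 0.4])
    return SimulationScenario(n=n, T=T, M=M, edges=edges, alpha=alpha, beta=beta,
                              gamma=gamma, mu=mu, sigma=sigma)


def generate_annotations(T: int, M: int, proportion: float,
                         rng: np.random.Generator) -> AnnotationMatrix:
    """Binary annotations: each column has exactly round(proportion * T) ones.

    Positions are uniform without replacement, independently per column, so
    column sums are deterministic.
    """
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion must lie in (0, 1)")
    n_ones = int(round(proportion * T))
    a = np.zeros((T, M), dtype=np.int8)
    for m in range(M):
        a[rng.choice(T, size=n_ones, replace=False), m] = 1
    return AnnotationMatrix([f"snp{t + 1}" for t in range(T)],
                            [f"A{m + 1}" for m in range(M)], a)


def generate_latent(scenario: SimulationScenario, annotations,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw latent indicators by single-site Gibbs from the annotation-aware field.

    Starts from all zeros and runs ``scenario.gibbs_iters`` full sweeps; SNPs
    are independent so each phenotype update is vectorized across SNPs.
    """
    scenario.validate()
    A = annotations.a if isinstance(annotations, AnnotationMatrix) else \
        np.asarray(annotations)
    if A.shape != (scenario.T, scenario.M):
        raise ValueError("annotations must be T x M")
    alpha_eff = scenario.alpha[None, :] + A.astype(float) @ scenario.gamma.T  # (T, n)
    e = np.zeros((scenario.T, scenario.n))
    for _ in range(scenario.gibbs_iters):
        U = rng.random((scenario.T, scenario.n))
        for i in range(scenario.n):
            logit = conditional_logits(e, i, alpha_eff[:, i], scenario.beta)
            e[:, i] = (U[:, i] < expit(logit)).astype(float)
    return e.astype(np.int8)


def generate_observations(e: np.ndarray, mu, sigma, rng: np.random.Generator):
    """Emit ``y`` from the mixture and the matching p-values ``p = 1 - Phi(y)``.

    Associated entries are LN(mu_i, sigma_i^2); null entries are N(0, 1).
    Returns ``(y, pvalues)`` arrays.
    """
    e = np.asarray(e)
    T, n = e.shape
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n,))
    z = rng.standard_normal((T, n))
    y_null = z
    y_assoc = np.exp(mu[None, :] + sigma[None, :] * rng.standard_normal((T, n)))
    y = np.where(e == 1, y_assoc, y_null)
    return y, norm.sf(y)


def shuffle_annotations(annotations: AnnotationMatrix,
                        rng: np.random.Generator) -> AnnotationMatrix:
    """Permute annotation rows uniformly, breaking SNP-annotation linkage.

    Column sums are preserved; SNP ids keep their original order so the
    shuffled matrix stays aligned with the summary statistics by position,
    which is the point of the robustness exercise.
    """
    perm = rng.permutation(len(annotations.snp_ids))
    return AnnotationMatrix(list(annotations.snp_ids),
                            list(annotations.annotation_names),
                            annotations.a[perm])


def simulate(scenario: SimulationScenario | None = None,
             seed: int = 0) -> SimulationTruth:
    """Run the full generative pipeline for one dataset."""
    scenario = scenario or default_scenario()
    scenario.validate()
    rng = np.random.default_rng(seed)
    annotations = generate_annotations(scenario.T, scenario.M,
                                       scenario.annotation_proportion, rng)
    e = generate_latent(scenario, annotations, rng)
    y, p = generate_observations(e, scenario.mu, scenario.sigma, rng)
    snp_ids = annotations.snp_ids
    names = [f"P{i + 1}" for i in range(scenario.n)]
    return SimulationTruth(
        scenario=scenario,
        e=e,
        annotations=annotations,
        y=ZMatrix(list(snp_ids), names, y),
        pvalues=SummaryStatsTable(list(snp_ids), names, p),
    )
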