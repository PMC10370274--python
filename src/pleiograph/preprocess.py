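"""Input/output and preprocessing for GWAS summary statistics and annotations.

Covers the standard preparation steps for multi-trait summary-statistic
analysis: the probit transform of association p-values
(``y = Phi^{-1}(1 - p)``), binarization of continuous functional-annotation
scores at a cutoff, keep-one-in-k SNP thinning to reduce linkage
disequilibrium between retained SNPs, and decorrelation of phenotype groups
with overlapping study samples via the inverse square root of their sample
correlation matrix.

All tables are delimited text (tab or comma, auto-detected) with a header
row whose first column holds SNP identifiers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SummaryStatsTable",
    "ZMatrix",
    "AnnotationMatrix",
    "PriorGraph",
    "read_summary_stats",
    "read_annotations",
    "read_prior_graph",
    "write_table",
    "transform_pvalues",
    "binarize_annotations",
    "thin_snps",
    "align_annotations",
    "decorrelate",
]

logger = logging.getLogger(__name__)

#: Default p-value clipping bounds, keeping the probit transform finite.
CLIP_LOW_DEFAULT = 1e-300
CLIP_HIGH_DEFAULT = 1.0 - 1e-16


@dataclass
class SummaryStatsTable:
    """Per-SNP association p-values, one column per phenotype."""

    snp_ids: list
    phenotype_names: list
    pvalues: np.ndarray  # T x n, in (0, 1] after loading

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvalues, index=pd.Index(self.snp_ids, name="snp"),
                            columns=self.phenotype_names)


@dataclass
class ZMatrix:
    """Probit-transformed association statistics ``y_it = Phi^{-1}(1 - p_it)``."""

    snp_ids: list
    phenotype_names: list
    y: np.ndarray  # T x n, finite

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.y, index=pd.Index(self.snp_ids, name="snp"),
                            columns=self.phenotype_names)


@dataclass
class AnnotationMatrix:
    """Binary SNP-level functional annotations (T x M, entries 0/1)."""

    snp_ids: list
    annotation_names: list
    a: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a.astype(int), index=pd.Index(self.snp_ids, name="snp"),
                            columns=self.annotation_names)


@dataclass
class PriorGraph:
    """Prior phenotype graph: unordered label pairs (no self-edges)."""

    phenotype_names: list
    edges: set = field(default_factory=set)

    def __post_init__(self):
        norm_edges = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"prior graph contains a self-edge at {a!r}")
            for lab in (a, b):
                if lab not in self.phenotype_names:
                    raise ValueError(f"prior-graph label {lab!r} not among phenotype names")
            norm_edges.add(frozenset((a, b)))
        self.edges = norm_edges

    def edge_index_pairs(self, phenotype_names=None):
        names = list(phenotype_names if phenotype_names is not None
                     else self.phenotype_names)
        return [tuple(sorted(names.index(x) for x in e)) for e in self.edges]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path, delimiter=None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path, "r", newline="") as fh:
        sample = fh.read(64 * 1024)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_summary_stats(path, delimiter=None) -> SummaryStatsTable:
    """Load a delimited p-value table (header; first column = SNP id).

    Rows with any missing p-value are dropped (the count is logged); values
    are then required to lie in [0, 1].
    """
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d SNP(s) with missing p-values from %s", n_dropped, path)
    p = df.to_numpy(dtype=float)
    _check_pvalue_range(p, df.index, df.columns)
    return SummaryStatsTable(list(df.index), list(df.columns), p)


def read_annotations(path, delimiter=None, cutoff: float | None = 0.5):
    """Load annotation scores; non-binary columns are binarized at ``cutoff``.

    Returns an :class:`AnnotationMatrix`.  With ``cutoff=None`` the values
    must already be 0/1.
    """
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0,
                     float_precision="round_trip").dropna()
    scores = df.to_numpy(dtype=float)
    if np.isin(scores, (0.0, 1.0)).all():
        a = scores.astype(np.int8)
    elif cutoff is None:
        raise ValueError(f"annotation file {path} is not binary and no cutoff was given")
    else:
        a = binarize_scores(scores, cutoff)
    return AnnotationMatrix(list(df.index), list(df.columns), a)


def read_prior_graph(path, phenotype_names, delimiter=None) -> PriorGraph:
    """Load a two-column edge list of phenotype labels."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    edges = {(str(r.iloc[0]).strip(), str(r.iloc[1]).strip()) for _, r in df.iterrows()}
    return PriorGraph(list(phenotype_names), edges)


def write_table(table, path, delimiter="\t") -> None:
    """Write any of the table types (or a DataFrame) as delimited text."""
    df = table if isinstance(table, pd.DataFrame) else table.to_frame()
    df.to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def _check_pvalue_range(p, snp_ids, phenotype_names):
    bad = (p < 0) | (p > 1) | ~np.isfinite(p)
    if np.any(bad):
        t, i = np.argwhere(bad)[0]
        raise ValueError(
            f"p-value out of [0, 1] for SNP {list(snp_ids)[t]!r}, "
            f"phenotype {list(phenotype_names)[i]!r}: {p[t, i]!r}"
        )


def transform_pvalues(table: SummaryStatsTable,
                      clip_low: float = CLIP_LOW_DEFAULT,
                      clip_high: float = CLIP_HIGH_DEFAULT) -> ZMatrix:
    """Probit-transform p-values: ``y = Phi^{-1}(1 - p)`` after clipping.

    Clipping to ``[clip_low, clip_high]`` keeps the transform finite for
    p = 0 and p = 1.  Strictly decreasing in p; y = 0 at p = 0.5.
    """
    if not 0.0 < clip_low < clip_high < 1.0:
        raise ValueError("clip bounds must satisfy 0 < clip_low < clip_high < 1")
    p = np.asarray(table.pvalues, dtype=float)
    _check_pvalue_range(p, table.snp_ids, table.phenotype_names)
    y = norm.isf(np.clip(p, clip_low, clip_high))
    return ZMatrix(list(table.snp_ids), list(table.phenotype_names), y)


def binarize_scores(scores: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """0/1 by strict comparison: 1 iff score > cutoff."""
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 1) | ~np.isfinite(scores)):
        raise ValueError("annotation scores must lie in [0, 1]")
    return (scores > cutoff).astype(np.int8)


def binarize_annotations(scores, cutoff: float = 0.5, snp_ids=None,
                         annotation_names=None) -> AnnotationMatrix:
    """Binarize a score matrix (values in [0, 1]) at ``cutoff`` (strict >)."""
    if isinstance(scores, AnnotationMatrix):
        return AnnotationMatrix(scores.snp_ids, scores.annotation_names,
                                binarize_scores(scores.a, cutoff))
    a = binarize_scores(np.asarray(scores, dtype=float), cutoff)
    T, M = a.shape
    snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{t + 1}" for t in range(T)]
    annotation_names = (list(annotation_names) if annotation_names is not None
                        else [f"A{m + 1}" for m in range(M)])
    return AnnotationMatrix(snp_ids, annotation_names, a)


def thin_snps(table, k: int):
    """Keep rows 1, 1+k, 1+2k, ... (1-based) of a table; k = 1 is the identity.

    Works on any of the row-indexed table types; apply it to the summary
    statistics and annotations separately (alignment by SNP id commutes with
    thinning).
    """
    if int(k) != k or k < 1:
        raise ValueError(f"thinning factor k must be a positive integer, got {k!r}")
    k = int(k)
    if isinstance(table, SummaryStatsTable):
        return SummaryStatsTable(table.snp_ids[::k], list(table.phenotype_names),
                                 table.pvalues[::k])
    if isinstance(table, ZMatrix):
        return ZMatrix(table.snp_ids[::k], list(table.phenotype_names), table.y[::k])
    if isinstance(table, AnnotationMatrix):
        return AnnotationMatrix(table.snp_ids[::k], list(table.annotation_names),
                                table.a[::k])
    raise TypeError(f"unsupported table type {type(table).__name__}")


def align_annotations(z: ZMatrix | SummaryStatsTable,
                      annotations: AnnotationMatrix) -> AnnotationMatrix:
    """Reorder annotation rows to match the summary-statistic SNP ids.

    Alignment is by identifier, never by position; missing SNPs raise.
    """
    pos = {s: t for t, s in enumerate(annotations.snp_ids)}
    try:
        order = np.array([pos[s] for s in z.snp_ids], dtype=np.intp)
    except KeyError as err:
        raise ValueError(f"annotation file is missing SNP {err.args[0]!r}") from None
    return AnnotationMatrix(list(z.snp_ids), list(annotations.annotation_names),
                            annotations.a[order])


def decorrelate(z: ZMatrix, group, min_eigenvalue: float = 1e-10) -> ZMatrix:
    """Remove sample-overlap correlation within a phenotype group.

    The selected columns are standardized, multiplied by the symmetric
    inverse square root of their sample correlation matrix ``C`` (via
    eigendecomposition), and restored to their original location/scale, so
    the output group has exactly identity sample correlation and the
    operation is idempotent.  Unselected columns are untouched.
    """
    group = list(group)
    if len(group) < 2:
        raise ValueError("decorrelation group must contain at least two phenotypes")
    names = list(z.phenotype_names)
    missing = [g for g in group if g not in names]
    if missing:
        raise ValueError(f"phenotype label(s) not found: {missing}")
    cols = np.array([names.index(g) for g in group], dtype=np.intp)
    X = np.asarray(z.y, dtype=float)[:, cols]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("a selected column is constant; correlation undefined")
    Xs = (X - mean) / sd
    C = np.corrcoef(Xs, rowvar=False)
    w, V = np.linalg.eigh(C)
    if w.min() < min_eigenvalue:
        raise ValueError(
            f"sample correlation matrix is singular or not positive definite "
            f"(smallest eigenvalue {w.min():.3e} < {min_eigenvalue:g})"
        )
    C_inv_sqrt = (V / np.sqrt(w)) @ V.T
    out = np.array(z.y, dtype=float, copy=True)
    out[:, cols] = (Xs @ C_inv_sqrt) * sd + mean
    return ZMatrix(list(z.snp_ids), names, out)
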