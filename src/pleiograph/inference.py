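"""Posterior decision rules: phenotype graph, annotation calls, FDR-controlled
association lists.

The phenotype pair (i, j) is called genetically correlated when
``p(E(i,j) | Y) > 0.5`` and ``p(beta_ij > 0 | Y) > 0.95`` (both strict);
annotation m is called relevant for phenotype i when
``p(gamma_im > 0 | Y) > 0.95``.  Association mapping uses the direct
posterior probability approach: rank items by posterior association
probability and take the largest prefix whose mean local false discovery
rate (1 minus the probability) stays at or below the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import PosteriorSummary

__all__ = [
    "GraphDecision",
    "decide_graph",
    "decide_annotations",
    "fdr_select",
    "association_calls",
    "pleiotropy_calls",
    "write_dot",
]


@dataclass
class GraphDecision:
    """Edge table plus the decided adjacency matrix."""

    phenotype_names: list
    table: pd.DataFrame      # one row per unordered pair
    adjacency: np.ndarray    # (n, n) 0/1

    @property
    def edges(self):
        return {(r.phenotype_i, r.phenotype_j)
                for r in self.table.itertuples() if r.edge}


def decide_graph(summary: PosteriorSummary, p_edge_cut: float = 0.5,
                 p_sign_cut: float = 0.95) -> GraphDecision:
    """Call edges where both posterior probabilities strictly exceed their cuts."""
    for name, cut in (("p_edge_cut", p_edge_cut), ("p_sign_cut", p_sign_cut)):
        if not 0.0 < cut < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    names = summary.phenotype_names
    n = len(names)
    adjacency = np.zeros((n, n), dtype=np.int8)
    rows = []
    for i, j in summary.pair_list:
        p_edge = summary.edge_prob[i, j]
        p_pos = summary.beta_pos_prob[i, j]
        call = bool(p_edge > p_edge_cut and p_pos > p_sign_cut)
        adjacency[i, j] = adjacency[j, i] = call
        rows.append({"phenotype_i": names[i], "phenotype_j": names[j],
                     "p_edge": p_edge, "p_beta_pos": p_pos,
                     "beta_mean": summary.beta_mean[i, j], "edge": call})
    return GraphDecision(list(names), pd.DataFrame(rows), adjacency)


def decide_annotations(summary: PosteriorSummary,
                       p_sign_cut: float = 0.95) -> pd.DataFrame:
    """Annotation-relevance table: call iff p(gamma_im > 0 | Y) > cut (strict)."""
    if not 0.0 < p_sign_cut < 1.0:
        raise ValueError("p_sign_cut must lie in (0, 1)")
    rows = []
    for i, phen in enumerate(summary.phenotype_names):
        for m, ann in enumerate(summary.annotation_names):
            p = summary.gamma_pos_prob[i, m]
            rows.append({"phenotype": phen, "annotation": ann,
                         "p_gamma_pos": p, "gamma_mean": summary.gamma_mean[i, m],
                         "call": bool(p > p_sign_cut)})
    return pd.DataFrame(rows)


def fdr_select(probs, level: float) -> np.ndarray:
    """Direct-posterior-probability FDR selection.

    Sort by posterior association probability (descending, ties kept in
    input order) and select the largest prefix whose mean local fdr
    (mean of 1 - prob) does not exceed ``level``.  Returns the selected
    indices in ascending input order.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1:
        raise ValueError("probs must be one-dimensional")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    if not 0.0 < level < 1.0:
        raise ValueError("FDR level must lie in (0, 1)")
    order = np.argsort(-probs, kind="stable")
    cum_lfdr = np.cumsum(1.0 - probs[order]) / np.arange(1, probs.size + 1)
    n_sel = int(np.count_nonzero(cum_lfdr <= level))  # cum mean is nondecreasing
    return np.sort(order[:n_sel])


def association_calls(summary: PosteriorSummary, phenotype,
                      levels=(0.05,)) -> pd.DataFrame:
    """Single-trait association table with significance flags per FDR level."""
    i = summary.phenotype_names.index(phenotype) \
        if not isinstance(phenotype, (int, np.integer)) else int(phenotype)
    probs = summary.marginal_prob[:, i]
    return _call_table(summary.snp_ids, probs,
                       summary.phenotype_names[i], levels)


def pleiotropy_calls(summary: PosteriorSummary, phenotype_set,
                     levels=(0.05,)) -> pd.DataFrame:
    """Pleiotropic association table for a phenotype pair or larger set.

    Uses the accumulated joint posterior probability that every indicator in
    the set is 1.  Sets of size > 2 must have been requested at sampling
    time (``MCMCConfig.pair_sets``); otherwise an error advises a re-run.
    """
    idx = tuple(sorted(
        summary.phenotype_names.index(p) if not isinstance(p, (int, np.integer))
        else int(p) for p in phenotype_set))
    if len(idx) < 2 or len(set(idx)) != len(idx):
        raise ValueError("phenotype_set must contain at least two distinct phenotypes")
    if len(idx) == 2:
        probs = summary.pairwise_prob[:, summary.pair_index(*idx)]
    elif idx in summary.set_prob:
        probs = summary.set_prob[idx]
    else:
        raise ValueError(
            f"joint probabilities for phenotype set {idx} were not accumulated; "
            "re-run the sampler with this set in MCMCConfig.pair_sets"
        )
    target = "+".join(summary.phenotype_names[i] for i in idx)
    return _call_table(summary.snp_ids, probs, target, levels)


def _call_table(snp_ids, probs, target, levels) -> pd.DataFrame:
    df = pd.DataFrame({
        "snp": list(snp_ids),
        "target": target,
        "posterior_prob": probs,
        "local_fdr": 1.0 - probs,
    })
    for level in sorted(levels):
        flag = np.zeros(len(df), dtype=bool)
        flag[fdr_select(probs, level)] = True
        df[f"significant_at_{level:g}"] = flag
    return df


def write_dot(decision: GraphDecision, path) -> None:
    """Write the decided phenotype graph in DOT format for visualization."""
    lines = ["graph phenotypes {", "  node [shape=circle];"]
    for name in decision.phenotype_names:
        lines.append(f'  "{name}";')
    for r in decision.table.itertuples():
        if r.edge:
            lines.append(f'  "{r.phenotype_i}" -- "{r.phenotype_j}" '
                         f'[label="{r.beta_mean:.2f}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
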