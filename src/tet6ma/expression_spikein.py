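"""Spike-in size factors, normalization and differential-expression summaries.

Size factors follow the exogenous-spike-in recipe: each sample's spike-in
read total divided by the exponential of the mean natural log of the
totals (geometric-mean centring), so the factors multiply to 1 exactly.

Differential expression here is a deliberately simple, documented adapter:
Welch's t-test on log2(normalized + 0.5) with Benjamini-Hochberg
correction. The scientific content is the size-factor normalization; the
test is replaceable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_LFC_CUTOFF = -1.0
DEFAULT_PADJ_CUTOFF = 0.05


def spike_size_factors(spike_totals) -> pd.Series:
    """factor_i = z_i / exp(mean_j ln z_j) for spike-in totals z."""
    totals = pd.Series(spike_totals, dtype=float)
    bad = totals[totals <= 0]
    if len(bad):
        raise ValueError(f"non-positive spike-in total for sample(s): {list(bad.index)}")
    factors = totals / np.exp(np.log(totals).mean())
    factors.name = "size_factor"
    return factors


def normalize_counts(matrix: pd.DataFrame, factors) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if len(factors) != matrix.shape[1]:
        raise ValueError("number of size factors must match number of samples")
    return matrix / factors


def differential_expression(matrix: pd.DataFrame, factors, group_labels,
                            control: str | None = None,
                            treatment: str | None = None,
                            pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Two-group DE summary on spike-in-normalized counts.

    log2FoldChange = log2((mean norm treatment + pc) / (mean norm control
    + pc)); p-values from Welch's t-test on log2(normalized + pc), BH
    adjusted. Both groups need >= 2 samples.
    """
    labels = pd.Series(list(group_labels), index=matrix.columns)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError("group_labels must contain exactly two groups")
    control = control if control is not None else uniq[0]
    treatment = treatment if treatment is not None else next(u for u in uniq if u != control)
    norm = normalize_counts(matrix, factors)
    a = norm.loc[:, (labels == treatment).to_numpy()]
    b = norm.loc[:, (labels == control).to_numpy()]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    lfc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "baseMean": norm.mean(axis=1),
        "log2FoldChange": lfc,
        "pvalue": p,
        "padj": padj}, index=matrix.index)


@dataclass
class CoDownregulation:
    per_condition: dict[str, set] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], set] = field(default_factory=dict)
    all_conditions: set = field(default_factory=set)


def co_downregulated(de_results: dict[str, pd.DataFrame],
                     meth_deltas: dict[str, pd.Series],
                     lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
                     padj_cutoff: float = DEFAULT_PADJ_CUTOFF) -> CoDownregulation:
    """Genes with reduced 6mA and decreased expression, per condition.

    Per condition: log2FoldChange <= lfc_cutoff (boundary included),
    padj < padj_cutoff, and 6mA delta < 0. Returns the per-condition sets
    and every pairwise and all-way intersection.
    """
    result = CoDownregulation()
    for cond, de in de_results.items():
        delta = meth_deltas[cond]
        down = de[(de["log2FoldChange"] <= lfc_cutoff) & (de["padj"] < padj_cutoff)]
        reduced = set(delta[delta < 0].index)
        result.per_condition[cond] = set(down.index) & reduced
    for a, b in combinations(result.per_condition, 2):
        result.pairwise[(a, b)] = result.per_condition[a] & result.per_condition[b]
    sets = list(result.per_condition.values())
    result.all_conditions = set.intersection(*sets) if sets else set()
    return result
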