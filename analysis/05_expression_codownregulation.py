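#!/usr/bin/env python
"""Spike-in normalized differential expression and co-downregulation sets.

Simulates three perturbation conditions against a shared control with
overlapping sets of truly downregulated genes (all also losing 6mA),
computes spike-in size factors and DE per condition, and reports the
pairwise and three-way co-downregulated intersections.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tet6ma.expression_spikein import (co_downregulated, differential_expression,
                                       spike_size_factors)
from tet6ma.synthetic_data import simulate_counts

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

n_genes = 2_000
rng = np.random.default_rng(args.seed)
down = {  # truly downregulated genes per condition (nested like the strains)
    "dAMT1": np.arange(0, 300),
    "APPA": np.arange(100, 400),
    "RNAi": np.arange(250, 450),
}
de_results, deltas = {}, {}
for i, (cond, idx) in enumerate(down.items()):
    lfc = np.zeros(n_genes)
    lfc[idx] = -2.0
    factors_true = rng.uniform(0.7, 1.4, size=6)
    sc, _ = simulate_counts(n_genes, 6, lfc, factors_true, 0.01,
                            seed=args.seed + i)
    factors = spike_size_factors(sc.spike_totals)
    de_results[cond] = differential_expression(sc.counts, factors,
                                               ["c"] * 3 + ["t"] * 3)
    delta = -np.ones(n_genes) * 0.1  # every gene loses a little 6mA
    deltas[cond] = pd.Series(delta, index=sc.counts.index)
    n_sig = int(((de_results[cond].log2FoldChange <= -1)
                 & (de_results[cond].padj < 0.05)).sum())
    print(f"{cond}: {len(idx)} genes truly down, {n_sig} called "
          f"(log2FC <= -1, padj < 0.05)")

out = co_downregulated(de_results, deltas)
ab = out.pairwise[("dAMT1", "APPA")]
print(f"Group A (APPA ∩ dAMT1): {len(ab)} genes (expected overlap 200)")
print(f"Group B (three-way):    {len(out.all_conditions)} genes (expected overlap 50)")

membership = pd.DataFrame({
    "gene_id": sorted(set.union(*out.per_condition.values())),
})
for cond, s in out.per_condition.items():
    membership[cond] = membership.gene_id.isin(s)
membership.to_csv(OUT / "codownregulated_sets.tsv", sep="\t", index=False)
print(f"wrote {OUT / 'codownregulated_sets.tsv'}")
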