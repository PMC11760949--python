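#!/usr/bin/env python
"""Nucleosome positioning-degree recovery and a ChIP-enrichment example.

Simulates MNase-like fragments at known positioning degrees and recovers
them; then builds a toy ChIP/input pair where one gene holds twice its
input share of fragments and confirms the 2x enrichment.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tet6ma.chromatin_metrics import (chip_enrichment, filter_fragment_lengths,
                                      gene_positioning_degree, positioning_degrees)
from tet6ma.models import GeneModel
from tet6ma.synthetic_data import simulate_fragments

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

dyads = np.arange(1_000, 80_000, 300)
rows = []
for target in (0.4, 0.6, 0.8, 1.0):
    fr = filter_fragment_lengths(
        simulate_fragments(dyads, target, 10_000, seed=args.seed + int(10 * target)))
    est = positioning_degrees(pd.DataFrame({"chrom": "chr1", "pos": dyads}), fr)
    rows.append({"target_degree": target, "estimated": round(est.degree.mean(), 4)})
    print(f"positioning degree {target:.1f}: recovered {est.degree.mean():.4f}")
pd.DataFrame(rows).to_csv(OUT / "positioning_recovery.tsv", sep="\t", index=False)

gene = GeneModel("gA", "chr1", 10_000, 20_000, "+")
fr = simulate_fragments(dyads, 0.8, 20_000, seed=args.seed)
deg = positioning_degrees(pd.DataFrame(
    {"chrom": "chr1", "pos": dyads[(dyads >= 10_000) & (dyads < 20_000)]}), fr)
print(f"TSS-adjacent nucleosome degree of gA: {gene_positioning_degree(gene, deg):.4f}")

rng = np.random.default_rng(args.seed)
def toy(n_gene, n_rest):
    start = np.concatenate([rng.integers(10_000, 19_800, n_gene),
                            rng.integers(30_000, 79_800, n_rest)])
    return pd.DataFrame({"chrom": "chr1", "start": start, "end": start + 180})

enr = chip_enrichment([gene], toy(2_000, 8_000), toy(1_000, 9_000))
print(f"ChIP enrichment of gA (20% ChIP vs 10% input share): "
      f"{enr.enrichment.iloc[0]:.3f}")
enr.to_csv(OUT / "chip_enrichment_example.tsv", sep="\t", index=False)
print(f"wrote tables under {OUT}")
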