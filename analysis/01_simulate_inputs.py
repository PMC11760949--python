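#!/usr/bin/env python
"""Generate one synthetic input bundle and sanity-check the ground truth.

Writes a small molecule TSV, gene BED and ground-truth site table under
results/, and prints the realized duplex-state frequencies of the WT
preset against its configured probabilities.
"""
from pathlib import Path

import numpy as np

from tet6ma import PRESETS, make_genome, simulate_molecules
from tet6ma.io import write_genes_bed, write_molecules_tsv

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

genome = make_genome(seed=1, chrom_len=20_000, n_genes=4, apt_density=120)
preset = PRESETS["WT"]
molecules, truth = simulate_molecules(genome, preset, n_molecules=200,
                                      mean_len=500, seed=1)

write_molecules_tsv(molecules[:20], OUT / "example_molecules.tsv")
write_genes_bed(genome.genes, OUT / "example_genes.bed")
truth.site_table.to_csv(OUT / "example_site_truth.tsv", sep="\t", index=False)

freq = truth.state_counts / truth.state_counts.sum()
print(f"genome: 20 kb, {genome.n_apt} ApT duplexes, {len(genome.genes)} genes")
print(f"designated methylated fraction: {truth.apt_fraction:.4f} "
      f"(configured {preset.apt_fraction})")
print("duplex-state frequencies over all observations (Full/Hemi-W/Hemi-C/Un):")
print("  observed :", np.round(freq, 4))
expected = preset.apt_fraction * preset.state_probs
expected[3] += 1 - preset.apt_fraction
print("  expected :", np.round(expected, 4))
print(f"wrote example tables under {OUT}")
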