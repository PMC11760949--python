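"""Plain-text readers/writers for the pipeline's tabular formats.

Molecules travel as a long TSV (one row per strand-position record), genes
as BED6, fragments and dyads as BED3(+), counts and penetrance as TSV.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .models import BASES, GeneModel, SingleMolecule

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


def write_molecules_tsv(molecules: list[SingleMolecule], path) -> None:
    frames = []
    for m in molecules:
        for strand, pos, base, ipd in (("W", m.watson_pos, m.watson_base, m.watson_ipd),
                                       ("C", m.crick_pos, m.crick_base, m.crick_ipd)):
            frames.append(pd.DataFrame({
                "molecule_id": m.molecule_id, "chrom": m.chrom,
                "start": m.start, "end": m.end, "passes": m.passes,
                "strand": strand, "position": pos,
                "base": BASES[base], "ipd_ratio": ipd}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.4f")


def read_molecules_tsv(path) -> list[SingleMolecule]:
    df = pd.read_csv(path, sep="\t")
    molecules = []
    for mid, g in df.groupby("molecule_id", sort=True):
        parts = {}
        for strand in ("W", "C"):
            s = g[g["strand"] == strand].sort_values("position")
            parts[strand] = (s["position"].to_numpy(np.int64),
                             np.array([_BASE_CODE[b] for b in s["base"]], dtype=np.uint8),
                             s["ipd_ratio"].to_numpy(float))
        first = g.iloc[0]
        molecules.append(SingleMolecule(
            molecule_id=str(mid), chrom=str(first["chrom"]),
            start=int(first["start"]), end=int(first["end"]),
            passes=int(first["passes"]),
            watson_pos=parts["W"][0], watson_base=parts["W"][1], watson_ipd=parts["W"][2],
            crick_pos=parts["C"][0], crick_base=parts["C"][1], crick_ipd=parts["C"][2]))
    return molecules


def write_genes_bed(genes: list[GeneModel], path) -> None:
    pd.DataFrame({
        "chrom": [g.chrom for g in genes], "start": [g.start for g in genes],
        "end": [g.end for g in genes], "name": [g.gene_id for g in genes],
        "score": 0, "strand": [g.strand for g in genes],
    }).to_csv(path, sep="\t", index=False, header=False)


def read_genes_bed(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return [GeneModel(str(r["name"]), str(r["chrom"]), int(r["start"]),
                      int(r["end"]), str(r["strand"])) for _, r in df.iterrows()]


def write_bed3(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_bed3(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])


def write_penetrance_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
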