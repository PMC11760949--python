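"""ChIP enrichment and nucleosome positioning degree from fragment intervals.

Fragments are BED-like half-open intervals; a fragment is assigned to a
feature by its midpoint ((start + end) // 2). The positioning degree of a
nucleosome dyad is the count of fragment midpoints within +/-25 bp divided
by the count within +/-75 bp (closed windows); for uniform midpoints this
statistic has a floor of 51/151.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .models import GeneModel

INNER_WINDOW = 25
OUTER_WINDOW = 75
DEFAULT_MIN_LEN = 120
DEFAULT_MAX_LEN = 260


def filter_fragment_lengths(fragments: pd.DataFrame,
                            min_len: int = DEFAULT_MIN_LEN,
                            max_len: int = DEFAULT_MAX_LEN) -> pd.DataFrame:
    """Retain fragments with min_len <= length <= max_len (both inclusive)."""
    length = fragments["end"] - fragments["start"]
    return fragments[(length >= min_len) & (length <= max_len)].reset_index(drop=True)


def fragment_midpoints(fragments: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"chrom": fragments["chrom"],
                         "mid": (fragments["start"] + fragments["end"]) // 2})


def _counts_in_genes(genes: list[GeneModel], mids: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(genes), dtype=np.int64)
    by_chrom = {c: np.sort(g["mid"].to_numpy()) for c, g in mids.groupby("chrom")}
    for i, g in enumerate(genes):
        m = by_chrom.get(g.chrom)
        if m is None:
            continue
        counts[i] = np.searchsorted(m, g.end - 1, side="right") - np.searchsorted(m, g.start)
    return counts


def chip_enrichment(genes: list[GeneModel], chip_fragments: pd.DataFrame,
                    input_fragments: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ChIP/input enrichment of total-normalized midpoint counts.

    ratio = (gene ChIP count / total ChIP) / (gene input count / total
    input); genes without input midpoints get NaN.
    """
    if len(chip_fragments) == 0 or len(input_fragments) == 0:
        raise ValueError("both ChIP and input fragment sets must be non-empty")
    chip_mid = fragment_midpoints(chip_fragments)
    input_mid = fragment_midpoints(input_fragments)
    chip_counts = _counts_in_genes(genes, chip_mid)
    input_counts = _counts_in_genes(genes, input_mid)
    chip_frac = chip_counts / len(chip_mid)
    input_frac = input_counts / len(input_mid)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(input_counts > 0, chip_frac / input_frac, np.nan)
    return pd.DataFrame({"gene_id": [g.gene_id for g in genes],
                         "chip_count": chip_counts, "input_count": input_counts,
                         "enrichment": ratio})


def positioning_degree(dyad: int, midpoints: np.ndarray,
                       inner: int = INNER_WINDOW, outer: int = OUTER_WINDOW) -> float:
    """Fraction of +/-outer midpoints concentrated within +/-inner of the dyad."""
    mids = np.sort(np.asarray(midpoints))
    n_outer = np.searchsorted(mids, dyad + outer, side="right") - np.searchsorted(mids, dyad - outer)
    if n_outer == 0:
        return float("nan")
    n_inner = np.searchsorted(mids, dyad + inner, side="right") - np.searchsorted(mids, dyad - inner)
    return float(n_inner / n_outer)


def positioning_degrees(dyads: pd.DataFrame, fragments: pd.DataFrame,
                        inner: int = INNER_WINDOW, outer: int = OUTER_WINDOW) -> pd.DataFrame:
    """Positioning degree for every dyad (columns chrom, pos) from fragments."""
    mids = fragment_midpoints(fragments)
    by_chrom = {c: np.sort(g["mid"].to_numpy()) for c, g in mids.groupby("chrom")}
    deg = [positioning_degree(int(r.pos), by_chrom.get(r.chrom, np.array([])), inner, outer)
           for r in dyads.itertuples()]
    out = dyads.copy()
    out["degree"] = deg
    return out


def gene_positioning_degree(gene: GeneModel, dyads: pd.DataFrame,
                            max_nucleosomes: int = 3, min_nucleosomes: int = 2) -> float:
    """Mean positioning degree of the 2-3 nucleosomes just downstream of the TSS.

    Considers dyads inside the gene body, ordered by distance from the TSS
    in the gene's orientation; averages the defined degrees of the nearest
    up to three. Fewer than two defined degrees -> NaN.
    """
    sel = dyads[(dyads["chrom"] == gene.chrom)
                & (dyads["pos"] >= gene.start) & (dyads["pos"] < gene.end)]
    if len(sel) == 0:
        return float("nan")
    dist = (sel["pos"] - gene.start if gene.strand == "+" else gene.end - 1 - sel["pos"])
    degrees = sel.assign(dist=dist).sort_values("dist")["degree"].to_numpy()[:max_nucleosomes]
    degrees = degrees[np.isfinite(degrees)]
    if len(degrees) < min_nucleosomes:
        return float("nan")
    return float(degrees.mean())
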