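"""6mA threshold fitting, duplex-state calling and summary statistics.

The per-sample IPD-ratio threshold is obtained by deconvolving the pooled
adenine IPD distribution into two log-normal components (a 2-component
Gaussian mixture on ln IPD); the cutoff is the equal-posterior point
between the component means. When the fit is not convincingly bimodal
(Ashman's D = |m1 - m0| / sqrt((s0^2 + s1^2) / 2) below 2, or minor weight
below 1%), the conservative working cutoff of 2.8 is used instead.

Each molecule's view of each covered ApT duplex is classified Full /
Hemi-W / Hemi-C / Un by comparing the two adenine IPD ratios to the
cutoff (ties methylated). Penetrance at an adenine site is the fraction of
covering molecules methylated there; a site is a high-confidence 6mA site
when methylation is supported by at least three molecules.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import STATE_NAMES, GeneModel, SimGenome, SingleMolecule

FALLBACK_CUTOFF = 2.8
HIGH_CONFIDENCE_SUPPORT = 3

STATE_FULL, STATE_HEMI_W, STATE_HEMI_C, STATE_UN = 0, 1, 2, 3


@dataclass
class IpdThreshold:
    cutoff: float
    weights: np.ndarray  # component weights, low-IPD component first
    means: np.ndarray  # ln-IPD locations
    scales: np.ndarray  # ln-IPD scales
    log_likelihood: float
    bimodal: bool

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.bimodal:
            lo, hi = np.exp(self.means)
            if not lo < self.cutoff < hi:
                raise ValueError("cutoff must lie between component means")


def _equal_posterior_point(w: np.ndarray, m: np.ndarray, s: np.ndarray) -> float | None:
    """ln-IPD point between the means where the two posteriors are equal.

    Solves log(w1 N1(x)) = log(w2 N2(x)); quadratic in x for unequal
    scales, linear otherwise. Returns None when no root falls between the
    means.
    """
    a = 0.5 * (1.0 / s[1] ** 2 - 1.0 / s[0] ** 2)
    b = m[0] / s[0] ** 2 - m[1] / s[1] ** 2
    c = (0.5 * (m[1] ** 2 / s[1] ** 2 - m[0] ** 2 / s[0] ** 2)
         + np.log(w[0] / w[1]) + np.log(s[1] / s[0]))
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return None
        roots = np.array([-c / b])
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            return None
        roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * a)
    inside = roots[(roots > m[0]) & (roots < m[1])]
    return float(inside[0]) if len(inside) else None


def fit_ipd_threshold(adenine_ipds: np.ndarray, seed: int = 0,
                      fallback_cutoff: float = FALLBACK_CUTOFF,
                      min_separation: float = 2.0, min_weight: float = 0.01,
                      max_fit_points: int = 100_000) -> IpdThreshold:
    """Deconvolve the pooled adenine IPD-ratio distribution.

    Requires >= 100 finite non-negative values. Deterministic for a given
    seed (the seed controls the mixture initialisation and any
    subsampling of very large pools).
    """
    vals = np.asarray(adenine_ipds, dtype=float)
    if len(vals) < 100:
        raise ValueError("need at least 100 adenine IPD values")
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise ValueError("adenine IPD values must be finite and >= 0")
    rng = np.random.default_rng(seed)
    if len(vals) > max_fit_points:
        vals = rng.choice(vals, size=max_fit_points, replace=False)
    logv = np.log(np.maximum(vals, 1e-6))

    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, covariance_type="diag", n_init=2,
                         random_state=int(rng.integers(2 ** 31)))
    gm.fit(logv[:, None])
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_[order]
    m = gm.means_.ravel()[order]
    s = np.sqrt(gm.covariances_.ravel()[order])
    ll = float(gm.score(logv[:, None]) * len(logv))

    ashman_d = float((m[1] - m[0]) / np.sqrt((s[0] ** 2 + s[1] ** 2) / 2.0))
    bimodal = ashman_d >= min_separation and w.min() >= min_weight
    cutoff = None
    if bimodal:
        x = _equal_posterior_point(w, m, s)
        if x is None:
            bimodal = False
        else:
            cutoff = float(np.exp(x))
    if not bimodal:
        cutoff = fallback_cutoff
    thr = IpdThreshold(cutoff=cutoff, weights=w, means=m, scales=s,
                       log_likelihood=ll, bimodal=bimodal)
    thr.validate()
    return thr


def _apt_positions(apt_sites) -> dict[str, np.ndarray]:
    if isinstance(apt_sites, SimGenome):
        return apt_sites.apt_positions
    if isinstance(apt_sites, dict):
        return {c: np.asarray(p, dtype=np.int64) for c, p in apt_sites.items()}
    out: dict[str, list[int]] = {}
    for chrom, pos in apt_sites:
        out.setdefault(chrom, []).append(pos)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in out.items()}


def call_duplexes(molecules: list[SingleMolecule], apt_sites,
                  threshold: IpdThreshold | float) -> pd.DataFrame:
    """Classify every molecule x covered ApT duplex into the four states.

    A duplex is covered when the molecule has the Watson adenine record at
    the site position and the Crick adenine record at position + 1; sites
    with a missing strand are skipped (tallied in ``attrs['n_skipped']``).
    IPD >= cutoff calls a strand methylated.

    Returns a frame with molecule_id, chrom, pos (Watson-A), watson_ipd,
    crick_ipd, state code and state name.
    """
    cutoff = threshold.cutoff if isinstance(threshold, IpdThreshold) else float(threshold)
    sites = _apt_positions(apt_sites)
    rows_mol, rows_chrom, rows_pos = [], [], []
    rows_w, rows_c = [], []
    n_skipped = 0
    for m in molecules:
        pos = sites.get(m.chrom)
        if pos is None or len(pos) == 0:
            continue
        cand = pos[(pos >= m.start) & (pos < m.end - 1)]
        if len(cand) == 0:
            continue
        iw = np.searchsorted(m.watson_pos, cand)
        ok_w = (iw < len(m.watson_pos)) & (m.watson_pos[np.minimum(iw, len(m.watson_pos) - 1)] == cand)
        ok_w &= m.watson_base[np.minimum(iw, len(m.watson_base) - 1)] == 0
        ic = np.searchsorted(m.crick_pos, cand + 1)
        ok_c = (ic < len(m.crick_pos)) & (m.crick_pos[np.minimum(ic, len(m.crick_pos) - 1)] == cand + 1)
        ok_c &= m.crick_base[np.minimum(ic, len(m.crick_base) - 1)] == 0
        ok = ok_w & ok_c
        n_skipped += int((~ok).sum())
        if not ok.any():
            continue
        rows_mol.append(np.full(int(ok.sum()), m.molecule_id, dtype=object))
        rows_chrom.append(np.full(int(ok.sum()), m.chrom, dtype=object))
        rows_pos.append(cand[ok])
        rows_w.append(m.watson_ipd[iw[ok]])
        rows_c.append(m.crick_ipd[ic[ok]])
    if not rows_pos:
        calls = pd.DataFrame(columns=["molecule_id", "chrom", "pos",
                                      "watson_ipd", "crick_ipd", "state", "state_name"])
        calls.attrs["n_skipped"] = n_skipped
        return calls
    w_ipd = np.concatenate(rows_w)
    c_ipd = np.concatenate(rows_c)
    w_meth = w_ipd >= cutoff
    c_meth = c_ipd >= cutoff
    state = np.full(len(w_ipd), STATE_UN, dtype=np.int8)
    state[w_meth & c_meth] = STATE_FULL
    state[w_meth & ~c_meth] = STATE_HEMI_W
    state[~w_meth & c_meth] = STATE_HEMI_C
    calls = pd.DataFrame({
        "molecule_id": np.concatenate(rows_mol),
        "chrom": np.concatenate(rows_chrom),
        "pos": np.concatenate(rows_pos),
        "watson_ipd": w_ipd, "crick_ipd": c_ipd,
        "state": state, "state_name": STATE_NAMES[state]})
    calls.attrs["n_skipped"] = n_skipped
    return calls


def full_hemi_ratio(calls: pd.DataFrame) -> float:
    """count(Full) / count(Hemi-W or Hemi-C) over duplex-molecule observations.

    Returns inf when hemi observations are absent but Full ones exist, and
    NaN when both are absent.
    """
    counts = np.bincount(calls["state"].to_numpy(dtype=int), minlength=4) if len(calls) else np.zeros(4)
    hemi = counts[STATE_HEMI_W] + counts[STATE_HEMI_C]
    if hemi == 0:
        return float("inf") if counts[STATE_FULL] else float("nan")
    return float(counts[STATE_FULL] / hemi)


def penetrance_table(calls: pd.DataFrame,
                     min_support: int = HIGH_CONFIDENCE_SUPPORT) -> pd.DataFrame:
    """Per-adenine-site penetrance from duplex-molecule calls.

    Each duplex contributes two sites: the Watson adenine at the duplex
    position ('W') and the Crick adenine at position + 1 ('C'). Full calls
    methylate both, Hemi-W/Hemi-C their own strand only. ``duplex_pos``
    keeps the Watson-A address of the parent duplex for gene assignment.
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "duplex_pos",
                                     "methylated", "covered", "penetrance",
                                     "high_confidence"])
    state = calls["state"].to_numpy(dtype=int)
    frames = []
    for strand, offset, meth_states in (("W", 0, (STATE_FULL, STATE_HEMI_W)),
                                        ("C", 1, (STATE_FULL, STATE_HEMI_C))):
        df = pd.DataFrame({
            "chrom": calls["chrom"].to_numpy(),
            "duplex_pos": calls["pos"].to_numpy(),
            "meth": np.isin(state, meth_states)})
        g = df.groupby(["chrom", "duplex_pos"], sort=True)["meth"].agg(["sum", "count"])
        g = g.reset_index()
        g["strand"] = strand
        g["pos"] = g["duplex_pos"] + offset
        frames.append(g)
    table = pd.concat(frames, ignore_index=True)
    table = table.rename(columns={"sum": "methylated", "count": "covered"})
    table["methylated"] = table["methylated"].astype(int)
    table["penetrance"] = table["methylated"] / table["covered"]
    table["high_confidence"] = table["methylated"] >= min_support
    return table[["chrom", "pos", "strand", "duplex_pos", "methylated",
                  "covered", "penetrance", "high_confidence"]].sort_values(
        ["chrom", "duplex_pos", "strand"]).reset_index(drop=True)


def gene_methylation(genes: list[GeneModel], table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ΣP and 6mApT/ApT over covered sites.

    A duplex belongs to a gene when its Watson-A position falls in
    [start, end); both of its adenine sites are counted. ΣP sums penetrance
    over those sites; n_6mApT counts high-confidence methylated sites;
    ratio = n_6mApT / n_apt (NaN when the gene has no covered ApT site).
    """
    recs = []
    for g in genes:
        sel = table[(table["chrom"] == g.chrom)
                    & (table["duplex_pos"] >= g.start)
                    & (table["duplex_pos"] < g.end)]
        n_apt = len(sel)
        n_6ma = int(sel["high_confidence"].sum())
        recs.append({
            "gene_id": g.gene_id,
            "sigma_p": float(sel["penetrance"].sum()),
            "n_apt": n_apt,
            "n_6mApT": n_6ma,
            "ratio_6mApT_per_ApT": n_6ma / n_apt if n_apt else float("nan")})
    return pd.DataFrame(recs)


def genome_6mApT_fraction(table: pd.DataFrame) -> float:
    """High-confidence methylated ApT adenine sites over covered ApT sites."""
    if len(table) == 0:
        return float("nan")
    return float(table["high_confidence"].sum() / len(table))


def metagene_profile(genes: list[GeneModel], table: pd.DataFrame,
                     n_bins: int = 30) -> pd.DataFrame:
    """Summed penetrance in scaled bins over upstream flank, body, downstream.

    Each gene is scaled to unit length and extended by one unit on each
    side; each unit is divided into ``n_bins`` bins, oriented 5'->3' (bin 0
    of the body at the TSS for both strands). Sites are assigned by their
    duplex position; the profile sums penetrance per bin across genes.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sums = np.zeros(3 * n_bins)
    for g in genes:
        length = g.length
        sel = table[(table["chrom"] == g.chrom)
                    & (table["duplex_pos"] >= g.start - length)
                    & (table["duplex_pos"] < g.end + length)]
        if len(sel) == 0:
            continue
        dpos = sel["duplex_pos"].to_numpy()
        if g.strand == "+":
            t = dpos - g.start
        else:
            t = (g.end - 1) - dpos
        gbin = np.floor((t + length) * n_bins / length).astype(int)
        gbin = np.clip(gbin, 0, 3 * n_bins - 1)
        np.add.at(sums, gbin, sel["penetrance"].to_numpy())
    segment = np.repeat(["upstream", "body", "downstream"], n_bins)
    return pd.DataFrame({"segment": segment,
                         "bin": np.tile(np.arange(n_bins), 3),
                         "sum_penetrance": sums})
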