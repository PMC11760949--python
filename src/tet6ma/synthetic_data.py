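"""Synthetic inputs for the 6mA pipeline with exported ground truth.

Generates AT-rich genomes with a controlled density of ApT duplex sites,
single molecules with simulated SMRT inter-pulse-duration (IPD) kinetics
under named strain presets, MNase-like fragment pileups around nucleosome
dyads, spike-in-normalized count matrices, and qPCR Ct tables.

The methylation model is site-heterogeneous: a configured fraction of ApT
duplexes is designated methylated (the genome-wide 6mApT/ApT of the strain),
and per-molecule duplex states are drawn i.i.d. from the preset's
conditional state probabilities at designated sites; undesignated duplexes
are always unmethylated. This mirrors the strongly bimodal per-site
penetrance seen in ciliate 6mA data, where methylated ApT sites carry high
penetrance and the rest of the genome is clean.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import GeneModel, GroundTruth, SimGenome, SingleMolecule, complement_codes

# base composition of the AT-rich macronuclear genome (A, C, G, T)
_BASE_PROBS = np.array([0.375, 0.125, 0.125, 0.375])

# degree-statistic floor: uniform midpoints over +/-75 bp yield 51/151
DEGREE_FLOOR = 51.0 / 151.0


@dataclass(frozen=True)
class EmissionModel:
    """Log-normal IPD-ratio emissions (locations/scales on the ln scale).

    Unmethylated adenines and non-A bases sit near an IPD ratio of 1;
    methylated adenines around 5, well separated from the 2.8 working
    cutoff so that strand-level misclassification is negligible relative
    to the rare hemi-methylated class.
    """

    unmeth_loc: float = 0.0  # ln(1.0)
    unmeth_scale: float = 0.25
    meth_loc: float = math.log(5.0)
    meth_scale: float = 0.18
    non_a_loc: float = 0.0
    non_a_scale: float = 0.25


@dataclass(frozen=True)
class MethylationPreset:
    """Named strain condition driving the molecule simulator.

    ``apt_fraction`` is the genome-wide 6mApT/ApT (fraction of ApT duplexes
    designated methylated); ``full_hemi_ratio`` the Full/(Hemi-W + Hemi-C)
    ratio among duplex-molecule observations at methylated sites;
    ``meth_intensity`` the per-molecule probability that a designated duplex
    shows any methylation. The conditional duplex-state probabilities follow
    from these three numbers.
    """

    name: str
    apt_fraction: float
    full_hemi_ratio: float
    meth_intensity: float
    emissions: EmissionModel = EmissionModel()
    base_sd: float = 0.0  # per-molecule extra log-scale noise, clean molecules
    dispersed_fraction: float = 0.02
    dispersed_sd: float = 0.30  # pushes unmethylated-A IPD SD past 0.35
    nstar_fraction: float = 0.02
    nstar_run: tuple[int, int] = (4, 6)  # inserted N* cluster size range
    passes_range: tuple[int, int] = (10, 40)  # discrete uniform, inclusive
    sigma_p_overrides: dict[str, float] = field(default_factory=dict)
    site_fraction_overrides: dict[str, float] = field(default_factory=dict)
    override_penetrance: float = 0.95  # per-site penetrance of ΣP-override blocks

    @property
    def state_probs(self) -> np.ndarray:
        """(P_full, P_hemiW, P_hemiC, P_un) at a designated methylated duplex."""
        m, r = self.meth_intensity, self.full_hemi_ratio
        if math.isinf(r):
            full, hemi = m, 0.0
        else:
            full = m * r / (1.0 + r)
            hemi = m / (1.0 + r) / 2.0
        probs = np.array([full, hemi, hemi, 1.0 - m])
        if abs(probs.sum() - 1.0) > 1e-12 or np.any(probs < -1e-12):
            raise ValueError("state probabilities must be a distribution")
        return probs

    def with_overrides(self, sigma_p: dict[str, float] | None = None,
                       site_fraction: dict[str, float] | None = None) -> "MethylationPreset":
        return replace(self, sigma_p_overrides=sigma_p or {},
                       site_fraction_overrides=site_fraction or {})


#: Strain presets calibrated to the published genome-wide 6mApT/ApT and
#: full/hemi estimates: WT 2.03% / 7.58, catalytically dead APPA 0.50% / 0.02,
#: AMT1 knockout 0.53% / 0.02, AMT1 RNAi knockdown 1.02%. The RNAi full/hemi
#: ratio is reported only as "lower than WT"; 2.0 is used as a plausible
#: intermediate between WT and the knockout.
PRESETS: dict[str, MethylationPreset] = {
    "WT": MethylationPreset("WT", 0.0203, 7.58, 0.962),
    "APPA": MethylationPreset("APPA", 0.0050, 0.02, 0.918),
    "dAMT1": MethylationPreset("dAMT1", 0.0053, 0.02, 0.918),
    "RNAi": MethylationPreset("RNAi", 0.0102, 2.0, 0.95),
}


def _round_count(fraction: float, n: int) -> int:
    return int(round(fraction * n))


def make_genome(seed: int, n_chrom: int = 1, chrom_len: int = 50_000,
                n_genes: int = 10, apt_density: float = 140.0,
                mean_gene_len: int = 2_000) -> SimGenome:
    """Build a synthetic AT-rich genome with non-overlapping genes.

    ``apt_density`` is the target ApT duplex density in sites/kb; sites are
    placed uniformly at random with >= 2 bp spacing and the rest of the
    sequence contains no ApT dinucleotide, so the site list is exhaustive.
    """
    if chrom_len < 1000:
        raise ValueError("chrom_len must be >= 1000")
    if apt_density < 0:
        raise ValueError("apt_density must be >= 0")
    if n_genes * mean_gene_len > n_chrom * chrom_len:
        raise ValueError("cannot pack genes: n_genes * mean gene length exceeds genome size")
    rng = np.random.default_rng(seed)

    seq_codes: dict[str, np.ndarray] = {}
    apt_positions: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    gene_counter = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        codes = rng.choice(4, size=chrom_len, p=_BASE_PROBS).astype(np.uint8)
        # remove every accidental ApT: replace the T with C or G (cannot
        # create a new ApT and occurrences never share a T)
        apt = np.flatnonzero((codes[:-1] == 0) & (codes[1:] == 3))
        codes[apt + 1] = rng.choice([1, 2], size=len(apt)).astype(np.uint8)

        n_sites = _round_count(apt_density * chrom_len / 1000.0, 1)
        if n_sites > 0:
            slots = chrom_len - 3 - 2 * (n_sites - 1)
            if slots < n_sites:
                raise ValueError("apt_density too high for chromosome length")
            ys = np.sort(rng.choice(slots, size=n_sites, replace=False))
            pos = ys + 2 * np.arange(n_sites) + 1
            codes[pos] = 0
            codes[pos + 1] = 3
        else:
            pos = np.array([], dtype=np.int64)
        seq_codes[chrom] = codes
        apt_positions[chrom] = pos.astype(np.int64)

        k = per_chrom[ci]
        if k:
            lens = rng.integers(int(0.75 * mean_gene_len), int(1.25 * mean_gene_len) + 1, size=k)
            free = chrom_len - int(lens.sum())
            if free < 0:
                raise ValueError(f"cannot pack {k} genes into {chrom}")
            gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
            start = 0
            for gi in range(k):
                start += int(gaps[gi])
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(f"g{gene_counter:03d}", chrom, start,
                                       start + int(lens[gi]), strand))
                start += int(lens[gi])
                gene_counter += 1

    genome = SimGenome(seq_codes, genes, apt_positions)
    genome.validate()
    return genome


def _designate_sites(genome: SimGenome, preset: MethylationPreset,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Assign per-site duplex-state probabilities and true penetrance.

    Exact designated counts (rounded from the configured fractions) with
    random placement keep the realized genome-wide 6mApT/ApT at the
    configured value up to rounding.
    """
    frames = []
    base_probs = preset.state_probs
    for chrom, pos in genome.apt_positions.items():
        n = len(pos)
        df = pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "gene_id": "",
            "designated": False,
            "p_full": 0.0, "p_hemi_w": 0.0, "p_hemi_c": 0.0,
        })
        genes = [g for g in genome.genes if g.chrom == chrom]
        claimed = np.zeros(n, dtype=bool)
        for g in genes:
            in_gene = (pos >= g.start) & (pos < g.end)
            df.loc[in_gene, "gene_id"] = g.gene_id
            if g.gene_id in preset.sigma_p_overrides:
                target = preset.sigma_p_overrides[g.gene_id]
                idx = np.flatnonzero(in_gene)
                p_b = preset.override_penetrance
                k = int(target / (2 * p_b))
                rem = target / 2.0 - k * p_b  # per-strand remainder penetrance
                need = k + (1 if rem > 1e-9 else 0)
                if need > len(idx):
                    raise ValueError(f"gene {g.gene_id} has too few ApT sites for ΣP override")
                chosen = rng.choice(idx, size=need, replace=False)
                pen = np.full(need, p_b)
                if rem > 1e-9:
                    pen[-1] = rem
                df.loc[chosen, "p_full"] = pen
                df.loc[chosen, "designated"] = True
                claimed[in_gene] = True
            elif g.gene_id in preset.site_fraction_overrides:
                frac = preset.site_fraction_overrides[g.gene_id]
                idx = np.flatnonzero(in_gene)
                k = _round_count(frac, len(idx))
                chosen = rng.choice(idx, size=k, replace=False)
                df.loc[chosen, ["p_full", "p_hemi_w", "p_hemi_c"]] = base_probs[:3]
                df.loc[chosen, "designated"] = True
                claimed[in_gene] = True
        rest = np.flatnonzero(~claimed)
        k = _round_count(preset.apt_fraction, len(rest))
        if k:
            chosen = rng.choice(rest, size=k, replace=False)
            df.loc[chosen, ["p_full", "p_hemi_w", "p_hemi_c"]] = base_probs[:3]
            df.loc[chosen, "designated"] = True
        frames.append(df)
    sites = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "gene_id", "designated", "p_full", "p_hemi_w", "p_hemi_c"])
    sites["p_watson"] = sites["p_full"] + sites["p_hemi_w"]
    sites["p_crick"] = sites["p_full"] + sites["p_hemi_c"]
    return sites


def simulate_molecules(genome: SimGenome, preset: MethylationPreset,
                       n_molecules: int, mean_len: int, seed: int,
                       ) -> tuple[list[SingleMolecule], GroundTruth]:
    """Simulate CCS single molecules with per-position IPD ratios.

    Molecule intervals are uniform over each chromosome; every covered
    position carries one Watson and one Crick record. Duplex states are
    drawn i.i.d. per molecule from the site-specific state probabilities;
    a ``dispersed_fraction`` of molecules receives extra multiplicative IPD
    noise (global dispersion artifact) and an ``nstar_fraction`` an inserted
    run of high-IPD non-A positions (local N* artifact).
    """
    if mean_len < 500:
        raise ValueError("mean_len must be >= 500")
    rng = np.random.default_rng(seed)
    sites = _designate_sites(genome, preset, rng)
    truth = _ground_truth_skeleton(genome, sites)
    if n_molecules == 0:
        truth.molecule_table = pd.DataFrame(
            columns=["molecule_id", "chrom", "passes", "dispersed", "nstar"])
        truth.duplex_states = pd.DataFrame(columns=["molecule_id", "chrom", "pos", "state"])
        return [], truth

    chroms = list(genome.seq_codes)
    chrom_lens = np.array([genome.chrom_len(c) for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_molecules, p=chrom_lens / chrom_lens.sum())
    lens = rng.integers(int(0.8 * mean_len), int(1.2 * mean_len) + 1, size=n_molecules)
    lens = np.minimum(lens, chrom_lens[chrom_idx].astype(int))
    starts = (rng.random(n_molecules) * (chrom_lens[chrom_idx] - lens + 1)).astype(int)
    passes = rng.integers(preset.passes_range[0], preset.passes_range[1] + 1, size=n_molecules)
    dispersed = rng.random(n_molecules) < preset.dispersed_fraction
    nstar = rng.random(n_molecules) < preset.nstar_fraction
    mol_sd = np.where(dispersed, preset.dispersed_sd, preset.base_sd)

    molecules: list[SingleMolecule] = []
    state_rows: list[pd.DataFrame] = []
    state_counts = np.zeros(4, dtype=np.int64)
    em = preset.emissions
    for ci, chrom in enumerate(chroms):
        codes = genome.seq_codes[chrom]
        mmask = chrom_idx == ci
        midx = np.flatnonzero(mmask)
        if len(midx) == 0:
            continue
        s_chr = sites[sites["chrom"] == chrom]
        site_pos = s_chr["pos"].to_numpy()
        site_cum = np.cumsum(
            s_chr[["p_full", "p_hemi_w", "p_hemi_c"]].to_numpy(), axis=1)

        l_arr = lens[midx]
        s_arr = starts[midx]
        offsets = np.concatenate([[0], np.cumsum(l_arr)])
        total = int(offsets[-1])
        row = np.arange(total)
        mol_of = np.repeat(np.arange(len(midx)), l_arr)
        pos_flat = row - offsets[mol_of] + s_arr[mol_of]
        wbase = codes[pos_flat]
        cbase = complement_codes(wbase)

        # duplex states per (molecule, covered site); both adenines must be
        # inside the mapped interval, so the Watson A is at pos <= end - 2
        lo = np.searchsorted(site_pos, s_arr)
        hi = np.searchsorted(site_pos, s_arr + l_arr - 1)
        n_cov = hi - lo
        site_flat = np.concatenate(
            [np.arange(a, b) for a, b in zip(lo, hi)]) if n_cov.sum() else np.array([], int)
        smol = np.repeat(np.arange(len(midx)), n_cov)
        u = rng.random(len(site_flat))
        state = (u[:, None] > site_cum[site_flat]).sum(axis=1).astype(np.int8)
        state_counts += np.bincount(state, minlength=4)

        w_meth = np.zeros(total, dtype=bool)
        c_meth = np.zeros(total, dtype=bool)
        dpos = site_pos[site_flat]
        rows_w = offsets[smol] + dpos - s_arr[smol]
        w_meth[rows_w[(state == 0) | (state == 1)]] = True
        rows_c = rows_w + 1
        c_meth[rows_c[(state == 0) | (state == 2)]] = True

        sd_flat = mol_sd[midx][mol_of]
        w_ipd = _draw_ipds(rng, wbase, w_meth, sd_flat, em)
        c_ipd = _draw_ipds(rng, cbase, c_meth, sd_flat, em)

        # local N* artifacts: a run of high-IPD non-A positions on one strand
        for j in np.flatnonzero(nstar[midx]):
            strand_ipd, strand_base = (w_ipd, wbase) if rng.random() < 0.5 else (c_ipd, cbase)
            sl = slice(offsets[j], offsets[j + 1])
            non_a = np.flatnonzero(strand_base[sl] != 0) + offsets[j]
            run = int(rng.integers(preset.nstar_run[0], preset.nstar_run[1] + 1))
            if len(non_a) < run:
                continue
            k0 = int(rng.integers(0, len(non_a) - run + 1))
            sel = non_a[k0:k0 + run]
            strand_ipd[sel] = np.exp(em.meth_loc + em.meth_scale * rng.standard_normal(run))

        for j, mi in enumerate(midx):
            sl = slice(int(offsets[j]), int(offsets[j + 1]))
            p = pos_flat[sl]
            molecules.append(SingleMolecule(
                molecule_id=f"m{mi:06d}", chrom=chrom,
                start=int(s_arr[j]), end=int(s_arr[j] + l_arr[j]),
                passes=int(passes[mi]),
                watson_pos=p, watson_base=wbase[sl], watson_ipd=w_ipd[sl],
                crick_pos=p.copy(), crick_base=cbase[sl], crick_ipd=c_ipd[sl]))
        state_rows.append(pd.DataFrame({
            "molecule_id": np.array([f"m{mi:06d}" for mi in midx])[smol],
            "chrom": chrom, "pos": dpos, "state": state}))

    molecules.sort(key=lambda m: m.molecule_id)
    truth.molecule_table = pd.DataFrame({
        "molecule_id": [f"m{i:06d}" for i in range(n_molecules)],
        "chrom": [chroms[i] for i in chrom_idx],
        "passes": passes, "dispersed": dispersed, "nstar": nstar})
    truth.duplex_states = (pd.concat(state_rows, ignore_index=True)
                           if state_rows else
                           pd.DataFrame(columns=["molecule_id", "chrom", "pos", "state"]))
    truth.state_counts = state_counts
    return molecules, truth


def _draw_ipds(rng: np.random.Generator, base: np.ndarray, meth: np.ndarray,
               mol_sd: np.ndarray, em: EmissionModel) -> np.ndarray:
    loc = np.where(base == 0, em.unmeth_loc, em.non_a_loc)
    scale = np.where(base == 0, em.unmeth_scale, em.non_a_scale)
    loc = np.where(meth, em.meth_loc, loc)
    scale = np.where(meth, em.meth_scale, scale)
    total = np.sqrt(scale ** 2 + mol_sd ** 2)
    return np.exp(loc + total * rng.standard_normal(len(base)))


def _ground_truth_skeleton(genome: SimGenome, sites: pd.DataFrame) -> GroundTruth:
    gene_sigma = {}
    for g in genome.genes:
        sel = sites[(sites["chrom"] == g.chrom)
                    & (sites["pos"] >= g.start) & (sites["pos"] < g.end)]
        gene_sigma[g.gene_id] = float((sel["p_watson"] + sel["p_crick"]).sum())
    n_total = len(sites)
    return GroundTruth(
        site_table=sites[["chrom", "pos", "gene_id", "designated",
                          "p_watson", "p_crick"]].copy(),
        gene_sigma_p=pd.Series(gene_sigma, name="sigma_p"),
        molecule_table=pd.DataFrame(),
        duplex_states=pd.DataFrame(),
        apt_fraction=(sites["designated"].sum() / n_total) if n_total else float("nan"),
    )


def simulate_fragments(dyads: np.ndarray, positioning: float, n_fragments: int,
                       frag_len_range: tuple[int, int] = (120, 260),
                       seed: int = 0, chrom: str = "chr1") -> pd.DataFrame:
    """MNase-like fragments whose midpoints cluster around nucleosome dyads.

    Midpoints are a mixture of uniform draws over the tight (+/-25 bp) and
    loose (+/-75 bp) windows, weighted so the expected measured positioning
    degree equals ``positioning``. Values below the statistic's floor of
    51/151 (fully uniform placement) are clamped to the floor.
    """
    if not 0.0 <= positioning <= 1.0:
        raise ValueError("positioning must be in [0, 1]")
    dyads = np.asarray(dyads, dtype=np.int64)
    if dyads.size == 0:
        raise ValueError("dyads must be non-empty")
    rng = np.random.default_rng(seed)
    w = max(0.0, (positioning - DEGREE_FLOOR) / (1.0 - DEGREE_FLOOR))
    centers = rng.choice(dyads, size=n_fragments)
    tight = rng.random(n_fragments) < w
    offs = np.where(tight, rng.integers(-25, 26, size=n_fragments),
                    rng.integers(-75, 76, size=n_fragments))
    mid = centers + offs
    length = rng.integers(frag_len_range[0], frag_len_range[1] + 1, size=n_fragments)
    start = mid - length // 2
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})


@dataclass
class SampleCounts:
    """Gene x sample count matrix with per-sample spike-in totals."""

    counts: pd.DataFrame
    spike_totals: pd.Series


@dataclass
class CountsTruth:
    log2_fold_change: np.ndarray
    size_factors: np.ndarray  # true factors, geometric-mean centred
    treated: np.ndarray
    baseline: np.ndarray


def simulate_counts(n_genes: int, n_samples: int, fold_changes: np.ndarray,
                    spike_true_factors: np.ndarray, dispersion: float, seed: int,
                    baseline_mean: float = 500.0, treated: np.ndarray | None = None,
                    spike_mean: float = 1_000_000.0,
                    ) -> tuple[SampleCounts, CountsTruth]:
    """Negative-binomial RNA-seq counts with Poisson spike-in totals.

    ``fold_changes`` (per-gene log2FC) applies to samples flagged in
    ``treated`` (default: second half); means are
    baseline * 2^(lfc * treated) * factor. ``dispersion`` is the NB
    dispersion alpha with var = mu + alpha * mu^2.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    spike_true_factors = np.asarray(spike_true_factors, dtype=float)
    if np.any(spike_true_factors <= 0):
        raise ValueError("spike_true_factors must be > 0")
    if len(spike_true_factors) != n_samples:
        raise ValueError("spike_true_factors length must equal n_samples")
    fold_changes = np.broadcast_to(np.asarray(fold_changes, dtype=float), (n_genes,))
    if treated is None:
        treated = np.arange(n_samples) >= n_samples // 2
    treated = np.asarray(treated, dtype=bool)
    rng = np.random.default_rng(seed)
    baseline = np.full(n_genes, float(baseline_mean))
    mu = baseline[:, None] * (2.0 ** (fold_changes[:, None] * treated[None, :]))
    mu = mu * spike_true_factors[None, :]
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    spikes = rng.poisson(spike_mean * spike_true_factors)
    samples = [f"s{j}" for j in range(n_samples)]
    sc = SampleCounts(
        counts=pd.DataFrame(counts, index=[f"gene{i:04d}" for i in range(n_genes)],
                            columns=samples),
        spike_totals=pd.Series(spikes, index=samples, name="spike_total"))
    centred = spike_true_factors / np.exp(np.mean(np.log(spike_true_factors)))
    return sc, CountsTruth(fold_changes.copy(), centred, treated, baseline)


def simulate_rt_qpcr(true_fold: float, noise_sd: float = 0.1, seed: int = 0,
                     n_rep: int = 3):
    """Ct tables for a two-strain RT-qPCR with a known expression fold.

    Returns (target_gene, target_internal, control_gene, control_internal)
    CtRecords; the target strain expresses the gene ``true_fold``-fold
    relative to the control strain against a shared internal control.
    """
    from .assay_stats import CtRecord

    rng = np.random.default_rng(seed)

    def rec(target, role, mean):
        return CtRecord(target, role, tuple(mean + noise_sd * rng.standard_normal(n_rep)))

    return (rec("gene", "target_strain", 22.0 - math.log2(true_fold)),
            rec("internal", "target_strain", 20.0),
            rec("gene", "control_strain", 22.0),
            rec("internal", "control_strain", 20.0))
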