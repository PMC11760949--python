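"""Single-molecule quality control for SMRT-CCS kinetics.

Three per-molecule filters, applied independently:

* consensus passes >= 20 (high-confidence molecules only);
* global dispersion: sample SD of IPD ratios over unmethylated adenines
  (IPD < 2.8) >= 0.35 on the Watson and/or Crick strand removes the
  molecule;
* local N* artifacts: a same-strand chain of >= 4 non-A positions with
  IPD >= 2.8 whose successive gaps are <= 25 bp removes the molecule.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import SingleMolecule

DEFAULT_MIN_PASSES = 20
DEFAULT_UNMETH_CUTOFF = 2.8
DEFAULT_SD_CUTOFF = 0.35
DEFAULT_NSTAR_IPD = 2.8
DEFAULT_NSTAR_GAP = 25
DEFAULT_NSTAR_COUNT = 4


def filter_passes(molecules: list[SingleMolecule],
                  min_passes: int = DEFAULT_MIN_PASSES) -> list[SingleMolecule]:
    """Retain molecules with passes >= min_passes (inclusive), order preserved."""
    if min_passes < 1:
        raise ValueError("min_passes must be >= 1")
    return [m for m in molecules if m.passes >= min_passes]


@dataclass
class DispersionResult:
    keep: bool
    sd_watson: float  # NaN when < 2 qualifying adenines
    sd_crick: float
    no_adenine: bool = False


def global_dispersion_filter(molecule: SingleMolecule,
                             unmeth_cutoff: float = DEFAULT_UNMETH_CUTOFF,
                             sd_cutoff: float = DEFAULT_SD_CUTOFF) -> DispersionResult:
    """Flag globally dispersed molecules by per-strand unmethylated-A IPD SD.

    Sample SD (n-1 denominator) over adenine positions with IPD below the
    unmethylated cutoff; a strand with fewer than two qualifying adenines
    contributes no SD and cannot trigger removal. A molecule with no
    adenines at all is kept and flagged.
    """
    sds = []
    n_adenine = 0
    for base, ipd in ((molecule.watson_base, molecule.watson_ipd),
                      (molecule.crick_base, molecule.crick_ipd)):
        is_a = base == 0
        n_adenine += int(is_a.sum())
        vals = ipd[is_a & (ipd < unmeth_cutoff)]
        sds.append(float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan"))
    remove = any(np.isfinite(s) and s >= sd_cutoff for s in sds)
    return DispersionResult(keep=not remove, sd_watson=sds[0], sd_crick=sds[1],
                            no_adenine=n_adenine == 0)


@dataclass
class ArtifactResult:
    keep: bool
    clusters: list[tuple[str, np.ndarray]] = field(default_factory=list)


def local_artifact_filter(molecule: SingleMolecule,
                          nstar_ipd: float = DEFAULT_NSTAR_IPD,
                          max_gap: int = DEFAULT_NSTAR_GAP,
                          min_count: int = DEFAULT_NSTAR_COUNT) -> ArtifactResult:
    """Detect same-strand chains of high-IPD non-A positions (N* clusters).

    Positions are chained while each successive gap is <= max_gap; any chain
    with >= min_count members removes the molecule. Strands are never pooled.
    """
    clusters: list[tuple[str, np.ndarray]] = []
    for name, pos, base, ipd in (("W", molecule.watson_pos, molecule.watson_base, molecule.watson_ipd),
                                 ("C", molecule.crick_pos, molecule.crick_base, molecule.crick_ipd)):
        hits = np.sort(pos[(base != 0) & (ipd >= nstar_ipd)])
        if len(hits) < min_count:
            continue
        breaks = np.flatnonzero(np.diff(hits) > max_gap)
        for chain in np.split(hits, breaks + 1):
            if len(chain) >= min_count:
                clusters.append((name, chain))
    return ArtifactResult(keep=not clusters, clusters=clusters)


@dataclass
class QCReport:
    n_input: int
    n_fail_passes: int
    n_removed_global: int
    n_removed_local: int
    n_retained: int
    per_molecule: pd.DataFrame  # molecule_id, passes, reason ('' if retained)

    def validate(self) -> None:
        if self.n_input != (self.n_retained + self.n_fail_passes
                            + self.n_removed_global + self.n_removed_local):
            raise AssertionError("QC tallies do not sum to input count")


def run_qc(molecules: list[SingleMolecule],
           min_passes: int = DEFAULT_MIN_PASSES,
           unmeth_cutoff: float = DEFAULT_UNMETH_CUTOFF,
           sd_cutoff: float = DEFAULT_SD_CUTOFF,
           nstar_ipd: float = DEFAULT_NSTAR_IPD,
           nstar_gap: int = DEFAULT_NSTAR_GAP,
           nstar_count: int = DEFAULT_NSTAR_COUNT,
           ) -> tuple[list[SingleMolecule], QCReport]:
    """Apply passes, global-dispersion and local-artifact filters in order.

    A molecule is retained iff it passes all three; removals are attributed
    to the first failing filter for the report.
    """
    retained: list[SingleMolecule] = []
    ids, passes_col, reasons = [], [], []
    n_pass_fail = n_global = n_local = 0
    for m in molecules:
        ids.append(m.molecule_id)
        passes_col.append(m.passes)
        if m.passes < min_passes:
            n_pass_fail += 1
            reasons.append("passes")
            continue
        if not global_dispersion_filter(m, unmeth_cutoff, sd_cutoff).keep:
            n_global += 1
            reasons.append("global_dispersion")
            continue
        if not local_artifact_filter(m, nstar_ipd, nstar_gap, nstar_count).keep:
            n_local += 1
            reasons.append("local_nstar")
            continue
        reasons.append("")
        retained.append(m)
    report = QCReport(
        n_input=len(molecules), n_fail_passes=n_pass_fail,
        n_removed_global=n_global, n_removed_local=n_local,
        n_retained=len(retained),
        per_molecule=pd.DataFrame({"molecule_id": ids, "passes": passes_col,
                                   "reason": reasons}))
    report.validate()
    return retained, report
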