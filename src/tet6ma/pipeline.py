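"""End-to-end composition: simulate -> QC -> threshold -> calls -> statistics."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import methylation_calling as mc
from . import molecule_qc as qc
from .models import GroundTruth, SimGenome, SingleMolecule
from .molecule_qc import QCReport
from .synthetic_data import MethylationPreset, simulate_molecules


def pooled_adenine_ipds(molecules: list[SingleMolecule]) -> np.ndarray:
    """All adenine IPD ratios of both strands, pooled across molecules."""
    chunks = []
    for m in molecules:
        chunks.append(m.watson_ipd[m.watson_base == 0])
        chunks.append(m.crick_ipd[m.crick_base == 0])
    return np.concatenate(chunks) if chunks else np.array([])


@dataclass
class PipelineResult:
    genome: SimGenome
    truth: GroundTruth
    qc_report: QCReport
    threshold: mc.IpdThreshold
    calls: pd.DataFrame
    table: pd.DataFrame

    @property
    def genome_fraction(self) -> float:
        return mc.genome_6mApT_fraction(self.table)

    @property
    def full_hemi(self) -> float:
        return mc.full_hemi_ratio(self.calls)

    def gene_stats(self) -> pd.DataFrame:
        return mc.gene_methylation(self.genome.genes, self.table)


def run_methylation_pipeline(genome: SimGenome, preset: MethylationPreset,
                             n_molecules: int, mean_len: int, seed: int,
                             ) -> PipelineResult:
    """Simulate a molecule batch and run QC, threshold fitting and calling."""
    rng = np.random.SeedSequence(seed)
    sim_seed, fit_seed = (int(s.generate_state(1)[0] % (2 ** 31)) for s in rng.spawn(2))
    molecules, truth = simulate_molecules(genome, preset, n_molecules, mean_len, sim_seed)
    retained, report = qc.run_qc(molecules)
    threshold = mc.fit_ipd_threshold(pooled_adenine_ipds(retained), seed=fit_seed)
    calls = mc.call_duplexes(retained, genome, threshold)
    table = mc.penetrance_table(calls)
    return PipelineResult(genome, truth, report, threshold, calls, table)
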