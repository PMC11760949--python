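"""Shared data containers for the 6mA analysis pipeline.

Coordinates are 0-based, half-open throughout. An ApT duplex site is
addressed by the position of its Watson-strand adenine; the paired Crick
adenine sits at position + 1 on the complementary strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with orientation.

    TSS/TES follow the half-open convention: for a plus-strand gene the TSS
    is ``start``; for a minus-strand gene it is ``end`` (the first
    transcribed base is ``end - 1``).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimGenome:
    """Synthetic genome: sequences, annotated genes and ApT duplex sites."""

    seq_codes: dict[str, np.ndarray]  # uint8 codes, 0=A 1=C 2=G 3=T
    genes: list[GeneModel]
    apt_positions: dict[str, np.ndarray]  # Watson-A positions per chromosome

    @property
    def sequences(self) -> dict[str, str]:
        return {c: "".join(BASES[v]) for c, v in self.seq_codes.items()}

    @property
    def apt_sites(self) -> list[tuple[str, int]]:
        return [(c, int(p)) for c, arr in self.apt_positions.items() for p in arr]

    @property
    def n_apt(self) -> int:
        return sum(len(v) for v in self.apt_positions.values())

    def chrom_len(self, chrom: str) -> int:
        return len(self.seq_codes[chrom])

    def validate(self) -> None:
        for chrom, pos in self.apt_positions.items():
            codes = self.seq_codes[chrom]
            if len(pos) and (np.any(codes[pos] != 0) or np.any(codes[pos + 1] != 3)):
                raise AssertionError(f"{chrom}: ApT site without A followed by T")
        spans: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            if g.start < 0 or g.end > self.chrom_len(g.chrom):
                raise AssertionError(f"gene {g.gene_id} outside chromosome bounds")
            spans.setdefault(g.chrom, []).append((g.start, g.end))
        for chrom, ivs in spans.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise AssertionError(f"{chrom}: overlapping genes")


@dataclass
class SingleMolecule:
    """One mapped CCS molecule with per-position IPD ratios on both strands.

    Watson records lie on the reference forward strand; Crick records use
    the same coordinate axis. Positions are sorted and unique per strand.
    """

    molecule_id: str
    chrom: str
    start: int
    end: int
    passes: int
    watson_pos: np.ndarray
    watson_base: np.ndarray  # uint8 base codes on Watson
    watson_ipd: np.ndarray
    crick_pos: np.ndarray
    crick_base: np.ndarray  # uint8 base codes of the Crick strand itself
    crick_ipd: np.ndarray

    def validate(self) -> None:
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        for pos, ipd in ((self.watson_pos, self.watson_ipd), (self.crick_pos, self.crick_ipd)):
            if len(pos) and (pos.min() < self.start or pos.max() >= self.end):
                raise ValueError("record outside mapped interval")
            if len(np.unique(pos)) != len(pos):
                raise ValueError("duplicate (position, strand) record")
            if not np.all(np.isfinite(ipd)) or np.any(ipd < 0):
                raise ValueError("IPD ratios must be finite and >= 0")


@dataclass
class GroundTruth:
    """Exported generator truth for one simulated molecule batch."""

    site_table: pd.DataFrame  # chrom, pos, designated, p_watson, p_crick, gene_id
    gene_sigma_p: pd.Series  # gene_id -> true sum of per-adenine penetrance
    molecule_table: pd.DataFrame  # molecule_id, passes, dispersed, nstar
    duplex_states: pd.DataFrame  # molecule_id, chrom, pos, state code
    state_counts: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))
    apt_fraction: float = float("nan")  # designated / total ApT duplexes

    @property
    def full_hemi(self) -> float:
        hemi = self.state_counts[1] + self.state_counts[2]
        if hemi == 0:
            return float("inf") if self.state_counts[0] else float("nan")
        return self.state_counts[0] / hemi


STATE_NAMES = np.array(["Full", "Hemi-W", "Hemi-C", "Un"])
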