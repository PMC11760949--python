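"""ΔΔCt arithmetic for 6mA-IP qPCR enrichment and RT-qPCR expression.

Technical replicates are averaged to a mean Ct; fold values use the
standard Livak form 2^(−ΔΔCt).

IP enrichment:  ΔCt = Ct(IP) − Ct(Input);
                ΔΔCt = ΔCt(methylated gene) − ΔCt(unmethylated rDNA).
RT expression:  ΔCt = Ct(target gene) − Ct(internal control);
                ΔΔCt = ΔCt(target strain) − ΔCt(control strain).
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CtRecord:
    target: str
    role: str
    replicates: tuple[float, ...]

    def __post_init__(self):
        if not self.replicates:
            raise ValueError("CtRecord needs at least one replicate")
        if any(ct <= 0 for ct in self.replicates):
            raise ValueError("Ct values must be > 0")

    @property
    def mean_ct(self) -> float:
        return sum(self.replicates) / len(self.replicates)


@dataclass(frozen=True)
class DdctResult:
    delta_ct_target: float
    delta_ct_reference: float
    ddct: float
    fold: float


def _require(record: CtRecord | None, name: str) -> CtRecord:
    if record is None:
        raise ValueError(f"missing Ct record: {name}")
    return record


def ip_qpcr_enrichment(target_ip: CtRecord, target_input: CtRecord,
                       reference_ip: CtRecord, reference_input: CtRecord) -> DdctResult:
    """Fold 6mA-IP enrichment of a methylated target over unmethylated rDNA."""
    t_ip = _require(target_ip, "target IP")
    t_in = _require(target_input, "target Input")
    r_ip = _require(reference_ip, "reference IP")
    r_in = _require(reference_input, "reference Input")
    d_target = t_ip.mean_ct - t_in.mean_ct
    d_ref = r_ip.mean_ct - r_in.mean_ct
    ddct = d_target - d_ref
    return DdctResult(d_target, d_ref, ddct, 2.0 ** (-ddct))


def rt_qpcr_relative_expression(target_gene: CtRecord, target_internal: CtRecord,
                                control_gene: CtRecord, control_internal: CtRecord,
                                ) -> DdctResult:
    """Relative mRNA level of a target strain versus a control strain."""
    tg = _require(target_gene, "target-strain gene")
    ti = _require(target_internal, "target-strain internal control")
    cg = _require(control_gene, "control-strain gene")
    ci = _require(control_internal, "control-strain internal control")
    d_target = tg.mean_ct - ti.mean_ct
    d_control = cg.mean_ct - ci.mean_ct
    ddct = d_target - d_control
    return DdctResult(d_target, d_control, ddct, 2.0 ** (-ddct))
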