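"""QC filter behaviour: boundaries, oracles and recovery of injected artifacts."""
import numpy as np
import pytest
from dataclasses import replace

from tet6ma import PRESETS, make_genome, simulate_molecules
from tet6ma.molecule_qc import (filter_passes, global_dispersion_filter,
                                local_artifact_filter, run_qc)

from conftest import build_molecule


def brute_force_strand_sd(ipds, cutoff=2.8):
    """Independent sample-SD oracle over unmethylated adenines (plain python)."""
    vals = [x for x in ipds if x < cutoff]
    if len(vals) < 2:
        return None
    mean = sum(vals) / len(vals)
    return (sum((x - mean) ** 2 for x in vals) / (len(vals) - 1)) ** 0.5


def brute_force_nstar(positions, ipds, bases, nstar_ipd=2.8, max_gap=25, min_count=4):
    """Independent chain oracle: walk sorted qualifying positions in python."""
    hits = sorted(p for p, b, x in zip(positions, bases, ipds)
                  if b != "A" and x >= nstar_ipd)
    run = 0
    prev = None
    best = 0
    for p in hits:
        run = run + 1 if prev is not None and p - prev <= max_gap else 1
        best = max(best, run)
        prev = p
    return best >= min_count


class TestFilterPasses:
    def test_boundary_is_inclusive(self):
        m20 = build_molecule(watson=[(0, "A", 1.0)], passes=20)
        m19 = build_molecule(watson=[(0, "A", 1.0)], passes=19)
        assert filter_passes([m20, m19]) == [m20]

    def test_empty_input(self):
        assert filter_passes([]) == []

    def test_invalid_min_passes(self):
        with pytest.raises(ValueError):
            filter_passes([], min_passes=0)


class TestGlobalDispersion:
    def test_identical_ipds_kept(self):
        m = build_molecule(watson=[(i, "A", 1.2) for i in range(5)],
                           crick=[(i, "A", 1.2) for i in range(5)])
        assert global_dispersion_filter(m).keep

    def test_hand_computed_sd_removes(self):
        # sample SD of {1.0, 1.7} = 0.7/sqrt(2) ~ 0.495 >= 0.35
        m = build_molecule(watson=[(0, "A", 1.0), (10, "A", 1.7)])
        res = global_dispersion_filter(m)
        assert not res.keep
        assert res.sd_watson == pytest.approx(0.7 / np.sqrt(2), abs=1e-12)

    def test_cutoff_boundary_is_inclusive(self):
        m = build_molecule(watson=[(0, "A", 1.0), (10, "A", 1.7)])
        sd = global_dispersion_filter(m).sd_watson
        assert not global_dispersion_filter(m, sd_cutoff=sd).keep  # SD == cutoff removes
        assert global_dispersion_filter(m, sd_cutoff=np.nextafter(sd, 1)).keep

    def test_high_ipd_adenines_excluded_from_sd(self):
        # one methylated-looking adenine (IPD 5.0) must not inflate the SD
        m = build_molecule(watson=[(0, "A", 1.0), (5, "A", 1.0), (9, "A", 5.0)])
        res = global_dispersion_filter(m)
        assert res.keep and res.sd_watson == 0.0

    def test_single_qualifying_adenine_does_not_trigger(self):
        m = build_molecule(watson=[(0, "A", 1.0)], crick=[(0, "T", 1.0)])
        res = global_dispersion_filter(m)
        assert res.keep and np.isnan(res.sd_watson)

    def test_no_adenine_molecule_kept_and_flagged(self):
        m = build_molecule(watson=[(0, "C", 1.0)], crick=[(0, "G", 1.0)])
        res = global_dispersion_filter(m)
        assert res.keep and res.no_adenine


class TestLocalArtifacts:
    def test_four_chained_nstar_positions_remove(self):
        m = build_molecule(watson=[(p, "C", 3.0) for p in (100, 110, 120, 130)])
        assert not local_artifact_filter(m).keep

    def test_three_positions_kept(self):
        m = build_molecule(watson=[(p, "C", 3.0) for p in (100, 110, 120)])
        assert local_artifact_filter(m).keep

    def test_strands_not_pooled(self):
        m = build_molecule(watson=[(100, "C", 3.0), (110, "C", 3.0)],
                           crick=[(100, "G", 3.0), (110, "G", 3.0)])
        assert local_artifact_filter(m).keep

    def test_gap_boundary_inclusive_and_exclusive(self):
        chained = build_molecule(watson=[(0, "C", 2.8), (25, "C", 2.8),
                                         (50, "C", 2.8), (75, "C", 2.8)])
        assert not local_artifact_filter(chained).keep
        broken = build_molecule(watson=[(0, "C", 2.8), (26, "C", 2.8),
                                        (52, "C", 2.8), (78, "C", 2.8)])
        assert local_artifact_filter(broken).keep

    def test_adenines_never_count_as_nstar(self):
        m = build_molecule(watson=[(p, "A", 5.0) for p in (100, 110, 120, 130)])
        assert local_artifact_filter(m).keep


def _random_molecule(rng):
    n = rng.integers(2, 200)
    pos = np.sort(rng.choice(400, size=n, replace=False))
    bases = rng.choice(list("ACGT"), size=n, p=[0.4, 0.15, 0.15, 0.3])
    # IPD values concentrated around the 2.8 decision boundary and 25-bp gaps
    ipds = rng.choice([1.0, 2.0, 2.79, 2.8, 3.5, 6.0], size=n)
    recs = list(zip(pos.tolist(), bases.tolist(), ipds.tolist()))
    half = rng.integers(0, n + 1)
    return build_molecule(watson=recs[:half], crick=recs[half:],
                          start=0, end=400)


class TestOracleEquivalence:
    def test_filters_agree_with_brute_force_on_random_molecules(self):
        """Vectorized SD / chain detection matches plain-python enumeration."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            m = _random_molecule(rng)
            res = global_dispersion_filter(m)
            for sd, pos, base, ipd in ((res.sd_watson, m.watson_pos, m.watson_base, m.watson_ipd),
                                       (res.sd_crick, m.crick_pos, m.crick_base, m.crick_ipd)):
                oracle = brute_force_strand_sd(ipd[base == 0].tolist())
                if oracle is None:
                    assert np.isnan(sd)
                else:
                    assert sd == pytest.approx(oracle, abs=1e-12)
            expect_remove = any(
                brute_force_nstar(p.tolist(), i.tolist(), ["ACGT"[b] for b in bs])
                for p, bs, i in ((m.watson_pos, m.watson_base, m.watson_ipd),
                                 (m.crick_pos, m.crick_base, m.crick_ipd)))
            assert local_artifact_filter(m).keep == (not expect_remove)


class TestRunQc:
    def test_bookkeeping_attributes_first_failing_filter(self):
        ok = build_molecule(watson=[(i, "A", 1.0) for i in range(5)], passes=30,
                            molecule_id="ok")
        low_passes = build_molecule(watson=[(i, "A", 1.0) for i in range(5)],
                                    passes=5, molecule_id="lp")
        dispersed = build_molecule(watson=[(0, "A", 1.0), (5, "A", 2.5)],
                                   passes=30, molecule_id="gd")
        nstar = build_molecule(watson=[(i, "A", 1.0) for i in range(5)]
                               + [(10 + 5 * k, "C", 4.0) for k in range(4)],
                               passes=30, molecule_id="ns")
        retained, report = run_qc([ok, low_passes, dispersed, nstar])
        assert [m.molecule_id for m in retained] == ["ok"]
        assert (report.n_input, report.n_fail_passes, report.n_removed_global,
                report.n_removed_local, report.n_retained) == (4, 1, 1, 1, 1)
        reasons = dict(zip(report.per_molecule.molecule_id, report.per_molecule.reason))
        assert reasons == {"ok": "", "lp": "passes", "gd": "global_dispersion",
                           "ns": "local_nstar"}

    def test_removal_is_order_independent(self):
        rng = np.random.default_rng(3)
        mols = [_random_molecule(rng) for _ in range(50)]
        retained, _ = run_qc(mols, min_passes=1)
        expected = [m for m in mols
                    if global_dispersion_filter(m).keep and local_artifact_filter(m).keep]
        assert [m.molecule_id for m in retained] == [m.molecule_id for m in expected]

    def test_artifact_free_batch_retention_over_95pct(self, small_genome):
        preset = replace(PRESETS["WT"], dispersed_fraction=0.0,
                         nstar_fraction=0.0, passes_range=(20, 40))
        mols, _ = simulate_molecules(small_genome, preset, 300, 500, seed=8)
        retained, report = run_qc(mols)
        assert report.n_retained / report.n_input >= 0.95

    def test_injected_dispersed_molecules_recalled(self, small_genome):
        preset = replace(PRESETS["WT"], dispersed_fraction=0.10, nstar_fraction=0.0)
        mols, truth = simulate_molecules(small_genome, preset, 400, 500, seed=9)
        _, report = run_qc(mols, min_passes=1)
        merged = report.per_molecule.merge(truth.molecule_table, on="molecule_id")
        injected = merged[merged.dispersed]
        assert len(injected) > 10
        recall = (injected.reason == "global_dispersion").mean()
        assert recall >= 0.9

    def test_injected_nstar_molecules_recalled(self, small_genome):
        preset = replace(PRESETS["WT"], dispersed_fraction=0.0, nstar_fraction=0.10)
        mols, truth = simulate_molecules(small_genome, preset, 400, 500, seed=10)
        _, report = run_qc(mols, min_passes=1)
        merged = report.per_molecule.merge(truth.molecule_table, on="molecule_id")
        injected = merged[merged.nstar]
        assert len(injected) > 10
        assert (injected.reason == "local_nstar").mean() >= 0.9
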