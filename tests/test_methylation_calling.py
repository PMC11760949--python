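"""Threshold deconvolution, duplex calling and methylation summaries."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tet6ma import PRESETS, make_genome, run_methylation_pipeline
from tet6ma.methylation_calling import (call_duplexes, fit_ipd_threshold,
                                        full_hemi_ratio, gene_methylation,
                                        genome_6mApT_fraction, metagene_profile,
                                        penetrance_table)
from tet6ma.models import GeneModel

from conftest import build_molecule


def grid_equal_posterior(w, mu, sigma, lo=0.05, hi=None):
    """Dense-grid oracle for the equal-posterior crossing on the ln scale."""
    hi = hi if hi is not None else max(mu) - 0.01
    xs = np.linspace(lo, hi, 200_001)
    diff = (np.log(w[0]) + stats.norm.logpdf(xs, mu[0], sigma[0])
            - np.log(w[1]) - stats.norm.logpdf(xs, mu[1], sigma[1]))
    return float(np.exp(xs[np.argmin(np.abs(diff))]))


class TestFitIpdThreshold:
    def test_bimodal_pool_matches_grid_oracle(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([np.exp(0.25 * rng.standard_normal(5_000)),
                               np.exp(np.log(5) + 0.30 * rng.standard_normal(5_000))])
        thr = fit_ipd_threshold(vals, seed=1)
        assert thr.bimodal
        assert 2.0 <= thr.cutoff <= 2.8
        oracle = grid_equal_posterior([0.5, 0.5], [0.0, np.log(5)], [0.25, 0.30])
        assert thr.cutoff == pytest.approx(oracle, rel=0.10)

    def test_unimodal_pool_falls_back(self):
        rng = np.random.default_rng(1)
        vals = np.exp(0.25 * rng.standard_normal(5_000))
        thr = fit_ipd_threshold(vals, seed=1)
        assert not thr.bimodal
        assert thr.cutoff == 2.8

    def test_rejects_small_or_nonfinite_input(self):
        with pytest.raises(ValueError):
            fit_ipd_threshold(np.ones(99))
        bad = np.ones(200)
        bad[0] = np.nan
        with pytest.raises(ValueError):
            fit_ipd_threshold(bad)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([np.exp(0.25 * rng.standard_normal(2_000)),
                               np.exp(np.log(5) + 0.18 * rng.standard_normal(2_000))])
        assert fit_ipd_threshold(vals, seed=5).cutoff == fit_ipd_threshold(vals, seed=5).cutoff


def _duplex_molecule(mid, w_ipd, c_ipd, pos=10):
    return build_molecule(
        molecule_id=mid,
        watson=[(pos, "A", w_ipd), (pos + 1, "T", 1.0)],
        crick=[(pos, "T", 1.0), (pos + 1, "A", c_ipd)],
        start=pos - 1, end=pos + 3)


APT = {"chr1": np.array([10])}


class TestCallDuplexes:
    @pytest.mark.parametrize("w,c,expected", [
        (5.0, 5.0, "Full"),
        (5.0, 1.0, "Hemi-W"),
        (1.0, 5.0, "Hemi-C"),
        (1.0, 1.0, "Un"),
        (2.6, 2.6, "Full"),  # tie at the cutoff called methylated
    ])
    def test_state_assignment(self, w, c, expected):
        calls = call_duplexes([_duplex_molecule("m", w, c)], APT, 2.6)
        assert list(calls.state_name) == [expected]

    def test_missing_strand_skipped_and_counted(self):
        m = build_molecule(watson=[(10, "A", 5.0), (11, "T", 1.0)],
                           crick=[(10, "T", 1.0)], start=9, end=13)
        calls = call_duplexes([m], APT, 2.6)
        assert len(calls) == 0
        assert calls.attrs["n_skipped"] == 1

    def test_molecule_without_apt_contributes_nothing(self):
        m = build_molecule(watson=[(100, "A", 5.0)], crick=[(100, "T", 1.0)],
                           start=99, end=105)
        assert len(call_duplexes([m], APT, 2.6)) == 0

    def test_state_partition_is_conserved(self, small_genome):
        res = run_methylation_pipeline(small_genome, PRESETS["WT"], 300, 500, seed=3)
        counts = np.bincount(res.calls.state, minlength=4)
        assert counts.sum() == len(res.calls)


class TestFullHemiRatio:
    def test_ratio_arithmetic(self):
        mols = ([_duplex_molecule(f"f{i}", 5.0, 5.0) for i in range(10)]
                + [_duplex_molecule(f"h{i}", 5.0, 1.0) for i in range(3)]
                + [_duplex_molecule(f"c{i}", 1.0, 5.0) for i in range(2)])
        calls = call_duplexes(mols, APT, 2.6)
        assert full_hemi_ratio(calls) == 2.0

    def test_zero_full_gives_zero(self):
        calls = call_duplexes([_duplex_molecule("h", 5.0, 1.0)], APT, 2.6)
        assert full_hemi_ratio(calls) == 0.0

    def test_no_hemi_gives_inf_sentinel(self):
        calls = call_duplexes([_duplex_molecule("f", 5.0, 5.0)], APT, 2.6)
        assert full_hemi_ratio(calls) == math.inf

    def test_empty_gives_nan(self):
        calls = call_duplexes([], APT, 2.6)
        assert math.isnan(full_hemi_ratio(calls))


class TestPenetranceTable:
    def test_three_of_ten_is_high_confidence(self):
        mols = ([_duplex_molecule(f"m{i}", 5.0, 1.0) for i in range(3)]
                + [_duplex_molecule(f"u{i}", 1.0, 1.0) for i in range(7)])
        table = penetrance_table(call_duplexes(mols, APT, 2.6))
        watson = table[table.strand == "W"].iloc[0]
        assert watson.methylated == 3 and watson.covered == 10
        assert watson.penetrance == pytest.approx(0.3)
        assert bool(watson.high_confidence)

    def test_two_of_ten_is_not_high_confidence(self):
        mols = ([_duplex_molecule(f"m{i}", 5.0, 1.0) for i in range(2)]
                + [_duplex_molecule(f"u{i}", 1.0, 1.0) for i in range(8)])
        table = penetrance_table(call_duplexes(mols, APT, 2.6))
        watson = table[table.strand == "W"].iloc[0]
        assert watson.penetrance == pytest.approx(0.2)
        assert not bool(watson.high_confidence)

    def test_full_counts_both_strands(self):
        table = penetrance_table(call_duplexes([_duplex_molecule("f", 5.0, 5.0)], APT, 2.6))
        assert set(table.strand) == {"W", "C"}
        assert (table.methylated == 1).all()
        # Crick adenine addressed at duplex position + 1
        assert set(table.pos) == {10, 11}

    def test_uncovered_sites_absent(self):
        table = penetrance_table(call_duplexes([_duplex_molecule("f", 5.0, 5.0)],
                                               {"chr1": np.array([10, 500])}, 2.6))
        assert set(table.duplex_pos) == {10}


def _toy_table(rows):
    df = pd.DataFrame(rows, columns=["chrom", "duplex_pos", "strand", "penetrance",
                                     "methylated", "covered"])
    df["pos"] = df.duplex_pos + (df.strand == "C").astype(int)
    df["high_confidence"] = df.methylated >= 3
    return df


class TestGeneMethylation:
    def test_sigma_p_sums_site_penetrance(self):
        genes = [GeneModel("g", "chr1", 0, 100, "+")]
        table = _toy_table([("chr1", 10, "W", 0.5, 5, 10), ("chr1", 20, "W", 0.25, 2, 8)])
        out = gene_methylation(genes, table).iloc[0]
        assert out.sigma_p == pytest.approx(0.75)
        assert out.n_apt == 2 and out.n_6mApT == 1
        assert out.ratio_6mApT_per_ApT == pytest.approx(0.5)

    def test_gene_without_apt_gets_nan_ratio(self):
        genes = [GeneModel("empty", "chr1", 500, 600, "+")]
        out = gene_methylation(genes, _toy_table([("chr1", 10, "W", 0.5, 5, 10)])).iloc[0]
        assert out.sigma_p == 0.0 and math.isnan(out.ratio_6mApT_per_ApT)

    def test_sigma_p_additive_over_interval_partition(self, small_genome):
        res = run_methylation_pipeline(small_genome, PRESETS["WT"], 400, 500, seed=4)
        g = small_genome.genes[0]
        mid = (g.start + g.end) // 2
        whole = gene_methylation([g], res.table).iloc[0].sigma_p
        left = gene_methylation([GeneModel("l", g.chrom, g.start, mid, g.strand)],
                                res.table).iloc[0].sigma_p
        right = gene_methylation([GeneModel("r", g.chrom, mid, g.end, g.strand)],
                                 res.table).iloc[0].sigma_p
        assert whole == pytest.approx(left + right, abs=1e-9)

    def test_all_unmethylated_preset_gives_zero_sigma_p(self, small_genome):
        from tet6ma.synthetic_data import MethylationPreset

        preset = MethylationPreset("null", 0.0, 1.0, 0.9, dispersed_fraction=0,
                                   nstar_fraction=0)
        res = run_methylation_pipeline(small_genome, preset, 200, 500, seed=5)
        stats_ = res.gene_stats()
        assert (stats_.sigma_p <= 0.2).all()  # only rare IPD-noise false calls
        assert res.truth.gene_sigma_p.eq(0).all()


class TestGenomeFraction:
    def test_fully_methylated_toy_genome(self):
        mols = [_duplex_molecule(f"m{i}", 5.0, 5.0) for i in range(5)]
        table = penetrance_table(call_duplexes(mols, APT, 2.6))
        assert genome_6mApT_fraction(table) == 1.0

    def test_empty_table_is_nan(self):
        assert math.isnan(genome_6mApT_fraction(penetrance_table(call_duplexes([], APT, 2.6))))


class TestMetageneProfile:
    def _uniform_table(self, start, end, step=10, penetrance=0.5):
        rows = [("chr1", p, "W", penetrance, 5, 10) for p in range(start, end, step)]
        return _toy_table(rows)

    def test_uniform_penetrance_gives_flat_body(self):
        genes = [GeneModel("g", "chr1", 3_000, 9_000, "+")]
        table = self._uniform_table(0, 12_000, step=4)
        prof = metagene_profile(genes, table)
        body = prof[prof.segment == "body"].sum_penetrance.to_numpy()
        assert body.std() / body.mean() < 0.1

    def test_five_prime_quarter_signal_lands_in_first_bins(self):
        genes = [GeneModel("g", "chr1", 1_000, 5_000, "+")]
        table = self._uniform_table(1_000, 2_000, step=5)  # 5' quarter only
        prof = metagene_profile(genes, table)
        body = prof[prof.segment == "body"].sum_penetrance.to_numpy()
        assert body[:8].sum() >= 0.8 * body.sum()

    def test_minus_strand_profile_mirrors_plus(self):
        table_hi = self._uniform_table(4_000, 5_000, step=5)  # near coordinate end
        plus = metagene_profile([GeneModel("g", "chr1", 1_000, 5_000, "+")], table_hi)
        minus = metagene_profile([GeneModel("g", "chr1", 1_000, 5_000, "-")], table_hi)
        plus_body = plus[plus.segment == "body"].sum_penetrance.to_numpy()
        minus_body = minus[minus.segment == "body"].sum_penetrance.to_numpy()
        np.testing.assert_allclose(minus_body, plus_body[::-1], atol=1e-9)

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            metagene_profile([], _toy_table([]), n_bins=0)
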