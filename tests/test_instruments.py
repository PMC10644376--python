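"""Instrument selection, LD clumping, F statistics, variance explained."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrkit.errors import ConfigurationError, ValidationError
from mrkit.instruments import (LDMatrix, build_instrument_set,
                               exclude_outcome_significant, f_statistic,
                               filter_exposure_significant, ld_clump,
                               variance_explained)
from mrkit.synthetic import make_block_ld_fixture

from conftest import make_pair, make_record


class TestExposureSignificance:
    def test_strict_inequality_at_threshold(self):
        recs = [make_record(f"rs{i}", pval=p)
                for i, p in enumerate([4e-8, 5e-8, 1e-9])]
        kept = filter_exposure_significant(recs)
        assert sorted(r.pval for r in kept) == [1e-9, 4e-8]

    def test_empty_input(self):
        assert filter_exposure_significant([]) == []

    def test_count_matches_enumeration(self, rng):
        pvals = 10.0 ** rng.uniform(-12, 0, 100)
        recs = [make_record(f"rs{i}", pval=p) for i, p in enumerate(pvals)]
        kept = filter_exposure_significant(recs)
        assert len(kept) == int(np.sum(pvals < 5e-8))


class TestOutcomeExclusion:
    @pytest.mark.parametrize("pval_y,kept", [(1e-9, False), (0.3, True)])
    def test_examples(self, pval_y, kept):
        pairs = [make_pair(pval_y=pval_y)]
        assert (len(exclude_outcome_significant(pairs)) == 1) is kept

    def test_count_matches_enumeration(self, rng):
        pvals = np.concatenate([rng.uniform(1e-3, 1, 48), [1e-9, 4e-9]])
        rng.shuffle(pvals)
        pairs = [make_pair(f"rs{i}", pval_y=p) for i, p in enumerate(pvals)]
        assert len(exclude_outcome_significant(pairs)) == 48


class TestFStatistic:
    def test_arithmetic(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)

    def test_value_at_genome_wide_significance_boundary(self):
        # a SNP exactly at p = 5e-8 (two-sided normal) has F = z².  This is
        # the smallest F a genome-wide-significant instrument can have, ~29.7
        z = stats.norm.isf(2.5e-8)
        se = 0.02
        assert f_statistic(z * se, se) == pytest.approx(z**2)
        assert 29.5 < z**2 < 30.0

    def test_se_must_be_positive(self):
        with pytest.raises(ValidationError):
            f_statistic(0.1, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(beta=st.floats(-3, 3), se=st.floats(1e-4, 2),
           c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, beta, se, c):
        assert f_statistic(c * beta, c * se) == pytest.approx(
            f_statistic(beta, se), rel=1e-9)


class TestVarianceExplained:
    def test_algebraic_fixed_point(self):
        n = 1000
        assert variance_explained([n - 2], n) == pytest.approx(0.5)

    def test_zero_f_gives_zero(self):
        assert variance_explained([0.0, 0.0], 100) == 0.0

    def test_panel_with_reported_mean_strength(self):
        # 77 independent instruments of mean F 116.4 in a study of n=58,284
        # explain ~15.3% of exposure variance under r² = F/(F+n−2)
        r2 = variance_explained([116.4] * 77, 58_284)
        assert 0.152 <= r2 <= 0.155

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            variance_explained([10.0], 2)


def _records_for(ld, pvals, positions=None):
    recs = []
    for i, s in enumerate(ld.snp_ids):
        chrom, pos = (positions[s] if positions else (None, None))
        recs.append(make_record(s, pval=pvals[i], chrom=chrom, pos=pos))
    return recs


class TestLDClump:
    def test_dominated_pair_keeps_smaller_p(self):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        recs = [make_record("a", pval=1e-10), make_record("b", pval=1e-9)]
        kept = ld_clump(recs, ld)
        assert [r.snp_id for r in kept] == ["a"]

    def test_below_threshold_pair_both_kept(self):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.0005], [0.0005, 1.0]]))
        recs = [make_record("a", pval=1e-10), make_record("b", pval=1e-9)]
        assert len(ld_clump(recs, ld)) == 2

    def test_block_fixture_keeps_min_p_per_block(self, rng):
        ld, positions = make_block_ld_fixture(4, 5, within_r2=0.9, seed=1)
        pvals = 10.0 ** rng.uniform(-12, -8, 20)
        recs = _records_for(ld, pvals, positions)
        kept = ld_clump(recs, ld)
        assert len(kept) == 4
        # exhaustive per-block check: each survivor is its block's min-p SNP
        expected = set()
        for b in range(4):
            block = [r for r in recs if r.snp_id.startswith(f"blk{b}_")]
            expected.add(min(block, key=lambda r: r.pval).snp_id)
        assert {r.snp_id for r in kept} == expected

    def test_identity_ld_matrix_is_identity(self, rng):
        ld, positions = make_block_ld_fixture(3, 4, within_r2=0.0, seed=2)
        recs = _records_for(ld, 10.0 ** rng.uniform(-12, -8, 12), positions)
        assert len(ld_clump(recs, ld)) == 12

    def test_window_excludes_distant_pairs_from_comparison(self):
        # two SNPs in high LD but 20,000 kb apart: outside the 10,000 kb
        # window, so both survive
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        ld = LDMatrix(["a", "b"], r2)
        recs = [make_record("a", pval=1e-10, chrom="1", pos=1_000_000),
                make_record("b", pval=1e-9, chrom="1", pos=21_000_000)]
        assert len(ld_clump(recs, ld)) == 2
        # same pair within the window: dominated
        recs[1] = make_record("b", pval=1e-9, chrom="1", pos=5_000_000)
        assert len(ld_clump(recs, ld)) == 1

    def test_cross_chromosome_pairs_always_independent(self):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        recs = [make_record("a", pval=1e-10, chrom="1", pos=1000),
                make_record("b", pval=1e-9, chrom="2", pos=1000)]
        assert len(ld_clump(recs, ld)) == 2

    def test_snp_absent_from_ld_dropped_with_warning(self, caplog):
        ld = LDMatrix(["a"], np.array([[1.0]]))
        recs = [make_record("a", pval=1e-10), make_record("zz", pval=1e-9)]
        with caplog.at_level("WARNING"):
            kept = ld_clump(recs, ld)
        assert [r.snp_id for r in kept] == ["a"]
        assert "zz" in caplog.text

    def test_bad_threshold_rejected(self):
        ld = LDMatrix(["a"], np.array([[1.0]]))
        with pytest.raises(ConfigurationError):
            ld_clump([make_record("a")], ld, r2_threshold=0.0)

    def test_output_satisfies_independence_rule(self, rng):
        # exhaustive pairwise verification of the r²/window rule on survivors
        ld, positions = make_block_ld_fixture(3, 5, within_r2=0.4, seed=3)
        recs = _records_for(ld, 10.0 ** rng.uniform(-12, -8, 15), positions)
        kept = ld_clump(recs, ld, r2_threshold=0.3)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if a.chrom == b.chrom and abs(a.pos - b.pos) <= 10_000_000 * 1000:
                    assert ld.lookup(a.snp_id, b.snp_id) < 0.3


class TestLDMatrixIO:
    def test_wide_round_trip(self, tmp_path):
        import pandas as pd
        m = np.array([[1.0, 0.2], [0.2, 1.0]])
        path = tmp_path / "ld.tsv"
        pd.DataFrame(m, index=["a", "b"], columns=["a", "b"]).to_csv(path, sep="\t")
        ld = LDMatrix.from_wide(path)
        assert ld.lookup("a", "b") == pytest.approx(0.2)

    def test_long_format(self, tmp_path):
        path = tmp_path / "ld_long.tsv"
        path.write_text("snp_a\tsnp_b\tr2\na\tb\t0.35\n")
        ld = LDMatrix.from_long(path)
        assert ld.lookup("a", "b") == pytest.approx(0.35)
        assert ld.lookup("a", "a") == 1.0

    @pytest.mark.parametrize("bad", [
        np.array([[1.0, 0.5], [0.2, 1.0]]),   # asymmetric
        np.array([[0.9, 0.2], [0.2, 1.0]]),   # diagonal != 1
        np.array([[1.0, 1.5], [1.5, 1.0]]),   # out of range
    ])
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValidationError):
            LDMatrix(["a", "b"], bad)


class TestBuildInstrumentSet:
    def test_f_gate_and_selection_log_monotone(self):
        pairs = [make_pair("strong", beta_x=0.2, se_x=0.02),   # F = 100
                 make_pair("weak", beta_x=0.02, se_x=0.02),    # F = 1
                 make_pair("dropped", action_flag="dropped_palindromic")]
        log = []
        iset = build_instrument_set(pairs, n_exposure=10_000, selection_log=log)
        assert iset.snp_ids == ["strong"]
        assert iset.f_stats[0] == pytest.approx(100.0)
        assert all(iset.f_stats > 10)
        assert iset.r2_exposure[0] == pytest.approx(100 / (100 + 9998))
        for entry in log:
            assert entry["n_out"] <= entry["n_in"]
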