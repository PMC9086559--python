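"""Quantification formulas, TMM, and the two-group count test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernaforge.errors import InvalidArgumentError
from cernaforge.expression import (ExprMatrix, call_de, de_test, fpkm, srpbm,
                                   tmm_factors)
from cernaforge.synth import gen_count_matrix


def _mat(values, lib, lengths=None):
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(len(df))]
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return ExprMatrix(df, kind="count",
                      lib_sizes=pd.Series(lib, index=df.columns),
                      feature_lengths_kb=pd.Series(lengths, index=df.index)
                      if lengths is not None else None)


class TestFpkmSrpbm:
    def test_fpkm_hand_values(self):
        # 100 frags / (1e6/1e6 * 1 kb) = 100; 50 / (2 * 0.5) = 50; zeros stay 0
        m = _mat([[100, 50], [0, 50]], [1_000_000, 2_000_000], [1.0, 0.5])
        out = fpkm(m)
        assert out.values.loc["g0", "s0"] == 100.0
        assert out.values.loc["g1", "s1"] == 50.0
        assert out.values.loc["g1", "s0"] == 0.0

    def test_srpbm_hand_values(self):
        m = _mat([[5, 10], [0, 0]], [1_000_000_000, 2_000_000_000])
        out = srpbm(m)
        assert out.values.loc["g0", "s0"] == 5.0
        assert out.values.loc["g0", "s1"] == 5.0
        assert out.values.loc["g1", "s1"] == 0.0

    def test_fpkm_requires_lengths(self):
        m = _mat([[1, 2]], [10, 10])
        with pytest.raises(InvalidArgumentError):
            fpkm(m)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(1, 6), st.integers(2, 5), st.integers(0, 10**6))
    def test_linear_in_counts_inverse_in_depth(self, nf, ns, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 500, size=(nf, ns))
        lib = rng.integers(10**5, 10**7, size=ns)
        lengths = rng.uniform(0.2, 5.0, size=nf)
        m = _mat(counts, lib, lengths)
        m2 = _mat(counts * 3, lib, lengths)
        m3 = _mat(counts, lib * 2, lengths)
        np.testing.assert_allclose(fpkm(m2).values, fpkm(m).values * 3)
        np.testing.assert_allclose(fpkm(m3).values, fpkm(m).values / 2)
        np.testing.assert_allclose(srpbm(m2).values, srpbm(m).values * 3)
        np.testing.assert_allclose(srpbm(m3).values, srpbm(m).values / 2)


class TestTMM:
    def test_identical_columns_factor_one(self):
        col = np.arange(1, 101)
        m = _mat(np.column_stack([col, col, col]), [col.sum()] * 3)
        np.testing.assert_allclose(tmm_factors(m).to_numpy(), 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 1000, size=200)
        m = _mat(np.column_stack([col, 2 * col]), [col.sum(), 2 * col.sum()])
        np.testing.assert_allclose(tmm_factors(m).to_numpy(), 1.0, atol=1e-12)

    def test_trimming_shrugs_off_outlier_features(self):
        # same nominal depth in both samples; 5% of features spiked x50 in
        # sample 2.  The spike falls inside the trimmed M tail, so the
        # factor stays near the clean value of 1.
        rng = np.random.default_rng(1)
        base = rng.integers(50, 500, size=400)
        spiked = base.copy()
        spiked[:20] *= 50
        lib = [10 * base.sum()] * 2
        f_clean = tmm_factors(_mat(np.column_stack([base, base]), lib)).to_numpy()
        f_spiked = tmm_factors(_mat(np.column_stack([base, spiked]), lib)).to_numpy()
        assert np.all(np.abs(f_spiked - f_clean) / f_clean < 0.05)

    def test_all_zero_sample_rejected(self):
        m = _mat([[1, 0], [2, 0]], [3, 1])
        with pytest.raises(InvalidArgumentError):
            tmm_factors(m)

    def test_matches_edger_reference(self, tmp_path):
        """Cross-check factors against the Bioconductor reference on a
        small random matrix (run through Rscript)."""
        import subprocess
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 0.01, size=(300, 4))
        m = _mat(counts, counts.sum(axis=0))
        ours = tmm_factors(m).to_numpy()

        csv = tmp_path / "counts.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.csv("{csv}"))\n'
            'f <- calcNormFactors(x, method="TMM")\n'
            'cat(sprintf("%.10f", f), sep="\\n")\n')
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        theirs = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(ours, theirs, rtol=1e-6)


class TestDETest:
    def _paired_mat(self, values, lib):
        m = _mat(values, lib)
        return m, ["N"] * (m.values.shape[1] // 2) + ["T"] * (m.values.shape[1] // 2)

    def test_identical_groups_null(self):
        vals = np.tile(np.arange(10, 110, 10)[:, None], (1, 4))
        m, groups = self._paired_mat(vals, [vals[:, 0].sum()] * 4)
        res = de_test(m, groups, reference="N")
        assert all(r.p == 1.0 for r in res)
        assert all(r.logFC == 0.0 for r in res)

    def test_zero_vs_twenty_two_sided_binomial(self):
        # background features keep TMM factors at 1; the focal feature has
        # group sums 0 vs 20 at equal effective depth
        rng = np.random.default_rng(0)
        bg = np.tile(rng.integers(50, 500, size=99)[:, None], (1, 4))
        focal = np.array([[0, 0, 10, 10]])
        vals = np.vstack([bg, focal])
        m, groups = self._paired_mat(vals, [10_000] * 4)
        res = de_test(m, groups, reference="N")
        assert res[-1].p == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_bh_step_up_example(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_bh_monotone_and_bounded_below_by_p(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 300, size=(150, 6))
        m = _mat(vals, vals.sum(axis=0))
        res = de_test(m, ["N"] * 3 + ["T"] * 3, reference="N")
        assert all(r.adj_p >= r.p for r in res)
        by_p = sorted(res, key=lambda r: r.p)
        adj = [r.adj_p for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_paired_mode_runs_and_detects_planted(self):
        mat, truth = gen_count_matrix(300, 6, 0.1, 8.0, 0.05, [50_000] * 12, seed=9)
        groups = ["N"] * 6 + ["T"] * 6
        pairs = [f"p{i}" for i in range(6)] * 2
        res = de_test(mat, groups, reference="N", paired=True, pairs=pairs)
        called = {r.feature_id for r in call_de(res, 2, 0.05, use_adjusted=True)}
        planted = {f for f, _ in truth.de_features}
        assert len(called & planted) / len(planted) > 0.8

    def test_single_level_group_rejected(self):
        m = _mat([[1, 2, 3, 4]], [10] * 4)
        with pytest.raises(InvalidArgumentError):
            de_test(m, ["A"] * 4)


class TestCallDE:
    def _r(self, logfc, p, adj):
        from cernaforge.expression import DEResult
        return DEResult("g", logfc, p, adj)

    def test_kept_up(self):
        r = self._r(2.5, 0.001, 0.01)
        assert call_de([r], 2, 0.05) == [r] and r.direction == "up"

    def test_boundary_is_strict(self):
        r = self._r(2.0, 0.001, 0.01)
        assert call_de([r], 2, 0.05) == [] and r.direction == "ns"
        r2 = self._r(3.0, 0.001, 0.05)
        assert call_de([r2], 2, 0.05) == []

    def test_kept_down_and_raw_p_mode(self):
        r = self._r(-3.0, 0.04, 0.2)
        assert call_de([r], 2, 0.05, use_adjusted=False) == [r]
        assert r.direction == "down"
        assert call_de([r], 2, 0.05, use_adjusted=True) == []


class TestCalibrationAndRecovery:
    def test_null_false_positive_rate(self):
        """Poisson-limit null: raw p < 0.05 for ~5% of features."""
        mat, _ = gen_count_matrix(5000, 8, 0.0, 1.0, 0.0,
                                  [200_000] * 16, seed=17)
        res = de_test(mat, ["N"] * 8 + ["T"] * 8, reference="N")
        fpr = np.mean([r.p < 0.05 for r in res])
        assert abs(fpr - 0.05) <= 0.01

    def test_planted_recovery_at_study_design(self):
        """fc=6, dispersion=0.1, 8 pairs: sensitivity >= 0.9, FDR <= 0.05."""
        mat, truth = gen_count_matrix(2000, 8, 0.1, 6.0, 0.1,
                                      [5_000_000] * 16, seed=23)
        res = de_test(mat, ["N"] * 8 + ["T"] * 8, reference="N")
        called = {r.feature_id for r in call_de(res, 2.0, 0.05, use_adjusted=True)}
        planted = {f for f, _ in truth.de_features}
        assert len(called & planted) / len(planted) >= 0.90
        assert len(called - planted) / max(1, len(called)) <= 0.05

    def test_planted_directions_match(self):
        mat, truth = gen_count_matrix(500, 8, 0.2, 6.0, 0.1,
                                      [1_000_000] * 16, seed=29)
        res = de_test(mat, ["N"] * 8 + ["T"] * 8, reference="N")
        called = call_de(res, 2.0, 0.05, use_adjusted=True)
        directions = dict(truth.de_features)
        wrong = [r for r in called if r.feature_id in directions
                 and directions[r.feature_id] != r.direction]
        assert not wrong
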