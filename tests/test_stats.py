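import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import octavg as og
from octavg.exceptions import UndefinedStatisticError
from octavg.stats import simulate_icc_matrix


def _anova_icc21(x):
    """Independent mean-squares oracle for ICC(2,1)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_no_within_subject_variance_gives_one(self):
        x = np.repeat(np.array([[1.0], [2.0], [5.0], [9.0]]), 5, axis=1)
        assert og.icc(x).icc == pytest.approx(1.0)

    def test_pure_noise_is_near_zero(self, rng):
        x = rng.normal(0, 1, (50, 5))
        assert abs(og.icc(x).icc) <= 0.15

    def test_small_matrix_matches_anova_oracle(self, rng):
        x = rng.normal(10, 2, (4, 3)) + rng.normal(0, 3, 4)[:, None]
        assert og.icc(x).icc == pytest.approx(_anova_icc21(x), rel=1e-10)

    def test_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(10, 2, (8, 5)) + rng.normal(0, 3, 8)[:, None]
        res = og.icc(x)
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(8), 5),
            "rater": np.tile(np.arange(5), 8),
            "y": x.ravel(),
        })
        table = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
        row = table[table["Type"] == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(table["Type"]) else table.iloc[1]
        assert res.icc == pytest.approx(float(row["ICC"]), abs=1e-8)
        lo, hi = row[table.columns[-1]]
        assert res.ci95[0] == pytest.approx(lo, abs=0.01)
        assert res.ci95[1] == pytest.approx(hi, abs=0.01)

    def test_ci_brackets_estimate(self, rng):
        for _ in range(5):
            x = simulate_icc_matrix(0.6, 12, 5, rng)
            res = og.icc(x)
            assert res.ci95[0] <= res.icc <= res.ci95[1] <= 1.0

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            og.icc(np.full((5, 4), 3.0))

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            og.icc(np.zeros((1, 5)))
        with pytest.raises(ValueError):
            og.icc(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestSpearman:
    def test_perfectly_monotone(self):
        x = np.array([1.0, 2, 4, 8, 9])
        rho, _ = og.spearman(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = og.spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)

        def ranks(v):
            order = np.argsort(v)
            r = np.empty(len(v))
            r[order] = np.arange(1, len(v) + 1)
            return r  # no ties in continuous draws

        rx, ry = ranks(x), ranks(y)
        oracle = np.sum((rx - rx.mean()) * (ry - ry.mean())) / np.sqrt(
            np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2)
        )
        rho, _ = og.spearman(x, y)
        assert rho == pytest.approx(oracle, rel=1e-10)

    @given(seed=st.integers(0, 100))
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r1, _ = og.spearman(x, y)
        r2, _ = og.spearman(y, x)
        r3, _ = og.spearman(np.exp(x), y)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedStatisticError):
            og.spearman([1, 1, 1], [1, 2, 3])


class TestCompareMeans:
    def test_identical_paired_samples(self):
        res = og.compare_means([1.0, 2, 3], [1.0, 2, 3], paired=True)
        assert res.t == 0.0 and res.p == 1.0

    def test_exact_shift_paired(self):
        res = og.compare_means([11.0, 12, 13], [1.0, 2, 3], paired=True)
        assert res.p == 0.0 and np.isinf(res.t)

    def test_welch_matches_textbook_formula(self, rng):
        a = rng.normal(5, 2, 12)
        b = rng.normal(6, 3, 9)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_oracle = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t_oracle), df_oracle)
        res = og.compare_means(a, b)
        assert res.t == pytest.approx(t_oracle, rel=1e-10)
        assert res.p == pytest.approx(p_oracle, rel=1e-10)

    def test_double_zero_variance_unpaired_raises(self):
        with pytest.raises(UndefinedStatisticError):
            og.compare_means([1.0, 1.0], [2.0, 2.0])


class TestGraderAgreement:
    def test_identical_vectors(self):
        res = og.grader_agreement([0, 1, 1, 0], [0, 1, 1, 0])
        assert res.agreement_rate == 1.0 and res.pearson_r == pytest.approx(1.0)

    def test_complementary_vectors(self):
        res = og.grader_agreement([0, 1, 0, 1], [1, 0, 1, 0])
        assert res.agreement_rate == 0.0 and res.pearson_r == pytest.approx(-1.0)

    def test_half_agreement(self):
        res = og.grader_agreement([0] * 5 + [1] * 5, [0] * 10)
        assert res.agreement_rate == 0.5
        assert res.pearson_r is None  # grader 2 constant

    @given(seed=st.integers(0, 60))
    def test_label_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.integers(0, 2, 12)
        g2 = rng.integers(0, 2, 12)
        a = og.grader_agreement(g1, g2)
        b = og.grader_agreement(1 - g1, 1 - g2)
        assert a.agreement_rate == b.agreement_rate


class TestRepeatabilityReport:
    @staticmethod
    def _tidy(values):
        rows = []
        for (eye, group, area, slab), vals in values.items():
            for k, v in enumerate(vals, 1):
                rows.append(dict(eye=eye, group=group, area=area, slab=slab,
                                 acquisition=k, vd=v))
        return pd.DataFrame(rows)

    def test_no_within_noise_gives_icc_one(self):
        values = {
            (f"E{i}", "healthy", "A3x3", "SVP"): [0.2 + 0.01 * i] * 5 for i in range(4)
        }
        tables = og.repeatability_report(self._tidy(values))
        assert np.allclose(tables["icc_table"]["icc"], 1.0)
        overall = tables["summary"].query("factor == 'overall'")
        assert overall["mean_icc"].iloc[0] == pytest.approx(1.0)

    def test_stratified_structure_and_comparisons(self, rng):
        values = {}
        for group in ("healthy", "oedema"):
            for slab in ("SVP", "DVC"):
                for i in range(5):
                    base = 0.3 + 0.05 * i
                    noise = 0.002 if group == "healthy" else 0.02
                    values[(f"{group}{slab}{i}", group, "A3x3", slab)] = list(
                        base + rng.normal(0, noise, 5)
                    )
        tables = og.repeatability_report(self._tidy(values))
        assert len(tables["icc_table"]) == 4
        comp = tables["comparisons"].set_index("factor")
        assert comp.loc["group", "mean_a"] > comp.loc["group", "mean_b"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            og.repeatability_report(pd.DataFrame({"eye": [], "vd": []}))
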