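"""Normative z-scores, exact Wilcoxon rank-sum, ICC(A,1)."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retmap.stats import (
    NormativeTable,
    icc_a1,
    wilcoxon_rank_sum,
    zscore,
)
from retmap.synthetic import PhantomSpec, gen_normative


def anova_icc_oracle(x: np.ndarray) -> float:
    """Brute-force two-way ANOVA decomposition for ICC(A,1)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def enumeration_p(x, y) -> float:
    """Exhaustive two-sided rank-sum p-value (independent oracle)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2.0
    count = total = 0
    for c in combinations(ranks, n):
        total += 1
        if abs(sum(c) - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


@pytest.fixture(scope="module")
def table():
    return gen_normative(PhantomSpec(seed=0))


class TestZScore:
    def test_definition_and_abnormal_flag(self, table):
        row = table.table.iloc[0]
        val = row["mean"] - 2.5 * row["sd"]
        zr = zscore(val, table, row["measure"], row["eccentricity_mm"],
                    row["meridian"])
        assert zr.z == pytest.approx(-2.5, abs=1e-12)
        assert zr.abnormal

    def test_value_at_mean_is_zero(self, table):
        row = table.table.iloc[3]
        zr = zscore(float(row["mean"]), table, row["measure"],
                    row["eccentricity_mm"], row["meridian"])
        assert zr.z == 0.0
        assert not zr.abnormal

    def test_boundary_minus_two_is_not_abnormal(self, table):
        # strict inequality: exactly -2 SD is still 'normal'
        row = table.table.iloc[0]
        zr = zscore(row["mean"] - 2.0 * row["sd"], table, row["measure"],
                    row["eccentricity_mm"], row["meridian"])
        assert zr.z == pytest.approx(-2.0, abs=1e-12)
        assert not zr.abnormal

    def test_missing_eccentricity_errors_with_available_keys(self, table):
        with pytest.raises(KeyError, match="rows at"):
            zscore(1.0, table, "cone_density", 7.5, "nasal")

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(shift=st.floats(-1e3, 1e3), scale=st.floats(0.01, 100.0))
    def test_affine_equivariance(self, shift, scale):
        df = pd.DataFrame([{
            "measure": "rt", "eccentricity_mm": 1.0, "meridian": "nasal",
            "mean": 300.0, "sd": 12.0, "n": 10,
        }])
        base = zscore(280.0, NormativeTable(df), "rt", 1.0, "nasal").z
        df2 = df.assign(mean=(300.0 + shift) * 1, sd=12.0)
        shifted = zscore(280.0 + shift, NormativeTable(df2), "rt", 1.0,
                         "nasal").z
        assert shifted == pytest.approx(base, abs=1e-9)
        df3 = df.assign(mean=300.0 * scale, sd=12.0 * scale)
        scaled = zscore(280.0 * scale, NormativeTable(df3), "rt", 1.0,
                        "nasal").z
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_invalid_normative_sd_rejected(self):
        df = pd.DataFrame([{
            "measure": "rt", "eccentricity_mm": 1.0, "meridian": "nasal",
            "mean": 300.0, "sd": 0.0, "n": 10,
        }])
        with pytest.raises(ValueError, match="SD"):
            NormativeTable(df)


class TestWilcoxon:
    def test_fully_separated_triplets(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([2.0, 2.0, 5.0], [2.0, 2.0, 5.0])
        assert p == 1.0

    def test_symmetric_under_sample_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(1.0, 1.0, size=8)
        _, pxy = wilcoxon_rank_sum(x, y)
        _, pyx = wilcoxon_rank_sum(y, x)
        assert pxy == pytest.approx(pyx, abs=1e-12)
        assert 0.0 < pxy <= 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(0.8, 1.0, size=6)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_exact_mwu(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=7)
            y = rng.normal(0.5, 1.0, size=8)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(100):
            x = rng.normal(size=7)
            y = rng.normal(0.3, 1.0, size=13)
            _, pe = wilcoxon_rank_sum(x, y, mode="exact")
            _, pa = wilcoxon_rank_sum(x, y, mode="normal_approx")
            diffs.append(abs(pe - pa))
        assert max(diffs) < 0.02

    def test_exact_mode_bounded_sample_size(self):
        with pytest.raises(ValueError, match="<= 20"):
            wilcoxon_rank_sum(np.zeros(11) + np.arange(11),
                              np.arange(12) + 0.5, mode="exact")

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_reps = 10000
        for _ in range(n_reps):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            rejections += p < 0.05
        assert 0.04 <= rejections / n_reps <= 0.06


class TestICC:
    def test_perfect_agreement_gives_one(self):
        mat = np.column_stack([np.arange(5.0), np.arange(5.0)])
        r = icc_a1(mat)
        assert r.icc == pytest.approx(1.0, abs=1e-12)
        assert r.ci_low <= r.icc <= r.ci_high

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            mat = (rng.normal(0, 3, (6, 1)) + rng.normal(0, 1, (6, 3))
                   + rng.normal(0, 0.5, (1, 3)))
            r = icc_a1(mat)
            assert r.icc == pytest.approx(anova_icc_oracle(mat), abs=1e-10)

    def test_matches_pingouin_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        mat = rng.normal(0, 1, (8, 2)) + rng.normal(0, 3, (8, 1))
        r = icc_a1(mat)
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(8), 2),
            "rater": np.tile([0, 1], 8),
            "y": mat.ravel(),
        })
        ref = pg.intraclass_corr(data=df, targets="subj", raters="rater",
                                 ratings="y")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert r.icc == pytest.approx(float(row["ICC"]), abs=1e-9)
        lo, hi = row["CI95"]
        assert r.ci_low == pytest.approx(lo, abs=0.01)
        assert r.ci_high == pytest.approx(hi, abs=0.01)

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(0, 1, (7, 2)) + rng.normal(0, 2, (7, 1))
        perm = rng.permutation(7)
        assert icc_a1(mat).icc == pytest.approx(icc_a1(mat[perm]).icc,
                                                abs=1e-12)

    def test_noise_decreases_icc_monotonically(self):
        rng = np.random.default_rng(8)
        subject_effect = rng.normal(0, 3, (10, 1))
        iccs = []
        for noise_sd in (0.1, 0.5, 1.0, 2.0, 4.0):
            vals = [
                icc_a1(subject_effect
                       + np.random.default_rng(s).normal(0, noise_sd, (10, 2))
                       ).icc
                for s in range(50)
            ]
            iccs.append(np.mean(vals))
        assert all(b < a for a, b in zip(iccs, iccs[1:]))

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_a1(np.full((4, 2), 3.0))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc_a1(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            icc_a1(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestNormativeGenerator:
    def test_foveal_density_within_healthy_range(self):
        t = gen_normative(PhantomSpec(seed=3)).table
        fov = t[(t["measure"] == "cone_density")
                & (t["eccentricity_mm"] == 0.0)]
        assert ((fov["mean"] > 100000) & (fov["mean"] < 170000)).all()

    def test_unique_keys_and_positive_sd(self, table):
        assert (table.table["sd"] > 0).all()
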