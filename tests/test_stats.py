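import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from relrbl.stats import (
    ICCResult,
    InsufficientDataError,
    ReliabilityStudy,
    icc_inter,
    icc_intra,
    paired_t_test,
    percent_change,
    summarize_study,
)


# --- brute-force ANOVA mean-squares oracles ---------------------------------

def icc2_oracle(x):
    """ICC(2,1) from explicitly summed two-way mean squares."""
    n, k = x.shape
    gm = x.mean()
    msb = k * sum((row.mean() - gm) ** 2 for row in x) / (n - 1)
    msj = n * sum((col.mean() - gm) ** 2 for col in x.T) / (k - 1)
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + gm) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)


def icc1_oracle(x):
    """ICC(1,1) from explicitly summed one-way mean squares."""
    n, k = x.shape
    gm = x.mean()
    msb = k * sum((row.mean() - gm) ** 2 for row in x) / (n - 1)
    msw = sum((x[i, j] - x[i].mean()) ** 2
              for i in range(n) for j in range(k)) / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestPairedT:
    def test_closed_form_on_unit_differences(self):
        # differences {1,2,3}: t = mean/ (sd/sqrt(3)) = 2*sqrt(3)
        res = paired_t_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2.0 * math.sqrt(3.0), abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(
            2.0 * sps.t.sf(2.0 * math.sqrt(3.0), 2), abs=1e-12
        )
        assert res.p == pytest.approx(0.0742, abs=5e-4)

    def test_identical_pairs_give_null(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0
        assert res.flag == "zero_variance"

    def test_constant_nonzero_shift_flagged_certain(self):
        res = paired_t_test([0.0, 1.0], [2.0, 3.0])
        assert res.p == 0.0 and res.flag == "zero_variance"
        assert res.t == math.inf

    def test_sign_antisymmetry(self):
        a, b = [0.0, 0.5, 0.1], [1.0, 2.0, 3.0]
        res = paired_t_test(a, b)
        neg = paired_t_test(b, a)
        assert neg.t == pytest.approx(-res.t)
        assert neg.p == pytest.approx(res.p)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            paired_t_test([1.0], [2.0])

    def test_null_p_values_are_uniform(self, rng):
        """Under H0 the paired-test p-value is Uniform(0,1)."""
        ps = []
        for _ in range(2000):
            d0 = rng.normal(size=40)
            d1 = d0 + rng.normal(size=40)  # zero-mean paired differences
            ps.append(paired_t_test(d0, d1).p)
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3


class TestIccAgainstOracles:
    def test_matches_two_way_oracle_on_random_matrices(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 7))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2.0
            res = icc_inter(x)
            assert res.icc == pytest.approx(icc2_oracle(x), abs=1e-10)

    def test_matches_one_way_oracle_on_random_cubes(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 7))
            r = int(rng.integers(2, 3))
            x = rng.normal(size=(n, 3, r)) + rng.normal(size=(n, 1, 1)) * 2.0
            per, pooled = icc_intra(x)
            for j in range(3):
                assert per[j].icc == pytest.approx(icc1_oracle(x[:, j, :]),
                                                   abs=1e-10)
            weights = np.full(3, n)
            expect = float(
                np.average([per[j].icc for j in range(3)], weights=weights)
            )
            assert pooled.icc == pytest.approx(expect, abs=1e-12)

    def test_matches_pingouin_estimates_and_intervals(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(10):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 5))
            x = (rng.normal(size=(n, k))
                 + rng.normal(size=(n, 1)) * 2.0
                 + rng.normal(size=(1, k)) * 0.3)
            long = (pd.DataFrame(x).reset_index()
                    .melt("index", var_name="r", value_name="y"))
            table = pg.intraclass_corr(long, targets="index", raters="r",
                                       ratings="y").set_index("Type")
            mine = icc_inter(x)
            assert mine.icc == pytest.approx(table.loc["ICC(A,1)", "ICC"],
                                             abs=1e-10)
            lo, hi = table.loc["ICC(A,1)", "CI95"]
            assert mine.ci_low == pytest.approx(lo, abs=0.006)
            assert mine.ci_high == pytest.approx(hi, abs=0.006)

    def test_parameter_recovery(self, rng):
        """Estimated ICC recovers sigma_b^2/(sigma_b^2 + sigma_e^2)."""
        sigma_b, sigma_e = 2.0, 1.0
        truth = sigma_b**2 / (sigma_b**2 + sigma_e**2)
        estimates = []
        for _ in range(500):
            site = rng.normal(0.0, sigma_b, size=(15, 1))
            x = site + rng.normal(0.0, sigma_e, size=(15, 4))
            estimates.append(icc_inter(x).icc)
        mean = float(np.mean(estimates))
        se = float(np.std(estimates) / math.sqrt(len(estimates)))
        # small-sample ICC is slightly biased; allow bias + 4 MC Ses
        assert abs(mean - truth) < 0.02 + 4 * se


class TestIccDegenerateCases:
    def test_perfect_agreement_on_varying_sites(self):
        col = np.array([[1.0], [2.0], [5.0], [9.0]])
        x = np.repeat(col, 4, axis=1)
        res = icc_inter(x)
        assert res.icc == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_identical_duplicate_reads(self):
        cube = np.stack([np.tile([[1.0], [4.0], [7.0]], (1, 2))] * 2, axis=1)
        per, pooled = icc_intra(cube)
        assert pooled.icc == 1.0

    def test_constant_data_is_undefined(self):
        res = icc_inter(np.full((4, 3), 2.5))
        assert math.isnan(res.icc)
        assert res.flag == "no_variance"

    def test_pure_noise_on_constant_sites_is_flagged(self):
        rng = np.random.default_rng(1)
        x = 5.0 + rng.normal(0.0, 1.0, size=(6, 4))
        res = icc_inter(x)
        assert res.flag == "no_between_target_variance"
        assert res.icc <= 0.0

    def test_single_repeat_insufficient(self):
        with pytest.raises(InsufficientDataError):
            icc_intra(np.zeros((4, 2, 1)))

    def test_too_few_targets(self):
        with pytest.raises(InsufficientDataError):
            icc_inter(np.zeros((1, 3)))


class TestPercentChange:
    @pytest.mark.parametrize(
        "m0, m30, expected",
        [(7.0, 7.8, 11.4), (31.4, 31.6, 0.6), (5.0, 5.0, 0.0)],
    )
    def test_reported_changes(self, m0, m30, expected):
        assert percent_change(m0, m30) == expected

    def test_zero_baseline(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)


def _readings_frame(site_values, angles=(0.0, 30.0), metric="rbl"):
    """Long-format readings with one examiner/repeat from a mapping
    site -> (value at angle 0, value at angle 30)."""
    rows = []
    for site, (v0, v1) in site_values.items():
        for angle, v in zip(angles, (v0, v1)):
            rows.append({"site": site, "examiner": "E1", "repeat": 1,
                         "angle": angle, "metric": metric, "value": v})
    return pd.DataFrame(rows)


class TestSummarizeStudy:
    def test_noise_free_ratio_invariance_summary(self):
        df = _readings_frame({f"s{i}": (30.0 + i, 30.0 + i) for i in range(5)},
                             metric="rel_rbl")
        summary = summarize_study(df)
        row = summary.table.loc["rel_rbl"]
        assert row["percent_change"] == 0.0
        assert row["p_value"] == 1.0
        assert row["flag"] == "zero_variance"

    def test_unpaired_sites_are_dropped_and_counted(self):
        df = _readings_frame({f"s{i}": (7.0 + i, 8.0 + i) for i in range(4)})
        df = df.drop(df[(df.site == "s0") & (df.angle == 30.0)].index)
        summary = summarize_study(df)
        assert summary.table.loc["rbl", "n"] == 3
        assert summary.n_dropped == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_study(pd.DataFrame(columns=["site", "examiner", "repeat",
                                                  "angle", "metric", "value"]))

    def test_requires_two_angles(self):
        df = _readings_frame({"s0": (7.0, 8.0)})
        with pytest.raises(ValueError):
            summarize_study(df[df.angle == 0.0])


class TestReliabilityStudy:
    def test_fit_returns_estimates_for_each_metric(self, rng):
        rows = []
        for site in range(6):
            base = {"length": 20 + site, "rbl": 6 + 0.3 * site,
                    "rel_rbl": 30 + site}
            for angle in (0.0, 30.0):
                for e in range(3):
                    for r in (1, 2):
                        for metric, v in base.items():
                            rows.append({
                                "site": f"s{site}", "examiner": f"E{e}",
                                "repeat": r, "angle": angle, "metric": metric,
                                "value": v + rng.normal(0, 0.05),
                            })
        results = ReliabilityStudy(pd.DataFrame(rows)).fit()
        assert set(results.icc_inter) == {"length", "rbl", "rel_rbl"}
        assert set(results.icc_intra) == {"length", "rbl", "rel_rbl"}
        for res in results.icc_inter.values():
            assert isinstance(res, ICCResult)
            assert res.ci_low <= res.icc <= res.ci_high
        text = results.summary_text()
        assert "ICC" in text and "rel_rbl" in text

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ReliabilityStudy(pd.DataFrame({"site": []}))
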