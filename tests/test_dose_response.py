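"""Tests of count normalization, series preprocessing, Hill fitting and the
capped (modified) ED50."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from dosechrom.dose_response import (
    CountMatrix,
    DoseSeries,
    HillFit,
    cpm,
    fit_hill,
    modified_ed50,
    preprocess_series,
    tmm_factors,
)


def reference_tmm(counts: np.ndarray, sample: int, ref: int, trim_m=0.30, trim_a=0.05):
    """Independent, deliberately naive trimmed-mean-of-M reference."""
    n_s, n_r = counts[:, sample].sum(), counts[:, ref].sum()
    ms, as_, ws = [], [], []
    for g in range(counts.shape[0]):
        ys, yr = counts[g, sample], counts[g, ref]
        if ys <= 0 or yr <= 0:
            continue
        ms.append(np.log2((ys / n_s) / (yr / n_r)))
        as_.append(0.5 * np.log2((ys / n_s) * (yr / n_r)))
        ws.append(1.0 / ((n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr)))
    ms, as_, ws = map(np.asarray, (ms, as_, ws))
    n = ms.size
    lo_m, hi_m = int(np.floor(n * trim_m)) + 1, n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)) + 1, n - int(np.floor(n * trim_a))
    rank = lambda x: np.argsort(np.argsort(x)) + 1
    keep = ((rank(ms) >= lo_m) & (rank(ms) <= hi_m)
            & (rank(as_) >= lo_a) & (rank(as_) <= hi_a))
    return 2.0 ** (np.sum(ws[keep] * ms[keep]) / np.sum(ws[keep]))


def toy_matrix(counts: np.ndarray, doses=None, batches=None):
    n_re, n_s = counts.shape
    cols = [f"s{j}" for j in range(n_s)]
    doses = doses if doses is not None else np.linspace(100, 0, n_s)
    batches = batches if batches is not None else ["b1"] * n_s
    sheet = pd.DataFrame(dict(sample=cols, dosage_pct=doses, batch=batches,
                              replicate=range(1, n_s + 1)))
    return CountMatrix(pd.DataFrame(counts, index=[f"re_{i}" for i in range(n_re)],
                                    columns=cols), sheet)


class TestTMM:
    def test_identical_columns(self):
        y = np.tile(np.array([[10], [200], [3000], [50], [7], [400]]), (1, 2))
        f = tmm_factors(toy_matrix(y).counts)
        assert np.allclose(f, 1.0)

    def test_pure_depth_change(self):
        a = np.array([10, 200, 3000, 50, 7, 400, 120, 900])
        y = np.c_[a, 2 * a]
        f = tmm_factors(toy_matrix(y).counts)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_naive_reference_with_inflated_feature(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 5000, size=6)
        y = np.c_[base, base.copy()]
        y[0, 1] *= 10  # one RE inflated 10x in sample 1
        cmx = toy_matrix(y)
        f = tmm_factors(cmx.counts)
        # our factors are rescaled to geometric mean 1; compare ratios
        raw_ref = reference_tmm(y.astype(float), sample=1, ref=0)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(raw_ref, abs=1e-4)

    def test_all_zero_sample_raises(self):
        y = np.array([[5, 0], [10, 0], [3, 0], [8, 0]])
        with pytest.raises(ValueError, match="s1"):
            tmm_factors(toy_matrix(y).counts)

    def test_cpm_columns_scale_to_million_under_unit_factors(self):
        y = np.tile(np.array([[10], [200], [3000], [50]]), (1, 2))
        table = cpm(toy_matrix(y))
        assert np.allclose(table.sum(axis=0), 1e6)


class TestPreprocess:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(1)
        y = rng.integers(100, 10000, size=(8, 10))
        cmx = toy_matrix(y)
        table = cpm(cmx)
        ser = preprocess_series(cmx, "re_0")
        expected = table.loc["re_0"].to_numpy()
        expected = expected / np.abs(expected).max()
        assert np.allclose(ser.value, expected, rtol=1e-12)

    def test_exact_log_batch_offset_removed(self):
        # matched dosages across two batches; RE has a 2^0.7 batch-2 effect
        doses = np.array([100, 100, 60, 60, 30, 30, 0, 0], dtype=float)
        batches = ["b1", "b2"] * 4
        # large CPM values keep the log pseudocount (0.5) negligible
        base = 1e6 * np.array([10, 10, 7, 7, 4, 4, 1, 1], dtype=float)
        values = base * np.where(np.array(batches) == "b2", 2**0.7, 1.0)
        cmx = toy_matrix(np.tile(values, (4, 1)).astype(int), doses=doses, batches=batches)
        table = pd.DataFrame(np.tile(values, (4, 1)),
                             index=cmx.counts.index, columns=cmx.counts.columns)
        ser = preprocess_series(cmx, "re_0", cpm_table=table)
        v = ser.value
        for k in range(0, 8, 2):  # batch pairs at equal dosage agree
            assert v[k] == pytest.approx(v[k + 1], rel=1e-6)

    def test_extreme_sample_masked(self):
        doses = np.repeat([100, 60, 30, 12, 0], 4).astype(float)
        values = np.linspace(1.0, 2.0, 20) * 1000
        values[7] *= 50.0
        cmx = toy_matrix(np.tile(values, (2, 1)).astype(int), doses=doses)
        table = pd.DataFrame(np.tile(values, (2, 1)),
                             index=cmx.counts.index, columns=cmx.counts.columns)
        ser = preprocess_series(cmx, "re_0", cpm_table=table)
        # oracle z-score on the scaled vector
        scaled = values / values.max()
        z = (scaled - scaled.mean()) / scaled.std(ddof=1)
        assert np.abs(z[7]) > 3
        assert not ser.include[7]
        assert ser.include.sum() == 19

    def test_missing_re_raises(self):
        cmx = toy_matrix(np.ones((3, 4), dtype=int) * 50)
        with pytest.raises(KeyError):
            preprocess_series(cmx, "nope")


class TestFitHill:
    def test_noiseless_recovery(self, hill_series):
        fit = fit_hill(hill_series(30.0, 2.0, a_min=0.1, a_max=1.0))
        assert fit.converged
        assert fit.e == pytest.approx(30.0, rel=1e-4)
        assert fit.h == pytest.approx(2.0, rel=1e-4)

    @pytest.mark.parametrize("e,h", [(10, 1), (60, 3), (90, 0.9)])
    def test_noiseless_recovery_grid(self, hill_series, e, h):
        fit = fit_hill(hill_series(float(e), float(h)))
        assert fit.e == pytest.approx(e, rel=1e-4)
        assert fit.h == pytest.approx(h, rel=1e-4)

    def test_three_param_selected_for_free_plateau(self, hill_series):
        # plateau 0.6 above the observed 100%-dosage value forces the free max
        fit = fit_hill(hill_series(30.0, 2.0, a_min=0.0, a_max=0.6))
        assert fit.model_kind == "three_param"
        assert fit.aic_two - fit.aic_three > 2
        assert fit.free_max == pytest.approx(0.6, rel=1e-3)

    def test_constant_series_unfittable(self):
        d = np.repeat([100.0, 60, 30, 12, 0], 4)
        ser = DoseSeries("c", d, np.ones_like(d), np.ones_like(d, dtype=bool))
        fit = fit_hill(ser)
        assert not fit.converged
        assert "constant" in fit.reason

    def test_up_direction_recorded_and_fitted(self, hill_series):
        ser = hill_series(30.0, 2.0)
        ser.value = 1.0 - ser.value  # gains accessibility on depletion
        fit = fit_hill(ser)
        assert fit.direction == "up"
        assert fit.e == pytest.approx(30.0, rel=1e-3)

    def test_too_few_points_flagged(self):
        d = np.array([100.0, 0.0, 100.0])
        ser = DoseSeries("x", d, np.array([1.0, 0.2, 0.9]), np.ones(3, dtype=bool))
        assert not fit_hill(ser).converged


class TestModifiedED50:
    def worked_fit(self, e, h):
        return HillFit("w", "two_param", e, h, 0.0, 1.0, 1.0, 0, 0, 0.0, 20,
                       "down", True)

    def test_worked_value_e20_h2(self):
        # algebra: f(100)=10^4/(10^4+400)=0.96154; solve d^2/(d^2+400)=0.48077
        fit = self.worked_fit(20.0, 2.0)
        target = 0.5 * (100**2 / (100**2 + 400))
        exact = np.sqrt(400 * target / (1 - target))
        assert modified_ed50(fit) == pytest.approx(exact, abs=1e-3)
        assert modified_ed50(fit) == pytest.approx(19.245, abs=1e-2)

    def test_worked_value_e200_h1(self):
        # f(100)=1/3; d/(d+200)=1/6 => d=40: raw e=200 is compressed below 100
        fit = self.worked_fit(200.0, 1.0)
        assert modified_ed50(fit) == pytest.approx(40.0, abs=1e-3)

    def test_capped_at_100_for_randomized_fits(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            e = 10.0 ** rng.uniform(0, 3)
            h = 10.0 ** rng.uniform(-0.5, 1.0)
            a_min = rng.uniform(0.0, 0.4)
            fit = HillFit("r", "two_param", e, h, a_min, 1.0, 1.0, 0, 0, 0.0,
                          20, "down", True)
            assert 0.0 <= modified_ed50(fit) <= 100.0

    def test_monotone_in_e(self):
        vals = [modified_ed50(self.worked_fit(float(e), 2.0))
                for e in (5, 10, 20, 50, 100, 150, 200, 300)]
        assert all(a < b or (a == b == 100.0) for a, b in zip(vals, vals[1:]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(0.5, 1000.0), st.floats(0.3, 8.0), st.floats(0.0, 0.45))
    def test_always_capped_property(self, e, h, a_min):
        fit = HillFit("p", "two_param", e, h, a_min, 1.0, 1.0, 0, 0, 0.0,
                      20, "down", True)
        assert 0.0 <= modified_ed50(fit) <= 100.0

    def test_approaches_e_for_small_e(self):
        for e in (2.0, 5.0, 10.0):
            got = modified_ed50(self.worked_fit(e, 2.0))
            assert got == pytest.approx(e, rel=0.05)


class TestPipelineRecovery:
    def test_ed50_recovery_against_high_replicate_run(self):
        """Full-pipeline ED50 recovery on generated counts, benchmarked
        against the residual error of a high-replicate (low-noise) run."""
        from dosechrom.simulate import SimDoseConfig, hill_cpm_factor, simulate_dose_counts

        def implied_ed50(row):
            f = lambda d: float(hill_cpm_factor(d, row.true_log2fc, row.true_ed50, row.true_h))
            target = 0.5 * f(100.0)
            if f(0.0) >= target:
                return 0.0
            return brentq(lambda d: f(d) - target, 1e-9, 100.0)

        def median_err(n_res, reps, seed):
            cfg = SimDoseConfig(n_res=n_res, replicates_per_level=reps, seed=seed)
            counts, samples, truth = simulate_dose_counts(cfg)
            cmx = CountMatrix(counts, samples)
            table = cpm(cmx)
            errs = []
            for _, row in truth[truth.direction == "down"].iterrows():
                fit = fit_hill(preprocess_series(cmx, row.re_id, cpm_table=table))
                if fit.converged:
                    errs.append(abs(fit.ed50_mod - implied_ed50(row)))
            return float(np.median(errs)), len(errs)

        err_default, n_default = median_err(200, 4, seed=9)
        err_hi, _ = median_err(60, 20, seed=10)
        assert n_default >= 40
        # default-noise error is finite and within 5x of the high-replicate floor,
        # and in absolute terms small on the 0-100% dosage scale
        assert err_default < max(5 * err_hi, 5.0)
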