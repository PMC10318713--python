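import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import shapely
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from lambwatch import (
    LambingCall,
    build_lsd_table,
    build_rsf_table,
    compare_selection,
    decay_transform,
    fit_random_intercept_logistic,
    pool_and_standardize,
    pooled_mcp,
    simulate_landscape,
)


@pytest.fixture(scope="module")
def stack():
    return simulate_landscape(extent=(0, 0, 4000, 4000), resolution=50, seed=40)


def _traj(points, start="2022-05-15", freq_h=2.0, animal="A"):
    t = pd.date_range(start, periods=len(points), freq=pd.Timedelta(hours=freq_h), tz="UTC")
    xs, ys = zip(*points)
    return pd.DataFrame({"animal_id": animal, "timestamp": t, "x": xs, "y": ys, "fix_class": "3D"})


def _glmm_table(rng, beta, sigma, n_groups=12, n_per=150, colnames=("a", "b", "c")):
    rows = []
    for g in range(n_groups):
        X = rng.normal(size=(n_per, len(colnames)))
        u = rng.normal(0, sigma) if sigma > 0 else 0.0
        eta = beta[0] + X @ beta[1:] + u
        y = (rng.uniform(size=n_per) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame(X, columns=list(colnames))
        df["response"] = y
        df["animal_id"] = f"g{g:02d}"
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestDecayTransform:
    def test_closed_form_values(self):
        assert decay_transform(0.0) == 1.0
        assert decay_transform(500.0) == pytest.approx(np.exp(-3))
        assert decay_transform(5000.0) < 1e-12

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            decay_transform(-1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1e5), st.floats(min_value=1e-6, max_value=1e5))
    def test_strictly_decreasing(self, d, delta):
        assert decay_transform(d + delta) < decay_transform(d)


class TestLsdTable:
    def test_balanced_thirty_days(self, stack):
        # 40 days of 2-h fixes; call at day 20 -> 180 + 180 rows
        pts = [(2000.0 + 0.1 * i, 2000.0) for i in range(480)]
        traj = _traj(pts)
        call_time = traj["timestamp"].iloc[240]
        call = LambingCall("A", True, pd.Timestamp(call_time), 0.9)
        tab = build_lsd_table(traj, call, stack)
        assert (tab["response"] == 0).sum() == 180
        assert (tab["response"] == 1).sum() == 180
        assert not tab.attrs["unbalanced"]
        # the call fix itself is postpartum
        assert tab["response"].iloc[180] == 1

    def test_call_at_track_start_flags_unbalanced(self, stack):
        pts = [(2000.0, 2000.0 + i) for i in range(360)]
        traj = _traj(pts)
        call = LambingCall("A", True, pd.Timestamp(traj["timestamp"].iloc[0]), 0.9)
        tab = build_lsd_table(traj, call, stack)
        assert (tab["response"] == 0).sum() == 0
        assert tab.attrs["unbalanced"]

    def test_covariates_match_cell_values(self, stack):
        rng = np.random.default_rng(1)
        pts = rng.uniform(200, 3800, size=(100, 2)).tolist()
        traj = _traj(pts)
        call = LambingCall("A", True, pd.Timestamp(traj["timestamp"].iloc[50]), 0.9)
        tab = build_lsd_table(traj, call, stack, span_days=15)
        layer = stack.layers["elevation"]
        for k in range(len(tab)):
            x, y = pts[k]
            col = int((x - layer.x_min) // layer.resolution)
            row = int((layer.y_max - y) // layer.resolution)
            assert tab["elevation"].iloc[k] == layer.values[row, col]

    def test_decay_applied_to_linear_features(self, stack):
        pts = [(2000.0, 2000.0)] * 360
        traj = _traj(pts)
        call = LambingCall("A", True, pd.Timestamp(traj["timestamp"].iloc[180]), 0.9)
        tab = build_lsd_table(traj, call, stack)
        assert ((tab["dist_road"] > 0) & (tab["dist_road"] <= 1)).all()

    def test_undetected_call_rejected(self, stack):
        traj = _traj([(2000.0, 2000.0)] * 360)
        with pytest.raises(ValueError):
            build_lsd_table(traj, LambingCall("A", False, None, 0.2), stack)


class TestRsfTable:
    def test_available_ratio_and_containment(self, stack):
        rng = np.random.default_rng(2)
        used = pd.DataFrame(
            {
                "animal_id": np.repeat(["a", "b"], 60),
                "x": rng.uniform(500, 3500, 120),
                "y": rng.uniform(500, 3500, 120),
            }
        )
        tab = build_rsf_table(used, stack, ratio=10, seed=3)
        assert (tab["response"] == 0).sum() == 1200
        assert (tab["response"] == 1).sum() == 120
        tab2 = build_rsf_table(used, stack, ratio=10, seed=3)
        pd.testing.assert_frame_equal(tab, tab2)  # seeded determinism

    def test_available_covariate_mean_matches_polygon_mean(self, stack):
        rng = np.random.default_rng(4)
        used = pd.DataFrame(
            {
                "animal_id": np.repeat(["a", "b"], 30),
                "x": rng.uniform(500, 3500, 60),
                "y": rng.uniform(500, 3500, 60),
            }
        )
        tab = build_rsf_table(used, stack, ratio=200, seed=5)
        hr = pooled_mcp(used)
        layer = stack.layers["elevation"]
        gx, gy = layer.cell_centers()
        inside = shapely.contains(hr, shapely.points(np.column_stack([gx.ravel(), gy.ravel()])))
        poly_mean = layer.values.ravel()[inside].mean()
        avail_mean = tab.loc[tab["response"] == 0, "elevation"].mean()
        assert avail_mean == pytest.approx(poly_mean, abs=3 * layer.values.ravel()[inside].std() / np.sqrt(inside.sum()) + 0.05)

    def test_mcp_needs_three_distinct_points(self, stack):
        used = pd.DataFrame({"animal_id": ["a", "a"], "x": [0.0, 1.0], "y": [0.0, 0.0]})
        with pytest.raises(ValueError):
            build_rsf_table(used, stack)


class TestStandardization:
    def test_pooled_zscore(self, stack):
        rng = np.random.default_rng(6)
        frames = []
        for aid in ("a", "b"):
            frames.append(
                pd.DataFrame(
                    {
                        "response": rng.integers(0, 2, 50),
                        "animal_id": aid,
                        "elevation": rng.normal(5, 2, 50),
                        "dist_road": rng.uniform(0, 1, 50),
                    }
                )
            )
        pooled = pool_and_standardize(frames)
        for c in ("elevation", "dist_road"):
            assert abs(pooled[c].mean()) < 1e-10
            assert pooled[c].std(ddof=0) == pytest.approx(1.0)


class TestGlmm:
    def test_zero_variance_matches_plain_logistic(self, rng):
        tab = _glmm_table(rng, beta=[0.4, 1.0, -0.7, 0.2], sigma=0.0)
        fit = fit_random_intercept_logistic(tab)
        X = sm.add_constant(tab[["a", "b", "c"]].to_numpy())
        plain = sm.Logit(tab["response"].to_numpy(), X).fit(disp=0)
        assert fit.sigma_animal < 0.05
        np.testing.assert_allclose(fit.coefs.to_numpy(), plain.params, atol=1e-3)

    def test_parameter_recovery_within_three_se(self, rng):
        beta = [0.5, 1.0, -1.0, 0.0]
        tab = _glmm_table(rng, beta=beta, sigma=0.5, n_groups=20, n_per=400)
        fit = fit_random_intercept_logistic(tab)
        for term, true in zip(fit.params.index, beta):
            est, se = fit.params.loc[term, "coef"], fit.params.loc[term, "se"]
            assert abs(est - true) < 3 * se
        assert np.sign(fit.params.loc["a", "coef"]) == 1
        assert np.sign(fit.params.loc["b", "coef"]) == -1

    def test_response_flip_negates_coefficients(self, rng):
        tab = _glmm_table(rng, beta=[0.3, 0.8, -0.5, 0.1], sigma=0.4, n_groups=8, n_per=100)
        fit = fit_random_intercept_logistic(tab)
        flipped = tab.assign(response=1 - tab["response"])
        fit2 = fit_random_intercept_logistic(flipped)
        np.testing.assert_allclose(fit2.coefs.to_numpy(), -fit.coefs.to_numpy(), atol=5e-3)

    def test_matches_lme4_glmer(self, tmp_path):
        """Cross-check against R lme4's adaptive-quadrature glmer fit."""
        rng = np.random.default_rng(42)
        rows = []
        for g in range(8):
            X = rng.normal(size=(80, 2))
            u = rng.normal(0, 0.6)
            eta = 0.3 + X @ [1.0, -0.8] + u
            y = (rng.uniform(size=80) < 1 / (1 + np.exp(-eta))).astype(int)
            df = pd.DataFrame(X, columns=["a", "b"])
            df["response"] = y
            df["animal_id"] = f"g{g}"
            rows.append(df)
        tab = pd.concat(rows, ignore_index=True)
        fit = fit_random_intercept_logistic(tab)
        csv = tmp_path / "tab.csv"
        tab.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(response ~ a + b + (1|animal_id), data=d, family=binomial, nAGQ=15)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")
            """
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        np.testing.assert_allclose(fit.coefs.to_numpy(), vals[:3], atol=1e-2)
        assert fit.sigma_animal == pytest.approx(vals[3], abs=2e-2)

    def test_separation_detected(self, rng):
        tab = _glmm_table(rng, beta=[0.0, 1.0], sigma=0.3, colnames=("a",), n_groups=4, n_per=30)
        tab["sep"] = (tab["response"] * 2 - 1) * rng.uniform(0.5, 1.0, len(tab))
        with pytest.raises(ValueError, match="separation"):
            fit_random_intercept_logistic(tab, covariate_cols=["a", "sep"])

    def test_single_group_rejected(self, rng):
        tab = _glmm_table(rng, beta=[0.0, 1.0], sigma=0.0, colnames=("a",), n_groups=1)
        with pytest.raises(ValueError):
            fit_random_intercept_logistic(tab)


class TestCompareSelection:
    def test_self_comparison(self, rng):
        tab = _glmm_table(rng, beta=[0.2, 0.6, -0.6, 0.0], sigma=0.3, n_groups=6, n_per=80)
        fit = fit_random_intercept_logistic(tab)
        comp = compare_selection(fit, fit)
        assert (comp["difference"] == 0).all()
        assert comp["ci_overlap"].all()
        assert list(comp.index) == sorted(comp.index)

    def test_large_shift_detected(self, rng):
        a = _glmm_table(rng, beta=[0.0, 2.0, 0.0], sigma=0.2, colnames=("u", "v"), n_groups=10, n_per=400)
        b = _glmm_table(rng, beta=[0.0, 0.0, 0.0], sigma=0.2, colnames=("u", "v"), n_groups=10, n_per=400)
        comp = compare_selection(
            fit_random_intercept_logistic(a), fit_random_intercept_logistic(b)
        )
        assert not comp.loc["u", "ci_overlap"]
        assert comp.loc["v", "ci_overlap"]

    def test_mismatched_rosters_rejected(self, rng):
        a = _glmm_table(rng, beta=[0.0, 1.0], sigma=0.2, colnames=("u",), n_groups=4, n_per=40)
        b = _glmm_table(rng, beta=[0.0, 1.0], sigma=0.2, colnames=("w",), n_groups=4, n_per=40)
        with pytest.raises(ValueError):
            compare_selection(
                fit_random_intercept_logistic(a), fit_random_intercept_logistic(b)
            )
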