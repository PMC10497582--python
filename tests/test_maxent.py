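"""Occurrence handling, feature expansion, and the penalized MaxEnt fitter.

The fitter is cross-checked against an independent generic convex optimizer
(scipy L-BFGS-B on the split-coefficient reformulation of the L1 penalty).
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import spearmanr

import riverscape as rs
from riverscape.maxent import regularization_weights


# ------------------------------------------------------- independent oracle


def oracle_fit(Xp: np.ndarray, Xb: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """L-BFGS-B on beta = b_plus - b_minus with b+/- >= 0 (exact L1)."""
    J = Xp.shape[1]
    mp = Xp.mean(axis=0)

    def objective(v):
        beta = v[:J] - v[J:]
        eta = Xb @ beta
        lz = logsumexp(eta)
        w = np.exp(eta - lz)
        grad_beta = (w @ Xb) - mp
        f = -mp @ beta + lz + lam @ (v[:J] + v[J:])
        grad = np.concatenate([grad_beta + lam, -grad_beta + lam])
        return f, grad

    res = minimize(objective, np.zeros(2 * J), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * J,
                   options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10})
    assert res.success or res.fun is not None
    return res.x[:J] - res.x[J:]


def design(df: pd.DataFrame, classes="l"):
    spec = rs.FeatureExpansion(classes=classes).fit(df)
    return spec


# --------------------------------------------------------------- occurrences


class TestCleaning:
    @pytest.fixture()
    def grid(self):
        return rs.ElevationGrid(values=np.full((10, 10), 100.0), cell_size=100.0,
                                origin=(0.0, 1000.0))

    def occ(self, rows):
        return rs.OccurrenceSet(species="sp", records=pd.DataFrame(rows))

    def test_uncertain_record_dropped(self, grid):
        occ = self.occ([
            {"x": 50.0, "y": 50.0, "uncertainty_m": 250.0},
            {"x": 150.0, "y": 150.0, "uncertainty_m": 50.0},
        ])
        clean, report = rs.clean_occurrences(occ, grid)
        assert report == {"uncertain": 1, "off_grid": 0, "duplicate": 0, "kept": 1}

    def test_same_cell_deduplicated(self, grid):
        occ = self.occ([
            {"x": 50.0, "y": 50.0, "uncertainty_m": 10.0},
            {"x": 60.0, "y": 40.0, "uncertainty_m": 10.0},  # same 100 m cell
        ])
        clean, report = rs.clean_occurrences(occ, grid)
        assert len(clean) == 1 and report["duplicate"] == 1

    def test_clean_records_pass_through(self, grid):
        rows = [{"x": 50.0 + 100 * i, "y": 50.0, "uncertainty_m": 10.0} for i in range(10)]
        clean, report = rs.clean_occurrences(self.occ(rows), grid)
        assert len(clean) == 10
        assert report["uncertain"] == report["off_grid"] == report["duplicate"] == 0

    def test_nothing_left_raises(self, grid):
        occ = self.occ([{"x": 50.0, "y": 50.0, "uncertainty_m": 500.0}])
        with pytest.raises(ValueError, match="no usable occurrences"):
            rs.clean_occurrences(occ, grid)


class TestBackground:
    def test_buffer_covering_network_returns_all(self, valley_landscape):
        net = valley_landscape["net"]
        occ = rs.OccurrenceSet(species="sp", records=pd.DataFrame([
            {"x": 6400.0, "y": 6400.0, "uncertainty_m": 10.0}]))
        got = rs.sample_background(occ, net, buffer_km=100.0, n_background=10 ** 6, seed=0)
        assert sorted(got) == sorted(net.reaches)

    def test_same_seed_same_sample(self, valley_landscape):
        net = valley_landscape["net"]
        occ = rs.OccurrenceSet(species="sp", records=pd.DataFrame([
            {"x": 6400.0, "y": 6400.0, "uncertainty_m": 10.0}]))
        a = rs.sample_background(occ, net, 100.0, 50, seed=4)
        b = rs.sample_background(occ, net, 100.0, 50, seed=4)
        assert a == b
        c = rs.sample_background(occ, net, 100.0, 50, seed=5)
        assert a != c

    def test_sample_within_brute_force_intersection(self, valley_landscape):
        from shapely.geometry import LineString, Point
        net = valley_landscape["net"]
        occ = rs.OccurrenceSet(species="sp", records=pd.DataFrame([
            {"x": 4000.0, "y": 4000.0, "uncertainty_m": 10.0}]))
        got = rs.sample_background(occ, net, buffer_km=5.0, n_background=40, seed=1)
        disk = Point(4000.0, 4000.0).buffer(5000.0)
        allowed = {rid for rid, r in net.reaches.items()
                   if LineString(r.geometry).intersects(disk)}
        assert set(got) <= allowed

    def test_no_reach_in_buffer_raises(self, valley_landscape):
        net = valley_landscape["net"]
        occ = rs.OccurrenceSet(species="sp", records=pd.DataFrame([
            {"x": 1e7, "y": 1e7, "uncertainty_m": 10.0}]))
        with pytest.raises(ValueError, match="no reach within"):
            rs.sample_background(occ, net, buffer_km=0.5, n_background=10, seed=0)


# ------------------------------------------------------------------ features


class TestFeatureExpansion:
    def test_linear_is_minmax_scaled(self):
        bg = pd.DataFrame({"t": np.linspace(5.0, 25.0, 50)})
        spec = design(bg, "l")
        D = rs.expand_features(pd.DataFrame({"t": [5.0, 15.0, 25.0]}), spec)
        np.testing.assert_allclose(D["lin:t"], [0.0, 0.5, 1.0])

    def test_quadratic_is_one_at_variable_max(self):
        bg = pd.DataFrame({"t": np.linspace(0.0, 10.0, 20)})
        spec = design(bg, "q")
        D = rs.expand_features(pd.DataFrame({"t": [10.0]}), spec)
        assert D["quad:t"].iloc[0] == pytest.approx(1.0)

    def test_hinge_matches_hand_computed_ramps(self):
        bg = pd.DataFrame({"t": np.linspace(0.0, 1.0, 11)})
        spec = rs.FeatureExpansion(classes="h", n_hinge_knots=5).fit(bg)
        x = np.array([0.0, 0.3, 0.5, 0.9, 1.0])
        D = rs.expand_features(pd.DataFrame({"t": x}), spec)
        knots = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
        for k in knots:
            np.testing.assert_allclose(
                D[f"hinge:t@{k:.6f}"], np.clip((x - k) / (1 - k), 0, None),
                atol=1e-12, err_msg=f"forward hinge at {k}")
            kr = k + 0.2
            np.testing.assert_allclose(
                D[f"rhinge:t@{kr:.6f}"], np.clip((kr - x) / kr, 0, None),
                atol=1e-12, err_msg=f"reverse hinge at {kr}")

    def test_background_features_in_unit_interval(self):
        rng = np.random.default_rng(8)
        bg = pd.DataFrame({"a": rng.normal(size=100), "b": rng.uniform(-5, 5, 100)})
        spec = rs.FeatureExpansion(classes="lqpht", n_hinge_knots=10,
                                   n_threshold_knots=10).fit(bg)
        D = rs.expand_features(bg, spec)
        assert (D.to_numpy() >= -1e-12).all() and (D.to_numpy() <= 1 + 1e-12).all()

    def test_degenerate_predictor_omitted_with_warning(self):
        bg = pd.DataFrame({"t": np.linspace(0, 1, 20), "k": np.ones(20)})
        with pytest.warns(UserWarning, match="degenerate"):
            spec = design(bg, "l")
        D = rs.expand_features(bg, spec)
        assert list(D.columns) == ["lin:t"]


# -------------------------------------------------------------------- fitter


class TestFitter:
    def test_null_data_gives_zero_coefficients(self):
        rng = np.random.default_rng(10)
        bg = pd.DataFrame({"a": rng.normal(size=200), "b": rng.uniform(size=200)})
        spec = design(bg, "lq")
        model = rs.fit_maxent(bg, bg, spec, reg_multiplier=1.0)
        assert (model.coefficients.abs() <= 1e-3).all()
        pred = rs.predict_suitability(model, bg)
        np.testing.assert_allclose(pred["raw"], 1.0 / len(bg), rtol=1e-9)

    def test_binary_predictor_matches_oracle(self):
        # all presences at 1, half the background at 1
        pres = pd.DataFrame({"v": np.ones(20)})
        bg = pd.DataFrame({"v": np.r_[np.ones(50), np.zeros(50)]})
        spec = design(bg, "l")
        model = rs.fit_maxent(pres, bg, spec, reg_multiplier=1.0, tol=1e-10)
        Xp = rs.expand_features(pres, spec).to_numpy()
        Xb = rs.expand_features(bg, spec).to_numpy()
        lam = regularization_weights(rs.expand_features(pres, spec))
        beta = oracle_fit(Xp, Xb, lam)
        np.testing.assert_allclose(model.coefficients.to_numpy(), beta, atol=1e-4)

    @pytest.mark.parametrize("seed,classes", [(0, "l"), (1, "lq"), (2, "lq")])
    def test_matches_oracle_on_small_problems(self, seed, classes):
        rng = np.random.default_rng(seed)
        n_p, n_b = 40, 300
        bg = pd.DataFrame({"a": rng.normal(size=n_b), "b": rng.uniform(-2, 2, n_b)})
        # biased presences: shift in a
        pres = pd.DataFrame({"a": rng.normal(loc=0.8, size=n_p),
                             "b": rng.uniform(-2, 2, n_p)})
        spec = design(bg, classes)
        model = rs.fit_maxent(pres, bg, spec, reg_multiplier=1.0, tol=1e-10)
        Fp = rs.expand_features(pres, spec)
        lam = regularization_weights(Fp)
        beta = oracle_fit(Fp.to_numpy(), rs.expand_features(bg, spec).to_numpy(), lam)
        assert np.max(np.abs(model.coefficients.to_numpy() - beta)) < 1e-4

    def test_positive_response_recovers_positive_coefficient(self, valley_landscape):
        table = valley_landscape["table"]
        net = valley_landscape["net"]
        vs = rs.VirtualSpeciesSpec(species="v", linear={"upstr_temperature": 2.0},
                                   prevalence=0.2, n_presence=120, seed=5)
        occ, truth = rs.simulate_virtual_species(net, table, vs)
        pres_ids = occ.records["reach_id"].unique()
        cols = ["upstr_temperature", "gradient_pct"]
        spec = design(table[cols], "l")
        model = rs.fit_maxent(table.loc[pres_ids, cols], table[cols], spec)
        assert model.coefficients["lin:upstr_temperature"] > 0

    def test_raw_sums_to_one_and_entropy_consistent(self, valley_landscape):
        table, net = valley_landscape["table"], valley_landscape["net"]
        cols = ["upstr_temperature", "gradient_pct", "catchment_area_km2"]
        rng = np.random.default_rng(3)
        pres = table.iloc[rng.choice(len(table), 60, replace=False)][cols]
        spec = design(table[cols], "lq")
        model = rs.fit_maxent(pres, table[cols], spec)
        raw = rs.predict_suitability(model, table[cols])["raw"].to_numpy()
        assert raw.sum() == pytest.approx(1.0, abs=1e-8)
        h = -(raw * np.log(raw)).sum()
        assert h == pytest.approx(model.entropy, abs=1e-6)
        assert 0 <= model.entropy <= np.log(len(table))

    def test_sparsity_nonincreasing_in_regularization(self, valley_landscape):
        table = valley_landscape["table"]
        cols = ["upstr_temperature", "gradient_pct", "sinuosity", "stream_density"]
        rng = np.random.default_rng(6)
        w = np.exp(2.0 * (table["upstr_temperature"] - table["upstr_temperature"].mean())
                   / table["upstr_temperature"].std())
        pres = table.iloc[rng.choice(len(table), 80, replace=False, p=w / w.sum())][cols]
        counts = []
        for m in [0.25, 0.5, 1.0, 2.0, 4.0]:
            spec = design(table[cols], "lq")
            model = rs.fit_maxent(pres, table[cols], spec, reg_multiplier=m)
            counts.append(int((model.coefficients.abs() > 1e-8).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_too_few_presences_raises(self):
        bg = pd.DataFrame({"a": np.linspace(0, 1, 30)})
        with pytest.raises(ValueError, match="at least 5"):
            rs.fit_maxent(bg.head(3), bg, design(bg, "l"))


class TestPrediction:
    def test_uniform_model_predicts_uniform(self):
        bg = pd.DataFrame({"a": np.linspace(0, 1, 40)})
        spec = design(bg, "l")
        model = rs.fit_maxent(bg, bg, spec)
        pred = rs.predict_suitability(model, bg)
        assert pred["cloglog"].nunique() == 1

    def test_cloglog_preserves_raw_ranking(self, valley_landscape):
        table = valley_landscape["table"]
        cols = ["upstr_temperature", "gradient_pct"]
        rng = np.random.default_rng(9)
        pres = table.iloc[rng.choice(len(table), 50, replace=False)][cols]
        model = rs.fit_maxent(pres, table[cols], design(table[cols], "lq"))
        pred = rs.predict_suitability(model, table[cols])
        assert spearmanr(pred["raw"], pred["cloglog"]).statistic == pytest.approx(1.0)

    def test_missing_predictor_named_in_error(self):
        bg = pd.DataFrame({"a": np.linspace(0, 1, 40), "b": np.linspace(2, 3, 40)})
        model = rs.fit_maxent(bg, bg, design(bg, "l"))
        with pytest.raises(KeyError, match="'b'"):
            rs.predict_suitability(model, bg[["a"]])

    def test_model_json_roundtrip(self, tmp_path):
        bg = pd.DataFrame({"a": np.linspace(0, 2, 60)})
        pres = pd.DataFrame({"a": np.linspace(1.2, 2, 20)})
        model = rs.fit_maxent(pres, bg, design(bg, "lq"))
        p = tmp_path / "model.json"
        model.to_json(p)
        back = rs.MaxEntModel.from_json(p)
        probe = pd.DataFrame({"a": np.linspace(0, 2, 11)})
        np.testing.assert_allclose(
            rs.predict_suitability(back, probe)["cloglog"],
            rs.predict_suitability(model, probe)["cloglog"])
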