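"""AUC, Moran's I, permutation calibration, and prior-sensitivity comparison."""

import subprocess
import textwrap
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import occutrend as ot


class TestAucRank:
    def test_degenerate_cases_exact(self):
        assert ot.auc_rank([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
        assert ot.auc_rank([0.5, 0.5], [1, 0]) == 0.5
        assert ot.auc_rank([0.2, 0.9], [1, 0]) == 0.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="positive"):
            ot.auc_rank([0.1, 0.2], [1, 1])

    def test_exhaustive_small_sets_match_mann_whitney(self):
        """Equals normalized Mann-Whitney U on all 2-5 point label/score sets
        over a small score alphabet (includes ties)."""
        alphabet = (0.0, 0.5, 1.0)
        for n in range(2, 6):
            for scores in product(alphabet, repeat=n):
                for labels in product((0, 1), repeat=n):
                    n1, n0 = sum(labels), n - sum(labels)
                    if n1 == 0 or n0 == 0:
                        continue
                    s = np.asarray(scores)
                    pos = s[np.asarray(labels) == 1]
                    neg = s[np.asarray(labels) == 0]
                    u = sum(
                        1.0 if a > b else (0.5 if a == b else 0.0)
                        for a in pos for b in neg
                    )
                    np.testing.assert_allclose(
                        ot.auc_rank(scores, labels), u / (n1 * n0), atol=1e-12)

    def test_matches_sklearn_on_random_inputs(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 40)
            scores = rng.choice([0.1, 0.3, 0.5, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            np.testing.assert_allclose(
                ot.auc_rank(scores, labels),
                sklearn_metrics.roc_auc_score(labels, scores), atol=1e-12)


class TestPosteriorAuc:
    def _flat_draws(self, z):
        """Draws with psi constant across sites (all parameters zero)."""
        names = ot.param_names(0)
        m = z.shape[0]
        values = np.zeros((1, m, len(names)))
        return ot.PosteriorDraws(names=names, values=values,
                                 z_draws=z[None, :, :, None].astype(np.int8),
                                 n_transitions=0)

    def test_constant_psi_gives_half(self):
        from conftest import make_dataset
        rng = np.random.default_rng(1)
        n = 30
        z = rng.integers(0, 2, size=(50, n))
        z[:, 0], z[:, 1] = 0, 1   # both classes in every draw
        draws = self._flat_draws(z)
        data = make_dataset(np.zeros((n, 1, 2)))
        auc = ot.posterior_auc(draws, data, year=1)
        assert auc.mean == 0.5 and auc.sd == 0.0
        assert auc.n_skipped == 0

    def test_single_class_draws_skipped_and_counted(self):
        from conftest import make_dataset
        rng = np.random.default_rng(2)
        z = rng.integers(0, 2, size=(40, 20))
        z[:10] = 1   # single-class draws
        draws = self._flat_draws(z)
        data = make_dataset(np.zeros((20, 1, 2)))
        auc = ot.posterior_auc(draws, data, year=1)
        assert auc.n_skipped == 10
        assert auc.n_draws == 30

    def test_covariate_driven_model_separates(self):
        """Strong forest effect (|beta_forest| = 2) yields posterior-mean
        AUC well above chance."""
        sc = ot.ScenarioConfig(seed=10, n_sites=200, T=1, J=4,
                               preset="hoary-2010", n_cells=900)
        data, truth = ot.generate_dataset(sc)
        p = truth.params
        p.beta = np.array([2.0, 0.0, 0.0, 0.0])
        z_true, _ = ot.simulate_truth(p, data.covariates, 1, seed=11)
        y, date_raw = ot.simulate_surveys(z_true, p.alpha0, p.alpha1, 4, seed=12)
        data = ot.SurveyDataset(
            site_id=data.site_id, y=y, date=data.date,
            covariates=data.covariates, coords=data.coords, years=(2016,))
        priors = ot.vague_priors(ot.param_names(0))
        cfg = ot.McmcConfig(seed=13, n_chains=1, n_burnin=200, n_retained=300,
                            thin=1)
        draws = ot.fit_model(data, priors, cfg)
        auc = ot.posterior_auc(draws, data)
        assert auc.mean > 0.7


class TestMoransI:
    def test_two_site_antithetic_pair(self):
        coords = np.array([[0.0, 0.0], [5.0, 0.0]])
        np.testing.assert_allclose(
            ot.morans_i([1.0, -1.0], coords, 10.0), -1.0)

    def test_checkerboard_is_negative(self):
        xs, ys = np.meshgrid(np.arange(6), np.arange(6))
        coords = np.column_stack([xs.ravel() * 10.0, ys.ravel() * 10.0])
        x = ((xs + ys) % 2 * 2 - 1).ravel().astype(float)
        assert ot.morans_i(x, coords, 10.0) < -0.5

    def test_iid_null_mean(self):
        """Averaged over replicates, I for iid residuals is about -1/(n-1)."""
        rng = np.random.default_rng(3)
        n = 100
        coords = rng.uniform(0, 100, size=(n, 2))
        vals = [ot.morans_i(rng.normal(size=n), coords, 30.0)
                for _ in range(200)]
        np.testing.assert_allclose(np.mean(vals), -1.0 / (n - 1), atol=0.01)

    @settings(derandomize=True, max_examples=20)
    @given(a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-10, 10))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(4)
        n = 25
        coords = rng.uniform(0, 50, size=(n, 2))
        x = rng.normal(size=n)
        np.testing.assert_allclose(
            ot.morans_i(x, coords, 25.0),
            ot.morans_i(a * x + b, coords, 25.0), atol=1e-9)

    def test_errors(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        with pytest.raises(ValueError, match="5"):
            ot.morans_i([1.0, -1.0], coords, 5.0)
        with pytest.raises(ValueError, match="variance"):
            ot.morans_i([2.0, 2.0], coords, 200.0)

    def test_matches_r_ape_oracle(self, tmp_path):
        """Cross-check against ape::Moran.I on a ring where every site has
        exactly two neighbors.

        ape row-standardizes the supplied weight matrix; with equal row sums
        row-standardized and binary Moran's I coincide, so the comparison is
        exact.
        """
        rng = np.random.default_rng(5)
        n = 24
        R = 10.0 * n / (2 * np.pi)
        theta = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([R * np.cos(theta), R * np.sin(theta)])
        x = rng.normal(size=n)
        thr = 15.0  # adjacent chord ~10 km, second neighbor ~20 km
        ours = ot.morans_i(x, coords, thr)
        np.savetxt(tmp_path / "x.txt", x)
        np.savetxt(tmp_path / "coords.txt", coords)
        script = textwrap.dedent(f"""
            suppressMessages(library(ape))
            x <- scan("{tmp_path}/x.txt", quiet=TRUE)
            co <- matrix(scan("{tmp_path}/coords.txt", quiet=TRUE),
                         ncol=2, byrow=TRUE)
            d <- as.matrix(dist(co))
            w <- (d > 0 & d <= {thr}) * 1.0
            cat(sprintf("%.12f", Moran.I(x, w, scaled=FALSE)$observed))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        np.testing.assert_allclose(ours, float(out.stdout.strip()), atol=1e-9)


class TestMoranProfile:
    def _grid_data(self, n_side=6, T=1):
        from conftest import make_dataset
        xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side))
        coords = np.column_stack([xs.ravel() * 10.0, ys.ravel() * 10.0])
        n = n_side * n_side
        y = np.zeros((n, T, 2))
        return make_dataset(y, coords=coords), n

    def _draws_with_z(self, z):
        names = ot.param_names(0)
        m = z.shape[0]
        return ot.PosteriorDraws(
            names=names, values=np.zeros((1, m, len(names))),
            z_draws=z[None, :, :, None].astype(np.int8), n_transitions=0)

    def test_default_thresholds_echoed(self):
        data, n = self._grid_data()
        rng = np.random.default_rng(6)
        z = rng.integers(0, 2, size=(30, n))
        prof = ot.moran_profile(self._draws_with_z(z), data, seed=1)
        assert prof.thresholds_km == (10.0, 20.0, 30.0, 40.0, 50.0)
        np.testing.assert_allclose(prof.null_mean, -1.0 / (n - 1))
        assert ((prof.p >= 0) & (prof.p <= 1)).all()

    def test_clustered_occupancy_raises_small_threshold_i(self):
        """Blocky (regionally clustered) z inflates Moran's I at the
        adjacency threshold well above the null mean."""
        data, n = self._grid_data()
        west = (data.coords[:, 0] < 30.0).astype(np.int8)
        rng = np.random.default_rng(7)
        z = np.array([np.where(rng.random(n) < 0.9, west, 1 - west)
                      for _ in range(40)])
        prof = ot.moran_profile(self._draws_with_z(z), data, seed=2)
        assert prof.I[0] > prof.null_mean + 0.2
        assert prof.p[0] < 0.05

    def test_iid_residuals_rarely_flagged(self):
        """With iid occupancy errors the profile flags thresholds at roughly
        the nominal 5% rate: across 20 replicates x 5 thresholds, at most
        12% of (replicate, threshold) pairs show p <= 0.05, and most
        replicates are completely clean."""
        data, n = self._grid_data(n_side=7)
        rng = np.random.default_rng(8)
        reps = 20
        flagged = 0
        clean_reps = 0
        for r in range(reps):
            z = rng.integers(0, 2, size=(30, n))
            prof = ot.moran_profile(self._draws_with_z(z), data,
                                    n_perm=499, seed=100 + r)
            flagged += int((prof.p <= 0.05).sum())
            clean_reps += (prof.p > 0.05).all()
        assert flagged <= 0.12 * reps * 5
        assert clean_reps >= 0.7 * reps


class TestPermutationCalibration:
    def test_p_values_super_uniform_under_null(self):
        """One-sided permutation p-values are (super-)uniform for iid data:
        a KS test finds no evidence of anti-conservatism."""
        from scipy.stats import kstest
        rng = np.random.default_rng(9)
        n = 60
        coords = rng.uniform(0, 80, size=(n, 2))
        ps = [
            ot.moran_permutation_p(rng.normal(size=n), coords, 30.0,
                                   n_perm=199, rng=rng)[1]
            for _ in range(200)
        ]
        res = kstest(ps, "uniform", alternative="greater")
        assert res.pvalue > 0.01


class TestPriorSensitivity:
    def _draws(self, values):
        names = ot.param_names(1)
        return ot.PosteriorDraws(names=names, values=values, n_transitions=1)

    def test_identical_draws_ratio_one(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=(1, 500, len(ot.param_names(1))))
        table, dens = ot.prior_sensitivity(self._draws(v), self._draws(v.copy()))
        np.testing.assert_allclose(table["sd_ratio"], 1.0)
        assert table["sign_agreement"].all()
        assert set(dens["kind"]) == {"posterior"}

    def test_tighter_informative_draws_ratio_below_one(self):
        rng = np.random.default_rng(11)
        K = len(ot.param_names(1))
        v = rng.normal(size=(1, 500, K))
        table, _ = ot.prior_sensitivity(self._draws(v), self._draws(0.5 * v))
        assert (table["sd_ratio"] < 1.0).all()

    def test_parameter_mismatch_errors(self):
        rng = np.random.default_rng(12)
        a = self._draws(rng.normal(size=(1, 100, len(ot.param_names(1)))))
        names2 = ot.param_names(2)
        b = ot.PosteriorDraws(names=names2,
                              values=rng.normal(size=(1, 100, len(names2))),
                              n_transitions=2)
        with pytest.raises(ValueError, match="differ"):
            ot.prior_sensitivity(a, b)

    def test_prior_curves_exported_when_spec_given(self):
        rng = np.random.default_rng(13)
        names = ot.param_names(1)
        v = rng.normal(size=(1, 300, len(names)))
        pv = ot.vague_priors(names)
        table, dens = ot.prior_sensitivity(self._draws(v), self._draws(v),
                                           priors_vague=pv)
        kinds = dens[dens["regime"] == "vague"]["kind"].unique()
        assert set(kinds) == {"posterior", "prior"}
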