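import numpy as np
import pytest
from scipy.stats import spearmanr

from glvinfer.benchmark import (
    GroundTruth,
    SimulationRegime,
    dirichlet_multinomial,
    generate_ground_truth,
    holdout_forecast,
    network_auc,
    recommend_min_timepoints,
    score_inference,
    simulate_dataset,
    spearman_baseline,
    trajectory_rmse,
)
from glvinfer.model import GLVParameters, build_gradient_match_system, integrate
from glvinfer.ridge import PenaltyConfig, fit_mlcrr

SMALL = dict(n_taxa=5, n_subjects=3, n_timepoints=12, read_depth=1000)


@pytest.fixture(scope="module")
def small_truth():
    regime = SimulationRegime(seed=100, **SMALL)
    rng = np.random.default_rng(regime.seed)
    truth = generate_ground_truth(regime, rng)
    ds, clean = simulate_dataset(truth, rng)
    return truth, ds, clean


class TestGenerateGroundTruth:
    def test_accepted_system_satisfies_constraints(self, small_truth):
        truth, _, _ = small_truth
        assert (truth.params.alpha > 0).all()
        assert (np.diag(truth.params.beta) < 0).all()
        assert (truth.steady_state > 0).all()

    def test_interaction_probability_matches_target(self):
        # binomial check over many raw candidates (before filtering)
        from glvinfer.benchmark import _sample_candidate

        regime = SimulationRegime(seed=7)
        rng = np.random.default_rng(7)
        n_off = 0
        n_total = 0
        for _ in range(100):
            p = _sample_candidate(rng, regime)
            off = ~np.eye(regime.n_taxa, dtype=bool)
            n_off += int((p.beta[off] != 0).sum())
            n_total += int(off.sum())
        frac = n_off / n_total
        # 3 sigma binomial band around 0.20
        sd = np.sqrt(0.2 * 0.8 / n_total)
        assert abs(frac - 0.20) < 3 * sd

    def test_fixed_point_system_rejected_by_cv_filter(self):
        """A system observed exactly at steady state has zero CV."""
        from glvinfer.benchmark import _trajectory_cv_ok

        regime = SimulationRegime(seed=1, n_taxa=3, init_disp_lo=0.0,
                                  init_disp_hi=1e-9)
        p = GLVParameters(alpha=[1.0, 1.0, 1.0], beta=-np.eye(3))
        x_star = np.ones(3)
        rng = np.random.default_rng(1)
        assert not _trajectory_cv_ok(p, x_star, 2, regime, rng)

    def test_impossible_filter_raises_after_bounded_rejections(self):
        regime = SimulationRegime(seed=1, n_taxa=3, max_rejections=5,
                                  cv_threshold=1e9)
        with pytest.raises(RuntimeError, match="rejections"):
            generate_ground_truth(regime)


class TestSimulateDataset:
    def test_counts_sum_to_depth_exactly(self, small_truth):
        _, ds, _ = small_truth
        for s in ds.subjects:
            np.testing.assert_array_equal(ds.read_depth(s), SMALL["read_depth"])

    def test_design_shape_and_invader_absent_before_dosing(self, small_truth):
        truth, ds, clean = small_truth
        for s in ds.subjects:
            assert ds.times[s].size == SMALL["n_timepoints"]
            pre = ds.times[s] <= truth.regime.invasion_day
            assert (clean[s][truth.invader, pre] == 0).all()
            assert clean[s][truth.invader, ~pre].max() > 0

    def test_dmd_first_moment_is_depth_times_proportion(self):
        rng = np.random.default_rng(0)
        p = np.array([0.5, 0.3, 0.2])
        depth = 1000
        draws = np.array([
            dirichlet_multinomial(rng, depth, p, concentration=50.0)
            for _ in range(10_000)
        ])
        mean = draws.mean(axis=0)
        # CLT band: DMD variance = n p (1-p) (n + c)/(c + 1)
        c = 50.0
        var = depth * p * (1 - p) * (depth + c) / (c + 1)
        band = 3.5 * np.sqrt(var / 10_000)
        assert (np.abs(mean - depth * p) < band).all()

    def test_dmd_large_concentration_approaches_multinomial(self):
        """Dispersion -> 0 limit: DMD variance -> multinomial variance."""
        rng = np.random.default_rng(1)
        p = np.array([0.6, 0.4])
        depth = 500
        for conc, tol in ((1e7, 0.1), (20.0, None)):
            draws = np.array([
                dirichlet_multinomial(rng, depth, p, concentration=conc)
                for _ in range(4000)
            ])
            v = draws[:, 0].var()
            v_multinom = depth * p[0] * (1 - p[0])
            if tol is not None:
                assert v == pytest.approx(v_multinom, rel=tol)
            else:
                # moment formula: inflation factor (depth + c) / (c + 1)
                infl = (depth + conc) / (conc + 1)
                assert v == pytest.approx(v_multinom * infl, rel=0.15)


class TestScoreInference:
    def _truth(self):
        beta = np.array([[-1.0, 0.5, 0.0],
                         [0.0, -1.0, 0.0],
                         [0.3, 0.0, -1.0]])
        p = GLVParameters(alpha=[1.0, 0.8, 1.2], beta=beta)
        regime = SimulationRegime(seed=0, n_taxa=3)
        return GroundTruth(params=p, invader=2,
                           steady_state=np.ones(3), n_rejected=0,
                           regime=regime)

    def test_perfect_inference_scores_perfectly(self):
        truth = self._truth()
        scores = np.abs(truth.params.beta).astype(float)
        m = score_inference(truth, truth.params, scores=scores)
        assert m["growth_rmse"] == 0.0
        assert m["interaction_rmse"] == 0.0
        assert m["network_auc"] == 1.0

    def test_anti_perfect_scores_auc_zero(self):
        truth = self._truth()
        adj = (truth.params.beta != 0) & ~np.eye(3, dtype=bool)
        scores = 1.0 - adj.astype(float)
        m = score_inference(truth, truth.params, scores=scores)
        assert m["network_auc"] == 0.0

    def test_hand_computed_auc_three_quarters(self):
        """Brute-force pair counting: scores .9(T) .8(F) .4(T) .1(F)."""
        adj = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=bool)
        scores = np.full((3, 3), np.nan)
        scores[0, 1], scores[0, 2] = 0.9, 0.8    # true, false
        scores[1, 2], scores[1, 0] = 0.4, 0.1    # true, false
        scores[2, 0], scores[2, 1] = -1.0, -1.0  # padding false, lowest
        adj2 = adj.copy()
        # restrict to the four scored edges by making the rest all-false lows
        auc = network_auc(scores, adj2)
        # oracle: pairs (true, false): (.9,.8)W (.9,.1)W (.9,-1)W (.9,-1)W
        # (.4,.8)L (.4,.1)W (.4,-1)W (.4,-1)W -> 7/8
        assert auc == pytest.approx(7 / 8)
        # the spec's four-edge variant, computed directly
        y = np.array([True, False, True, False])
        s = np.array([0.9, 0.8, 0.4, 0.1])
        wins = sum((si > sj) + 0.5 * (si == sj)
                   for si, yi in zip(s, y) if yi
                   for sj, yj in zip(s, y) if not yj)
        assert wins / 4 == pytest.approx(0.75)

    def test_single_class_adjacency_gives_nan(self):
        truth = self._truth()
        dense = GLVParameters(alpha=truth.params.alpha,
                              beta=np.where(truth.params.beta == 0, 0.1,
                                            truth.params.beta))
        t2 = GroundTruth(params=dense, invader=2, steady_state=np.ones(3),
                         n_rejected=0, regime=truth.regime)
        m = score_inference(t2, dense, scores=np.abs(dense.beta))
        assert np.isnan(m["network_auc"])

    def test_rmse_of_identical_vectors_is_zero(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert trajectory_rmse(x, x) == 0.0


class TestHoldoutForecast:
    def test_noise_free_identical_subjects_recovered(self, three_taxa_params):
        """Self-consistency: dense noise-free subjects forecast well."""
        from glvinfer.dataset import Dataset
        from glvinfer.trajectories import finite_difference_estimate

        p = three_taxa_params
        grid = np.linspace(0.0, 10.0, 41)
        traj = integrate(p, np.array([0.3, 0.5, 0.2]), (), grid)
        prop = traj / traj.sum(axis=0)
        counts = np.round(100_000 * prop).astype(np.int64)
        ds = Dataset(
            subjects=("m1", "m2"), taxa=("a", "b", "c"),
            times={"m1": grid, "m2": grid},
            counts={"m1": counts, "m2": counts.copy()},
            biomass={"m1": traj.sum(axis=0), "m2": traj.sum(axis=0)},
        )

        def fit_fn(train):
            te = finite_difference_estimate(train)
            sysm = build_gradient_match_system(te, train)
            return fit_mlcrr(sysm, PenaltyConfig(1e-6, 1e-6))

        report = holdout_forecast(ds, fit_fn, finite_difference_estimate)
        assert (report["rmse"] < 0.05).all()

    def test_training_subject_forecast_not_worse_than_heldout(self, small_truth):
        """Optimism direction: in-sample forecasts beat held-out on average."""
        truth, ds, _ = small_truth
        from glvinfer.ridge import _restrict_subjects
        from glvinfer.trajectories import finite_difference_estimate

        traj = finite_difference_estimate(ds)
        pen = PenaltyConfig(1e-2, 1e-2)

        def rmse_for(train_subjects, eval_subject):
            train = _restrict_subjects(ds, train_subjects)
            te = finite_difference_estimate(train)
            params = fit_mlcrr(build_gradient_match_system(te, train), pen)
            x0 = traj.f[eval_subject][:, 0]
            try:
                pred = integrate(params, x0, (), traj.grid[eval_subject])
            except Exception:
                return np.inf
            return trajectory_rmse(pred, traj.f[eval_subject])

        others = list(ds.subjects[1:])
        heldout = rmse_for(others, ds.subjects[0])
        insample = np.mean([rmse_for(others, s) for s in others])
        assert insample <= heldout * 1.5  # optimism, with stochastic slack


class TestSpearmanBaseline:
    def test_worked_four_point_series(self):
        # x = [1,2,3,4], y = [2,1,4,3] -> rho = 0.6 by the rank formula
        rho = spearmanr([1, 2, 3, 4], [2, 1, 4, 3]).statistic
        assert rho == pytest.approx(0.6)
        from conftest import make_dataset

        # constant read depth (100) so concentrations mirror counts;
        # taxon 2 is compositional filler
        ds = make_dataset(
            {"m1": [[10, 20, 30, 40], [20, 10, 40, 30], [70, 70, 30, 30]]},
            {"m1": [1.0, 1.0, 1.0, 1.0]},
            {"m1": [0.0, 1.0, 2.0, 3.0]},
        )
        s = spearman_baseline(ds)
        assert s[0, 1] == pytest.approx(0.6)
        assert s[1, 0] == pytest.approx(0.6)

    def test_independent_noise_scores_low(self):
        from conftest import make_dataset

        rng = np.random.default_rng(3)
        n = 100
        # six independent taxa: pairwise compositional coupling ~ -1/5
        counts = rng.integers(100, 200, size=(6, n))
        ds = make_dataset(
            {"m1": counts}, {"m1": np.ones(n)}, {"m1": np.arange(n, dtype=float)})
        s = spearman_baseline(ds)
        assert s[0, 1] < 0.3

    def test_constant_series_scores_zero(self):
        from conftest import make_dataset

        # constant depth 60: taxon 0's concentration series is constant
        ds = make_dataset(
            {"m1": [[10, 10, 10], [10, 20, 30], [40, 30, 20]]},
            {"m1": [1.0, 1.0, 1.0]},
            {"m1": [0.0, 1.0, 2.0]},
        )
        s = spearman_baseline(ds)
        assert s[0, 1] == 0.0
        assert s[0, 2] == 0.0


class TestDesignGuideline:
    @pytest.mark.parametrize("L,S,expected", [
        (13, 5, 17),   # worked example: ceil(84.5 / 5)
        (2, 1, 2),
        (10, 10, 5),
    ])
    def test_min_timepoints(self, L, S, expected):
        assert recommend_min_timepoints(L, S) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            recommend_min_timepoints(0, 5)
        with pytest.raises(ValueError):
            recommend_min_timepoints(5, 0)


class TestReproducibility:
    def test_same_seed_bitwise_identical_dataset(self):
        regime = SimulationRegime(seed=55, **SMALL)

        def build():
            rng = np.random.default_rng(regime.seed)
            truth = generate_ground_truth(regime, rng)
            ds, clean = simulate_dataset(truth, rng)
            return truth, ds, clean

        t1, d1, c1 = build()
        t2, d2, c2 = build()
        np.testing.assert_array_equal(t1.params.beta, t2.params.beta)
        for s in d1.subjects:
            np.testing.assert_array_equal(d1.counts[s], d2.counts[s])
            np.testing.assert_array_equal(d1.biomass[s], d2.biomass[s])
            np.testing.assert_array_equal(c1[s], c2[s])
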