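"""Simulation benchmark: ground-truth systems, noisy data, and metrics.

The generator emulates a typical gnotobiotic time-series study: a
10-taxon gLV community observed for 30 days with an invading taxon dosed
at day 10, ten subjects, and a handful of temporal designs (27, 18, 12 or
8 samples).  Counts are drawn from a Dirichlet-multinomial (compositional,
overdispersed — deliberately a different noise family than the inference
model assumes) and biomass from a log-normal around the true total.

Scoring covers the study's four metrics: growth-rate RMSE, interaction
RMSE, directed-network AUC, and held-out trajectory forecast RMSE, plus
the absolute-Spearman correlation baseline and the N^2/2 study-design
guideline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bayes import network_scores
from .dataset import Dataset
from .model import BlowUpError, GLVParameters, integrate

__all__ = [
    "SimulationRegime",
    "GroundTruth",
    "generate_ground_truth",
    "simulate_dataset",
    "dirichlet_multinomial",
    "score_inference",
    "network_auc",
    "holdout_forecast",
    "spearman_baseline",
    "recommend_min_timepoints",
]

_DESIGNS = (27, 18, 12, 8)


@dataclass(frozen=True)
class SimulationRegime:
    """Study conditions for one simulation benchmark regime.

    Defaults mirror the benchmark design: ten taxa over 30 days with an
    invader at day 10, ten subjects, 20% interaction probability, and a
    read depth of 1000 or 25,000 (a 200-25,000 sweep is supported).  The
    parameter-scale hyperparameters are calibrated by simulation, not
    measured from real data, and are exposed here for override.
    """

    seed: int
    n_taxa: int = 10
    horizon: float = 30.0
    invasion_day: float = 10.0
    n_subjects: int = 10
    n_timepoints: int = 27
    read_depth: int = 25_000
    interaction_prob: float = 0.20
    dmd_dispersion: float = 50.0      # Dirichlet concentration; smaller = noisier
    biomass_noise_sd: float = 0.1     # sd of log10 biomass noise
    growth_logmean: float = math.log(0.2)
    growth_logsd: float = 0.4
    self_logmean: float = math.log(0.5)
    self_logsd: float = 0.3
    interaction_sd: float = 0.15      # off-diagonal scale, same units as beta_ll
    init_disp_lo: float = 1.5         # min |log displacement| of x0 from x*
    init_disp_hi: float = 2.5         # max |log displacement| of x0 from x*
    invader_dose_frac: float = 0.1    # dose as fraction of steady-state total mass
    cv_threshold: float = 0.25
    cv_pass_frac: float = 0.75
    n_cv_inits: int = 20
    max_rejections: int = 10_000

    def design_days(self) -> np.ndarray:
        """Sample days: day 0 through the horizon with post-invasion coverage."""
        return np.linspace(0.0, self.horizon, self.n_timepoints)


@dataclass(frozen=True)
class GroundTruth:
    params: GLVParameters
    invader: int                  # taxon index dosed at invasion day
    steady_state: np.ndarray      # full-community interior fixed point
    n_rejected: int
    regime: SimulationRegime


def _sample_candidate(rng, regime: SimulationRegime) -> GLVParameters:
    L = regime.n_taxa
    alpha = rng.lognormal(regime.growth_logmean, regime.growth_logsd, L)
    beta = np.zeros((L, L))
    diag = -rng.lognormal(regime.self_logmean, regime.self_logsd, L)
    # scale off-diagonals so |beta_lj| * typical concentration ~ growth rates
    off_mask = (rng.uniform(size=(L, L)) < regime.interaction_prob)
    np.fill_diagonal(off_mask, False)
    beta[off_mask] = rng.normal(0.0, regime.interaction_sd, off_mask.sum())
    np.fill_diagonal(beta, diag)
    return GLVParameters(alpha=alpha, beta=beta, gamma=np.zeros((L, 0)))


def _draw_initial(rng, x_star: np.ndarray, regime: SimulationRegime) -> np.ndarray:
    """Initial concentrations displaced well away from the steady state.

    Each taxon starts a factor exp(U(lo, hi)) above or below its equilibrium
    (sign random): trajectories then carry genuine non-equilibrium signal,
    which is the situation the benchmark is about.
    """
    mag = rng.uniform(regime.init_disp_lo, regime.init_disp_hi, x_star.size)
    sign = rng.choice([-1.0, 1.0], x_star.size)
    return x_star * np.exp(sign * mag)


def _trajectory_cv_ok(params, x_star, invader, regime, rng) -> bool:
    """Dynamic-variability filter: CV > threshold for most random starts."""
    L = params.n_taxa
    t = np.linspace(0.0, regime.horizon, 40)
    passes = 0
    for _ in range(regime.n_cv_inits):
        x0 = _draw_initial(rng, x_star, regime)
        x0[invader] = 0.0
        try:
            pre = integrate(params, x0, (), t[t <= regime.invasion_day])
            x_mid = pre[:, -1].copy()
            x_mid[invader] = regime.invader_dose_frac * x_star.sum()
            post_t = t[t > regime.invasion_day]
            post = integrate(params, x_mid,
                             (), np.concatenate([[regime.invasion_day], post_t]))
            traj = np.hstack([pre, post[:, 1:]])
        except BlowUpError:
            continue
        mean = traj.mean(axis=1)
        cv = np.divide(traj.std(axis=1), mean, out=np.zeros(L),
                       where=mean > 0)
        if (cv > regime.cv_threshold).all():
            passes += 1
    return passes >= regime.cv_pass_frac * regime.n_cv_inits


def generate_ground_truth(regime: SimulationRegime,
                          rng: np.random.Generator | None = None) -> GroundTruth:
    """Rejection-sample a gLV system passing the benchmark acceptance filter.

    Accepts a candidate when (i) the full community has a feasible interior
    steady state, and (ii) across random initial conditions at least 75% of
    integrations give every taxon a trajectory coefficient of variation
    above 0.25 (a system pinned at its fixed point is uninformative for
    inference).
    """
    if rng is None:
        rng = np.random.default_rng(regime.seed)
    invader = regime.n_taxa - 1
    for rejected in range(regime.max_rejections):
        params = _sample_candidate(rng, regime)
        try:
            x_star = np.linalg.solve(params.beta, -params.alpha)
        except np.linalg.LinAlgError:
            continue
        if not (x_star > 0).all():
            continue
        if not _trajectory_cv_ok(params, x_star, invader, regime, rng):
            continue
        return GroundTruth(params=params, invader=invader, steady_state=x_star,
                           n_rejected=rejected, regime=regime)
    raise RuntimeError(
        f"no acceptable system within {regime.max_rejections} rejections; "
        "loosen the scale hyperparameters"
    )


def dirichlet_multinomial(rng, depth: int, proportions: np.ndarray,
                          concentration: float) -> np.ndarray:
    """One DMD draw: Dirichlet(concentration * proportions) then multinomial."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    pos = p > 0
    alpha = concentration * p[pos]
    mix = rng.dirichlet(alpha)
    out = np.zeros(p.size, dtype=np.int64)
    out[pos] = rng.multinomial(depth, mix)
    return out


def simulate_dataset(truth: GroundTruth,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[Dataset, dict[str, np.ndarray]]:
    """Simulate a noisy study dataset plus the noise-free trajectories.

    Per subject: lognormal initial concentrations around the steady state,
    invader dosed at the invasion day, gLV integrated through the design
    days; counts ~ DMD(depth, true proportions), biomass ~ 10^Normal around
    log10 of the true total.
    """
    regime = truth.regime
    if rng is None:
        rng = np.random.default_rng(regime.seed + 1)
    days = regime.design_days()
    L = regime.n_taxa
    times, counts, biomass, clean = {}, {}, {}, {}
    for si in range(regime.n_subjects):
        name = f"subject{si:02d}"
        for _attempt in range(20):
            x0 = _draw_initial(rng, truth.steady_state, regime)
            x0[truth.invader] = 0.0
            try:
                pre_days = days[days <= regime.invasion_day]
                pre_grid = np.unique(np.concatenate([[0.0], pre_days,
                                                     [regime.invasion_day]]))
                pre = integrate(truth.params, x0, (), pre_grid)
                x_mid = pre[:, -1].copy()
                x_mid[truth.invader] = (regime.invader_dose_frac
                                        * truth.steady_state.sum())
                post_days = days[days > regime.invasion_day]
                post_grid = np.concatenate([[regime.invasion_day], post_days])
                post = integrate(truth.params, x_mid, (), post_grid)
            except BlowUpError:
                continue
            traj = np.empty((L, days.size))
            for j, d in enumerate(days):
                if d <= regime.invasion_day:
                    traj[:, j] = pre[:, np.searchsorted(pre_grid, d)]
                else:
                    traj[:, j] = post[:, np.searchsorted(post_grid, d)]
            break
        else:
            raise RuntimeError(f"{name}: persistent integration blow-up")
        total = traj.sum(axis=0)
        y = np.empty((L, days.size), dtype=np.int64)
        for j in range(days.size):
            y[:, j] = dirichlet_multinomial(rng, regime.read_depth,
                                            traj[:, j] / total[j],
                                            regime.dmd_dispersion)
        w = 10.0 ** (np.log10(total) + rng.normal(0.0, regime.biomass_noise_sd,
                                                  days.size))
        times[name], counts[name], biomass[name] = days.copy(), y, w
        clean[name] = traj
    taxa = tuple(f"taxon{l:02d}" for l in range(L))
    ds = Dataset(subjects=tuple(times), taxa=taxa, times=times,
                 counts=counts, biomass=biomass)
    return ds, clean


# ---------------------------------------------------------------------------
# Metrics


def network_auc(scores: np.ndarray, adjacency: np.ndarray) -> float:
    """Directed-network AUC (midrank ties) of edge scores vs truth.

    Off-diagonal ordered pairs only; returns NaN when the truth has a
    single class.
    """
    from sklearn.metrics import roc_auc_score

    L = adjacency.shape[0]
    mask = ~np.eye(L, dtype=bool)
    y = adjacency[mask].astype(bool)
    s = scores[mask]
    if y.all() or not y.any():
        return float("nan")
    return float(roc_auc_score(y, s))


def trajectory_rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    """RMSE on log10 concentrations with a relative floor of 1e-10."""
    floor = 1e-10 * max(float(np.max(obs)), 1e-300)
    lp = np.log10(np.maximum(pred, floor))
    lo = np.log10(np.maximum(obs, floor))
    return float(np.sqrt(np.mean((lp - lo) ** 2)))


def score_inference(truth: GroundTruth, inferred: GLVParameters,
                    scores: np.ndarray | None = None,
                    heldout_rmse: float | None = None) -> dict:
    """The four benchmark metrics for one inferred system."""
    tp = truth.params
    L = tp.n_taxa
    out = {
        "growth_rmse": float(np.sqrt(np.mean((inferred.alpha - tp.alpha) ** 2))),
        "interaction_rmse": float(
            np.sqrt(np.mean((inferred.beta - tp.beta) ** 2))),
    }
    if scores is not None:
        adj = (tp.beta != 0) & ~np.eye(L, dtype=bool)
        out["network_auc"] = network_auc(scores, adj)
    if heldout_rmse is not None:
        out["forecast_rmse"] = heldout_rmse
    return out


def holdout_forecast(ds: Dataset, fit_fn, traj_fn) -> pd.DataFrame:
    """Hold-one-subject-out forecast RMSE per subject.

    ``fit_fn(train_ds)`` returns a :class:`GLVParameters` (point estimate or
    posterior median); ``traj_fn(ds)`` supplies the concentration estimates
    used both to initialize the forecast (held-out subject's first sample)
    and as the comparison series.  Subjects with a single time point are
    skipped with a note.
    """
    from .ridge import _restrict_subjects

    traj = traj_fn(ds)
    rows = []
    for s in ds.subjects:
        if ds.times[s].size < 2:
            rows.append({"subject": s, "rmse": np.nan, "note": "single timepoint"})
            continue
        train = _restrict_subjects(ds, [t for t in ds.subjects if t != s])
        params = fit_fn(train)
        x0 = traj.f[s][:, 0]
        try:
            pred = integrate(params, x0, ds.perturbations, traj.grid[s],
                             subject=s)
        except BlowUpError as exc:
            rows.append({"subject": s, "rmse": np.inf,
                         "note": f"blow-up at t={exc.t_blowup:.3g}"})
            continue
        rows.append({"subject": s,
                     "rmse": trajectory_rmse(pred, traj.f[s]), "note": ""})
    return pd.DataFrame(rows)


def spearman_baseline(ds: Dataset) -> np.ndarray:
    """Undirected |Spearman| score matrix of concentration series."""
    return network_scores("spearman", None, ds)


def recommend_min_timepoints(n_taxa: int, n_subjects: int) -> int:
    """Per-subject sample count for the N^2/2 total-data-point guideline."""
    if n_taxa < 1 or n_subjects < 1:
        raise ValueError("taxa and subject counts must be >= 1")
    return math.ceil(n_taxa**2 / 2.0 / n_subjects)


def run_spearman_benchmark(regime: SimulationRegime, n_replicates: int,
                           master_seed: int) -> pd.DataFrame:
    """Replicate Spearman-baseline AUCs under a simulation regime."""
    rows = []
    root = np.random.default_rng(master_seed)
    for rep in range(n_replicates):
        seed = int(root.integers(0, 2**31 - 1))
        reg = replace(regime, seed=seed)
        rng = np.random.default_rng(seed)
        truth = generate_ground_truth(reg, rng)
        ds, _ = simulate_dataset(truth, rng)
        scores = spearman_baseline(ds)
        adj = (truth.params.beta != 0) & ~np.eye(reg.n_taxa, dtype=bool)
        rows.append({"replicate": rep, "seed": seed,
                     "auc": network_auc(scores, adj)})
    return pd.DataFrame(rows)
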