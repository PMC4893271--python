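"""Maximum-likelihood ridge inference of gLV parameters.

Two fitters over the gradient-matching regression:

* :func:`fit_mlrr` — unconstrained ridge (Tikhonov) regression, solved in
  closed form per target taxon.
* :func:`fit_mlcrr` — the same objective subject to the biological
  constraints ``alpha_l > 0`` (positive growth) and ``beta_ll < 0``
  (self-limitation), solved as a box-constrained quadratic program.

The penalty matrix is diagonal with two values: one shared by the growth
and perturbation columns, one for the interaction columns.
:func:`select_lambda_cv` picks them by leave-one-subject-out forecast
error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .dataset import Dataset
from .model import (
    BlowUpError,
    GLVParameters,
    GradientMatchSystem,
    build_gradient_match_system,
    integrate,
)

__all__ = [
    "PenaltyConfig",
    "fit_mlrr",
    "fit_mlcrr",
    "select_lambda_cv",
    "ridge_objective",
]

#: strict-inequality buffer for the open constraints alpha > 0, beta_ll < 0
CONSTRAINT_EPS = 1e-5


@dataclass(frozen=True)
class PenaltyConfig:
    """Ridge penalties: growth+perturbation block and interaction block."""

    lambda_growth: float = 0.0
    lambda_interaction: float = 0.0

    def diagonal(self, L: int, P: int) -> np.ndarray:
        d = np.empty(1 + L + P)
        d[0] = self.lambda_growth
        d[1:1 + L] = self.lambda_interaction
        d[1 + L:] = self.lambda_growth
        return d


def _unpack(theta_by_taxon: dict[int, np.ndarray], sys: GradientMatchSystem,
            taxa=None) -> GLVParameters:
    L, P = sys.n_taxa, sys.n_perturbations
    alpha = np.zeros(L)
    beta = np.zeros((L, L))
    gamma = np.zeros((L, P))
    for l, th in theta_by_taxon.items():
        alpha[l] = th[0]
        beta[l] = th[1:1 + L]
        gamma[l] = th[1 + L:]
    return GLVParameters(alpha=alpha, beta=beta, gamma=gamma, taxa=taxa)


def ridge_objective(sys: GradientMatchSystem, params: GLVParameters,
                    penalties: PenaltyConfig) -> float:
    """Penalized residual sum of squares of a parameter set on a system."""
    lam = penalties.diagonal(sys.n_taxa, sys.n_perturbations)
    total = 0.0
    for l in range(sys.n_taxa):
        X, y = sys.rows_for_taxon(l)
        if y.size == 0:
            continue
        th = np.concatenate(([params.alpha[l]], params.beta[l], params.gamma[l]))
        resid = y - X @ th
        total += float(resid @ resid + th @ (lam * th))
    return total


def fit_mlrr(sys: GradientMatchSystem, penalties: PenaltyConfig,
             taxa=None) -> GLVParameters:
    """Unconstrained ridge solution, one closed-form solve per taxon."""
    lam = penalties.diagonal(sys.n_taxa, sys.n_perturbations)
    if (lam < 0).any():
        raise ValueError("penalties must be non-negative")
    out: dict[int, np.ndarray] = {}
    for l in range(sys.n_taxa):
        X, y = sys.rows_for_taxon(l)
        if y.size == 0:
            continue
        A = X.T @ X + np.diag(lam)
        try:
            theta = np.linalg.solve(A, X.T @ y)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"taxon block {l}: singular normal equations; "
                "use a positive ridge penalty"
            ) from exc
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e14:
            raise np.linalg.LinAlgError(
                f"taxon block {l}: singular normal equations; "
                "use a positive ridge penalty"
            )
        out[l] = theta
    return _unpack(out, sys, taxa)


def fit_mlcrr(sys: GradientMatchSystem, penalties: PenaltyConfig,
              taxa=None, eps: float = CONSTRAINT_EPS,
              kkt_tol: float = 1e-6) -> GLVParameters:
    """Constrained ridge: alpha_l >= eps and beta_ll <= -eps.

    Each taxon block is a bound-constrained least-squares problem (the ridge
    penalty is folded in as augmented rows); KKT conditions of the returned
    solution are verified to ``kkt_tol``.
    """
    L, P = sys.n_taxa, sys.n_perturbations
    lam = penalties.diagonal(L, P)
    out: dict[int, np.ndarray] = {}
    for l in range(L):
        X, y = sys.rows_for_taxon(l)
        if y.size == 0:
            continue
        d = X.shape[1]
        X_aug = np.vstack([X, np.diag(np.sqrt(lam))])
        y_aug = np.concatenate([y, np.zeros(d)])
        lb = np.full(d, -np.inf)
        ub = np.full(d, np.inf)
        lb[0] = eps            # growth rate
        ub[1 + l] = -eps       # self-interaction
        res = lsq_linear(X_aug, y_aug, bounds=(lb, ub),
                         method="bvls" if d <= 200 else "trf",
                         tol=1e-12)
        theta = res.x
        # KKT check: projected gradient must vanish
        g = X.T @ (X @ theta - y) + lam * theta
        scale = max(1.0, float(np.abs(g).max()), float(np.linalg.norm(X.T @ y)))
        for j in range(d):
            at_lb = np.isfinite(lb[j]) and abs(theta[j] - lb[j]) < 1e-10
            at_ub = np.isfinite(ub[j]) and abs(theta[j] - ub[j]) < 1e-10
            if at_lb:
                ok = g[j] >= -kkt_tol * scale
            elif at_ub:
                ok = g[j] <= kkt_tol * scale
            else:
                ok = abs(g[j]) <= kkt_tol * scale
            if not ok:
                raise RuntimeError(
                    f"taxon block {l}: KKT violation at coordinate {j} "
                    f"(gradient {g[j]:.3e})"
                )
        out[l] = theta
    return _unpack(out, sys, taxa)


def _forecast_rmse(params: GLVParameters, ds: Dataset, subject: str,
                   traj) -> float:
    """Log10 RMSE of an integrated forecast against estimated concentrations."""
    grid = traj.grid[subject]
    obs = traj.f[subject]
    x0 = obs[:, 0]
    try:
        pred = integrate(params, x0, ds.perturbations, grid, subject=subject)
    except BlowUpError:
        return float("inf")
    floor = 1e-10 * max(obs.max(), 1e-30)
    lo = np.log10(np.maximum(obs, floor))
    lp = np.log10(np.maximum(pred, floor))
    mask = obs > 0
    return float(np.sqrt(np.mean((lo[mask] - lp[mask]) ** 2)))


def select_lambda_cv(
    ds: Dataset,
    traj,
    grid: np.ndarray | None = None,
    constrained: bool = True,
    log_space: bool = False,
) -> PenaltyConfig:
    """Pick the two ridge penalties by held-out forecast error.

    Leave-one-subject-out: for each (lambda_growth, lambda_interaction) pair
    on the grid, fit on all-but-one subject's gradient-match rows and score
    the forecast RMSE (log10 scale) on the held-out subject; return the
    argmin.  With a single subject, falls back to holding out the later half
    of the time grid (with a warning attribute on the result is not needed;
    a UserWarning is emitted).
    """
    import warnings as _warnings

    if grid is None:
        grid = np.logspace(-3, 3, 7)
    grid = np.asarray(grid, dtype=float)
    pairs = list(itertools.product(grid, grid))
    fit = fit_mlcrr if constrained else fit_mlrr

    if ds.n_subjects >= 2:
        folds = [(s, [t for t in ds.subjects if t != s]) for s in ds.subjects]
    else:
        _warnings.warn("single subject: falling back to time-block hold-out")
        folds = None

    def system_for(subjects) -> GradientMatchSystem:
        sub = _restrict_subjects(ds, subjects)
        tr_sub = _restrict_traj(traj, subjects)
        return build_gradient_match_system(tr_sub, sub, log_space=log_space)

    best, best_score = None, np.inf
    for lg, li in pairs:
        pen = PenaltyConfig(lambda_growth=lg, lambda_interaction=li)
        if folds is not None:
            scores = []
            for heldout, train in folds:
                try:
                    params = fit(system_for(train), pen)
                except (np.linalg.LinAlgError, RuntimeError):
                    scores.append(np.inf)
                    continue
                scores.append(_forecast_rmse(params, ds, heldout, traj))
            score = float(np.mean(scores))
        else:
            s = ds.subjects[0]
            g = traj.grid[s]
            half = g.size // 2
            tr_half = _truncate_traj(traj, s, half)
            sys_half = build_gradient_match_system(tr_half, ds, log_space=log_space)
            try:
                params = fit(sys_half, pen)
                score = _forecast_rmse(params, ds, s, traj)
            except (np.linalg.LinAlgError, RuntimeError):
                score = np.inf
        if score < best_score - 1e-12:
            best, best_score = pen, score
    if best is None:
        raise RuntimeError("cross-validation failed for every penalty pair")
    return best


def _restrict_subjects(ds: Dataset, subjects) -> Dataset:
    from dataclasses import replace

    keep = tuple(subjects)
    return replace(
        ds,
        subjects=keep,
        times={s: ds.times[s] for s in keep},
        counts={s: ds.counts[s] for s in keep},
        biomass={s: ds.biomass[s] for s in keep},
        biomass_provenance={s: ds.biomass_provenance[s] for s in keep},
    )


def _restrict_traj(traj, subjects):
    from .trajectories import TrajectoryEstimate

    keep = tuple(subjects)
    return TrajectoryEstimate(
        grid={s: traj.grid[s] for s in keep},
        f={s: traj.f[s] for s in keep},
        fprime={s: traj.fprime[s] for s in keep},
        spread={s: traj.spread[s] for s in keep if s in traj.spread},
        taxa=traj.taxa,
    )


def _truncate_traj(traj, subject, n):
    from .trajectories import TrajectoryEstimate

    return TrajectoryEstimate(
        grid={subject: traj.grid[subject][:n]},
        f={subject: traj.f[subject][:, :n]},
        fprime={subject: traj.fprime[subject][:, :n]},
        taxa=traj.taxa,
    )
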