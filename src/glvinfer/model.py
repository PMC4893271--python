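"""Extended generalized Lotka-Volterra model and gradient matching.

The model for the concentration f_l of taxon l is

    df_l/dt = alpha_l f_l + sum_j beta_lj f_l f_j + sum_p gamma_lp f_l u_p(t)

with per-capita growth rate alpha_l (1/day), pairwise interaction
coefficients beta_lj (1/(day*concentration)) and perturbation effects
gamma_lp (1/day) switched by binary indicators u_p(t).

Because every term carries an f_l factor, inference can proceed by
"gradient matching": given trajectory estimates f-hat and gradient
estimates f-hat', the model becomes a linear regression of f-hat' on
(f-hat, f-hat * f-hat_j, f-hat * u_p), one independent block per target
taxon.  :func:`build_gradient_match_system` assembles that regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .dataset import Dataset, PerturbationSchedule

__all__ = [
    "GLVParameters",
    "GradientMatchSystem",
    "BlowUpError",
    "integrate",
    "net_growth",
    "build_gradient_match_system",
]

#: hard ceiling: a state exceeding this multiple of the largest initial
#: concentration is treated as finite-time blow-up.
BLOWUP_FACTOR = 1e12


class BlowUpError(RuntimeError):
    """Finite-time divergence of the gLV integration."""

    def __init__(self, t_blowup: float):
        super().__init__(f"gLV integration diverged at t = {t_blowup:.4g}")
        self.t_blowup = t_blowup


@dataclass(frozen=True)
class GLVParameters:
    """One point estimate (or one posterior draw) of the gLV parameters."""

    alpha: np.ndarray  # (L,) growth rates, 1/day
    beta: np.ndarray   # (L, L) interactions, 1/(day*concentration)
    gamma: np.ndarray = field(default=None)  # (L, P) perturbation effects, 1/day
    taxa: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        beta = np.asarray(self.beta, dtype=float)
        L = alpha.size
        if beta.shape != (L, L):
            raise ValueError(f"beta shape {beta.shape} != ({L}, {L})")
        gamma = self.gamma
        if gamma is None:
            gamma = np.zeros((L, 0))
        gamma = np.asarray(gamma, dtype=float).reshape(L, -1)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)

    @property
    def n_taxa(self) -> int:
        return self.alpha.size

    @property
    def n_perturbations(self) -> int:
        return self.gamma.shape[1]

    def restrict(self, subset: np.ndarray) -> "GLVParameters":
        """Parameters of the sub-community given by taxon indices."""
        idx = np.asarray(subset, dtype=int)
        return GLVParameters(
            alpha=self.alpha[idx],
            beta=self.beta[np.ix_(idx, idx)],
            gamma=self.gamma[idx],
            taxa=tuple(self.taxa[i] for i in idx) if self.taxa else None,
        )


def net_growth(params: GLVParameters, active_perturbations=()) -> np.ndarray:
    """Effective growth rate alpha_l + sum of active gamma_lp per taxon."""
    out = params.alpha.copy()
    for p in active_perturbations:
        out = out + params.gamma[:, p]
    return out


def _u_of_t(schedules, subject: str | None):
    """Vectorized perturbation indicator evaluator u(t) -> (P,)."""
    if not schedules:
        return lambda t: np.zeros(0)

    def u(t: float) -> np.ndarray:
        if subject is None:
            # schedules given as plain interval lists, shared by all subjects
            return np.array([
                1.0 if any(a <= t < b for a, b in sched) else 0.0
                for sched in schedules
            ])
        return np.array(
            [float(p.evaluate(subject, t)) for p in schedules]
        )

    return u


def _switch_points(schedules, subject):
    pts: list[float] = []
    for sched in schedules:
        if subject is None:
            for a, b in sched:
                pts.extend((a, b))
        else:
            pts.extend(sched.switch_times(subject))
    return sorted(set(pts))


def integrate(
    params: GLVParameters,
    x0: np.ndarray,
    schedules=(),
    t_grid: np.ndarray = None,
    subject: str | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> np.ndarray:
    """Integrate the gLV system on ``t_grid``; returns shape ``(L, len(t_grid))``.

    ``schedules`` is either a sequence of :class:`PerturbationSchedule`
    (evaluated for ``subject``) or, when ``subject`` is None, a sequence of
    plain interval lists ``[(start, end), ...]`` applied as-is.  Perturbation
    switch points are inserted as integration breakpoints so that the
    discontinuous u_p(t) never straddles an adaptive solver step.

    A taxon starting at exactly 0 stays at 0; strictly positive states stay
    positive (the solver works in the original coordinates and clips
    round-off-level negatives).  Divergence raises :class:`BlowUpError`
    carrying the blow-up time.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    x0 = np.asarray(x0, dtype=float)
    if (x0 < 0).any():
        raise ValueError("initial concentrations must be non-negative")

    if schedules and isinstance(next(iter(schedules)), PerturbationSchedule):
        sched_list = list(schedules)
        u_fun = _u_of_t(sched_list, subject)
        switches = _switch_points(sched_list, subject)
    else:
        sched_list = [list(s) for s in schedules]
        u_fun = _u_of_t(sched_list, None)
        switches = _switch_points(sched_list, None)

    cap = BLOWUP_FACTOR * max(x0.max(), 1e-30)
    alpha, beta, gamma = params.alpha, params.beta, params.gamma
    zero_mask = x0 == 0.0

    def rhs(t, x):
        x = np.maximum(x, 0.0)
        # near blow-up the solver may probe huge states; overflow is handled
        # by the cap check, not worth a warning
        with np.errstate(over="ignore", invalid="ignore"):
            growth = alpha + beta @ x
            if gamma.shape[1]:
                growth = growth + gamma @ u_fun(t)
            return x * growth

    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    breakpts = [t0] + [s for s in switches if t0 < s < t1] + [t1]
    out = np.empty((x0.size, t_grid.size))
    out[:, 0] = x0
    x = x0.copy()
    for a, b in zip(breakpts, breakpts[1:]):
        sel = (t_grid > a) & (t_grid <= b)
        t_eval = t_grid[sel]
        # evaluate u just inside the interval (half-open convention)
        sol = solve_ivp(
            rhs, (a, b), x, method="LSODA", t_eval=t_eval if t_eval.size else None,
            rtol=rtol, atol=atol, dense_output=False,
        )
        if not sol.success or np.abs(sol.y).max(initial=0) > cap or not np.isfinite(sol.y).all():
            t_bad = sol.t[-1] if sol.t.size else a
            raise BlowUpError(float(t_bad))
        if t_eval.size:
            out[:, sel] = np.maximum(sol.y, 0.0)
        x = np.maximum(sol.y[:, -1] if sol.y.size else x, 0.0)
        if np.abs(x).max(initial=0) > cap:
            raise BlowUpError(float(b))
        x[zero_mask] = 0.0
    out[zero_mask, :] = 0.0
    return out


@dataclass(frozen=True)
class GradientMatchSystem:
    """The linear regression obtained by gradient matching.

    One row per retained (taxon l, subject s, grid point t); the predictor
    layout is ``[f_l, f_l*f_1, ..., f_l*f_L, f_l*u_1, ..., f_l*u_P]`` so each
    row has ``1 + L + P`` columns.  The system is block-diagonal by target
    taxon: rows with ``taxon_index == l`` only involve taxon l's parameters.
    """

    response: np.ndarray        # (R,) gradient estimates
    predictors: np.ndarray      # (R, 1 + L + P)
    taxon_index: np.ndarray     # (R,) target taxon per row
    index_map: tuple            # (l, subject, day) per row
    n_taxa: int
    n_perturbations: int
    log_space: bool = False

    @property
    def n_rows(self) -> int:
        return self.response.size

    def rows_for_taxon(self, l: int) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) block for one target taxon."""
        sel = self.taxon_index == l
        return self.predictors[sel], self.response[sel]


def build_gradient_match_system(
    traj, ds: Dataset, log_space: bool = False
) -> GradientMatchSystem:
    """Assemble the gradient-matching regression from trajectory estimates.

    ``traj`` is a :class:`~glvinfer.trajectories.TrajectoryEstimate` carrying
    f-hat and f-hat' per subject on its own grid.  Rows where f-hat is not
    strictly positive are dropped (taxa never observed in a subject
    contribute no rows for that subject).  With ``log_space=True`` each row
    is divided by f-hat, regressing the per-capita growth rate instead; the
    fitted parameters are identical in the noise-free limit.
    """
    L = ds.n_taxa
    P = ds.n_perturbations
    rows_X: list[np.ndarray] = []
    rows_y: list[float] = []
    rows_l: list[int] = []
    imap: list[tuple[int, str, float]] = []
    for s in ds.subjects:
        grid = traj.grid[s]
        f = traj.f[s]          # (L, G)
        fp = traj.fprime[s]    # (L, G)
        if f.shape != (L, grid.size):
            raise ValueError(
                f"trajectory for subject {s!r} has shape {f.shape}, "
                f"expected ({L}, {grid.size})"
            )
        u = ds.perturbation_matrix(s, grid)  # (P, G)
        for l in range(L):
            for g in range(grid.size):
                fl = f[l, g]
                if not fl > 0.0:
                    continue
                x = np.empty(1 + L + P)
                x[0] = fl
                x[1:1 + L] = fl * f[:, g]
                if P:
                    x[1 + L:] = fl * u[:, g]
                y = fp[l, g]
                if log_space:
                    x /= fl
                    y = y / fl
                rows_X.append(x)
                rows_y.append(y)
                rows_l.append(l)
                imap.append((l, s, float(grid[g])))
    if not rows_X:
        raise ValueError("gradient-match system is empty (no positive f-hat)")
    return GradientMatchSystem(
        response=np.array(rows_y),
        predictors=np.array(rows_X),
        taxon_index=np.array(rows_l),
        index_map=tuple(imap),
        n_taxa=L,
        n_perturbations=P,
        log_space=log_space,
    )
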