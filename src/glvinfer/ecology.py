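"""Ecological predictions from inferred gLV parameters.

Given parameter draws (or a point estimate), this module answers the
downstream questions the model exists for:

* which sub-communities have a feasible (all-positive) and stable interior
  steady state, and with what posterior probability;
* how well a stable community resists invasion by a challenger taxon
  (simulated dosing plus forward integration);
* which taxa are "keystones" — whose removal most displaces the remaining
  community's steady state;
* whether two perturbation regimes support different biodiversity among
  their stable states (Wilcoxon rank-sum on coexisting-taxon counts).

An interior steady state of the sub-community solves
``beta_sub x* = -(alpha_sub + gamma-adjustment)``; it is stable when all
eigenvalues of the Jacobian ``diag(x*) @ beta_sub`` have negative real part.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .bayes import PosteriorSamples
from .model import BlowUpError, GLVParameters, integrate, net_growth

__all__ = [
    "SteadyStateResult",
    "StabilityReport",
    "steady_state",
    "is_stable",
    "enumerate_subcommunities",
    "challenge_invasion",
    "rank_exclusion_communities",
    "keystoneness",
    "compare_regime_biodiversity",
]

#: enumeration hard cap: 2^L sub-communities
MAX_ENUM_TAXA = 20


@dataclass(frozen=True)
class SteadyStateResult:
    x: np.ndarray | None   # concentrations on the subset, or None
    feasible: bool
    degenerate: bool = False  # singular interaction submatrix


def steady_state(params: GLVParameters, subset,
                 active_perturbations=()) -> SteadyStateResult:
    """Interior fixed point of the sub-community, or infeasible/degenerate.

    Solves ``beta_sub x = -(alpha + active gamma)_sub``.  ``degenerate``
    (singular submatrix) is distinct from ``feasible=False`` (a solution
    exists but has a non-positive component).
    """
    idx = np.asarray(sorted(subset), dtype=int)
    b = params.beta[np.ix_(idx, idx)]
    a = net_growth(params, active_perturbations)[idx]
    try:
        x = np.linalg.solve(b, -a)
    except np.linalg.LinAlgError:
        return SteadyStateResult(x=None, feasible=False, degenerate=True)
    if not np.isfinite(x).all() or np.linalg.cond(b) > 1e12:
        return SteadyStateResult(x=None, feasible=False, degenerate=True)
    feasible = bool((x > 0).all())
    return SteadyStateResult(x=x if feasible else x, feasible=feasible)


def is_stable(params: GLVParameters, subset, x_star: np.ndarray) -> bool:
    """Linear stability of an interior fixed point of the subset system.

    At an interior fixed point the gLV Jacobian reduces to
    ``diag(x*) @ beta_sub``; stability means every eigenvalue has negative
    real part.
    """
    idx = np.asarray(sorted(subset), dtype=int)
    J = np.diag(x_star) @ params.beta[np.ix_(idx, idx)]
    eig = np.linalg.eigvals(J)
    return bool(np.max(eig.real) < 0.0)


@dataclass
class StabilityReport:
    """Steady-state summary of one sub-community across posterior draws."""

    subcommunity: tuple[int, ...]
    stability_prob: float
    n_draws: int
    n_feasible: int
    n_degenerate: int
    steady_states: np.ndarray          # (n_stable, |subset|) feasible-stable draws
    stable_draw_ids: np.ndarray
    challenge_outcome: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.subcommunity)

    def median_state(self) -> np.ndarray | None:
        if self.steady_states.shape[0] == 0:
            return None
        return np.median(self.steady_states, axis=0)


def _as_draws(ps) -> list[GLVParameters]:
    if isinstance(ps, GLVParameters):
        return [ps]
    if isinstance(ps, PosteriorSamples):
        return ps.draws()
    return list(ps)


def analyze_subcommunity(draws, subset, active_perturbations=()) -> StabilityReport:
    """Feasibility and stability of one subset across draws."""
    subset = tuple(sorted(subset))
    states, ids = [], []
    n_feas = n_deg = 0
    for d, params in enumerate(draws):
        res = steady_state(params, subset, active_perturbations)
        if res.degenerate:
            n_deg += 1
            continue
        if not res.feasible:
            continue
        n_feas += 1
        if is_stable(params, subset, res.x):
            states.append(res.x)
            ids.append(d)
    n = len(draws)
    return StabilityReport(
        subcommunity=subset,
        stability_prob=len(states) / n,
        n_draws=n,
        n_feasible=n_feas,
        n_degenerate=n_deg,
        steady_states=(np.array(states) if states
                       else np.empty((0, len(subset)))),
        stable_draw_ids=np.array(ids, dtype=int),
    )


def enumerate_subcommunities(ps, active_perturbations=(),
                             stability_threshold: float = 0.9,
                             extra_thinning: int = 1,
                             taxa_subset=None) -> list[StabilityReport]:
    """Screen every non-empty sub-community for probable stable coexistence.

    For each of the 2^L - 1 subsets, the fraction of draws with a feasible
    and stable interior steady state is computed; subsets with
    ``stability_prob > stability_threshold`` are returned (sorted by
    descending probability, then size).  ``extra_thinning`` subsamples the
    retained draws to keep large enumerations tractable.
    """
    draws = _as_draws(ps)
    if extra_thinning > 1:
        draws = draws[extra_thinning - 1::extra_thinning]
    L = draws[0].n_taxa
    pool = list(range(L)) if taxa_subset is None else sorted(taxa_subset)
    if len(pool) > MAX_ENUM_TAXA:
        raise ValueError(
            f"{len(pool)} taxa exceed the enumeration cap of {MAX_ENUM_TAXA}; "
            "group taxa before stability screening"
        )
    reports = []
    for size in range(1, len(pool) + 1):
        for subset in combinations(pool, size):
            rep = analyze_subcommunity(draws, subset, active_perturbations)
            if rep.stability_prob > stability_threshold:
                reports.append(rep)
    reports.sort(key=lambda r: (-r.stability_prob, r.size, r.subcommunity))
    return reports


def count_subcommunities(L: int) -> int:
    """Number of non-empty sub-communities screened for L taxa."""
    if L > MAX_ENUM_TAXA:
        raise ValueError(f"{L} taxa exceed the enumeration cap of {MAX_ENUM_TAXA}")
    return 2**L - 1


def challenge_invasion(ps, report: StabilityReport, invader: int,
                       dose: float, horizon: float,
                       active_perturbations=(),
                       n_grid: int = 57) -> dict:
    """Simulate dosing an invader into a stable sub-community.

    For every feasible-stable draw, the commensals start at that draw's own
    steady state, the invader is added at ``dose``, and the joint system is
    integrated for ``horizon`` days; the invader's final concentration is
    recorded.  Returns the median and median absolute deviation across
    draws, plus the count of draws excluded for integration blow-up.
    """
    if invader in report.subcommunity:
        raise ValueError("invader must not belong to the sub-community")
    draws = _as_draws(ps)
    members = list(report.subcommunity)
    full = sorted(members + [invader])
    inv_pos = full.index(invader)
    finals = []
    n_blowup = 0
    t_grid = np.linspace(0.0, horizon, n_grid)
    active = list(active_perturbations)
    for d, x_star in zip(report.stable_draw_ids, report.steady_states):
        params = draws[d].restrict(np.array(full))
        if active:
            # fold active perturbations into the growth term
            params = GLVParameters(
                alpha=net_growth(params, active),
                beta=params.beta,
                gamma=np.zeros((params.n_taxa, 0)),
            )
        x0 = np.zeros(len(full))
        for i, taxon in enumerate(members):
            x0[full.index(taxon)] = x_star[i]
        x0[inv_pos] = dose
        try:
            traj = integrate(params, x0, (), t_grid)
        except BlowUpError:
            n_blowup += 1
            continue
        finals.append(traj[inv_pos, -1])
    finals = np.array(finals)
    med = float(np.median(finals)) if finals.size else float("nan")
    mad = float(np.median(np.abs(finals - med))) if finals.size else float("nan")
    return {"median": med, "mad": mad, "n_draws": int(finals.size),
            "n_blowup": n_blowup}


def rank_exclusion_communities(reports: list[StabilityReport],
                               taxa=None) -> pd.DataFrame:
    """Best invader-excluding stable community per community size.

    Each report must carry a ``challenge_outcome``; per size, the community
    minimizing the median invader concentration at horizon wins, with ties
    in the median broken by higher stability probability.  Sizes with no
    stable community are omitted.
    """
    rows = []
    by_size: dict[int, list[StabilityReport]] = {}
    for rep in reports:
        if not rep.challenge_outcome:
            continue
        by_size.setdefault(rep.size, []).append(rep)
    for size in sorted(by_size):
        best = min(
            by_size[size],
            key=lambda r: (r.challenge_outcome["median"], -r.stability_prob),
        )
        members = (tuple(taxa[i] for i in best.subcommunity) if taxa
                   else best.subcommunity)
        rows.append({
            "size": size,
            "members": ";".join(map(str, members)),
            "invader_median": best.challenge_outcome["median"],
            "invader_mad": best.challenge_outcome["mad"],
            "stability_prob": best.stability_prob,
        })
    return pd.DataFrame(rows)


def keystoneness(ps, active_perturbations=(),
                 stability_threshold: float = 0.9,
                 baseline: StabilityReport | None = None,
                 extra_thinning: int = 1) -> pd.DataFrame:
    """Rank taxa by the steady-state displacement their removal causes.

    Baseline = the largest sub-community with stability probability above
    the threshold (ties broken by higher probability, then lexicographic).
    For each member taxon, the reduced community's steady state is
    recomputed per draw; keystoneness Ky is the Euclidean distance between
    baseline and reduced steady states over the surviving taxa only
    (median across draws where both are stable).  Removals that leave no
    stable configuration are reported with ``stable_after_removal=False``
    and Ky = NaN.
    """
    draws = _as_draws(ps)
    if extra_thinning > 1:
        draws = draws[extra_thinning - 1::extra_thinning]
    if baseline is None:
        reports = enumerate_subcommunities(
            draws, active_perturbations, stability_threshold)
        if not reports:
            raise ValueError("no stable sub-community above the threshold")
        baseline = max(
            reports, key=lambda r: (r.size, r.stability_prob,
                                    tuple(-i for i in r.subcommunity)),
        )
    members = list(baseline.subcommunity)
    rows = []
    for taxon in members:
        reduced = tuple(t for t in members if t != taxon)
        keep = [i for i, t in enumerate(members) if t != taxon]
        dists = []
        for d, base_x in zip(baseline.stable_draw_ids, baseline.steady_states):
            if not reduced:
                continue
            res = steady_state(draws[d], reduced, active_perturbations)
            if res.degenerate or not res.feasible:
                continue
            if not is_stable(draws[d], reduced, res.x):
                continue
            dists.append(np.linalg.norm(base_x[keep] - res.x))
        stable_after = len(dists) > 0
        rows.append({
            "taxon": taxon,
            "keystoneness": float(np.median(dists)) if stable_after else np.nan,
            "stable_after_removal": stable_after,
            "n_draws": len(dists),
        })
    df = pd.DataFrame(rows)
    return df.sort_values("keystoneness", ascending=False,
                          na_position="last").reset_index(drop=True)


def compare_regime_biodiversity(reports_a: list[StabilityReport],
                                reports_b: list[StabilityReport]) -> dict:
    """Wilcoxon rank-sum on coexisting-taxon counts of two regimes' stable states."""
    counts_a = [r.size for r in reports_a]
    counts_b = [r.size for r in reports_b]
    if not counts_a or not counts_b:
        raise ValueError("each regime needs at least one stable state")
    res = mannwhitneyu(counts_a, counts_b, alternative="two-sided",
                       method="exact" if max(len(counts_a), len(counts_b)) <= 25
                       else "asymptotic")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "counts_a": counts_a, "counts_b": counts_b}
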