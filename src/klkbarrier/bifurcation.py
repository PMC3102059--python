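"""Bifurcation analysis over the external stimulus level.

The stimulus ``mu`` is the bifurcation parameter.  A scan enumerates
steady states on a ``mu`` grid; the resulting diagram is classified into
one of four patterns:

* ``reversible_bistable`` — hysteresis with both the inflammation
  threshold ``mu_on`` (where the low branch destabilises and the system
  jumps to high inflammation) and the deactivation threshold ``mu_off``
  (below which the high branch folds away) inside the feasible region
  ``mu > 0``; the bistability range is ``delta_mu = mu_on - mu_off``.
* ``irreversible_bistable`` — the high branch persists all the way to
  ``mu = 0``: once ignited, inflammation never ceases.
* ``continuous_monostable`` — a single stable branch everywhere.
* ``discontinuous_monostable`` — single stable branches at low and high
  stimulus separated by a window with no stable steady state.

The low branch is the analytic zero-activation branch (Kact = C = 0),
which exists for every ``mu``; ``mu_on`` is therefore located grid-free
by bisecting its Routh–Hurwitz verdict, and ``mu_off`` by bisecting the
fold of the numerically continued high branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import (
    ModelState,
    ParameterSet,
    ValidationError,
    _jac_arr,
    _rhs_arr,
    klk5_production,
    lekti_production,
    simulate,
)
from .steady import (
    STABLE,
    SearchConfig,
    SteadyState,
    classify_stability,
    find_steady_states,
    zero_activation_state,
)

__all__ = [
    "BifurcationDiagram",
    "BifurcationSummary",
    "PATTERNS",
    "scan_mu",
    "classify_pattern",
    "low_branch_threshold",
    "summarize_cell",
    "sweep_feedback_grid",
    "production_curves",
    "total_klk5_curve",
]

REVERSIBLE = "reversible_bistable"
IRREVERSIBLE = "irreversible_bistable"
CONTINUOUS = "continuous_monostable"
DISCONTINUOUS = "discontinuous_monostable"
UNCLASSIFIED = "unclassified"
PATTERNS = (REVERSIBLE, IRREVERSIBLE, CONTINUOUS, DISCONTINUOUS)

# A steady state is "ignited" (off the zero-activation branch) when its
# active-KLK5 level exceeds this absolute tolerance.
_KACT_TOL = 1e-6


@dataclass
class BifurcationDiagram:
    """Steady states per stimulus grid point, sorted by Pact."""

    mu_grid: np.ndarray
    branches: list[list[SteadyState]]
    params: ParameterSet | None = None  # None for hand-constructed diagrams

    def stable_counts(self) -> np.ndarray:
        return np.array(
            [sum(s.stability == STABLE for s in col) for col in self.branches]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mu, col in zip(self.mu_grid, self.branches):
            for b, s in enumerate(col):
                rows.append(
                    dict(
                        mu=mu,
                        branch=b,
                        **{f: getattr(s.state, f) for f in
                           ("L", "K", "Kact", "C", "P", "Pact")},
                        stability=s.stability,
                        residual=s.residual_norm,
                    )
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BifurcationSummary:
    """Pattern label plus thresholds for one mu-scan."""

    pattern: str
    mu_on: float | None
    mu_off: float | None
    delta_mu: float | None
    diagnostics: str = ""


def scan_mu(
    params: ParameterSet,
    mu_grid: Sequence[float],
    search: SearchConfig | None = None,
) -> BifurcationDiagram:
    """Enumerate and classify steady states at every stimulus grid point.

    States found at the previous grid point warm-start the next one, so
    branches are followed continuously through folds.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if mu_grid.ndim != 1 or len(mu_grid) < 2 or np.any(np.diff(mu_grid) <= 0):
        raise ValidationError("mu grid must be 1-D, strictly increasing")
    if mu_grid[0] < 0:
        raise ValidationError("mu grid must be non-negative")
    branches: list[list[SteadyState]] = []
    warm: list[np.ndarray] = []
    for mu in mu_grid:
        p = params.with_(mu=float(mu))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            states = find_steady_states(p, search=search, warm_starts=warm)
        branches.append(states)
        warm = [s.state.to_array() for s in states]
    return BifurcationDiagram(mu_grid=mu_grid, branches=branches, params=params)


def _low_branch_verdict(params: ParameterSet, mu: float) -> bool:
    """True when the analytic zero-activation branch is stable at mu."""
    p = params.with_(mu=float(mu))
    return classify_stability(zero_activation_state(p), p).stability == STABLE


def low_branch_threshold(
    params: ParameterSet,
    mu_max: float,
    rel_precision: float = 1e-4,
    coarse: int = 61,
) -> float | None:
    """Inflammation threshold mu_on: where the low branch destabilises.

    Scans a coarse grid for the first stability change of the analytic
    zero-activation branch, then bisects the change point to relative
    precision ``rel_precision``.  Returns None when the branch is stable
    on all of [0, mu_max].
    """
    grid = np.linspace(0.0, mu_max, coarse)
    verdicts = [_low_branch_verdict(params, m) for m in grid]
    idx = next((i for i, v in enumerate(verdicts) if not v), None)
    if idx is None:
        return None
    if idx == 0:
        return 0.0
    lo, hi = grid[idx - 1], grid[idx]
    while (hi - lo) > rel_precision * max(hi, 1e-6):
        mid = 0.5 * (lo + hi)
        if _low_branch_verdict(params, mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _newton_refine(y: np.ndarray, params: ParameterSet, iters: int = 3) -> np.ndarray:
    """A few exact-Newton steps to push the residual to solver tolerance."""
    for _ in range(iters):
        f = _rhs_arr(y, params)
        if np.max(np.abs(f)) < 1e-12:
            break
        try:
            step = np.linalg.solve(_jac_arr(y, params), -f)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        y = y + step
    return y


def _polish(y0: np.ndarray, params: ParameterSet) -> np.ndarray | None:
    sol = root(
        lambda y: _rhs_arr(y, params),
        y0,
        jac=lambda y: _jac_arr(y, params),
        method="hybr",
    )
    if not sol.success:
        return None
    x = _newton_refine(sol.x, params)
    if np.any(x < -1e-8):
        return None
    y = np.clip(x, 0.0, None)
    if np.max(np.abs(_rhs_arr(y, params))) > 1e-9:
        return None
    return y


def _stable_high_state(
    params: ParameterSet, mu: float, warm: np.ndarray | None = None
) -> np.ndarray | None:
    """A stable ignited (Kact > 0) steady state at mu, or None."""
    p = params.with_(mu=float(mu))
    candidates: list[np.ndarray] = []
    if warm is not None:
        candidates.append(warm)
    else:
        # Relax from a kicked zero-activation state: lands on whatever
        # attractor exists above threshold.
        y0 = zero_activation_state(p).to_array()
        y0[2] += 1.0
        for t_end in (300.0, 1500.0):
            try:
                traj = simulate(p, np.clip(y0, 0, None), [0.0, t_end],
                                rtol=1e-8, atol=1e-10)
            except Exception:
                return None
            yf = np.clip(traj.y[-1], 0.0, None)
            if np.max(np.abs(_rhs_arr(yf, p))) < 1e-6:
                break
            y0 = yf
        candidates.append(yf)
    for y0 in candidates:
        y = _polish(np.asarray(y0, float), p)
        if y is None or y[2] <= _KACT_TOL:
            continue
        st = classify_stability(ModelState.from_array(y), p)
        if st.stability == STABLE:
            return y
    return None


def _high_branch_floor(
    params: ParameterSet,
    mu_start: float,
    y_start: np.ndarray,
    rel_precision: float = 1e-4,
    n_steps: int = 120,
) -> float | None:
    """Continue the stable high branch from mu_start down toward 0.

    Returns the fold location (smallest mu where the branch survives,
    refined by bisection), or None when the branch persists at mu = 0.
    """
    grid = np.linspace(mu_start, 0.0, n_steps)
    y = y_start
    lo_ok, hi_bad = mu_start, None
    for mu in grid[1:]:
        y_next = _stable_high_state(params, mu, warm=y)
        if y_next is None:
            hi_bad = mu
            break
        y, lo_ok = y_next, mu
    if hi_bad is None:
        return None  # survives to mu = 0
    # bisect the fold between hi_bad (no branch) and lo_ok (branch)
    lo, hi = hi_bad, lo_ok
    while (hi - lo) > rel_precision * max(hi, 1e-6):
        mid = 0.5 * (lo + hi)
        y_mid = _stable_high_state(params, mid, warm=y)
        if y_mid is None:
            lo = mid
        else:
            y, hi = y_mid, mid
    return 0.5 * (lo + hi)


def summarize_cell(
    params: ParameterSet,
    mu_max: float = 60.0,
    rel_precision: float = 1e-4,
) -> BifurcationSummary:
    """Classify the bifurcation pattern of one parameter set directly.

    Fast path used by the feedback-strength sweeps: mu_on from the
    analytic low branch, mu_off from high-branch continuation, without
    a full multi-start scan at every grid point.
    """
    mu_on = low_branch_threshold(params, mu_max, rel_precision)
    # probe for an ignited attractor just above threshold (or at mu_max)
    mu_probe = mu_max if mu_on is None else min(mu_on * 1.02 + 0.05, mu_max)
    y_high = _stable_high_state(params, mu_probe)
    if y_high is None:
        if mu_on is None:
            return BifurcationSummary(CONTINUOUS, None, None, None)
        return BifurcationSummary(
            DISCONTINUOUS, mu_on, None, None,
            diagnostics="no stable state above the inflammation threshold",
        )
    fold = _high_branch_floor(params, mu_probe, y_high, rel_precision)
    if fold is None or fold <= 1e-9:
        if mu_on is None:
            return BifurcationSummary(
                UNCLASSIFIED, None, None, None,
                diagnostics="bistable at every scanned mu; increase mu_max",
            )
        return BifurcationSummary(IRREVERSIBLE, mu_on, None, None)
    if mu_on is None:
        return BifurcationSummary(
            UNCLASSIFIED, None, fold, None,
            diagnostics="bistable window open at mu_max; increase mu_max",
        )
    # The ignited branch can fold above the low-branch threshold: then a
    # stimulus window with no stable state separates the two monostable
    # regimes.  Within refinement precision of the threshold the branches
    # connect and the transition is continuous instead.
    gap_tol = max(10 * rel_precision * mu_on, 1e-3)
    if fold >= mu_on - gap_tol:
        if fold - mu_on > gap_tol:
            return BifurcationSummary(
                DISCONTINUOUS, mu_on, None, None,
                diagnostics=f"no stable state for mu in ({mu_on:.4g}, {fold:.4g})",
            )
        return BifurcationSummary(CONTINUOUS, None, None, None)
    return BifurcationSummary(REVERSIBLE, mu_on, fold, mu_on - fold)


def classify_pattern(
    diagram: BifurcationDiagram, refine: bool = True
) -> BifurcationSummary:
    """Assign one of the four bifurcation patterns to a mu-scan.

    Pattern edges are read from the grid (the bistable window is the set
    of mu with at least two stable states); when the diagram carries its
    parameter set and ``refine`` is true, mu_on and mu_off are sharpened
    grid-free via bisection.
    """
    counts = diagram.stable_counts()
    mu = diagram.mu_grid
    bistable = counts >= 2
    if bistable.any():
        first, last = np.flatnonzero(bistable)[[0, -1]]
        at_zero = bool(bistable[0])
        open_at_max = bool(bistable[-1])
        if open_at_max:
            if at_zero:
                return BifurcationSummary(
                    UNCLASSIFIED, None, None, None,
                    diagnostics="bistable at every scanned mu; increase mu_max",
                )
            return BifurcationSummary(
                UNCLASSIFIED, None, float(mu[first]), None,
                diagnostics="bistable window open at mu_max; increase mu_max",
            )
        mu_on = float(mu[last])
        mu_off = None if at_zero else float(mu[first])
        if refine and diagram.params is not None:
            refined_on = low_branch_threshold(diagram.params, float(mu[-1]))
            if refined_on is not None:
                mu_on = refined_on
            if mu_off is not None:
                col = diagram.branches[first]
                high = max(
                    (s for s in col if s.stability == STABLE), key=lambda s: s.Pact
                )
                fold = _high_branch_floor(
                    diagram.params, float(mu[first]), high.state.to_array()
                )
                mu_off = None if (fold is None or fold <= 1e-9) else fold
        if mu_off is None:
            return BifurcationSummary(IRREVERSIBLE, mu_on, None, None)
        return BifurcationSummary(REVERSIBLE, mu_on, mu_off, mu_on - mu_off)
    if (counts == 0).all():
        return BifurcationSummary(
            UNCLASSIFIED, None, None, None, diagnostics="no stable state anywhere"
        )
    if (counts == 0).any():
        return BifurcationSummary(
            DISCONTINUOUS, None, None, None,
            diagnostics="stable-state gap inside the scanned mu range",
        )
    return BifurcationSummary(CONTINUOUS, None, None, None)


def sweep_feedback_grid(
    condition: str,
    variant: int,
    alphaK_range: tuple[float, float] = (0.0, 1.0),
    alphaL_range: tuple[float, float] | None = None,
    resolution: int = 21,
    mu_max: float = 60.0,
    overrides: dict | None = None,
) -> pd.DataFrame:
    """Pattern / mu_on / delta_mu maps over a feedback-strength grid.

    Returns a long-format frame with columns (condition, variant,
    alphaK, alphaL, pattern, mu_on, mu_off, delta_mu).  Default ranges
    follow the printed ones: alphaK in [0, 1]; alphaL in [0, 0.5] for
    variant 1 and [0, 10] for variant 2.
    """
    from .model import build_parameters

    if alphaL_range is None:
        alphaL_range = (0.0, 0.5) if variant == 1 else (0.0, 10.0)
    aKs = np.linspace(*alphaK_range, resolution)
    aLs = np.linspace(*alphaL_range, resolution)
    rows = []
    for aL in aLs:
        for aK in aKs:
            over = dict(overrides or {})
            over.update(alphaK=float(aK), alphaL=float(aL))
            p = build_parameters(condition, variant, over)
            s = summarize_cell(p, mu_max=mu_max)
            rows.append(
                dict(
                    condition=condition,
                    variant=variant,
                    alphaK=float(aK),
                    alphaL=float(aL),
                    pattern=s.pattern,
                    mu_on=s.mu_on,
                    mu_off=s.mu_off,
                    delta_mu=s.delta_mu,
                )
            )
    return pd.DataFrame(rows)


def production_curves(
    params: ParameterSet, mu_grid: Sequence[float],
    search: SearchConfig | None = None,
    diagram: BifurcationDiagram | None = None,
) -> pd.DataFrame:
    """Realised production rates f_K, f_L per steady-state branch.

    For every steady state of the scan, reports the production inputs
    evaluated at (mu, Pact) together with the inflammation level —
    the axes of the model-vs-expression comparison.
    """
    diagram = diagram or scan_mu(params, mu_grid, search=search)
    rows = []
    for mu, col in zip(diagram.mu_grid, diagram.branches):
        for b, s in enumerate(col):
            rows.append(
                dict(
                    mu=float(mu),
                    branch=b,
                    Pact=s.Pact,
                    stability=s.stability,
                    f_K=klk5_production(float(mu), s.Pact, params),
                    f_L=lekti_production(float(mu), s.Pact, params),
                )
            )
    return pd.DataFrame(rows)


def total_klk5_curve(
    params: ParameterSet, mu_grid: Sequence[float],
    search: SearchConfig | None = None,
    diagram: BifurcationDiagram | None = None,
) -> pd.DataFrame:
    """Total KLK5-lineage material (K + Kact + C) per branch vs mu."""
    diagram = diagram or scan_mu(params, mu_grid, search=search)
    rows = []
    for mu, col in zip(diagram.mu_grid, diagram.branches):
        for b, s in enumerate(col):
            st = s.state
            rows.append(
                dict(
                    mu=float(mu),
                    branch=b,
                    Pact=s.Pact,
                    stability=s.stability,
                    total_klk5=st.K + st.Kact + st.C,
                )
            )
    return pd.DataFrame(rows)
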