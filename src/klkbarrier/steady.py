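"""Steady-state enumeration and Routh–Hurwitz stability classification.

The model admits one analytically tractable steady state for every
stimulus level: the zero-activation branch with Kact = C = 0 (active
KLK5 never appears because self-activation needs a seed of KLK5*).  All
other branches are found numerically by damped Newton iteration from a
deterministic multi-start set.  Stability is read off the characteristic
polynomial of the analytic Jacobian through the Routh–Hurwitz criterion,
with the leading eigenvalue real part kept as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import root
from scipy.stats import qmc

from .model import (
    ModelState,
    ParameterSet,
    ValidationError,
    _jac_arr,
    _rhs_arr,
    klk5_production,
    lekti_production,
)

__all__ = [
    "SteadyState",
    "SearchConfig",
    "zero_activation_state",
    "find_steady_states",
    "characteristic_polynomial",
    "routh_hurwitz_verdict",
    "classify_stability",
]

STABLE, UNSTABLE, MARGINAL = "stable", "unstable", "marginal"


@dataclass(frozen=True)
class SteadyState:
    """One verified fixed point of the model."""

    state: ModelState
    residual_norm: float
    stability: str  # "stable" | "unstable" | "marginal"
    leading_eigenvalue_real: float

    @property
    def Pact(self) -> float:
        return self.state.Pact


@dataclass(frozen=True)
class SearchConfig:
    """Multi-start root-search settings.

    The start set is deterministic: the analytic zero-activation state,
    a high-activation heuristic state, ``n_quasirandom`` unscrambled
    Sobol' points mapped log-uniformly onto per-species scale ranges,
    plus any caller-supplied warm starts.
    """

    n_quasirandom: int = 32
    residual_tol: float = 1e-9
    dedup_rtol: float = 1e-6
    log_range: tuple[float, float] = (1e-2, 1e3)


def zero_activation_state(params: ParameterSet) -> ModelState:
    """The analytic zero-inflammation steady state (exists for every mu).

    With no active KLK5 the complex and activated PAR2 drain away
    (Kact = C = Pact = 0) and the remaining species sit at their linear
    production/degradation balances: K = f_K(mu,0)/deltaK,
    L = f_L(mu,0)/deltaL, P = bP/deltaP.
    """
    p = params
    K = klk5_production(p.mu, 0.0, p) / p.deltaK
    L = lekti_production(p.mu, 0.0, p) / p.deltaL
    return ModelState(L=L, K=K, Kact=0.0, C=0.0, P=p.bP / p.deltaP, Pact=0.0)


def _high_activation_heuristic(params: ParameterSet) -> np.ndarray:
    """Rough location of a fully ignited state, used only to seed Newton."""
    p = params
    Kact = max(p.kA / max(p.deltaKact, 1e-6), 1.0)
    a = p.deltaP
    b = p.kP * Kact + p.deltaP * p.mP - p.bP
    c = -p.bP * p.mP
    P = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    Pact = p.kP * (Kact + p.mu) * P / (p.mP + P) / max(p.deltaPact, 1e-6)
    K = klk5_production(p.mu, Pact, p) / p.deltaK
    L = lekti_production(p.mu, Pact, p) / max(
        p.deltaL + p.kon * Kact * 0.5, 1e-6
    )
    C = p.kon * L * Kact / max(p.koff + p.deltaC, 1e-6)
    return np.array([L, K, Kact, C, P, Pact])


_SOBOL_CACHE: dict[int, np.ndarray] = {}


def _sobol_unit(n: int) -> np.ndarray:
    if n not in _SOBOL_CACHE:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non power-of-two draws
            _SOBOL_CACHE[n] = qmc.Sobol(d=6, scramble=False).random(n)
    return _SOBOL_CACHE[n]


def _start_points(
    params: ParameterSet,
    config: SearchConfig,
    warm_starts: Iterable[Sequence[float]] = (),
) -> list[np.ndarray]:
    starts = [zero_activation_state(params).to_array(), _high_activation_heuristic(params)]
    lo, hi = config.log_range
    scale = np.array(
        [
            max(params.bL / params.deltaL, 1e-3),
            max(params.mK, 1e-3),
            max(params.kA / max(params.deltaKact, 1e-6), 1e-3),
            max(params.bL / params.deltaL, 1e-3),
            max(params.bP / params.deltaP, 1e-3),
            max(params.kA / max(params.deltaPact, 1e-6), 1e-3),
        ]
    )
    if config.n_quasirandom > 0:
        u = _sobol_unit(config.n_quasirandom)
        pts = scale * lo * (hi / lo) ** u  # log-uniform over scale*[lo, hi]
        starts.extend(pts)
    starts.extend(np.asarray(w, dtype=float) for w in warm_starts)
    return starts


def find_steady_states(
    params: ParameterSet,
    search: SearchConfig | None = None,
    warm_starts: Iterable[Sequence[float]] = (),
) -> list[SteadyState]:
    """Enumerate distinct non-negative steady states, classified.

    Roots found from different starts are merged when equal to relative
    tolerance ``search.dedup_rtol`` (the lowest-residual representative
    is kept); every returned state satisfies max|rhs| < residual_tol.
    States are sorted by the inflammation level Pact.
    """
    config = search or SearchConfig()
    found: list[tuple[np.ndarray, float]] = []
    for y0 in _start_points(params, config, warm_starts):
        sol = root(
            lambda y: _rhs_arr(y, params),
            y0,
            jac=lambda y: _jac_arr(y, params),
            method="hybr",
        )
        if not sol.success:
            continue
        y = sol.x
        # a few exact-Newton steps to reach the residual tolerance
        for _ in range(3):
            f = _rhs_arr(y, params)
            if np.max(np.abs(f)) < 1e-12:
                break
            try:
                y_next = y + np.linalg.solve(_jac_arr(y, params), -f)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(y_next)):
                break
            y = y_next
        if np.any(y < -1e-8):
            continue
        y = np.clip(y, 0.0, None)
        res = float(np.max(np.abs(_rhs_arr(y, params))))
        if res > config.residual_tol:
            continue
        merged = False
        for i, (yk, rk) in enumerate(found):
            denom = np.maximum(np.abs(yk), 1.0)
            if np.max(np.abs(y - yk) / denom) < config.dedup_rtol:
                if res < rk:
                    found[i] = (y, res)
                merged = True
                break
        if not merged:
            found.append((y, res))
    if not found:
        warnings.warn(
            "no steady state found from any start point", RuntimeWarning, stacklevel=2
        )
    out = [
        classify_stability(ModelState.from_array(y), params, residual=res)
        for y, res in found
    ]
    return sorted(out, key=lambda s: s.Pact)


def characteristic_polynomial(matrix: np.ndarray) -> np.ndarray:
    """Monic coefficients of det(lambda*I - J), highest degree first."""
    J = np.asarray(matrix, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {J.shape}")
    return np.poly(J)


def routh_hurwitz_verdict(
    coefficients: Sequence[float], marginal_rtol: float = 1e-9
) -> str:
    """Routh–Hurwitz stability verdict from polynomial coefficients.

    Builds the Routh array; all first-column entries strictly positive
    (after normalising the leading coefficient to +1) means every root
    has negative real part.  A first-column entry within
    ``marginal_rtol`` of zero relative to its row scale yields
    "marginal"; any sign change yields "unstable".
    """
    a = np.asarray(coefficients, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise ValidationError("need a polynomial of degree >= 1")
    if a[0] == 0:
        raise ValidationError("leading coefficient must be nonzero")
    a = a / a[0]
    n = len(a) - 1
    width = (n + 2) // 2
    table = np.zeros((n + 1, width + 1))
    table[0, : len(a[0::2])] = a[0::2]
    table[1, : len(a[1::2])] = a[1::2]
    scale = float(np.max(np.abs(a)))
    marginal = False
    if n >= 1 and abs(table[1, 0]) <= marginal_rtol * scale:
        marginal = True
        table[1, 0] = marginal_rtol * scale  # epsilon continuation
    for i in range(2, n + 1):
        pivot = table[i - 1, 0]
        for j in range(width):
            table[i, j] = (
                table[i - 1, 0] * table[i - 2, j + 1]
                - table[i - 2, 0] * table[i - 1, j + 1]
            ) / pivot
        row_scale = max(float(np.max(np.abs(table[i - 2 : i + 1]))), scale)
        if abs(table[i, 0]) <= marginal_rtol * row_scale:
            marginal = True
            table[i, 0] = marginal_rtol * row_scale
    first_col = table[: n + 1, 0]
    if np.any(first_col < 0):
        return UNSTABLE
    return MARGINAL if marginal else STABLE


def classify_stability(
    state: ModelState,
    params: ParameterSet,
    residual: float | None = None,
    marginal_rtol: float = 1e-9,
) -> SteadyState:
    """Stability of a verified steady state via the Routh–Hurwitz route.

    The eigenvalue with the largest real part is recorded as a
    diagnostic; the verdict itself comes from the Routh array of the
    characteristic polynomial so that it never relies on an eigensolver.
    """
    J = _jac_arr(state.to_array(), params)
    coeffs = characteristic_polynomial(J)
    verdict = routh_hurwitz_verdict(coeffs, marginal_rtol=marginal_rtol)
    lead = float(np.max(np.linalg.eigvals(J).real))
    if residual is None:
        residual = float(np.max(np.abs(_rhs_arr(state.to_array(), params))))
    return SteadyState(
        state=state,
        residual_norm=residual,
        stability=verdict,
        leading_eigenvalue_real=lead,
    )
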