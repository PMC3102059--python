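"""Core ODE model of KLK5–LEKTI–PAR2 feedback regulation in the skin barrier.

The model tracks six species at the granular/cornified-layer interface:
LEKTI (``L``), inactive KLK5 (``K``), proteolytically active KLK5
(``Kact``), the inert LEKTI–KLK5* complex (``C``), inactive PAR2 (``P``)
and activated PAR2 (``Pact``).  ``Pact`` is the model's inflammation
readout.  Active KLK5 self-activates its precursor and cleaves PAR2, both
through saturating (Michaelis–Menten) kinetics; LEKTI sequesters active
KLK5 into a reversible complex; every species degrades first-order.

The external stimulus ``mu`` drives KLK5 and LEKTI production through
the input functions ``f_K``/``f_L``; PAR2 is cleaved by active KLK5
only.  The zero-activation state (Kact = Pact = 0) is therefore a fixed
point at every stimulus level, and inflammation "outbreaks" when that
branch loses stability at the threshold stimulus.

Two model variants differ in the hypothesised feedback from activated
PAR2 to LEKTI production: variant 1 has positive feedback
(``f_L = rho_L (b_L + kappa_L mu + alpha_L Pact)``), variant 2 negative
feedback (``f_L = rho_L (b_L + kappa_L mu) k_I / (k_I + Pact)``).  KLK5
production carries positive feedback in both
(``f_K = b_K + kappa_K mu + alpha_K Pact``).

All quantities are nondimensionalised with the pH-4.5 LEKTI–KLK5*
association/dissociation rates set to 1; a unit degradation rate
corresponds to a protein half-life of roughly 15 minutes (see
:func:`half_life_minutes`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelState",
    "ParameterSet",
    "CONDITIONS",
    "TIED_PARAMETERS",
    "build_parameters",
    "klk5_production",
    "lekti_production",
    "rhs",
    "jacobian",
    "simulate",
    "Trajectory",
    "half_life_minutes",
    "NONDIMENSIONAL_TIME_MINUTES",
]

#: One nondimensional time unit expressed in minutes, implied by the
#: half-life calibration (degradation rate 1 <-> 15 min half-life):
#: t_unit = 15 / ln 2 ~ 21.6 min.  Documentation constant only; never
#: used in any computation.
NONDIMENSIONAL_TIME_MINUTES = 15.0 / float(np.log(2.0))

STATE_FIELDS = ("L", "K", "Kact", "C", "P", "Pact")


class ConfigurationError(ValueError):
    """Unknown condition, variant or parameter name."""


class ValidationError(ValueError):
    """A value violates a model precondition (e.g. negativity)."""


@dataclass(frozen=True)
class ModelState:
    """Concentrations of the six model species (nondimensional).

    Component order is fixed as (L, K, Kact, C, P, Pact) so that state
    vectors round-trip losslessly through :meth:`to_array` /
    :meth:`from_array`.
    """

    L: float
    K: float
    Kact: float
    C: float
    P: float
    Pact: float

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"concentration {name}={v!r} must be finite and >= 0"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise ValidationError(f"state vector must have shape (6,), got {y.shape}")
        return cls(*map(float, y))


# Table of nominal rate constants.  pH-dependent entries (kon, koff, kA)
# and the LEKTI production capability rhoL are overridden per condition.
_NOMINAL = dict(
    kon=1.0,        # LEKTI-KLK5* association rate (1 at pH 4.5)
    koff=1.0,       # LEKTI-KLK5* dissociation rate (1 at pH 4.5)
    kA=10.0,        # KLK5 activation rate (10 at pH 4.5)
    kP=10.0,        # PAR2 activation rate; tied to kA
    deltaL=0.5,     # LEKTI degradation rate
    deltaK=1.0,     # KLK5 degradation rate
    deltaC=0.5,     # LEKTI-KLK5* complex degradation rate
    deltaKact=1.0,  # KLK5* degradation rate; tied to deltaK
    deltaP=0.5,     # PAR2 degradation rate
    deltaPact=0.5,  # PAR2* degradation rate; tied to deltaP
    rhoL=1.0,       # LEKTI production capability (1 HC, 0.5 AD-LEKTI)
    mK=50.0,        # half-saturation of KLK5 activation
    mP=50.0,        # half-saturation of PAR2 activation; tied to mK
    kI=5.0,         # inhibition constant (variant 2 only)
    bP=10.0,        # basal PAR2 production rate
    bL=1.0,         # basal LEKTI production rate
    bK=0.0,         # basal KLK5 production rate (0: pure level shift)
    kappaK=0.5,     # rate of KLK5 production by stimulus
    kappaL=0.05,    # rate of LEKTI production by stimulus (0 in variant 2)
    alphaK=0.5,     # feedback strength PAR2* -> KLK5 (printed range 0-1)
    alphaL=0.25,    # feedback strength PAR2* -> LEKTI (mid printed range)
    mu=0.0,         # external stimulus level
)

# pH-dependent triples: (kon, koff, kA).  The pH-6.5 dissociation rate is
# 2.5e2, i.e. ~83x weaker LEKTI-KLK5* affinity at AD-like surface pH.
_PH_RATES = {4.5: (1.0, 1.0, 10.0), 6.5: (3.0, 250.0, 50.0)}

#: Condition presets: name -> (rhoL, pH).
CONDITIONS = {
    "HC": (1.0, 4.5),
    "AD-LEKTI": (0.5, 4.5),
    "AD-pH": (1.0, 6.5),
    "AD-LEKTI/pH": (0.5, 6.5),
}

#: Equality ties stated as modelling assumptions: dependent -> source.
#: Applied last in :func:`build_parameters` unless the dependent name is
#: overridden explicitly.
TIED_PARAMETERS = {
    "kP": "kA",
    "mP": "mK",
    "deltaKact": "deltaK",
    "deltaPact": "deltaP",
}

_PARAM_NAMES = tuple(_NOMINAL)


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants and inputs for one model variant/condition."""

    variant: int = 1
    kon: float = 1.0
    koff: float = 1.0
    kA: float = 10.0
    kP: float = 10.0
    deltaL: float = 0.5
    deltaK: float = 1.0
    deltaC: float = 0.5
    deltaKact: float = 1.0
    deltaP: float = 0.5
    deltaPact: float = 0.5
    rhoL: float = 1.0
    mK: float = 50.0
    mP: float = 50.0
    kI: float = 5.0
    bP: float = 10.0
    bL: float = 1.0
    bK: float = 0.0
    kappaK: float = 0.5
    kappaL: float = 0.05
    alphaK: float = 0.5
    alphaL: float = 0.25
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in (1, 2):
            raise ConfigurationError(f"variant must be 1 or 2, got {self.variant!r}")
        for name in _PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"parameter {name}={v!r} must be finite and >= 0")

    def with_(self, **overrides: float) -> "ParameterSet":
        unknown = set(overrides) - set(_PARAM_NAMES) - {"variant"}
        if unknown:
            raise ConfigurationError(f"unknown parameter name(s): {sorted(unknown)}")
        return replace(self, **overrides)

    def as_dict(self) -> dict:
        d = {"variant": self.variant}
        d.update({n: getattr(self, n) for n in _PARAM_NAMES})
        return d


def build_parameters(
    condition: str,
    variant: int = 1,
    overrides: Mapping[str, float] | None = None,
) -> ParameterSet:
    """Assemble a :class:`ParameterSet` for a named condition.

    Nominal values are taken from the simulation parameter table, the
    condition-specific LEKTI production capability and pH-dependent
    (kon, koff, kA) triple are applied, then user overrides, and finally
    the stated equality ties (kP=kA, mP=mK, deltaKact=deltaK,
    deltaPact=deltaP) — a tie is broken only when its dependent name is
    set explicitly in ``overrides``.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(
            f"unknown condition {condition!r}; expected one of {sorted(CONDITIONS)}"
        )
    if variant not in (1, 2):
        raise ConfigurationError(f"variant must be 1 or 2, got {variant!r}")
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(_PARAM_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown parameter name(s): {sorted(unknown)}")

    values = dict(_NOMINAL)
    rhoL, ph = CONDITIONS[condition]
    values["rhoL"] = rhoL
    values["kon"], values["koff"], values["kA"] = _PH_RATES[ph]
    if variant == 2:
        # Stimulus-driven LEKTI production is absent in the
        # negative-feedback variant; its feedback range is 0-10.
        values["kappaL"] = 0.0
        values["alphaL"] = 5.0
    values.update(overrides)
    for dependent, source in TIED_PARAMETERS.items():
        if dependent not in overrides:
            values[dependent] = values[source]
    return ParameterSet(variant=variant, **values)


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise ValidationError(f"{name}={v!r} must be >= 0")


def klk5_production(mu: float, Pact: float, params: ParameterSet) -> float:
    """KLK5 production input f_K = bK + kappaK*mu + alphaK*Pact."""
    _check_nonneg(mu=mu, Pact=Pact)
    return params.bK + params.kappaK * mu + params.alphaK * Pact


def lekti_production(mu: float, Pact: float, params: ParameterSet) -> float:
    """LEKTI production input f_L, scaled by the capability rhoL.

    Variant 1 (positive feedback): rhoL*(bL + kappaL*mu + alphaL*Pact).
    Variant 2 (negative feedback): rhoL*(bL + kappaL*mu)*kI/(kI + Pact).
    """
    _check_nonneg(mu=mu, Pact=Pact)
    base = params.bL + params.kappaL * mu
    if params.variant == 1:
        return params.rhoL * (base + params.alphaL * Pact)
    return params.rhoL * base * params.kI / (params.kI + Pact)


def _rhs_arr(y: np.ndarray, p: ParameterSet) -> np.ndarray:
    L, K, Kact, C, P, Pact = y
    fK = p.bK + p.kappaK * p.mu + p.alphaK * Pact
    if p.variant == 1:
        fL = p.rhoL * (p.bL + p.kappaL * p.mu + p.alphaL * Pact)
    else:
        fL = p.rhoL * (p.bL + p.kappaL * p.mu) * p.kI / (p.kI + Pact)
    activation = p.kA * Kact * K / (p.mK + K)
    assoc = p.kon * L * Kact
    dissoc = p.koff * C
    par2_act = p.kP * Kact * P / (p.mP + P)
    return np.array(
        [
            fL - assoc + dissoc - p.deltaL * L,
            fK - activation - p.deltaK * K,
            activation - assoc + dissoc - p.deltaKact * Kact,
            assoc - dissoc - p.deltaC * C,
            p.bP - par2_act - p.deltaP * P,
            par2_act - p.deltaPact * Pact,
        ]
    )


def rhs(state: ModelState | Sequence[float], params: ParameterSet) -> np.ndarray:
    """Time derivatives (dL, dK, dKact, dC, dP, dPact) at ``state``."""
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state, float)
    if y.shape != (6,):
        raise ValidationError(f"state vector must have shape (6,), got {y.shape}")
    return _rhs_arr(y, params)


def _jac_arr(y: np.ndarray, p: ParameterSet) -> np.ndarray:
    L, K, Kact, C, P, Pact = y
    J = np.zeros((6, 6))
    # d(activation)/dK and /dKact for kA*Kact*K/(mK+K)
    act_K = p.kA * Kact * p.mK / (p.mK + K) ** 2
    act_Ka = p.kA * K / (p.mK + K)
    # PAR2 activation kP*Kact*P/(mP+P)
    pa_Ka = p.kP * P / (p.mP + P)
    pa_P = p.kP * Kact * p.mP / (p.mP + P) ** 2
    # f_K partials
    fK_Pa = p.alphaK
    # f_L partials
    if p.variant == 1:
        fL_Pa = p.rhoL * p.alphaL
    else:
        fL_Pa = -p.rhoL * (p.bL + p.kappaL * p.mu) * p.kI / (p.kI + Pact) ** 2

    # dL/dt = fL - kon*L*Kact + koff*C - deltaL*L
    J[0, 0] = -p.kon * Kact - p.deltaL
    J[0, 2] = -p.kon * L
    J[0, 3] = p.koff
    J[0, 5] = fL_Pa
    # dK/dt = fK - activation - deltaK*K
    J[1, 1] = -act_K - p.deltaK
    J[1, 2] = -act_Ka
    J[1, 5] = fK_Pa
    # dKact/dt = activation - kon*L*Kact + koff*C - deltaKact*Kact
    J[2, 0] = -p.kon * Kact
    J[2, 1] = act_K
    J[2, 2] = act_Ka - p.kon * L - p.deltaKact
    J[2, 3] = p.koff
    # dC/dt = kon*L*Kact - koff*C - deltaC*C
    J[3, 0] = p.kon * Kact
    J[3, 2] = p.kon * L
    J[3, 3] = -p.koff - p.deltaC
    # dP/dt = bP - par2_act - deltaP*P
    J[4, 2] = -pa_Ka
    J[4, 4] = -pa_P - p.deltaP
    # dPact/dt = par2_act - deltaPact*Pact
    J[5, 2] = pa_Ka
    J[5, 4] = pa_P
    J[5, 5] = -p.deltaPact
    return J


def jacobian(state: ModelState | Sequence[float], params: ParameterSet) -> np.ndarray:
    """Analytic 6x6 Jacobian of :func:`rhs` at ``state``."""
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state, float)
    if y.shape != (6,):
        raise ValidationError(f"state vector must have shape (6,), got {y.shape}")
    return _jac_arr(y, params)


@dataclass
class Trajectory:
    """Time-indexed solution of the model ODEs."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), 6), columns in STATE_FIELDS order

    def state(self, i: int) -> ModelState:
        return ModelState.from_array(np.clip(self.y[i], 0.0, None))

    def final(self) -> ModelState:
        return self.state(-1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.y, columns=list(STATE_FIELDS)).assign(time=self.t)[
            ["time", *STATE_FIELDS]
        ]


class IntegrationError(RuntimeError):
    pass


def simulate(
    params: ParameterSet,
    initial: ModelState | Sequence[float],
    t: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model with a stiff-capable solver (LSODA).

    ``t`` is a strictly increasing time grid; the trajectory is sampled
    at exactly those times.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValidationError("time grid must be 1-D, strictly increasing, length >= 2")
    y0 = initial.to_array() if isinstance(initial, ModelState) else np.asarray(initial, float)
    sol = solve_ivp(
        lambda _t, y: _rhs_arr(y, params),
        (t[0], t[-1]),
        y0,
        t_eval=t,
        method="LSODA",
        jac=lambda _t, y: _jac_arr(y, params),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return Trajectory(t=sol.t, y=sol.y.T)


def half_life_minutes(
    rate: float, calibration: tuple[float, float] = (1.0, 15.0)
) -> float:
    """Convert a nondimensional degradation rate to a half-life in minutes.

    Exponential decay scales inversely with the rate, so with the default
    calibration (rate 1.0 <-> 15 minutes) a rate of 0.5 gives 30 minutes
    and 0.2 gives 75 minutes.
    """
    if rate <= 0:
        raise ValidationError(f"degradation rate must be > 0, got {rate!r}")
    ref_rate, ref_minutes = calibration
    if ref_rate <= 0 or ref_minutes <= 0:
        raise ValidationError("calibration must be positive")
    return ref_minutes * ref_rate / rate
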