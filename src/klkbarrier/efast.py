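"""Extended Fourier Amplitude Sensitivity Test (eFAST).

Variance-based global sensitivity analysis: each parameter is driven
along a sinusoidal search curve through its range, the model output is
Fourier-analysed, and the variance at the frequency assigned to the
parameter of interest (plus harmonics) gives its first-order index
``Si``, while one minus the variance at the complementary (low)
frequencies gives its total-order index ``STi``.

Parameter ranges default to one order of magnitude total span centred
geometrically on the baseline, i.e. [baseline/sqrt(10), baseline*sqrt(10)],
sampled log-uniformly; linear intervals are also supported for test
functions.  The applied sensitivity entry point evaluates the model's
steady-state inflammation level [PAR2*] reached by relaxation from a
KLK5*-seeded state (the "ignited-start" convention, deterministic in
the bistable regime); see :func:`run_model_sensitivity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import ParameterSet, build_parameters, simulate, _rhs_arr, _jac_arr

__all__ = [
    "ParamRange",
    "EfastDesign",
    "SensitivityResult",
    "efast_design",
    "efast_indices",
    "run_model_sensitivity",
]


class NyquistError(ValueError):
    """Samples per curve too few for the requested frequencies."""


@dataclass(frozen=True)
class ParamRange:
    """Sampling range for one factor.

    ``log`` ranges are (baseline, factor): the interval
    [baseline/sqrt(factor), baseline*sqrt(factor)] sampled log-uniformly.
    ``linear`` ranges are plain (low, high) intervals.
    """

    name: str
    a: float
    b: float
    scale: str = "log"  # "log" | "linear"

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map unit-interval samples onto the parameter range."""
        if self.scale == "log":
            if self.a <= 0 or self.b <= 0:
                raise ValueError(f"{self.name}: log range needs positive baseline/factor")
            return self.a * self.b ** (u - 0.5)
        return self.a + (self.b - self.a) * u

    def bounds(self) -> tuple[float, float]:
        lo, hi = self.transform(np.array([0.0, 1.0]))
        return float(lo), float(hi)


@dataclass
class EfastDesign:
    """Sample matrix plus the frequency bookkeeping needed for analysis."""

    names: list[str]
    samples: np.ndarray          # (k * resamples * n_per_curve, k)
    n_per_curve: int
    resamples: int
    omega_max: int
    harmonics: int
    seed: int

    @property
    def n_rows(self) -> int:
        return self.samples.shape[0]


def _complementary_frequencies(k: int, omega_max: int, harmonics: int) -> np.ndarray:
    """Low frequencies for the k-1 complementary factors."""
    m = max(omega_max // (2 * harmonics), 1)
    if k == 1:
        return np.array([], dtype=int)
    if m >= k - 1:
        return np.floor(np.linspace(1, m, k - 1)).astype(int)
    return (np.arange(k - 1) % m) + 1


def efast_design(
    param_ranges: Sequence[ParamRange] | Mapping[str, tuple[float, float]],
    n_per_curve: int = 65,
    resamples: int = 1,
    harmonics: int = 4,
    seed: int = 0,
) -> EfastDesign:
    """Build the eFAST search-curve sample matrix.

    One block of ``n_per_curve`` rows is generated per (factor,
    resample) pair; within a block the factor of interest oscillates at
    the highest resolvable frequency ``omega_max = (n_per_curve-1)/(2*M)``
    while the others move at low complementary frequencies.  Random
    phase shifts (one draw per block, from ``seed``) decorrelate
    resamples.  Nyquist requires ``omega_max >= 2*M``; violations raise
    :class:`NyquistError`.
    """
    if isinstance(param_ranges, Mapping):
        param_ranges = [
            ParamRange(name, a, b) for name, (a, b) in param_ranges.items()
        ]
    names = [pr.name for pr in param_ranges]
    k = len(names)
    if k == 0:
        raise ValueError("need at least one parameter")
    if n_per_curve % 2 == 0:
        raise NyquistError("n_per_curve must be odd")
    omega_max = (n_per_curve - 1) // (2 * harmonics)
    if omega_max < 2 * harmonics:
        raise NyquistError(
            f"n_per_curve={n_per_curve} too small for {harmonics} harmonics: "
            f"need at least {4 * harmonics**2 + 1}"
        )
    rng = np.random.default_rng(seed)
    omega_c = _complementary_frequencies(k, omega_max, harmonics)
    s = np.pi * (2 * np.arange(1, n_per_curve + 1) - n_per_curve - 1) / n_per_curve
    blocks = []
    for i in range(k):
        omega = np.empty(k)
        omega[i] = omega_max
        omega[np.arange(k) != i] = omega_c
        for _ in range(resamples):
            phi = rng.uniform(0, 2 * np.pi, size=k)
            angle = np.outer(s, omega) + phi
            u = 0.5 + np.arcsin(np.sin(angle)) / np.pi
            x = np.column_stack(
                [param_ranges[j].transform(u[:, j]) for j in range(k)]
            )
            blocks.append(x)
    return EfastDesign(
        names=names,
        samples=np.vstack(blocks),
        n_per_curve=n_per_curve,
        resamples=resamples,
        omega_max=omega_max,
        harmonics=harmonics,
        seed=seed,
    )


@dataclass
class SensitivityResult:
    """First/total-order eFAST indices per parameter."""

    names: list[str]
    Si: np.ndarray
    STi: np.ndarray
    n_samples: int
    omega_max: int
    resamples: int
    seed: int
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"parameter": self.names, "Si": self.Si, "STi": self.STi})
        df["rank"] = df["STi"].rank(ascending=False, method="min").astype(int)
        return df.sort_values("rank").reset_index(drop=True)

    def ranked(self, by: str = "STi") -> list[str]:
        order = np.argsort(-(self.STi if by == "STi" else self.Si))
        return [self.names[i] for i in order]


def efast_indices(outputs: np.ndarray, design: EfastDesign) -> SensitivityResult:
    """Compute (Si, STi) per parameter from per-row model outputs.

    ``Si`` is the output variance at the factor's assigned frequency and
    its first M harmonics divided by total variance; ``STi`` is one
    minus the share at the complementary frequencies (all frequencies up
    to omega_max/2).  Indices are averaged over resample blocks.  A
    zero-variance block contributes all-zero indices with a warning.
    """
    y = np.asarray(outputs, dtype=float)
    if y.shape != (design.n_rows,):
        raise ValueError(
            f"outputs must have shape ({design.n_rows},), got {y.shape}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("outputs must be finite; filter failures first")
    k = len(design.names)
    NS, M, wmax = design.n_per_curve, design.harmonics, design.omega_max
    Si = np.zeros(k)
    STi = np.zeros(k)
    idx = 0
    for i in range(k):
        si_acc, sti_acc = [], []
        for _ in range(design.resamples):
            yb = y[idx : idx + NS]
            idx += NS
            c = np.fft.rfft(yb - yb.mean()) / NS
            power = 2.0 * np.abs(c[1 : (NS - 1) // 2 + 1]) ** 2
            V = power.sum()
            if V <= 0:
                warnings.warn(
                    "zero output variance in an eFAST block; indices set to 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
                si_acc.append(0.0)
                sti_acc.append(0.0)
                continue
            D1 = power[[p * wmax - 1 for p in range(1, M + 1)]].sum()
            Dt = power[: wmax // 2].sum()
            si_acc.append(D1 / V)
            sti_acc.append(1.0 - Dt / V)
        Si[i] = np.mean(si_acc)
        STi[i] = np.mean(sti_acc)
    return SensitivityResult(
        names=list(design.names),
        Si=Si,
        STi=STi,
        n_samples=design.n_rows,
        omega_max=wmax,
        resamples=design.resamples,
        seed=design.seed,
    )


# Parameters perturbed in the applied analysis.  Equality ties are
# broken here on purpose: the active/inactive degradation rates, the
# two activation rates and the two half-saturations are varied
# independently so their sensitivities can be compared.
_MODEL_FACTORS = (
    "kon", "koff", "kA", "kP",
    "deltaL", "deltaK", "deltaKact", "deltaC", "deltaP", "deltaPact",
    "rhoL", "mK", "mP", "bP", "bL", "kappaK", "kappaL", "alphaK", "alphaL",
)


def _steady_pact(params: ParameterSet, t_end: float = 400.0) -> float:
    """Steady-state [PAR2*] by relaxation from a KLK5*-seeded state.

    The relaxation starts from a high-activation heuristic state, so it
    settles on the ignited attractor whenever one exists and otherwise
    on the basal branch ("ignited-start" convention, deterministic in
    the bistable regime).  The basal branch carries Kact = 0 exactly,
    so a basal-branch output would be structurally blind to the whole
    KLK5 module; the ignited state is the inflammation level the
    analysis targets.
    """
    from .steady import _high_activation_heuristic

    class _Diverged(RuntimeError):
        pass

    y = np.clip(_high_activation_heuristic(params), 0.0, None)
    with np.errstate(over="ignore", invalid="ignore"):
        for t in (t_end, 4 * t_end):
            traj = simulate(params, y, [0.0, t], rtol=1e-8, atol=1e-10)
            y_new = np.clip(traj.y[-1], 0.0, None)
            if not np.all(np.isfinite(y_new)) or np.max(y_new) > 1e8:
                # runaway positive feedback: no finite steady state
                raise _Diverged("trajectory diverges")
            grew = np.max(y_new) > 2.0 * max(np.max(y), 1.0)
            y = y_new
            if np.max(np.abs(_rhs_arr(y, params))) < 1e-7:
                break
        else:
            if grew:
                raise _Diverged("trajectory still growing")
        sol = root(
            lambda z: _rhs_arr(z, params),
            y,
            jac=lambda z: _jac_arr(z, params),
            method="hybr",
        )
    if sol.success and np.all(sol.x > -1e-8) and np.all(np.isfinite(sol.x)):
        y = np.clip(sol.x, 0.0, None)
    if not np.all(np.isfinite(y)) or np.max(y) > 1e8:
        raise _Diverged("no finite steady state")
    return float(y[5])


def run_model_sensitivity(
    variant: int = 1,
    condition: str = "HC",
    mu: float = 45.0,
    n_total: int = 2000,
    resamples: int = 1,
    harmonics: int = 4,
    range_factor: float = 10.0,
    seed: int = 0,
    output: Callable[[ParameterSet], float] | None = None,
) -> SensitivityResult:
    """eFAST indices of steady-state [PAR2*] for one model variant.

    Each of the model's rate parameters is perturbed log-uniformly over
    ``range_factor`` total span around its condition baseline (basal
    KLK5 production stays at its fixed zero).  ``n_total`` caps the
    number of model evaluations; the per-curve sample count is the
    largest odd value fitting the cap.  Per-sample solver failures are
    replaced by the block median and counted in ``n_failed``.
    """
    base = build_parameters(condition, variant, {"mu": mu})
    factors = [f for f in _MODEL_FACTORS if getattr(base, f) > 0]
    if variant == 2:
        factors.append("kI")
    k = len(factors)
    n_per_curve = n_total // (k * resamples)
    if n_per_curve % 2 == 0:
        n_per_curve -= 1
    design = efast_design(
        [ParamRange(f, getattr(base, f), range_factor) for f in factors],
        n_per_curve=n_per_curve,
        resamples=resamples,
        harmonics=harmonics,
        seed=seed,
    )
    evaluate = output or _steady_pact
    y = np.empty(design.n_rows)
    failed = np.zeros(design.n_rows, dtype=bool)
    for r, row in enumerate(design.samples):
        p = base.with_(**dict(zip(factors, map(float, row))))
        try:
            y[r] = evaluate(p)
        except Exception:
            failed[r] = True
            y[r] = np.nan
    if failed.any():
        # replace failures with their block median to keep the FFT grid
        NS = design.n_per_curve
        for b in range(design.n_rows // NS):
            blk = slice(b * NS, (b + 1) * NS)
            med = np.nanmedian(y[blk])
            y[blk] = np.where(np.isnan(y[blk]), med, y[blk])
    result = efast_indices(y, design)
    result.n_failed = int(failed.sum())
    return result
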