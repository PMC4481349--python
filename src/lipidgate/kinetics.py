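"""Michaelis–Menten and competition-assay kinetics.

Saturation curves v(S) = Vmax·S / (Km + S) are fitted by unweighted
nonlinear least squares with a Hanes–Woolf linearisation start; competition
time courses are fitted as simple exponential decays y(t) = A·exp(−k·t)
(optionally + plateau c), and substrate preference is summarised as the
ratio of decay rates with first-order error propagation.  An assay
simulator with multiplicative Gaussian noise supports recovery studies.

Units: concentrations in µM, velocities in pmol·min⁻¹·µg⁻¹, times in min,
rates in min⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "RateCurve",
    "MMFit",
    "DecayCurve",
    "DecayFit",
    "SelectivityRatio",
    "fit_michaelis_menten",
    "fit_exponential_decay",
    "selectivity_ratio",
    "simulate_assay",
    "MM_CONCENTRATIONS_UM",
    "DECAY_TIMES_MIN",
]

#: Standard assay designs: substrate concentrations for saturation kinetics
#: and sampling times for the competition time course.
MM_CONCENTRATIONS_UM = (3.3, 6.25, 12.5, 25.0, 33.0, 50.0)
DECAY_TIMES_MIN = (0.0, 5.0, 15.0, 30.0)


@dataclass
class RateCurve:
    """Substrate concentration (µM) vs initial velocity."""

    concentrations: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.concentrations.shape != self.velocities.shape:
            raise ValueError("concentrations and velocities must be aligned")
        if self.concentrations.size < 3:
            raise ValueError("need at least 3 points")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be > 0")
        order = np.argsort(self.concentrations, kind="stable")
        self.concentrations = self.concentrations[order]
        self.velocities = self.velocities[order]


@dataclass
class MMFit:
    Vmax: float
    Km: float
    se_Vmax: float
    se_Km: float
    rss: float
    flagged: bool = False  # non-positive parameter at the optimum

    def velocity(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.Vmax * S / (self.Km + S)


@dataclass
class DecayCurve:
    """Time (min) vs remaining substrate (concentration or peak area)."""

    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must be aligned")
        if self.times.size < 3:
            raise ValueError("need at least 3 time points")


@dataclass
class DecayFit:
    amplitude: float
    k: float  # min^-1
    plateau: float
    se_amplitude: float
    se_k: float
    rss: float
    flagged: bool = False  # rate indistinguishable from zero


@dataclass
class SelectivityRatio:
    ratio: float
    se: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("selectivity ratio must be > 0")


def _mm_model(S, Vmax, Km):
    return Vmax * S / (Km + S)


def fit_michaelis_menten(curve: RateCurve, init: tuple[float, float] | None = None) -> MMFit:
    """Nonlinear least squares of v = Vmax·S/(Km+S).

    Starting values default to the Hanes–Woolf linearisation
    (S/v = S/Vmax + Km/Vmax, linear in S).
    """
    S, v = curve.concentrations, curve.velocities
    if np.unique(S).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if init is None:
        pos = v > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(S[pos], S[pos] / v[pos], 1)
            Vmax0 = 1.0 / slope if slope > 0 else max(v.max(), 1e-9)
            Km0 = intercept * Vmax0 if intercept * Vmax0 > 0 else np.median(S)
        else:
            Vmax0, Km0 = max(v.max(), 1e-9), float(np.median(S))
        init = (Vmax0, Km0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(_mm_model, S, v, p0=init, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    Vmax, Km = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    rss = float(np.sum((v - _mm_model(S, *popt)) ** 2))
    return MMFit(float(Vmax), float(Km), float(se[0]), float(se[1]), rss,
                 flagged=bool(Vmax <= 0 or Km <= 0))


def fit_exponential_decay(curve: DecayCurve, with_plateau: bool = False) -> DecayFit:
    """Least squares of y = A·exp(−k·t) (+ c with *with_plateau*).

    Starting values come from log-linear regression on the positive part of
    the signal.  A fitted rate smaller than its standard error is flagged
    as indistinguishable from zero.
    """
    t, y = curve.times, curve.signal
    if np.allclose(y, 0):
        raise ValueError("all-zero signal cannot be fitted")
    c0 = float(y.min()) * 0.5 if with_plateau else 0.0
    resid = y - c0
    pos = resid > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(resid[pos]), 1)
        A0 = float(np.exp(intercept))
        k0 = float(max(-slope, 1e-6))
    else:
        A0, k0 = float(max(y.max(), 1e-9)), 0.1

    try:
        with warnings.catch_warnings():
            # a flat signal yields a singular covariance; we flag it below
            warnings.simplefilter("ignore", OptimizeWarning)
            if with_plateau:
                popt, pcov = curve_fit(
                    lambda tt, A, k, c: A * np.exp(-k * tt) + c,
                    t, y, p0=(A0, k0, c0), maxfev=10000,
                )
                A, k, c = popt
                fit_y = A * np.exp(-k * t) + c
            else:
                popt, pcov = curve_fit(
                    lambda tt, A, k: A * np.exp(-k * tt), t, y, p0=(A0, k0),
                    maxfev=10000,
                )
                A, k = popt
                c = 0.0
                fit_y = A * np.exp(-k * t)
    except RuntimeError as exc:
        raise RuntimeError(f"decay fit did not converge: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    rss = float(np.sum((y - fit_y) ** 2))
    flagged = bool(k <= 0 or k <= se[1])
    return DecayFit(float(A), float(k), float(c), float(se[0]), float(se[1]),
                    rss, flagged=flagged)


def selectivity_ratio(fit1: DecayFit, fit2: DecayFit) -> SelectivityRatio:
    """k1/k2 with first-order (delta-method) standard error."""
    if fit2.k <= 0:
        raise ValueError("denominator rate must be > 0")
    if fit1.k <= 0:
        raise ValueError("numerator rate must be > 0")
    r = fit1.k / fit2.k
    se = r * np.sqrt(
        (fit1.se_k / fit1.k) ** 2 + (fit2.se_k / fit2.k) ** 2
    )
    return SelectivityRatio(float(r), float(se))


def simulate_assay(
    kind: str,
    params: dict,
    design=None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    replicates: int = 1,
):
    """Simulate noisy assay data.

    ``kind="mm"``: *params* has Vmax and Km, *design* is the concentration
    list; ``kind="decay"``: *params* has amplitude and k (optional plateau),
    *design* is the time-point list.  Noise is multiplicative Gaussian with
    relative SD *noise_sd*.  Returns one curve (replicates == 1) or a list.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = []
    if kind == "mm":
        S = np.asarray(
            MM_CONCENTRATIONS_UM if design is None else design, dtype=float
        )
        if S.size < 3 or np.any(S <= 0):
            raise ValueError("invalid concentration design")
        clean = _mm_model(S, params["Vmax"], params["Km"])
        for _ in range(replicates):
            noisy = clean * (1.0 + noise_sd * rng.standard_normal(S.size))
            out.append(RateCurve(S, noisy))
    elif kind == "decay":
        t = np.asarray(DECAY_TIMES_MIN if design is None else design, dtype=float)
        if t.size < 3 or not np.any(np.isclose(t, 0.0)):
            raise ValueError("invalid time design: must include t = 0")
        clean = params["amplitude"] * np.exp(-params["k"] * t) + params.get(
            "plateau", 0.0
        )
        for _ in range(replicates):
            noisy = clean * (1.0 + noise_sd * rng.standard_normal(t.size))
            out.append(DecayCurve(t, noisy))
    else:
        raise ValueError(f"unknown assay kind {kind!r}")
    return out[0] if replicates == 1 else out
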