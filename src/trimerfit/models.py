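"""Closed-form equilibrium, kinetic and thermal models with single-trace fitting.

Three measurement models for fluorescence-polarization and gel-based readouts of
the Hsf1 monomer/trimer system:

* **Ligand-depletion equilibrium binding** — the probe (labelled HSE-DNA) is at a
  concentration comparable to ``K_D``, so the free-titrant approximation fails and
  the bound-complex concentration is the quadratic root of the law of mass action
  (:func:`quadratic_bound`). :func:`fit_titration` estimates ``K_D`` from a
  saturation titration under this model.

* **Delayed single-exponential dissociation** — chaperone-driven dissociation of
  trimeric Hsf1 from DNA shows a short lag before the exponential phase; the
  composite curve is flat at ``y_max`` until ``t0`` and decays as
  ``y_0 + (y_max − y_0)·exp(−k(t − t0))`` afterwards (:func:`delay_exponential`,
  :func:`fit_dissociation`).

* **Two-state thermal transition** — the temperature-induced monomer→trimer
  transition is summarised by a four-parameter Boltzmann sigmoid on the trimer
  fraction; the midpoint is the transition temperature ``Tm``
  (:func:`thermal_fraction`, :func:`fit_thermal`).

Units: concentrations in nM, time in minutes, rates per minute, temperature in
degrees Celsius.  Polarization signals are unit-agnostic (mP-like).

Fit failures caused by the *data* (no amplitude, no decay, no transition) are
returned as structured results with ``success=False`` and a message; exceptions
are reserved for violated preconditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "TitrationPoint",
    "TitrationFit",
    "DissociationFit",
    "ThermalFit",
    "quadratic_bound",
    "fit_titration",
    "delay_exponential",
    "fit_dissociation",
    "thermal_fraction",
    "fit_thermal",
    "read_titration_csv",
    "read_trace_csv",
    "read_melt_csv",
    "fit_report_json",
]

# Optimizer contract shared by all fits in the package: bounded trust-region
# nonlinear least squares, tight tolerances, seeded multi-start fallback.
LSQ_KWS = dict(method="least_squares", ftol=1e-12, xtol=1e-12, gtol=1e-12)
N_MULTISTART = 5
MULTISTART_SEED = 20210713

# t0 bound reflects the observed 5-10 min lag before the exponential phase.
T0_BOUNDS = (0.0, 15.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationPoint:
    """One point of a saturation titration: total titrant (nM) and signal."""

    titrant_total: float
    signal: float

    def __post_init__(self) -> None:
        if self.titrant_total < 0:
            raise ValueError("titrant_total must be >= 0")
        if not np.isfinite(self.signal):
            raise ValueError("signal must be finite")


@dataclass
class FitResultBase:
    """Common fit bookkeeping: convergence flag, message, stderr per parameter."""

    stderr: dict = field(default_factory=dict)
    success: bool = True
    message: str = ""
    rss: float = float("nan")

    def to_json(self) -> str:
        return fit_report_json(self)


@dataclass
class TitrationFit(FitResultBase):
    """Equilibrium Kd fit under ligand depletion."""

    Kd: float = float("nan")
    signal_free: float = float("nan")
    signal_bound: float = float("nan")
    probe_total: float = float("nan")


@dataclass
class DissociationFit(FitResultBase):
    """Delayed single-exponential dissociation fit; k in per minute."""

    y_max: float = float("nan")
    y_0: float = float("nan")
    k: float = float("nan")
    t0: float = float("nan")


@dataclass
class ThermalFit(FitResultBase):
    """Two-state thermal-transition fit; Tm in degrees Celsius."""

    Tm: float = float("nan")
    steepness: float = float("nan")
    baseline_low: float = float("nan")
    baseline_high: float = float("nan")


def fit_report_json(fit: FitResultBase) -> str:
    """Serialize a fit result: parameter estimates, stderr, convergence flag."""
    d = asdict(fit)
    return json.dumps(d, indent=2, default=float)


# ---------------------------------------------------------------------------
# equilibrium binding under ligand depletion
# ---------------------------------------------------------------------------

def quadratic_bound(ligand_total, receptor_total, Kd):
    """Bound-complex concentration from the quadratic root of mass action.

    Solves ``Kd = (L − x)(R − x)/x`` for the complex ``x``:

        x = ((L + R + Kd) − sqrt((L + R + Kd)² − 4·L·R)) / 2

    Parameters are total concentrations (any consistent unit); broadcasting over
    array inputs is supported.  ``0 ≤ x ≤ min(L, R)`` always holds.

    Raises ``ValueError`` for negative totals or non-positive ``Kd``.
    """
    L = np.asarray(ligand_total, dtype=float)
    R = np.asarray(receptor_total, dtype=float)
    if np.any(L < 0) or np.any(R < 0):
        raise ValueError("total concentrations must be >= 0")
    if np.any(np.asarray(Kd, dtype=float) <= 0):
        raise ValueError("Kd must be > 0")
    s = L + R + Kd
    disc = s * s - 4.0 * L * R
    # disc >= (L-R)^2 + Kd^2 > 0 analytically; clip guards rounding
    x = (s - np.sqrt(np.clip(disc, 0.0, None))) / 2.0
    x = np.clip(x, 0.0, np.minimum(L, R))
    return x if x.ndim else float(x)


def _as_xy(points: Iterable, names=("titrant_total", "signal")) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p in points:
        if hasattr(p, names[0]):
            xs.append(getattr(p, names[0]))
            ys.append(getattr(p, names[1]))
        else:
            x, y = p
            xs.append(x)
            ys.append(y)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def _minimize_multistart(residual, params, rng_scales, args=()):
    """Single minimize; on failure retry from N_MULTISTART seeded perturbed starts.

    ``rng_scales`` maps parameter name -> perturbation scale (log-uniform factor
    for positive-bounded parameters, additive otherwise).
    """
    best = lmfit.minimize(residual, params, args=args, **LSQ_KWS)
    if best.success:
        return best
    rng = np.random.default_rng(MULTISTART_SEED)
    for _ in range(N_MULTISTART):
        trial = params.copy()
        for name, scale in rng_scales.items():
            p = trial[name]
            if p.min is not None and p.min >= 0 and p.value > 0:
                p.value = float(np.clip(p.value * np.exp(rng.normal(0, scale)),
                                        p.min + 1e-12 if p.min == 0 else p.min, p.max))
            else:
                lo = -np.inf if p.min is None else p.min
                hi = np.inf if p.max is None else p.max
                p.value = float(np.clip(p.value + rng.normal(0, scale), lo, hi))
        res = lmfit.minimize(residual, trial, args=args, **LSQ_KWS)
        if res.success and (not best.success or res.chisqr < best.chisqr):
            best = res
        if best.success:
            break
    return best


def fit_titration(points: Sequence, probe_total: float) -> TitrationFit:
    """Fit ``Kd`` to a saturation titration under ligand depletion.

    Model: ``signal = s_free + (s_bound − s_free)·bound(probe, titrant, Kd)/probe``
    with ``bound`` the quadratic mass-action solution.  Requires >= 5 points.
    Returns a :class:`TitrationFit` with asymptotic standard errors; a degenerate
    (zero-amplitude) titration yields ``success=False`` rather than an exception.
    """
    titrant, signal = _as_xy(points)
    if titrant.size < 5:
        raise ValueError("need at least 5 titration points")
    if probe_total <= 0:
        raise ValueError("probe_total must be > 0")

    amp = float(np.ptp(signal))
    fail = TitrationFit(probe_total=probe_total, success=False)
    if amp == 0.0 or amp < 1e-9 * max(1.0, abs(float(np.mean(signal)))):
        fail.message = "zero amplitude: all signals identical, no binding transition"
        fail.signal_free = fail.signal_bound = float(signal[0])
        return fail

    order = np.argsort(titrant)
    s_lo, s_hi = float(signal[order[0]]), float(signal[order[-1]])
    half = (s_lo + s_hi) / 2.0
    # Kd start: titrant closest to half-saturation signal
    kd0 = float(titrant[order][np.argmin(np.abs(signal[order] - half))])
    kd0 = max(kd0, 1e-3)

    params = lmfit.Parameters()
    params.add("Kd", value=kd0, min=1e-9, max=1e9)
    params.add("signal_free", value=s_lo)
    params.add("signal_bound", value=s_hi)

    def residual(p):
        frac = quadratic_bound(probe_total, titrant, p["Kd"].value) / probe_total
        model = p["signal_free"].value + (p["signal_bound"].value - p["signal_free"].value) * frac
        return model - signal

    res = _minimize_multistart(residual, params,
                               {"Kd": 1.0, "signal_free": 0.1 * amp, "signal_bound": 0.1 * amp})
    out = TitrationFit(
        Kd=float(res.params["Kd"].value),
        signal_free=float(res.params["signal_free"].value),
        signal_bound=float(res.params["signal_bound"].value),
        probe_total=probe_total,
        stderr={n: (float(res.params[n].stderr) if res.params[n].stderr is not None else float("nan"))
                for n in ("Kd", "signal_free", "signal_bound")},
        success=bool(res.success),
        message="" if res.success else f"fit did not converge: {res.message}",
        rss=float(res.chisqr),
    )
    if abs(out.signal_bound - out.signal_free) < 1e-9 * max(1.0, amp):
        out.success = False
        out.message = "zero amplitude: fitted bound and free signals coincide"
    return out


# ---------------------------------------------------------------------------
# delayed single-exponential dissociation
# ---------------------------------------------------------------------------

def delay_exponential(t, y_max, y_0, k, t0):
    """Composite dissociation curve, continuous at the lag boundary.

    ``y = y_max`` for ``t <= t0``; ``y = y_0 + (y_max − y_0)·exp(−k(t − t0))``
    afterwards.  Accepts a :class:`DissociationFit` in place of the four scalars.
    """
    if isinstance(y_max, DissociationFit):
        fit = y_max
        y_max, y_0, k, t0 = fit.y_max, fit.y_0, fit.k, fit.t0
    t = np.asarray(t, dtype=float)
    y = y_0 + (y_max - y_0) * np.exp(-k * np.clip(t - t0, 0.0, None))
    return y if y.ndim else float(y)


def _trace_xy(trace) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(trace, "times"):
        return np.asarray(trace.times, float), np.asarray(trace.signals, float)
    t, y = trace
    return np.asarray(t, float), np.asarray(y, float)


def _has_decay(times: np.ndarray, signals: np.ndarray) -> bool:
    """Heuristic pre-check that the trace actually decreases beyond noise."""
    n = signals.size
    head = signals[: max(2, n // 5)].mean()
    tail = signals[-max(2, n // 5):].mean()
    noise = np.std(np.diff(signals)) / np.sqrt(2.0) if n > 2 else 0.0
    return (head - tail) > 3.0 * noise and (head - tail) > 0.0


def fit_dissociation(trace) -> DissociationFit:
    """Fit the delayed single-exponential to one dissociation trace.

    ``trace`` is anything with ``times``/``signals`` attributes or a
    ``(times, signals)`` pair; times in minutes, strictly increasing, >= 10
    points.  ``t0`` is a free parameter bounded to [0, 15] min.  A flat or
    rising trace returns ``success=False`` with message "no decay".
    """
    times, signals = _trace_xy(trace)
    if times.size < 10:
        raise ValueError("need at least 10 time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    if not _has_decay(times, signals):
        return DissociationFit(success=False, message="no decay",
                               y_max=float(signals.max()), y_0=float(signals.min()))

    y_max0 = float(signals[: max(2, signals.size // 10)].mean())
    y_00 = float(signals.min())
    span = float(times[-1] - times[0])
    t0_hi = min(T0_BOUNDS[1], span / 2.0)

    params = lmfit.Parameters()
    params.add("y_max", value=y_max0)
    params.add("y_0", value=y_00)
    params.add("k", value=3.0 / max(span, 1e-9), min=0.0, max=1e3)
    params.add("t0", value=min(5.0, t0_hi / 2.0), min=T0_BOUNDS[0], max=t0_hi)

    def residual(p):
        return delay_exponential(times, p["y_max"].value, p["y_0"].value,
                                 p["k"].value, p["t0"].value) - signals

    amp = max(float(np.ptp(signals)), 1e-9)
    res = _minimize_multistart(residual, params,
                               {"k": 1.0, "t0": 2.0, "y_max": 0.05 * amp, "y_0": 0.05 * amp})
    return DissociationFit(
        y_max=float(res.params["y_max"].value),
        y_0=float(res.params["y_0"].value),
        k=float(res.params["k"].value),
        t0=float(res.params["t0"].value),
        stderr={n: (float(res.params[n].stderr) if res.params[n].stderr is not None else float("nan"))
                for n in ("y_max", "y_0", "k", "t0")},
        success=bool(res.success),
        message="" if res.success else f"fit did not converge: {res.message}",
        rss=float(res.chisqr),
    )


# ---------------------------------------------------------------------------
# thermal transition
# ---------------------------------------------------------------------------

def thermal_fraction(T, Tm, steepness, baseline_low, baseline_high):
    """Four-parameter Boltzmann sigmoid on the trimer fraction.

    ``f(T) = b_low + (b_high − b_low) / (1 + exp((Tm − T)·steepness))`` with
    ``steepness > 0`` in 1/°C, so ``f → b_low`` as ``T → −∞`` and
    ``f(Tm)`` is the midpoint of the baselines.  Accepts a :class:`ThermalFit`
    in place of the four scalars.
    """
    if isinstance(Tm, ThermalFit):
        fit = Tm
        Tm, steepness = fit.Tm, fit.steepness
        baseline_low, baseline_high = fit.baseline_low, fit.baseline_high
    T = np.asarray(T, dtype=float)
    f = baseline_low + (baseline_high - baseline_low) * expit((T - Tm) * steepness)
    return f if f.ndim else float(f)


def fit_thermal(points: Sequence) -> ThermalFit:
    """Fit the two-state sigmoid to (temperature °C, trimer fraction) data.

    Requires >= 5 temperatures bracketing the transition; ``Tm`` is bounded to
    the measured range.  Data with no transition (flat fraction) return
    ``success=False``.
    """
    T, f = _as_xy(points, names=("temperature", "fraction"))
    if T.size < 5:
        raise ValueError("need at least 5 temperatures")

    amp = float(np.ptp(f))
    if amp < 1e-9:
        return ThermalFit(success=False, message="no transition within range",
                          baseline_low=float(f[0]), baseline_high=float(f[0]))

    order = np.argsort(T)
    Ts, fs = T[order], f[order]
    half = (fs[0] + fs[-1]) / 2.0
    tm0 = float(Ts[np.argmin(np.abs(fs - half))])

    params = lmfit.Parameters()
    params.add("Tm", value=tm0, min=float(Ts[0]), max=float(Ts[-1]))
    params.add("steepness", value=2.0 / max(float(Ts[-1] - Ts[0]) / 4.0, 1e-6), min=1e-6, max=1e3)
    params.add("baseline_low", value=float(fs[0]))
    params.add("baseline_high", value=float(fs[-1]))

    def residual(p):
        return thermal_fraction(T, p["Tm"].value, p["steepness"].value,
                                p["baseline_low"].value, p["baseline_high"].value) - f

    res = _minimize_multistart(residual, params,
                               {"Tm": 2.0, "steepness": 0.5,
                                "baseline_low": 0.1 * amp, "baseline_high": 0.1 * amp})
    out = ThermalFit(
        Tm=float(res.params["Tm"].value),
        steepness=float(res.params["steepness"].value),
        baseline_low=float(res.params["baseline_low"].value),
        baseline_high=float(res.params["baseline_high"].value),
        stderr={n: (float(res.params[n].stderr) if res.params[n].stderr is not None else float("nan"))
                for n in ("Tm", "steepness", "baseline_low", "baseline_high")},
        success=bool(res.success),
        message="" if res.success else f"fit did not converge: {res.message}",
        rss=float(res.chisqr),
    )
    if abs(out.baseline_high - out.baseline_low) < 1e-9:
        out.success = False
        out.message = "no transition within range"
    return out


# ---------------------------------------------------------------------------
# CSV dialects (comma-separated, header row, '.', UTF-8)
# ---------------------------------------------------------------------------

def read_titration_csv(path) -> list[TitrationPoint]:
    """Read `titrant_nM,signal` CSV into titration points."""
    df = pd.read_csv(path)
    return [TitrationPoint(float(r.titrant_nM), float(r.signal)) for r in df.itertuples()]


def read_trace_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read `time_min,signal` CSV into (times, signals) arrays."""
    df = pd.read_csv(path)
    return df["time_min"].to_numpy(float), df["signal"].to_numpy(float)


def read_melt_csv(path) -> list[tuple[float, float]]:
    """Read `temp_C,fraction_trimer` CSV into (temperature, fraction) pairs."""
    df = pd.read_csv(path)
    return list(zip(df["temp_C"].astype(float), df["fraction_trimer"].astype(float)))
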