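"""Binomial trimer-composition model and global multi-species dissociation kinetics.

Hsf1 binds DNA as a trimer.  When wild-type monomers (carrying an Hsc70 binding
site next to the trimerization domain) are mixed with mutant monomers lacking
that site in ratio ``a:b``, trimers assemble with binomially distributed
composition: with ``p = a/(a+b)`` the fractions of trimers exposing 3, 2, 1 or 0
chaperone sites are ``p³, 3p²(1−p), 3p(1−p)², (1−p)³`` — the normalized
coefficients of ``(a+b)³``.

The kinetic model ties dissociation to the number of accessible sites: each
species decays as a delayed exponential with its own rate (``k3`` for three
sites, ``k2`` for two, ``k1`` for one) and the 0-site species never dissociates
(its rate is identically zero).  A trace measured at mixing ratio ``a:b`` is the
composition-weighted sum

    y(t) = y_0 + (y_max − y_0)·[f0 + f1·E(k1) + f2·E(k2) + f3·E(k3)]

with ``E(k) = 1`` for ``t ≤ t0`` and ``exp(−k(t − t0))`` after the lag.  Rates
are shared across all traces of an experiment (global fit); amplitudes and lag
are per trace.  Two null models are fitted for comparison by AIC:

* ``single_site_null`` — one chaperone site suffices for dissociation at the
  maximal rate: every species with ≥ 1 site decays with one shared rate
  (decaying amplitude ``1 − f0``).
* ``three_sites_null`` — all three sites are required: only the all-wild-type
  species decays (amplitude ``f3``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .models import delay_exponential, fit_dissociation, _minimize_multistart

__all__ = [
    "MixRatio",
    "MixtureComposition",
    "KineticTrace",
    "GlobalKineticModel",
    "GlobalFitResult",
    "VARIANTS",
    "trimer_composition",
    "mixture_signal",
    "null_prediction",
    "global_fit_mixture",
    "compare_models",
    "read_traces_csv",
    "write_traces_csv",
]

VARIANTS = ("full", "single_site_null", "three_sites_null")

# a species' rate is treated as unidentifiable when its total composition
# weight across all traces falls below this
_IDENT_WEIGHT = 1e-6


@dataclass(frozen=True)
class MixRatio:
    """Mixing ratio of wild-type (a) to mutant (b) monomers, e.g. 2:1."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b <= 0:
            raise ValueError("require a >= 0, b >= 0, a + b > 0")

    @property
    def p_wt(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class MixtureComposition:
    """Fractions of trimers with 3 / 2 / 1 / 0 accessible chaperone sites."""

    f3: float
    f2: float
    f1: float
    f0: float

    def __post_init__(self) -> None:
        fs = (self.f3, self.f2, self.f1, self.f0)
        if any(f < -1e-12 or f > 1 + 1e-12 for f in fs):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fs) - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        """Fractions ordered by site count (f0, f1, f2, f3)."""
        return np.array([self.f0, self.f1, self.f2, self.f3])


@dataclass
class KineticTrace:
    """One dissociation trace: polarization vs time at a given mixing ratio."""

    times: np.ndarray
    signals: np.ndarray
    ratio: MixRatio
    label: str = ""
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.shape != self.signals.shape:
            raise ValueError("times and signals must have equal length")
        if self.times.size < 10:
            raise ValueError("need at least 10 points per trace")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GlobalKineticModel:
    """Shared rates plus per-trace amplitudes/lag for one model variant.

    ``k1``/``k2``/``k3`` are the dissociation rates (per minute) of trimers with
    one, two or three accessible chaperone sites; the 0-site rate is identically
    zero.  For the null variants the single shared rate is stored in all three
    slots.  ``y_max``, ``y_0`` and ``t0`` are parallel per-trace lists.
    """

    k1: float
    k2: float
    k3: float
    y_max: list[float]
    y_0: list[float]
    t0: list[float]
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    def rates_by_sites(self) -> np.ndarray:
        """Rates indexed by site count 0..3 (k0 == 0 always)."""
        return np.array([0.0, self.k1, self.k2, self.k3])


@dataclass
class GlobalFitResult:
    """Global-fit output: model, uncertainties and information criteria."""

    model: GlobalKineticModel
    stderr: dict
    rss: float
    n_obs: int
    n_params: int
    aic: float
    aicc: float
    bic: float
    success: bool
    message: str = ""
    under_determined: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def trimer_composition(ratio) -> MixtureComposition:
    """Binomial composition of trimers assembled from an ``a:b`` monomer mix.

    With ``p = a/(a+b)``: ``f3 = p³``, ``f2 = 3p²(1−p)``, ``f1 = 3p(1−p)²``,
    ``f0 = (1−p)³`` — trimers form with composition probabilities given by the
    normalized coefficients of ``(a·wt + b·mut)³``.
    """
    if not isinstance(ratio, MixRatio):
        ratio = MixRatio(*ratio)
    p = ratio.p_wt
    q = 1.0 - p
    return MixtureComposition(f3=p**3, f2=3 * p**2 * q, f1=3 * p * q**2, f0=q**3)


# ---------------------------------------------------------------------------
# forward curves
# ---------------------------------------------------------------------------

def _decay_factor(t: np.ndarray, k: float, t0: float) -> np.ndarray:
    """E(k): 1 during the lag, exp(−k(t−t0)) afterwards."""
    return np.exp(-k * np.clip(np.asarray(t, float) - t0, 0.0, None))


def _mixture_curve(t, y_max, y_0, t0, comp: MixtureComposition, rates: np.ndarray):
    fs = comp.as_array()  # (f0, f1, f2, f3)
    mix = sum(f * _decay_factor(t, k, t0) for f, k in zip(fs, rates))
    return y_0 + (y_max - y_0) * mix


def mixture_signal(t, model: GlobalKineticModel, comp: MixtureComposition,
                   trace_index: int = 0):
    """Predicted polarization of a mixed-trimer trace under a fitted model.

    Composition-weighted sum of delayed exponentials; the 0-site species
    contributes a constant (it never dissociates).  At ``t ≤ t0`` the curve
    equals ``y_max`` for every composition.
    """
    y = _mixture_curve(t, model.y_max[trace_index], model.y_0[trace_index],
                       model.t0[trace_index], comp, model.rates_by_sites())
    y = np.asarray(y)
    return y if y.ndim else float(y)


def null_prediction(variant: str, comp: MixtureComposition, shared_k: float,
                    y_max: float, y_0: float, t0: float = 0.0, t=None):
    """Theoretical dissociation curve under a null hypothesis, at a fixed rate.

    ``shared_k`` is the rate fitted on the pure wild-type trace.  Under
    ``single_site_null`` all species with at least one site decay at that rate
    (decaying amplitude ``1 − f0``); under ``three_sites_null`` only the 3-site
    species decays (amplitude ``f3``).  Returns the predicted signal at ``t``.
    """
    if variant == "single_site_null":
        amp = 1.0 - comp.f0
    elif variant == "three_sites_null":
        amp = comp.f3
    else:
        raise ValueError(f"unknown null variant {variant!r}")
    if t is None:
        raise ValueError("t is required")
    t = np.asarray(t, float)
    y = y_0 + (y_max - y_0) * ((1.0 - amp) + amp * _decay_factor(t, shared_k, t0))
    return y if y.ndim else float(y)


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------

def _init_rates(traces: Sequence[KineticTrace]) -> float:
    """Seed-free rate initialization from a single-exponential fit of the trace
    richest in wild-type monomer (the pure-wt trace when present)."""
    best = max(traces, key=lambda tr: tr.ratio.p_wt)
    fit = fit_dissociation((best.times, best.signals))
    if fit.success and fit.k > 0:
        return fit.k
    span = max(float(best.times[-1] - best.times[0]), 1.0)
    return 3.0 / span


def _trace_amp_weights(traces, comps, variant):
    """Per-trace decaying amplitude fraction under each variant."""
    if variant == "full":
        return [1.0 - c.f0 for c in comps]
    if variant == "single_site_null":
        return [1.0 - c.f0 for c in comps]
    return [c.f3 for c in comps]


def global_fit_mixture(traces: Sequence[KineticTrace], variant: str = "full",
                       share_amplitudes: bool = True) -> GlobalFitResult:
    """Globally fit shared dissociation rates across traces at different ratios.

    Rates are shared across all traces; the lag ``t0`` is fitted per trace.
    With ``share_amplitudes=True`` (default) a single (``y_max``, ``y_0``) pair
    is shared by all traces — every mixing ratio is measured at identical probe
    and total-protein concentrations, so the bound and free polarization levels
    are common, and the undissociable 0-site trace then anchors the plateau,
    which is what makes the slow single-site rate identifiable within a finite
    observation window.  Set ``share_amplitudes=False`` to fit amplitudes per
    trace.  Compositions are computed from each trace's mixing ratio.  For the
    null variants a single shared rate replaces (k1, k2, k3).  Rates whose
    species carry no composition weight anywhere in the design are flagged in
    ``under_determined`` and reported with infinite standard error.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    comps = [trimer_composition(tr.ratio) for tr in traces]

    k_start = _init_rates(traces)
    params = lmfit.Parameters()
    if variant == "full":
        # deterministic stagger: k3 from the pure-wt single-exponential fit
        params.add("k3", value=k_start, min=0.0, max=1e3)
        params.add("k2", value=k_start / 2.0, min=0.0, max=1e3)
        params.add("k1", value=k_start / 10.0, min=0.0, max=1e3)
        rate_names = ["k1", "k2", "k3"]
        weights = {
            "k1": sum(c.f1 for c in comps),
            "k2": sum(c.f2 for c in comps),
            "k3": sum(c.f3 for c in comps),
        }
    else:
        params.add("k", value=k_start, min=0.0, max=1e3)
        rate_names = ["k"]
        amp_w = _trace_amp_weights(traces, comps, variant)
        weights = {"k": sum(amp_w)}

    under = [name for name in rate_names if weights[name] < _IDENT_WEIGHT]
    for name in under:
        params[name].vary = False

    amp_w = _trace_amp_weights(traces, comps, variant)
    any_identifiable = any(w > _IDENT_WEIGHT for w in amp_w)
    for i, (tr, c) in enumerate(zip(traces, comps)):
        head = float(tr.signals[: max(2, tr.signals.size // 10)].mean())
        tail = float(tr.signals[-max(2, tr.signals.size // 10):].mean())
        identifiable = amp_w[i] > _IDENT_WEIGHT
        if share_amplitudes and i > 0:
            params.add(f"ymax_{i}", expr="ymax_0")
            params.add(f"y0_{i}", expr="y0_0")
        elif share_amplitudes:
            # pool levels across traces: highest head, lowest tail
            heads = [float(t.signals[: max(2, t.signals.size // 10)].mean())
                     for t in traces]
            tails = [float(t.signals[-max(2, t.signals.size // 10):].mean())
                     for t in traces]
            params.add("ymax_0", value=max(heads))
            params.add("y0_0", value=min(tails), vary=any_identifiable)
        else:
            params.add(f"ymax_{i}", value=head)
            # for an undissociable trace the amplitude has zero gradient
            params.add(f"y0_{i}", value=tail if identifiable else head,
                       vary=identifiable)
        t0_hi = min(15.0, float(tr.times[-1] - tr.times[0]) / 2.0)
        params.add(f"t0_{i}", value=min(5.0, t0_hi / 2.0), min=0.0, max=t0_hi,
                   vary=identifiable)

    def residual(p):
        if variant == "full":
            rates = np.array([0.0, p["k1"].value, p["k2"].value, p["k3"].value])
        else:
            rates = None
        out = []
        for i, (tr, c) in enumerate(zip(traces, comps)):
            ym, y0, t0 = p[f"ymax_{i}"].value, p[f"y0_{i}"].value, p[f"t0_{i}"].value
            if variant == "full":
                y = _mixture_curve(tr.times, ym, y0, t0, c, rates)
            else:
                amp = amp_w[i]
                y = y0 + (ym - y0) * ((1.0 - amp) + amp * _decay_factor(tr.times, p["k"].value, t0))
            out.append(y - tr.signals)
        return np.concatenate(out)

    scales = {name: 1.0 for name in rate_names if name not in under}
    res = _minimize_multistart(residual, params, scales)

    def _val(name):
        return float(res.params[name].value)

    def _err(name):
        if name in under:
            return float("inf")
        e = res.params[name].stderr
        return float(e) if e is not None else float("nan")

    if variant == "full":
        k1, k2, k3 = _val("k1"), _val("k2"), _val("k3")
        stderr = {n: _err(n) for n in rate_names}
    else:
        k1 = k2 = k3 = _val("k")
        stderr = {"k": _err("k")}
    n = len(traces)
    model = GlobalKineticModel(
        k1=k1, k2=k2, k3=k3,
        y_max=[_val(f"ymax_{i}") for i in range(n)],
        y_0=[_val(f"y0_{i}") for i in range(n)],
        t0=[_val(f"t0_{i}") for i in range(n)],
        variant=variant,
    )
    for i in range(n):
        for pname in (f"ymax_{i}", f"y0_{i}", f"t0_{i}"):
            e = res.params[pname].stderr
            stderr[pname] = float(e) if e is not None else float("nan")

    rss = float(res.chisqr)
    n_obs = int(res.ndata)
    n_params = int(res.nvarys)
    aic = n_obs * math.log(max(rss, 1e-300) / n_obs) + 2 * n_params
    denom = n_obs - n_params - 1
    aicc = aic + (2 * n_params * (n_params + 1) / denom if denom > 0 else float("inf"))
    bic = n_obs * math.log(max(rss, 1e-300) / n_obs) + n_params * math.log(n_obs)

    msg = "" if res.success else f"fit did not converge: {res.message}"
    if under:
        msg = (msg + "; " if msg else "") + (
            "under-determined: no composition weight for " + ", ".join(under))
    return GlobalFitResult(model=model, stderr=stderr, rss=rss, n_obs=n_obs,
                           n_params=n_params, aic=aic, aicc=aicc, bic=bic,
                           success=bool(res.success), message=msg,
                           under_determined=under)


def compare_models(traces: Sequence[KineticTrace]) -> pd.DataFrame:
    """Fit all model variants to the same traces and rank them by AIC.

    Returns a table with one row per variant: residual sum of squares, number of
    fitted parameters, AIC / AICc / BIC, ΔAIC relative to the best variant, and
    a ``best`` flag.  Fit failures are recorded per variant, never raised.
    """
    rows = []
    for variant in VARIANTS:
        try:
            fit = global_fit_mixture(traces, variant=variant)
            rows.append(dict(variant=variant, success=fit.success, rss=fit.rss,
                             n_params=fit.n_params, aic=fit.aic, aicc=fit.aicc,
                             bic=fit.bic, message=fit.message))
        except Exception as exc:  # propagate as a recorded failure
            rows.append(dict(variant=variant, success=False, rss=float("nan"),
                             n_params=0, aic=float("inf"), aicc=float("inf"),
                             bic=float("inf"), message=str(exc)))
    df = pd.DataFrame(rows)
    finite = df["aic"].where(df["success"], float("inf"))
    df["daic"] = finite - finite.min()
    df["best"] = finite == finite.min()
    return df


# ---------------------------------------------------------------------------
# multi-trace CSV dialect: trace_id,ratio_wt,ratio_mut,time_min,signal
# ---------------------------------------------------------------------------

def read_traces_csv(path) -> list[KineticTrace]:
    df = pd.read_csv(path)
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        ratio = MixRatio(float(grp["ratio_wt"].iloc[0]), float(grp["ratio_mut"].iloc[0]))
        grp = grp.sort_values("time_min")
        traces.append(KineticTrace(times=grp["time_min"].to_numpy(float),
                                   signals=grp["signal"].to_numpy(float),
                                   ratio=ratio, label=str(tid)))
    return traces


def write_traces_csv(traces: Sequence[KineticTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "trace_id": tr.label or f"ratio_{tr.ratio.a:g}to{tr.ratio.b:g}",
            "ratio_wt": tr.ratio.a, "ratio_mut": tr.ratio.b,
            "time_min": tr.times, "signal": tr.signals,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
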