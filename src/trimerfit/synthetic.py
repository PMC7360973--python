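"""Seeded generators for every input the analysis stages consume.

Each generator emulates the statistical structure of one experimental design:

* saturation titrations of labelled HSE-DNA with trimeric Hsf1 under ligand
  depletion (probe at a concentration comparable to ``K_D``);
* delayed-exponential dissociation traces of DNA-bound trimers after chaperone
  addition, alone or as mixed-trimer experiments across wild-type:mutant
  monomer ratios (1:0, 2:1, 1:1, 1:2, 0:1);
* bimodal isotope envelopes as two-Gaussian mass mixtures sampled at isotopic
  stick spacing;
* sigmoidal trimer-fraction melt curves over the standard temperature series
  4, 20, 25, 30, 35, 39, 42 °C.

Noise is additive homoscedastic Gaussian on the signal (multiplicative for
envelope intensities, clamped non-negative).  Every generator takes a
mandatory seed and is fully deterministic: identical spec, identical output.
Each dataset embeds its ground-truth parameters in a ``truth`` mapping so
recovery tests are self-describing.

Default designs: 5 nM probe for titrations; kinetics on a 0–100 min grid at
1-min spacing with amplitudes ``y_max = 200``, ``y_0 = 80`` (mP-like) and
a 5-min lag; rates (k1, k2, k3) = (0.005, 0.02, 0.05) per minute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .models import TitrationPoint, quadratic_bound, delay_exponential, thermal_fraction
from .mixture import KineticTrace, MixRatio, trimer_composition, _mixture_curve
from .hxms import IsotopeEnvelope

__all__ = [
    "GeneratorSpec",
    "DEFAULT_RATIOS",
    "DEFAULT_RATES",
    "DEFAULT_TIMES",
    "DEFAULT_TEMPS",
    "gen_titration",
    "gen_trace",
    "gen_mixture_experiment",
    "gen_envelope",
    "gen_melt",
    "gen_sequence",
    "generate",
    "manifest_json",
]

DEFAULT_RATIOS = ((1, 0), (2, 1), (1, 1), (1, 2), (0, 1))
DEFAULT_RATES = (0.005, 0.02, 0.05)  # (k1, k2, k3) per minute
DEFAULT_TIMES = np.arange(0.0, 101.0, 1.0)  # minutes
DEFAULT_TEMPS = (4.0, 20.0, 25.0, 30.0, 35.0, 39.0, 42.0)  # °C
DEFAULT_YMAX, DEFAULT_Y0, DEFAULT_T0 = 200.0, 80.0, 5.0

ISOTOPE_SPACING = 1.00235  # Da, average peptide isotopic spacing


@dataclass(frozen=True)
class GeneratorSpec:
    """Self-describing recipe for one synthetic dataset.

    ``kind`` selects the generator; ``parameters`` are its model parameters;
    ``seed`` is mandatory — there is no silent global RNG.
    """

    kind: str
    parameters: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    n_points: int = 0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = {"titration", "trace", "mixture_experiment", "envelope", "melt",
                 "sequence"}
        if self.kind not in kinds:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def manifest_json(spec: GeneratorSpec, truth: dict) -> str:
    """Serialize a generator spec plus ground truth for a dataset manifest."""
    return json.dumps({"spec": asdict(spec), "truth": truth}, indent=2, default=float)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_titration(Kd: float = 4.7, probe_total: float = 5.0,
                  titrant: Sequence[float] | None = None,
                  signal_free: float = 60.0, signal_bound: float = 220.0,
                  noise_sd: float = 0.0, seed: int = 0
                  ) -> tuple[list[TitrationPoint], dict]:
    """Saturation titration under ligand depletion (probe fixed, titrant varied)."""
    if Kd <= 0:
        raise ValueError("Kd must be > 0")
    if titrant is None:
        titrant = np.geomspace(0.1, 200.0, 12)
    titrant = np.asarray(titrant, dtype=float)
    frac = quadratic_bound(probe_total, titrant, Kd) / probe_total
    signal = signal_free + (signal_bound - signal_free) * frac
    signal = signal + _rng(seed).normal(0.0, noise_sd, size=signal.shape)
    truth = dict(Kd=Kd, probe_total=probe_total, signal_free=signal_free,
                 signal_bound=signal_bound, noise_sd=noise_sd, seed=seed)
    return [TitrationPoint(float(x), float(y)) for x, y in zip(titrant, signal)], truth


def gen_trace(k: float = 0.05, y_max: float = DEFAULT_YMAX, y_0: float = DEFAULT_Y0,
              t0: float = DEFAULT_T0, times: Sequence[float] | None = None,
              noise_sd: float = 0.0, seed: int = 0
              ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Single delayed-exponential dissociation trace."""
    times = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    y = delay_exponential(times, y_max, y_0, k, t0)
    y = y + _rng(seed).normal(0.0, noise_sd, size=y.shape)
    truth = dict(k=k, y_max=y_max, y_0=y_0, t0=t0, noise_sd=noise_sd, seed=seed)
    return times.copy(), y, truth


def gen_mixture_experiment(ratios: Sequence[tuple[float, float]] = DEFAULT_RATIOS,
                           rates: Sequence[float] = DEFAULT_RATES,
                           y_max: float = DEFAULT_YMAX, y_0: float = DEFAULT_Y0,
                           t0: float = DEFAULT_T0,
                           times: Sequence[float] | None = None,
                           noise_sd: float = 0.0, seed: int = 0
                           ) -> list[KineticTrace]:
    """Mixed-trimer dissociation experiment across wild-type:mutant ratios.

    Each trace is the composition-weighted sum of delayed exponentials with the
    given (k1, k2, k3); the 0-site species never decays.  Ground truth is
    embedded in each trace's ``truth`` mapping.
    """
    times = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    k1, k2, k3 = rates
    all_rates = np.array([0.0, k1, k2, k3])
    rng = _rng(seed)
    traces = []
    for a, b in ratios:
        ratio = MixRatio(a, b)
        comp = trimer_composition(ratio)
        y = _mixture_curve(times, y_max, y_0, t0, comp, all_rates)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
        traces.append(KineticTrace(
            times=times.copy(), signals=y, ratio=ratio,
            label=f"{a:g}to{b:g}",
            truth=dict(k1=k1, k2=k2, k3=k3, y_max=y_max, y_0=y_0, t0=t0,
                       noise_sd=noise_sd, seed=seed)))
    return traces


def gen_envelope(p_high: float = 0.30, mu_low: float = 1252.0, separation: float = 3.0,
                 sigma_low: float = 0.6, sigma_high: float = 0.6,
                 spacing: float = ISOTOPE_SPACING, n_sticks: int = 18,
                 noise_sd: float = 0.0, seed: int = 0,
                 peptide: str = "", condition: str = "", replicate: int = 0
                 ) -> tuple[IsotopeEnvelope, dict]:
    """Bimodal isotope envelope: two-Gaussian mass mixture sampled at stick spacing.

    Intensities are the mixture density at the stick masses multiplied by
    ``(1 + noise)`` with Gaussian relative noise, clamped non-negative.
    """
    if not 0.0 <= p_high <= 1.0:
        raise ValueError("p_high must lie in [0, 1]")
    mu_high = mu_low + separation
    start = mu_low - 4.0 * sigma_low - spacing
    masses = start + spacing * np.arange(n_sticks)

    def dens(m, mu, s):
        return np.exp(-0.5 * ((m - mu) / s) ** 2) / (s * np.sqrt(2 * np.pi))

    inten = (1.0 - p_high) * dens(masses, mu_low, sigma_low) \
        + p_high * dens(masses, mu_high, sigma_high)
    inten = inten * (1.0 + _rng(seed).normal(0.0, noise_sd, size=inten.shape))
    inten = np.clip(inten, 0.0, None)
    truth = dict(p_high=p_high, mu_low=mu_low, mu_high=mu_high,
                 sigma_low=sigma_low, sigma_high=sigma_high, spacing=spacing,
                 noise_sd=noise_sd, seed=seed)
    env = IsotopeEnvelope(masses=masses, intensities=inten, peptide=peptide,
                          condition=condition, replicate=replicate)
    return env, truth


def gen_melt(Tm: float = 36.0, steepness: float = 0.8,
             baseline_low: float = 0.05, baseline_high: float = 0.95,
             temperatures: Sequence[float] = DEFAULT_TEMPS,
             noise_sd: float = 0.0, seed: int = 0
             ) -> tuple[list[tuple[float, float]], dict]:
    """Sigmoidal trimer-fraction melt over the standard temperature series.

    Fractions are clamped to [0, 1] after noise.
    """
    T = np.asarray(temperatures, dtype=float)
    if not T.min() <= Tm <= T.max():
        raise ValueError("Tm must lie within the temperature grid")
    f = thermal_fraction(T, Tm, steepness, baseline_low, baseline_high)
    f = np.clip(f + _rng(seed).normal(0.0, noise_sd, size=f.shape), 0.0, 1.0)
    truth = dict(Tm=Tm, steepness=steepness, baseline_low=baseline_low,
                 baseline_high=baseline_high, noise_sd=noise_sd, seed=seed)
    return list(zip(T.tolist(), f.tolist())), truth


def gen_sequence(length: int = 60, seed: int = 0,
                 alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    """Uniform-random protein sequence for scanning tests."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    return "".join(rng.choice(list(alphabet), size=length))


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to its generator."""
    p = dict(spec.parameters)
    if spec.kind == "titration":
        return gen_titration(noise_sd=spec.noise_sd, seed=spec.seed, **p)
    if spec.kind == "trace":
        return gen_trace(noise_sd=spec.noise_sd, seed=spec.seed, **p)
    if spec.kind == "mixture_experiment":
        return gen_mixture_experiment(noise_sd=spec.noise_sd, seed=spec.seed, **p)
    if spec.kind == "envelope":
        return gen_envelope(noise_sd=spec.noise_sd, seed=spec.seed, **p)
    if spec.kind == "melt":
        return gen_melt(noise_sd=spec.noise_sd, seed=spec.seed, **p)
    if spec.kind == "sequence":
        return gen_sequence(seed=spec.seed, **p)
    raise ValueError(f"unknown generator kind {spec.kind!r}")
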