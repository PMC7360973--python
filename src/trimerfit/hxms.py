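"""Hydrogen-exchange MS stage: centroids, back-exchange correction, difference
tables, and two-Gaussian deconvolution of bimodal (EX1-type) isotope envelopes.

Peptide-level deuteron uptake is computed from decharged stick spectra
(mass, intensity): the intensity-weighted centroid is corrected for back
exchange against undeuterated and fully (100 %) deuterated reference centroids
and expressed as deuterons or as a fraction of the peptide's maximum
exchangeable amides.  Conditions are compared peptide-by-peptide in a
difference table (protection is negative by convention).

Envelopes with two coexisting conformational subpopulations exchanging to
different extents are bimodal; :func:`fit_bimodal` resolves them as a mixture of
two Gaussian mass distributions evaluated at the stick masses, returning the
fraction of the high-exchanging subpopulation and, when reference centroids are
supplied, the relative deuteration of each subpopulation.

Raw m/z profile extraction, charge-state deconvolution and retention-time
alignment are out of scope; inputs are stick spectra in CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .models import _minimize_multistart

__all__ = [
    "PeptideRecord",
    "IsotopeEnvelope",
    "DeuterationResult",
    "BimodalFit",
    "centroid",
    "max_exchangeable",
    "correct_back_exchange",
    "difference_table",
    "fit_bimodal",
    "subpopulation_summary",
    "read_envelopes_csv",
    "read_peptides_csv",
    "read_reference_centroids_csv",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# natural isotope envelopes are never narrower than this (Da)
SIGMA_FLOOR = 0.3
# mixture weights this close to 0/1 mean the envelope is effectively unimodal
UNIMODAL_P = 0.02


@dataclass(frozen=True)
class PeptideRecord:
    """A peptic peptide: sequence plus 1-based inclusive residue span."""

    id: str
    sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("residue span does not match sequence length")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")


@dataclass
class IsotopeEnvelope:
    """Stick spectrum (mass in Da, intensity) for one peptide/condition/replicate."""

    masses: np.ndarray
    intensities: np.ndarray
    peptide: str = ""
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.masses.shape != self.intensities.shape:
            raise ValueError("masses and intensities must have equal length")
        if self.masses.size < 4:
            raise ValueError("need at least 4 sticks")
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if self.intensities.sum() <= 0:
            raise ValueError("total intensity must be > 0")


@dataclass
class DeuterationResult:
    """Back-exchange-corrected uptake: centroid (Da), deuterons, relative uptake."""

    centroid: float
    deuterons: float
    relative: float


@dataclass
class BimodalFit:
    """Two-Gaussian envelope deconvolution.

    ``p_high`` is the weight of the high-mass (high-exchanging) mode;
    ``mu_low < mu_high`` is enforced by construction.  ``rel_low``/``rel_high``
    are per-subpopulation relative deuterations when reference centroids were
    provided, else NaN.
    """

    p_high: float
    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    amplitude: float
    rel_low: float = float("nan")
    rel_high: float = float("nan")
    stderr: dict = field(default_factory=dict)
    success: bool = True
    message: str = ""
    effectively_unimodal: bool = False
    rss: float = float("nan")


# ---------------------------------------------------------------------------
# centroids and uptake
# ---------------------------------------------------------------------------

def centroid(envelope) -> float:
    """Intensity-weighted mean mass Σ mᵢIᵢ / Σ Iᵢ of a stick spectrum."""
    if isinstance(envelope, IsotopeEnvelope):
        m, I = envelope.masses, envelope.intensities
    else:
        m, I = (np.asarray(a, dtype=float) for a in envelope)
    total = I.sum()
    if total <= 0:
        raise ValueError("total intensity must be > 0")
    return float((m * I).sum() / total)


def max_exchangeable(peptide) -> int:
    """Maximum number of exchange-competent backbone amides of a peptide.

    Convention: ``length − 2 − (prolines at positions 3..end)``.  The first two
    residues are treated as fully back-exchanging and prolines have no amide
    hydrogen.  Accepts a sequence string or a :class:`PeptideRecord`.
    """
    seq = peptide.sequence if isinstance(peptide, PeptideRecord) else str(peptide)
    if len(seq) < 3:
        raise ValueError("peptide too short to retain deuterium")
    return len(seq) - 2 - seq[2:].count("P")


def correct_back_exchange(observed: float, undeut: float, fulldeut: float,
                          n_max: int) -> DeuterationResult:
    """Correct an observed centroid for back exchange via a 100 %-deuterated control.

    ``deuterons = (observed − undeut) / (fulldeut − undeut) · n_max`` and
    ``relative = deuterons / n_max``.
    """
    if fulldeut <= undeut:
        raise ValueError("fully deuterated centroid must exceed undeuterated centroid")
    deut = (observed - undeut) / (fulldeut - undeut) * n_max
    return DeuterationResult(centroid=float(observed), deuterons=float(deut),
                             relative=float(deut / n_max))


# ---------------------------------------------------------------------------
# condition differences
# ---------------------------------------------------------------------------

def difference_table(condition_results: Mapping[str, Sequence[float]],
                     reference_results: Mapping[str, Sequence[float]],
                     alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Per-peptide deuteron-uptake differences between a condition and a reference.

    Inputs map peptide id -> replicate deuteron counts (>= 2 replicates each
    side).  Output row per matched peptide: ΔD (condition mean − reference
    mean; protection is negative), pooled SD, Welch-t p-value and a
    significance flag requiring BOTH p < alpha AND |ΔD| > 2 × pooled SD.
    Peptides present on only one side are returned in the ``unmatched`` dict,
    never silently dropped.
    """
    cond_ids, ref_ids = set(condition_results), set(reference_results)
    matched = sorted(cond_ids & ref_ids)
    unmatched = {
        "condition_only": sorted(cond_ids - ref_ids),
        "reference_only": sorted(ref_ids - cond_ids),
    }
    rows = []
    for pid in matched:
        c = np.asarray(condition_results[pid], dtype=float)
        r = np.asarray(reference_results[pid], dtype=float)
        if c.size < 2 or r.size < 2:
            raise ValueError(f"peptide {pid!r}: need >= 2 replicates per side")
        dd = float(c.mean() - r.mean())
        pooled = float(np.sqrt(((c.size - 1) * c.var(ddof=1) + (r.size - 1) * r.var(ddof=1))
                               / (c.size + r.size - 2)))
        if c.var(ddof=1) == 0 and r.var(ddof=1) == 0:
            pval = 0.0 if dd != 0 else 1.0
        else:
            pval = float(stats.ttest_ind(c, r, equal_var=False).pvalue)
        rows.append(dict(peptide_id=pid, delta_deuterons=dd, pooled_sd=pooled,
                         n_condition=int(c.size), n_reference=int(r.size),
                         p_value=pval,
                         significant=bool(pval < alpha and abs(dd) > 2 * pooled)))
    return pd.DataFrame(rows), unmatched


# ---------------------------------------------------------------------------
# bimodal deconvolution
# ---------------------------------------------------------------------------

def _gauss(m: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((m - mu) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def _weighted_quantile(m: np.ndarray, w: np.ndarray, q: float) -> float:
    cw = np.cumsum(w) / w.sum()
    return float(np.interp(q, cw, m))


def fit_bimodal(envelope: IsotopeEnvelope, undeut: float | None = None,
                fulldeut: float | None = None, n_max: int | None = None) -> BimodalFit:
    """Resolve a bimodal isotope envelope into two Gaussian subpopulations.

    Fits ``I(m) = A·[(1−p)·G(m; mu_low, σ_low) + p·G(m; mu_low+δ, σ_high)]``
    at the stick masses with ``δ > 0`` (so ``mu_low < mu_high`` by
    construction), independent widths bounded below by the natural envelope
    width floor, and initial means at the 25th/75th intensity-weighted
    percentiles.  ``p_high`` is the weight of the high-mass mode.  When
    ``p_high`` converges below 0.02 or above 0.98 the envelope is flagged
    ``effectively_unimodal``.  If the undeuterated / fully deuterated reference
    centroids and the maximum exchangeable-amide count are supplied, each
    subpopulation mean is converted to a relative deuteration.
    """
    m, I = envelope.masses, envelope.intensities
    if m.size < 8:
        raise ValueError("need at least 8 sticks spanning both modes")

    q25 = _weighted_quantile(m, I, 0.25)
    q75 = _weighted_quantile(m, I, 0.75)
    mu0 = centroid(envelope)
    sd = float(np.sqrt(np.clip(((m - mu0) ** 2 * I).sum() / I.sum(), SIGMA_FLOOR**2, None)))

    params = lmfit.Parameters()
    params.add("A", value=float(I.sum() * np.median(np.diff(m))), min=1e-12)
    params.add("p", value=0.5, min=0.0, max=1.0)
    params.add("mu_low", value=q25)
    params.add("delta", value=max(q75 - q25, 0.5), min=1e-6)
    params.add("sigma_low", value=max(sd / 2.0, SIGMA_FLOOR), min=SIGMA_FLOOR)
    params.add("sigma_high", value=max(sd / 2.0, SIGMA_FLOOR), min=SIGMA_FLOOR)

    def residual(p):
        low = _gauss(m, p["mu_low"].value, p["sigma_low"].value)
        high = _gauss(m, p["mu_low"].value + p["delta"].value, p["sigma_high"].value)
        model = p["A"].value * ((1.0 - p["p"].value) * low + p["p"].value * high)
        return model - I

    res = _minimize_multistart(residual, params,
                               {"p": 0.2, "mu_low": sd, "delta": 0.5,
                                "sigma_low": 0.3, "sigma_high": 0.3})
    p_high = float(res.params["p"].value)
    mu_low = float(res.params["mu_low"].value)
    mu_high = mu_low + float(res.params["delta"].value)

    # A single-mode envelope leaves the two-component weight split on a ridge
    # (both Gaussians coincide).  Collapse to a one-Gaussian refit with all
    # weight in the low mode so the reported split is well defined.
    sig_scale = max(float(res.params["sigma_low"].value),
                    float(res.params["sigma_high"].value))
    if (mu_high - mu_low) < 0.5 * sig_scale:
        params1 = lmfit.Parameters()
        params1.add("A", value=float(res.params["A"].value), min=1e-12)
        params1.add("p", value=0.0, vary=False)
        params1.add("mu_low", value=mu0)
        params1.add("delta", value=1e-6, vary=False)
        params1.add("sigma_low", value=max(sd, SIGMA_FLOOR), min=SIGMA_FLOOR)
        params1.add("sigma_high", value=SIGMA_FLOOR, vary=False)
        res = _minimize_multistart(residual, params1, {"mu_low": sd, "sigma_low": 0.3})
        p_high = 0.0
        mu_low = float(res.params["mu_low"].value)
        mu_high = mu_low + float(res.params["delta"].value)
    fit = BimodalFit(
        p_high=p_high, mu_low=mu_low, mu_high=mu_high,
        sigma_low=float(res.params["sigma_low"].value),
        sigma_high=float(res.params["sigma_high"].value),
        amplitude=float(res.params["A"].value),
        stderr={n: (float(res.params[n].stderr) if res.params[n].stderr is not None
                    else float("nan"))
                for n in ("p", "mu_low", "delta", "sigma_low", "sigma_high", "A")},
        success=bool(res.success),
        message="" if res.success else f"fit did not converge: {res.message}",
        effectively_unimodal=bool(p_high < UNIMODAL_P or p_high > 1.0 - UNIMODAL_P),
        rss=float(res.chisqr),
    )
    if fit.effectively_unimodal:
        fit.message = (fit.message + "; " if fit.message else "") + "effectively unimodal"
    if undeut is not None and fulldeut is not None and n_max is not None:
        fit.rel_low = correct_back_exchange(mu_low, undeut, fulldeut, n_max).relative
        fit.rel_high = correct_back_exchange(mu_high, undeut, fulldeut, n_max).relative
    return fit


def subpopulation_summary(fits: pd.DataFrame, reference_condition: str | None = None
                          ) -> pd.DataFrame:
    """Summarise high-exchanging subpopulation fractions per peptide and condition.

    ``fits`` has columns ``peptide_id``, ``condition``, ``p_high`` (one row per
    replicate fit).  Returns mean ± SD and replicate count per group; when a
    reference condition is named, conditions whose mean ``p_high`` exceeds the
    reference mean by more than 2 pooled SD are flagged ``elevated``.
    """
    g = fits.groupby(["peptide_id", "condition"])["p_high"]
    out = g.agg(mean_p_high="mean", sd_p_high=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
                n="count").reset_index()
    out["elevated"] = False
    if reference_condition is not None:
        ref = out[out["condition"] == reference_condition].set_index("peptide_id")
        for i, row in out.iterrows():
            if row["condition"] == reference_condition or row["peptide_id"] not in ref.index:
                continue
            r = ref.loc[row["peptide_id"]]
            pooled = np.sqrt((row["sd_p_high"] ** 2 + r["sd_p_high"] ** 2) / 2.0)
            out.at[i, "elevated"] = bool(row["mean_p_high"] - r["mean_p_high"] > 2 * pooled)
    return out


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_envelopes_csv(path) -> list[IsotopeEnvelope]:
    """Read `peptide_id,condition,replicate,mass_da,intensity` into envelopes."""
    df = pd.read_csv(path)
    envs = []
    for (pid, cond, rep), grp in df.groupby(["peptide_id", "condition", "replicate"],
                                            sort=False):
        grp = grp.sort_values("mass_da")
        envs.append(IsotopeEnvelope(masses=grp["mass_da"].to_numpy(float),
                                    intensities=grp["intensity"].to_numpy(float),
                                    peptide=str(pid), condition=str(cond),
                                    replicate=int(rep)))
    return envs


def read_peptides_csv(path) -> dict[str, PeptideRecord]:
    """Read `peptide_id,sequence,start,end` into peptide records keyed by id."""
    df = pd.read_csv(path)
    return {str(r.peptide_id): PeptideRecord(str(r.peptide_id), str(r.sequence),
                                             int(r.start), int(r.end))
            for r in df.itertuples()}


def read_reference_centroids_csv(path) -> dict[str, tuple[float, float]]:
    """Read `peptide_id,undeut_da,fulldeut_da` into (undeut, fulldeut) pairs."""
    df = pd.read_csv(path)
    return {str(r.peptide_id): (float(r.undeut_da), float(r.fulldeut_da))
            for r in df.itertuples()}
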