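"""Sliding-window Hsp70/Hsc70 binding-site scanning of protein sequences.

Chaperones of the Hsp70 family select substrates with a hydrophobic core
flanked by positively charged residues.  A position-specific scoring matrix
(rows: the 20 amino acids; columns: window offsets −6..+6) assigns each
13-residue window an additive score which is attributed to the window's center
residue; low (negative) scores mark good binding sites, with ``score ≤ −5`` the
conventional call threshold.  The matrix itself (e.g. the DnaK peptide-library
energy matrix) is a required input with provenance recorded — no matrix values
ship with this package.

Coordinates are 1-based and ranges inclusive throughout, matching protein
residue numbering.  Termini are untiled: centers run from residue 7 to L−6.
Variants are rescored after substitution, and deletions are scanned after
excision with a coordinate map back to the original numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ScoringMatrix",
    "ScoreProfile",
    "BindingSite",
    "WINDOW",
    "OFFSETS",
    "DEFAULT_THRESHOLD",
    "window_scores",
    "call_sites",
    "count_sites_in_range",
    "count_runs_in_range",
    "rescore_variant",
    "read_matrix_csv",
    "read_fasta",
]

WINDOW = 13
OFFSETS = tuple(range(-6, 7))
DEFAULT_THRESHOLD = -5.0
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ScoringMatrix:
    """Additive position-specific scores: one value per (residue, offset).

    ``entries`` is a DataFrame indexed by the 20 one-letter amino-acid codes
    with integer columns −6..+6.  ``name`` records provenance of the matrix.
    """

    entries: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        self.entries = self.entries.copy()
        self.entries.columns = [int(c) for c in self.entries.columns]
        missing_aa = set(AMINO_ACIDS) - set(self.entries.index)
        if missing_aa:
            raise ValueError(f"matrix missing residues: {sorted(missing_aa)}")
        missing_off = set(OFFSETS) - set(self.entries.columns)
        if missing_off:
            raise ValueError(f"matrix missing offsets: {sorted(missing_off)}")
        if not np.isfinite(self.entries.to_numpy(dtype=float)).all():
            raise ValueError("matrix entries must be finite")
        self.entries = self.entries.loc[list(AMINO_ACIDS), list(OFFSETS)].astype(float)

    @classmethod
    def constant(cls, value: float, name: str = "constant") -> "ScoringMatrix":
        df = pd.DataFrame(value, index=list(AMINO_ACIDS), columns=list(OFFSETS),
                          dtype=float)
        return cls(df, name=name)

    def lookup(self, residue: str, offset: int) -> float:
        return float(self.entries.at[residue, offset])


@dataclass
class ScoreProfile:
    """Per-center window scores for one sequence (1-based residue numbering)."""

    seq_id: str
    centers: np.ndarray
    scores: np.ndarray
    coordinate_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.centers.shape != self.scores.shape:
            raise ValueError("centers and scores must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"seq_id": self.seq_id, "center": self.centers,
                             "score": self.scores})


@dataclass(frozen=True)
class BindingSite:
    """Maximal run of consecutive below-threshold centers (1-based, inclusive)."""

    start: int
    end: int
    min_score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")


def _validate_sequence(sequence: str) -> str:
    sequence = str(sequence).upper()
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return sequence


def window_scores(sequence: str, matrix: ScoringMatrix, seq_id: str = "") -> ScoreProfile:
    """Score every full 13-residue window of a sequence.

    The window score is the sum over offsets −6..+6 of the matrix entry for the
    residue at that offset; it is assigned to the center residue.  No terminal
    padding: centers span residues 7 .. L−6, so sequences shorter than 13
    residues are an error.
    """
    sequence = _validate_sequence(sequence)
    L = len(sequence)
    if L < WINDOW:
        raise ValueError("sequence shorter than window (13 residues)")
    tbl = matrix.entries.to_numpy()
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    idx = np.array([aa_index[r] for r in sequence])
    # entry matrix per (position, offset); sum along the diagonal band
    scores = np.empty(L - WINDOW + 1)
    for j in range(L - WINDOW + 1):
        scores[j] = tbl[idx[j:j + WINDOW], np.arange(WINDOW)].sum()
    centers = np.arange(7, L - 5)
    return ScoreProfile(seq_id=seq_id, centers=centers, scores=scores)


def call_sites(profile: ScoreProfile, threshold: float = DEFAULT_THRESHOLD
               ) -> list[BindingSite]:
    """Call binding sites as maximal runs of consecutive centers with score ≤ threshold."""
    sites: list[BindingSite] = []
    run_start = None
    run_min = np.inf
    prev_center = None
    for c, s in zip(profile.centers, profile.scores):
        hit = s <= threshold
        contiguous = prev_center is not None and c == prev_center + 1
        if hit:
            if run_start is None or not contiguous:
                if run_start is not None:
                    sites.append(BindingSite(run_start, prev_hit_center, run_min))
                run_start, run_min = int(c), float(s)
            else:
                run_min = min(run_min, float(s))
            prev_hit_center = int(c)
        elif run_start is not None:
            sites.append(BindingSite(run_start, prev_hit_center, run_min))
            run_start, run_min = None, np.inf
        prev_center = c
    if run_start is not None:
        sites.append(BindingSite(run_start, prev_hit_center, run_min))
    return sites


def count_sites_in_range(profile: ScoreProfile, residue_range: tuple[int, int],
                         threshold: float = DEFAULT_THRESHOLD) -> int:
    """Count centers within an inclusive residue range scoring ≤ threshold.

    An empty overlap between the range and the profile's centers returns 0.
    """
    lo, hi = residue_range
    mask = (profile.centers >= lo) & (profile.centers <= hi)
    if not mask.any():
        import warnings
        warnings.warn(f"range {lo}-{hi} does not overlap scored centers", stacklevel=2)
        return 0
    return int((profile.scores[mask] <= threshold).sum())


def count_runs_in_range(profile: ScoreProfile, residue_range: tuple[int, int],
                        threshold: float = DEFAULT_THRESHOLD) -> int:
    """Count called sites (maximal runs) whose span intersects the inclusive range."""
    lo, hi = residue_range
    return sum(1 for s in call_sites(profile, threshold)
               if s.end >= lo and s.start <= hi)


def rescore_variant(sequence: str,
                    substitutions: Sequence[tuple[int, str]] = (),
                    matrix: ScoringMatrix | None = None,
                    deletions: Sequence[tuple[int, int]] = (),
                    seq_id: str = "") -> ScoreProfile:
    """Score a sequence variant: point substitutions and/or deletions.

    Substitutions are ``(1-based position, new residue)``.  Deletions are
    inclusive residue ranges excised before scanning; the returned profile's
    centers carry the ORIGINAL residue numbering of the retained residues via
    the profile's ``coordinate_map`` (variant position -> original position),
    with centers reported in original coordinates.
    """
    if matrix is None:
        raise ValueError("a scoring matrix is required")
    sequence = _validate_sequence(sequence)
    L = len(sequence)
    residues = list(sequence)
    for pos, new in substitutions:
        if not 1 <= pos <= L:
            raise ValueError(f"substitution position {pos} out of range 1..{L}")
        if new not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {new!r}")
        residues[pos - 1] = new

    keep = np.ones(L, dtype=bool)
    for lo, hi in deletions:
        if not (1 <= lo <= hi <= L):
            raise ValueError(f"deletion range {lo}-{hi} out of range 1..{L}")
        keep[lo - 1:hi] = False
    variant_seq = "".join(r for r, k in zip(residues, keep) if k)
    orig_positions = np.flatnonzero(keep) + 1  # variant index -> original residue no.

    profile = window_scores(variant_seq, matrix, seq_id=seq_id)
    coord_map = {int(i + 1): int(orig_positions[i]) for i in range(len(variant_seq))}
    centers = np.array([coord_map[int(c)] for c in profile.centers])
    return ScoreProfile(seq_id=seq_id, centers=centers, scores=profile.scores,
                        coordinate_map=coord_map)


# ---------------------------------------------------------------------------
# I/O: matrix CSV (rows = amino acids, columns = offsets −6..+6), FASTA
# ---------------------------------------------------------------------------

def read_matrix_csv(path, name: str | None = None) -> ScoringMatrix:
    df = pd.read_csv(path, index_col=0)
    return ScoringMatrix(df, name=name or str(path))


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record) FASTA into an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
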