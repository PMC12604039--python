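"""Peak-list matching (MALDI fingerprint path) and extract-style candidate
filtering with target-decoy FDR.

The fingerprint path assigns every prediction within tolerance to a peak:
a peak explained by a single prediction is a mass match; several
predictions within tolerance of the same peak are all flagged ambiguous
with mutual partners (ties are never resolved winner-take-all); peaks
below the signal-to-noise gate (default S/N > 3) never yield a match
regardless of mass distance.

The extract path filters candidate variants (length >= 5 residues, neutral
mass <= 10 kDa, <= 3 variable PTMs with a disulfide counted once per
bridge) and estimates the false discovery rate from a reversed-sequence
decoy search; the scoring plugged into the FDR machinery is the
fragment-match count, and the machinery itself is score-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from pathlib import Path

import numpy as np
import pandas as pd

from .masses import IonSpec, MassSpec, peptide_mass

__all__ = [
    "Peak",
    "PeakList",
    "Tolerance",
    "MaldiTolerance",
    "FilterParams",
    "MatchRecord",
    "FdrResult",
    "MatchingError",
    "read_peaklist",
    "match_peaks",
    "filter_candidates",
    "estimate_fdr",
    "reverse_decoy",
]

DEFAULT_MASS_RANGE = (600.0, 10000.0)
DEFAULT_SNR_MIN = 3.0


class MatchingError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0
    snr: Optional[float] = None


@dataclass
class PeakList:
    """An observed spectrum reduced to (m/z, intensity, S/N) rows."""

    source_id: str
    peaks: List[Peak]
    mass_range: Tuple[float, float] = DEFAULT_MASS_RANGE

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        lo, hi = self.mass_range
        for p in self.peaks:
            if not lo <= p.mz <= hi:
                raise MatchingError(
                    f"{self.source_id}: peak {p.mz} outside mass range "
                    f"{self.mass_range}")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])


def read_peaklist(path, source_id: Optional[str] = None,
                  mass_range: Optional[Tuple[float, float]] = None) -> PeakList:
    """Parse a whitespace/comma separated text table: mz intensity [snr]."""
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", comment="#",
                     header=None)
    if df.shape[1] < 2:
        raise MatchingError(f"{path}: need at least mz and intensity columns")
    peaks = []
    for row in df.itertuples(index=False):
        snr = float(row[2]) if len(row) > 2 and pd.notna(row[2]) else None
        peaks.append(Peak(mz=float(row[0]), intensity=float(row[1]), snr=snr))
    if mass_range is None:
        lo = min(DEFAULT_MASS_RANGE[0], min(p.mz for p in peaks) - 1.0)
        hi = max(DEFAULT_MASS_RANGE[1], max(p.mz for p in peaks) + 1.0)
        mass_range = (lo, hi)
    return PeakList(source_id=source_id or Path(path).stem, peaks=peaks,
                    mass_range=mass_range)


@dataclass(frozen=True)
class Tolerance:
    """A single symmetric match window, in Da or ppm."""

    value: float
    unit: str = "da"  # "da" | "ppm"

    def __post_init__(self):
        if self.value <= 0:
            raise MatchingError(f"tolerance must be positive, got {self.value}")
        if self.unit not in ("da", "ppm"):
            raise MatchingError(f"unknown tolerance unit {self.unit!r}")

    def window(self, mz: float) -> float:
        return self.value if self.unit == "da" else mz * self.value * 1e-6


@dataclass(frozen=True)
class MaldiTolerance:
    """Default fingerprint window: +/-0.1 Da below the crossover m/z and a
    ppm window above it, where a fixed Da window would become needlessly
    wide."""

    da: float = 0.1
    ppm: float = 50.0
    crossover: float = 4000.0

    def __post_init__(self):
        if self.da <= 0 or self.ppm <= 0:
            raise MatchingError("tolerance must be positive")

    def window(self, mz: float) -> float:
        return self.da if mz < self.crossover else mz * self.ppm * 1e-6


@dataclass(frozen=True)
class FilterParams:
    """Extract-path candidate filters and FDR target."""

    min_len: int = 5
    max_mw: float = 10000.0
    max_var_ptms: int = 3
    parent_tol: float = 0.1
    fragment_tol: float = 0.05
    fdr_threshold: float = 0.01

    def __post_init__(self):
        for name in ("min_len", "max_mw", "max_var_ptms", "parent_tol",
                     "fragment_tol", "fdr_threshold"):
            if getattr(self, name) <= 0:
                raise MatchingError(f"{name} must be positive")


@dataclass
class MatchRecord:
    """One predicted-ion-to-peak assignment."""

    peptide_ref: str
    variant: str
    adduct: str
    predicted_mz: float
    observed_mz: float
    error_da: float
    error_ppm: float
    snr_pass: bool
    source_id: str = ""
    ambiguity_partners: tuple = ()
    status: str = "mass_match"  # mass_match | below_snr | ambiguous


def match_peaks(
    predicted: Sequence[IonSpec],
    peaks: PeakList,
    tol=MaldiTolerance(),
    snr_min: float = DEFAULT_SNR_MIN,
) -> List[MatchRecord]:
    """Assign every prediction within tolerance to every peak it explains.

    The match set is monotone in the tolerance: widening the window can
    only add records.
    """
    if not predicted:
        raise MatchingError("no predictions to match")
    if not peaks.peaks:
        raise MatchingError("empty peak list")

    pred_mz = np.array([ion.mz for ion in predicted])
    obs_mz = peaks.mz_array
    records: List[MatchRecord] = []
    per_peak_hits: List[List[int]] = [[] for _ in peaks.peaks]

    for j, ion in enumerate(predicted):
        w = tol.window(ion.mz)
        lo = np.searchsorted(obs_mz, ion.mz - w, side="left")
        hi = np.searchsorted(obs_mz, ion.mz + w, side="right")
        for i in range(lo, hi):
            per_peak_hits[i].append(j)

    for i, hit_idx in enumerate(per_peak_hits):
        if not hit_idx:
            continue
        peak = peaks.peaks[i]
        snr_ok = peak.snr is None or peak.snr >= snr_min
        ambiguous = len(hit_idx) > 1
        refs = [predicted[j].parent_ref for j in hit_idx]
        for j in hit_idx:
            ion = predicted[j]
            err = peak.mz - ion.mz
            if not snr_ok:
                status = "below_snr"
            elif ambiguous:
                status = "ambiguous"
            else:
                status = "mass_match"
            partners = tuple(r for r in refs if r != ion.parent_ref)
            records.append(MatchRecord(
                peptide_ref=ion.parent_ref, variant=ion.variant,
                adduct=ion.adduct, predicted_mz=ion.mz, observed_mz=peak.mz,
                error_da=err, error_ppm=err / ion.mz * 1e6,
                snr_pass=snr_ok, source_id=peaks.source_id,
                ambiguity_partners=partners, status=status))
    return records


def n_variable_ptms(ptms) -> int:
    """Count variable PTMs, a disulfide bridge counting once."""
    return len(list(ptms))


def filter_candidates(
    peptides: Sequence,
    params: FilterParams = FilterParams(),
) -> Tuple[list, list]:
    """Apply the extract-path candidate filters.

    Takes MaturePeptide-like objects (``sequence`` and ``ptms``
    attributes). Returns (kept, rejected) where each rejection is
    ``(peptide, rule_id)`` with rule ids ``min_len``, ``max_mw``,
    ``max_var_ptms``.
    """
    kept, rejected = [], []
    for pep in peptides:
        if len(pep.sequence) < params.min_len:
            rejected.append((pep, "min_len"))
            continue
        if n_variable_ptms(pep.ptms) > params.max_var_ptms:
            rejected.append((pep, "max_var_ptms"))
            continue
        if peptide_mass(pep.sequence, pep.ptms).neutral_mono > params.max_mw:
            rejected.append((pep, "max_mw"))
            continue
        kept.append(pep)
    return kept, rejected


@dataclass
class FdrResult:
    threshold: Optional[float]
    qvalues: np.ndarray  # per target record, aligned with input order
    fdr_at_threshold: Optional[float]

    def accepted(self, target_scores) -> np.ndarray:
        if self.threshold is None:
            return np.zeros(len(target_scores), dtype=bool)
        return np.asarray(target_scores) >= self.threshold


def estimate_fdr(
    target_scores: Sequence[float],
    decoy_scores: Sequence[float],
    fdr_threshold: float = 0.01,
) -> FdrResult:
    """Target-decoy FDR: FDR(s) = #decoys >= s / max(1, #targets >= s).

    The returned threshold is the smallest observed target score whose FDR
    estimate is below ``fdr_threshold`` (None when no score qualifies);
    the q-value of a record is the minimum FDR over thresholds at or below
    its score, hence non-increasing in score.
    """
    targets = np.asarray(target_scores, dtype=float)
    decoys = np.asarray(decoy_scores, dtype=float)
    if targets.size == 0:
        raise MatchingError("empty target score list")

    order = np.argsort(targets)  # ascending
    sorted_t = targets[order]
    sorted_d = np.sort(decoys)
    # counts >= s for each candidate threshold s = sorted_t[i]
    n_t_ge = targets.size - np.arange(targets.size)
    n_d_ge = decoys.size - np.searchsorted(sorted_d, sorted_t, side="left")
    fdr = n_d_ge / np.maximum(1, n_t_ge)

    # q-value at threshold s_i = min FDR over thresholds <= s_i
    q_sorted = np.minimum.accumulate(fdr)
    qvalues = np.empty_like(q_sorted)
    qvalues[order] = q_sorted

    passing = np.nonzero(fdr < fdr_threshold)[0]
    if passing.size:
        i = passing[0]
        return FdrResult(threshold=float(sorted_t[i]), qvalues=qvalues,
                         fdr_at_threshold=float(fdr[i]))
    return FdrResult(threshold=None, qvalues=qvalues, fdr_at_threshold=None)


def reverse_decoy(sequence: str) -> str:
    """Whole-sequence reversal of a precursor, the decoy construction used
    for FDR estimation (same processing rules are then applied)."""
    return sequence[::-1]


def matches_to_frame(records: Sequence[MatchRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
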