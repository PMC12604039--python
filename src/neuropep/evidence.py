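"""Fragment-level verification and evidence-tier aggregation across tissues.

Evidence per peptide per tissue is the maximum over a total tier ordering

    absent < mass_match (+) < partial ((+)) < confirmed (++)

where ``confirmed`` requires an accepted MS/MS fragment verification,
``partial`` a verification covering at least half of the residue junctions,
and ``mass_match`` at least one unambiguous fingerprint match. Matches on
peaks below the signal-to-noise gate never raise a cell above absent, but
are kept in a footnote section so that a sub-threshold signal (like the
proctolin ion in the clock neuropil) remains auditable.

Isoleucine/leucine positions are mass-identical and are reported as I/L
ambiguities, never as verification failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .masses import Ptm, fragment_series, il_ambiguous_positions
from .matching import MatchRecord, MatchingError, PeakList, Tolerance

__all__ = [
    "TIERS",
    "VerificationResult",
    "EvidenceRow",
    "fragment_verify",
    "aggregate_evidence",
    "evidence_table",
]

TIERS = ("absent", "mass_match", "partial", "confirmed")
_TIER_RANK = {t: i for i, t in enumerate(TIERS)}
TIER_SYMBOL = {"absent": "", "mass_match": "+", "partial": "(+)",
               "confirmed": "++"}


@dataclass
class VerificationResult:
    """Outcome of checking a peptide variant against an MS/MS peak list."""

    peptide_ref: str
    status: str  # confirmed | partial | failed
    junction_coverage: float
    covered_junctions: tuple
    matched_ions: tuple  # (label, theoretical mz, observed mz)
    il_ambiguities: tuple
    source_id: str = ""


def fragment_verify(
    sequence: str,
    ptms: Iterable[Ptm],
    msms_peaks: PeakList,
    fragment_tol: float = 0.05,
    partial_fraction: float = 0.5,
    peptide_ref: str = "",
) -> VerificationResult:
    """Compare theoretical b/y fragment masses with an observed MS/MS list.

    Junction i (between residues i and i+1) counts as covered when b_i or
    y_(n-i) is matched within ``fragment_tol`` Da. ``confirmed`` requires
    every junction covered, ``partial`` at least ``partial_fraction`` of
    them.
    """
    if len(sequence) < 2:
        raise MatchingError("fragment verification needs length >= 2")
    if not msms_peaks.peaks:
        raise MatchingError("empty MS/MS peak list")
    tol = Tolerance(fragment_tol, "da")
    obs = msms_peaks.mz_array
    n = len(sequence)
    covered = set()
    matched = []
    import numpy as np

    for label, mz in fragment_series(sequence, ptms):
        w = tol.window(mz)
        lo = np.searchsorted(obs, mz - w, side="left")
        hi = np.searchsorted(obs, mz + w, side="right")
        if hi > lo:
            matched.append((label, mz, float(obs[lo])))
            idx = int(label[1:])
            covered.add(idx if label[0] == "b" else n - idx)
    coverage = len(covered) / (n - 1)
    if coverage == 1.0:
        status = "confirmed"
    elif coverage >= partial_fraction:
        status = "partial"
    else:
        status = "failed"
    return VerificationResult(
        peptide_ref=peptide_ref, status=status, junction_coverage=coverage,
        covered_junctions=tuple(sorted(covered)), matched_ions=tuple(matched),
        il_ambiguities=tuple(il_ambiguous_positions(sequence)),
        source_id=msms_peaks.source_id)


@dataclass
class EvidenceRow:
    """Per-peptide evidence across an ordered tissue list."""

    peptide_ref: str
    precursor_id: str
    cells: Dict[str, str]  # tissue -> tier
    footnotes: tuple = ()  # below-S/N observations
    confirmations: tuple = ()  # backing VerificationResults

    def tier(self, tissue: str) -> str:
        return self.cells.get(tissue, "absent")


def _raise(cells: Dict[str, str], tissue: str, tier: str) -> None:
    if _TIER_RANK[tier] > _TIER_RANK[cells.get(tissue, "absent")]:
        cells[tissue] = tier


def aggregate_evidence(
    matches: Sequence[MatchRecord],
    confirmations: Sequence[VerificationResult] = (),
    known_peptides: Optional[Iterable[str]] = None,
    precursor_of: Optional[Dict[str, str]] = None,
) -> List[EvidenceRow]:
    """Fold match and verification records into one row per peptide.

    Aggregation is idempotent: re-aggregating the records behind a row set
    reproduces it. When ``known_peptides`` is given, records referencing a
    peptide outside it raise.
    """
    known = set(known_peptides) if known_peptides is not None else None
    rows: Dict[str, EvidenceRow] = {}
    precursor_of = precursor_of or {}

    def row_for(ref: str) -> EvidenceRow:
        if known is not None and ref not in known:
            raise MatchingError(f"record references unknown peptide {ref!r}")
        if ref not in rows:
            rows[ref] = EvidenceRow(
                peptide_ref=ref,
                precursor_id=precursor_of.get(ref, ref.rsplit("-", 1)[0]),
                cells={})
        return rows[ref]

    for m in matches:
        row = row_for(m.peptide_ref)
        if m.status == "below_snr":
            row.footnotes = row.footnotes + (
                f"{m.source_id}: signal at m/z {m.observed_mz:.2f} below "
                f"S/N gate",)
            continue
        # ambiguous matches still witness a mass within tolerance
        _raise(row.cells, m.source_id, "mass_match")

    for c in confirmations:
        row = row_for(c.peptide_ref)
        if c.status == "confirmed":
            _raise(row.cells, c.source_id, "confirmed")
            row.confirmations = row.confirmations + (c,)
        elif c.status == "partial":
            _raise(row.cells, c.source_id, "partial")
            row.confirmations = row.confirmations + (c,)

    return [rows[k] for k in sorted(rows)]


def evidence_table(
    rows: Sequence[EvidenceRow],
    tissues: Sequence[str],
    symbols: bool = True,
) -> pd.DataFrame:
    """Render rows into a tissue-column table; ``(+)`` stands for partial
    confirmation in plain text output."""
    data = {
        "peptide": [r.peptide_ref for r in rows],
        "precursor": [r.precursor_id for r in rows],
    }
    for t in tissues:
        col = [r.tier(t) for r in rows]
        data[t] = [TIER_SYMBOL[v] for v in col] if symbols else col
    data["footnotes"] = ["; ".join(r.footnotes) for r in rows]
    return pd.DataFrame(data)
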