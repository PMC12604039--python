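"""Precursor (prepropeptide) catalogue: loading, validation, classification
and persistence.

Sequences come from FASTA; per-precursor annotations (signal peptide end,
class label, completeness) come from a tab-separated table, since
signal-peptide prediction is consumed as an annotation rather than
recomputed. Coordinates are 1-based and inclusive on the preproprotein.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PrecursorRecord",
    "CurationOverride",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "load_overrides",
    "classify_product",
    "catalog_to_json",
    "bundled_catalog_paths",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
CLASS_LABELS = ("neuropeptide", "neuropeptide_like", "protein_hormone",
                "unclassified")

# Products of neuronal/endocrine cells up to this many residues are called
# neuropeptides; anything longer is a protein hormone.
NEUROPEPTIDE_MAX_LEN = 45


class CatalogError(ValueError):
    """Malformed catalogue input (FASTA, annotations or overrides)."""


@dataclass
class PrecursorRecord:
    """One prepropeptide.

    ``signal_end`` is the 1-based position of the last signal-peptide
    residue, or ``None`` when no signal peptide is annotated (incomplete
    precursors). ``complete`` is False whenever the signal peptide or stop
    codon was missing in the source data.
    """

    id: str
    name: str
    sequence: str
    signal_end: Optional[int] = None
    class_label: str = "unclassified"
    complete: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise CatalogError(f"{self.id}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in VALID_RESIDUES:
                raise CatalogError(
                    f"{self.id}: invalid residue {aa!r} at position {pos}")
        if self.class_label not in CLASS_LABELS:
            raise CatalogError(
                f"{self.id}: unknown class label {self.class_label!r}")
        if self.signal_end is not None:
            if not 1 <= self.signal_end < len(self.sequence):
                raise CatalogError(
                    f"{self.id}: signal_end {self.signal_end} outside "
                    f"1..{len(self.sequence) - 1}")
        elif self.complete:
            raise CatalogError(
                f"{self.id}: record without signal peptide cannot be complete")

    @property
    def proprotein(self) -> str:
        """Sequence downstream of the signal peptide (all of it when no
        signal peptide is annotated; incomplete precursors are processed
        from residue 1)."""
        if self.signal_end is None:
            return self.sequence
        return self.sequence[self.signal_end:]

    @property
    def proprotein_offset(self) -> int:
        """0-based offset of the proprotein on the preproprotein."""
        return self.signal_end or 0


@dataclass(frozen=True)
class CurationOverride:
    """One manual-assignment action replayed on top of the rule engine."""

    precursor_id: str
    action: str  # force_cleavage | suppress_cleavage | force_ptm | set_role
    position: Optional[int] = None
    payload: str = ""

    _ACTIONS = ("force_cleavage", "suppress_cleavage", "force_ptm", "set_role")

    def __post_init__(self):
        if self.action not in self._ACTIONS:
            raise CatalogError(f"unknown override action {self.action!r}")
        if self.action in ("force_cleavage", "suppress_cleavage") \
                and self.position is None:
            raise CatalogError(f"{self.action} requires a position")


def _parse_annotations(annotations_path) -> pd.DataFrame:
    df = pd.read_csv(annotations_path, sep="\t", dtype=str,
                     keep_default_na=False, comment="#")
    required = {"id", "name", "signal_end", "class", "complete"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"annotation table missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise CatalogError(f"duplicate annotation ids: {dups}")
    return df


def load_catalog(fasta_path, annotations_path=None) -> List[PrecursorRecord]:
    """Load precursors from FASTA plus an optional annotation table.

    Every FASTA entry yields one record. Annotation rows whose id has no
    FASTA entry raise; FASTA entries without an annotation row are kept as
    ``unclassified`` / ``complete=False``.
    """
    seqs: Dict[str, SeqRecord] = {}
    order: List[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise CatalogError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = rec
        order.append(rec.id)
    if not order:
        logger.warning("no sequences found in %s", fasta_path)
        return []

    ann: Dict[str, dict] = {}
    if annotations_path is not None:
        df = _parse_annotations(annotations_path)
        unknown = [i for i in df["id"] if i not in seqs]
        if unknown:
            raise CatalogError(
                f"annotation ids without FASTA entry: {unknown}")
        ann = df.set_index("id").to_dict("index")

    records = []
    for rid in order:
        rec = seqs[rid]
        row = ann.get(rid)
        if row is None:
            if annotations_path is not None:
                logger.warning("%s has no annotation row; kept unclassified",
                               rid)
            records.append(PrecursorRecord(
                id=rid, name=rec.description.split(None, 1)[-1]
                if " " in rec.description else rid,
                sequence=str(rec.seq).upper()))
            continue
        signal_end = int(row["signal_end"]) if row["signal_end"] else None
        complete = row["complete"].strip().lower() in ("1", "true", "yes", "+")
        records.append(PrecursorRecord(
            id=rid, name=row["name"], sequence=str(rec.seq).upper(),
            signal_end=signal_end, class_label=row["class"] or "unclassified",
            complete=complete))
        if signal_end is None:
            logger.warning(
                "%s: no signal peptide annotated; processing from residue 1",
                rid)
    return records


def write_catalog(records: Sequence[PrecursorRecord], fasta_path,
                  annotations_path) -> None:
    """Persist a catalogue back to FASTA + annotation table (round-trips
    with :func:`load_catalog`)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.name)
        for r in records
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    df = pd.DataFrame({
        "id": [r.id for r in records],
        "name": [r.name for r in records],
        "signal_end": ["" if r.signal_end is None else str(r.signal_end)
                       for r in records],
        "class": [r.class_label for r in records],
        "complete": ["true" if r.complete else "false" for r in records],
    })
    df.to_csv(annotations_path, sep="\t", index=False)


def catalog_to_json(records: Sequence[PrecursorRecord]) -> str:
    return json.dumps([asdict(r) for r in records], indent=2)


def load_overrides(path) -> List[CurationOverride]:
    """Read the tab-separated curation table
    (precursor_id, action, position, payload)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    required = {"precursor_id", "action", "position", "payload"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"override table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        pos = int(row.position) if row.position else None
        out.append(CurationOverride(precursor_id=row.precursor_id,
                                    action=row.action, position=pos,
                                    payload=row.payload))
    return out


def classify_product(peptide_length: int, origin: str = "neuronal_endocrine") -> str:
    """Length-threshold product classification.

    Neuronal/endocrine products of up to 45 residues are neuropeptides;
    longer products are protein hormones.
    """
    if origin != "neuronal_endocrine":
        raise ValueError(f"unknown origin {origin!r}")
    if peptide_length < 1:
        raise ValueError(f"peptide length must be positive, got {peptide_length}")
    return ("neuropeptide" if peptide_length <= NEUROPEPTIDE_MAX_LEN
            else "protein_hormone")


def bundled_catalog_paths() -> dict:
    """Paths of the bundled synthetic catalogue fixture.

    The fixture mirrors the published gene table (names, accessions,
    class and completeness of 68 precursors) but its sequences are
    synthetic stand-ins: the deposited precursor sequences are not
    redistributed here. A few mature peptides inside them are
    literature-reconstructed anchors (proctolin, PDF, AKH, NVP-2).
    """
    d = Path(__file__).parent / "data"
    return {
        "fasta": d / "synthetic_catalog.fasta",
        "annotations": d / "synthetic_catalog_annotations.tsv",
        "overrides": d / "synthetic_catalog_overrides.tsv",
    }
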