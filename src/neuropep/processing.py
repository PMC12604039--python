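"""Prohormone convertase cleavage prediction and mature-peptide derivation.

The rule engine implements the conservative dibasic core (KR, RR) with every
further predicate switchable: KK/RK dibasic pairs, the monobasic-Arg context
rule (an additional basic residue at relative position -4, -6 or -8), the
furin R-X-X-R motif, and the proline block (no cleavage when the residue
immediately C-terminal to the site is Pro). Manual assignments are replayed
through explicit curation overrides rather than hidden in code.

After cleavage the proprotein is partitioned into segments; motif basic
residues are stripped, a C-terminal Gly is converted into an amide on the
preceding residue, and N-terminal Gln (optionally Glu) yields an additional
pyroglutamate variant. Peptides carrying an amidation or pyroGlu signal (or
curated as bioactive) are classed bioactive candidates, the rest as
precursor peptides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import yaml

from .catalog import CurationOverride, PrecursorRecord
from .masses import Ptm

__all__ = [
    "RuleConfig",
    "CleavageSite",
    "MaturePeptide",
    "ProcessingError",
    "predict_cleavage_sites",
    "derive_mature_peptides",
    "process_precursor",
]

BASIC = set("KR")
DIBASIC_CONFIDENCE = {"KR": "high", "RR": "high", "RK": "low", "KK": "low"}


class ProcessingError(ValueError):
    pass


@dataclass(frozen=True)
class RuleConfig:
    """Switchable cleavage and PTM predicates.

    Defaults reproduce the conservative core: KR and RR on, KK and RK off,
    monobasic Arg off, proline block on. PyroGlu from Glu and disulfide
    variants are emitted alongside the unmodified forms; sulfation (labile
    in MALDI) is off by default.
    """

    kr: bool = True
    rr: bool = True
    kk: bool = False
    rk: bool = False
    mono_r: bool = False
    furin_rxxr: bool = False
    proline_block: bool = True
    amidation: bool = True
    pyroglu_from_q: bool = True
    pyroglu_from_e: bool = True
    disulfide_variants: bool = True
    sulfation_on_y: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RuleConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ProcessingError(f"unknown rule keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass(frozen=True)
class CleavageSite:
    """A convertase site; ``position`` (1-based, on the proprotein) is the
    last basic residue of the motif and cleavage occurs C-terminal to it."""

    position: int
    motif: str  # KR, RR, RK, KK, mono_R, furin_RXXR
    confidence: str  # high, low, curated

    @property
    def strip_len(self) -> int:
        """How many residues at the C-terminal end of the motif are removed
        from the flanking segments (the whole dibasic pair; only the final
        Arg of a furin or monobasic site)."""
        return 2 if self.motif in DIBASIC_CONFIDENCE else 1


@dataclass(frozen=True)
class MaturePeptide:
    """A processed product. ``start``/``end`` are 1-based inclusive
    coordinates of the stored (trimmed) sequence on the preproprotein;
    an amidated peptide's Gly donor sits at ``end + 1``."""

    precursor_id: str
    start: int
    end: int
    sequence: str
    ptms: frozenset  # of masses.Ptm
    role: str  # bioactive_candidate | precursor_peptide
    name: str = ""

    def ptm_label(self) -> str:
        return "+".join(sorted(str(p) for p in self.ptms)) or "none"

    def key(self) -> tuple:
        return (self.precursor_id, self.start, self.end,
                frozenset(str(p) for p in self.ptms))


def _site_at(seq: str, p: int, rules: RuleConfig) -> Optional[CleavageSite]:
    """Evaluate the rule predicates at 1-based position ``p``; dibasic
    motifs win over monobasic/furin readings of the same position."""
    r = seq[p - 1]
    if r not in BASIC:
        return None
    if rules.proline_block and p < len(seq) and seq[p] == "P":
        return None
    if p >= 2:
        pair = seq[p - 2] + r
        if pair in DIBASIC_CONFIDENCE and getattr(rules, pair.lower()):
            return CleavageSite(p, pair, DIBASIC_CONFIDENCE[pair])
    if r == "R":
        if rules.furin_rxxr and p >= 4 and seq[p - 4] == "R":
            return CleavageSite(p, "furin_RXXR", "high")
        if rules.mono_r:
            context = any(
                p - off >= 1 and seq[p - off - 1] in BASIC
                for off in (4, 6, 8)
            )
            not_p_next = p == len(seq) or seq[p] != "P"
            if context and not_p_next:
                return CleavageSite(p, "mono_R", "low")
    return None


def predict_cleavage_sites(
    proprotein: str,
    rules: RuleConfig = RuleConfig(),
    overrides: Iterable[CurationOverride] = (),
) -> List[CleavageSite]:
    """Scan the post-signal-peptide sequence for convertase sites.

    Low-confidence motifs (KK, RK) appear only when enabled. Overrides are
    applied last: ``force_cleavage`` adds a curated site (must sit on K/R),
    ``suppress_cleavage`` removes whatever the rules proposed there.
    """
    if not proprotein:
        return []
    sites = {}
    for p in range(1, len(proprotein) + 1):
        site = _site_at(proprotein, p, rules)
        if site is not None:
            sites[p] = site
    for ov in overrides:
        if ov.action == "force_cleavage":
            if not 1 <= ov.position <= len(proprotein):
                raise ProcessingError(
                    f"override position {ov.position} outside proprotein")
            if proprotein[ov.position - 1] not in BASIC:
                raise ProcessingError(
                    f"force_cleavage at {ov.position}: residue "
                    f"{proprotein[ov.position - 1]!r} is not basic")
            motif = ov.payload or "mono_R"
            sites[ov.position] = CleavageSite(ov.position, motif, "curated")
        elif ov.action == "suppress_cleavage":
            if not 1 <= ov.position <= len(proprotein):
                raise ProcessingError(
                    f"override position {ov.position} outside proprotein")
            sites.pop(ov.position, None)
    return [sites[p] for p in sorted(sites)]


def _segments(proprotein: str, sites: Sequence[CleavageSite]):
    """Partition the proprotein into (start, end) segments (1-based,
    inclusive) and the set of motif residue positions.

    Every residue lands in exactly one segment or the motif set, for any
    rule configuration; overlapping motifs (e.g. KRR read as KR and RR)
    are resolved by clipping motif ranges at the previous cut point.
    """
    positions = [s.position for s in sites]
    if len(set(positions)) != len(positions):
        raise ProcessingError("duplicate cleavage sites")
    if sorted(positions) != positions:
        raise ProcessingError("sites must be sorted by position")
    n = len(proprotein)
    motif_positions = set()
    segments = []
    prev_cut = 0  # residues 1..prev_cut already consumed
    for site in sites:
        motif_start = max(prev_cut + 1, site.position - site.strip_len + 1)
        if motif_start > site.position:  # motif fully swallowed by overlap
            prev_cut = max(prev_cut, site.position)
            continue
        if motif_start > prev_cut + 1:
            segments.append((prev_cut + 1, motif_start - 1))
        motif_positions.update(range(motif_start, site.position + 1))
        prev_cut = site.position
    if prev_cut < n:
        segments.append((prev_cut + 1, n))
    return segments, motif_positions


def _peptides_from_segment(
    precursor_id: str,
    proprotein: str,
    seg: Tuple[int, int],
    rules: RuleConfig,
    curated_bioactive: bool,
    forced_ptms: Sequence[Ptm],
) -> List[MaturePeptide]:
    start, end = seg
    seq = proprotein[start - 1:end]
    base_ptms: List[Ptm] = list(forced_ptms)

    if rules.amidation and seq.endswith("G") and len(seq) > 1:
        seq = seq[:-1]
        end -= 1
        base_ptms.append(Ptm("amidation"))

    # Independent optional variant axes; each yields modified + unmodified.
    axes: List[List[Tuple[Ptm, ...]]] = []
    if seq[0] == "Q" and rules.pyroglu_from_q:
        axes.append([(), (Ptm("pyroglu_Q"),)])
    elif seq[0] == "E" and rules.pyroglu_from_e:
        axes.append([(), (Ptm("pyroglu_E"),)])
    n_cys = seq.count("C")
    if rules.disulfide_variants and n_cys >= 2 and n_cys % 2 == 0:
        cys = [i + 1 for i, aa in enumerate(seq) if aa == "C"]
        bridges = tuple(
            Ptm("disulfide", position=cys[k], partner=cys[k + 1])
            for k in range(0, n_cys, 2)
        )
        axes.append([(), bridges])
    if rules.sulfation_on_y and "Y" in seq:
        axes.append([(), (Ptm("sulfation", position=seq.index("Y") + 1),)])

    has_signal_ptm = any(p.kind == "amidation" for p in base_ptms)
    pyro_capable = bool(axes) and seq[0] in "QE" and (
        (seq[0] == "Q" and rules.pyroglu_from_q)
        or (seq[0] == "E" and rules.pyroglu_from_e))
    role = ("bioactive_candidate"
            if has_signal_ptm or pyro_capable or curated_bioactive
            else "precursor_peptide")

    peptides = []
    for combo in itertools.product(*axes) if axes else [()]:
        ptms = frozenset(base_ptms + [p for group in combo for p in group])
        peptides.append(MaturePeptide(
            precursor_id=precursor_id, start=start, end=end,
            sequence=seq, ptms=ptms, role=role))
    return peptides


def derive_mature_peptides(
    proprotein: str,
    sites: Sequence[CleavageSite],
    config: RuleConfig = RuleConfig(),
    precursor_id: str = "",
    overrides: Iterable[CurationOverride] = (),
    coordinate_offset: int = 0,
) -> List[MaturePeptide]:
    """Cut the proprotein at ``sites`` and emit mature peptide variants.

    ``coordinate_offset`` shifts reported coordinates onto the
    preproprotein (the signal-peptide length). ``set_role`` overrides with
    a position inside a segment force that segment bioactive (or back to
    precursor peptide, per payload); ``force_ptm`` overrides add a PTM
    ``kind[:position]`` to the segment containing the position.
    """
    segments, motif_positions = _segments(proprotein, sites)

    role_ov = {}
    ptm_ov = {}
    for ov in overrides:
        if ov.action == "set_role" and ov.position is not None:
            role_ov[ov.position] = ov.payload or "bioactive_candidate"
        elif ov.action == "force_ptm" and ov.position is not None:
            kind, _, pos = ov.payload.partition(":")
            ptm_ov.setdefault(ov.position, []).append(
                Ptm(kind, position=int(pos)) if pos else Ptm(kind))

    out: List[MaturePeptide] = []
    for seg in segments:
        curated = None
        forced: List[Ptm] = []
        for pos, payload in role_ov.items():
            if seg[0] <= pos <= seg[1]:
                curated = payload
        for pos, ptms in ptm_ov.items():
            if seg[0] <= pos <= seg[1]:
                forced.extend(ptms)
        peps = _peptides_from_segment(
            precursor_id, proprotein, seg, config,
            curated_bioactive=(curated == "bioactive_candidate"),
            forced_ptms=forced)
        if curated is not None:
            peps = [replace(p, role=curated) for p in peps]
        out.extend(peps)

    if coordinate_offset:
        out = [replace(p, start=p.start + coordinate_offset,
                       end=p.end + coordinate_offset) for p in out]
    out.sort(key=lambda p: (p.start, p.end, sorted(str(x) for x in p.ptms)))

    # name multi-copy products by their position order within the precursor
    counter = 0
    named = []
    seen_coords = None
    for p in out:
        if (p.start, p.end) != seen_coords:
            counter += 1
            seen_coords = (p.start, p.end)
        named.append(replace(p, name=f"{precursor_id or 'pep'}-{counter}"))
    return named


def process_precursor(
    record: PrecursorRecord,
    rules: RuleConfig = RuleConfig(),
    overrides: Iterable[CurationOverride] = (),
) -> List[MaturePeptide]:
    """Full processing of one precursor: slice off the annotated signal
    peptide, predict sites, derive products (coordinates reported on the
    preproprotein)."""
    ovs = [o for o in overrides if o.precursor_id == record.id]
    offset = record.proprotein_offset
    # override positions are given on the preproprotein; shift them
    shifted = []
    for o in ovs:
        if o.position is not None and o.action in (
                "force_cleavage", "suppress_cleavage", "set_role", "force_ptm"):
            shifted.append(replace_override(o, o.position - offset))
        else:
            shifted.append(o)
    sites = predict_cleavage_sites(
        record.proprotein, rules,
        [o for o in shifted if o.action in ("force_cleavage",
                                            "suppress_cleavage")])
    return derive_mature_peptides(
        record.proprotein, sites, rules, precursor_id=record.id,
        overrides=[o for o in shifted if o.action in ("set_role",
                                                      "force_ptm")],
        coordinate_offset=offset)


def replace_override(ov: CurationOverride, position: int) -> CurationOverride:
    return CurationOverride(precursor_id=ov.precursor_id, action=ov.action,
                            position=position, payload=ov.payload)


def peptides_to_frame(peptides: Sequence[MaturePeptide]):
    """TSV-ready table (precursor_id, name, start, end, sequence, ptms,
    role)."""
    import pandas as pd

    return pd.DataFrame({
        "precursor_id": [p.precursor_id for p in peptides],
        "name": [p.name for p in peptides],
        "start": [p.start for p in peptides],
        "end": [p.end for p in peptides],
        "sequence": [p.sequence for p in peptides],
        "ptms": [p.ptm_label() for p in peptides],
        "role": [p.role for p in peptides],
    })
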