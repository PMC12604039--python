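"""Monoisotopic and average mass arithmetic for peptides, PTMs, adducts and
b/y fragment series.

Masses follow the protonated-species convention m = M + cation mass; the
electron mass (< 0.001 Da) is neglected, well below every tolerance used in
matching. All matching is done on monoisotopic values; average masses are
carried for display only.

Post-translational modifications are applied as fixed mass deltas with an
elemental bookkeeping so that the neutral monoisotopic mass of any peptide
always equals the dot product of its elemental composition with the atomic
monoisotopic masses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "MassSpec",
    "IonSpec",
    "Ptm",
    "MassError",
    "PtmError",
    "peptide_mass",
    "ionize",
    "fragment_series",
    "composition_of",
    "PROTON",
    "CATION_MASSES",
    "WATER_MONO",
    "RESIDUE_MONO",
]


class MassError(ValueError):
    """Unknown residue, bad charge, or otherwise uncomputable mass."""


class PtmError(MassError):
    """A PTM placed on an incompatible residue or position."""


# Residue (amino-acid minus water) monoisotopic masses, Da.
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Residue average masses, Da (display only).
RESIDUE_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# Residue elemental formulas (amino acid minus water).
RESIDUE_COMP = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER_MONO = 18.010565
WATER_AVG = 18.01528
WATER_COMP = {"H": 2, "O": 1}

PROTON = 1.007276
CATION_MASSES = {"M+H": 1.007276, "M+Na": 22.989218, "M+K": 38.963158}

# PTM name -> (monoisotopic delta Da, average delta Da, elemental delta).
PTM_DELTAS = {
    # C-terminal -OH -> -NH2
    "amidation": (-0.98402, -0.9847, {"O": -1, "N": 1, "H": 1}),
    # N-terminal Gln cyclization, loss of NH3
    "pyroglu_Q": (-17.02655, -17.0305, {"N": -1, "H": -3}),
    # N-terminal Glu cyclization, loss of H2O
    "pyroglu_E": (-18.01056, -18.0153, {"O": -1, "H": -2}),
    # one Cys-Cys bridge, loss of 2 H
    "disulfide": (-2.01565, -2.0159, {"H": -2}),
    "sulfation": (79.95682, 80.063, {"S": 1, "O": 3}),
    "phosphorylation": (79.96633, 79.980, {"H": 1, "P": 1, "O": 3}),
    "oxidation": (15.99491, 15.999, {"O": 1}),
    "methylation": (14.01565, 14.027, {"C": 1, "H": 2}),
    "acetylation": (42.01057, 42.037, {"C": 2, "H": 2, "O": 1}),
}

# Residues a positional PTM may sit on (None = unconstrained).
_PTM_TARGETS = {
    "sulfation": set("Y"),
    "phosphorylation": set("STY"),
    "oxidation": set("MWCHF"),
    "methylation": None,
    "acetylation": set("K"),
}


@dataclass(frozen=True)
class Ptm:
    """One modification instance.

    ``position`` is 1-based on the mature peptide where applicable
    (``None`` for the terminus-defined amidation/pyroGlu, and for
    N-terminal acetylation).  ``partner`` is the second cysteine of a
    disulfide bridge.
    """

    kind: str
    position: Optional[int] = None
    partner: Optional[int] = None

    def __post_init__(self):
        if self.kind not in PTM_DELTAS:
            raise PtmError(f"unknown PTM kind {self.kind!r}")

    def __str__(self) -> str:
        if self.kind == "disulfide":
            return f"disulfide({self.position},{self.partner})"
        if self.position is not None:
            return f"{self.kind}({self.position})"
        return self.kind


@dataclass(frozen=True)
class MassSpec:
    """Neutral mass of a (possibly modified) peptide."""

    neutral_mono: float
    neutral_avg: float
    composition: tuple  # sorted (element, count) pairs

    def composition_dict(self) -> dict:
        return dict(self.composition)


@dataclass(frozen=True)
class IonSpec:
    """A singly or multiply charged cation of a parent peptide variant."""

    mz: float
    adduct: str
    charge: int
    parent_ref: str = ""
    variant: str = ""


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise MassError("empty peptide sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in RESIDUE_MONO:
            raise MassError(f"unknown residue {aa!r} at position {i}")


def _validate_ptms(sequence: str, ptms: Iterable[Ptm]) -> None:
    n = len(sequence)
    for ptm in ptms:
        if ptm.kind == "pyroglu_Q" and sequence[0] != "Q":
            raise PtmError("pyroglu_Q requires an N-terminal Q")
        if ptm.kind == "pyroglu_E" and sequence[0] != "E":
            raise PtmError("pyroglu_E requires an N-terminal E")
        if ptm.kind == "disulfide":
            i, j = ptm.position, ptm.partner
            if i is None or j is None or not (1 <= i < j <= n):
                raise PtmError(f"disulfide needs two positions with i < j, got {ptm}")
            if sequence[i - 1] != "C" or sequence[j - 1] != "C":
                raise PtmError(f"disulfide partners must both be C: {ptm}")
        elif ptm.position is not None:
            if not 1 <= ptm.position <= n:
                raise PtmError(f"{ptm} position outside peptide of length {n}")
            targets = _PTM_TARGETS.get(ptm.kind)
            if targets is not None and sequence[ptm.position - 1] not in targets:
                raise PtmError(
                    f"{ptm.kind} not allowed on residue "
                    f"{sequence[ptm.position - 1]!r} at {ptm.position}"
                )


def composition_of(sequence: str, ptms: Iterable[Ptm] = ()) -> dict:
    """Elemental composition of the neutral modified peptide."""
    _validate_sequence(sequence)
    comp: Counter = Counter(WATER_COMP)
    for aa in sequence:
        comp.update(RESIDUE_COMP[aa])
    for ptm in ptms:
        for el, k in PTM_DELTAS[ptm.kind][2].items():
            comp[el] += k
    return {el: k for el, k in comp.items() if k}


def peptide_mass(sequence: str, ptms: Iterable[Ptm] = ()) -> MassSpec:
    """Neutral mass of ``sequence`` with the given PTM set.

    mass = sum of residue masses + water + sum of PTM deltas.
    """
    ptms = tuple(ptms)
    _validate_sequence(sequence)
    _validate_ptms(sequence, ptms)
    mono = WATER_MONO + sum(RESIDUE_MONO[aa] for aa in sequence)
    avg = WATER_AVG + sum(RESIDUE_AVG[aa] for aa in sequence)
    for ptm in ptms:
        dm, da, _ = PTM_DELTAS[ptm.kind]
        mono += dm
        avg += da
    comp = composition_of(sequence, ptms)
    return MassSpec(mono, avg, tuple(sorted(comp.items())))


def ionize(mass: MassSpec, adduct: str = "M+H", charge: int = 1,
           parent_ref: str = "", variant: str = "") -> IonSpec:
    """Cationize a neutral peptide: m/z = (M + z * cation) / z.

    The MALDI path uses charge 1 only; Na/K adducts are not supported at
    higher charge states.
    """
    if adduct not in CATION_MASSES:
        raise MassError(f"unknown adduct {adduct!r}")
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    if charge > 1 and adduct != "M+H":
        raise MassError(f"{adduct} only supported singly charged")
    mz = (mass.neutral_mono + charge * CATION_MASSES[adduct]) / charge
    return IonSpec(mz=mz, adduct=adduct, charge=charge,
                   parent_ref=parent_ref, variant=variant)


def _positional_deltas(sequence: str, ptms: Sequence[Ptm]) -> list:
    """Map each PTM delta onto one residue position for fragment bookkeeping.

    Amidation sits on the C-terminal residue and pyroGlu on the N-terminal
    one, so they shift y- and b-series respectively. A disulfide bridge is
    attached to its later cysteine: a fragment carries the -2H only once it
    contains both partners (fragments spanning a single partner of an intact
    bridge are not meaningful ions and their masses are nominal).
    """
    n = len(sequence)
    deltas = [0.0] * n
    for ptm in ptms:
        dm = PTM_DELTAS[ptm.kind][0]
        if ptm.kind == "amidation":
            deltas[n - 1] += dm
        elif ptm.kind in ("pyroglu_Q", "pyroglu_E"):
            deltas[0] += dm
        elif ptm.kind == "disulfide":
            deltas[ptm.partner - 1] += dm
        elif ptm.position is not None:
            deltas[ptm.position - 1] += dm
        else:  # N-terminal acetylation etc.
            deltas[0] += dm
    return deltas


def fragment_series(sequence: str, ptms: Iterable[Ptm] = ()) -> list:
    """Full singly charged b and y series, PTM aware.

    Returns ``[(label, mz), ...]`` with labels b1..b(n-1) then y1..y(n-1).
    b_i = sum of the first i residue masses + proton;
    y_i = sum of the last i residue masses + water + proton.
    """
    ptms = tuple(ptms)
    _validate_sequence(sequence)
    _validate_ptms(sequence, ptms)
    n = len(sequence)
    if n < 2:
        raise MassError("fragment series needs length >= 2")
    deltas = _positional_deltas(sequence, ptms)
    res = [RESIDUE_MONO[aa] + d for aa, d in zip(sequence, deltas)]
    out = []
    acc = PROTON
    for i in range(n - 1):
        acc += res[i]
        out.append((f"b{i + 1}", acc))
    acc = WATER_MONO + PROTON
    for i in range(n - 1):
        acc += res[n - 1 - i]
        out.append((f"y{i + 1}", acc))
    return out


def il_ambiguous_positions(sequence: str) -> list:
    """1-based positions where I and L cannot be distinguished by mass."""
    return [i for i, aa in enumerate(sequence, start=1) if aa in "IL"]
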