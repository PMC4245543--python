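"""Theoretical target library for N-acyl homoserine lactones (AHLs).

AHLs are the canonical quorum-sensing autoinducers of Gram-negative
bacteria: a homoserine lactone ring amide-linked to an acyl chain of 4-18
carbons, optionally carrying a 3-oxo or 3-hydroxy substituent, and existing
either as the intact lactone ("closed") or its hydrolysed open-ring acid
(one water heavier).  This module builds elemental formulas, monoisotopic
masses, singly-charged positive adduct m/z values ([M+H]+, [M+Na]+,
[M+NH4]+ with optional 13C isotopologues) and the three diagnostic
homoserine-ring fragment ions used to recognise AHLs in tandem-MS data.

All m/z arithmetic subtracts one electron mass when forming a cation, which
reproduces the reference fragment masses (e.g. the homoserine ring cation
C4H8NO2+ at m/z 102.05495) to the fifth decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import InvalidTargetError, ValidationError

# Monoisotopic atomic masses (Da).
ATOMIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
}

ELECTRON_MASS = 0.00054858
#: Mass spacing of one 13C substitution (13C minus 12C), Da.
C13_DELTA = 1.0033548

#: Neutral mass added by each adduct before the electron correction.
ADDUCT_DELTA: Mapping[str, float] = {
    "[M+H]+": ATOMIC_MASS["H"],
    "[M+Na]+": ATOMIC_MASS["Na"],
    "[M+NH4]+": ATOMIC_MASS["N"] + 4 * ATOMIC_MASS["H"],
}

ADDUCT_KINDS: tuple[str, ...] = tuple(ADDUCT_DELTA)


class SubstClass(str, Enum):
    """Acyl-chain C3 substitution of an AHL."""

    UNSUBSTITUTED = "unsubstituted"
    OXO = "3-oxo"
    HYDROXY = "3-hydroxy"


class RingState(str, Enum):
    """Lactone ring state: intact ring or hydrolysed (ring + H2O)."""

    CLOSED = "closed"
    OPEN = "open"


_CLASS_PREFIX = {
    SubstClass.UNSUBSTITUTED: "",
    SubstClass.OXO: "O-",
    SubstClass.HYDROXY: "OH-",
}


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map restricted to C, H, N, O, Na."""

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in ATOMIC_MASS:
                raise ValidationError(f"unsupported element {el!r}")
            if n < 0:
                raise ValidationError(f"negative count for {el}")
            if n:
                clean[el] = int(n)
        if clean.get("C", 0) < 1:
            raise ValidationError("formula must contain at least one carbon")
        object.__setattr__(self, "counts", clean)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(ATOMIC_MASS[el] * n for el, n in self.counts.items())

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __str__(self) -> str:
        out = []
        for el in ("C", "H", "N", "O", "Na"):
            n = self.counts.get(el, 0)
            if n == 1:
                out.append(el)
            elif n > 1:
                out.append(f"{el}{n}")
        return "".join(out)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass (Da) of a neutral elemental formula."""
    m = formula.mass
    if m <= 0:
        raise ValidationError("formula mass must be positive")
    return m


def build_formula(
    subst: SubstClass | str, chain_length: int, ring_state: RingState | str = RingState.CLOSED
) -> ElementalFormula:
    """Elemental formula of an AHL target.

    Closed-ring formulas, with n = acyl chain carbons:
    unsubstituted C(n+4)H(2n+5)NO3, 3-oxo C(n+4)H(2n+3)NO4,
    3-hydroxy C(n+4)H(2n+5)NO4.  The open (hydrolysed) ring adds H2O.
    """
    subst = SubstClass(subst)
    ring_state = RingState(ring_state)
    if chain_length < 4:
        raise InvalidTargetError(
            f"acyl chain must have >= 4 carbons, got {chain_length}"
        )
    n = int(chain_length)
    if subst is SubstClass.UNSUBSTITUTED:
        counts = {"C": n + 4, "H": 2 * n + 5, "N": 1, "O": 3}
    elif subst is SubstClass.OXO:
        counts = {"C": n + 4, "H": 2 * n + 3, "N": 1, "O": 4}
    else:  # 3-hydroxy
        counts = {"C": n + 4, "H": 2 * n + 5, "N": 1, "O": 4}
    if ring_state is RingState.OPEN:
        counts["H"] += 2
        counts["O"] += 1
    return ElementalFormula(counts)


def adduct_mz(mass: float, kind: str, n_13c: int = 0) -> float:
    """m/z of a singly charged positive adduct of a neutral mass.

    mz = M + delta(kind) - electron mass + n_13c * 1.0033548.
    """
    if mass <= 0:
        raise ValidationError("neutral mass must be positive")
    if kind not in ADDUCT_DELTA:
        raise InvalidTargetError(f"unknown adduct kind {kind!r}")
    if n_13c < 0:
        raise ValidationError("n_13c must be >= 0")
    return mass + ADDUCT_DELTA[kind] - ELECTRON_MASS + n_13c * C13_DELTA


#: Elemental compositions of the diagnostic fragment cations.
_FRAGMENT_COMPOSITION = {
    # intact homoserine ring cation
    "ring": ElementalFormula({"C": 4, "H": 8, "N": 1, "O": 2}),
    # ring after further loss of CH2O2 (CO + H2O / HCOOH)
    "ring_loss": ElementalFormula({"C": 3, "H": 6, "N": 1}),
    # open (hydrolysed) homoserine ring cation
    "open_ring": ElementalFormula({"C": 4, "H": 10, "N": 1, "O": 3}),
}

DIAGNOSTIC_FRAGMENTS: tuple[str, ...] = tuple(_FRAGMENT_COMPOSITION)


def fragment_mz(name: str) -> float:
    """m/z of one of the three diagnostic homoserine-ring fragment cations.

    ring -> 102.05495 (C4H8NO2+), ring_loss -> 56.04948 (C3H6N+),
    open_ring -> 120.06552 (C4H10NO3+).
    """
    try:
        comp = _FRAGMENT_COMPOSITION[name]
    except KeyError:
        raise InvalidTargetError(f"unknown diagnostic fragment {name!r}") from None
    return comp.mass - ELECTRON_MASS


@dataclass(frozen=True)
class AdductIon:
    """One adduct (or 13C isotopologue) ion of an AHL species."""

    kind: str
    mz: float
    n_13c: int = 0
    charge: int = 1

    @property
    def label(self) -> str:
        if self.n_13c:
            return f"{self.kind} +{self.n_13c}x13C"
        return self.kind


@dataclass(frozen=True)
class AhlSpecies:
    """One theoretical AHL target (class, chain length, ring state)."""

    subst: SubstClass
    chain_length: int
    ring_state: RingState = RingState.CLOSED
    formula: ElementalFormula = field(default=None)  # type: ignore[assignment]
    monoisotopic_mass: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        f = build_formula(self.subst, self.chain_length, self.ring_state)
        if self.formula is None:
            object.__setattr__(self, "formula", f)
        elif self.formula != f:
            raise ValidationError(f"formula {self.formula} inconsistent for {self.name}")
        m = self.formula.mass
        if self.monoisotopic_mass is None:
            object.__setattr__(self, "monoisotopic_mass", m)
        elif abs(self.monoisotopic_mass - m) > 1e-6:
            raise ValidationError("monoisotopic mass inconsistent with formula")

    @property
    def name(self) -> str:
        """Conventional short name, e.g. C6, OH-C10, O-C12, OH-C6(open)."""
        base = f"{_CLASS_PREFIX[self.subst]}C{self.chain_length}"
        if self.ring_state is RingState.OPEN:
            base += "(open)"
        return base

    def adduct(self, kind: str, n_13c: int = 0) -> AdductIon:
        return AdductIon(kind=kind, n_13c=n_13c,
                         mz=adduct_mz(self.monoisotopic_mass, kind, n_13c))

    def adduct_ions(self, n_13c_max: int = 1) -> tuple[AdductIon, ...]:
        """All adduct ions, each with isotopologues 0..n_13c_max."""
        return tuple(
            self.adduct(kind, k)
            for kind in ADDUCT_KINDS
            for k in range(n_13c_max + 1)
        )


DEFAULT_CHAIN_LENGTHS: tuple[int, ...] = tuple(range(4, 15))


class TargetLibrary:
    """An ordered set of AHL species with precomputed adduct m/z values.

    The default configuration - three substitution classes crossed with
    acyl chain lengths 4-14, closed ring only - yields 33 target species.
    """

    def __init__(self, species: Sequence[AhlSpecies], n_13c_max: int = 1):
        if not species:
            raise ValidationError("library must contain at least one species")
        seen = set()
        for sp in species:
            key = (sp.subst, sp.chain_length, sp.ring_state)
            if key in seen:
                raise ValidationError(f"duplicate library entry {sp.name}")
            seen.add(key)
        self.species: tuple[AhlSpecies, ...] = tuple(species)
        self.n_13c_max = int(n_13c_max)
        self._ions: list[tuple[float, AhlSpecies, AdductIon]] = sorted(
            (ion.mz, sp, ion)
            for sp in self.species
            for ion in sp.adduct_ions(self.n_13c_max)
        )

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def get(self, name: str) -> AhlSpecies:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    @property
    def fragments(self) -> Mapping[str, float]:
        """The three diagnostic fragment m/z values."""
        return {name: fragment_mz(name) for name in DIAGNOSTIC_FRAGMENTS}

    def lookup(self, observed_mz: float, tol: float = 0.01,
               kinds: Iterable[str] | None = None,
               n_13c_max: int | None = None):
        """All (species, ion) whose adduct m/z lies within ``tol`` of
        ``observed_mz``.  ``kinds`` restricts the adduct kinds searched."""
        kinds = set(kinds) if kinds is not None else set(ADDUCT_KINDS)
        cap = self.n_13c_max if n_13c_max is None else n_13c_max
        hits = []
        for mz, sp, ion in self._ions:
            if abs(mz - observed_mz) <= tol and ion.kind in kinds and ion.n_13c <= cap:
                hits.append((sp, ion))
        return hits

    # -- serialisation ----------------------------------------------------

    _COLUMNS = ("class", "chain_length", "ring_state", "formula", "M",
                "mz_MH", "mz_MNa", "mz_MNH4")

    def to_records(self) -> list[dict]:
        recs = []
        for sp in self.species:
            recs.append({
                "class": sp.subst.value,
                "chain_length": sp.chain_length,
                "ring_state": sp.ring_state.value,
                "formula": str(sp.formula),
                "M": round(sp.monoisotopic_mass, 6),
                "mz_MH": round(sp.adduct("[M+H]+").mz, 5),
                "mz_MNa": round(sp.adduct("[M+Na]+").mz, 5),
                "mz_MNH4": round(sp.adduct("[M+NH4]+").mz, 5),
            })
        return recs

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self._COLUMNS) + "\n")
            for rec in self.to_records():
                fh.write("\t".join(str(rec[c]) for c in self._COLUMNS) + "\n")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=1)

    @classmethod
    def from_records(cls, records: Iterable[Mapping], n_13c_max: int = 1) -> "TargetLibrary":
        species = [
            AhlSpecies(SubstClass(r["class"]), int(r["chain_length"]),
                       RingState(r["ring_state"]))
            for r in records
        ]
        return cls(species, n_13c_max=n_13c_max)

    @classmethod
    def from_tsv(cls, path, n_13c_max: int = 1) -> "TargetLibrary":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            records = [dict(zip(header, line.rstrip("\n").split("\t")))
                       for line in fh if line.strip()]
        return cls.from_records(records, n_13c_max=n_13c_max)

    @classmethod
    def from_json(cls, path, n_13c_max: int = 1) -> "TargetLibrary":
        with open(path) as fh:
            return cls.from_records(json.load(fh), n_13c_max=n_13c_max)


def build_library(
    classes: Iterable[SubstClass | str] = tuple(SubstClass),
    chain_lengths: Iterable[int] = DEFAULT_CHAIN_LENGTHS,
    include_open: bool = False,
    n_13c_max: int = 1,
) -> TargetLibrary:
    """Build the AHL target library.

    Defaults cover the 33 closed-ring targets (3 classes x chains 4-14);
    ``include_open`` appends an open-ring counterpart for every species.
    """
    classes = [SubstClass(c) for c in classes]
    chain_lengths = sorted(set(int(n) for n in chain_lengths))
    if not classes or not chain_lengths:
        raise InvalidTargetError("library configuration is empty")
    species = [
        AhlSpecies(c, n, RingState.CLOSED)
        for c in classes
        for n in chain_lengths
    ]
    if include_open:
        species += [
            AhlSpecies(c, n, RingState.OPEN)
            for c in classes
            for n in chain_lengths
        ]
    return TargetLibrary(species, n_13c_max=n_13c_max)
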