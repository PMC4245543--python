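"""MS/MS mining for known and unexpected AHLs.

Every AHL that retains the homoserine ring produces up to three diagnostic
fragment cations under collision-induced dissociation: m/z 102.05495
(homoserine ring), 56.04948 (ring after CH2O2 loss) and 120.06552 (open
homoserine ring).  Scanning all MS2 spectra of a run for these ions -
flagging scans where at least two of the three are present as candidates -
is the in-silico counterpart of precursor-ion scanning, and finds AHLs
that are not in the target library at all.

Candidate precursors are attributed to library species through their
[M+H]+ / [M+NH4]+ m/z; unmatched candidates are reported with the
acyl-side complement mass (precursor minus ring fragment) for manual
formula reasoning, optionally supported by an exhaustive CHNO composition
search.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .masslib import (ATOMIC_MASS, DIAGNOSTIC_FRAGMENTS, ELECTRON_MASS,
                      AhlSpecies, RingState, TargetLibrary, fragment_mz)
from .spectra import Run, Spectrum

logger = logging.getLogger(__name__)


@dataclass
class FragmentHit:
    """One MS2 spectrum containing >= 1 diagnostic homoserine-ring ion."""

    spectrum_index: int
    rt: float
    precursor_mz: float
    collision_energy: float | None
    ions: Mapping[str, float]  # diagnostic ion name -> summed intensity

    def __post_init__(self):
        if not self.ions:
            raise ValidationError("FragmentHit requires at least one diagnostic ion")

    @property
    def candidate(self) -> bool:
        """True iff at least 2 of the 3 diagnostic ions are present."""
        return len(self.ions) >= 2


@dataclass
class AhlAttribution:
    """Interpretation of one candidate FragmentHit."""

    hit: FragmentHit
    species: AhlSpecies | None          # matched library species, if any
    adduct_kind: str | None             # which adduct matched the precursor
    ring_interpretation: RingState      # closed, or open when m/z 120 dominates
    complement_mass: float              # precursor_mz - ring fragment m/z

    @property
    def unexpected(self) -> bool:
        return self.species is None


def scan_diagnostic(run: Run, tol: float = 0.01) -> list[FragmentHit]:
    """One FragmentHit per MS2 spectrum containing >= 1 diagnostic ion
    within ``tol``; the candidate flag marks the >=2-of-3 rule."""
    if tol <= 0:
        raise ValidationError("tol must be positive")
    ms2 = [(i, s) for i, s in enumerate(run.spectra) if s.ms_level == 2]
    if not ms2:
        logger.warning("run %s has no MS2 spectra to mine", run.label or "<unnamed>")
        return []
    targets = {name: fragment_mz(name) for name in DIAGNOSTIC_FRAGMENTS}
    hits = []
    for idx, s in ms2:
        present = {}
        for name, mz in targets.items():
            lo, hi = np.searchsorted(s.mz, (mz - tol, mz + tol + 1e-12))
            if hi > lo:
                present[name] = float(s.intensity[lo:hi].sum())
        if present:
            hits.append(FragmentHit(
                spectrum_index=idx, rt=s.rt, precursor_mz=s.precursor_mz,
                collision_energy=s.collision_energy, ions=present))
    return hits


def attribute_precursors(
    hits: Sequence[FragmentHit],
    library: TargetLibrary,
    tol: float = 0.01,
    candidates_only: bool = True,
) -> list[AhlAttribution]:
    """Match candidate hits to library [M+H]+ / [M+NH4]+ precursors.

    The sodium adduct is excluded: it does not survive CID and is never
    auto-selected into useful MS2 spectra.  Unmatched candidates come back
    flagged unexpected, carrying the acyl-side complement mass.
    """
    if not hits:
        raise ValidationError("no fragment hits to attribute")
    ring = fragment_mz("ring")
    out = []
    for hit in hits:
        if candidates_only and not hit.candidate:
            continue
        matches = library.lookup(hit.precursor_mz, tol=tol,
                                 kinds=("[M+H]+", "[M+NH4]+"), n_13c_max=0)
        species = adduct = None
        if matches:
            # closest adduct m/z wins; ties resolved by species name
            sp, ion = min(matches, key=lambda m: (abs(m[1].mz - hit.precursor_mz),
                                                  m[0].name))
            species, adduct = sp, ion.kind
        open_dominant = (
            "open_ring" in hit.ions
            and hit.ions["open_ring"] >= max(hit.ions.values()) - 1e-12
        )
        ring_state = RingState.OPEN if open_dominant else RingState.CLOSED
        if species is not None:
            ring_state = species.ring_state
        out.append(AhlAttribution(
            hit=hit, species=species, adduct_kind=adduct,
            ring_interpretation=ring_state,
            complement_mass=hit.precursor_mz - ring,
        ))
    return out


def match_spectrum(observed: Spectrum, reference: Spectrum, tol: float = 0.01) -> float:
    """Cosine similarity of two MS2 spectra with greedy m/z alignment.

    Peak pairs are matched greedily by ascending m/z difference within
    ``tol``; unmatched peaks contribute only to the norms.  Symmetric,
    1.0 for identical spectra, 0.0 for disjoint ones.
    """
    if observed.ms_level != 2 or reference.ms_level != 2:
        raise ValidationError("spectral matching requires two MS2 spectra")
    if (observed.collision_energy is not None
            and reference.collision_energy is not None
            and observed.collision_energy != reference.collision_energy):
        raise ValidationError("collision energies differ")
    if len(observed) == 0 or len(reference) == 0:
        logger.warning("empty spectrum in match_spectrum; score 0")
        return 0.0
    pairs = sorted(
        (abs(mo - mr), i, j)
        for i, mo in enumerate(observed.mz)
        for j, mr in enumerate(reference.mz)
        if abs(mo - mr) <= tol
    )
    used_o: set[int] = set()
    used_r: set[int] = set()
    dot = 0.0
    for _, i, j in pairs:
        if i in used_o or j in used_r:
            continue
        used_o.add(i)
        used_r.add(j)
        dot += observed.intensity[i] * reference.intensity[j]
    norm = (np.linalg.norm(observed.intensity) * np.linalg.norm(reference.intensity))
    return float(dot / norm) if norm > 0 else 0.0


# ---------------------------------------------------------------------------
# formula reasoning for unexpected AHLs
# ---------------------------------------------------------------------------

def _rdbe(c: int, h: int, n: int) -> float:
    """Ring-plus-double-bond equivalents of a CcHhNnOo cation/neutral."""
    return c - h / 2 + n / 2 + 1


def enumerate_formulas(
    target_mz: float,
    tol: float = 0.005,
    max_counts: Mapping[str, int] | None = None,
    charged: bool = True,
) -> list[tuple[str, float, float]]:
    """Exhaustive CHNO compositions for an observed m/z.

    Searches up to C12H24N2O6 by default, keeps RDBE >= 0, and returns
    (formula string, exact m/z, error) sorted by |error|.  Intended for the
    acyl-side complement of unexpected homoserine-ring candidates.
    """
    limits = {"C": 12, "H": 24, "N": 2, "O": 6}
    if max_counts:
        limits.update(max_counts)
    e_corr = ELECTRON_MASS if charged else 0.0
    out = []
    for c in range(1, limits["C"] + 1):
        for n in range(limits["N"] + 1):
            for o in range(limits["O"] + 1):
                base = c * ATOMIC_MASS["C"] + n * ATOMIC_MASS["N"] + o * ATOMIC_MASS["O"]
                for h in range(limits["H"] + 1):
                    mz = base + h * ATOMIC_MASS["H"] - e_corr
                    err = mz - target_mz
                    if abs(err) <= tol and _rdbe(c, h - (1 if charged else 0), n) >= 0:
                        parts = [f"C{c}" if c > 1 else "C"]
                        if h:
                            parts.append(f"H{h}" if h > 1 else "H")
                        if n:
                            parts.append(f"N{n}" if n > 1 else "N")
                        if o:
                            parts.append(f"O{o}" if o > 1 else "O")
                        out.append(("".join(parts), mz, err))
    out.sort(key=lambda t: (abs(t[2]), t[0]))
    return out


def hits_to_tsv(hits: Sequence[FragmentHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("spectrum_index\trt\tprecursor_mz\tce\tcandidate\t"
                 + "\t".join(DIAGNOSTIC_FRAGMENTS) + "\n")
        for h in hits:
            ce = "" if h.collision_energy is None else f"{h.collision_energy:g}"
            ions = "\t".join(f"{h.ions.get(n, 0.0):.6g}" for n in DIAGNOSTIC_FRAGMENTS)
            fh.write(f"{h.spectrum_index}\t{h.rt:.4f}\t{h.precursor_mz:.5f}\t"
                     f"{ce}\t{int(h.candidate)}\t{ions}\n")


def attributions_to_tsv(attributions: Sequence[AhlAttribution], path,
                        with_formulas: bool = False) -> None:
    """Export attributions; unexpected candidates carry complement masses
    and (optionally) enumerated complement formulas."""
    with open(path, "w") as fh:
        fh.write("rt\tprecursor_mz\tspecies\tadduct\tring\tcomplement_mass"
                 + ("\tcandidate_formulas" if with_formulas else "") + "\n")
        for a in attributions:
            name = a.species.name if a.species else "unexpected"
            adduct = a.adduct_kind or ""
            row = (f"{a.hit.rt:.4f}\t{a.hit.precursor_mz:.5f}\t{name}\t{adduct}\t"
                   f"{a.ring_interpretation.value}\t{a.complement_mass:.5f}")
            if with_formulas:
                formulas = ""
                if a.unexpected:
                    cands = enumerate_formulas(a.complement_mass, tol=0.005,
                                               charged=False)
                    formulas = ";".join(f for f, _, _ in cands[:5])
                row += f"\t{formulas}"
            fh.write(row + "\n")
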