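"""Synthetic LC-MS/MS runs, dilution series and sequence alignments.

The run generator emulates the features of a QTOF acquisition that the
screening and mining code depends on: Gaussian chromatographic elution of
pseudomolecular adduct ions with tune-mode-dependent adduct ratios
(standard tune favours [M+Na]+, small-molecule tune favours [M+H]+),
one-13C isotope satellites at natural abundance, folded-Gaussian baseline
noise both inside every library extraction window and at random m/z, and
top-3 data-dependent MS/MS acquisition restricted to m/z 170-460 with a
0.04-min dynamic-exclusion window.  AHL precursors yield the diagnostic
homoserine-ring fragments; decoy compounds yield unrelated fragments.

It deliberately does not model detector resolution curves, peak tailing,
in-source fragmentation or matrix suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from . import masslib
from .masslib import AhlSpecies, RingState, SubstClass, fragment_mz
from .phylo import Alignment, Tree
from .profiles import (DetectionMatrix, StrainRecord, load_detection_matrix,
                       load_strains)
from .spectra import Run, Spectrum

#: default adduct apex ratios per tune mode (H : Na : NH4); the orderings
#: (Na-dominant under standard tune, H-dominant under small-molecule tune)
#: follow the instrument behaviour the screen is designed around, the
#: magnitudes are a modelling choice.
ADDUCT_RATIOS: Mapping[str, Mapping[str, float]] = {
    "standard": {"[M+H]+": 0.2, "[M+Na]+": 0.7, "[M+NH4]+": 0.1},
    "small_molecule": {"[M+H]+": 0.7, "[M+Na]+": 0.2, "[M+NH4]+": 0.1},
}

#: relative MS2 fragment yields (fraction of precursor intensity)
_FRAG_CLOSED = {"ring": 1.0, "ring_loss": 0.6, "open_ring": 0.2}
_FRAG_OPEN = {"open_ring": 1.0, "ring": 0.6, "ring_loss": 0.4}
_RING_NEUTRAL_MASS = 101.047679  # C4H7NO2, homoserine lactone neutral loss

DDA_MZ_RANGE = (170.0, 460.0)
DDA_TOP_N = 3
DDA_EXCLUSION_MIN = 0.04
DDA_COLLISION_ENERGIES = (10.0, 20.0)


@dataclass(frozen=True)
class PlantedAhl:
    """One AHL planted into a synthetic run."""

    species: AhlSpecies
    rt_center: float
    abundance: float                 # summed apex height over all adducts, counts
    adduct_ratios: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: ADDUCT_RATIOS)
    include_13c: bool = True

    def __post_init__(self):
        if self.abundance <= 0:
            raise ValidationError("abundance must be positive")
        for mode, ratios in self.adduct_ratios.items():
            if abs(sum(ratios.values()) - 1.0) > 1e-9:
                raise ValidationError(f"adduct ratios for {mode!r} must sum to 1")


@dataclass(frozen=True)
class DecoyCompound:
    """A non-AHL compound: visible in MS1, fragments carry no homoserine
    ring ions."""

    mz: float
    rt_center: float
    abundance: float
    fragments: tuple[float, ...] = ()

    def resolved_fragments(self) -> tuple[float, ...]:
        frags = self.fragments or (self.mz - 18.010565, self.mz - 46.005479, 91.05423)
        diag = [fragment_mz(n) for n in masslib.DIAGNOSTIC_FRAGMENTS]
        for f in frags:
            if any(abs(f - d) <= 0.02 for d in diag):
                raise ValidationError(
                    f"decoy fragment {f:.5f} collides with a diagnostic ion")
        return tuple(f for f in frags if f > 0)


@dataclass(frozen=True)
class RunSpec:
    """Full description of one synthetic acquisition."""

    planted: tuple[PlantedAhl, ...] = ()
    decoys: tuple[DecoyCompound, ...] = ()
    gradient_length: float = 6.0       # min
    scan_period: float = 0.004         # min per acquired spectrum (MS1 or MS2)
    peak_sigma: float = 0.05           # chromatographic sd, min
    noise_sd: float = 10.0             # baseline noise sd, counts
    mz_sigma: float = 0.002            # mass-measurement jitter, Da
    tune_mode: str = "standard"
    n_random_noise: int = 100          # random-m/z noise centroids per MS1 scan
    mz_range: tuple[float, float] = (50.0, 500.0)
    dda_min_intensity: float | None = None   # default 5 x noise_sd
    noise_channels: tuple[float, ...] | None = None  # default: library windows
    label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.tune_mode not in ADDUCT_RATIOS:
            raise ValidationError(f"unknown tune mode {self.tune_mode!r}")
        for name in ("gradient_length", "scan_period", "peak_sigma", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _default_noise_channels() -> tuple[float, ...]:
    """m/z channels given a baseline noise floor: every adduct ion (plus
    one-13C satellite) of the default 33-species library."""
    lib = masslib.build_library()
    return tuple(sorted(ion.mz for sp in lib for ion in sp.adduct_ions(1)))


def generate_run(spec: RunSpec) -> Run:
    """Simulate one centroided LC-MS/MS run from a :class:`RunSpec`.

    Deterministic for a fixed spec (including its seed): the same spec
    produces byte-identical mzML output.
    """
    rng = np.random.default_rng(spec.seed)
    channels = (np.asarray(spec.noise_channels) if spec.noise_channels is not None
                else np.asarray(_default_noise_channels()))
    dda_floor = (5.0 * spec.noise_sd if spec.dda_min_intensity is None
                 else spec.dda_min_intensity)

    # planted ion table: (mz, apex_height, rt_center, sigma, kind, planted_idx)
    ion_rows = []
    for pi, p in enumerate(spec.planted):
        ratios = p.adduct_ratios[spec.tune_mode]
        n_carbon = p.species.formula.counts.get("C", 0)
        for kind, frac in ratios.items():
            if frac <= 0:
                continue
            apex = p.abundance * frac
            ion_rows.append((p.species.adduct(kind).mz, apex, p, kind, pi))
            if p.include_13c:
                ion_rows.append((p.species.adduct(kind, 1).mz,
                                 apex * 0.011 * n_carbon, p, kind, pi))
    for di, dec in enumerate(spec.decoys):
        dec.resolved_fragments()  # validate early
        ion_rows.append((dec.mz, dec.abundance, dec, None, -1 - di))

    spectra: list[Spectrum] = []
    exclusion: list[tuple[float, float]] = []  # (mz, rt when selected)
    t = 0.0
    while t < spec.gradient_length:
        # ---- MS1 scan -------------------------------------------------
        mzs, intens, origin = [], [], []
        for mz0, apex, compound, kind, tag in ion_rows:
            rt_c = compound.rt_center
            sigma = spec.peak_sigma
            h = apex * math.exp(-0.5 * ((t - rt_c) / sigma) ** 2)
            if h < 1e-3:
                continue
            mzs.append(mz0 + rng.normal(0.0, spec.mz_sigma))
            intens.append(h)
            origin.append((tag, kind))
        # baseline noise inside every library extraction window
        ch_noise = np.abs(rng.normal(0.0, spec.noise_sd, size=len(channels)))
        ch_mz = channels + rng.uniform(-0.008, 0.008, size=len(channels))
        mzs.extend(ch_mz)
        intens.extend(ch_noise)
        origin.extend([(None, None)] * len(channels))
        # random-m/z noise
        r_mz = rng.uniform(*spec.mz_range, size=spec.n_random_noise)
        r_int = np.abs(rng.normal(0.0, spec.noise_sd, size=spec.n_random_noise))
        mzs.extend(r_mz)
        intens.extend(r_int)
        origin.extend([(None, None)] * spec.n_random_noise)

        mzs = np.asarray(mzs)
        intens = np.asarray(intens)
        spectra.append(Spectrum(ms_level=1, rt=round(t, 6), mz=mzs.copy(),
                                intensity=intens.copy()))
        t += spec.scan_period

        # ---- DDA: pick top-3 precursors from this MS1 scan -------------
        exclusion = [(m, t0) for m, t0 in exclusion if t - t0 <= DDA_EXCLUSION_MIN]
        eligible = [
            i for i in range(len(mzs))
            if DDA_MZ_RANGE[0] <= mzs[i] <= DDA_MZ_RANGE[1]
            and intens[i] >= dda_floor
            and not any(abs(mzs[i] - m) <= 0.01 for m, _ in exclusion)
        ]
        eligible.sort(key=lambda i: (-intens[i], mzs[i]))
        for i in eligible[:DDA_TOP_N]:
            prec_mz = float(mzs[i])
            exclusion.append((prec_mz, t))
            tag, kind = origin[i]
            for ce in DDA_COLLISION_ENERGIES:
                f_mz, f_int = _fragment_spectrum(
                    tag, kind, prec_mz, float(intens[i]), spec, rng, ce)
                spectra.append(Spectrum(
                    ms_level=2, rt=round(t, 6), mz=f_mz, intensity=f_int,
                    precursor_mz=prec_mz, collision_energy=ce))
                t += spec.scan_period

    return Run(spectra=spectra, tune_mode=spec.tune_mode, label=spec.label)


def _fragment_spectrum(tag, kind, prec_mz, prec_int, spec, rng, ce):
    """Product-ion spectrum for one selected precursor."""
    yield_scale = 1.0 if ce <= 10 else 0.8  # harsher CE loses a little signal
    mzs: list[float] = []
    ints: list[float] = []
    if tag is not None and tag >= 0 and kind in ("[M+H]+", "[M+NH4]+"):
        planted = spec.planted[tag]
        table = (_FRAG_OPEN if planted.species.ring_state is RingState.OPEN
                 else _FRAG_CLOSED)
        for name, rel in table.items():
            mzs.append(fragment_mz(name) + rng.normal(0.0, spec.mz_sigma))
            ints.append(prec_int * rel * yield_scale)
        # acyl-side fragment: neutral loss of the homoserine lactone ring
        mzs.append(prec_mz - _RING_NEUTRAL_MASS + rng.normal(0.0, spec.mz_sigma))
        ints.append(prec_int * 0.3 * yield_scale)
        mzs.append(prec_mz + rng.normal(0.0, spec.mz_sigma))
        ints.append(prec_int * 0.1)
    elif tag is not None and tag < 0:
        decoy = spec.decoys[-1 - tag]
        for f in decoy.resolved_fragments():
            mzs.append(f + rng.normal(0.0, spec.mz_sigma))
            ints.append(prec_int * 0.5 * yield_scale)
        mzs.append(prec_mz + rng.normal(0.0, spec.mz_sigma))
        ints.append(prec_int * 0.2)
    else:
        # sodium adducts and noise precursors do not fragment usefully
        mzs.append(prec_mz + rng.normal(0.0, spec.mz_sigma))
        ints.append(prec_int * 0.8)
    # a little fragment-level noise, kept away from the diagnostic windows
    diag = [fragment_mz(n) for n in masslib.DIAGNOSTIC_FRAGMENTS]
    for _ in range(3):
        m = float(rng.uniform(50.0, max(60.0, prec_mz)))
        if any(abs(m - d) <= 0.03 for d in diag):
            m += 0.1
        mzs.append(m)
        ints.append(float(np.abs(rng.normal(0.0, spec.noise_sd))))
    return np.asarray(mzs), np.asarray(ints)


def generate_dilution_series(
    spec: RunSpec, concentrations: Sequence[float],
) -> list[tuple[float, Run]]:
    """Scale planted abundances linearly with concentration.

    All runs share the spec's seed, so the baseline noise realisation is
    identical across levels and only the signal scales.
    """
    if any(c <= 0 for c in concentrations):
        raise ValidationError("concentrations must be positive")
    out = []
    for conc in concentrations:
        planted = tuple(replace(p, abundance=p.abundance * conc)
                        for p in spec.planted)
        out.append((conc, generate_run(replace(spec, planted=planted))))
    return out


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_jc_alignment(tree: Tree, n_sites: int, seed: int = 0) -> Alignment:
    """Evolve an alignment on a tree under the one-parameter (equal-rates)
    nucleotide substitution model.

    Sites are i.i.d.; along a branch of length t (expected substitutions
    per site) a base stays itself with probability 1/4 + 3/4 exp(-4t/3),
    otherwise it becomes one of the other three uniformly.
    """
    if n_sites <= 0:
        raise ValidationError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    root_state = rng.integers(0, 4, size=n_sites)
    seqs: dict[str, np.ndarray] = {}

    def descend(node, state):
        for child in node.children:
            t = max(child.length or 0.0, 0.0)
            p_same = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
            stay = rng.random(n_sites) < p_same
            shift = rng.integers(1, 4, size=n_sites)
            child_state = np.where(stay, state, (state + shift) % 4)
            if child.is_leaf():
                seqs[child.label] = child_state
            else:
                descend(child, child_state)

    if tree.root.is_leaf():
        seqs[tree.root.label] = root_state
    descend(tree.root, root_state)
    return Alignment([(name, "".join(_BASES[s]))
                      for name, s in sorted(seqs.items())])


def load_survey_fixture() -> tuple[list[StrainRecord], DetectionMatrix]:
    """The packaged survey fixture: 32 AHL-positive strains plus the
    reference strain, and their strain x AHL detection matrix."""
    strains = load_strains()
    matrix = load_detection_matrix(strains)
    return strains, matrix
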