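"""Full-scan screening of LC-HRMS runs against the AHL target library.

For every library species the pseudomolecular ions [M+H]+, [M+Na]+ and
[M+NH4]+ (plus their one-13C isotopologues as qualifier ions) are
extracted with a narrow absolute m/z window, chromatographic peaks are
picked with a signal-to-noise cut-off (default s/n >= 10; peaks below it
are not integrated), and co-eluting ion evidence is merged into one
:class:`Detection` per species per elution group.

Identification confidence follows the two-tier convention of the source
screen: tier "b" when at least two distinct co-eluting ions support the
species (adducts and/or 13C qualifiers), tier "c" when a single ion does
and that ion is [M+H]+ or [M+Na]+.  A lone [M+NH4]+ or lone 13C satellite
is kept as sub-threshold evidence, never as an identification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .masslib import ADDUCT_KINDS, AhlSpecies, TargetLibrary
from .spectra import Eic, Run, extract_eic

logger = logging.getLogger(__name__)

TIER_MULTI_ION = "b"
TIER_SINGLE_ION = "c"

#: adduct kinds that may carry a single-ion (tier c) identification
_SINGLE_ION_KINDS = ("[M+H]+", "[M+Na]+")


@dataclass
class ScreenConfig:
    """Tunable parameters of the full-scan screen."""

    mz_tol: float = 0.01          # extraction window half-width, Da
    snr_min: float = 10.0         # integration cut-off, s/n
    rt_group_tol: float = 0.02    # co-elution window for ion grouping, min
    rt_ref_tol: float = 0.02      # rt-identity window vs reference standards, min
    n_13c_max: int = 1            # isotopologue qualifiers considered
    count_13c_for_tier: bool = True

    def __post_init__(self):
        for name in ("mz_tol", "snr_min", "rt_group_tol", "rt_ref_tol"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class ChromPeak:
    """One integrated chromatographic peak of one extracted ion."""

    rt_apex: float
    height: float
    area: float
    snr: float

    def __post_init__(self):
        if self.height <= 0 or self.area <= 0 or self.snr < 0:
            raise ValidationError("peak height/area must be > 0 and snr >= 0")


@dataclass
class Detection:
    """One AHL identified in one run, with its per-ion peak evidence."""

    species: AhlSpecies
    ions: Mapping[str, ChromPeak]   # ion label -> peak
    rt_apex: float
    tier: str                       # "b" | "c"
    run_label: str = ""

    @property
    def area(self) -> float:
        """Total integrated area over all supporting ions."""
        return sum(p.area for p in self.ions.values())


@dataclass
class SubThresholdEvidence:
    """Single-ion evidence too weak for a tier assignment (e.g. a lone
    [M+NH4]+ peak)."""

    species: AhlSpecies
    ion: str
    peak: ChromPeak
    run_label: str = ""


@dataclass
class ScreenResult:
    detections: list[Detection] = field(default_factory=list)
    subthreshold: list[SubThresholdEvidence] = field(default_factory=list)


def _mad_noise(values: np.ndarray) -> float:
    """Robust noise level: 1.4826 x median absolute deviation."""
    if len(values) == 0:
        return 0.0
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict-then-flat local maxima (plateau start wins)."""
    idx = []
    n = len(y)
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[j]:
                j += 1
            if j < n - 1 and y[j + 1] < y[j]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return idx


def _peak_bounds(y: np.ndarray, apex: int) -> tuple[int, int]:
    """Walk outward from the apex to the surrounding local minima."""
    left = apex
    while left > 0 and y[left - 1] <= y[left]:
        left -= 1
    right = apex
    while right < len(y) - 1 and y[right + 1] <= y[right]:
        right += 1
    return left, right


def _regions(above: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) inclusive index pairs."""
    out = []
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return out
    start = prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            out.append((start, prev))
            start = i
        prev = i
    out.append((start, prev))
    return out


def detect_peaks(eic: Eic, snr_min: float = 10.0,
                 min_width: int = 3) -> list[ChromPeak]:
    """Pick chromatographic peaks from an EIC.

    Noise is estimated as 1.4826 x MAD of the trace in two passes: a first
    pass flags candidate peak regions, which are excluded before the noise
    is re-estimated, so large peaks do not inflate their own noise floor.
    A peak is a contiguous region whose core exceeds ``snr_min`` x noise,
    extended by hysteresis down to half that threshold so one noisy
    chromatographic peak is reported once, not once per flank wiggle.
    Height is the region apex, area the trapezoid integral between the
    local minima flanking the region; peaks with s/n below ``snr_min`` are
    not integrated, and regions narrower than ``min_width`` scans are
    treated as electronic spikes, not chromatography.
    """
    if snr_min <= 0:
        raise ValidationError("snr_min must be positive")
    y = eic.intensity
    rt = eic.rt
    if len(y) < 5:
        logger.warning("EIC with %d points is too short for peak detection", len(y))
        return []

    noise0 = _mad_noise(y)
    # pass 1: mask candidate peak regions against the naive noise estimate
    thr0 = snr_min * noise0
    mask = np.zeros(len(y), dtype=bool)
    for rlo, rhi in _regions(y > thr0 if noise0 > 0 else y > 0):
        apex = rlo + int(np.argmax(y[rlo:rhi + 1]))
        blo, bhi = _peak_bounds(y, apex)
        mask[min(blo, rlo):max(bhi, rhi) + 1] = True
    baseline = y[~mask]
    noise = _mad_noise(baseline) if len(baseline) >= 5 else noise0

    if noise > 0:
        core = y >= snr_min * noise
        keep = y >= 0.5 * snr_min * noise
    else:
        core = y > 0
        keep = y > 0
    # grow every core region outward through the hysteresis band
    keep_regions = _regions(keep)
    peaks = []
    for klo, khi in keep_regions:
        if not core[klo:khi + 1].any():
            continue
        if khi - klo + 1 < min_width:
            continue
        apex = klo + int(np.argmax(y[klo:khi + 1]))
        height = float(y[apex])
        blo, bhi = _peak_bounds(y, apex)
        lo, hi = min(blo, klo), max(bhi, khi)
        if hi - lo < 1:
            continue
        if height <= max(float(y[lo]), float(y[hi])):
            continue  # no prominence: flat trace, not a peak
        snr = math.inf if noise == 0.0 else height / noise
        if snr < snr_min:
            continue
        area = float(np.trapezoid(y[lo:hi + 1], rt[lo:hi + 1]))
        if area <= 0:
            continue
        peaks.append(ChromPeak(rt_apex=float(rt[apex]), height=height,
                               area=area, snr=snr))
    return peaks


def _ion_labels(config: ScreenConfig) -> list[tuple[str, int, str]]:
    """(adduct kind, n_13c, label) for every ion screened per species."""
    out = []
    for kind in ADDUCT_KINDS:
        for k in range(config.n_13c_max + 1):
            label = kind if k == 0 else f"{kind} +{k}x13C"
            out.append((kind, k, label))
    return out


def _group_peaks(ion_peaks: list[tuple[str, ChromPeak]], rt_tol: float):
    """Greedy co-elution grouping anchored on the largest-area peak.

    Within a group each ion keeps its largest-area peak (tie: earlier rt).
    Deterministic for a fixed input.
    """
    pending = sorted(ion_peaks, key=lambda ip: (-ip[1].area, ip[1].rt_apex, ip[0]))
    groups = []
    while pending:
        anchor_ion, anchor = pending[0]
        members = [(ion, p) for ion, p in pending
                   if abs(p.rt_apex - anchor.rt_apex) <= rt_tol]
        best: dict[str, ChromPeak] = {}
        for ion, p in members:
            cur = best.get(ion)
            if cur is None or (p.area, -p.rt_apex) > (cur.area, -cur.rt_apex):
                best[ion] = p
        groups.append((anchor.rt_apex, best))
        chosen = {(ion, p) for ion, p in members}
        pending = [ip for ip in pending if ip not in chosen]
    return groups


def _assign_tier(ions: Mapping[str, ChromPeak], config: ScreenConfig) -> str | None:
    """Tier per the two-tier rule; None means sub-threshold evidence."""
    labels = set(ions)
    if not config.count_13c_for_tier:
        labels = {l for l in labels if "13C" not in l}
    if len(labels) >= 2:
        return TIER_MULTI_ION
    if len(labels) == 1:
        (label,) = labels
        if label in _SINGLE_ION_KINDS:
            return TIER_SINGLE_ION
    return None


def screen_run(
    run: Run,
    library: TargetLibrary,
    config: ScreenConfig | None = None,
    reference_rt: Mapping[str, float] | None = None,
) -> ScreenResult:
    """Screen all library species against the MS1 scans of a run.

    ``reference_rt`` optionally maps species names to the retention time of
    a co-analysed authentic standard; when given, detections of those
    species must match it within ``config.rt_ref_tol``.
    """
    config = config or ScreenConfig()
    if len(library) == 0:
        raise ValidationError("empty target library")
    result = ScreenResult()
    for species in library:
        ion_peaks: list[tuple[str, ChromPeak]] = []
        for kind, n13c, label in _ion_labels(config):
            eic = extract_eic(run, species.adduct(kind, n13c).mz, config.mz_tol)
            for peak in detect_peaks(eic, config.snr_min):
                ion_peaks.append((label, peak))
        if not ion_peaks:
            continue
        for rt_apex, ions in _group_peaks(ion_peaks, config.rt_group_tol):
            if reference_rt is not None and species.name in reference_rt:
                if abs(rt_apex - reference_rt[species.name]) > config.rt_ref_tol:
                    continue
            tier = _assign_tier(ions, config)
            if tier is None:
                for ion, peak in sorted(ions.items()):
                    result.subthreshold.append(SubThresholdEvidence(
                        species=species, ion=ion, peak=peak, run_label=run.label))
            else:
                result.detections.append(Detection(
                    species=species, ions=dict(sorted(ions.items())),
                    rt_apex=rt_apex, tier=tier, run_label=run.label))
    result.detections.sort(key=lambda d: (d.rt_apex, d.species.name))
    return result


def estimate_lod(
    dilution_runs: Sequence[tuple[float, Run]],
    species: AhlSpecies,
    library: TargetLibrary | None = None,
    config: ScreenConfig | None = None,
) -> float:
    """Empirical limit of detection from a descending dilution series.

    Returns the lowest planted concentration at which the species is still
    detected; ``math.inf`` if it is never detected.
    """
    if len(dilution_runs) < 2:
        raise ValidationError("need at least two concentrations")
    concs = [c for c, _ in dilution_runs]
    if any(b >= a for a, b in zip(concs, concs[1:])):
        raise ValidationError("dilution series must be strictly descending")
    if library is None:
        library = TargetLibrary([species])
    lod = math.inf
    for conc, run in dilution_runs:
        names = {d.species.name for d in screen_run(run, library, config).detections}
        if species.name in names:
            lod = conc
        else:
            break
    return lod


def detections_to_tsv(detections: Sequence[Detection], path) -> None:
    """Export detections as TSV: run, species, tier, rt_apex, per-ion areas."""
    with open(path, "w") as fh:
        fh.write("run\tspecies\ttier\trt_apex\tion\tarea\theight\tsnr\n")
        for d in detections:
            for ion, p in d.ions.items():
                snr = "inf" if math.isinf(p.snr) else f"{p.snr:.2f}"
                fh.write(f"{d.run_label}\t{d.species.name}\t{d.tier}\t"
                         f"{d.rt_apex:.4f}\t{ion}\t{p.area:.6g}\t"
                         f"{p.height:.6g}\t{snr}\n")
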