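"""Data model and I/O for centroided LC-MS/MS runs.

A :class:`Run` is an rt-ordered list of centroided :class:`Spectrum`
objects (MS1 full scans and MS2 product-ion scans with precursor
metadata).  Runs are read from and written to mzML via a small built-in
parser/serialiser (reading supports 32/64-bit float arrays, plain or
zlib-compressed; writing emits uncompressed 64-bit floats) and to a flat
TSV convenient for text fixtures.

Extracted ion chromatograms (:class:`Eic`) are computed from MS1 scans
only, with an absolute m/z tolerance (the acquisition-software convention
for narrow extraction windows, default +-0.01).
"""

from __future__ import annotations

import base64
import logging
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import UnsupportedDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Centroid:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValidationError("centroid m/z must be positive")
        if self.intensity < 0:
            raise ValidationError("centroid intensity must be >= 0")


@dataclass
class Spectrum:
    """One centroided scan.

    rt is in minutes.  MS2 scans carry the precursor isolation m/z and
    collision energy (eV).
    """

    ms_level: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    collision_energy: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("m/z and intensity arrays differ in length")
        if self.ms_level not in (1, 2):
            raise ValidationError(f"unsupported ms_level {self.ms_level}")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValidationError("MS2 spectrum requires precursor_mz")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def centroids(self) -> tuple[Centroid, ...]:
        return tuple(Centroid(m, i) for m, i in zip(self.mz, self.intensity))

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Run:
    """An rt-ordered LC-MS/MS acquisition for one sample."""

    spectra: list[Spectrum] = field(default_factory=list)
    tune_mode: str = "standard"  # "standard" | "small_molecule"
    label: str = ""

    def __post_init__(self):
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValidationError("spectra must be in non-decreasing rt order")
        self._ms1_cache = None

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    @property
    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def _ms1_arrays(self):
        """Flattened, m/z-sorted (mz, intensity, scan index) over all MS1
        scans, cached; the workhorse behind fast EIC extraction."""
        if self._ms1_cache is None:
            ms1 = self.ms1
            if ms1:
                mz = np.concatenate([s.mz for s in ms1])
                inten = np.concatenate([s.intensity for s in ms1])
                idx = np.concatenate([
                    np.full(len(s), i, dtype=np.intp) for i, s in enumerate(ms1)
                ])
                order = np.argsort(mz, kind="stable")
                rts = np.array([s.rt for s in ms1])
                self._ms1_cache = (mz[order], inten[order], idx[order], rts)
            else:
                self._ms1_cache = (np.empty(0), np.empty(0),
                                   np.empty(0, dtype=np.intp), np.empty(0))
        return self._ms1_cache


@dataclass
class Eic:
    """Extracted ion chromatogram: one intensity per MS1 scan."""

    target_mz: float
    tolerance: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValidationError("rt and intensity arrays differ in length")

    def __len__(self) -> int:
        return len(self.rt)


def extract_eic(run: Run, target_mz: float, tolerance: float = 0.01) -> Eic:
    """Sum MS1 centroid intensities within ``target_mz`` +- ``tolerance``
    for every MS1 scan of the run."""
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    mz, inten, idx, rts = run._ms1_arrays()
    out = np.zeros(len(rts))
    lo, hi = np.searchsorted(mz, (target_mz - tolerance, target_mz + tolerance + 1e-12))
    np.add.at(out, idx[lo:hi], inten[lo:hi])
    return Eic(target_mz=target_mz, tolerance=tolerance, rt=rts, intensity=out)


# ---------------------------------------------------------------------------
# mzML I/O
# ---------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, str]:
    """accession -> value for the direct cvParam children of ``elem``."""
    return {
        c.get("accession"): c.get("value", "")
        for c in elem if _strip(c.tag) == "cvParam"
    }


def _find(elem, *names):
    """First descendant (depth-first) whose local tag matches the chain."""
    cur = [elem]
    for name in names:
        nxt = []
        for e in cur:
            nxt.extend(c for c in e.iter() if _strip(c.tag) == name)
        cur = nxt
        if not cur:
            return None
    return cur[0]


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    binary = _find(bda, "binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # 32-bit vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    Profile-mode spectra raise :class:`UnsupportedDataError`.  Retention
    times are converted to minutes.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise UnsupportedDataError(f"cannot parse {path} as mzML: {exc}") from exc
    spectra = []
    label = ""
    for el in tree.getroot().iter():
        if _strip(el.tag) == "run":
            label = el.get("id", "") or ""
            break
    for sp in tree.getroot().iter():
        if _strip(sp.tag) != "spectrum":
            continue
        params = _cv_params(sp)
        if "MS:1000128" in params:
            raise UnsupportedDataError(
                f"profile-mode spectrum in {path}; centroided data required")
        ms_level = int(params.get("MS:1000511", 1))
        scan = _find(sp, "scanList", "scan")
        rt = 0.0
        if scan is not None:
            for c in scan:
                if _strip(c.tag) == "cvParam" and c.get("accession") == "MS:1000016":
                    rt = float(c.get("value"))
                    if c.get("unitName", "minute") in ("second", "s"):
                        rt /= 60.0
        prec_mz = None
        ce = None
        if ms_level >= 2:
            si = _find(sp, "precursorList", "selectedIon")
            if si is not None:
                prec_mz = float(_cv_params(si).get("MS:1000744"))
            act = _find(sp, "precursorList", "activation")
            if act is not None and "MS:1000045" in _cv_params(act):
                ce = float(_cv_params(act)["MS:1000045"])
        mz_arr = np.empty(0)
        int_arr = np.empty(0)
        for bda in sp.iter():
            if _strip(bda.tag) != "binaryDataArray":
                continue
            params_b = _cv_params(bda)
            if "MS:1000514" in params_b:
                mz_arr = _decode_binary_array(bda)
            elif "MS:1000515" in params_b:
                int_arr = _decode_binary_array(bda)
        spectra.append(Spectrum(
            ms_level=ms_level, rt=rt, mz=mz_arr, intensity=int_arr,
            precursor_mz=prec_mz, collision_energy=ce,
        ))
    if not spectra:
        logger.warning("mzML file %s contains no spectra", path)
    return Run(spectra=spectra, label=label)


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(arr)}d", *arr)).decode()


def _cv(parent, accession, name, value="", **extra):
    attrib = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
    attrib.update(extra)
    ET.SubElement(parent, "cvParam", attrib)


def write_mzml(run: Run, path) -> None:
    """Serialise a run to mzML (centroided, 64-bit float, uncompressed).

    The output is deliberately minimal but valid enough for standard
    readers; ``read_mzml(write_mzml(run))`` preserves rt, ms level,
    precursor metadata and all centroids.
    """
    for s in run.spectra:
        if s.ms_level == 2 and s.precursor_mz is None:
            raise ValidationError("MS2 spectrum lacks precursor_mz")

    root = ET.Element("mzML", {
        "xmlns": "http://psi.hupo.org/ms/mzml",
        "version": "1.1.0", "id": run.label or "run",
    })
    cvlist = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cvlist, "cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    ET.SubElement(cvlist, "cv", {
        "id": "UO", "fullName": "Unit Ontology",
        "URI": "http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"})
    fdesc = ET.SubElement(root, "fileDescription")
    fcont = ET.SubElement(fdesc, "fileContent")
    _cv(fcont, "MS:1000579", "MS1 spectrum")
    _cv(fcont, "MS:1000127", "centroid spectrum")
    soft = ET.SubElement(root, "softwareList", {"count": "1"})
    ET.SubElement(soft, "software", {"id": "ahlscreen", "version": "0.1.0"})
    icl = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(icl, "instrumentConfiguration", {"id": "IC1"})
    dpl = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dpl, "dataProcessing", {"id": "DP1"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "ahlscreen"})
    _cv(pm, "MS:1000544", "Conversion to mzML")

    srun = ET.SubElement(root, "run", {
        "id": run.label or "run", "defaultInstrumentConfigurationRef": "IC1"})
    slist = ET.SubElement(srun, "spectrumList", {
        "count": str(len(run.spectra)), "defaultDataProcessingRef": "DP1"})
    for i, s in enumerate(run.spectra):
        sp = ET.SubElement(slist, "spectrum", {
            "index": str(i), "id": f"scan={i + 1}",
            "defaultArrayLength": str(len(s.mz))})
        _cv(sp, "MS:1000511", "ms level", s.ms_level)
        _cv(sp, "MS:1000579" if s.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if s.ms_level == 1 else "MSn spectrum")
        _cv(sp, "MS:1000127", "centroid spectrum")
        _cv(sp, "MS:1000130", "positive scan")
        sl = ET.SubElement(sp, "scanList", {"count": "1"})
        _cv(sl, "MS:1000795", "no combination")
        scan = ET.SubElement(sl, "scan")
        _cv(scan, "MS:1000016", "scan start time", repr(float(s.rt)),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        if s.ms_level == 2:
            pl = ET.SubElement(sp, "precursorList", {"count": "1"})
            prec = ET.SubElement(pl, "precursor")
            iw = ET.SubElement(prec, "isolationWindow")
            _cv(iw, "MS:1000827", "isolation window target m/z", repr(float(s.precursor_mz)))
            sil = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            si = ET.SubElement(sil, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)))
            _cv(si, "MS:1000041", "charge state", 1)
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000133", "collision-induced dissociation")
            if s.collision_energy is not None:
                _cv(act, "MS:1000045", "collision energy", repr(float(s.collision_energy)))
        bal = ET.SubElement(sp, "binaryDataArrayList", {"count": "2"})
        for arr, acc, name in ((s.mz, "MS:1000514", "m/z array"),
                               (s.intensity, "MS:1000515", "intensity array")):
            payload = _b64(arr)
            bda = ET.SubElement(bal, "binaryDataArray", {"encodedLength": str(len(payload))})
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name)
            ET.SubElement(bda, "binary").text = payload

    ET.indent(root)
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# TSV fixture format
# ---------------------------------------------------------------------------

_TSV_HEADER = "rt\tms_level\tmz\tintensity\tprecursor_mz\tce"


def run_to_tsv(run: Run, path) -> None:
    """One row per centroid: rt, ms_level, mz, intensity, precursor_mz, ce."""
    with open(path, "w") as fh:
        fh.write(f"# tune_mode={run.tune_mode}\tlabel={run.label}\n")
        fh.write(_TSV_HEADER + "\n")
        for i, s in enumerate(run.spectra):
            prec = "" if s.precursor_mz is None else repr(s.precursor_mz)
            ce = "" if s.collision_energy is None else repr(s.collision_energy)
            if len(s.mz) == 0:
                fh.write(f"{s.rt!r}\t{s.ms_level}\t\t\t{prec}\t{ce}\n")
            for m, inten in zip(s.mz, s.intensity):
                fh.write(f"{s.rt!r}\t{s.ms_level}\t{float(m)!r}\t{float(inten)!r}"
                         f"\t{prec}\t{ce}\n")


def run_from_tsv(path) -> Run:
    tune_mode, label = "standard", ""
    groups: dict[tuple, tuple[list, list]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line[1:].split("\t"):
                    k, _, v = tok.strip().partition("=")
                    if k == "tune_mode":
                        tune_mode = v
                    elif k == "label":
                        label = v
                continue
            if not line or line.startswith("rt\t"):
                continue
            rt, lvl, mz, inten, prec, ce = (line.split("\t") + [""] * 6)[:6]
            key = (float(rt), int(lvl),
                   float(prec) if prec else None, float(ce) if ce else None)
            mzs, intens = groups.setdefault(key, ([], []))
            if mz:
                mzs.append(float(mz))
                intens.append(float(inten))
    spectra = [
        Spectrum(ms_level=lvl, rt=rt, mz=mzs, intensity=intens,
                 precursor_mz=prec, collision_energy=ce)
        for (rt, lvl, prec, ce), (mzs, intens) in sorted(groups.items(),
                                                         key=lambda kv: kv[0][0])
    ]
    return Run(spectra=spectra, tune_mode=tune_mode, label=label)
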