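"""Strain x AHL detection matrices, occurrence statistics, binary-profile
clustering, clade fingerprints and the geography (Mantel) test.

The central object is the :class:`DetectionMatrix`: for every strain and
AHL species it stores the integrated peak area in each of the two
analytical runs plus the identification tier, with presence defined as
detection in either run.  A curated fixture transcribing the published
survey of 32 AHL-positive Vibrionaceae strains (plus the V. anguillarum
reference strain) ships with the package and is the ground truth for the
profile statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError

logger = logging.getLogger(__name__)

_CLASS_ORDER = {"": 0, "OH-": 1, "O-": 2}


def ahl_sort_key(name: str):
    """Canonical column order: unsubstituted, 3-hydroxy, 3-oxo; each by
    ascending chain length; open-ring forms after their closed twin."""
    base = name
    open_ring = base.endswith("(open)")
    if open_ring:
        base = base[:-6]
    for prefix in ("OH-", "O-", ""):
        if base.startswith(prefix):
            chain = int(base[len(prefix) + 1:])
            return (_CLASS_ORDER[prefix], chain, open_ring)
    raise ValidationError(f"unparseable AHL name {name!r}")


@dataclass(frozen=True)
class StrainRecord:
    """Strain metadata: taxonomy, clade, isolation site, growth medium."""

    strain: str
    species: str
    clade: str
    latitude: float | None
    longitude: float | None
    medium: str = "LB10"
    reference: bool = False

    def __post_init__(self):
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValidationError(f"latitude {self.latitude} out of range")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValidationError(f"longitude {self.longitude} out of range")


class DetectionMatrix:
    """Strains x AHL species table of run-1/run-2 areas and tiers."""

    def __init__(self, strains: Sequence[str], ahls: Sequence[str],
                 area1: pd.DataFrame, area2: pd.DataFrame, tier: pd.DataFrame):
        if len(set(ahls)) != len(ahls):
            raise ValidationError("duplicate AHL column labels")
        self.strains = list(strains)
        self.ahls = list(ahls)
        for df in (area1, area2, tier):
            if list(df.index) != self.strains or list(df.columns) != self.ahls:
                raise ValidationError("matrix components misaligned")
        self.area1 = area1
        self.area2 = area2
        self.tier = tier

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean presence: detected in either analytical run."""
        return (self.area1 > 0) | (self.area2 > 0)

    @classmethod
    def empty(cls, strains: Sequence[str], ahls: Sequence[str]) -> "DetectionMatrix":
        shape = (len(strains), len(ahls))
        z = lambda fill: pd.DataFrame(np.full(shape, fill, dtype=object if fill == "" else float),
                                      index=list(strains), columns=list(ahls))
        return cls(strains, ahls, z(0.0).astype(float), z(0.0).astype(float), z(""))

    def set_cell(self, strain: str, ahl: str, area1: float, area2: float, tier: str):
        self.area1.loc[strain, ahl] = area1
        self.area2.loc[strain, ahl] = area2
        self.tier.loc[strain, ahl] = tier


def build_matrix(
    detections_per_run: Mapping[str, Sequence[Sequence]],
    strains: Sequence[StrainRecord | str],
) -> DetectionMatrix:
    """Assemble a DetectionMatrix from per-strain screening results.

    ``detections_per_run`` maps strain id to up to two sequences of
    :class:`~ahlscreen.screen.Detection` (one per analytical run); presence
    is the union of both runs.  Duplicate detections of one species within
    a run have their areas summed (with a warning).  The best tier across
    runs is stored ("b" over "c").
    """
    ids = [s.strain if isinstance(s, StrainRecord) else str(s) for s in strains]
    known = set(ids)
    ahls: set[str] = set()
    for strain, runs in detections_per_run.items():
        if strain not in known:
            raise ValidationError(f"detections reference unknown strain {strain!r}")
        if len(runs) > 2:
            raise ValidationError(f"strain {strain!r} has more than two runs")
        for dets in runs:
            ahls.update(d.species.name for d in dets)
    columns = sorted(ahls, key=ahl_sort_key)
    matrix = DetectionMatrix.empty(ids, columns)
    for strain, runs in detections_per_run.items():
        for run_idx, dets in enumerate(runs):
            area_df = matrix.area1 if run_idx == 0 else matrix.area2
            for d in dets:
                name = d.species.name
                if area_df.loc[strain, name] > 0:
                    logger.warning("duplicate detection of %s in %s run %d; "
                                   "areas summed", name, strain, run_idx + 1)
                area_df.loc[strain, name] += d.area
                cur = matrix.tier.loc[strain, name]
                if cur == "" or (cur == "c" and d.tier == "b"):
                    matrix.tier.loc[strain, name] = d.tier
    return matrix


def tally_occurrences(matrix: DetectionMatrix,
                      exclude: Iterable[str] = ()) -> pd.Series:
    """Number of strains in which each AHL occurs; strains named in
    ``exclude`` (typically the reference strain) are not counted."""
    if not matrix.strains:
        raise ValidationError("empty matrix")
    pres = matrix.presence.drop(index=list(exclude), errors="ignore")
    return pres.sum(axis=0).astype(int)


def per_strain_counts(matrix: DetectionMatrix) -> pd.Series:
    """Number of distinct AHL species detected per strain."""
    if not matrix.strains:
        raise ValidationError("empty matrix")
    return matrix.presence.sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ProfileClustering:
    """Result of agglomerative clustering of binary AHL profiles."""

    labels: list[str]            # input strains that entered the clustering
    merges: list[tuple]          # (cluster_a, cluster_b, distance) as leaf-label frozensets
    newick: str
    order: list[str]             # dendrogram leaf order
    matrix: pd.DataFrame         # binary presence, rows in leaf order

    def clusters(self) -> set[frozenset]:
        """All merged leaf sets; a topology signature independent of
        input row order."""
        out = set()
        for a, b, _ in self.merges:
            out.add(a | b)
        return out


def _jaccard(u: np.ndarray, v: np.ndarray) -> float:
    union = np.logical_or(u, v).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(u, v).sum() / union


_METRICS = {"jaccard": _jaccard,
            "hamming": lambda u, v: float(np.mean(u != v))}


def cluster_profiles(matrix: DetectionMatrix, metric: str = "jaccard",
                     linkage: str = "average",
                     include_absent: bool = False) -> ProfileClustering:
    """Agglomerative clustering of binary presence profiles.

    Average linkage over Jaccard distances by default.  Merge order is
    fully deterministic: ties in the minimum pairwise distance are broken
    by the lexicographically smallest pair of cluster representatives
    (minimum strain id per cluster), so the result is invariant to row
    permutation of the input.
    """
    if linkage not in ("average", "single", "complete"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    dist_fn = _METRICS.get(metric)
    if dist_fn is None:
        raise ValidationError(f"unsupported metric {metric!r}")
    pres = matrix.presence
    if not include_absent:
        pres = pres.loc[pres.any(axis=1)]
    if len(pres) < 2:
        raise ValidationError("need >= 2 strains with >= 1 AHL present")
    labels = sorted(pres.index)
    data = {l: pres.loc[l].to_numpy() for l in labels}

    # active clusters: representative -> (leaf set, size); distances between
    # clusters maintained explicitly (n <= a few dozen strains)
    clusters: dict[str, frozenset] = {l: frozenset([l]) for l in labels}
    dists: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dists[(a, b)] = dist_fn(data[a], data[b])

    def d(a: str, b: str) -> float:
        return dists[(a, b) if a < b else (b, a)]

    merges: list[tuple] = []
    node_heights: dict[str, float] = {l: 0.0 for l in labels}
    newick_repr: dict[str, str] = {l: l for l in labels}
    order_repr: dict[str, list[str]] = {l: [l] for l in labels}

    active = sorted(clusters)
    while len(active) > 1:
        best = min(
            ((d(a, b), a, b) for i, a in enumerate(active) for b in active[i + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, a, b = best
        merges.append((clusters[a], clusters[b], h))
        na, nb = len(clusters[a]), len(clusters[b])
        rep = min(a, b)
        other = b if rep == a else a
        for c in active:
            if c in (a, b):
                continue
            if linkage == "average":
                new = (d(a, c) * na + d(b, c) * nb) / (na + nb)
            elif linkage == "single":
                new = min(d(a, c), d(b, c))
            else:
                new = max(d(a, c), d(b, c))
            dists[(rep, c) if rep < c else (c, rep)] = new
        la = max(h / 2 - node_heights[a], 0.0)
        lb = max(h / 2 - node_heights[b], 0.0)
        newick_repr[rep] = (f"({newick_repr[a]}:{la:.6g},{newick_repr[b]}:{lb:.6g})")
        order_repr[rep] = order_repr[a] + order_repr[other] if rep == a \
            else order_repr[other] + order_repr[b]
        clusters[rep] = clusters[a] | clusters[b]
        node_heights[rep] = h / 2
        active = [c for c in active if c not in (a, b) or c == rep]

    root = active[0]
    order = order_repr[root]
    return ProfileClustering(
        labels=labels, merges=merges,
        newick=newick_repr[root] + ";",
        order=order,
        matrix=pres.loc[order].astype(int),
    )


def clade_fingerprint(matrix: DetectionMatrix,
                      strains: Sequence[StrainRecord],
                      clade: str | Sequence[str],
                      q: float = 1.0) -> set[str]:
    """AHL species present in at least fraction ``q`` of a clade's strains.

    ``clade`` is either a clade label (resolved through ``strains``) or an
    explicit sequence of strain ids (a subclade).
    """
    if not 0 < q <= 1:
        raise ValidationError("q must be in (0, 1]")
    if isinstance(clade, str):
        members = [s.strain for s in strains if s.clade == clade]
        if not members:
            raise ValidationError(f"unknown clade {clade!r}")
    else:
        members = list(clade)
    missing = [m for m in members if m not in matrix.strains]
    if missing:
        raise ValidationError(f"strains absent from matrix: {missing}")
    pres = matrix.presence.loc[members]
    frac = pres.mean(axis=0)
    return set(frac.index[frac >= q - 1e-12])


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geo_distance_matrix(strains: Sequence[StrainRecord]) -> pd.DataFrame:
    """Pairwise great-circle distances between isolation sites; strains
    without coordinates (the reference strain) are excluded."""
    located = [s for s in strains if s.latitude is not None and s.longitude is not None]
    n = len(located)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = located[i], located[j]
            mat[i, j] = mat[j, i] = great_circle_km(
                a.latitude, a.longitude, b.latitude, b.longitude)
    ids = [s.strain for s in located]
    return pd.DataFrame(mat, index=ids, columns=ids)


def profile_distance_matrix(matrix: DetectionMatrix,
                            metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise binary-profile distances between strains with >= 1 AHL."""
    pres = matrix.presence
    pres = pres.loc[pres.any(axis=1)]
    condensed = pdist(pres.to_numpy().astype(bool), metric=metric)
    return pd.DataFrame(squareform(condensed), index=pres.index, columns=pres.index)


def mantel_test(d1: pd.DataFrame, d2: pd.DataFrame,
                n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices with a
    row/column permutation null.

    Returns (statistic, one-sided p-value).  Matrices must share labels in
    identical order; p = (1 + #{perm r >= observed r}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    if list(d1.index) != list(d2.index) or list(d1.columns) != list(d2.columns):
        raise ValidationError("distance matrices have mismatched labels")
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValidationError("distance matrices must be symmetric")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    if np.std(x) == 0 or np.std(b[iu]) == 0:
        raise ValidationError("constant distance matrix: correlation undefined")

    def corr(mat_b):
        return float(np.corrcoef(x, mat_b[iu])[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(b[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def _read_tsv(path_or_buf) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str)


def load_strains(path=None) -> list[StrainRecord]:
    """Load strain metadata; defaults to the packaged survey fixture."""
    if path is None:
        path = resources.files("ahlscreen.data") / "strains.tsv"
    df = _read_tsv(path)
    records = []
    for row in df.itertuples(index=False):
        lat = None if pd.isna(row.latitude) else float(row.latitude)
        lon = None if pd.isna(row.longitude) else float(row.longitude)
        records.append(StrainRecord(
            strain=row.strain, species=row.species, clade=row.clade,
            latitude=lat, longitude=lon, medium=row.medium,
            reference=bool(int(row.reference))))
    refs = [r for r in records if r.reference]
    if len(refs) != 1:
        raise ValidationError(f"fixture must flag exactly one reference strain, got {len(refs)}")
    return records


def load_detection_matrix(strains: Sequence[StrainRecord], path=None) -> DetectionMatrix:
    """Load the strain x AHL fixture table into a DetectionMatrix."""
    if path is None:
        path = resources.files("ahlscreen.data") / "detections.tsv"
    df = _read_tsv(path)
    ids = [s.strain for s in strains]
    columns = sorted(df["ahl"].unique(), key=ahl_sort_key)
    matrix = DetectionMatrix.empty(ids, columns)
    for row in df.itertuples(index=False):
        if row.strain not in set(ids):
            raise ValidationError(f"fixture detection for unknown strain {row.strain!r}")
        matrix.set_cell(row.strain, row.ahl, float(row.area_run1),
                        float(row.area_run2), row.tier)
    return matrix


def tallies_to_tsv(tallies: pd.Series, path) -> None:
    tallies.rename_axis("ahl").rename("n_strains").to_csv(path, sep="\t")


def plot_heatmap(clustering: ProfileClustering, path) -> None:
    """Binary presence heatmap with rows in dendrogram order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = clustering.matrix
    fig, ax = plt.subplots(figsize=(0.35 * len(m.columns) + 2, 0.25 * len(m) + 2))
    ax.imshow(m.to_numpy(), aspect="auto", cmap="Greys", vmin=0, vmax=1.4)
    ax.set_xticks(range(len(m.columns)), m.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(m)), m.index, fontsize=7)
    ax.set_xlabel("AHL species")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
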