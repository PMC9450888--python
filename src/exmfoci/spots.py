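"""Spot-based detection and classification of DNA-damage focus structures.

The analysis chain implemented here mirrors the semi-automated workflow used
on expanded nuclei:

1. **Detection** — per channel, sub-resolution puncta are found as local
   maxima of a Laplacian-of-Gaussian (LoG) filtered volume; maxima are kept
   if their *prominence* relative to the local neighbourhood (the spot
   quality) exceeds a threshold, and positions are refined to sub-voxel
   accuracy by a quadratic fit.
2. **Clustering** — spots of the designated *site* channel (BRCA1 in the
   two-channel analysis, RAD51 in the three-channel analysis) are grouped
   into the connected components of the graph linking all spots within a
   fixed radius; each component's unweighted centre of mass is the core of
   one repair-focus structure.
3. **Assembly** — partner-channel spots within a search radius (default
   2 µm post-expansion) of a core are attached to that structure.
4. **Classification** — per-structure spot counts, together with a
   geometric *encapsulation* test (is the core surrounded by its partner
   satellites?), are mapped to a class label by an editable rule set.  The
   default two-channel taxonomy has five classes; the default three-channel
   taxonomy (RAD51-centred) has ten.
5. **Subclassification** — class-5 structures are binned by core-to-
   satellite distance (contracted / control-like / extended), and
   multi-spot accumulations are labelled continuous or discontinuous from
   the image crop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .image import VoxelGrid
from .units import ExmError

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationError",
    "StructureCluster",
    "ClassRule",
    "ClassRuleSet",
    "EncapsulationParams",
    "DEFAULT_SEARCH_RADIUS_NM",
    "detect_spots",
    "cluster_site_spots",
    "assemble_structures",
    "encapsulation_test",
    "classify_structure",
    "classify_three_channel",
    "subclassify_by_distance",
    "continuity_test",
    "crop_structure",
    "two_channel_rules",
    "three_channel_rules",
    "export_crops_for_review",
    "ingest_manual_labels",
    "DEFAULT_DISTANCE_BINS_NM",
    "classify_counts",
    "class_frequency_table",
]

#: Partner spots are attached to a core within this radius (post-expansion).
DEFAULT_SEARCH_RADIUS_NM = 2000.0


class ClassificationError(ExmError):
    """No rule (or more than one) applies to a structure's spot counts."""


# ---------------------------------------------------------------------------
# Spot detection
# ---------------------------------------------------------------------------

def detect_spots(
    volume: VoxelGrid,
    expected_radius_nm: float | Sequence[float],
    quality_threshold: float,
) -> pd.DataFrame:
    """Detect diffraction-limited puncta in a single-channel volume.

    A Laplacian-of-Gaussian filter at the blob scale ``sigma = r / sqrt(3)``
    (per axis, so anisotropic voxels are handled) turns puncta of radius
    ``r`` into local maxima of the (negated, scale-normalised) response.
    Maxima within a radius-sized neighbourhood are candidate spots; each is
    scored by its prominence (response minus the neighbourhood minimum) and
    kept if the score reaches ``quality_threshold``.  Positions are refined
    per axis by a three-point quadratic fit.

    Returns a DataFrame sorted by quality (descending) with columns
    ``z, y, x`` (nm, global frame), ``quality`` and the integer voxel index
    columns ``vz, vy, vx``.
    """
    if volume.data.ndim != 3:
        raise ValueError("detect_spots expects a single-channel (Z, Y, X) volume")
    radius = np.broadcast_to(np.asarray(expected_radius_nm, dtype=float), (3,)).copy()
    voxel = np.asarray(volume.voxel_size)
    if np.any(radius < voxel):
        raise ValueError(
            f"expected radius {tuple(radius)} nm is below the voxel size "
            f"{tuple(voxel)} nm on at least one axis"
        )
    sigma_nm = radius / np.sqrt(3.0)
    sigma_vox = sigma_nm / voxel

    img = volume.data.astype(np.float64, copy=False)
    # Scale-normalised negated LoG: puncta become positive peaks.
    norm = float(np.prod(sigma_vox) ** (2.0 / 3.0))
    resp = -norm * ndimage.gaussian_laplace(img, sigma_vox)

    size = tuple(2 * int(np.ceil(r / v)) + 1 for r, v in zip(radius, voxel))
    max_f = ndimage.maximum_filter(resp, size=size, mode="nearest")
    min_f = ndimage.minimum_filter(resp, size=size, mode="nearest")
    peaks = (resp >= max_f) & (resp > 0)
    prominence = resp - min_f

    vz, vy, vx = np.nonzero(peaks)
    qual = prominence[vz, vy, vx]
    keep = qual >= quality_threshold
    vz, vy, vx, qual = vz[keep], vy[keep], vx[keep], qual[keep]

    # Sub-voxel refinement: independent 3-point quadratic per axis.
    offsets = np.zeros((len(vz), 3))
    idx = np.stack([vz, vy, vx], axis=1)
    for ax in range(3):
        at = idx[:, ax]
        interior = (at > 0) & (at < resp.shape[ax] - 1)
        lo = idx.copy()
        hi = idx.copy()
        lo[:, ax] = np.maximum(lo[:, ax] - 1, 0)
        hi[:, ax] = np.minimum(hi[:, ax] + 1, resp.shape[ax] - 1)
        f0 = resp[idx[:, 0], idx[:, 1], idx[:, 2]]
        fm = resp[lo[:, 0], lo[:, 1], lo[:, 2]]
        fp = resp[hi[:, 0], hi[:, 1], hi[:, 2]]
        denom = fm - 2.0 * f0 + fp
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * (fm - fp) / denom
        delta = np.where(interior & (denom < 0) & np.isfinite(delta), delta, 0.0)
        offsets[:, ax] = np.clip(delta, -0.5, 0.5)

    pos = volume.index_to_physical(idx + offsets) if len(vz) else np.empty((0, 3))
    df = pd.DataFrame(
        {
            "z": pos[:, 0] if len(vz) else [],
            "y": pos[:, 1] if len(vz) else [],
            "x": pos[:, 2] if len(vz) else [],
            "quality": qual,
            "vz": vz,
            "vy": vy,
            "vx": vx,
        }
    )
    # Quality descending; lexicographic voxel index breaks ties.
    df = df.sort_values(
        ["quality", "vz", "vy", "vx"], ascending=[False, True, True, True]
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Fixed-radius connected-component clustering
# ---------------------------------------------------------------------------

class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_site_spots(
    positions: np.ndarray, link_radius_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster site-channel spots into fixed-radius connected components.

    Two spots belong to the same cluster iff they are connected through a
    chain of links each no longer than ``link_radius_nm`` (graph
    connected-component semantics, so a chain can span far more than one
    radius end to end).

    Returns ``(labels, cores)``: integer cluster labels (0-based, ordered by
    each cluster's first spot index) and the unweighted centre of mass of
    each cluster, shape ``(n_clusters, 3)`` nm.
    """
    if not link_radius_nm > 0:
        raise ValueError(f"link_radius_nm must be positive, got {link_radius_nm}")
    pts = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int), np.empty((0, 3))
    dsu = _DisjointSet(n)
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(r=link_radius_nm):
        dsu.union(i, j)
    roots = np.array([dsu.find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    cores = np.stack([pts[labels == k].mean(axis=0) for k in range(labels.max() + 1)])
    return labels, cores


# ---------------------------------------------------------------------------
# Structure assembly
# ---------------------------------------------------------------------------

@dataclass
class StructureCluster:
    """One repair-focus structure: a site-channel cluster plus the partner
    spots within the search radius of its centre of mass."""

    structure_id: int
    site_channel: str
    core_position: np.ndarray  # (3,) nm, z y x
    site_members: np.ndarray  # (m, 3) nm
    site_indices: np.ndarray  # indices into the site spot table
    members: dict[str, np.ndarray] = field(default_factory=dict)  # channel -> (k, 3)
    member_indices: dict[str, np.ndarray] = field(default_factory=dict)
    shared_members: dict[str, np.ndarray] = field(default_factory=dict)  # bool flags
    class_label: int | None = None
    distance_subclass: str | None = None
    continuity_subclass: str | None = None
    crop_bounds: tuple | None = None

    @property
    def site_count(self) -> int:
        return len(self.site_members)

    def partner_count(self, channel: str) -> int:
        return len(self.members.get(channel, ()))


def assemble_structures(
    site_positions: np.ndarray,
    labels: np.ndarray,
    cores: np.ndarray,
    partner_spots: dict[str, np.ndarray],
    search_radius_nm: float = DEFAULT_SEARCH_RADIUS_NM,
    site_channel: str = "site",
) -> list[StructureCluster]:
    """Attach partner-channel spots to each site cluster.

    A partner spot is a member of every structure whose core lies within
    ``search_radius_nm`` of it; multiply attached spots are flagged in
    ``shared_members``.
    """
    if not search_radius_nm > 0:
        raise ValueError(f"search_radius_nm must be positive, got {search_radius_nm}")
    site_positions = np.asarray(site_positions, dtype=float).reshape(-1, 3)
    structures: list[StructureCluster] = []
    trees = {
        ch: (cKDTree(np.asarray(p, dtype=float).reshape(-1, 3)) if len(p) else None)
        for ch, p in partner_spots.items()
    }
    attach_counts = {
        ch: np.zeros(len(np.asarray(p).reshape(-1, 3)), dtype=int)
        for ch, p in partner_spots.items()
    }
    hits: list[dict[str, np.ndarray]] = []
    for k in range(len(cores)):
        per_channel: dict[str, np.ndarray] = {}
        for ch, tree in trees.items():
            if tree is None:
                per_channel[ch] = np.empty(0, dtype=int)
                continue
            found = np.sort(np.asarray(tree.query_ball_point(cores[k], search_radius_nm), dtype=int))
            per_channel[ch] = found
            attach_counts[ch][found] += 1
        hits.append(per_channel)
    for k in range(len(cores)):
        member_pos = {}
        member_idx = {}
        shared = {}
        for ch, found in hits[k].items():
            pts = np.asarray(partner_spots[ch], dtype=float).reshape(-1, 3)
            member_pos[ch] = pts[found]
            member_idx[ch] = found
            shared[ch] = attach_counts[ch][found] > 1
        in_cluster = labels == k
        structures.append(
            StructureCluster(
                structure_id=k,
                site_channel=site_channel,
                core_position=cores[k],
                site_members=site_positions[in_cluster],
                site_indices=np.nonzero(in_cluster)[0],
                members=member_pos,
                member_indices=member_idx,
                shared_members=shared,
            )
        )
    return structures


# ---------------------------------------------------------------------------
# Encapsulation geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncapsulationParams:
    """Geometric definition of "core encapsulated by satellites".

    ``min_satellites`` spots are required; the core must lie inside the 3D
    convex hull of the satellites, or — when the satellites are coplanar
    within ``coplanar_tol_nm`` (hull degenerate, e.g. an in-plane ring) —
    the core must lie within ``coplanar_tol_nm`` of the satellite plane and
    the angular coverage of the satellites around it in that plane must
    reach ``min_arc_deg``.
    """

    min_satellites: int = 3
    min_arc_deg: float = 180.0
    use_hull: bool = True
    coplanar_tol_nm: float = 200.0


def _planar_coverage_deg(core: np.ndarray, satellites: np.ndarray) -> float:
    """Angular coverage of satellites around the core, in the satellites'
    best-fit plane.  Coverage = 360° minus the largest angular gap."""
    centroid = satellites.mean(axis=0)
    _, _, vt = np.linalg.svd(satellites - centroid)
    e1, e2 = vt[0], vt[1]
    rel = satellites - core
    ang = np.arctan2(rel @ e2, rel @ e1)
    ang = np.sort(ang)
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    return float(np.degrees(2 * np.pi - gaps.max()))


def encapsulation_test(
    core: np.ndarray,
    satellites: np.ndarray,
    params: EncapsulationParams = EncapsulationParams(),
) -> bool:
    """Is the core spot surrounded by its satellite spots?

    True iff the satellite count reaches ``params.min_satellites`` and the
    core passes the hull (or, for coplanar satellites, angular-coverage)
    criterion.  Degenerate hulls route to the planar fallback rather than
    erroring.
    """
    satellites = np.asarray(satellites, dtype=float).reshape(-1, 3)
    core = np.asarray(core, dtype=float).reshape(3)
    if len(satellites) < 1:
        raise ValueError("encapsulation_test requires at least one satellite")
    if len(satellites) < params.min_satellites:
        return False

    centred = satellites - satellites.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    thickness = svals[-1] / np.sqrt(len(satellites))  # std along flattest axis
    coplanar = thickness < params.coplanar_tol_nm or len(satellites) < 4

    if params.use_hull and not coplanar:
        try:
            hull = ConvexHull(satellites)
        except QhullError:
            coplanar = True
        else:
            eq = hull.equations  # (n_facets, 4): normal . p + offset <= 0 inside
            inside = np.all(eq[:, :3] @ core + eq[:, 3] <= 1e-9 * max(1.0, np.abs(satellites).max()))
            return bool(inside)
    # planar fallback: core must sit in the ring plane and be surrounded
    centroid = satellites.mean(axis=0)
    _, _, vt = np.linalg.svd(satellites - centroid)
    off_plane = abs(float((core - centroid) @ vt[-1]))
    if off_plane > max(params.coplanar_tol_nm, 1e-9):
        return False
    return _planar_coverage_deg(core, satellites) >= params.min_arc_deg


# ---------------------------------------------------------------------------
# Class rule sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassRule:
    """One classification predicate.

    Count conditions are ``(min, max)`` ranges with ``None`` = unbounded;
    ``encapsulated`` is ``True``/``False``/``None`` (don't care).
    """

    label: int
    site: tuple[int, int | None]
    partners: tuple[tuple[str, int, int | None], ...]  # (channel, min, max)
    encapsulated: bool | None = None

    def matches(self, site_count: int, partner_counts: dict[str, int], encapsulated: bool) -> bool:
        lo, hi = self.site
        if site_count < lo or (hi is not None and site_count > hi):
            return False
        for ch, plo, phi in self.partners:
            c = partner_counts.get(ch, 0)
            if c < plo or (phi is not None and c > phi):
                return False
        if self.encapsulated is not None and encapsulated != self.encapsulated:
            return False
        return True


@dataclass
class ClassRuleSet:
    """An ordered, exhaustive and mutually exclusive set of class rules."""

    name: str
    site_channel: str
    partner_channels: tuple[str, ...]
    rules: tuple[ClassRule, ...]
    encapsulation_channel: str | None = None  # defaults to first partner channel
    encapsulation: EncapsulationParams = field(default_factory=EncapsulationParams)

    def __post_init__(self) -> None:
        if self.encapsulation_channel is None:
            self.encapsulation_channel = self.partner_channels[0]
        self.validate()

    def validate(self, max_count: int = 6) -> None:
        """Check rules fire exactly once on every reachable count combination.

        The reachable space is enumerated up to ``max_count`` spots per
        channel; encapsulation can only be True when the encapsulation
        channel has at least ``min_satellites`` spots.
        """
        from itertools import product

        counts = range(0, max_count + 1)
        for site_count in range(1, max_count + 1):
            for combo in product(counts, repeat=len(self.partner_channels)):
                pc = dict(zip(self.partner_channels, combo))
                enc_states = [False]
                if pc[self.encapsulation_channel] >= self.encapsulation.min_satellites:
                    enc_states.append(True)
                for enc in enc_states:
                    matched = [r.label for r in self.rules if r.matches(site_count, pc, enc)]
                    if len(set(matched)) != 1:
                        raise ClassificationError(
                            f"rule set {self.name!r}: counts site={site_count}, "
                            f"partners={pc}, encapsulated={enc} matched classes "
                            f"{sorted(set(matched))} (need exactly one)"
                        )

    def classify(self, site_count: int, partner_counts: dict[str, int], encapsulated: bool) -> int:
        for rule in self.rules:
            if rule.matches(site_count, partner_counts, encapsulated):
                return rule.label
        raise ClassificationError(
            f"rule set {self.name!r} has no rule for counts site={site_count}, "
            f"partners={partner_counts}, encapsulated={encapsulated}"
        )

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "site_channel": self.site_channel,
            "partner_channels": list(self.partner_channels),
            "encapsulation_channel": self.encapsulation_channel,
            "encapsulation": {
                "min_satellites": self.encapsulation.min_satellites,
                "min_arc_deg": self.encapsulation.min_arc_deg,
                "use_hull": self.encapsulation.use_hull,
                "coplanar_tol_nm": self.encapsulation.coplanar_tol_nm,
            },
            "rules": [
                {
                    "class": r.label,
                    "site": list(r.site),
                    "partners": {ch: [lo, hi] for ch, lo, hi in r.partners},
                    "encapsulated": r.encapsulated,
                }
                for r in self.rules
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ClassRuleSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        enc = doc.get("encapsulation", {})
        rules = tuple(
            ClassRule(
                label=int(r["class"]),
                site=tuple(r["site"]),
                partners=tuple(
                    (ch, lo, hi) for ch, (lo, hi) in sorted(r.get("partners", {}).items())
                ),
                encapsulated=r.get("encapsulated"),
            )
            for r in doc["rules"]
        )
        return cls(
            name=doc["name"],
            site_channel=doc["site_channel"],
            partner_channels=tuple(doc["partner_channels"]),
            rules=rules,
            encapsulation_channel=doc.get("encapsulation_channel"),
            encapsulation=EncapsulationParams(
                min_satellites=int(enc.get("min_satellites", 3)),
                min_arc_deg=float(enc.get("min_arc_deg", 180.0)),
                use_hull=bool(enc.get("use_hull", True)),
                coplanar_tol_nm=float(enc.get("coplanar_tol_nm", 200.0)),
            ),
        )


def two_channel_rules(
    site_channel: str = "brca1",
    partner_channel: str = "53bp1",
    encapsulation: EncapsulationParams | None = None,
) -> ClassRuleSet:
    """Default five-class taxonomy for site + one partner channel.

    * class 1 — only site-channel spots (no partner spot);
    * class 2 — one site spot and one partner spot;
    * class 3 — multiple site spots and one partner spot;
    * class 4 — multiple site and multiple partner spots, or one site spot
      with multiple partner spots that do **not** encapsulate it;
    * class 5 — one site spot encapsulated by multiple partner spots.
    """
    enc = encapsulation or EncapsulationParams()
    p = partner_channel
    rules = (
        ClassRule(1, (1, None), ((p, 0, 0),)),
        ClassRule(2, (1, 1), ((p, 1, 1),)),
        ClassRule(3, (2, None), ((p, 1, 1),)),
        ClassRule(4, (2, None), ((p, 2, None),)),
        ClassRule(4, (1, 1), ((p, 2, None),), encapsulated=False),
        ClassRule(5, (1, 1), ((p, enc.min_satellites, None),), encapsulated=True),
    )
    return ClassRuleSet(
        name="two_channel_default",
        site_channel=site_channel,
        partner_channels=(p,),
        rules=rules,
        encapsulation=enc,
    )


def three_channel_rules(
    site_channel: str = "rad51",
    partner_53bp1: str = "53bp1",
    partner_brca1: str = "brca1",
    encapsulation: EncapsulationParams | None = None,
) -> ClassRuleSet:
    """Default ten-class taxonomy with RAD51 as the structure centre.

    The enumeration runs over (single/multiple RAD51) x (absent/single/
    multiple 53BP1) x (absent/present BRCA1), constrained so that class 4 is
    multiple RAD51 with multiple 53BP1 and no BRCA1, classes 7-9 contain all
    three proteins, and class 9 is multiple RAD51 with BRCA1 encapsulated by
    multiple 53BP1.  Classes not pinned down by those constraints are a
    documented reconstruction; edit the shipped YAML rules file to change
    them.
    """
    enc = encapsulation or EncapsulationParams()
    p, b = partner_53bp1, partner_brca1
    rules = (
        ClassRule(1, (1, 1), ((p, 0, 0), (b, 0, 0))),
        ClassRule(2, (1, 1), ((p, 1, 1), (b, 0, 0))),
        ClassRule(3, (1, 1), ((p, 2, None), (b, 0, 0))),
        ClassRule(4, (2, None), ((p, 2, None), (b, 0, 0))),
        ClassRule(5, (2, None), ((p, 1, 1), (b, 0, 0))),
        ClassRule(6, (2, None), ((p, 0, 0), (b, 0, 0))),
        ClassRule(7, (1, 1), ((p, 1, None), (b, 1, None))),
        ClassRule(8, (2, None), ((p, 1, 1), (b, 1, None))),
        ClassRule(8, (2, None), ((p, 2, None), (b, 1, None)), encapsulated=False),
        ClassRule(9, (2, None), ((p, 2, None), (b, 1, None)), encapsulated=True),
        ClassRule(10, (1, None), ((p, 0, 0), (b, 1, None))),
    )
    return ClassRuleSet(
        name="three_channel_default",
        site_channel=site_channel,
        partner_channels=(p, b),
        rules=rules,
        encapsulation_channel=p,
        encapsulation=enc,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_counts(
    rules: ClassRuleSet,
    site_count: int,
    partner_counts: dict[str, int],
    core: np.ndarray | None = None,
    satellites: np.ndarray | None = None,
) -> int:
    """Classify from counts (and, if needed, an explicit encapsulation
    geometry).  Used both on detected structures and directly on planted
    ground-truth coordinates."""
    encapsulated = False
    if (
        satellites is not None
        and core is not None
        and len(satellites) >= rules.encapsulation.min_satellites
    ):
        encapsulated = encapsulation_test(core, satellites, rules.encapsulation)
    return rules.classify(site_count, partner_counts, encapsulated)


def classify_structure(structure: StructureCluster, rules: ClassRuleSet) -> int:
    """Assign a class label to one assembled structure (stored on the
    structure and returned).  Deterministic: depends only on member counts
    and the encapsulation geometry, not on spot ordering."""
    partner_counts = {ch: structure.partner_count(ch) for ch in rules.partner_channels}
    sats = structure.members.get(rules.encapsulation_channel, np.empty((0, 3)))
    label = classify_counts(
        rules, structure.site_count, partner_counts, structure.core_position, sats
    )
    structure.class_label = label
    return label


def classify_three_channel(structure: StructureCluster, rules: ClassRuleSet | None = None) -> int:
    """Classify a structure under the ten-class RAD51-centred taxonomy."""
    return classify_structure(structure, rules or three_channel_rules())


def class_frequency_table(structures: Iterable[StructureCluster]) -> pd.DataFrame:
    """Count structures per class label.  The counts sum to the number of
    classified structures."""
    labels = [s.class_label for s in structures if s.class_label is not None]
    counts = pd.Series(labels, dtype=int).value_counts().sort_index()
    return pd.DataFrame({"class": counts.index, "count": counts.to_numpy()})


# ---------------------------------------------------------------------------
# Distance subclassification (class-5 structures)
# ---------------------------------------------------------------------------

#: Default core-to-satellite distance bins (post-expansion nm): contracted
#: (< 0.5 um), control-like (1.8-2 um) and extended (2-2.5 um) per the
#: measured phenotypes, with the intermediate interval auto-filled.
DEFAULT_DISTANCE_BINS_NM: tuple[tuple[float, float, str], ...] = (
    (0.0, 500.0, "contracted"),
    (500.0, 1800.0, "intermediate"),
    (1800.0, 2000.0, "control_like"),
    (2000.0, 2500.0, "extended"),
)


def subclassify_by_distance(
    structure: StructureCluster,
    bins: Sequence[tuple[float, float, str]] = DEFAULT_DISTANCE_BINS_NM,
    channel: str | None = None,
) -> str:
    """Bin a class-5 structure by its representative core-to-satellite
    distance (the **median** over partner spots).

    Distances beyond the last bin go to an ``"overflow"`` label with a
    warning rather than an error.
    """
    ch = channel or next(iter(structure.members))
    sats = structure.members.get(ch, np.empty((0, 3)))
    if len(sats) == 0:
        raise ExmError(
            f"structure {structure.structure_id} has no {ch!r} satellites to measure"
        )
    dist = float(np.median(np.linalg.norm(sats - structure.core_position, axis=1)))
    for lo, hi, label in bins:
        if lo < dist <= hi or (lo == 0.0 and dist == 0.0):
            structure.distance_subclass = label
            return label
    logger.warning(
        "structure %d: median satellite distance %.0f nm outside all bins",
        structure.structure_id,
        dist,
    )
    structure.distance_subclass = "overflow"
    return "overflow"


# ---------------------------------------------------------------------------
# Continuity subclassification
# ---------------------------------------------------------------------------

def continuity_test(
    crop: VoxelGrid,
    member_positions_nm: np.ndarray,
    intensity_fraction: float = 0.5,
) -> str:
    """Label a multi-spot accumulation ``"continuous"`` or ``"discontinuous"``.

    The crop is thresholded at ``intensity_fraction`` of its maximum;
    the accumulation is continuous iff at least two member-spot centres fall
    inside one connected foreground component (26-connectivity).
    Member positions are given in the crop's global physical frame (nm).
    """
    pts = np.asarray(member_positions_nm, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ExmError("continuity_test requires at least 2 member spots")
    if crop.data.ndim != 3:
        raise ValueError("continuity_test expects a single-channel crop")
    data = crop.data
    fg = data >= intensity_fraction * data.max()
    comp, _ = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
    idx = np.rint(crop.physical_to_index(pts)).astype(int)
    idx = np.clip(idx, 0, np.asarray(data.shape) - 1)
    labels_at_members = comp[idx[:, 0], idx[:, 1], idx[:, 2]]
    labels_at_members = labels_at_members[labels_at_members > 0]
    if len(labels_at_members) >= 2:
        vals, counts = np.unique(labels_at_members, return_counts=True)
        if counts.max() >= 2:
            return "continuous"
    return "discontinuous"


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

def crop_structure(
    stack: VoxelGrid, core_position_nm: np.ndarray, box_edge_nm: float = 5000.0
) -> VoxelGrid:
    """Axis-aligned cubic crop (default 5 µm edge) centred on a structure.

    Regions outside the image are zero-padded so every crop of a given edge
    has the same voxel shape; the crop's ``origin_nm`` keeps positions in
    the global frame.
    """
    if not box_edge_nm > 0:
        raise ValueError("box_edge_nm must be positive")
    core = np.asarray(core_position_nm, dtype=float).reshape(3)
    voxel = np.asarray(stack.voxel_size)
    shape = np.asarray(stack.spatial_shape)
    n = np.maximum(1, np.rint(box_edge_nm / voxel).astype(int))
    centre_idx = np.rint((core - np.asarray(stack.origin_nm)) / voxel - 0.5).astype(int)
    start = centre_idx - n // 2
    stop = start + n
    if np.any(stop <= 0) or np.any(start >= shape):
        raise ExmError("crop box does not intersect the image")

    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(stop, shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)

    multi = stack.data.ndim == 4
    out_shape = ((stack.data.shape[0],) if multi else ()) + tuple(n)
    out = np.zeros(out_shape, dtype=float)
    src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
    if multi:
        out[(slice(None),) + dst] = stack.data[(slice(None),) + src]
    else:
        out[dst] = stack.data[src]
    origin = np.asarray(stack.origin_nm) + start * voxel
    return VoxelGrid(out, tuple(voxel), stack.channels, tuple(origin))


# ---------------------------------------------------------------------------
# Manual-review mode
# ---------------------------------------------------------------------------

def export_crops_for_review(
    stack: VoxelGrid,
    structures: Sequence[StructureCluster],
    out_dir,
    box_edge_nm: float = 5000.0,
) -> "pd.DataFrame":
    """Write one crop TIFF per structure plus a label-template CSV.

    The automated rule-based labels operationalise the verbal class
    definitions; this file-based manual mode lets a reviewer inspect each
    crop (``structure_<id>.tif``) and fill in (or amend) the ``class``
    column of ``manual_labels.csv``, which :func:`ingest_manual_labels`
    reads back.
    """
    from pathlib import Path

    from .image import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in structures:
        crop = crop_structure(stack, s.core_position, box_edge_nm)
        write_volume(out / f"structure_{s.structure_id}.tif", crop)
        rows.append(
            {
                "structure_id": s.structure_id,
                "file": f"structure_{s.structure_id}.tif",
                "auto_class": s.class_label if s.class_label is not None else "",
                "class": "",
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "manual_labels.csv", index=False)
    return table


def ingest_manual_labels(structures: Sequence[StructureCluster], csv_path) -> int:
    """Apply hand-assigned class labels from a review CSV.

    Rows with an empty ``class`` field keep their automated label; returns
    the number of structures relabelled.
    """
    df = pd.read_csv(csv_path)
    if not {"structure_id", "class"}.issubset(df.columns):
        raise ExmError("manual label CSV needs 'structure_id' and 'class' columns")
    by_id = {s.structure_id: s for s in structures}
    n = 0
    for _, row in df.iterrows():
        if pd.isna(row["class"]) or row["class"] == "":
            continue
        sid = int(row["structure_id"])
        if sid not in by_id:
            raise ExmError(f"manual label for unknown structure id {sid}")
        by_id[sid].class_label = int(row["class"])
        n += 1
    return n
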