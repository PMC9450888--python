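"""Seeded synthetic 3D multi-channel scenes with planted ground truth.

No raw microscope data accompany the analyses this package reproduces, so
every downstream stage is exercised on simulated specimens that emulate
their essential features:

* S-phase-like nuclei (ellipsoidal masks with early/mid/late DNA textures)
  containing repair-focus structures planted according to the class
  taxonomies of :mod:`exmfoci.spots` — e.g. a central BRCA1 spot ringed by
  several 53BP1 satellites for a class-5 structure;
* an anisotropic Gaussian point-spread function, Poisson shot noise and
  Gaussian read noise;
* ~4x linear expansion modelled as a similarity transform (scale, rotation,
  translation) plus an optional smooth random distortion field, whose true
  parameters are recorded for recovery tests.

Geometry parameters are quoted in **post-expansion nm** (the frame the
analysis runs in); when a structure is planted in the pre-expansion scene
its geometry is divided by the expansion factor.

Everything is driven by a single integer seed: identical configuration and
seed give bit-identical volumes and ground-truth tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .image import VoxelGrid
from .registration import ControlPointSet, SimilarityTransform3D
from .spots import ClassRuleSet, classify_counts, three_channel_rules, two_channel_rules
from .units import ExmError

logger = logging.getLogger(__name__)

__all__ = [
    "GenerationError",
    "ClassGeometry",
    "SimulationConfig",
    "GroundTruth",
    "plant_structure",
    "render_volume",
    "simulate_expansion",
    "distortion_field",
    "generate_nucleus_scene",
    "generate_structure_scene",
    "match_to_ground_truth",
]


class GenerationError(ExmError):
    """Requested scene or structure geometry cannot be generated."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassGeometry:
    """Geometric parameters used to plant structures (post-expansion nm).

    ``satellite_radius_nm`` is the core-to-satellite distance of class-5
    rings; satellite counts for "multiple" classes default to 3-8, uniform.
    ``site_spread_nm`` bounds the distance of extra site spots from the
    first one in multi-site classes (must stay below the analysis link
    radius so a planted cluster is one connected component).
    """

    satellite_radius_nm: float = 650.0
    satellite_count_range: tuple[int, int] = (3, 8)
    satellite_arrangement: str = "ring"  # "ring" (tilted circle) or "sphere"
    tilt_range_deg: tuple[float, float] = (0.0, 90.0)
    satellite_jitter_deg: float = 8.0
    site_count_range: tuple[int, int] = (2, 3)
    site_spread_nm: tuple[float, float] = (800.0, 1200.0)
    min_site_separation_nm: float = 800.0
    partner_count_range: tuple[int, int] = (2, 4)
    partner_distance_nm: tuple[float, float] = (600.0, 1800.0)
    min_partner_separation_nm: float = 500.0

    def __post_init__(self) -> None:
        if self.satellite_radius_nm <= 0:
            raise GenerationError("satellite_radius_nm must be positive")
        if self.satellite_arrangement not in ("ring", "sphere"):
            raise GenerationError(f"unknown arrangement {self.satellite_arrangement!r}")

    def scaled(self, s: float) -> "ClassGeometry":
        """Geometry with all lengths multiplied by ``s`` (frame change)."""
        return dataclasses.replace(
            self,
            satellite_radius_nm=self.satellite_radius_nm * s,
            site_spread_nm=tuple(v * s for v in self.site_spread_nm),
            min_site_separation_nm=self.min_site_separation_nm * s,
            partner_distance_nm=tuple(v * s for v in self.partner_distance_nm),
            min_partner_separation_nm=self.min_partner_separation_nm * s,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic specimen.

    Identical config + seed give bit-identical outputs.  Defaults emulate a
    small irradiated S-phase nucleus imaged pre-expansion (SIM-like
    sampling) and post ~4x expansion (widefield/SPIM-like sampling).
    """

    taxonomy: str = "two_channel"  # or "three_channel"
    site_channel: str = "brca1"
    partner_channels: tuple[str, ...] = ("53bp1",)
    dna_channel: str = "dna"
    n_structures_per_class: dict = field(
        default_factory=lambda: {1: 3, 2: 3, 3: 2, 4: 2, 5: 4}
    )
    class_geometry: ClassGeometry = field(default_factory=ClassGeometry)
    s_phase: str = "mid"  # "early" | "mid" | "late" (cosmetic DNA texture)
    nucleus_semiaxes_pre_nm: tuple[float, float, float] = (1500.0, 3200.0, 4000.0)
    voxel_size_pre_nm: tuple[float, float, float] = (250.0, 120.0, 120.0)
    voxel_size_post_nm: tuple[float, float, float] = (250.0, 100.0, 100.0)
    psf_sigma_pre_nm: tuple[float, float, float] = (300.0, 120.0, 120.0)
    psf_sigma_post_nm: tuple[float, float, float] = (300.0, 100.0, 100.0)
    margin_pre_nm: float = 600.0
    spot_intensity: float = 2000.0
    dna_intensity: float = 80.0
    background: float = 20.0
    poisson_noise: bool = True
    gaussian_noise_sd: float = 2.0
    expansion_factor: float = 4.0
    distortion_amplitude_nm: float = 0.0
    distortion_scale_nm: float = 3000.0
    min_structure_separation_nm: float = 5000.0  # post frame
    seed: int = 0

    def rule_set(self) -> ClassRuleSet:
        if self.taxonomy == "two_channel":
            return two_channel_rules(self.site_channel, self.partner_channels[0])
        if self.taxonomy == "three_channel":
            return three_channel_rules(self.site_channel, *self.partner_channels)
        raise GenerationError(f"unknown taxonomy {self.taxonomy!r}")

    @property
    def image_channels(self) -> tuple[str, ...]:
        return (self.dna_channel, self.site_channel, *self.partner_channels)


@dataclass
class GroundTruth:
    """Planted spots, structure records and the true expansion transform.

    ``spots`` columns: ``spot_id, structure_id, channel, z, y, x`` (analysis
    = post-expansion frame, nm), ``pre_z, pre_y, pre_x`` (native frame, when
    a pre-expansion scene exists) and ``intensity``.  ``structures``
    columns: ``structure_id, class_id, taxonomy, core_z/y/x`` (post frame),
    per-channel counts, and for ring structures ``ring_radius_nm``,
    ``tilt_deg`` and the ring normal.
    """

    spots: pd.DataFrame
    structures: pd.DataFrame
    transform: SimilarityTransform3D | None
    distortion: dict
    seed: int

    def control_point_set(self) -> ControlPointSet:
        """Matched pre/post planted spot positions as registration landmarks."""
        if not {"pre_z", "pre_y", "pre_x"}.issubset(self.spots.columns):
            raise ExmError("ground truth has no pre-expansion coordinates")
        df = self.spots
        return ControlPointSet(
            df[["pre_z", "pre_y", "pre_x"]].to_numpy(),
            df[["z", "y", "x"]].to_numpy(),
            ids=df["spot_id"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# Structure planting
# ---------------------------------------------------------------------------

def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _ring_basis(tilt_deg: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (normal, e1, e2) for a ring whose normal makes
    ``tilt_deg`` with the optical (z) axis.  Axis order is (z, y, x)."""
    theta = np.radians(tilt_deg)
    phi = rng.uniform(0, 2 * np.pi)
    n = np.array([np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)])
    helper = np.array([0.0, 1.0, 0.0]) if abs(n[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return n, e1, e2


def _ring_points(
    centre: np.ndarray,
    radius: float,
    count: int,
    tilt_deg: float,
    jitter_deg: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced points on a tilted circle, with angular jitter bounded
    so neighbouring points never swap.  Returns (points, ring normal)."""
    n, e1, e2 = _ring_basis(tilt_deg, rng)
    base = np.linspace(0, 2 * np.pi, count, endpoint=False) + rng.uniform(0, 2 * np.pi)
    max_jitter = min(np.radians(jitter_deg), 0.3 * 2 * np.pi / count)
    ang = base + rng.uniform(-max_jitter, max_jitter, size=count)
    pts = centre + radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
    return pts, n


def _sphere_points(
    centre: np.ndarray, radius: float, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Near-uniform points on a sphere (jittered Fibonacci lattice) so the
    centre lies inside their convex hull for count >= 4."""
    i = np.arange(count)
    golden = (1 + 5**0.5) / 2
    zc = 1 - 2 * (i + 0.5) / count
    theta = 2 * np.pi * i / golden + rng.uniform(0, 2 * np.pi)
    r_xy = np.sqrt(np.clip(1 - zc**2, 0, 1))
    dirs = np.stack([zc, r_xy * np.sin(theta), r_xy * np.cos(theta)], axis=1)
    return centre + radius * dirs


def _scattered_points(
    centre: np.ndarray,
    count: int,
    distance_range: tuple[float, float],
    min_separation: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    pts: list[np.ndarray] = []
    for _ in range(count):
        for _try in range(max_tries):
            p = centre + rng.uniform(*distance_range) * _unit_vector(rng)
            if all(np.linalg.norm(p - q) >= min_separation for q in pts):
                pts.append(p)
                break
        else:
            raise GenerationError(
                f"could not place {count} spots at separation >= {min_separation} nm "
                f"within distance range {distance_range}"
            )
    return np.asarray(pts)


#: (site count sampler key, partner plan) per two-channel class.
_TWO_CHANNEL_PLANS = {1: "site_only", 2: "one_partner", 3: "multi_site_one_partner",
                      4: "multi_both", 5: "ring"}


def plant_structure(
    class_id: int,
    centre: np.ndarray,
    geometry: ClassGeometry,
    rng: np.random.Generator,
    taxonomy: str = "two_channel",
    site_channel: str = "brca1",
    partner_channels: tuple[str, ...] = ("53bp1",),
    rules: ClassRuleSet | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Plant one structure of ``class_id`` around ``centre`` (nm, z y x).

    Returns ``(record, spots)`` where ``spots`` has columns
    ``channel, z, y, x`` and ``record`` carries the class label, the core
    position (centre of mass of the site spots) and, for ring classes, the
    true ring radius, tilt and normal.  The planted arrangement is
    re-classified through the rule set as a self-check; a mismatch raises
    :class:`GenerationError`.
    """
    centre = np.asarray(centre, dtype=float).reshape(3)
    geom = geometry
    record: dict = {"class_id": int(class_id), "taxonomy": taxonomy}
    site_pts: np.ndarray
    partner_pts: dict[str, np.ndarray] = {ch: np.empty((0, 3)) for ch in partner_channels}
    ring_info: tuple | None = None

    def _multi_site() -> np.ndarray:
        n_site = int(rng.integers(geom.site_count_range[0], geom.site_count_range[1] + 1))
        extra = _scattered_points(
            centre, n_site - 1, geom.site_spread_nm, geom.min_site_separation_nm, rng
        )
        pts = np.vstack([centre[None, :], extra])
        # every extra site sits within site_spread of the first: one component
        return pts

    def _ring(k_range: tuple[int, int], ring_centre: np.ndarray) -> tuple[np.ndarray, tuple]:
        # satellites surround the site cluster's centre of mass
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        if geom.satellite_arrangement == "sphere":
            if k < 4:
                k = 4  # hull of <4 points cannot contain the core
            pts = _sphere_points(ring_centre, geom.satellite_radius_nm, k, rng)
            return pts, (geom.satellite_radius_nm, float("nan"), np.full(3, np.nan))
        tilt = rng.uniform(*geom.tilt_range_deg)
        pts, normal = _ring_points(
            ring_centre, geom.satellite_radius_nm, k, tilt, geom.satellite_jitter_deg, rng
        )
        return pts, (geom.satellite_radius_nm, tilt, normal)

    if taxonomy == "two_channel":
        partner = partner_channels[0]
        plan = _TWO_CHANNEL_PLANS.get(class_id)
        if plan is None:
            raise GenerationError(f"class {class_id} not in the two-channel taxonomy")
        if plan == "site_only":
            site_pts = centre[None, :]
        elif plan == "one_partner":
            site_pts = centre[None, :]
            partner_pts[partner] = _scattered_points(
                centre, 1, geom.partner_distance_nm, geom.min_partner_separation_nm, rng
            )
        elif plan == "multi_site_one_partner":
            site_pts = _multi_site()
            partner_pts[partner] = _scattered_points(
                centre, 1, geom.partner_distance_nm, geom.min_partner_separation_nm, rng
            )
        elif plan == "multi_both":
            site_pts = _multi_site()
            n_p = int(rng.integers(geom.partner_count_range[0], geom.partner_count_range[1] + 1))
            partner_pts[partner] = _scattered_points(
                centre, n_p, geom.partner_distance_nm, geom.min_partner_separation_nm, rng
            )
        else:  # ring -> class 5
            site_pts = centre[None, :]
            partner_pts[partner], ring_info = _ring(geom.satellite_count_range, centre)
    elif taxonomy == "three_channel":
        p53, brca = partner_channels
        plans = {
            1: (1, 0, 0), 2: (1, 1, 0), 3: (1, "multi", 0), 4: ("multi", "multi", 0),
            5: ("multi", 1, 0), 6: ("multi", 0, 0), 7: (1, "any", 1),
            8: ("multi", 1, 1), 9: ("multi", "ring", 1), 10: ("any", 0, 1),
        }
        if class_id not in plans:
            raise GenerationError(f"class {class_id} not in the three-channel taxonomy")
        r_plan, p_plan, b_count = plans[class_id]
        if r_plan == 1:
            site_pts = centre[None, :]
        elif r_plan == "multi":
            site_pts = _multi_site()
        else:  # any
            site_pts = centre[None, :] if rng.random() < 0.5 else _multi_site()
        if p_plan == "ring":
            partner_pts[p53], ring_info = _ring(geom.satellite_count_range, site_pts.mean(axis=0))
        elif p_plan == "multi":
            n_p = int(rng.integers(max(2, geom.partner_count_range[0]),
                                   geom.partner_count_range[1] + 1))
            partner_pts[p53] = _scattered_points(
                centre, n_p, geom.partner_distance_nm, geom.min_partner_separation_nm, rng
            )
        elif p_plan == "any":
            n_p = int(rng.integers(1, geom.partner_count_range[1] + 1))
            partner_pts[p53] = _scattered_points(
                centre, n_p, geom.partner_distance_nm, geom.min_partner_separation_nm, rng
            )
        elif p_plan == 1:
            partner_pts[p53] = _scattered_points(
                centre, 1, geom.partner_distance_nm, geom.min_partner_separation_nm, rng
            )
        if b_count:
            partner_pts[brca] = _scattered_points(
                centre, 1, geom.partner_distance_nm, geom.min_partner_separation_nm, rng
            )
    else:
        raise GenerationError(f"unknown taxonomy {taxonomy!r}")

    core = site_pts.mean(axis=0)
    record.update(
        core_z=core[0], core_y=core[1], core_x=core[2],
        n_site=len(site_pts),
        **{f"n_{ch}": len(partner_pts[ch]) for ch in partner_channels},
    )
    if ring_info is not None:
        record.update(
            ring_radius_nm=ring_info[0], tilt_deg=ring_info[1],
            normal_z=ring_info[2][0], normal_y=ring_info[2][1], normal_x=ring_info[2][2],
        )
    else:
        record.update(ring_radius_nm=np.nan, tilt_deg=np.nan,
                      normal_z=np.nan, normal_y=np.nan, normal_x=np.nan)

    # Self-check: the planted coordinates must classify as planted.
    ruleset = rules or (
        two_channel_rules(site_channel, partner_channels[0], None)
        if taxonomy == "two_channel"
        else three_channel_rules(site_channel, *partner_channels)
    )
    enc_ch = ruleset.encapsulation_channel
    got = classify_counts(
        ruleset,
        len(site_pts),
        {ch: len(partner_pts[ch]) for ch in partner_channels},
        core=core,
        satellites=partner_pts.get(enc_ch, np.empty((0, 3))),
    )
    if got != class_id:
        raise GenerationError(
            f"planted class {class_id} re-classifies as {got}; geometry violates the rule set"
        )

    rows = [{"channel": site_channel, "z": p[0], "y": p[1], "x": p[2]} for p in site_pts]
    for ch in partner_channels:
        rows += [{"channel": ch, "z": p[0], "y": p[1], "x": p[2]} for p in partner_pts[ch]]
    return record, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_volume(
    spots: pd.DataFrame,
    shape_vox: tuple[int, int, int],
    voxel_size_nm: tuple[float, float, float],
    channels: tuple[str, ...],
    psf_sigma_nm: tuple[float, float, float],
    intensity: float = 2000.0,
    background: float = 20.0,
    poisson_noise: bool = True,
    gaussian_noise_sd: float = 2.0,
    rng: np.random.Generator | None = None,
    base_image: np.ndarray | None = None,
) -> VoxelGrid:
    """Render planted spots into a noisy multi-channel volume.

    Each spot becomes a separable anisotropic Gaussian whose voxel sum
    equals its intensity (photon count), added to a constant background
    (plus an optional per-channel ``base_image``, e.g. a DNA texture).
    Poisson shot noise is applied first, then additive Gaussian read noise;
    the result is clipped at zero.  Spots outside the physical bounds are
    rendered clipped, with a warning.
    """
    rng = rng or np.random.default_rng(0)
    shape = tuple(int(n) for n in shape_vox)
    voxel = np.asarray(voxel_size_nm, dtype=float)
    sigma = np.asarray(psf_sigma_nm, dtype=float)
    vol = np.zeros((len(channels),) + shape, dtype=float)
    if base_image is not None:
        vol += base_image

    extent = np.asarray(shape) * voxel
    half = np.ceil(4 * sigma / voxel).astype(int)
    n_out = 0
    for row in spots.itertuples(index=False):
        ci = channels.index(row.channel)
        pos = np.array([row.z, row.y, row.x], dtype=float)
        amp = float(getattr(row, "intensity", np.nan))
        if not np.isfinite(amp):
            amp = intensity
        if np.any(pos < 0) or np.any(pos >= extent):
            n_out += 1
        cidx = pos / voxel - 0.5  # fractional voxel index of the spot centre
        lo = np.maximum(np.floor(cidx).astype(int) - half, 0)
        hi = np.minimum(np.floor(cidx).astype(int) + half + 1, shape)
        if np.any(hi <= lo):
            continue
        axes = [
            (np.arange(lo[a], hi[a]) - cidx[a]) * voxel[a] for a in range(3)
        ]
        gs = [
            np.exp(-0.5 * (ax / sigma[a]) ** 2) * voxel[a] / (sigma[a] * np.sqrt(2 * np.pi))
            for a, ax in enumerate(axes)
        ]
        kernel = amp * gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
        vol[ci, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += kernel
    if n_out:
        logger.warning("%d spot(s) outside the image bounds were clipped", n_out)

    vol += background
    if poisson_noise:
        vol = rng.poisson(np.clip(vol, 0, None)).astype(float)
    if gaussian_noise_sd > 0:
        vol = vol + rng.normal(0.0, gaussian_noise_sd, size=vol.shape)
    vol = np.clip(vol, 0, None)
    return VoxelGrid(vol, tuple(voxel), tuple(channels))


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------

def distortion_field(
    amplitude_nm: float, scale_nm: float, seed: int, n_modes: int = 8
):
    """Smooth random displacement field with RMS magnitude ``amplitude_nm``
    and correlation length ``scale_nm``: a band-limited sum of random
    harmonics.  Returns a callable mapping (n, 3) nm points to (n, 3)
    displacements."""
    rng = np.random.default_rng(seed)
    if amplitude_nm == 0:
        return lambda pts: np.zeros_like(np.atleast_2d(np.asarray(pts, dtype=float)))
    k_dirs = np.stack([_unit_vector(rng) for _ in range(n_modes)])
    k_mags = (2 * np.pi / scale_nm) * rng.uniform(0.5, 1.5, size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    u_dirs = np.stack([_unit_vector(rng) for _ in range(n_modes)])
    coeff = amplitude_nm * np.sqrt(2.0 / n_modes)

    def field(pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        phase = p @ (k_dirs * k_mags[:, None]).T + phases  # (n, modes)
        return coeff * np.sin(phase) @ u_dirs

    return field


def simulate_expansion(
    points: np.ndarray,
    factor: float = 4.0,
    distortion_amplitude_nm: float = 0.0,
    distortion_scale_nm: float = 3000.0,
    seed: int = 0,
    rotation: np.ndarray | None = None,
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, SimilarityTransform3D]:
    """Map pre-expansion coordinates into the post-expansion frame.

    ``y = s R x + t + d(s R x + t)`` where *d* is a smooth random field of
    RMS amplitude ``distortion_amplitude_nm`` (zero amplitude gives a pure
    similarity).  Returns the mapped points and the **true** similarity
    transform for recovery tests.
    """
    if not factor > 0:
        raise ValueError("expansion factor must be positive")
    if distortion_amplitude_nm < 0:
        raise ValueError("distortion amplitude must be >= 0")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    transform = SimilarityTransform3D.from_matrix(factor, R, translation)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    mapped = transform.apply(pts)
    field = distortion_field(distortion_amplitude_nm, distortion_scale_nm, seed)
    out = mapped + field(mapped)
    return (out if np.asarray(points).ndim > 1 else out[0]), transform


# ---------------------------------------------------------------------------
# Nucleus scene
# ---------------------------------------------------------------------------

def _ellipsoid_rho(shape, voxel, centre_nm, semiaxes_nm) -> np.ndarray:
    """Normalised ellipsoid coordinate (rho <= 1 inside) on the voxel grid."""
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * v for n, v in zip(shape, voxel)], indexing="ij"
    )
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre_nm, semiaxes_nm))
    return np.sqrt(rho2)


def _dna_texture(rho: np.ndarray, preset: str, rng: np.random.Generator) -> np.ndarray:
    """Cosmetic S-phase-like DNA pattern inside the nucleus (rho <= 1).

    early: diffuse; mid: patchy interior blobs; late: brighter periphery.
    Textures keep the whole interior well above background so intensity
    segmentation sees one body per nucleus; classification never reads this
    channel."""
    # soft antialiased edge, width ~5% of the semi-axes
    soft = np.clip((1.0 - rho) / 0.05, 0, 1)
    noise = rng.normal(size=rho.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=2.0)
    smooth = (smooth - smooth.min()) / max(float(np.ptp(smooth)), 1e-12)
    if preset == "early":
        tex = 0.8 + 0.4 * smooth
    elif preset == "mid":
        tex = 0.75 + 0.85 * smooth**2
    elif preset == "late":
        shell = np.clip((rho - 0.6) / 0.4, 0, 1)
        tex = 0.6 + 1.0 * shell * (0.5 + 0.5 * smooth)
    else:
        raise GenerationError(f"unknown s_phase preset {preset!r}")
    return soft * tex


def _sample_centres(
    n: int,
    semiaxes_nm: np.ndarray,
    centre_nm: np.ndarray,
    margin_frac: float,
    min_separation_nm: float,
    rng: np.random.Generator,
    max_tries: int = 5000,
) -> np.ndarray:
    out: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(max_tries):
            u = rng.uniform(-1, 1, size=3)
            if np.sum(u**2) > 1:
                continue
            p = centre_nm + u * semiaxes_nm * margin_frac
            if all(np.linalg.norm(p - q) >= min_separation_nm for q in out):
                out.append(p)
                break
        else:
            raise GenerationError(
                f"could not place {n} structures at separation >= "
                f"{min_separation_nm:.0f} nm inside the nucleus; enlarge the "
                "nucleus or reduce the structure count"
            )
    return np.asarray(out).reshape(n, 3)


def _assemble_truth(
    records: list[dict], spot_frames: list[pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    structures = pd.DataFrame(records)
    structures.insert(0, "structure_id", np.arange(len(records)))
    all_spots = []
    for sid, df in enumerate(spot_frames):
        df = df.copy()
        df.insert(0, "structure_id", sid)
        all_spots.append(df)
    spots = pd.concat(all_spots, ignore_index=True) if all_spots else pd.DataFrame(
        columns=["structure_id", "channel", "z", "y", "x"]
    )
    spots.insert(0, "spot_id", np.arange(len(spots)))
    return spots, structures


def generate_nucleus_scene(
    config: SimulationConfig,
) -> tuple[VoxelGrid, VoxelGrid, GroundTruth]:
    """Simulate one nucleus pre- and post-expansion with matched truth.

    The pre-expansion scene holds an ellipsoidal nucleus with an S-phase
    DNA texture and the configured structures planted inside it (geometry
    scaled down by the expansion factor); the post-expansion scene is the
    similarity-mapped (plus optional distortion) rendering of the same
    ground truth.  Returns ``(pre, post, truth)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    semi_pre = np.asarray(cfg.nucleus_semiaxes_pre_nm, dtype=float)
    voxel_pre = np.asarray(cfg.voxel_size_pre_nm, dtype=float)
    margin = cfg.margin_pre_nm
    shape_pre = tuple(int(np.ceil((2 * a + 2 * margin) / v)) for a, v in zip(semi_pre, voxel_pre))
    centre_pre = np.asarray(shape_pre) * voxel_pre / 2

    f = cfg.expansion_factor
    n_total = int(sum(cfg.n_structures_per_class.values()))
    centres = _sample_centres(
        n_total, semi_pre, centre_pre, 0.75, cfg.min_structure_separation_nm / f, rng
    )

    rules = cfg.rule_set()
    geom_pre = cfg.class_geometry.scaled(1.0 / f)
    records: list[dict] = []
    frames: list[pd.DataFrame] = []
    i = 0
    for class_id in sorted(cfg.n_structures_per_class):
        for _ in range(cfg.n_structures_per_class[class_id]):
            rec, spot_df = plant_structure(
                class_id, centres[i], geom_pre, rng,
                taxonomy=cfg.taxonomy, site_channel=cfg.site_channel,
                partner_channels=cfg.partner_channels, rules=rules,
            )
            records.append(rec)
            frames.append(spot_df)
            i += 1
    spots_pre, structures = _assemble_truth(records, frames)

    # Map ground truth into the post-expansion frame.
    pre_xyz = spots_pre[["z", "y", "x"]].to_numpy()
    post_xyz, transform = simulate_expansion(
        pre_xyz, f, cfg.distortion_amplitude_nm, cfg.distortion_scale_nm, seed=cfg.seed + 1,
    )
    spots = spots_pre.rename(columns={"z": "pre_z", "y": "pre_y", "x": "pre_x"})
    spots[["z", "y", "x"]] = post_xyz
    spots["intensity"] = cfg.spot_intensity

    # Structure records in the post frame (core = mean of mapped site spots).
    for rec_id in structures["structure_id"]:
        m = (spots["structure_id"] == rec_id) & (spots["channel"] == cfg.site_channel)
        core = spots.loc[m, ["z", "y", "x"]].to_numpy().mean(axis=0)
        structures.loc[structures["structure_id"] == rec_id, ["core_z", "core_y", "core_x"]] = core
    structures["ring_radius_nm"] *= f  # planted at pre-frame radius, reported post  # planted pre-frame radius, reported post
    truth = GroundTruth(
        spots=spots,
        structures=structures,
        transform=transform,
        distortion={
            "amplitude_nm": cfg.distortion_amplitude_nm,
            "scale_nm": cfg.distortion_scale_nm,
            "seed": cfg.seed + 1,
        },
        seed=cfg.seed,
    )

    # --- pre-expansion render ---
    rho_pre = _ellipsoid_rho(shape_pre, voxel_pre, centre_pre, semi_pre)
    dna_pre = cfg.dna_intensity * _dna_texture(rho_pre, cfg.s_phase, np.random.default_rng(cfg.seed + 2))
    base_pre = np.zeros((len(cfg.image_channels),) + shape_pre)
    base_pre[0] = dna_pre
    spots_render_pre = spots_pre.assign(intensity=cfg.spot_intensity)
    pre = render_volume(
        spots_render_pre, shape_pre, tuple(voxel_pre), cfg.image_channels,
        cfg.psf_sigma_pre_nm, cfg.spot_intensity, cfg.background,
        cfg.poisson_noise, cfg.gaussian_noise_sd,
        rng=np.random.default_rng(cfg.seed + 3), base_image=base_pre,
    )

    # --- post-expansion render (identity rotation: extent scales directly) ---
    voxel_post = np.asarray(cfg.voxel_size_post_nm, dtype=float)
    shape_post = tuple(
        int(np.ceil(e * f / v)) for e, v in zip(pre.physical_extent, voxel_post)
    )
    rho_post = _ellipsoid_rho(shape_post, voxel_post, centre_pre * f, semi_pre * f)
    dna_post = cfg.dna_intensity * _dna_texture(rho_post, cfg.s_phase, np.random.default_rng(cfg.seed + 4))
    base_post = np.zeros((len(cfg.image_channels),) + shape_post)
    base_post[0] = dna_post
    post = render_volume(
        spots, shape_post, tuple(voxel_post), cfg.image_channels,
        cfg.psf_sigma_post_nm, cfg.spot_intensity, cfg.background,
        cfg.poisson_noise, cfg.gaussian_noise_sd,
        rng=np.random.default_rng(cfg.seed + 5), base_image=base_post,
    )
    return pre, post, truth


# ---------------------------------------------------------------------------
# Flat structure scene (no nucleus): dense ground truth for detector and
# classifier benchmarks
# ---------------------------------------------------------------------------

def generate_structure_scene(
    n_per_class: dict[int, int],
    config: SimulationConfig | None = None,
    seed: int = 0,
    pitch_nm: float = 5200.0,
) -> tuple[VoxelGrid, GroundTruth]:
    """Post-expansion-frame scene with structures on a jittered grid.

    Used for detector/classifier recovery benchmarks where a nuclear
    context is irrelevant: structures are planted directly at analysis-frame
    geometry on an XY grid (one Z plane of structures), rendered with the
    post-expansion PSF and noise model.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    n_total = int(sum(n_per_class.values()))
    nx = int(np.ceil(np.sqrt(n_total)))
    ny = int(np.ceil(n_total / nx))
    margin = 2600.0
    voxel = np.asarray(cfg.voxel_size_post_nm, dtype=float)
    z_half = 3200.0
    extent = (
        2 * z_half,
        margin * 2 + (ny - 1) * pitch_nm,
        margin * 2 + (nx - 1) * pitch_nm,
    )
    shape = tuple(int(np.ceil(e / v)) for e, v in zip(extent, voxel))

    class_list = [c for c in sorted(n_per_class) for _ in range(n_per_class[c])]
    order = rng.permutation(n_total)
    jit = pitch_nm * 0.08
    records, frames = [], []
    for slot, idx in enumerate(order):
        class_id = class_list[idx]
        gy, gx = divmod(slot, nx)
        centre = np.array(
            [
                z_half + rng.uniform(-300, 300),
                margin + gy * pitch_nm + rng.uniform(-jit, jit),
                margin + gx * pitch_nm + rng.uniform(-jit, jit),
            ]
        )
        rec, df = plant_structure(
            class_id, centre, cfg.class_geometry, rng,
            taxonomy=cfg.taxonomy, site_channel=cfg.site_channel,
            partner_channels=cfg.partner_channels,
        )
        records.append(rec)
        frames.append(df)
    spots, structures = _assemble_truth(records, frames)
    spots["intensity"] = cfg.spot_intensity

    render_channels = (cfg.site_channel, *cfg.partner_channels)
    grid = render_volume(
        spots, shape, tuple(voxel), render_channels, cfg.psf_sigma_post_nm,
        cfg.spot_intensity, cfg.background, cfg.poisson_noise,
        cfg.gaussian_noise_sd, rng=np.random.default_rng(seed + 1),
    )
    truth = GroundTruth(
        spots=spots, structures=structures, transform=None,
        distortion={"amplitude_nm": 0.0}, seed=seed,
    )
    return grid, truth


def match_to_ground_truth(
    detected: np.ndarray, truth: np.ndarray, max_distance_nm: float
) -> np.ndarray:
    """For each detected position, the index of the nearest ground-truth
    position within ``max_distance_nm`` (-1 if none)."""
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if len(truth) == 0:
        return np.full(len(detected), -1)
    tree = cKDTree(truth)
    dist, idx = tree.query(detected)
    return np.where(dist <= max_distance_nm, idx, -1)
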