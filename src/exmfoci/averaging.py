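"""Average focus structures, radial profiles and profile measurements.

To measure the typical geometry of a class-5 focus (a central site-channel
spot ringed by partner satellites), structures oriented roughly parallel to
the focal plane are selected, their crops are averaged voxel-wise (aligned
by translation only — the core sits at the crop centre), and a **radial
intensity profile** is computed per channel by binning central-slice pixels
into fixed-width concentric bands around the centre.

From the profile come the quantities reported for such structures:

* ``peak_to_peak`` — twice the radius of the annular intensity maximum of
  the satellite channel (a symmetric average profile has its two peaks at
  ±r).  A profile whose maximum sits in the innermost band has no annular
  peak — the "void lost" phenotype — and is flagged instead.
* ``span`` — twice the outermost radius at which a channel's profile still
  reaches a given fraction (default half) of its maximum.
* ``gap`` — the empty interval between the core's outer edge and the
  satellite ring's inner edge at that same fraction, clamped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .image import VoxelGrid
from .spots import StructureCluster
from .units import ExmError, PhysicalLength

logger = logging.getLogger(__name__)

__all__ = [
    "AverageStructure",
    "RadialProfile",
    "PeakMeasurement",
    "UndefinedSpanError",
    "select_in_plane",
    "average_structures",
    "radial_profile",
    "peak_to_peak",
    "span_and_gap",
]


class UndefinedSpanError(ExmError):
    """A flat profile has no half-maximum edges."""


@dataclass
class AverageStructure:
    """Voxel-wise mean of aligned structure crops."""

    mean: VoxelGrid
    n: int
    contributor_ids: tuple[int, ...]


@dataclass
class RadialProfile:
    """Mean central-slice intensity per fixed-width concentric band.

    ``radii_nm`` are band-centre radii ``(i + 0.5) * band_width``;
    ``values[channel]`` is the mean intensity of the pixels in each band and
    ``n_pixels`` the band populations.
    """

    band_width_nm: float
    radii_nm: np.ndarray
    values: dict[str, np.ndarray]
    n_pixels: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return self.values[name]


def select_in_plane(
    structures: list[StructureCluster],
    max_tilt_deg: float = 20.0,
    band_width_nm: float = 100.0,
    channel: str | None = None,
) -> list[StructureCluster]:
    """Keep structures whose satellite ring lies roughly in a focal plane.

    The best-fit plane through the partner spots (principal-axes fit) must
    have its normal within ``max_tilt_deg`` of the optical (z) axis, and
    the core must lie within half a band width of that plane.  Structures
    with fewer than 3 partner spots have no defined plane and are skipped
    with a log entry.
    """
    selected = []
    for s in structures:
        ch = channel or next(iter(s.members), None)
        sats = s.members.get(ch, np.empty((0, 3))) if ch else np.empty((0, 3))
        if len(sats) < 3:
            logger.info(
                "structure %d skipped: %d partner spots, plane undefined",
                s.structure_id, len(sats),
            )
            continue
        centred = sats - sats.mean(axis=0)
        _, _, vt = np.linalg.svd(centred)
        normal = vt[-1]
        tilt = np.degrees(np.arccos(np.clip(abs(normal[0]), 0.0, 1.0)))  # z axis first
        if tilt > max_tilt_deg:
            continue
        core_off = abs(float((s.core_position - sats.mean(axis=0)) @ normal))
        if core_off > band_width_nm / 2:
            continue
        selected.append(s)
    return selected


def average_structures(crops: list[VoxelGrid], ids: list[int] | None = None) -> AverageStructure:
    """Voxel-wise arithmetic mean of same-shape, same-voxel-size crops."""
    if not crops:
        raise ExmError("average_structures requires at least one crop")
    ref = crops[0]
    for c in crops[1:]:
        if c.data.shape != ref.data.shape or c.voxel_size != ref.voxel_size:
            raise ExmError("all crops must share shape and voxel size")
    mean = np.mean([c.data for c in crops], axis=0)
    grid = VoxelGrid(mean, ref.voxel_size, ref.channels)
    ids = list(range(len(crops))) if ids is None else list(ids)
    return AverageStructure(mean=grid, n=len(crops), contributor_ids=tuple(ids))


def radial_profile(
    avg: AverageStructure | VoxelGrid,
    band_width_nm: float,
    channels: list[str] | None = None,
) -> RadialProfile:
    """Radial intensity profile of the central Z slice.

    Each pixel joins band ``floor(distance_to_centre / band_width)``; the
    profile value of a band is the mean intensity of its pixels.  The
    centre is the crop's physical centre (where the core was aligned).
    """
    grid = avg.mean if isinstance(avg, AverageStructure) else avg
    if band_width_nm < min(grid.voxel_size[1:]):
        raise ValueError("band width must be at least one pixel")
    multi = grid.data.ndim == 4
    names = list(grid.channels) if grid.channels else ["intensity"]
    if channels is not None:
        names = [c for c in names if c in channels]

    nz, ny, nx = grid.spatial_shape
    zc = nz // 2
    dy, dx = grid.voxel_size[1], grid.voxel_size[2]
    yy = ((np.arange(ny) + 0.5) * dy - ny * dy / 2.0)[:, None]
    xx = ((np.arange(nx) + 0.5) * dx - nx * dx / 2.0)[None, :]
    dist = np.sqrt(yy**2 + xx**2)
    band = np.floor(dist / band_width_nm).astype(int)
    n_bands = band.max() + 1
    counts = np.bincount(band.ravel(), minlength=n_bands)

    values: dict[str, np.ndarray] = {}
    for name in names:
        if multi:
            sl = grid.data[grid.channels.index(name), zc]
        else:
            sl = grid.data[zc]
        sums = np.bincount(band.ravel(), weights=sl.ravel().astype(float), minlength=n_bands)
        with np.errstate(invalid="ignore"):
            values[name] = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    radii = (np.arange(n_bands) + 0.5) * band_width_nm
    return RadialProfile(band_width_nm, radii, values, counts)


@dataclass(frozen=True)
class PeakMeasurement:
    """Result of :func:`peak_to_peak`."""

    peak_to_peak: PhysicalLength
    peak_radius_nm: float
    flag: str | None = None  # "no annular peak" when the maximum is central


def peak_to_peak(profile: RadialProfile, channel: str) -> PeakMeasurement:
    """Peak-to-peak distance of a channel's radial distribution.

    Twice the radius of the global profile maximum, refined by a
    three-point quadratic fit over the neighbouring bands.  If the maximum
    sits in the innermost band the distribution peaks at the centre (no
    annular ring — e.g. a collapsed satellite shell) and the measurement is
    0 with flag ``"no annular peak"``.
    """
    v = np.asarray(profile.channel(channel), dtype=float)
    if len(v) < 3:
        raise ExmError("peak_to_peak requires a profile with at least 3 bands")
    i = int(np.argmax(v))
    if i == 0:
        return PeakMeasurement(
            PhysicalLength(0.0, "nm", "post_expansion"), 0.0, flag="no annular peak"
        )
    if 0 < i < len(v) - 1:
        denom = v[i - 1] - 2 * v[i] + v[i + 1]
        delta = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom < 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    radius = (i + delta + 0.5) * profile.band_width_nm
    return PeakMeasurement(PhysicalLength(2 * radius, "nm", "post_expansion"), radius)


def _outer_edge_radius(radii: np.ndarray, v: np.ndarray, level: float, bw: float) -> float:
    """Outermost radius at which the profile still reaches ``level``,
    linearly interpolated on the outward crossing."""
    above = np.nonzero(v >= level)[0]
    i = int(above[-1])
    if i == len(v) - 1:
        return float(radii[i])
    r0, r1, v0, v1 = radii[i], radii[i + 1], v[i], v[i + 1]
    return float(r0 + (v0 - level) / max(v0 - v1, 1e-300) * (r1 - r0))


def _inner_edge_radius(radii: np.ndarray, v: np.ndarray, level: float) -> float:
    """Innermost radius at which the profile reaches ``level`` (inward
    crossing, interpolated)."""
    above = np.nonzero(v >= level)[0]
    i = int(above[0])
    if i == 0:
        return float(radii[0])
    r0, r1, v0, v1 = radii[i - 1], radii[i], v[i - 1], v[i]
    return float(r1 - (v1 - level) / max(v1 - v0, 1e-300) * (r1 - r0))


def span_and_gap(
    profile: RadialProfile,
    site_channel: str,
    partner_channel: str,
    fraction: float = 0.5,
) -> dict[str, PhysicalLength]:
    """Core span, satellite span, and the radial gap between them.

    ``span = 2 x`` the outermost radius at which a channel's profile is at
    least ``fraction`` of its maximum; ``gap`` is the satellite channel's
    inner edge minus the core channel's outer edge at the same fraction,
    clamped at 0 (overlapping distributions — the "void lost" phenotype —
    report a zero gap).  All lengths are post-expansion nm.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    out: dict[str, PhysicalLength] = {}
    edges: dict[str, tuple[float, float]] = {}
    for role, ch in (("core", site_channel), ("partner", partner_channel)):
        v = np.asarray(profile.channel(ch), dtype=float)
        if np.ptp(v) == 0:
            raise UndefinedSpanError(f"channel {ch!r} has a flat radial profile")
        level = fraction * v.max()
        outer = _outer_edge_radius(profile.radii_nm, v, level, profile.band_width_nm)
        inner = _inner_edge_radius(profile.radii_nm, v, level)
        edges[role] = (inner, outer)
        out[f"{role}_span"] = PhysicalLength(2 * outer, "nm", "post_expansion")
    gap = max(0.0, edges["partner"][0] - edges["core"][1])
    out["gap"] = PhysicalLength(gap, "nm", "post_expansion")
    return out
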