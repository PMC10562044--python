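"""Digital phantoms for Lu-177 planar scintigraphy simulation.

Every phantom is a :class:`VoxelPhantom`: a voxelized activity map (MBq per
voxel) co-registered with a linear-attenuation map at 208 keV (1/mm).  The
coordinate convention used throughout the package is ``(x, y, z)`` with the
projection (depth) axis along ``y``: the anterior camera views the volume
from the -y side, the posterior camera from +y.  Axial is ``z``.

The Hoffman brain phantom and the NCAT anthropomorphic phantom used in the
original study are licensed voxel datasets; this module ships parametric
look-alikes (a folded two-compartment "brain" and an ellipsoidal torso with
liver, spleen and two kidneys).  They are surrogates that match the *role*
of those phantoms (anatomical complexity, realistic organ layout), not their
exact anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

#: linear attenuation coefficient of water at 208 keV, 1/mm
#: (interpolated from NIST XCOM mass-attenuation data, narrow beam)
MU_WATER_208KEV = 0.0136

#: water density used for MBq/kg -> MBq/cm^3 conversions, g/cm^3
WATER_DENSITY_G_CM3 = 1.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VoxelPhantom:
    """Co-registered activity (MBq/voxel) and attenuation (1/mm) grids."""

    activity: np.ndarray
    attenuation: np.ndarray
    voxel_size: tuple[float, float, float]
    name: str = "phantom"

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=np.float64)
        self.attenuation = np.asarray(self.attenuation, dtype=np.float64)
        if self.activity.shape != self.attenuation.shape:
            raise ValueError("activity and attenuation grids must share shape")
        if self.activity.ndim != 3:
            raise ValueError("phantom grids must be 3D")
        if np.any(self.activity < 0):
            raise ValueError("activity must be non-negative")
        if np.any(self.attenuation < 0):
            raise ValueError("attenuation must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.activity.shape

    def scaled(self, factor: float, name: str | None = None) -> "VoxelPhantom":
        """Return a copy with the activity map scaled by ``factor``."""
        return VoxelPhantom(self.activity * factor, self.attenuation,
                            self.voxel_size, name or self.name)


@dataclass
class OrganLabelMap:
    """Integer label grid: 0 = background, k > 0 = named structure."""

    labels: np.ndarray
    organ_names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.organ_names)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class RodSpec:
    """Geometry and activity of the hot-rod resolution phantom.

    Defaults reproduce the study object: a 340 mm diameter, 78 mm tall
    cylinder holding one rod per diameter in {10, 13, 17, 22, 28, 33} mm,
    rods at 10 MBq/kg and background at rods/TBR.
    """

    diameters: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 33.0)
    height: float = 78.0
    phantom_diameter: float = 340.0
    rod_concentration: float = 10.0  # MBq/kg
    tbr: float = 5.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.diameters):
            raise ValueError("rod diameters must be positive")
        if self.tbr < 1:
            raise ValueError("target-to-background ratio must be >= 1")

    def rod_volume_cm3(self) -> float:
        """Exact summed cylinder volume of the rods, cm^3."""
        r_cm = np.asarray(self.diameters) / 20.0
        return float(np.sum(np.pi * r_cm**2 * self.height / 10.0))

    def phantom_volume_cm3(self) -> float:
        r_cm = self.phantom_diameter / 20.0
        return float(np.pi * r_cm**2 * self.height / 10.0)


@dataclass
class TimeActivityCurve:
    """Per-organ percent-injected-activity samples over time."""

    times: np.ndarray  # hours post injection, strictly increasing
    values: dict[str, np.ndarray]  # organ -> %IA at each time
    injected_activity: float = 700.0  # MBq

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for organ, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.times.shape:
                raise ValueError(f"curve for {organ} does not match times")
            if np.any(v < 0) or np.any(v > 100):
                raise ValueError("%IA must lie in [0, 100]")
            self.values[organ] = v

    @property
    def organs(self) -> list[str]:
        return list(self.values)

    def percent_ia(self, organ: str, time_h: float,
                   extrapolate: bool = False) -> float:
        t = np.asarray(self.times)
        if not extrapolate and not (t[0] <= time_h <= t[-1]):
            raise ValueError(
                f"time {time_h} h outside curve support [{t[0]}, {t[-1]}]; "
                "pass extrapolate=True to allow")
        return float(np.interp(time_h, t, self.values[organ]))

    def activity_mbq(self, organ: str, time_h: float,
                     extrapolate: bool = False) -> float:
        return self.percent_ia(organ, time_h, extrapolate) / 100.0 \
            * self.injected_activity


@dataclass
class TrainingCorpusSpec:
    """Layout of the slice-duplication training corpus.

    Each base phantom is interpolated to ``matrix x matrix x n_slices`` and
    every axial slice is duplicated ``n_duplicates`` times along the depth
    axis, giving one thin-slab scene per slice; two base phantoms yield
    ``2 * n_slices`` scenes (300 by default).  Per-scene total activities are
    spaced evenly across the configured range of each family.
    """

    n_slices: int = 150
    n_duplicates: int = 30
    matrix: int = 256
    activity_range_a: tuple[float, float] = (2.88, 20.6)  # MBq
    activity_range_b: tuple[float, float] = (1.36, 31.0)  # MBq

    def __post_init__(self) -> None:
        for lo, hi in (self.activity_range_a, self.activity_range_b):
            if lo <= 0 or hi <= 0:
                raise ValueError("activity ranges must be positive")

    @property
    def n_sets(self) -> int:
        return 2 * self.n_slices


# ---------------------------------------------------------------------------
# Shepp-Logan
# ---------------------------------------------------------------------------

# 3D Shepp-Logan ellipsoids (modified intensities): value, semi-axes a,b,c,
# center x0,y0,z0, rotation about z in degrees.  Normalized coordinates.
_SHEPP_LOGAN_3D = [
    (1.00, 0.6900, 0.9200, 0.810, 0.0, 0.0, 0.0, 0.0),
    (-0.80, 0.6624, 0.8740, 0.780, 0.0, -0.0184, 0.0, 0.0),
    (-0.20, 0.1100, 0.3100, 0.220, 0.22, 0.0, 0.0, -18.0),
    (-0.20, 0.1600, 0.4100, 0.280, -0.22, 0.0, 0.0, 18.0),
    (0.10, 0.2100, 0.2500, 0.410, 0.0, 0.35, -0.15, 0.0),
    (0.10, 0.0460, 0.0460, 0.050, 0.0, 0.10, 0.25, 0.0),
    (0.10, 0.0460, 0.0460, 0.050, 0.0, -0.10, 0.25, 0.0),
    (0.10, 0.0460, 0.0230, 0.050, -0.08, -0.605, 0.0, 0.0),
    (0.10, 0.0230, 0.0230, 0.020, 0.0, -0.606, 0.0, 0.0),
    (0.10, 0.0230, 0.0460, 0.020, 0.06, -0.605, 0.0, 0.0),
]


def _normalized_grid(shape: Sequence[int]):
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def shepp_logan_support(shape: Sequence[int]) -> np.ndarray:
    """Boolean mask of the outer head ellipsoid on a normalized grid."""
    x, y, z = _normalized_grid(shape)
    a, b, c = _SHEPP_LOGAN_3D[0][1:4]
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


def make_shepp_logan(shape: Sequence[int] = (128, 128, 96),
                     voxel_size: tuple[float, float, float] = (2.2, 2.2, 2.2),
                     total_activity: float | None = None,
                     mu_water: float = MU_WATER_208KEV) -> VoxelPhantom:
    """3D Shepp-Logan head phantom with intensities mapped to activity.

    Attenuation is water inside the outer ellipsoid, zero outside.  When
    ``total_activity`` (MBq) is given the activity map is scaled to that
    total; otherwise raw ellipsoid intensities are used.
    """
    shape = tuple(int(n) for n in shape)
    if any(n <= 0 for n in shape):
        raise ValueError("shape must be positive")
    x, y, z = _normalized_grid(shape)
    act = np.zeros(shape, dtype=np.float64)
    for val, a, b, c, x0, y0, z0, phi in _SHEPP_LOGAN_3D:
        ph = np.deg2rad(phi)
        xr = (x - x0) * np.cos(ph) + (y - y0) * np.sin(ph)
        yr = -(x - x0) * np.sin(ph) + (y - y0) * np.cos(ph)
        inside = (xr / a) ** 2 + (yr / b) ** 2 + ((z - z0) / c) ** 2 <= 1.0
        act[inside] += val
    act = np.clip(act, 0.0, None)
    support = shepp_logan_support(shape)
    act[~support] = 0.0
    if total_activity is not None:
        s = act.sum()
        if s > 0:
            act *= total_activity / s
    atten = np.where(support, mu_water, 0.0)
    return VoxelPhantom(act, atten, voxel_size, name="shepp_logan")


# ---------------------------------------------------------------------------
# parametric brain look-alike (Hoffman surrogate)
# ---------------------------------------------------------------------------

def make_brain_like(shape: Sequence[int] = (128, 128, 96),
                    voxel_size: tuple[float, float, float] = (2.2, 2.2, 2.2),
                    seed: int = 0,
                    gm_wm_ratio: float = 4.0,
                    total_activity: float | None = None,
                    mu_water: float = MU_WATER_208KEV) -> VoxelPhantom:
    """Parametric brain-like phantom: folded high/low activity compartments.

    A smooth random field inside a head-shaped ellipsoid is thresholded at
    its median into a convoluted "grey matter" compartment (activity
    ``gm_wm_ratio``) and a "white matter" compartment (activity 1).  The
    pattern is deterministic under ``seed``.  This is a synthetic surrogate
    for the licensed Hoffman voxel phantom: it matches its role (high
    anatomical complexity at a 4:1 grey:white uptake ratio), not its anatomy.
    """
    shape = tuple(int(n) for n in shape)
    if any(n <= 0 for n in shape):
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    x, y, z = _normalized_grid(shape)
    support = (x / 0.85) ** 2 + (y / 0.92) ** 2 + (z / 0.80) ** 2 <= 1.0
    noise = rng.standard_normal(shape)
    sigma = max(1.0, min(shape) / 16.0)
    folded = ndimage.gaussian_filter(noise, sigma)
    inside_vals = folded[support]
    thr = np.median(inside_vals)
    act = np.zeros(shape, dtype=np.float64)
    act[support] = np.where(folded[support] >= thr, gm_wm_ratio, 1.0)
    if total_activity is not None:
        act *= total_activity / act.sum()
    atten = np.where(support, mu_water, 0.0)
    return VoxelPhantom(act, atten, voxel_size, name="brain_like")


# ---------------------------------------------------------------------------
# Derenzo-style hot-rod phantom
# ---------------------------------------------------------------------------

def derenzo_booked_activity(spec: RodSpec,
                            rod_volume_cm3: float = 180.0,
                            total_volume_cm3: float = 7000.0) -> float:
    """Total phantom activity (MBq) from book-keeping volumes.

    Uses the conventional rounded volumes (180 cm^3 of rods in a 7000 cm^3
    cylinder) and unit water density: with 10 MBq/kg rods this gives
    15.44 MBq at TBR 5:1 and 5.21 MBq at TBR 20:1.
    """
    conc = spec.rod_concentration * WATER_DENSITY_G_CM3 / 1000.0  # MBq/cm^3
    return conc * (rod_volume_cm3 + (total_volume_cm3 - rod_volume_cm3) / spec.tbr)


def _default_rod_centers(spec: RodSpec) -> list[tuple[float, float]]:
    """One rod centre per diameter, evenly spread on a ring (mm, in-plane).

    The original phantom's exact sector layout is not documented; the ring
    layout is chosen only for non-overlap and generous spacing.
    """
    n = len(spec.diameters)
    ring = 0.28 * spec.phantom_diameter
    centers = []
    for i in range(n):
        ang = 2.0 * np.pi * i / n
        centers.append((ring * np.cos(ang), ring * np.sin(ang)))
    return centers


def make_derenzo(spec: RodSpec | None = None,
                 shape: Sequence[int] = (156, 30, 156),
                 voxel_size: tuple[float, float, float] = (2.2, 2.6, 2.2),
                 centers_mm: Sequence[tuple[float, float]] | None = None,
                 normalize_total: bool = True,
                 book_volumes: tuple[float, float] = (180.0, 7000.0),
                 mu_water: float = MU_WATER_208KEV,
                 ) -> tuple[VoxelPhantom, OrganLabelMap]:
    """Hot-rod phantom: one cylindrical rod per diameter in a warm cylinder.

    The rod axis is the depth axis ``y`` so planar views see the rods
    face-on, as in the resolution-phantom scintigraphy it emulates.  Voxel
    activities follow the rod/background concentrations; with
    ``normalize_total`` the map is rescaled so the grand total equals the
    booked activity from :func:`derenzo_booked_activity` (which matches the
    conventional rounded-volume arithmetic exactly, independent of the voxel
    discretization error of the cylinders).
    """
    spec = spec or RodSpec()
    shape = tuple(int(n) for n in shape)
    dx, dy, dz = voxel_size
    nx, ny, nz = shape
    if nx * dx < spec.phantom_diameter or nz * dz < spec.phantom_diameter:
        raise ValueError("grid too small for phantom diameter")
    centers = list(centers_mm) if centers_mm is not None \
        else _default_rod_centers(spec)
    if len(centers) != len(spec.diameters):
        raise ValueError("need one centre per rod diameter")
    # overlap / containment checks in continuous coordinates
    radii = [d / 2.0 for d in spec.diameters]
    r_phantom = spec.phantom_diameter / 2.0
    for i, ((xi, zi), ri) in enumerate(zip(centers, radii)):
        if np.hypot(xi, zi) + ri > r_phantom:
            raise ValueError(f"rod {spec.diameters[i]} mm does not fit inside phantom")
        for j in range(i):
            xj, zj = centers[j]
            if np.hypot(xi - xj, zi - zj) < ri + radii[j]:
                raise ValueError("overlapping rods")

    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    xx, zz = np.meshgrid(x, z, indexing="ij")
    in_phantom = xx**2 + zz**2 <= r_phantom**2

    ny_rod = min(ny, int(round(spec.height / dy)))
    ysel = slice((ny - ny_rod) // 2, (ny - ny_rod) // 2 + ny_rod)

    conc_rod = spec.rod_concentration * WATER_DENSITY_G_CM3 / 1000.0  # MBq/cm^3
    vox_cm3 = dx * dy * dz / 1000.0
    act = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    act[:, ysel, :] = np.where(in_phantom, conc_rod / spec.tbr * vox_cm3,
                               0.0)[:, None, :]
    names: dict[int, str] = {}
    for k, ((xc, zc), r) in enumerate(zip(centers, radii), start=1):
        rod = (xx - xc) ** 2 + (zz - zc) ** 2 <= r**2
        act[:, ysel, :][rod[:, None, :] & np.ones(ny_rod, bool)[None, :, None]] = \
            conc_rod * vox_cm3
        labels[:, ysel, :][rod[:, None, :] & np.ones(ny_rod, bool)[None, :, None]] = k
        names[k] = f"rod_{spec.diameters[k - 1]:g}mm"
        if not rod.any():
            raise ValueError("rod smaller than voxel grid resolution")
    if normalize_total:
        booked = derenzo_booked_activity(spec, *book_volumes)
        act *= booked / act.sum()
    atten = np.zeros(shape)
    atten[:, ysel, :] = np.where(in_phantom, mu_water, 0.0)[:, None, :]
    phantom = VoxelPhantom(act, atten, voxel_size,
                           name=f"derenzo_tbr{spec.tbr:g}")
    return phantom, OrganLabelMap(labels, names)


# ---------------------------------------------------------------------------
# anthropomorphic torso look-alike (NCAT surrogate)
# ---------------------------------------------------------------------------

#: default organ geometry: half-axes (mm) and centre (mm) in (x, y, z);
#: y is depth (anterior = -y), z axial.  A synthetic surrogate layout.
DEFAULT_ORGAN_PARAMS: dict[str, dict] = {
    "liver": {"half_axes": (75.0, 55.0, 55.0), "center": (-50.0, -10.0, 70.0)},
    "spleen": {"half_axes": (35.0, 30.0, 40.0), "center": (75.0, 15.0, 55.0)},
    "right_kidney": {"half_axes": (25.0, 18.0, 45.0), "center": (-48.0, 45.0, -30.0)},
    "left_kidney": {"half_axes": (25.0, 18.0, 45.0), "center": (48.0, 45.0, -30.0)},
}

#: default time-activity curves: sampling at 24/96/168 h with per-organ
#: retention scaling 1.0 : 0.6 : 0.4, the count-ratio structure of the
#: emulated study conditions.
DEFAULT_TAC_TIMES_H = (24.0, 96.0, 168.0)
DEFAULT_TAC_SHAPE = (1.0, 0.6, 0.4)
DEFAULT_PERCENT_IA_24H = {
    "liver": 8.0, "spleen": 1.5, "right_kidney": 1.2, "left_kidney": 1.0,
}


def default_tac(injected_activity: float = 700.0) -> TimeActivityCurve:
    shape = np.asarray(DEFAULT_TAC_SHAPE)
    values = {organ: base * shape
              for organ, base in DEFAULT_PERCENT_IA_24H.items()}
    return TimeActivityCurve(np.asarray(DEFAULT_TAC_TIMES_H), values,
                             injected_activity)


def make_anthropomorphic(organ_params: dict[str, dict] | None = None,
                         tac: TimeActivityCurve | None = None,
                         time_h: float = 24.0,
                         shape: Sequence[int] = (144, 96, 176),
                         voxel_size: tuple[float, float, float] = (2.2, 2.2, 2.2),
                         body_half_axes: tuple[float, float] = (150.0, 100.0),
                         body_length: float = 360.0,
                         extrapolate: bool = False,
                         mu_water: float = MU_WATER_208KEV,
                         ) -> tuple[VoxelPhantom, OrganLabelMap]:
    """Parametric torso with liver, spleen and kidneys as ellipsoids.

    Each organ carries ``%IA(time_h) * injected_activity`` MBq spread
    uniformly over its voxels; soft tissue is water-equivalent (ICRU-44
    compositions reduced to water in this analytic surrogate).  The body is
    an elliptic cylinder along ``z``.
    """
    organ_params = organ_params or DEFAULT_ORGAN_PARAMS
    tac = tac or default_tac()
    shape = tuple(int(n) for n in shape)
    nx, ny, nz = shape
    dx, dy, dz = voxel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    xx, yy, zzz = np.meshgrid(x, y, z, indexing="ij")
    ax, ay = body_half_axes
    body = ((xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0) \
        & (np.abs(zzz) <= body_length / 2.0)

    act = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    for k, (organ, p) in enumerate(organ_params.items(), start=1):
        a, b, c = p["half_axes"]
        x0, y0, z0 = p["center"]
        mask = ((xx - x0) / a) ** 2 + ((yy - y0) / b) ** 2 \
            + ((zzz - z0) / c) ** 2 <= 1.0
        mask &= body
        if not mask.any():
            raise ValueError(f"organ {organ} fell outside the body grid")
        labels[mask] = k
        names[k] = organ
    for k, organ in names.items():
        if organ not in tac.values:
            raise ValueError(f"no time-activity curve for organ {organ}")
        a_mbq = tac.activity_mbq(organ, time_h, extrapolate)
        mask = labels == k
        act[mask] = a_mbq / mask.sum()
    atten = np.where(body, mu_water, 0.0)
    phantom = VoxelPhantom(act, atten, voxel_size,
                           name=f"torso_{time_h:g}h")
    return phantom, OrganLabelMap(labels, names)


# ---------------------------------------------------------------------------
# training corpus
# ---------------------------------------------------------------------------

def _resample_volume(vol: np.ndarray, out_shape: tuple[int, int, int],
                     conserve_sum: bool) -> np.ndarray:
    factors = [o / s for o, s in zip(out_shape, vol.shape)]
    out = ndimage.zoom(vol, factors, order=1, mode="nearest", grid_mode=True)
    out = np.clip(out, 0.0, None)
    if conserve_sum and out.sum() > 0:
        out *= vol.sum() / out.sum()
    return out


def make_training_corpus(spec: TrainingCorpusSpec | None = None,
                         seed: int = 0,
                         bases: Sequence[VoxelPhantom] | None = None,
                         voxel_size: tuple[float, float, float] | None = None,
                         ) -> Iterator[VoxelPhantom]:
    """Yield the slice-duplication training scenes (300 by default).

    For each of the two base phantoms the volume is interpolated to
    ``matrix x matrix x n_slices`` (axial slices in the (x, z) plane,
    ``n_slices`` along depth ``y``... the corpus is built with the
    duplication axis along depth so each scene is a thin slab imaged
    face-on).  Every axial slice then becomes one scene of ``n_duplicates``
    identical copies.  Scene total activities are spaced evenly over the
    family's configured activity range; family A is the Shepp-Logan
    phantom, family B the brain-like surrogate.
    """
    spec = spec or TrainingCorpusSpec()
    if bases is None:
        small = (min(96, spec.matrix), min(96, spec.matrix), 64)
        bases = (make_shepp_logan(small), make_brain_like(small, seed=seed))
    if len(bases) != 2:
        raise ValueError("the corpus is built from two base phantoms")
    ranges = (spec.activity_range_a, spec.activity_range_b)
    for base, (lo, hi) in zip(bases, ranges):
        vs = voxel_size or base.voxel_size
        # crop to the occupied axial range so every interpolated slice has
        # signal, then interpolate; slices are indexed along the last axis
        occupied = np.nonzero(base.activity.sum(axis=(0, 1)) > 0)[0]
        lo_z, hi_z = int(occupied[0]), int(occupied[-1]) + 1
        vol = _resample_volume(base.activity[:, :, lo_z:hi_z],
                               (spec.matrix, spec.matrix, spec.n_slices),
                               conserve_sum=True)
        mu = float(base.attenuation.max())
        if spec.n_slices > 1:
            totals = np.linspace(lo, hi, spec.n_slices)
        else:
            totals = np.asarray([lo])
        for i in range(spec.n_slices):
            sl = vol[:, :, i]
            s = sl.sum()
            if s <= 0:  # empty axial slice: keep the set, zero activity floor
                sl = np.full_like(sl, 0.0)
                stack = np.repeat(sl[:, None, :], spec.n_duplicates, axis=1)
                atten = np.zeros_like(stack)
            else:
                sl = sl * (totals[i] / (s * spec.n_duplicates))
                stack = np.repeat(sl[:, None, :], spec.n_duplicates, axis=1)
                atten = np.where(stack > 0, mu, 0.0)
            yield VoxelPhantom(stack, atten, vs,
                               name=f"{base.name}_slice{i:03d}")


def total_activity(phantom: VoxelPhantom) -> float:
    """Total activity of the phantom in MBq (sum of the activity grid)."""
    return float(phantom.activity.sum())
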