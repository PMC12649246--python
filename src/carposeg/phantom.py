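"""Synthetic CT phantoms emulating a small carpal bone.

The generator produces Hounsfield-unit volumes containing a dense cortical
shell around a lower-intensity trabecular interior on a soft-tissue
background, with additive Gaussian acquisition noise — the intensity
structure a wrist CT presents to a threshold-based segmentation.  Two shape
families are supported:

* ``ellipsoid`` — a single (optionally rotated) ellipsoid; all ground-truth
  volumes have closed forms.
* ``two_lobe`` — a smooth-max blend of two overlapping ellipsoids, giving a
  waisted, scaphoid-like body; ground truth comes from oversampled
  quadrature restricted to surface-straddling voxels.

An optional second ellipsoidal body ("capitate-like") can be placed at a
controlled surface-to-surface gap for joint-space-thickness experiments.

Every phantom ships with a :class:`PhantomTruth` record so downstream
segmentation and meshing stages can be tested against analytic values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .grid import GridError, ImageVolume

#: Scan-protocol voxel spacing in mm (high-resolution wrist CT).
DEFAULT_SPACING = (0.17, 0.17, 0.2)
#: Approximate HU of the cortical layer; also the refill value used by the
#: smooth segmentation workflow.
CORTICAL_HU = 2106.0


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass(frozen=True)
class SecondBody:
    """An adjacent ellipsoidal body at a controlled gap along +x.

    ``gap_mm`` is the surface-to-surface distance between the main body's
    +x apex and the second body's -x apex (both bodies unrotated along that
    line, so the nominal gap is the true minimal gap for ellipsoid mains).
    """

    semi_axes: tuple[float, float, float] = (5.0, 5.0, 5.0)
    gap_mm: float = 1.3

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise PhantomError(f"second-body semi-axes must be positive, got {self.semi_axes}")
        if self.gap_mm <= 0:
            raise PhantomError(f"gap must be positive, got {self.gap_mm}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic carpal-bone phantom.

    Parameters
    ----------
    shape
        ``"ellipsoid"`` or ``"two_lobe"``.
    semi_axes
        Outer semi-axes of the (first) ellipsoid in mm.
    lobe2_semi_axes, lobe2_offset
        Second lobe for the ``two_lobe`` shape; the offset is the lobe-2
        center in the shape frame (convention: offset along +x).
    blend_sharpness
        Smooth-max sharpness ``k``; larger is closer to a hard union.
    rotation_deg, translation_mm
        Pose of the shape inside the grid (extrinsic xyz Euler angles).
        The grid itself stays axis-aligned.
    shell_thickness_mm
        Cortical shell thickness, implemented as a reduction of each
        semi-axis for the inner (trabecular) surface.
    hu_cortical, hu_trabecular, hu_background
        Intensity levels.  Defaults: 2106 HU cortical (dense carpal
        cortex), 300 HU trabecular, 40 HU soft tissue.
    noise_sd_hu
        Additive zero-mean Gaussian noise standard deviation.
    spacing
        Voxel spacing in mm; defaults to the 0.17 x 0.17 x 0.2 scan
        protocol.
    grid_shape
        Explicit grid extent in voxels; if ``None`` the grid is sized to
        the shape plus ``margin_voxels`` on every side.
    seed
        Seed for the noise draw.
    """

    shape: str = "ellipsoid"
    semi_axes: tuple[float, float, float] = (6.0, 6.0, 6.0)
    lobe2_semi_axes: tuple[float, float, float] | None = None
    lobe2_offset: tuple[float, float, float] = (5.0, 1.0, 0.0)
    blend_sharpness: float = 6.0
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shell_thickness_mm: float = 1.2
    hu_cortical: float = CORTICAL_HU
    hu_trabecular: float = 300.0
    hu_background: float = 40.0
    noise_sd_hu: float = 20.0
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    grid_shape: tuple[int, int, int] | None = None
    margin_voxels: int = 8
    seed: int = 0
    second_body: SecondBody | None = None

    def __post_init__(self):
        if self.shape not in ("ellipsoid", "two_lobe"):
            raise PhantomError(f"unknown shape {self.shape!r}")
        if min(self.semi_axes) <= 0:
            raise PhantomError(f"semi-axes must be positive, got {self.semi_axes}")
        if not (0 < self.shell_thickness_mm < min(self.semi_axes)):
            raise PhantomError(
                f"shell thickness must lie in (0, {min(self.semi_axes)}), "
                f"got {self.shell_thickness_mm}"
            )
        if not (self.hu_cortical > self.hu_trabecular > self.hu_background):
            raise PhantomError(
                "HU levels must be ordered cortical > trabecular > background, got "
                f"{self.hu_cortical} / {self.hu_trabecular} / {self.hu_background}"
            )
        if self.noise_sd_hu < 0:
            raise PhantomError("noise SD must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be positive, got {self.spacing}")
        if self.shape == "two_lobe":
            lobe2 = self.lobe2_semi_axes or self.semi_axes
            if self.shell_thickness_mm >= min(lobe2):
                raise PhantomError("shell thickness must be smaller than every lobe-2 semi-axis")

    # -- geometry -----------------------------------------------------------

    def rotation_matrix(self) -> np.ndarray:
        """Extrinsic xyz Euler rotation of the shape frame."""
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def _lobes(self, erode: float = 0.0):
        """(center, semi_axes) per lobe of the main body, shrunk by ``erode``."""
        axes1 = np.array(self.semi_axes) - erode
        lobes = [(np.zeros(3), axes1)]
        if self.shape == "two_lobe":
            axes2 = np.array(self.lobe2_semi_axes or self.semi_axes) - erode
            lobes.append((np.array(self.lobe2_offset, dtype=float), axes2))
        return lobes

    def implicit(self, points: np.ndarray, erode: float = 0.0) -> np.ndarray:
        """Implicit function of the main body in the shape frame.

        Negative inside; the zero level is the (possibly eroded) surface.
        For ``two_lobe`` the per-lobe quadrics are combined with a
        smooth-min (log-sum-exp), i.e. a smooth-max union of the solids.
        """
        points = np.atleast_2d(points)
        vals = []
        for center, axes in self._lobes(erode):
            q = points - center
            vals.append(np.einsum("ij,j->i", q * q, 1.0 / np.asarray(axes) ** 2) - 1.0)
        if len(vals) == 1:
            return vals[0]
        k = self.blend_sharpness
        stacked = np.stack(vals)
        m = stacked.min(axis=0)
        return m - np.log(np.exp(-k * (stacked - m)).sum(axis=0)) / k

    def second_body_center(self) -> np.ndarray:
        """Shape-frame center of the second body (along +x past the main apex)."""
        if self.second_body is None:
            raise PhantomError("spec has no second body")
        apex = max(c[0] + ax[0] for c, ax in self._lobes())
        return np.array([apex + self.second_body.gap_mm + self.second_body.semi_axes[0], 0.0, 0.0])

    def second_body_implicit(self, points: np.ndarray, erode: float = 0.0) -> np.ndarray:
        center = self.second_body_center()
        axes = np.array(self.second_body.semi_axes) - erode
        q = np.atleast_2d(points) - center
        return np.einsum("ij,j->i", q * q, 1.0 / axes**2) - 1.0

    def world_to_shape(self, points: np.ndarray) -> np.ndarray:
        R = self.rotation_matrix()
        return (np.atleast_2d(points) - np.array(self.translation_mm)) @ R

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Conservative world-frame AABB of all bodies (mm)."""
        R = self.rotation_matrix()
        t = np.array(self.translation_mm)
        mins, maxs = [], []
        bodies = self._lobes()
        if self.second_body is not None:
            bodies = bodies + [(self.second_body_center(), np.array(self.second_body.semi_axes))]
        for center, axes in bodies:
            # support of a rotated ellipsoid along each world axis
            support = np.sqrt(((R * axes) ** 2).sum(axis=1))
            c = R @ center + t
            mins.append(c - support)
            maxs.append(c + support)
        pad = 0.5 if self.shape == "two_lobe" else 0.0  # smooth-max bulge allowance
        return np.min(mins, axis=0) - pad, np.max(maxs, axis=0) + pad


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom."""

    outer_volume_mm3: float
    inner_volume_mm3: float
    gap_mm: float | None
    surface: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.outer_volume_mm3 <= 0:
            raise PhantomError("analytic volume must be positive")


def _ellipsoid_volume(axes) -> float:
    a, b, c = axes
    return 4.0 / 3.0 * np.pi * a * b * c


def _quadrature_volume(spec: PhantomSpec, volume: ImageVolume, oversample: int = 10) -> float:
    """Volume enclosed by the main outer surface via oversampled quadrature.

    Voxels are classified by the implicit value at their center; voxels whose
    26-neighbourhood contains a sign change are re-evaluated on an
    ``oversample``^3 sub-grid.  Exact for surfaces whose feature size exceeds
    a voxel (always true for the shapes generated here).
    """
    from scipy import ndimage

    xs, ys, zs = volume.voxel_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    f = spec.implicit(spec.world_to_shape(pts)).reshape(volume.shape)
    inside = f < 0
    boundary = ndimage.binary_dilation(
        inside ^ ndimage.binary_erosion(inside), iterations=2
    )
    vol = float((inside & ~boundary).sum()) * volume.voxel_volume

    idx = np.argwhere(boundary)
    if len(idx):
        s = np.array(volume.spacing)
        off = (np.arange(oversample) + 0.5) / oversample - 0.5
        ox, oy, oz = np.meshgrid(off * s[0], off * s[1], off * s[2], indexing="ij")
        offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
        centers = volume.index_to_physical(idx)
        frac = np.empty(len(idx))
        chunk = max(1, 4_000_000 // len(offsets))
        for lo in range(0, len(idx), chunk):
            sub = (centers[lo : lo + chunk, None, :] + offsets[None, :, :]).reshape(-1, 3)
            fs = spec.implicit(spec.world_to_shape(sub)) < 0
            frac[lo : lo + chunk] = fs.reshape(-1, len(offsets)).mean(axis=1)
        vol += float(frac.sum()) * volume.voxel_volume
    return vol


def generate_phantom(
    spec: PhantomSpec, truth_oversample: int = 10, compute_truth: bool = True
) -> tuple[ImageVolume, PhantomTruth | None]:
    """Render a phantom volume and its ground truth.

    Voxel centers strictly inside the inner surface receive the trabecular
    HU, centers between the inner and outer surfaces the cortical HU, all
    others the background HU; zero-mean Gaussian noise of the specified SD
    is then added.  The same spec (including seed) always produces a
    bit-identical volume.

    For ``two_lobe`` shapes the truth volumes come from quadrature, which
    costs a few seconds at the default ``truth_oversample``; pass
    ``compute_truth=False`` when only the image is needed.
    """
    bb_min, bb_max = spec.bounding_box()
    s = np.array(spec.spacing)
    m = spec.margin_voxels
    if spec.grid_shape is None:
        shape = tuple(int(np.ceil((bb_max[i] - bb_min[i]) / s[i])) + 2 * m + 1 for i in range(3))
        origin = tuple(bb_min - m * s)
    else:
        shape = tuple(int(n) for n in spec.grid_shape)
        center = 0.5 * (bb_min + bb_max)
        origin = tuple(center - 0.5 * (np.array(shape) - 1) * s)

    volume = ImageVolume(np.zeros(shape, dtype=np.float32), tuple(s), origin)

    # margin check: the shape AABB must keep >=5 voxels clear of every face
    lo_idx = volume.physical_to_index(bb_min)
    hi_idx = volume.physical_to_index(bb_max)
    for ax in range(3):
        if lo_idx[ax] < 5 or hi_idx[ax] > shape[ax] - 1 - 5:
            raise PhantomError(
                f"shape exits grid: axis {ax} margin "
                f"[{lo_idx[ax]:.1f}, {shape[ax] - 1 - hi_idx[ax]:.1f}] voxels, need >= 5"
            )

    xs, ys, zs = volume.voxel_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = spec.world_to_shape(np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]))

    data = np.full(int(np.prod(shape)), spec.hu_background, dtype=np.float32)
    f_out = spec.implicit(pts)
    f_in = spec.implicit(pts, erode=spec.shell_thickness_mm)
    data[f_out <= 0] = spec.hu_cortical
    data[f_in < 0] = spec.hu_trabecular
    if spec.second_body is not None:
        g_out = spec.second_body_implicit(pts)
        g_in = spec.second_body_implicit(pts, erode=spec.shell_thickness_mm)
        data[g_out <= 0] = spec.hu_cortical
        data[g_in < 0] = spec.hu_trabecular
    data = data.reshape(shape)

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd_hu, shape).astype(np.float32)
    volume.data = data.astype(np.float32)

    if not compute_truth:
        return volume, None

    if spec.shape == "ellipsoid":
        outer = _ellipsoid_volume(spec.semi_axes)
        inner = _ellipsoid_volume(np.array(spec.semi_axes) - spec.shell_thickness_mm)
    else:
        outer = _quadrature_volume(spec, volume, oversample=truth_oversample)
        inner_spec = dataclasses.replace(spec, second_body=None)
        inner = _quadrature_volume_eroded(inner_spec, volume, spec.shell_thickness_mm, truth_oversample)

    truth = PhantomTruth(
        outer_volume_mm3=float(outer),
        inner_volume_mm3=float(inner),
        gap_mm=spec.second_body.gap_mm if spec.second_body else None,
        surface={
            "shape": spec.shape,
            "semi_axes_mm": list(spec.semi_axes),
            "shell_thickness_mm": spec.shell_thickness_mm,
        },
    )
    return volume, truth


def _quadrature_volume_eroded(spec: PhantomSpec, volume: ImageVolume, erode: float, oversample: int) -> float:
    eroded = dataclasses.replace(
        spec,
        semi_axes=tuple(np.array(spec.semi_axes) - erode),
        lobe2_semi_axes=(
            tuple(np.array(spec.lobe2_semi_axes or spec.semi_axes) - erode)
            if spec.shape == "two_lobe"
            else spec.lobe2_semi_axes
        ),
        shell_thickness_mm=min(0.1, (min(spec.semi_axes) - erode) / 2),
    )
    return _quadrature_volume(eroded, volume, oversample)


def cortical_seed(spec: PhantomSpec, volume: ImageVolume) -> tuple[int, int, int]:
    """Voxel index of a guaranteed-cortical seed point (mid-shell, -x apex)."""
    p_shape = np.array([-(spec.semi_axes[0] - spec.shell_thickness_mm / 2.0), 0.0, 0.0])
    p_world = spec.rotation_matrix() @ p_shape + np.array(spec.translation_mm)
    idx = np.rint(volume.physical_to_index(p_world)).astype(int)
    return tuple(int(i) for i in idx)


def second_body_seed(spec: PhantomSpec, volume: ImageVolume) -> tuple[int, int, int]:
    """Voxel index of a cortical seed on the second body (+x apex, mid-shell)."""
    center = spec.second_body_center()
    p_shape = center + np.array([spec.second_body.semi_axes[0] - spec.shell_thickness_mm / 2.0, 0.0, 0.0])
    p_world = spec.rotation_matrix() @ p_shape + np.array(spec.translation_mm)
    idx = np.rint(volume.physical_to_index(p_world)).astype(int)
    return tuple(int(i) for i in idx)


@dataclass
class ConditionPairs:
    """Replicated two-condition scans of one phantom (e.g. frozen vs thawed)."""

    pairs: list[tuple[ImageVolume, ImageVolume]]
    truth_a: PhantomTruth
    truth_b: PhantomTruth
    spec_a: PhantomSpec
    spec_b: PhantomSpec


def generate_condition_pair(
    spec: PhantomSpec,
    volume_perturbation: float,
    n_replicates: int,
    seed: int,
) -> ConditionPairs:
    """Replicate scan pairs of one phantom under two conditions.

    Condition A is ``spec`` itself; condition B is the same shape scaled
    isotropically so its analytic volume is ``(1 + volume_perturbation)``
    times condition A's.  Replicates differ only by fresh noise draws.
    """
    if abs(volume_perturbation) >= 0.1:
        raise PhantomError(
            f"|volume_perturbation| must be < 0.1, got {volume_perturbation}"
        )
    if n_replicates < 1:
        raise PhantomError("n_replicates must be >= 1")

    scale = (1.0 + volume_perturbation) ** (1.0 / 3.0)
    spec_b = dataclasses.replace(
        spec,
        semi_axes=tuple(np.array(spec.semi_axes) * scale),
        lobe2_semi_axes=(
            tuple(np.array(spec.lobe2_semi_axes) * scale) if spec.lobe2_semi_axes else None
        ),
        lobe2_offset=tuple(np.array(spec.lobe2_offset) * scale),
        shell_thickness_mm=spec.shell_thickness_mm * scale,
        second_body=None,
    )
    spec_a = dataclasses.replace(spec, second_body=None)

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_replicates, 2))
    pairs = []
    truth_a = truth_b = None
    for rep in range(n_replicates):
        vol_a, truth_a = generate_phantom(dataclasses.replace(spec_a, seed=int(seeds[rep, 0])))
        vol_b, truth_b = generate_phantom(dataclasses.replace(spec_b, seed=int(seeds[rep, 1])))
        pairs.append((vol_a, vol_b))
    return ConditionPairs(pairs, truth_a, truth_b, spec_a, spec_b)
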