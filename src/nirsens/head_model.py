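"""Voxelized head models for photon-transport simulation.

Provides synthetic layered phantoms (concentric spheres and slabs) with the
five tissue classes used in near-infrared neuromonitoring — scalp, skull,
cerebrospinal fluid (CSF), gray matter and white matter — plus NIfTI
label-volume I/O so a real segmented head can be substituted, near-uniform
placement of photon injection points on the scalp surface, and construction
of concentric "depth shells" by iterative morphological erosion of the
intracranial mask.

Conventions
-----------
Tissue codes are ``0=air, 1=scalp, 2=skull, 3=CSF, 4=gray, 5=white``.
Voxels are isotropic; all physical coordinates are in millimetres with
0-based voxel indices, so the centre of voxel ``(i, j, k)`` lies at
``origin + (i + 0.5, j + 0.5, k + 0.5) * voxel_size``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

AIR, SCALP, SKULL, CSF, GRAY, WHITE = 0, 1, 2, 3, 4, 5

TISSUE_NAMES = {
    AIR: "air",
    SCALP: "scalp",
    SKULL: "skull",
    CSF: "csf",
    GRAY: "gray",
    WHITE: "white",
}

#: labels counted as brain when partitioning sensitivity maps
BRAIN_LABELS = (GRAY, WHITE)
#: labels forming the intracranial space (eroded into depth shells)
INTRACRANIAL_LABELS = (CSF, GRAY, WHITE)

_LAYER_ORDER = (SCALP, SKULL, CSF, GRAY)  # outer-to-inner finite layers


@dataclass
class HeadVolume:
    """A 3D integer tissue-label grid with isotropic voxels.

    Parameters
    ----------
    labels
        3D array of tissue codes in ``{0..5}``.
    voxel_size
        Edge length of a voxel in mm (> 0).
    origin
        mm offset of the corner of voxel (0, 0, 0).
    """

    labels: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        bad = set(np.unique(self.labels)) - set(TISSUE_NAMES)
        if bad:
            raise ValueError(f"unknown tissue codes: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_counts(self) -> dict[str, int]:
        """Number of voxels per tissue class."""
        return {
            TISSUE_NAMES[code]: int(np.count_nonzero(self.labels == code))
            for code in TISSUE_NAMES
        }

    def voxel_centers_mm(self, mask: np.ndarray) -> np.ndarray:
        """mm coordinates of the centres of the voxels selected by ``mask``."""
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.voxel_size

    def center_of_mass_mm(self) -> np.ndarray:
        """Centroid of all non-air voxels, in mm."""
        com = ndimage.center_of_mass(self.labels > 0)
        return self.origin + (np.asarray(com) + 0.5) * self.voxel_size

    def scalp_surface_mask(self) -> np.ndarray:
        """Boolean mask of non-air voxels that touch air on a voxel face."""
        tissue = self.labels > 0
        interior = ndimage.binary_erosion(
            tissue, structure=ndimage.generate_binary_structure(3, 1),
            border_value=0,
        )
        return tissue & ~interior


def _check_thicknesses(thicknesses, voxel_size: float) -> np.ndarray:
    t = np.asarray(thicknesses, dtype=float)
    if t.shape != (4,):
        raise ValueError(
            "thicknesses must give 4 values: (scalp, skull, CSF, gray) in mm"
        )
    if np.any(t < 0):
        raise ValueError("layer thicknesses must be non-negative")
    thin = (t > 0) & (t < voxel_size)
    if np.any(thin):
        names = [TISSUE_NAMES[_LAYER_ORDER[i]] for i in np.nonzero(thin)[0]]
        raise ValueError(
            f"layer(s) {names} thinner than one voxel ({voxel_size} mm); "
            "increase the thickness, set it to 0, or reduce voxel_size"
        )
    return t


def build_layered_sphere(
    outer_radius: float,
    thicknesses=(6.9, 6.1, 2.0, 4.0),
    voxel_size: float = 1.0,
    air_pad: int = 2,
) -> HeadVolume:
    """Concentric-sphere head phantom: scalp, skull, CSF, gray, white core.

    Defaults reproduce a mean adult scalp thickness of 6.9 mm and a combined
    scalp+skull thickness of 13 mm over a thin CSF layer and a cortical gray
    shell; everything deeper is white matter.

    Parameters
    ----------
    outer_radius
        Scalp outer radius in mm.
    thicknesses
        (scalp, skull, CSF, gray) thicknesses in mm; a value of 0 removes
        that layer.
    voxel_size
        Isotropic voxel edge in mm; each non-zero layer must be at least one
        voxel thick.
    air_pad
        Voxels of air padding around the sphere (photons must be able to
        exit into air on every side).
    """
    t = _check_thicknesses(thicknesses, voxel_size)
    if t.sum() >= outer_radius:
        raise ValueError("layer thicknesses must sum to less than outer_radius")
    n = int(np.ceil(2 * outer_radius / voxel_size)) + 2 * air_pad
    # centre of the grid in mm
    c = n * voxel_size / 2.0
    coords = (np.arange(n) + 0.5) * voxel_size - c
    r = np.sqrt(
        coords[:, None, None] ** 2
        + coords[None, :, None] ** 2
        + coords[None, None, :] ** 2
    )
    inner = outer_radius - np.cumsum(t)  # radii after each layer, outer→in
    labels = np.zeros((n, n, n), dtype=np.int16)
    prev = outer_radius
    for code, r_in in zip(_LAYER_ORDER, inner):
        if prev > r_in:  # zero-thickness layers collapse
            labels[(r <= prev) & (r > r_in)] = code
        prev = r_in
    labels[r <= inner[-1]] = WHITE
    return HeadVolume(labels, voxel_size=voxel_size, origin=np.zeros(3))


def build_layered_slab(
    extent=(60.0, 60.0, 60.0),
    thicknesses=(6.9, 6.1, 2.0, 4.0),
    voxel_size: float = 1.0,
    air_pad: int = 2,
) -> HeadVolume:
    """Flat layered phantom: layers stacked along the last axis.

    The scalp surface lies at depth 0 along axis 2; white matter fills the
    remaining depth of ``extent[2]``. The tissue block is surrounded by air
    padding on all sides.  The origin is set so that mm coordinate 0 along
    each axis is the corner of the tissue block (depth into the head is then
    simply the z coordinate).
    """
    t = _check_thicknesses(thicknesses, voxel_size)
    extent = np.asarray(extent, dtype=float)
    if t.sum() > extent[2]:
        raise ValueError("total layer thickness exceeds the slab depth extent")
    nvox = np.ceil(extent / voxel_size).astype(int)
    shape = nvox + 2 * air_pad
    labels = np.zeros(shape, dtype=np.int16)
    depth = (np.arange(nvox[2]) + 0.5) * voxel_size
    col = np.full(nvox[2], WHITE, dtype=np.int16)
    lo = 0.0
    for code, th in zip(_LAYER_ORDER, t):
        if th > 0:
            col[(depth >= lo) & (depth < lo + th)] = code
        lo += th
    p = air_pad
    labels[p : p + nvox[0], p : p + nvox[1], p : p + nvox[2]] = col[None, None, :]
    origin = -np.array([air_pad, air_pad, air_pad], dtype=float) * voxel_size
    return HeadVolume(labels, voxel_size=voxel_size, origin=origin)


# ---------------------------------------------------------------------------
# NIfTI label-volume I/O


def save_label_volume(head: HeadVolume, path) -> None:
    """Write a HeadVolume as an integer NIfTI volume (isotropic affine)."""
    affine = np.diag([head.voxel_size] * 3 + [1.0])
    affine[:3, 3] = head.origin
    img = nib.Nifti1Image(head.labels.astype(np.int16), affine)
    nib.save(img, str(path))


def load_label_volume(path) -> HeadVolume:
    """Read a segmented label volume (codes 0–5, isotropic voxels)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("label volume must contain integer tissue codes")
        data = np.round(data).astype(np.int16)
    bad = sorted(set(np.unique(data)) - set(TISSUE_NAMES))
    if bad:
        raise ValueError(f"unknown tissue codes in volume: {bad}")
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(
            f"anisotropic voxels {tuple(zooms)}; isotropic voxels are required"
        )
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return HeadVolume(data.astype(np.int16), voxel_size=float(zooms[0]),
                      origin=origin)


# ---------------------------------------------------------------------------
# Surface injection points


@dataclass
class SurfacePoint:
    """A photon injection (or collection) point on the outer scalp surface."""

    position: np.ndarray  # mm, centre of a scalp-surface voxel
    direction: np.ndarray  # unit vector pointing into the head

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if not np.isclose(nrm, 1.0, atol=1e-8):
            raise ValueError("direction must be a unit vector")


def fibonacci_sphere_count(radius: float, spacing: float) -> int:
    """Lattice size giving ~hexagonal nearest-neighbour ``spacing`` on a sphere.

    With N points covering area 4*pi*r^2 in a near-hexagonal packing, the
    nearest-neighbour distance is ``sqrt(8*pi/(sqrt(3)*N)) * r``; inverting
    for N gives the count used here (e.g. ~5200 points for spacing 5 mm on a
    95 mm sphere).
    """
    if spacing <= 0 or radius <= 0:
        raise ValueError("radius and spacing must be positive")
    return int(round(8 * np.pi * radius**2 / (np.sqrt(3) * spacing**2)))


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors from the Fibonacci (golden-angle) lattice."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _project_ray_to_surface(labels, shape, h, origin, start, direction,
                            max_steps: int = 100000):
    """First non-air voxel entered by a ray (exact face-to-face traversal)."""
    d = np.asarray(direction, dtype=float)
    p = (np.asarray(start, dtype=float) - origin) / h  # voxel units
    # advance to the grid bounding box if starting outside
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            continue
        if p[ax] < 0 and d[ax] > 0:
            t = (0 - p[ax]) / d[ax]
            p = p + t * d
        elif p[ax] > shape[ax] and d[ax] < 0:
            t = (shape[ax] - p[ax]) / d[ax]
            p = p + t * d
    iv = np.floor(p).astype(int)
    for _ in range(max_steps):
        if np.all(iv >= 0) and np.all(iv < shape):
            if labels[iv[0], iv[1], iv[2]] != AIR:
                return (int(iv[0]), int(iv[1]), int(iv[2]))
        elif np.any((iv < -1) & (d <= 0)) or np.any((iv > shape) & (d >= 0)):
            return None
        # distance (in ray parameter) to the next voxel face
        t_min, axis = np.inf, -1
        for ax in range(3):
            if d[ax] > 1e-12:
                t = (iv[ax] + 1 - p[ax]) / d[ax]
            elif d[ax] < -1e-12:
                t = (iv[ax] - p[ax]) / d[ax]
            else:
                continue
            if t < t_min:
                t_min, axis = t, ax
        if axis < 0 or not np.isfinite(t_min):
            return None
        p = p + t_min * d
        iv[axis] += 1 if d[axis] > 0 else -1
        p[axis] = iv[axis] + (0.0 if d[axis] > 0 else 1.0)
    return None


def place_surface_points(
    head: HeadVolume,
    spacing: float = 5.0,
    sphere_radius: float | None = None,
    center: np.ndarray | None = None,
    axis_min: dict[int, float] | None = None,
    axis_max: dict[int, float] | None = None,
) -> list[SurfacePoint]:
    """Place near-uniform injection points on the outer scalp surface.

    A Fibonacci lattice with ~``spacing`` mm nearest-neighbour distance is
    generated on a bounding sphere and each lattice direction is projected
    radially (toward the head centre) onto the first non-air voxel.  The
    returned direction is the inward radial unit vector.  Duplicate surface
    voxels are collapsed to one point.

    ``axis_min`` / ``axis_max`` map axis index -> mm threshold and drop
    projected points outside the range (anatomical pruning, e.g. excluding
    everything below the cerebellum in a real head volume).
    """
    surface = head.scalp_surface_mask()
    if not surface.any():
        raise ValueError("head volume has no scalp surface")
    if center is None:
        center = head.center_of_mass_mm()
    center = np.asarray(center, dtype=float)
    if sphere_radius is None:
        pts = head.voxel_centers_mm(head.labels > 0)
        sphere_radius = float(np.max(np.linalg.norm(pts - center, axis=1)))
    n = fibonacci_sphere_count(sphere_radius, spacing)
    if n < 2:
        raise ValueError(
            f"spacing {spacing} mm yields fewer than 2 surface points"
        )
    dirs = fibonacci_sphere(n)

    labels = head.labels
    h = head.voxel_size
    shape = np.asarray(labels.shape)
    r_start = sphere_radius + 2 * h
    points: list[SurfacePoint] = []
    seen: set[tuple[int, int, int]] = set()
    for d in dirs:
        # trace the ray from outside the head toward the centre, voxel face
        # to voxel face, and stop at the first non-air voxel entered
        key = _project_ray_to_surface(labels, shape, h, head.origin,
                                      center + r_start * d, -d)
        if key is not None and key not in seen:
            seen.add(key)
            pos = head.origin + (np.asarray(key) + 0.5) * h
            points.append(SurfacePoint(position=pos, direction=-d))
    if axis_min:
        points = [p for p in points
                  if all(p.position[a] >= v for a, v in axis_min.items())]
    if axis_max:
        points = [p for p in points
                  if all(p.position[a] <= v for a, v in axis_max.items())]
    if len(points) < 2:
        raise ValueError(
            f"spacing {spacing} mm yields fewer than 2 surface points"
        )
    return points


# ---------------------------------------------------------------------------
# Depth shells by iterative erosion of the intracranial mask


@dataclass
class ShellSet:
    """Partition of the head into scalp, skull and concentric depth shells.

    ``partition`` assigns 0 to air/unassigned voxels, 1 to scalp, 2 to skull
    and ``3..(2 + n_shells)`` to successive erosion shells (shell 1 is the
    outermost intracranial layer).  ``mean_depth_mm[k]`` is the mean
    distance of shell ``k+1``'s voxels from the inner skull surface and is
    the depth coordinate used in depth-sensitivity regressions.
    """

    partition: np.ndarray
    voxel_size: float
    mean_depth_mm: np.ndarray
    mean_thickness_mm: np.ndarray
    names: dict[int, str]
    truncated: bool = False
    core_label: int | None = None

    @property
    def n_shells(self) -> int:
        return len(self.mean_depth_mm)

    def shell_mask(self, k: int) -> np.ndarray:
        """Boolean mask of shell ``k`` (1-based)."""
        return self.partition == 2 + k


def compute_shells(
    head: HeadVolume,
    n_shells: int = 21,
    step_voxels: int = 2,
    include_core: bool = False,
) -> ShellSet:
    """Partition the intracranial space into concentric erosion shells.

    The intracranial mask (CSF + gray + white) is eroded ``step_voxels``
    times per shell with a 6-connected structuring element; shell *k* is the
    set difference between successive erosions.  Scalp and skull are kept as
    their own partitions.  Mean shell depth is measured with a Euclidean
    distance transform from the inner skull surface.

    If the mask is exhausted before ``n_shells`` erosions the result carries
    fewer shells and ``truncated=True`` (with a warning).  With
    ``include_core=True`` the voxels remaining after the final erosion are
    kept as one extra partition so the shells + core exhaust the
    intracranial volume.
    """
    intracranial = np.isin(head.labels, INTRACRANIAL_LABELS)
    if not intracranial.any():
        raise ValueError("intracranial mask (CSF+gray+white) is empty")
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connected

    # depth below the inner skull surface, mm (voxel centres sit half a
    # voxel inside the interface, hence the 0.5 offset)
    edt = ndimage.distance_transform_edt(intracranial)
    depth = (edt - 0.5) * head.voxel_size

    partition = np.zeros(head.shape, dtype=np.int16)
    partition[head.labels == SCALP] = 1
    partition[head.labels == SKULL] = 2

    names = {1: "scalp", 2: "skull"}
    mean_depths: list[float] = []
    thicknesses: list[float] = []
    truncated = False
    mask = intracranial
    outer_edge = 0.0  # running depth of the outer boundary of the next shell
    for k in range(1, n_shells + 1):
        eroded = mask
        for _ in range(step_voxels):
            # border_value=1: the grid edge is not a tissue surface, so a
            # mask touching it only erodes from real interfaces
            eroded = ndimage.binary_erosion(eroded, structure=struct,
                                            border_value=1)
        shell = mask & ~eroded
        if not shell.any():
            truncated = True
            warnings.warn(
                f"intracranial mask exhausted after {k - 1} of "
                f"{n_shells} shells",
                stacklevel=2,
            )
            break
        code = 2 + k
        partition[shell] = code
        names[code] = f"shell_{k}"
        d_mean = float(depth[shell].mean())
        # voxel centres in a shell span [outer_edge, outer_edge + t]
        t_k = max(2.0 * (d_mean - outer_edge), 0.0)
        mean_depths.append(d_mean)
        thicknesses.append(t_k)
        outer_edge += t_k
        mask = eroded
    core_label = None
    if include_core and mask.any():
        core_label = 2 + len(mean_depths) + 1
        partition[mask] = core_label
        names[core_label] = "core"
    return ShellSet(
        partition=partition,
        voxel_size=head.voxel_size,
        mean_depth_mm=np.asarray(mean_depths),
        mean_thickness_mm=np.asarray(thicknesses),
        names=names,
        truncated=truncated,
        core_label=core_label,
    )


@dataclass
class PartitionSpec:
    """A named integer partition of the voxel grid (0 = unassigned)."""

    grid: np.ndarray
    names: dict[int, str]


def tissue_partition(head: HeadVolume) -> PartitionSpec:
    """Partition by the five tissue classes (air unassigned)."""
    names = {c: TISSUE_NAMES[c] for c in (SCALP, SKULL, CSF, GRAY, WHITE)}
    return PartitionSpec(grid=head.labels, names=names)


def brain_partition(head: HeadVolume) -> PartitionSpec:
    """Two-way brain (gray+white) vs non-brain (scalp+skull+CSF) partition."""
    grid = np.zeros(head.shape, dtype=np.int16)
    grid[np.isin(head.labels, BRAIN_LABELS)] = 1
    grid[np.isin(head.labels, (SCALP, SKULL, CSF))] = 2
    return PartitionSpec(grid=grid, names={1: "brain", 2: "non_brain"})


def shell_partition(shells: ShellSet) -> PartitionSpec:
    """PartitionSpec view of a ShellSet (scalp, skull, shells, core)."""
    return PartitionSpec(grid=shells.partition, names=dict(shells.names))
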