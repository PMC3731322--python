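"""Source x detector sensitivity maps and their spatial quantification.

For continuous-wave NIRS the spatial sensitivity of one source-detector
(SD) pair to a local absorption change — the "3-point Green's function"
W(r) — is the voxelwise product of the two per-photon 2-point fluence
fields, one simulated from the source position and one from the detector
position (optical reciprocity).  Summing W over any partition of the head
(tissue classes, brain vs non-brain, depth shells) and dividing by the
total gives the fraction of the measurement's sensitivity attributable to
that partition.

Instrument dynamic range is emulated by masking W below a given number of
orders of magnitude from its peak before partition summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .head_model import PartitionSpec, SurfacePoint
from .mc_transport import FluenceGrid


@dataclass
class ThreePointMap:
    """Voxelwise SD-pair sensitivity W (product of two normalized fluences)."""

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray
    source_position: np.ndarray | None = None
    detector_position: np.ndarray | None = None
    separation: float | None = None
    source_id: int | None = None
    detector_id: int | None = None

    @property
    def total_sum(self) -> float:
        return float(self.values.sum())


@dataclass
class PartitionProportions:
    """Per-partition share of the summed 3-point sensitivity."""

    proportions: dict[str, float]
    n_voxels: dict[str, int]
    total_sum: float

    def __getitem__(self, name: str) -> float:
        return self.proportions[name]

    def get(self, name: str, default: float = 0.0) -> float:
        return self.proportions.get(name, default)


def three_point(src: FluenceGrid, det: FluenceGrid,
                source_id: int | None = None,
                detector_id: int | None = None) -> ThreePointMap:
    """W(r) = G_src(r) * G_det(r), voxel by voxel (symmetric in arguments).

    Both grids must be per-photon normalized and share the same geometry.
    """
    for name, g in (("source", src), ("detector", det)):
        if not g.normalized:
            raise ValueError(f"{name} fluence grid must be normalized first")
    if src.values.shape != det.values.shape:
        raise ValueError("fluence grids have mismatched shapes")
    if not np.isclose(src.voxel_size, det.voxel_size) or not np.allclose(
            src.origin, det.origin):
        raise ValueError("fluence grids have mismatched geometry")
    sep = None
    if src.source_position is not None and det.source_position is not None:
        sep = float(np.linalg.norm(src.source_position - det.source_position))
    return ThreePointMap(
        values=src.values * det.values,
        voxel_size=src.voxel_size,
        origin=src.origin.copy(),
        source_position=src.source_position,
        detector_position=det.source_position,
        separation=sep,
        source_id=source_id,
        detector_id=detector_id,
    )


def threshold_map(tpm: ThreePointMap, orders: float) -> ThreePointMap:
    """Zero voxels more than ``orders`` orders of magnitude below the peak.

    Emulates an instrument's dynamic range (2 orders ~ 40 dB).  ``orders``
    may be ``numpy.inf`` for no masking; values below 1 are rejected.
    """
    if orders < 1:
        raise ValueError("orders must be >= 1")
    if tpm.values.size == 0:
        raise ValueError("empty sensitivity map")
    values = tpm.values.copy()
    if np.isfinite(orders):
        cutoff = values.max() * 10.0 ** (-orders)
        values[values < cutoff] = 0.0
    return ThreePointMap(
        values=values,
        voxel_size=tpm.voxel_size,
        origin=tpm.origin.copy(),
        source_position=tpm.source_position,
        detector_position=tpm.detector_position,
        separation=tpm.separation,
        source_id=tpm.source_id,
        detector_id=tpm.detector_id,
    )


def partition_sums(tpm: ThreePointMap,
                   partition: PartitionSpec) -> PartitionProportions:
    """Fraction of the summed sensitivity in each named partition.

    Every voxel with W > 0 must be covered by the partition (air is excluded
    by construction since photons deposit no weight there).
    """
    if tpm.values.shape != partition.grid.shape:
        raise ValueError("map and partition have mismatched shapes")
    uncovered = int(np.count_nonzero((tpm.values > 0) & (partition.grid == 0)))
    if uncovered:
        raise ValueError(
            f"{uncovered} voxel(s) with positive sensitivity are not "
            "assigned to any partition"
        )
    total = tpm.total_sum
    sums = {}
    counts = {}
    for code, name in partition.names.items():
        mask = partition.grid == code
        counts[name] = int(np.count_nonzero(mask))
        sums[name] = float(tpm.values[mask].sum())
    if total > 0:
        props = {k: v / total for k, v in sums.items()}
    else:
        props = {k: 0.0 for k in sums}
    return PartitionProportions(proportions=props, n_voxels=counts,
                                total_sum=total)


# ---------------------------------------------------------------------------
# SD-pair enumeration and separation-binned curves


@dataclass
class PairSet:
    """Unordered surface-point pairs meeting separation/midpoint constraints."""

    pairs: list[tuple[int, int]]
    separations: np.ndarray
    midpoints: np.ndarray
    target: np.ndarray
    midpoint_radius: float
    max_separation: float

    def __len__(self) -> int:
        return len(self.pairs)


def enumerate_pairs(
    points: list[SurfacePoint],
    target,
    midpoint_radius: float = 10.0,
    max_separation: float = 60.0,
    min_separation: float = 0.0,
) -> PairSet:
    """All unordered point pairs separated by less than ``max_separation`` mm
    whose 3D midpoint lies within ``midpoint_radius`` mm of ``target``.

    Separations are straight-line Euclidean distances in mm.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 surface points")
    target = np.asarray(target, dtype=float)
    pos = np.asarray([p.position for p in points])
    pairs, seps, mids = [], [], []
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            sep = float(np.linalg.norm(pos[i] - pos[j]))
            if not (min_separation <= sep < max_separation):
                continue
            mid = 0.5 * (pos[i] + pos[j])
            if np.linalg.norm(mid - target) <= midpoint_radius:
                pairs.append((i, j))
                seps.append(sep)
                mids.append(mid)
    return PairSet(
        pairs=pairs,
        separations=np.asarray(seps),
        midpoints=np.asarray(mids).reshape(len(pairs), 3),
        target=target,
        midpoint_radius=midpoint_radius,
        max_separation=max_separation,
    )


@dataclass
class SensitivityCurve:
    """Mean partition proportions per SD-separation bin.

    ``table`` columns: bin_center_mm, partition, mean, se, n.  ``se`` is NaN
    where n == 1; empty bins are omitted rather than zero-filled.
    """

    table: pd.DataFrame
    bin_width: float = 5.0
    label: str | None = None

    def at(self, bin_center: float, partition: str) -> pd.Series:
        t = self.table
        row = t[(t.bin_center_mm == bin_center) & (t.partition == partition)]
        if row.empty:
            raise KeyError(f"no bin {bin_center} mm for partition {partition}")
        return row.iloc[0]

    def partitions(self) -> list[str]:
        return list(dict.fromkeys(self.table.partition))


def bin_curve(
    separations,
    proportions: list[PartitionProportions],
    bin_width: float = 5.0,
    label: str | None = None,
) -> SensitivityCurve:
    """Average per-pair partition proportions into SD-separation bins.

    Bins are centred at integer multiples of ``bin_width`` with half-open
    edges ``[c - w/2, c + w/2)`` — e.g. the 30 mm bin collects pairs
    27.5–32.5 mm apart.  The standard error is over pairs within the bin.
    """
    separations = np.asarray(separations, dtype=float)
    if len(separations) != len(proportions):
        raise ValueError("separations and proportions differ in length")
    if len(separations) == 0:
        raise ValueError("need at least one pair")
    centers = np.round(separations / bin_width) * bin_width
    # half-open edges: a separation exactly on the upper edge belongs up
    on_upper = np.isclose(separations, centers + bin_width / 2)
    centers[on_upper] += bin_width
    names: list[str] = []
    for p in proportions:
        for k in p.proportions:
            if k not in names:
                names.append(k)
    rows = []
    for c in np.unique(centers):
        sel = [p for p, cc in zip(proportions, centers) if cc == c]
        for name in names:
            vals = np.asarray([p.get(name, 0.0) for p in sel])
            n = len(vals)
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append({
                "bin_center_mm": float(c),
                "partition": name,
                "mean": float(vals.mean()),
                "se": se,
                "n": n,
            })
    return SensitivityCurve(table=pd.DataFrame(rows), bin_width=bin_width,
                            label=label)


def aggregate_locations(curves: list[SensitivityCurve]) -> SensitivityCurve:
    """Average per-location curves; SE becomes the across-location error.

    Bins present at only some locations are averaged over the locations
    that report them.  Order of the input curves does not matter.
    """
    if not curves:
        raise ValueError("need at least one curve")
    cat = pd.concat([c.table for c in curves], ignore_index=True)
    out = (
        cat.groupby(["bin_center_mm", "partition"], sort=True)["mean"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    out["se"] = np.where(out["count"] > 1,
                         out["std"] / np.sqrt(out["count"]), np.nan)
    out = out.rename(columns={"count": "n"}).drop(columns="std")
    out = out[["bin_center_mm", "partition", "mean", "se", "n"]]
    return SensitivityCurve(table=out, bin_width=curves[0].bin_width,
                            label="aggregate")


def save_curve_tsv(curve: SensitivityCurve, path) -> None:
    curve.table.to_csv(path, sep="\t", index=False)


def save_map_nifti(tpm: ThreePointMap, path) -> None:
    import nibabel as nib

    affine = np.diag([tpm.voxel_size] * 3 + [1.0])
    affine[:3, 3] = tpm.origin
    nib.save(nib.Nifti1Image(tpm.values.astype(np.float32), affine), str(path))
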