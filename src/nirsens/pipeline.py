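"""End-to-end orchestration: phantom -> MC -> sensitivity -> depth fits.

A single declarative :class:`RunConfig` drives the whole workflow with a
fixed seed; every artifact is written with a sidecar carrying the package
version, the seed and a hash of the configuration, and a JSON manifest
lists every output with its SHA-256 checksum.  Fluence grids are cached on
disk keyed by (phantom, source point, MC settings) so partial re-runs only
recompute what is missing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .depth_regression import depth_profile, fits_table, rule_of_thumb
from .head_model import (HeadVolume, SurfacePoint, build_layered_slab,
                         build_layered_sphere, compute_shells,
                         place_surface_points, save_label_volume,
                         tissue_partition, brain_partition)
from .mc_transport import (FluenceGrid, OpticalProperties, SimConfig,
                           normalize_fluence, run_mc)
from .sensitivity import (aggregate_locations, bin_curve, enumerate_pairs,
                          partition_sums, three_point, threshold_map)

log = logging.getLogger("nirsens")


@dataclass
class RunConfig:
    """Declarative description of one phantom sensitivity study."""

    # phantom
    geometry: str = "sphere"  # "sphere" | "slab"
    outer_radius_mm: float = 60.0
    extent_mm: tuple = (60.0, 60.0, 60.0)
    thicknesses_mm: tuple = (6.9, 6.1, 2.0, 4.0)
    voxel_size_mm: float = 1.0
    # optics
    anisotropy_g: float = 0.01
    refractive_index: float = 1.0
    # surface points & pairing
    point_spacing_mm: float = 5.0
    targets_mm: list | None = None  # default: phantom apex
    midpoint_radius_mm: float = 10.0
    max_separation_mm: float = 60.0
    bin_width_mm: float = 5.0
    max_points_per_target: int | None = 24
    # Monte Carlo
    n_photons: int = 1_000_000
    seed: int = 0
    t_max_ns: float = 10.0
    collection_radius_mm: float = 1.5
    # analysis
    masking_orders: list = field(default_factory=lambda: [float("inf")])
    n_shells: int = 21
    shell_step_voxels: int = 2
    rule_of_thumb_range_mm: tuple = (20.0, 40.0)
    out_dir: str = "nirsens_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "masking_orders" in data:
            data["masking_orders"] = [
                float("inf") if o in ("inf", "none", None) else float(o)
                for o in data["masking_orders"]
            ]
        for k in ("extent_mm", "thicknesses_mm", "rule_of_thumb_range_mm"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["masking_orders"] = [
            "inf" if np.isinf(o) else o for o in d["masking_orders"]
        ]
        for k in ("extent_mm", "thicknesses_mm", "rule_of_thumb_range_mm"):
            d[k] = list(d[k])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pkg_version() -> str:
    from . import __version__

    return __version__


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_meta(path: Path, cfg: RunConfig, extra: dict | None = None) -> None:
    meta = {
        "version": _pkg_version(),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }
    if extra:
        meta.update(extra)
    side = path.with_suffix(path.suffix + ".meta.json")
    side.write_text(json.dumps(meta, sort_keys=True, indent=1))


def _build_phantom(cfg: RunConfig) -> HeadVolume:
    if cfg.geometry == "sphere":
        return build_layered_sphere(cfg.outer_radius_mm, cfg.thicknesses_mm,
                                    cfg.voxel_size_mm)
    if cfg.geometry == "slab":
        return build_layered_slab(cfg.extent_mm, cfg.thicknesses_mm,
                                  cfg.voxel_size_mm)
    raise ValueError(f"unknown geometry {cfg.geometry!r}")


def _default_target(head: HeadVolume) -> np.ndarray:
    """Apex of the phantom: the surface voxel with the largest z."""
    surf = head.scalp_surface_mask()
    pts = head.voxel_centers_mm(surf)
    return pts[np.argmax(pts[:, 2])]


def _fluence_cache_key(cfg: RunConfig, point: SurfacePoint, seed: int) -> str:
    payload = json.dumps(
        {
            "phantom": [cfg.geometry, cfg.outer_radius_mm,
                        list(cfg.extent_mm), list(cfg.thicknesses_mm),
                        cfg.voxel_size_mm],
            "optics": [cfg.anisotropy_g, cfg.refractive_index],
            "pos": [round(float(x), 6) for x in point.position],
            "dir": [round(float(x), 6) for x in point.direction],
            "mc": [cfg.n_photons, seed, cfg.t_max_ns],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:20]


def _load_cached_fluence(path: Path, head: HeadVolume) -> FluenceGrid | None:
    if not path.exists():
        return None
    try:
        values = np.load(path)
        meta = json.loads(
            path.with_suffix(".json").read_text())
    except (OSError, ValueError):
        return None
    return FluenceGrid(
        values=values,
        n_launched=int(meta["n_launched"]),
        voxel_size=head.voxel_size,
        origin=head.origin.copy(),
        source_position=np.asarray(meta["source_position"]),
        normalized=False,
        seed=int(meta["seed"]),
        energy_balance=meta.get("energy_balance"),
    )


def simulate_point(
    head: HeadVolume,
    optics: OpticalProperties,
    point: SurfacePoint,
    n_photons: int,
    seed: int,
    t_max_ns: float = 10.0,
) -> FluenceGrid:
    """Run one MC simulation for an injection point (no detectors)."""
    cfg = SimConfig(n_photons=n_photons, seed=seed, t_max_ns=t_max_ns)
    grid, _ = run_mc(head, optics, point, detectors=None, config=cfg)
    return grid


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow for one configuration; return the manifest.

    Stages: phantom construction, surface-point placement, SD-pair
    enumeration around each target, one MC simulation per unique point
    (cached), 3-point map formation, tissue/brain/shell partition sums with
    optional dynamic-range masking, separation-binned curves per target,
    across-target aggregation, shell depth profiles and exponential fits.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache_dir = out / "fluence"
    cache_dir.mkdir(exist_ok=True)
    manifest: dict = {
        "version": _pkg_version(),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "artifacts": [],
    }

    def record(path: Path, stage: str, computed: bool = True) -> None:
        manifest["artifacts"].append({
            "path": str(path.relative_to(out)),
            "stage": stage,
            "sha256": _sha256(path),
            "computed": computed,
        })

    stage = "phantom"
    try:
        head = _build_phantom(cfg)
        phantom_path = out / "phantom.nii"
        save_label_volume(head, phantom_path)
        _write_meta(phantom_path, cfg)
        record(phantom_path, stage)

        stage = "surface_points"
        points = place_surface_points(head, spacing=cfg.point_spacing_mm)
        targets = (cfg.targets_mm if cfg.targets_mm is not None
                   else [_default_target(head)])
        targets = [np.asarray(t, dtype=float) for t in targets]

        stage = "pair_enumeration"
        pairsets = [
            enumerate_pairs(points, t, cfg.midpoint_radius_mm,
                            cfg.max_separation_mm)
            for t in targets
        ]
        needed: list[int] = []
        for k, ps in enumerate(pairsets):
            idx = sorted({i for pair in ps.pairs for i in pair})
            if (cfg.max_points_per_target is not None
                    and len(idx) > cfg.max_points_per_target):
                keep = np.linspace(0, len(idx) - 1,
                                   cfg.max_points_per_target).astype(int)
                kept = {idx[i] for i in keep}
                mask = np.array([p[0] in kept and p[1] in kept
                                 for p in ps.pairs], dtype=bool)
                ps.pairs = [p for p, m in zip(ps.pairs, mask) if m]
                ps.separations = ps.separations[mask]
                ps.midpoints = ps.midpoints[mask]
                idx = sorted(kept)
            needed.extend(idx)
        needed = sorted(set(needed))
        if not needed:
            raise RuntimeError("no SD pairs satisfy the constraints")
        log.info("pipeline: %d unique injection points to simulate",
                 len(needed))

        stage = "monte_carlo"
        optics = OpticalProperties.default_head(g=cfg.anisotropy_g,
                                                n=cfg.refractive_index)
        fluences: dict[int, FluenceGrid] = {}
        for i in needed:
            seed_i = (cfg.seed + 7919 * (i + 1)) % (2**31)
            key = _fluence_cache_key(cfg, points[i], seed_i)
            fpath = cache_dir / f"fluence_{key}.npy"
            grid = _load_cached_fluence(fpath, head)
            computed = grid is None
            if computed:
                log.info("MC %d/%d: point %d (%.0f photons)",
                         len(fluences) + 1, len(needed), i, cfg.n_photons)
                grid = simulate_point(head, optics, points[i],
                                      cfg.n_photons, seed_i, cfg.t_max_ns)
                np.save(fpath, grid.values)
                fpath.with_suffix(".json").write_text(json.dumps({
                    "n_launched": grid.n_launched,
                    "seed": grid.seed,
                    "source_position": [float(x) for x in
                                        grid.source_position],
                    "energy_balance": grid.energy_balance,
                }, sort_keys=True))
                _write_meta(fpath, cfg, {"point_index": i})
            record(fpath, stage, computed)
            fluences[i] = normalize_fluence(grid)

        stage = "sensitivity"
        tissue_spec = tissue_partition(head)
        brain_spec = brain_partition(head)
        shells = compute_shells(head, cfg.n_shells, cfg.shell_step_voxels,
                                include_core=True)
        primary_orders = cfg.masking_orders[0]
        curves: dict[tuple, list] = {}
        all_maps = []
        for tnum, ps in enumerate(pairsets):
            if not ps.pairs:
                continue
            props: dict[tuple, list] = {}
            seps = []
            for (i, j), sep in zip(ps.pairs, ps.separations):
                if i not in fluences or j not in fluences:
                    continue
                tpm = three_point(fluences[i], fluences[j],
                                  source_id=i, detector_id=j)
                for orders in cfg.masking_orders:
                    masked = (tpm if np.isinf(orders)
                              else threshold_map(tpm, orders))
                    for name, spec in (("tissue", tissue_spec),
                                       ("brain", brain_spec)):
                        props.setdefault((name, orders), []).append(
                            partition_sums(masked, spec))
                    if orders == primary_orders:
                        masked.separation = sep
                        all_maps.append(masked)
                seps.append(sep)
            for key, plist in props.items():
                curves.setdefault(key, []).append(
                    bin_curve(seps, plist, cfg.bin_width_mm,
                              label=f"target_{tnum}"))

        for (name, orders), clist in curves.items():
            agg = (aggregate_locations(clist) if len(clist) > 1
                   else clist[0])
            tag = "" if np.isinf(orders) else f"_om{int(orders)}"
            cpath = out / f"curve_{name}{tag}.tsv"
            agg.table.to_csv(cpath, sep="\t", index=False)
            _write_meta(cpath, cfg)
            record(cpath, stage)

        stage = "depth_regression"
        profile = depth_profile(all_maps, shells, cfg.bin_width_mm)
        ppath = out / "depth_profile.tsv"
        profile.curve.table.to_csv(ppath, sep="\t", index=False)
        _write_meta(ppath, cfg)
        record(ppath, stage)

        fits = [f for f in profile.fits() if f.converged]
        if fits:
            tab = fits_table(fits)
            tpath = out / "depth_fits.tsv"
            tab.to_csv(tpath, sep="\t", index=False)
            _write_meta(tpath, cfg)
            record(tpath, stage)
            lo, hi = cfg.rule_of_thumb_range_mm
            in_range = [f for f in fits if lo <= (f.separation or -1) <= hi]
            if in_range:
                b_bar, c_bar = rule_of_thumb(in_range)
                manifest["rule_of_thumb"] = {"b": b_bar, "c": c_bar}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# Demo fixtures


def make_demo_fixtures(out_dir, seed: int = 0) -> dict:
    """Write a small fixture set for fast tests and examples.

    Contents: a layered slab phantom, a 45 mm layered sphere phantom, the
    default optics table as TSV, and a pair of tiny precomputed fluence
    grids on the slab (with their checksums and seed recorded), all
    loadable through the public readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    slab = build_layered_slab(extent=(40.0, 40.0, 40.0), voxel_size=2.0)
    slab_path = out / "slab_phantom.nii"
    save_label_volume(slab, slab_path)
    files["slab_phantom"] = str(slab_path)

    sphere = build_layered_sphere(45.0, voxel_size=2.0)
    sphere_path = out / "sphere_phantom.nii"
    save_label_volume(sphere, sphere_path)
    files["sphere_phantom"] = str(sphere_path)

    optics = OpticalProperties.default_head()
    optics_path = out / "optics.tsv"
    optics.to_table().to_csv(optics_path, sep="\t", index=False)
    files["optics"] = str(optics_path)

    points = place_surface_points(slab, spacing=10.0)
    apex = _default_target(slab)
    points = sorted(points, key=lambda p: np.linalg.norm(p.position - apex))
    checks = {}
    for k, pt in enumerate(points[:2]):
        cfgk = SimConfig(n_photons=5000, seed=seed + k)
        grid, _ = run_mc(slab, optics, pt, config=cfgk)
        fpath = out / f"fluence_demo_{k}.npy"
        np.save(fpath, grid.values)
        files[f"fluence_{k}"] = str(fpath)
        checks[f"fluence_demo_{k}.npy"] = {
            "sha256": _sha256(fpath),
            "seed": cfgk.seed,
            "n_photons": cfgk.n_photons,
            "source_position": [float(x) for x in pt.position],
            "source_direction": [float(x) for x in pt.direction],
        }
    (out / "checksums.json").write_text(json.dumps(checks, sort_keys=True,
                                                   indent=1))
    files["checksums"] = str(out / "checksums.json")
    return files
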