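# nirsens

Monte Carlo photon transport and depth-sensitivity analysis for
near-infrared neuromonitoring (NIRS/NIN).

Continuous-wave NIRS infers brain hemodynamics from light re-emitted at the
scalp, but most of what a source–detector (SD) pair measures comes from
scalp, skull and CSF. `nirsens` quantifies *where* such a measurement is
sensitive: it simulates near-infrared photon migration through a voxelized
five-tissue head model (scalp, skull, CSF, gray, white), forms the spatial
sensitivity map of an SD pair, and summarizes how sensitivity partitions
over tissues and decays with depth below the inner skull surface.

## What it computes

- **2-point Green's function** `G(r_s, r)`: per-voxel photon fluence from a
  surface source, estimated by a weighted-photon random walk — exponential
  step lengths with the local scattering coefficient μ_s, Beer–Lambert
  absorption weighting `exp(-μ_a ℓ)` per voxel segment, Henyey–Greenstein
  scattering with anisotropy g, unpolarized Fresnel reflection at the
  tissue–air boundary, and a 10 ns time-of-flight cutoff.
- **3-point sensitivity map** `W(r) = G(r_s, r) · G(r, r_d)` (optical
  reciprocity): the banana-shaped sensitivity profile of one SD pair to a
  local absorption change. Instrument dynamic range is emulated by masking
  `W` below k orders of magnitude from its peak.
- **Partition sensitivities**: `S_p = Σ_{r∈p} W(r) / Σ_r W(r)` for any
  partition p — tissue classes, brain (gray+white) vs non-brain, or
  concentric depth shells obtained by iteratively eroding the intracranial
  mask.
- **Exponential depth model**: nonlinear least-squares fit of
  `S(d) = a + b·c^d` to the shell-resolved profile (d = depth in mm below
  the inner skull surface), and the rule-of-thumb summary obtained by
  averaging b and c over 20–40 mm separations, `S(d) ≈ 0.075 · 0.85^d`.

Synthetic layered head phantoms (concentric spheres or slabs with
configurable thicknesses; defaults: scalp 6.9, skull 6.1, CSF 2, gray 4 mm
over a white core) stand in for a segmented MRI template, so everything
runs with no external data; any segmented NIfTI label volume with codes
0=air … 5=white can be substituted.

## Worked example

```python
import numpy as np
import nirsens as ns

head = ns.build_layered_sphere(outer_radius=60.0)   # 5-layer head phantom
optics = ns.OpticalProperties.default_head()        # adult-head coefficients
points = ns.place_surface_points(head, spacing=5.0)

pos = np.array([p.position for p in points])
src = points[int(np.argmax(pos[:, 2]))]             # pole
det = points[int(np.argmin(np.abs(                  # ~30 mm away
    np.linalg.norm(pos - src.position, axis=1) - 30.0)))]

grids = []
for k, pt in enumerate((src, det)):
    g, _ = ns.run_mc(head, optics, pt,
                     config=ns.SimConfig(n_photons=200_000, seed=k))
    grids.append(ns.normalize_fluence(g))

tpm = ns.three_point(*grids)
props = ns.partition_sums(tpm, ns.tissue_partition(head))
print(f"separation: {tpm.separation:.1f} mm")
for name, p in props.proportions.items():
    print(f"  {name:6s} {100 * p:5.2f} %")

shells = ns.compute_shells(head, include_core=True)
fit = ns.depth_profile([tpm], shells).fit_at(30.0)
print(f"depth model: S(d) = {fit.a:.4f} + {fit.b:.4f} * {fit.c:.4f}^d "
      f"(adj R^2 = {fit.adj_r2:.3f})")
```

Output:

```
separation: 29.9 mm
  scalp  43.01 %
  skull  40.49 %
  csf     8.32 %
  gray    6.96 %
  white   1.22 %
depth model: S(d) = -0.0004 + 0.1134 * 0.6706^d (adj R^2 = 0.993)
```

Reading: at a 30 mm separation on this phantom, ~8% of the measurement's
sensitivity comes from brain tissue (gray+white) and over 80% from scalp
and skull; sensitivity inside the skull decays exponentially with depth,
dropping about an order of magnitude in the first ~6 mm. On a smooth
concentric phantom the decay (c ≈ 0.67 per mm) is steeper than in a real,
folded head — see `docs/methods.md` for why.

## Command line

```sh
nirsens phantom  --geometry sphere --radius 60 --out phantom.nii
nirsens simulate --head phantom.nii --source 62 62 6 --photons 1000000 \
                 --seed 1 --out run/
nirsens sensitivity --head phantom.nii --src-fluence run/fluence.npy \
                 --det-fluence run2/fluence.npy --partition tissues --out sens/
nirsens depthfit --profiles profiles.tsv --out table.tsv
nirsens pipeline --config study.yaml        # end-to-end, cached + manifest
nirsens fixtures --out fixtures/
```

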