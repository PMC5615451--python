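# csfpulse

Separation and quantification of cardiac- and respiratory-driven
cerebrospinal fluid (CSF) motion from asynchronous 2D phase-contrast (PC)
MRI velocity time series.

CSF in the cerebral aqueduct and at the foramen magnum oscillates with two
drivers: a fast pulsation locked to the heartbeat and a slower, larger
excursion locked to breathing. Given an ungated single-slice PC series
(frame interval Δt, velocity encoding VENC, positive velocity = cranial),
`csfpulse`:

1. decodes phase to velocity (v = VENC·φ/π) with aliasing detection;
2. segments CSF regions under partial volume with spatially regularized
   fuzzy c-means on the temporal-fluctuation image (or accepts mask files);
3. splits every voxel waveform by DFT band selection into a **cardiac**
   component (1.0–1.6 Hz), a **respiratory** component (0.018–0.3 Hz) and a
   residual, with exact additivity;
4. quantifies, per region × direction (cranial/caudal) × component, the
   peak velocity v_c, v_r, the per-excursion displacement
   `D = (1/N) Σ_n [Δt Σ_m v(m·Δt)]` (inner sum over the M same-sign time
   points of a directional excursion, averaged over excursions and the N
   ROI voxels), and the fractions `F_r = v_r/(v_r + v_c)`, `F_c = 1 − F_r`
   for both velocity and displacement;
5. compares fractions across a cohort with exact two-sided Mann–Whitney U
   and two-sample Kolmogorov–Smirnov tests.

A synthetic acquisition generator (256×256 slice, 253 frames at
Δt = 0.217 s, VENC 10 cm/s, guided respiration at 6/10/16 s, ground truth
included) provides everything needed to exercise and validate the chain
without scan data.

## Worked example

```python
import csfpulse as cp

cfg = cp.SyntheticConfig(grid_size=64, seed=3)     # one synthetic subject
phase, truth = cp.generate_subject(cfg)
vel = cp.phase_to_velocity(phase)
components = cp.decompose(vel)                      # band separation
metrics = cp.quantify_subject(components, truth.masks, meta=vel.meta)
for m in metrics:
    print(f"{m.region:15s} {m.direction:7s} v_c={m.v_c:.3f} v_r={m.v_r:.3f} "
          f"F_c={m.f_c:.2f} D_c={m.d_c:.3f} D_r={m.d_r:.3f} F_r_disp={m.f_r_disp:.2f}")
```

```
aqueduct        cranial v_c=0.120 v_r=0.071 F_c=0.63 D_c=0.027 D_r=0.109 F_r_disp=0.80
aqueduct        caudal  v_c=-0.121 v_r=-0.075 F_c=0.62 D_c=-0.027 D_r=-0.121 F_r_disp=0.82
foramen_magnum  cranial v_c=0.850 v_r=0.333 F_c=0.72 D_c=0.218 D_r=0.562 F_r_disp=0.72
foramen_magnum  caudal  v_c=-0.844 v_r=-0.339 F_c=0.71 D_c=-0.214 D_r=-0.624 F_r_disp=0.74
```

Reading the numbers: velocities are in cm/s (caudal negative),
displacements in cm. The cardiac component is the faster one — its peak
velocity dominates (F_c ≈ 0.6–0.7) — while the respiratory component,
though slower, integrates for ~3 s before reversing and therefore travels
farther per excursion (respiratory displacement fraction ≈ 0.7–0.8). The
aqueduct velocities sit below the injected 0.2/0.12 cm/s because the
1-voxel partial-volume blur attenuates a 2–3-voxel structure; fractions are
unaffected since both components attenuate identically.

A full cohort (7 subjects × 3 respiratory periods) with rank-test readout:

```python
result = cp.run_cohort_analysis(n_subjects=7,
                                base_config=cp.SyntheticConfig(grid_size=64, seed=11))
print(result.stats[["region", "direction", "metric", "comparison",
                    "resp_period", "p_mwu", "greater"]].head())
```

The same stages are available from the shell:

```bash
csfpulse simulate --config cfg.yaml --seed 1 --out sim/
csfpulse decompose --in sim/phase.nii --out comp/
csfpulse quantify --components comp/ --masks sim/truth_masks.nii --out metrics.csv
csfpulse stats --metrics metrics.csv --out stats.csv
csfpulse run-all --config cfg.yaml --seed 1 --out cohort/
```

Series are 4D NIfTI (x, y, 1, t) with a JSON sidecar carrying
`{dt, venc, duration, resp_period, subject_id}`; masks are integer label
NIfTIs; metric and statistics tables are CSV.

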