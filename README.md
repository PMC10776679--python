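# tiltscf

Quantitative diagnostics and planning for preferred-orientation pathology in
single-particle cryo-EM:

* **Fourier-shell sampling** of an orientation distribution via the
  central-slice theorem (each projection contributes its central-plane great
  circle to every shell), binned on a quasi-equal-area spherical grid;
* the **sampling compensation factor (SCF)** — harmonic mean of the shell
  sampling density divided by the arithmetic mean (1 for uniform coverage,
  8/π² ≈ 0.81 for pure side views, → 0 for concentrated distributions) — with
  explicit zero-bin policies (`strict` and the floored `SCF*` variant);
* the **stage-tilt transform** of an orientation set (a lab-frame rotation
  composed onto every particle; a preferred-orientation cluster spreads into
  a cone of half-angle equal to the tilt) plus the 1/cos(tilt) effective
  ice-thickness factor;
* a **minimal-tilt optimizer**: tilt sweeps with replicate averaging,
  decision heat-map grids over cone half-angle × sprinkle fraction × tilt,
  and a recommender that scans a given (experimental or synthetic)
  orientation set against the fully-sampled threshold 0.81;
* **global and directional FSC**: shell correlation of half-map pairs,
  resolution at the 0.143 threshold crossing, conical (directional) FSC,
  assembled 3D FSC volumes, and seeded synthetic half-map generators with
  prescribed per-shell SNR and optional directional attenuation.

Synthetic orientation scenarios (uniform, single cone, two orthogonal cones,
side-like, top-like, with "sprinkled" random views) are first-class, seeded
generators, so every analysis is reproducible without external data.

## Command line

```sh
# generate a synthetic scenario as a 3-column Euler angle file (degrees)
tiltscf simulate --scenario single_cone --half-angle 15 --sprinkles 0.2 \
    --n 10000 --seed 1 --out angles.txt

# SCF / SCF* of an orientation file (STAR or 3-column text), optionally tilted
tiltscf scf --angles angles.txt --tilt 60

# minimal qualifying stage tilt against the 0.81 threshold
tiltscf predict-tilt --angles particles.star --threshold 0.81 --fine

# decision grid over cone half-angle x sprinkle fraction x tilt
tiltscf heatmap --scenario single_cone --out grid.tsv --figure grid.png

# global and directional FSC of two MRC half maps
tiltscf fsc half1.mrc half2.mrc --out fsc.tsv
tiltscf fsc3d half1.mrc half2.mrc --volume-out fsc3d.mrc
```

Orientation files use the RELION ZYZ Euler convention (`rot`, `tilt`, `psi`,
degrees); STAR files need the `_rlnAngleRot/_rlnAngleTilt/_rlnAnglePsi`
columns (legacy and optics-group layouts both work). Volumes are MRC2014.

## Layout

| module | contents |
| --- | --- |
| `tiltscf.geometry` | Euler/rotation conversions, viewing directions, `OrientationSet` |
| `tiltscf.distributions` | seeded scenario generators and `DistributionSpec` |
| `tiltscf.tilt` | stage-tilt transform, ice-thickness factor |
| `tiltscf.sampling` | shell grid, great-circle accumulation, SCF/SCF* |
| `tiltscf.optimizer` | tilt scans, minimal-tilt search, heat-map grids |
| `tiltscf.fsc` | global/conical/3D FSC, synthetic half maps |
| `tiltscf.io` | STAR / 3-column Euler / MRC2014 readers and writers |
| `tiltscf.cli` | `tiltscf` command group |
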