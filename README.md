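# footmetry

3D morphometry of the weight-bearing foot skeleton from per-bone surface
meshes, for researchers studying foot deformity (in particular adult
flexible flatfoot, *pes planovalgus*) with weight-bearing cone-beam CT.

Standing radiographic angles — Meary, Hibb, Moreau–Costa–Bertani,
calcaneal pitch — are two-dimensional projections, sensitive to foot
positioning and bone superimposition. When each bone of a standing foot is
segmented into a 3D surface mesh, the same alignment quantities can be
computed objectively from anatomical axes embedded in the bones
themselves. `footmetry` implements that pipeline end to end:

* **Foot anatomical frame (FootAF).** Vertical axis `w` normal to the
  segmented ground plane; anteroposterior axis `u` along the ground-plane
  segment from the projected plantar point of the calcaneus to that of the
  second metatarsal head; `v = u × w` completes the right-handed triad.
* **PCA bone axes.** For each bone with welded surface vertices
  `x₁ … xₙ`, the eigenvectors of the covariance `C = (1/n) Σ (xᵢ−x̄)(xᵢ−x̄)ᵀ`
  ordered by decreasing eigenvalue give the longitudinal, mediolateral and
  dorsoplantar axes, with deterministic sign fixing against the FootAF.
* **32 measurements** over the tibia (TI), calcaneus (CA), talus (TA),
  navicular (NA), cuboid (CU), medial cuneiform (CM) and metatarsals
  (M1, M2, M5): absolute inclinations `I` and relative angles `R` of the
  longitudinal axes, each as lateral (`L`), frontal (`F`) and transverse
  (`T`) plane projections and as the single 3D angle (`3`); minimum bone
  heights above the ground `Hg`; and the foot–ankle offset `FAO` of the
  talus centre from the calcaneus–metatarsal weight-bearing tripod, in mm
  and as % of foot length. For example `RL_TAM1 = IL_M1 − IL_TA` is the
  Meary angle (negative in flatfoot) and `RL_CAM1 = 180° − (IL_M1 −
  IL_CA)` the Hibb angle.
* **Synthetic feet with exact ground truth.** Bones are posed
  superellipsoids, so every measurement's true value is available in
  closed form; perturbation modes emulate a dense noisy semi-automatic
  segmentation ("MIS-like") and a smooth decimated automatic one
  ("DIS-like").
* **Cohort statistics** for paired method comparison: Lilliefors-gated
  paired t / Wilcoxon signed-rank tests, Pearson r/r², per-code difference
  boxplots with a threshold count, and the a-priori sample-size formula
  `n = ⌈2 (z₁₋α⁄₂ + z₁₋β)² (σ/δ)²⌉`.

## Worked example

```sh
python examples/01_measure_synthetic_foot.py
```

```
foot flatfoot-template: 32 measurements
code        measured     truth  meaning
RL_TAM1       -11.93    -11.90  Meary angle (talus vs 1st metatarsal, lateral); negative = flatfoot
IL_CA          -8.99     -8.99  calcaneal inclination, lateral (negative = anterior end dorsal)
I3_CA          -8.94     -8.94  calcaneal pitch measured in 3D
IT_TA          27.59     27.45  talar internal rotation, transverse plane
RL_CAM1       158.54    158.55  Hibb angle; approaches 180 deg as the arch flattens
RL_TACAM1     139.31    139.71  Moreau-Costa-Bertani medial arch angle, lateral
Hg_NA          24.22     24.22  navicular height above ground, mm
FAO_%          13.31     13.32  foot-ankle offset, % of foot length (valgus positive)
```

The *measured* column is what the mesh pipeline recovered from the
triangulated bones; *truth* is the generator's closed-form value from the
design poses. A Meary angle of −12° with a flattened arch (Hibb near 160°)
and a large positive foot–ankle offset is the signature of a severe
flexible flatfoot. `examples/02_method_comparison.py` runs the paired
MIS-like vs DIS-like statistics on a small cohort, and
`examples/03_power_analysis.py` the sample-size computation (16 feet at
the reference design point).

## Command line

For measuring real segmentations exported as STL files
(`<footid>_<BONE>.stl` plus `<footid>_GROUND.stl` per directory, bone
codes as above):

```sh
footmetry generate --n 21 --seed 1 --out cohort/      # synthetic cohort
footmetry measure cohort/MIS-like --out mis.csv
footmetry measure cohort/DIS-like --out dis.csv
footmetry compare --a mis.csv --b dis.csv --out report/
footmetry power --alpha 0.05 --power 0.8 --delta 1 --sigma 1
```

Left feet (`--side LEFT`) are mirrored to right-side convention before
measurement so signed angles pool consistently.

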