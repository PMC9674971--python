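# wormstretcher

Growth and body-shape dynamics of *Caenorhabditis elegans* larvae from
large-particle flow-cytometer (COPAS BIOSORT–style) time courses, with a
seeded synthetic-data generator so the whole pipeline is testable without
instrument data.

## The problem

*C. elegans* grows through four larval stages (L1–L4) separated by molts, in
which the collagen-rich cuticle is shed and resynthesized. Cuticle-collagen
mutants (Dpy: short and wide; Lon: long) distort both size and developmental
timing. A high-throughput growth assay samples a growing population every
hour, measuring for every detected object:

- **TOF** (time of flight) — proportional to axial length,
- **EXT** (optical extinction); **norm.EXT = EXT/TOF** — a width proxy,
- **red fluorescence** of ingested beads — a feeding proxy, since feeding
  stops during lethargus, fluorescence dips mark molts.

The **Stretcher model** treats the cuticle as an elastic shell constraining
growth: while it stretches linearly, the local slope ratio

    r(t) = dW/dt ÷ dL/dt  =  dW/dL

is constant within a stage; as the cuticle stiffens near the end of a stage,
r(t) rises (nonlinear stretch); at the molt, shedding produces a *post-molt
relaxation* — a step change in shape whose direction (length vs width) can
differ by genotype.

## What the package does

| step | module | method |
|---|---|---|
| synthesize assay | `simulate` | seeded generator: 4 strain profiles (N2, *dpy-1*, *dpy-5*, *lon-3*), hourly sampling 1–42 h, per-stage growth with lethargus plateaus, planted dW/dL regimes, feeding dips, relaxation steps, contaminant objects |
| gate + summarize | `preprocess` | BIC-selected Gaussian-mixture gating on (log TOF, log EXT) pooled per hour; per-well medians; through-origin micron calibration against manual pixel measurements (3.2937 px/µm) |
| molt timing | `molts` | prominent minima of the kernel-smoothed population fluorescence; per-stage strain ranking |
| shape dynamics | `stretcher` | tricube local-linear kernel regression with derivative estimates; cluster bootstrap over wells; per-replicate slope ratio r(t) with SD band; linear/nonlinear segmentation; relaxation direction |
| figures/tables | `report` | Tukey boxplots, length–width phase plane, r(t) curves with SD shading, deterministic CSVs + manifest |

## Worked example

```python
import numpy as np
import wormstretcher as ws

cfg = ws.default_config(n_wells_per_hour=12, n_animals_per_well=30,
                        contaminant_rate=0.15, seed=3)
df = ws.simulate_dataset(cfg)                      # 60,480 object records
kept, removed = ws.gate_animals(df)
summ = ws.summarize_wells(kept, removed)
manual = ws.simulate_manual_measurements(df, seed=3)
model = ws.fit_calibration(manual, summ)
print(round(model.tof_to_um_slope, 5))             # 0.30358  (≈ 1/3.2937)
su = ws.convert_units(summ, model)

for s in ws.build_fluorescence_series(su):
    print(s.strain_id, ws.detect_molts(s).molt_times)
# N2    (14.0, 25.0, 33.0)
# dpy-1 (17.5, 28.75, 36.0)     <- dpy-1 molts latest at every transition
# dpy-5 (16.5, 27.0, 35.75)
# lon-3 (14.0, 25.5, 34.0)

curve, ratio, seg = ws.analyze_stage(su, ws.StageWindowConfig(),
                                     "N2", "L2", n_boot=300, seed=1)
print(round(float(np.nanmean(ratio.ratio)), 3))    # 0.056  (baseline dW/dL c2 = 0.06)
print(seg.onset_time)                              # 21.0   (nonlinear stretch onset, h)
```

The molt times recover the planted stage boundaries of each strain profile
(to the 0.25 h detection grid); the slope-ratio mean recovers the profile's
linear-regime aspect slope, and the detected onset (planted at 20.85 h for
N2's L2 stage) marks where dW/dL starts rising as the cuticle stiffens.

The same pipeline is available from the shell:

```bash
wormstretcher simulate --out sim/ --seed 3
wormstretcher preprocess --raw sim/raw.csv --manual sim/manual.csv --out well_summaries.csv
wormstretcher molts --summaries well_summaries.csv --out molts.csv
wormstretcher analyze --summaries well_summaries.csv --windows paper --out analysis/
wormstretcher report --summaries well_summaries.csv --out report/
```

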