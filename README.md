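# chromotrack

Analysis of two-colour 3D live-cell locus-tracking data.

Chromatin conformation can be probed in living cells by inserting two
operator arrays (lacO, tetO) around a genomic region of interest and
imaging the bound fluorescent repressor fusions as diffraction-limited
green and red spots. `chromotrack` takes the resulting spot-tracking
tables and computes the statistics that characterise the tagged pair:

* **channel alignment and measurement error** — a coarse affine map
  plus a fine constant translation estimated from a *colocalising*
  control strain (one spot carrying both fluorophores, so its true
  inter-channel distance is zero); the residual mean 3D distance on
  that control is the workflow's measurement error;
* **quality control** — frames are dropped when either spot drifts
  within 1 µm of the Z-stack boundary or falls below contrast and
  intensity thresholds;
* **distance and compaction** — per-frame 3D separation *d*, the
  effective genomic separation *z* = *a* + 0.5 *x*<sub>p</sub> +
  0.5 *x*<sub>q</sub> of a construct with spacer *a* and operator
  arrays *x*<sub>p</sub>, *x*<sub>q</sub>, and the compaction ratio
  0.34 α / *d* (contour length of α bp of B-DNA over the measured
  distance in nm);
* **orientation anisotropy D** — each inter-locus vector is mapped
  area-preservingly onto the unit square,
  *u* = (atan2(*y*, *x*) + π)/2π, *v* = (|**r**| − *z*)/2|**r**|, and
  *D* is the one-sample two-dimensional Kolmogorov–Smirnov statistic of
  the (*u*, *v*) points against uniformity;
* **RV coefficient** — a multivariate generalisation of the squared
  Pearson correlation between the two loci's displacement series;
* **MSCD** — the mean square change in distance,
  ⟨(*d*(*t*+τ) − *d*(*t*))²⟩, binned in τ, with a bootstrap
  *between-cell baseline* built from random time points of different
  cells and a count-weighted plateau estimate;
* **inheritance test** — log2 compaction ratios of related
  mother/daughter pairs against randomly drawn unrelated pairs,
  compared with a Mann–Whitney rank-sum test (exact enumeration for
  small samples).

A synthetic trajectory generator (`chromotrack.simulate`) produces
tracking tables with the statistical structure the analysis assumes —
a mean-reverting (Ornstein–Uhlenbeck) inter-locus vector, confined
midpoint motion, per-channel Gaussian localisation noise, a constant
chromatic offset, QC covariates and mother/daughter lineages with a
tunable inheritance coefficient — so every stage is testable without
microscopy data.

## Worked example

```python
import chromotrack as ct

# colocalising control with a planted chromatic offset
cfg = ct.SimulationConfig(noise_sd=27.9, channel_offset=(50.0, -20.0, 80.0),
                          n_frames=20_000)
coloc = ct.simulate_colocalising_videos(cfg, 5, seed=1)
offsets = ct.estimate_fine_offsets(coloc)
aligned = ct.apply_fine_offsets(coloc, offsets)
mean, sd, n = ct.measurement_error(aligned)
print(f"offsets ({offsets.dx:.1f}, {offsets.dy:.1f}, {offsets.dz:.1f}) nm")
print(f"measurement error {mean:.1f} nm (sd {sd:.1f}, n={n})")
print(f"effective separation {ct.effective_separation_kb(60.6, 10.4, 10.4):.0f} kb")
```

prints

```
offsets (50.3, -19.8, 80.0) nm
measurement error 63.0 nm (sd 26.6, n=100000)
effective separation 71 kb
```

The recovered offsets match the planted (50, −20, 80) nm to within
Monte Carlo error; with 27.9 nm per-axis localisation noise in each
channel the residual error is the Maxwell mean 4·27.9/√π ≈ 63 nm; and
a construct with a 60.6 kb spacer flanked by 10.4 kb of operator
half-arrays has a 71 kb effective separation.

The same analysis runs end to end from a shell:

```
chromotrack run --seed 11 --out results/
```

which simulates a population, aligns, filters, and writes per-strain
summaries, dynamics tables (per-video D and RV, MSCD curves with
baseline and plateau) and the inheritance test result, plus a
`manifest.json` with seeds and per-stage counts.

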