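# circaphen

Circadian and metabolic phenotyping of metabolic-cage studies in mice.

Developmental interventions — here, in vitro fertilization and the embryo
culture temperature during the first cleavage — can leave lasting marks on an
animal's energy metabolism, circadian rhythms, sleep architecture, and brain
epigenetics. Characterizing such phenotypes means turning days of continuous
metabolic-cage recordings (oxygen consumption, CO₂ production, feeding,
locomotion, beam-break activity), glucose-tolerance tests, body-mass tables,
and immunofluorescence micrographs into a small set of comparable per-animal
statistics. `circaphen` implements that full analysis surface as a tested,
reusable library plus CLI, for physiologists and biostatisticians running
indirect-calorimetry studies.

## What it computes

**Time series.** Raw channel exports are re-binned onto a uniform grid
(default 30 min), annotated with the light–dark schedule (default 14 h light :
10 h dark, with elapsed hour 0 = dark onset = ZT0), and summarised as overall,
dark-phase and light-phase averages plus folded 24-h diurnal profiles
(mean ± SEM across days). The respiratory exchange ratio is derived as
RER = V̇CO₂ / V̇O₂ on the intersected time grid.

**Cosinor regression.** Each binned series is fitted with the classical
single-component cosinor at fixed period τ = 24 h,

    y(t) = M + A·cos(2π(t − φ)/τ) + e(t),

estimated by least squares on the equivalent linear form
`M + β_c·cos(2πt/τ) + β_s·sin(2πt/τ)`, giving the mesor M (rhythm-adjusted
mean), amplitude A = √(β_c² + β_s²) and acrophase φ (hours of daily peak,
referenced to dark onset). Skewed channels (feeding, locomotion) are fitted
after a natural-log transform.

**Sleep.** Sleep bouts are maximal runs of consecutive zero-activity epochs
(10 s epochs, ≥ 2 min by default). From the bout list the package derives per-
phase sleep percentages, episodes per hour, mean sleep-bout and mean wake-
episode durations.

**Group statistics.** Body mass is compared by one-way ANCOVA with littermate
count as a continuous covariate (litter size confounds pre-weaning growth),
followed by Fisher's LSD on the covariate-adjusted means; every other endpoint
is compared pairwise by the Mann–Whitney U test (exact for small tie-free
samples, tie-corrected normal approximation otherwise). Glucose tolerance is
summarised as the net trapezoid-rule area of glucose above its fasting
baseline over 0–120 min.

**Histology.** Nuclei are segmented on the DAPI channel by local-mean
adaptive thresholding (61 × 61 px window) refined with five iterations of
morphological opening; each histone-mark signal (e.g. H3K36me3, H3K27me3,
H3K9me2) is quantified per nucleus as mean mark intensity divided by mean
DAPI intensity over the same pixels.

**Synthetic data.** `circaphen.synthetic` generates every input above with
known ground truth — cosine-shaped channels, alternating-renewal sleep/wake
activity, GTT curves, litter-confounded mass tables, and fields of elliptical
nuclei with planted intensity ratios — so the whole pipeline is testable
end-to-end without any raw data.

## Worked example

```python
import numpy as np
from circaphen import (SyntheticDesign, gen_channel_series, bin_series,
                       fit_cosinor, analyze_sleep, gen_activity_trace,
                       gen_mass_table, ancova, lsd_posthoc)

design = SyntheticDesign(seed=1)          # 3 groups: 7 CNT, 10 IVF35, 10 IVF37

# circadian rhythm of oxygen consumption for one control animal
vo2 = gen_channel_series(design, "CNT_01", "vo2")       # 96 h at 6-min samples
fit = fit_cosinor(bin_series(vo2, 0.5))                 # 30-min bins
print(f"M={fit.mesor:.3f} L/h/kg  A={fit.amplitude:.3f}  phi={fit.acrophase:.2f} h")
# -> M=3.004 L/h/kg  A=0.494  phi=5.07 h

# sleep architecture from the beam-break trace
trace, _ = gen_activity_trace(design, "CNT_01")
arch = analyze_sleep(trace)               # 10 s epochs, 2-min threshold
print(f"sleep {arch.pct_sleep_total:.1f}%  light {arch.pct_sleep_light:.1f}%  "
      f"dark {arch.pct_sleep_dark:.1f}%")
# -> sleep 49.9%  light 67.6%  dark 25.2%

# covariate-adjusted body-mass comparison
records, _ = gen_mass_table(design)
res = ancova(records, "mass_10w")
print(f"F_group({res.df_group[0]},{res.df_group[1]}) = {res.F_group:.2f}, "
      f"p = {res.p_group:.3f}")
# -> F_group(2,23) = 1.89, p = 0.173
for c in lsd_posthoc(res):
    print(f"  {c.group_a} vs {c.group_b}: diff {c.difference:+.2f} g, p = {c.p:.3f}")
```

The cosinor line reads: this animal's oxygen consumption oscillates around a
rhythm-adjusted mean of 3.0 L/h/kg with a half peak-to-trough swing of
0.49 L/h/kg, peaking ~5 h after lights-off — closely recovering the
parameters the generator planted (M = 3, A = 0.5, φ = 5 h). The ANCOVA F compares the three groups' 10-week masses
after removing the littermate-count trend; each LSD line is an unadjusted
pairwise contrast of the covariate-adjusted means.

A full pipeline run (ingest → bin → cosinor/sleep/profiles → stats →
histology) is one command:

```sh
circaphen simulate --seed 1 --out data/
circaphen run --config run.yaml          # data_dir/out_dir + options
```

which writes tidy CSVs (`averages.csv`, `cosinor.csv`, `profiles.csv`,
`sleep.csv`, `gtt.csv`, `nuclei.csv`, `histo_summary.csv`, `stats.csv`) and a
reproducibility manifest.

## Layout

- `circaphen.io_phenomaster` — channel-table / GTT / mass-table ingestion and validation
- `circaphen.timeseries` — binning, phase schedules, phase averages, diurnal profiles
- `circaphen.cosinor` — fixed-period cosinor fits (linear and log variants)
- `circaphen.sleep` — inactivity-defined bout detection and architecture metrics
- `circaphen.groupstats` — ANCOVA + Fisher LSD, Mann–Whitney U, GTT AUC
- `circaphen.histoquant` — nuclei segmentation and mark/DAPI quantification
- `circaphen.synthetic` — ground-truth generators for every input
- `circaphen.pipeline` / `circaphen.cli` — end-to-end orchestration and the `circaphen` command

See `docs/methods.md` for the statistical methods, defaults, and their
rationale.
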