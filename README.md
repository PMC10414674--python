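# remotefit

A toolkit for **remote, smartphone-based fitness testing** and for the
statistics used to validate such devices. It covers the two field tests
most used as proxies for cardiorespiratory fitness and lower-limb
strength:

* the **6-minute walk test (6MWT)** — distance walked in 6 minutes,
  estimated here from a GPS fix stream recorded every ~5 s;
* the **30-second sit-to-stand test (30s-STS)** — number of complete
  chair stands in 30 s, counted here from a per-frame 2-D skeleton
  keypoint stream (COCO-17 layout) produced by any pose-estimation model.

Around the two measurement engines sits the complete
**measurement-properties pipeline** a validation study needs — criterion
validity, test-retest reproducibility, and interpretability — plus
synthetic-data generators with known ground truth so everything is
testable without any recorded data.

## What it computes

**6MWT engine** (`remotefit.geo_walk`). Consecutive GPS fixes are joined
by great-circle chords (haversine, R = 6 371 000 m); each interval gets a
speed; intervals with implausible speed (above v_max = 4 m/s, or above 3×
the rolling median of neighboring intervals) are flagged as GPS glitches
and their distance replaced by neighbor-median speed × duration; the
corrected distances are summed. A start gate requires horizontal accuracy
< 15 m for ≥ 5 s, and the Enright–Sherrill reference equations convert
the result to percent-of-predicted.

**30s-STS counter** (`remotefit.sts`). Knee (hip–knee–ankle) and hip
(shoulder–hip–knee) angles drive a sitting / transition / standing
classifier (sit ≤ 110°, stand ≥ 160°, left/right averaged with
single-side fallback); a median-filtered, debounced (0.2 s) state machine
emits one repetition per completed sit→stand pass; a repetition is
*correct* when both wrists stay within 0.6× shoulder breadth of the
chest (arms crossed) during the transition, *incorrect* otherwise or
when extension is incomplete.

**Statistics** (`remotefit.agreement`), in standard notation:

* Pearson ρ (with Shapiro–Wilk pre-check) and Lin's concordance
  correlation coefficient
  CCC = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²), with |CCC| ≤ |ρ|;
* relative measurement error rME = 100·|device − gold| / gold;
* Bland–Altman limits of agreement d̄ ± 1.96·SD(d);
* ICC(2,1) — two-way random effects, absolute agreement, single
  measurement: ICC = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n) —
  with F-based confidence bounds, and a covariate-adjusted variant from a
  linear mixed model (REML) with subject random intercepts;
* SEM = √VarError, MDC = 1.96·√2·SEM, MDC% = 100·MDC / mean;
* ICC sample size (Walter–Eliasziw–Donner):
  n = 1 + 2k(z_{α/2} + z_β)² / ((k−1) ln²C₀), C₀ = (1+kθ₀)/(1+kθ₁),
  θ = ρ/(1−ρ), with a Monte-Carlo power cross-check.

## Worked example

Simulate a noisy 540 m walk (100 m back-and-forth course, 1.5 m/s,
5 m GPS noise, 5% glitch intervals) and analyze it:

```sh
$ remotefit simulate --kind walk --noise-sd 5 --outlier-rate 0.05 --seed 7 --out-dir demo
$ remotefit sixmwt --input demo/walk.csv --age 40 --sex male --height-cm 175 --weight-kg 70
{
  "total_distance_m": 540.5805504742228,
  "raw_distance_m": 1358.4796084653929,
  "n_intervals": 72,
  "n_outliers": 10,
  "predicted_m": 691.75,
  "percent_predicted": 78.14680888676875,
  "gate_time_s": null
}
```

The raw chord sum (1358 m) is wrecked by ten glitch intervals; after
outlier correction the engine lands 0.6 m from the simulator's true
540 m. The predicted distance for a 40-year-old, 175 cm, 70 kg man is
691.75 m, so the walk is 78.1% of predicted.

How many subjects does a reliability study need to show an ICC above
0.70 when 0.85 is expected (α = 0.05 two-sided, power 80%, two
administrations)?

```sh
$ remotefit samplesize --rho0 0.70 --rho1 0.85
53
```

Other subcommands: `remotefit sts` (keypoints → repetition counts),
`remotefit validate` (study CSV → validity + reliability JSON reports),
`remotefit simulate --kind sts|study`.

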