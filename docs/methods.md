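# Methods

## Scope and object of study

`ufdce` studies how the duration of an ultrafast DCE-MRI acquisition
affects two semi-quantitative kinetic parameters — maximum slope (MS)
and initial area under the concentration curve in 60 s (iAUC) — and
their power to separate benign from malignant breast lesions. Because
no patient data ship with the package, a synthetic cohort generator
stands in for the clinical study population; everything downstream
(relaxometry, truncation, parameter measurement, statistics) operates
identically on synthetic or real concentration curves.

## Time conventions

Contrast injection starts at the beginning of the first post-contrast
phase (t = 0). Post-contrast frame *i* (0-based) carries the timestamp
(i+1)·dt — the end of its acquisition window. With dt = 4.5 s and one
pre-contrast phase, a 9-phase dynamic set nominally lasts 40.5 s but
covers post-contrast time only to 36 s; a 15-phase set (67.5 s) covers
63 s and is the first to contain the full 60-s iAUC window. This
convention is what makes the two shortest sets "truncated" for iAUC.

## Synthetic cohort generator

**Arterial input.** A population AIF — two Gaussians (first and second
pass) plus an exponentially decaying sigmoid washout, in the standard
published parametrisation — is baseline-subtracted and clipped at zero
so that C_p(0) = 0 exactly, and scaled linearly in dose around the
0.1 mmol/kg reference. The first-pass peak sits ≈10.4 s after injection
start at ≈6 mmol/L.

**Tissue model.** Extended Tofts with parameters K^trans (min⁻¹), v_e,
v_p and an onset delay d (s). The convolution is evaluated exactly for
a piecewise-linear AIF on a 0.1 s internal grid (per-interval
exponential update, stable for any k_ep ≥ 0) and interpolated onto the
4.5 s sample grid.

**Cohort defaults** (the study conditions; one seed controls all draws):

| quantity | default | why |
|---|---|---|
| cohort size | 55 benign + 96 malignant | the clinical cohort composition this emulates |
| K^trans | log-normal, median 0.05 (benign) / 0.25 (malignant) min⁻¹, σ=0.5 | benign lesions wash in ~5× slower; spread wide enough that groups overlap |
| v_e | log-normal median 0.3, σ=0.3 | typical extravascular extracellular fraction |
| v_p | log-normal median 0.02, σ=0.5 (clipped < 0.5) | small plasma fraction of breast lesions |
| onset delay | log-normal median 25 s, σ=0.2 | injection plus saline flush plus transit; chosen so the 36 s set only partially covers the wash-in and the shortest-duration iAUC carries little of the 60-s area, matching the qualitative short-duration behaviour of clinical ultrafast data |
| T1₀ (lesion) | log-normal median 1300 ms, σ=0.1 | breast lesion tissue at 3 T |
| noise | Rician, σ = 0.02 × baseline signal | SNR 50 magnitude images |
| r₁ | 5.0 L mmol⁻¹ s⁻¹ | gadobutrol-class agent at 3 T; configurable |

The absolute scale of MS/iAUC in clinical reports depends on
undocumented vendor scaling; the generator therefore targets group
*ordering and separability*, not absolute parameter magnitudes.

**Volume rendering.** Each lesion occupies a 3×3×3-voxel block on a
lattice (background T1 1000 ms, M₀ = 1000 a.u. for all sequences).
Voxel T1 follows 1/T1(t) = 1/T1₀ + r₁C(t); the dynamic series is SPGR
signal at (TR 4.46 ms, 11°), the pre-contrast pair at (TR 5.03 ms,
2°/10°). Rician noise adds independent complex Gaussian components and
takes the magnitude. The generator does not attempt breast anatomy,
B1/flip-angle error, partial volume, or k-space/compressed-sensing
effects — so passing tests show the *measurement chain* is correct, not
that it is robust to those real-data effects. Lesion VOIs are exact by
construction; the variability that manual delineation adds in clinical
data is emulated only via the repeat-read jitter (below).

## Relaxometry

Two-point variable-flip-angle T1: with y = S/sin α and x = S/tan α the
SPGR equation is linear, y = E x + M₀(1−E); the two-point slope gives
E = e^{−TR/T1}. A slope outside (0, 1) is non-physical and raises (or
is NaN-masked for array inputs). Signal-to-concentration estimates M₀
from the single pre-contrast phase and the known/fitted T1₀, inverts
the SPGR equation per timepoint, and converts via rates in s⁻¹ (the one
ms→s conversion in the package). Noise can push samples below baseline
(clipped to 0, counted) or beyond the model's range (flagged NaN;
downstream measurements drop flagged samples). No B1 correction,
multi-flip fitting or registration is implemented; the T1 map is
assumed co-registered per lesion.

## Kinetics

MS is the maximum of consecutive-sample slopes including the (0, 0)
baseline segment, floored at 0; ties resolve to the earliest segment.
iAUC integrates trapezoidally from (0, 0) to min(60 s, last sample),
linearly interpolating the 60 s endpoint when it falls between samples,
and flags windows < 60 s as truncated. No smoothing is applied before
MS by default (a 3-point moving-average flag exists): at 4.5 s sampling
the curve is already heavily smoothed by acquisition.

A consequence of the fixed 60-s window: iAUC is *identical* from the
67.5 s set onward for the same lesion. Clinical reports based on vendor
software show iAUC continuing to drift at longer durations — likely
arrival-detection or windowing behaviour that is not documented and is
deliberately not emulated here.

The methods literature is inconsistent about the truncation grid; this
package uses all eight phase counts {9, 12, 15, 18, 21, 24, 27, 30},
consistent with the eight nominal durations 40.5–135 s.

## Diagnostics

- **Normality gate:** one-sample KS test against a normal with the
  sample's own mean/sd at α = 0.05 (with estimated parameters the test
  is conservative, which only makes the parametric route more likely);
  degenerate (zero-variance) samples are routed non-parametric.
- **Group comparison:** Student's t (equal variances) when both groups
  pass the gate, Mann–Whitney U otherwise; two-sided.
- **AUC:** Mann–Whitney probability with ties counted ½; variance and
  CIs by DeLong structural components; paired AUC comparison by the
  correlated-AUC z test. A zero-variance difference (identical scores,
  e.g. two durations past the iAUC plateau) reports p = 1 with a
  warning rather than failing.
- **Youden cutoff:** exhaustive scan over midpoints of consecutive
  sorted unique scores; positive class = malignant, called when
  score ≥ cutoff; ties in J resolve to the lowest cutoff
  (deterministic). All-equal scores yield a flagged non-informative
  result instead of an error.
- **Confusion panel:** percentages rounded to 2 decimals;
  Clopper–Pearson exact 95% CIs on each metric's own denominator
  (including the predicted-positive/negative margins for PPV/NPV).
  Metrics with empty denominators are reported missing.
- **Cross-duration comparisons:** all 28 duration pairs, paired t when
  the paired differences pass the gate, Wilcoxon signed-rank otherwise,
  Bonferroni ×28 capped at 1 (rendered "> 0.99"); a Friedman omnibus is
  reported alongside. A Cochran's Q test is sometimes named in this
  role in the clinical literature, but it applies to dichotomous
  outcomes; for continuous parameters the Friedman/Wilcoxon route is
  the appropriate nonparametric analogue, and that is what is
  implemented. Lesions with missing cells are excluded listwise and
  counted.
- **ICC:** two-way random-effects, single-measures, absolute-agreement
  ICC(2,1) from the ANOVA decomposition with the McGraw–Wong F-based
  CI. The pipeline has no human raters, so "repeat reads" are emulated
  by a seeded 5% multiplicative jitter on the measured parameters —
  enough to exercise the agreement machinery, not a model of observer
  behaviour.

## Pipeline and reproducibility

One `RunConfig` (YAML-serialisable, SHA-256 hashed) drives simulation,
optional volume rendering + relaxometry (`profile="volumes"`),
measurement and statistics. The default `curves` profile analyses the
simulated concentration curves directly and completes the full
151-lesion × 8-duration study in roughly a second on one CPU; the
volumes profile adds the rendering/inversion chain and stays well under
a minute. All randomness descends from the single seed; reports are
bit-identical across reruns and every table cell is recomputable from
the written `records.csv`.

## Known limitations

- The generator's kinetic distributions are stylised: no receptor-status
  subgroups, no lesion-size effects, no spatial heterogeneity within a
  VOI (per-lesion curves are the VOI mean by construction).
- Semi-quantitative parameters are reported in physical units
  (mmol L⁻¹ s⁻¹ and mmol L⁻¹ s); comparisons with vendor-scaled
  clinical values are only meaningful after rescaling.
- DeLong CIs are asymptotic; at extreme AUCs near 1 the clipped
  intervals are conservative.
- The KS gate with estimated parameters under-rejects; with n ≈ 55–96
  per group this mainly affects borderline non-normal samples.
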