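# ufdce — ultrafast DCE-MRI scan-duration analysis

How long does an ultrafast dynamic contrast-enhanced (DCE) breast MRI
scan need to be? Ultrafast protocols image the first pass of a contrast
bolus at a few seconds per phase; semi-quantitative kinetic parameters
measured on the early enhancement curve — the **maximum slope (MS)** and
the **initial area under the curve over 60 s (iAUC)** — separate benign
from malignant lesions, and every extra phase costs scan time. `ufdce`
is a library (plus a thin CLI) for studying that trade-off on fully
synthetic cohorts: it generates lesion concentration curves with a known
ground truth, truncates the dynamic series to a ladder of scan
durations, measures MS and iAUC on each truncation, and quantifies the
diagnostic performance at every duration.

It is aimed at researchers who design or evaluate abbreviated breast MRI
protocols and want a reproducible, fully synthetic testbed for the whole
measurement chain — from signal physics to ROC statistics.

## The model and the measurements

**Simulation.** Each lesion's plasma-to-tissue exchange follows the
extended Tofts model driven by a population arterial input function
C<sub>p</sub>(t) (bi-Gaussian first/second pass plus an
exponential-sigmoid washout tail):

C(t) = v<sub>p</sub> C<sub>p</sub>(t−d) + K<sup>trans</sup> ∫₀^{t−d} C<sub>p</sub>(τ) e^{−k<sub>ep</sub>(t−d−τ)} dτ,  k<sub>ep</sub> = K<sup>trans</sup>/v<sub>e</sub>

with benign and malignant lesions drawn from log-normal parameter
distributions (malignant K<sup>trans</sup> five-fold higher). The
acquisition mimics a 3 T ultrafast protocol: 4.5 s/phase, one
pre-contrast + 29 post-contrast phases, spoiled-gradient-echo (SPGR)
readout (TR 4.46 ms, flip 11°) and a two-flip-angle (2°/10°) T1-mapping
pair, with Rician noise.

**Relaxometry.** The SPGR equation
S = M₀ sin α (1−E)/(1−E cos α), E = e^{−TR/T1}
is inverted in closed form: the two-point variable-flip-angle fit gives
T1₀, and each dynamic sample is converted through
1/T1(t) = 1/T1₀ + r₁ C(t).

**Kinetics.** The series is cut into eight nested dynamic sets (40.5 s
/ 9 phases up to 135 s / 30 phases). MS is the steepest
consecutive-segment slope of C(t) including the (0, 0) injection
baseline; iAUC is the trapezoidal integral of C from injection to 60 s,
integrated only to the last sample (and flagged) for the two sets that
end earlier.

**Diagnostics.** Per duration: Student t / Mann–Whitney group comparison
behind a Kolmogorov–Smirnov normality gate; AUC with DeLong confidence
intervals; Youden-index cutoff with sensitivity, specificity, PPV, NPV
and accuracy (Clopper–Pearson exact CIs). Across durations: paired t /
Wilcoxon matrices with Bonferroni correction, DeLong paired AUC tests,
and ICC(2,1) agreement for emulated repeat reads.

## Worked example

```python
from ufdce import RunConfig, run_end_to_end

report = run_end_to_end(RunConfig().with_seed(5))
print(report.roc_panel.pivot_table(index="duration_label",
                                   columns="parameter", values="auc",
                                   sort=False))
```

prints

```
parameter          ms   iauc
duration_label
SD_40.5s        0.771  0.672
SD_54s          0.841  0.901
SD_67.5s        0.841  0.953
SD_81s          0.841  0.953
SD_94.5s        0.841  0.953
SD_108s         0.841  0.953
SD_121.5s       0.841  0.953
SD_135s         0.841  0.953
```

Each cell is the area under the ROC curve for discriminating the 96
malignant from the 55 benign synthetic lesions using that parameter at
that scan duration. The shortest scan (40.5 s) misses part of the
wash-in — the bolus only reaches lesion tissue ~25 s after injection —
so its AUCs are depressed; once the scan covers the full wash-in
(~67.5 s) performance saturates and longer scans add nothing. That
plateau is the quantity of interest: the shortest duration on it is the
efficient protocol.

The same run from a shell:

```bash
ufdce run --outdir out --seed 5          # tables + report.json
ufdce report --outdir out --seed 5       # + PNG figures
```

The `examples/` directory walks through each capability (simulation,
relaxometry round trip, truncation kinetics, ROC diagnostics, full
pipeline) as short narrative scripts.

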