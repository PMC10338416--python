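# qflow

Quantitative flow cytometry (qFlow) for circulating angiogenic cells:
absolute quantification of plasma-membrane VEGFR1 and VEGFR2 on circulating
progenitor cells (cPCs, CD34+CD31+) and the rare (~1%) circulating
endothelial cells (cECs, CD34+CD31+CD146+) found in CD34-enriched blood
samples.

Soluble angiogenic markers correlate poorly with what happens on vessel
walls; cECs and cPCs are non-invasive, cell-based proxies whose membrane
VEGFR load can be counted in absolute units.  `qflow` is for researchers who
want that measurement chain as tested, scriptable Python: every stage from
raw per-event tables to group-level effect sizes, plus a synthetic cohort
generator with known ground truth for validating the whole chain.

## What it computes

* **Calibration** — four-level Quantibrite PE bead regression,
  `log10(geomean F) = m·log10(#PE/bead) + b`; the inverse converts PE
  fluorescence to receptors/cell (1:1 PE:antibody stoichiometry).
* **Gating** — size (6 µm bead reference) → singlet (FSC width) → viability
  → CD34+CD31+ (cPC) → +CD146 (cEC), with positive boundaries at the 99.5th
  percentile of matching fluorescence-minus-one (FMO) controls.
* **Background subtraction** — stained PE values scaled by
  `1 − mean(FMO PE)/mean(stained PE)` before calibration.
* **Distributions and pooling** — per-subject medians/IQRs against the 500
  receptors/cell specific-binding threshold; equal-contribution group pools
  (10,000 cPC / 1,000 cEC cells per subject, resampled with replacement).
* **Mixture decomposition** — three-component EM for log-normal cEC
  subpopulations on log10 counts (tied dispersion, seeded restarts), with
  post-fit reduction to the 1–3 real VEGFR-low/intermediate/high
  subpopulations and BIC reporting.
* **Group statistics** — Shapiro–Wilk + skewness-gated log transform,
  factorial OLS in sex × race × age with two-way interactions, LS-means
  contrasts with t-based CIs, and Cohen's d = |contrast| / residual SD.
* **Synthetic cohorts** — seeded generator for bead, stained and FMO tubes
  whose group structure (sex-by-age VEGFR subpopulations, ~0.98% cEC
  fraction, debris/doublet/dead contamination, autofluorescence) serves as
  ground truth for all of the above.

## Worked example

Decompose pooled cEC VEGFR1/VEGFR2 distributions per sex-by-age group
(`examples/05_mixture_decomposition.py`):

```python
import qflow

cohort = qflow.generate_cohort(seed=5)          # 23 subjects, seeded
result = qflow.analyze_cohort(cohort)           # gate + calibrate + quantify
pooled = qflow.pooled_distribution(result, ["male_under50", "male_over50"],
                                   "cec", "vegfr1", seed=9)
fit = qflow.decompose(pooled.counts, k=3, seed=6)
```

Output of the example script:

```
female_post  cEC VEGFR1: 1 subpopulation(s): low 100.0% @ 2,882
female_pre   cEC VEGFR1: 2 subpopulation(s): low 55.6% @ 8,800, high 44.4% @ 145,508
female_pre   cEC VEGFR2: 3 subpopulation(s): low 56.0% @ 2,709, intermediate 24.5% @ 44,863, high 19.5% @ 272,635
male_all     cEC VEGFR1: 2 subpopulation(s): low 73.3% @ 3,159, high 26.7% @ 212,969
```

Each line is one pooled group: the number of cEC subpopulations surviving
reduction, and each subpopulation's share of cECs with its median receptors
per cell.  Postmenopausal cECs are uniformly VEGFR-low (~3,000/cell), while
premenopausal females and males carry VEGFR-high subpopulations of
10^5-order receptor density — recovered here through the full pipeline from
raw synthetic events, matching the generator's planted group structure.

The group-statistics example (`examples/06_group_statistics.py`) closes the
loop on the menopause contrast in cPC VEGFR1:

```
Shapiro-Wilk p = 0.0055, skewness = 1.67 -> log10 transform applied: True
post- vs premenopausal cPC VEGFR1 (log10 scale): estimate 0.94 [0.39, 1.49], p = 0.0024, Cohen's d = 2.36
```

The remaining examples cover simulation, bead calibration, gating audit
against planted truth, and quantification/pooling — each prints its numbers
with a line on what they mean.

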