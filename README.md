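# brcalike

A Python toolkit for asking whether a DNA copy-number biomarker of
homologous recombination deficiency (HRD) predicts chemotherapy benefit in
early-stage triple-negative breast cancer (TNBC). It implements the full
analytical chain of such a study — shallow whole-genome copy-number
profiling, BRCA1-like shrunken-centroid classification, cross-platform
score concordance, and Cox proportional-hazards treatment×biomarker
interaction analysis — together with synthetic-data generators that let
every stage be exercised end-to-end with known ground truth.

It is written for translational biostatisticians and computational biologists
who want a tested, reusable, inspectable implementation of this pipeline
rather than a pile of one-off scripts.

## What it computes

**Copy-number profiles from shallow WGS.** Reads are counted in fixed 20-kb
autosomal bins; bins in blacklisted regions or with reference mappability
below 0.2 are excluded. Local GC effects are removed with a robust loess fit
(tricube weights, degree 2) of counts on GC, trained on bins with
mappability above 0.8. A line through the origin is fitted to the
density-weighted centers of GC-corrected counts per mappability interval;
its slope *s* converts mappability into an expected reference count, and the
profile is

&nbsp;&nbsp;&nbsp;&nbsp;log2 ratio<sub>i</sub> = log₂( corrected count<sub>i</sub> / (*s* · mappability<sub>i</sub>) ).

The chain is exactly invariant to sequencing depth.

**BRCA1-like classification.** A two-class nearest shrunken centroid
classifier on interval features (mean log2 ratio per feature). Per feature
*k* and class *j*, the standardized contrast
d<sub>jk</sub> = (x̄<sub>jk</sub> − x̄<sub>k</sub>) / (m<sub>j</sub>(s<sub>k</sub> + s₀)) with
m<sub>j</sub> = √(1/n<sub>j</sub> − 1/n) is soft-thresholded by Δ, and
classification uses the diagonal discriminant
δ<sub>j</sub>(x) = Σ<sub>k</sub> (x<sub>k</sub> − x̄′<sub>jk</sub>)²/(s<sub>k</sub>+s₀)² − 2·log π<sub>j</sub>.
The posterior probability of the BRCA1-like class is the reported score; a
tumour is called BRCA1-like when the score is ≥ 0.63. The published model's
centroids are not public, so the package ships the trainer and a JSON model
format; all analyses here run on synthetically trained models.

**Score concordance.** When a second continuous biomarker (e.g. an RNA
expression signature) has no established cutoff, it is dichotomized at the
percentile the first score's cutoff occupies in the data, and agreement is
tabulated as a 2×2 table (marginal-matched concordance).

**Survival analysis.** Recurrence-free survival (time to recurrence or death
from any cause) and overall survival endpoints; Kaplan–Meier curves with
risk tables; median follow-up by the reverse Kaplan–Meier estimator; and a
Cox proportional-hazards interaction model, h(t | T, M) =
h<sub>0M</sub>(t)·exp(β₁T + β₃TM), with the baseline stratified by marker
status, so exp(β₁) and exp(β₁+β₃) are exactly the within-stratum treatment
hazard ratios and the Wald test on β₃ compares them. Efron (default) and
Breslow ties corrections are provided, adjustment is one covariate at a
time, and proportionality is checked with scaled Schoenfeld residuals.

## Worked example

`examples/` contains one short narrative script per capability. For
instance, training the classifier and calling a screening cohort of 202
synthetic tumours (73 of which fail profile quality control):

```sh
$ python examples/02_classifier.py
trained model: shrinkage delta = 12.45, 33/200 features active, decision threshold = 0.63

screened tumours: 202
failed quality control: 73 (36.1%) — too few usable bins
evaluable: 129 (63.9%)

class calls among evaluable tumours (score >= 0.63 -> BRCA1-like):
       BRCA1-like:  68 (52.7%)
   non-BRCA1-like:  61 (47.3%)

agreement with simulation ground truth: 129/129
```

The shrinkage Δ chosen by cross-validation keeps 33 of 200 interval
features; 63.9% of tumours yield an evaluable profile, and these split
47.3% / 52.7% between the two classes — the class balance the cohort was
constructed with, recovered by the classifier. The other examples profile a
simulated genome and recover a planted one-copy deletion
(`01_profile_pipeline.py`), compare paired DNA/RNA scores
(`03_score_concordance.py`), and run the treatment×marker interaction
analysis on a simulated randomized trial (`04_survival_interaction.py`).

A thin CLI wraps the same functions (`brcalike simulate | profile | train |
predict | concord | survival`); every command writes a provenance JSON
sufficient to repeat the run.

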