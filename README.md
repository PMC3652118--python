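# cervidx

Fuzzy-logic decision support for cervical cytology, aimed at the hardest
screening calls: **atypical glandular cells (AGC)**, where neither a clearly
positive nor a clearly negative diagnosis is available to the
cytotechnologist. The package reimplements a two-stage Mamdani expert
system that fuses a patient's clinical background with nucleus morphometry
measured on a stained cytology micrograph, and emits a three-way call —
Normal, AGC, or Positive-to-malignity — on a crisp 0–100 lesion scale.

It is a library first (importable API plus `examples/` scripts), with a
thin `cervidx` command-line tool on top for batch use.

## What it computes

**Phase 1 — clinical risk.** Seven record fields (age *E*, onset of sexual
activity *IVSA*, sexual partners *PS*, pregnancies *NG*, age at first
pregnancy *PG*, STD history, cervical lesions) are fuzzified through
trapezoidal membership functions, e.g. for age

```
μ_young(t):  0 below 10, rising 10→15, 1 on [15,18], falling 18→22, 0 above
```

and pushed through a Mamdani rule base (972 possible antecedent
combinations). The defuzzified centroid is the crisp risk score; scores
near 1 read *negative*, near 2 *positive*.

**Phase 2 — nucleus morphometry.** The micrograph is thresholded on its
green channel (Otsu by default — nuclei are darkest there with
hematoxylin-type stains), cleaned morphologically, and labeled. Four
image-level features result:

- `dn = Σ areaᵢ / n` — mean nucleus area (px),
- `tn = Σ meanStainᵢ / n` — mean staining on an inverted-grayscale 50–150
  scale (darker = more hyperchromatic = higher),
- `hn` — mean best-fit-ellipse eccentricity (0 round … 1 elongated),
- `pn` — total count of nucleoli (small dark interior spots).

**Phase 3 — injury resolution.** `dn, tn, hn, pn` plus the crisp risk score
feed a second Mamdani model (108 rules over set cardinalities 3·3·2·3·2)
whose output universe carries three trapezoids: Normal `(0 0 31 41)`, AGC
`(31 41 58 68)`, Positive `(58 68 100 100)`; overlap bands split at 36
and 63, ties break toward the more severe label.

**Calibration.** Membership plateaus for the morphometric sets come from
per-condition statistics: the two-sided σ-known normal confidence interval
`mean ± z_{α/2}·σ/√n` of each condition's feature mean is that set's
full-membership plateau (`cervidx.confidence_interval`,
`cervidx.intervals_to_membership`).

Because no real patient images are distributable, the package ships a
ground-truthed synthetic generator (`cervidx.generate_image`,
`cervidx.generate_cohort`): elliptical nuclei with controlled area,
eccentricity, staining and planted nucleoli on a lighter background, plus
clinical cohorts sampled from named risk strata.

## Worked example

```bash
python examples/03_full_diagnosis.py
```

pairs a risk-negative clinical record with a synthetic field drawn in the
AGC morphometric regime and prints (among the three cases):

```
--- agc-regime field ---
== Background evaluation ==
  risk score: 1.000  ->  negative
== Image data ==
  mean nucleus area (dn): 7202.3 px
  mean staining     (tn): 84.5
  mean eccentricity (hn): 0.872
  nucleolus count   (pn): 12
  nuclei detected      : 12
== Injury resolution ==
  score: 49.50 / 100
  call : AGC (atypical glandular cells)
```

The risk score 1.000 sits on the negative peak of the risk universe; the
medium mean area (7202 px), intermediate staining (84.5), elongated nuclei
(0.872) and a dozen nucleoli land crisply on the AGC antecedent plateaus,
so the lesion score 49.5 falls inside the AGC plateau [41, 58]. The other
two cases print scores 18.12 (Normal) and 81.39 (Positive to malignity).

The remaining examples cover risk scoring (`01`), feature extraction
against generator ground truth (`02`), confidence-interval calibration
(`04`), and rule-base inspection (`05`). The same operations are available
from the shell:

```bash
cervidx simulate --regime agc --n-nuclei 12 --seed 11 -o field
cervidx features field.png
cervidx diagnose records.csv field.png --text
cervidx enumerate-rules --model injury
```

## What this is not

The system is a decision-support aid, not a diagnostic device: the final
call always belongs to the specialist. CIN I/II/III sub-grading, overlap
splitting of touching nuclei, stain deconvolution, and whole-slide formats
are out of scope. The shipped rule-base generators are documented
*non-clinical* severity heuristics pinned to the published example rows —
they reproduce the published system's printed behavior, not validated
clinical judgment.
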