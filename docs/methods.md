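# Methods

## The inference model

Both diagnostic stages are classic Mamdani controllers over piecewise-linear
membership functions. A linguistic variable is a closed universe with an
ordered list of triangle/trapezoid sets given by breakpoints `(a, b, c[, d])`
— membership 0 outside `[a, d]`, 1 on the plateau `[b, c]`, linear on the
shoulders; degenerate edges (`a = b` or `c = d`) are vertical, which is how
the boolean-style sets `(0 0 0.5)` / `(0.51 1 1.5)` are encoded. The engine
defaults are AND = min over the antecedent degrees, implication = min
(clipping the consequent set at the rule activation), aggregation = max
across rules, and centroid defuzzification; AND = product is available, the
rest are fixed.

The winning output label is the set with maximal membership at the crisp
value. Ties, including the degenerate tie where the crisp value sits on a
shared open support edge, break toward the **more severe** (higher-indexed)
label: in screening, a false reassurance costs more than a false alarm,
so every ambiguity in this package resolves pessimistically.

### Centroid defuzzification

The aggregated output surface `max_s min(act_s, μ_s(x))` is piecewise
linear, so its centroid `∫xμ dx / ∫μ dx` has a segment-wise closed form.
The default defuzzifier computes it exactly: it collects every abscissa
where any clipped set changes slope (set breakpoints plus clip crossings),
fits each set's linear piece inside each cell from two interior points
(endpoint evaluation is wrong wherever a vertical edge sits on a knot),
adds pairwise crossings so the max is a single linear piece per cell, and
sums the closed-form segment integrals. This is resolution-independent,
deterministic, and agrees with a brute-force trapezoid-rule integration on
a 10⁵-point grid to ~10⁻⁹ relative error (the test suite enforces ≤10⁻⁶).
A uniform-grid sampled mode (`EngineOptions.defuzz_mode="sampled"`,
default 1001 points) is kept for cross-checking; it was not made the
default because its accuracy depends on how the grid lands on the surface's
kinks.

### Universe gaps and clamping

The shipped interval tables contain hairline coverage gaps (e.g.
pregnancies `(0 0 0.5)` vs `(0.51 4 8)`) that are transcription artifacts
of the source material. Inputs are evaluated as-is; if every set returns 0,
the value is snapped to the nearest support boundary and, when that edge is
itself open (membership still 0), the set with the nearest plateau receives
full membership. Both events are logged. Inputs outside a universe are
clamped to it with a warning. Real inputs — counts, ages, booleans — never
land in these gaps; the handling exists so the engine is total.

### Inconsistent risk universes

The source system prints three mutually inconsistent descriptions of the
risk output (a `(0 0 0.5)/(0.51 1 1.5)` pair, a prose banding on [1, 1.5]
vs ≥ 1.51, and a `(0.5 1 1.5)/(1.51 2 2.5)` pair where risk re-enters the
injury model). The shipped default is the last one, so the crisp risk score
feeds the injury model with no rescaling; the narrow variant remains
available as the `narrow` output preset in the risk config.

## Rule bases

Only 20 of the validated risk rules and 5 of the 108 injury rules were ever
published. Shipping only those rows would leave the models unable to fire
on most inputs, so each model pairs (a) the printed rows as a **locked
fixture** with (b) a documented severity-scoring policy that assigns a
consequent to every combination and is verified, at model build time, to
agree with every fixture row (a contradiction raises a configuration error
naming the row). The policies are deliberately simple counting heuristics
and are labeled non-clinical; they are fully overridable by config.

**Risk policy.** Points: many partners 3, unusually many partners 4, many
pregnancies 3, plus 1 if the first pregnancy was young alongside high
parity, STD history 1, visible lesions 1; positive at ≥ 3. The printed rows
pin this family: with few partners, STD history *plus* lesions still reads
negative (rows with both present), while many partners alone reads positive
— so partners must reach the threshold alone and the two boolean flags must
not. Combinations whose sexual-onset bracket is older than the current age
bracket are impossible and generated disabled (324 of 972).

**Injury policy.** Points: area small/medium/large 0/1/3, staining
clear/media/dark 0/1/2, shape regular/irregular 0/3, nucleoli
null/few/many 1/0/3, risk negative/positive 0/2; Normal ≤ 3, AGC 4–5,
Positive ≥ 6. The printed rows force dark staining with absent nucleoli to
stay Normal, which fixes the dark weight; visible (few) nucleoli score 0
because nucleolus presence is a feature of benign samples in this material,
whereas their *absence* (often a sign they are masked by hyperchromasia) and
their excess both score. Combinations pairing dark staining with detected
nucleoli are physically meaningless — nucleoli cannot be resolved inside a
hyperchromatic nucleus — and are generated disabled (24 of 108).

## Image pipeline

Defaults, all surfaced as parameters (`PipelineParams`) and CLI flags since
the source system never published its values:

| parameter | default | why |
|---|---|---|
| enhancement | identity | generator images need no stretch; percentile stretch `(p1, p99)` available |
| threshold | Otsu on green, dark class (`<=`) | nuclei are darkest in green; `<=` keeps the dark mode itself foreground on two-valued rasters |
| morphology | opening+closing, disk r=2; fill holes; drop areas < 50 px | removes speckle and debris without eroding plausible nuclei (smallest regime ≈ 2000 px) |
| connectivity | 8-connected, 0-based (row, col) | stated once, used everywhere |
| nucleolus spots | threshold mean + 2σ on the staining raster; area in [12 px, 0.5·nucleus] | see below |
| `tn` scale | `(255 − luminance)·150/255` | places darker nuclei higher on the 50–150 staining universe; raw-intensity mode is a switch |
| `hn` | mean eccentricity | an irregular-fraction mode is a switch |

**Nucleolus detection.** Within each nucleus, spots are pixels darker than
the region mean by `k` region standard deviations (computed on the
darker-is-higher staining raster, so the threshold is mean + k·σ), grouped
8-connected and size-filtered. `k = 2.0` with a 12 px minimum spot: under
Gaussian pixel noise a 1σ cut always marks ~16% of pixels regardless of the
noise level, which speckles every nucleus with false spots; at 2σ (~2.3%)
chance clusters above 12 px essentially never occur, while planted spots
(radius 3, ~29 px, ≈60 gray levels darker) are far beyond the cut. Both
are configurable.

**Embossing** is accepted as a parameter for config parity but is a
feature-neutral no-op: no operative description of it exists.

## Synthetic data

The generator emulates the study conditions the system was calibrated on:
three area regimes with the published per-condition statistics (means
3536.71 / 7658.24 / 13747.13 px, population variances 1,611,045.74 /
2,283,910.70 / 17,225,203.65), rendered as hard-edged filled ellipses whose
RGB is chosen so the luminance hits the target staining and the green
channel is ~12 levels darker (matching how such stains image). Staining
regimes land on the clear / media / dark bands (means 65 / 84.5 / 105),
shape regimes on regular / irregular (mean eccentricity 0.62 / 0.86), and
the mid regime plants one nucleolus per nucleus so a 12-nucleus field lands
on the "few" plateau. Background is a light cytoplasm-like (225, 210, 220);
pixel noise is Gaussian, σ = 6 by default.

Ground truth is pixel-exact: nuclei are rasterized without anti-aliasing
and the stored truth area is the rasterized pixel count, so the ±2%
area-recovery bound in the tests is honest rather than an artifact of
comparing analytic πab to a raster. Centers are integer pixels (fractional
centers make rasterized circles measurably eccentric, ~0.05). Placement is
rejection sampling with a separation margin (default 8 px) that must exceed
the bridging distance of the downstream closing (2·radius + 1 = 5 px at the
default disk radius 2), otherwise adjacent nuclei merge during cleanup;
total nucleus area is capped at 30% of the frame and placement failure
after bounded retries is an error, not a silent shortfall.

What the generator does **not** emulate: overlapping and folded cells,
cytoplasm texture and debris, stain batch variation, chromatic aberration,
uneven illumination. Passing recovery tests therefore demonstrate that the
pipeline measures what it claims on well-separated nuclei at documented
noise — not that it segments real smears, which were unavailable.

## Problem sizes in the shipped checks

The acceptance script and test suite size their experiments to keep the
whole run on a laptop-class single core: 50 recovery fields of 5–30 nuclei
(frames auto-sized to ~12% area load so placement always succeeds), 100
regime replicates (20 / 12 / 10 nuclei per field for the small / medium /
large regimes — enough nuclei that the field mean's sampling error is well
inside the ±1462 / ±1741 / ±3780 half-widths of the calibration intervals),
100 randomized activation patterns for the centroid oracle, and the three
end-to-end fixtures. All randomness flows from the single `--seed`.

## Known limitations

- The published 972→360 rule pruning criteria were never stated; the
  shipped policies mark impossibility, not clinical validity, and 360 is
  not reproducible. Likewise the published validation on hospital cases is
  not reproducible without the patient images; the end-to-end checks run on
  synthetic stand-ins.
- The calibration table's trailing unlabeled number pairs are not
  derivable from the σ-known formula and are excluded.
- `tn` depends on acquisition brightness; absent a stain-normalization
  step, the 50–150 calibration only transfers across images captured under
  the fixed camera settings the convention assumes.
- Touching or overlapping nuclei are merged by design (no watershed
  splitting); counts and means on crowded real fields will be biased.
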