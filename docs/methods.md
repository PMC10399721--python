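# Methods

## Model and assumptions

`xenotalk` treats a dual-species expression profile as two independent
compartments measured simultaneously: human probes report the tumor,
mouse probes the stroma. Three assumptions underlie the inference:

1. intensities are already log2-transformed and normalized (the package
   performs no background correction or quantile normalization);
2. after blacklist removal, each probe's signal is attributable to a
   single species;
3. a paracrine interaction is plausible when the ligand is expressed by
   the tumor, a cognate receptor is expressed by the stroma, and the
   ligand responds to treatment — receptor-side differential expression
   is reported but deliberately not used as a filter.

Differential expression is an ordinary two-sample t contrast on log2
values. Pooled variance is the default because arms are small (n = 3)
and measured on the same platform; Welch is available where
heteroscedasticity is suspected. Moderated-variance (empirical Bayes)
estimators are intentionally out of scope: the output contract is the
plain (log2ratio, raw p, BH p) triple. Benjamini–Hochberg adjustment is
applied across all genes of one species within one condition — the same
family structure as one per-condition results table.

### Degenerate inputs and numerical conventions

* Zero within-group variance in both groups: p = 1 if the means agree,
  p = 0 otherwise (documented convention; vectorized in the engine).
* The significance prefilter uses a strict `<` at the threshold, so a
  probe at exactly p = α in every contrast is dropped.
* Gene collapse ties (identical probe means) break to the
  lexicographically smallest probe id, making the pipeline fully
  deterministic.
* BH adjustment is the standard step-up with cumulative-minimum
  monotonization and capping at 1; the test suite checks it exhaustively
  against the hand formula on all permutations of up to six p-values.
* Log-rank with no events in either group returns (0, 1) by convention.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance threshold for contrasts and detection |
| `p_mode` | `raw` | p-value used by the combo-only detector (`raw`/`bh`) |
| `variance_mode` | `pooled` | t-contrast variance model (`pooled`/`welch`) |
| `prefilter_alpha` | 0.05 | probe prefilter threshold; `None`/`off` disables |
| `floor` | `auto` | expression-call floor (log2); `auto` = per-species median of gene means |
| `cr_threshold` | 0 mm³ | recorded volume at/below which a final reading is CR |
| `response_fraction` | 0.8 | nadir/baseline ratio that counts as having "responded" (SR rule) |

The relative `auto` floor is platform-independent: with no external
calibration of what intensity means "expressed", the per-species median
of gene-level means splits each compartment into a brighter, callable
half. Users with spike-in calibrations can pass an absolute floor.

The CR threshold defaults to a recorded volume of 0 (no palpable tumor)
because complete response has no published numeric definition; it is
configurable to a small detection floor. The SR "responded" criterion
(nadir < 0.8 × baseline) is likewise an operational interpretation of a
narrative class ("responded, then progressed") and is exposed as a flag.
Response classes are ratio-based and therefore invariant to uniform
volume rescaling, except the absolute CR threshold, which is documented
as absolute.

Percent renderings follow the reporting convention of preclinical
summaries: arm-level fractions at nearest integer (48% for 10/21) and
one decimal where finer precision is customary (14.3% for 1/7), both
with half-away-from-zero rounding.

## Pipeline order

The three probe rules run prefilter → blacklist → collapse, matching the
order in which they are usually described; the order is configuration,
not load-bearing, because each stage only selects rows (an invariant the
tests check by value-multiset containment). Probe-level prefilter
p-values come from the same contrast engine as gene-level statistics,
since no separate probe-level method is defined anywhere. Gene-level BH
families default to **all** collapsed genes of a species×condition —
adjusting within the full tested family is the standard practice and
keeps adjusted p-values meaningful when the prefilter is disabled.

## What the simulator emulates — and what it does not

The expression generator draws, per probe and sample:
`gene baseline + probe offset + condition effect + N(0, noise_sd)`,
with gene baselines N(7, 1.5), probe offsets N(0, 0.3), noise sd 0.25,
and 1–3 probes per gene. Default geometry is 200 human + 150 mouse
genes, five planted combo-specific ligands (+5 log2 in the combo arm
only), three decoys (+3 log2 in one monotherapy arm each, alternating),
10% cross-hybridizing probes, and a 60-pair compendium — a scaled-down
mirror of the real design's structure (five combo-specific ligands among
~80 candidates) that keeps the full test suite in seconds. Planted
ligands, decoys and planted receptors receive boosted baselines
(≈ +2 log2 over the population mean) so that they are called expressed
even with no treatment effect, and their probes are excluded from the
cross-hybridizing subset: the blacklist is a nuisance filter, not part
of the signal.

Compendium filler ligands are drawn from human genes *below the 40th
percentile* of gene-level mean intensity. The intent is "non-expressed
symbols"; the margin below the median floor guarantees that prefilter-
induced shifts of the auto floor cannot flip a filler ligand into the
candidate set, which keeps the planted-recovery benchmark well-defined.

The growth generator starts every mouse at the ~250 mm³ enrollment
volume and follows class-specific dynamics: exponential growth (NR,
rate 0.06/day), exponential decay to below a 10 mm³ detection limit
recorded as 0 (CR, rate 0.15/day), decay to a plateau at 35% of baseline
(DR), and decay to day 18 followed by regrowth at 0.09/day (SR).
Measurements carry lognormal noise (sd 0.10 on the log scale; 0 for
noiseless benchmarks) and are back-converted to caliper length/width
with the fixed aspect width = length/2, so volume inversion is exact.
The survival endpoint is a volume surrogate — first day the recorded
volume reaches 1500 mm³, otherwise censoring at day 60 — because the
real endpoint definition is not recoverable.

Not emulated: microarray covariance structure (noise is independent and
homoscedastic on the log2 scale), probe-sequence cross-hybridization
physics, inter-animal growth-rate heterogeneity beyond measurement
noise, and any immune-cell phenotyping data. Passing recovery tests
therefore demonstrate correctness of the *algorithms* under the stated
stochastic model, not robustness to real-platform artifacts.

## The recovery benchmark configuration

The planted-recovery benchmark (tests and acceptance script) runs the
pipeline with `p_mode="bh"`, `alpha=0.01`, and the prefilter disabled.
This is a power-analysis-driven choice, made before any benchmark was
run: under the default raw-p detector at α = 0.05, a truly combo-only
ligand is excluded whenever either monotherapy contrast fluctuates below
α, which happens with probability 1 − 0.95² ≈ 9.7% per ligand — exact
recovery of a five-ligand set would fail in ~40% of studies no matter
how strong the combo effect is, because null p-values are uniform.
BH-adjusting the detector's p-values over the full per-species gene
family (hence the disabled prefilter, which would shrink that family
~6-fold) at α = 0.01 drops the per-ligand chance-exclusion probability
to ~10⁻⁴ while the planted +5 log2 effect (t ≈ 24 at df 4) passes with
margin. The pipeline defaults remain raw p at α = 0.05 for fidelity to
the per-condition threshold style of the original analysis; both modes
are one flag apart.

## Known limitations

* The expression call has no absolute calibration; "expressed" is
  relative to the cohort analyzed.
* Directional compendium semantics mean autocrine (tumor→tumor) and
  reverse (stroma→tumor) signaling are out of scope, as are multi-subunit
  receptor complexes and confidence scoring.
* The preclinical classifier evaluates whole curves retrospectively; it
  does not model time-to-progression explicitly (the simulator records a
  true progression day for mice that progress, available to users).
* Mouse receptor naming follows canonical symbols (CSF2RA for the GM-CSF
  receptor alpha chain, mouse gene Csf2ra); the occasionally seen
  spelling "Csfr2a" is a transposition and is normalized, not propagated.
* The ANOVA/Tukey multi-group comparison occasionally used alongside
  these designs is not reimplemented; no pipeline output depends on it.
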