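# Methods

## The problem

Red blood cells (RBCs) carry miRNAs at concentrations far above plasma.
When RBCs lyse — in vivo, or more commonly during phlebotomy and sample
processing — their contents leak into the plasma fraction, raising the
measured level of every RBC-enriched species. For circulating-miRNA
biomarker work this is a first-order confounder: a candidate marker that
is also abundant in RBCs will track hemolysis, not disease. `hemomir`
operationalizes the QC workflow for this situation: score hemolysis
spectrophotometrically, quantify its per-miRNA effect in matched
non-hemolyzed/hemolyzed pairs and in an RBC spike dilution series, and
tier every assay by susceptibility.

## Hemolysis scoring

Free hemoglobin's Soret band peaks near 414 nm; its Q-bands at 541 and
576 nm only become visible at high concentrations. From a 350–650 nm
optical-density scan the package extracts A₄₁₄ by linear interpolation
between the bracketing grid points. Interpolation (rather than
nearest-neighbor) was chosen so 1-nm and 2-nm instrument grids agree;
spectra are validated to bracket 414 nm (full 350–650 nm coverage is not
hard-required because trimmed instrument exports are common, but the
Q-band scan raises a range error when its windows are not covered).

* **Threshold** — a sample is hemolyzed iff A₄₁₄ strictly exceeds 0.2 OD.
  The strict inequality is deliberate: the published classification rule
  is worded as "exceeds", and typical non-hemolyzed plasma reads
  0.14–0.18 OD, so the boundary value itself carries no evidence of
  lysis. In the bundled reference measurements no sample sits exactly at
  0.2, so the choice is conventionally safe.
* **Degree of hemolysis** — A₄₁₄(sample)/A₄₁₄(reference), the reference
  being the matched non-hemolyzed sample or the 0% point of a dilution
  series. When replicate scans exist, both ratio-of-means and
  mean-of-ratios are exposed (`relative_degree_replicates`); printed
  reference degrees are consistent with per-replicate averaging, but the
  two differ only in the third decimal, within printed rounding.
* **Severe hemolysis** — each Q-band window (541 ± 5, 576 ± 5 nm) must
  contain an interior point at least 0.02 OD above the straight line
  joining the window's endpoint absorbances. The 0.02 OD prominence is
  small enough to fire on visibly banded heavy-hemolysis spectra and
  large enough to ignore interpolation wiggle on a smooth baseline.

## Cq handling

Cq values live in (0, 40] (40 thermocycles); "Undetermined", "NA" and
empty cells parse to an undetected state carried as NaN. Detection is
strict: Cq < 35. This single rule keeps the per-sample detectability
filter ("detected at Cq < 35") and the global exclusion ("Cq above 35
everywhere") consistent for Cq = 35 exactly.

Replicate collapsing averages on the Cq scale (that is what deposited
"average of duplicates" data mean). When one duplicate is undetected and
the other is not, the default is to call the collapsed value undetected:
near the detection limit a missing duplicate usually signals stochastic
dropout, and trusting the surviving replicate inflates low-abundance
calls. A `detected_only` policy overrides this for users who prefer the
instrument's behavior.

The detectability filter keeps miRNAs detected in ≥ 4 of the 6 plasma
samples of a 3-pair design (configurable; the CLI caps the quorum at the
number of plasma samples so small designs remain analyzable). The filter
is idempotent and verified against a brute-force enumeration oracle.

## Paired fold changes

For each matched pair, relative abundance in the hemolyzed member is
2^−(Cq_H − Cq_NH), computed per independent isolation run and summarized
as arithmetic mean ± sample SD across runs — the convention used when
such results are tabulated; the geometric summary (identical to the fold
change of run-averaged Cqs, an algebraic identity that is tested) is
exposed but not default. No endogenous-control normalization is applied
anywhere: hemolysis perturbs candidate controls, so normalization would
hide exactly the effect being measured.

Pairs with no run in which both members are detected get a qualitative
status (`hemolyzed_only`, `nonhemolyzed_only`, `both_undetected`) rather
than a pseudo-count fold change. The rare pattern where both members are
detected but never in the same run also maps to `both_undetected` (no
evaluable run). Heat-map export clips log2 fold changes at ±3.3
(≈ ±10-fold) with non-evaluable cells left missing.

The miR-451/miR-23a ΔCq indicator (Cq_stable − Cq_affected; larger
means more RBC signal) is provided for RNA-only situations where the
plasma itself is no longer available for spectrophotometry. The assay
ids are configuration defaults, not validated constants, and no verdict
threshold is attached because published cutoffs vary.

## Susceptibility tiers

With mean fold changes per pair, a miRNA is elevated in a pair when
mean FC ≥ 2.0 (inclusive, reconciling ">2-fold" and "at least twofold"
phrasings of the same rule); tiers are: elevated in all pairs / in ≥ 2
pairs / in exactly 1; stable when every evaluable pair lies within the
multiplicative band [2/3, 1.5]; hemolysis-specific when detected in RBC
lysate and hemolyzed plasma but never in non-hemolyzed plasma (species
whose signal never clears Cq 35 are excluded by the strict detection
rule itself); everything else — notably species *decreased* more than
the band allows — is indeterminate. Tiers are mutually exclusive and
exhaustive, and the elevation counts nest (all ⊆ ≥2 ⊆ ≥1), both checked
by brute-force oracles on random inputs. In a single-pair design an
elevated species is tiered `elevated_one_pair`.

Subset selection restricts to pairs whose degree of hemolysis is ≥ 2.0
(a cutoff that separates extensively hemolyzed pairs, degree ≳ 2.4, from
mildly hemolyzed ones, degree ≈ 1.4): *changing* species are ≥ 2-fold
elevated in every selected pair with fold changes rank-concordant with
the pairs' degrees ("increases following the degree of hemolysis" is
operationalized as non-decreasing FC along increasing degree; with two
pairs this reduces to FC_high ≥ FC_low); *unaffected* species stay
inside the stability band in every selected pair. The two subsets are
disjoint by construction.

## Dilution-series analysis

The dilution design spikes lysed RBCs into clean plasma at 0, 0.008,
0.016, 0.031, 0.0625 and 0.125 %RBC by volume, prepared as independent
series. Replicates are collapsed per sample, then series are averaged
per spike level (averaging two independent series shrinks per-point
noise by ≈ 1/√2, which is tested). Per miRNA (≥ 4 detected points
required) the package reports the Cq range (max − min), the Spearman
rank correlation of Cq vs spike fraction (midrank ties; a constant
trajectory gets ρ = 0), and the endpoint net shift.

A miRNA is *affected* iff range ≥ 1.1 cycles **and** ρ ≤ −0.8. Both
conditions are required because the stability data contain a species
with a clearly negative trend but a sub-1.1-cycle range that is
considered stable — trend alone over-calls. Spearman was chosen over
Pearson or a regression on log-fraction because the 0% baseline makes
log-fraction undefined and only an ordinal trend is claimed. The 1.1
cycle threshold is the empirical stability bound of the reference data;
validated susceptible species move 1.5–2.4 cycles over the same range,
leaving a margin. Under the noise-free mixing model the affected call
flips exactly at k* = (2^1.1 − 1)/0.00125 ≈ 915 (verified against a
bisection oracle).

Note the direction convention: *increasing abundance* with contamination
means *decreasing* Cq; all statistics and thresholds here use the
Cq-decrease direction.

## Synthetic-data generator

The generator is first-class, tested code implementing the minimal model
consistent with a linear spike design and 2^−ΔCq semantics: lysing an
RBC volume fraction f multiplies a miRNA's linear abundance by 1 + f·k,

    Cq(f) = baseline_cq − log2(1 + f·k) + ε,   ε ~ N(0, σ²),

with per-reaction censoring above cycle 40. Noise-free paired fold
changes are therefore exactly 1 + f·k, the closed form every downstream
statistic is verified against. No exosome/protein-carrier
compartmentalization, platelet contribution or disease signal is
modeled; dropout arises solely from censoring, with Gaussian Cq noise as
the standard qPCR error model. Deposited values average n_reactions = 2
simulated duplicate reactions per run, mirroring how duplicate qPCR
reactions are reported.

Default study conditions (units in parentheses):

| parameter | default | why |
|---|---|---|
| n_mirs | 200 | panel scale of array-card profiling |
| n_pairs | 3 | matched-pair profiling design |
| pair f (volume fraction) | 0.0005, 0.00125, 0.0025 | spans mild-to-heavy hemolysis; spectrum model maps these to A414 degrees ≈ 2.4–7.8 |
| susceptible k | log-uniform [800, 20000] | 1–4.7-cycle shifts at the 0.125% spike, bracketing the 1.5–2.4-cycle shifts of validated susceptible species |
| stable k | uniform [0, 80] | ≤ 0.15-cycle shift at 0.125%, safely inside the stability band |
| specific k | log-uniform [10⁶, 10⁷] | detectable in hemolyzed plasma and lysate, never in clean plasma |
| baseline Cq (cycles) | uniform (24, 34) | plasma-detectable range; specific species sit at censor + U(0, 2) |
| σ (cycles/reaction) | 0.25 | typical TaqMan replicate scatter |
| runs × reactions | 2 × 2 | two isolations, duplicate reactions |
| label proportions | 0.50 / 0.45 / 0.05 | roughly two thirds of detectable plasma miRNAs respond to hemolysis; specific species are a handful per panel |

Spectra come from a flat 0.10 OD plasma baseline plus a Soret Gaussian
(center 414 nm, width 15 nm) whose amplitude is solved exactly so that
A₄₁₄(f) = 0.143 + 3.864·%RBC — calibrated to reference endpoints 0.143 OD
at 0% and 0.626 OD at 0.125% — and Q-band Gaussians (541/576 nm, width
4 nm) at one tenth the Soret amplitude, so Q-bands only clear the 0.02
prominence at heavy contamination. %RBC (interfaces, sample sheets) and
volume fraction (mixing model) are linked by the single constant
`PERCENT_TO_FRACTION = 0.01`. Seeds are mandatory; there is no hidden
global randomness, and equal seeds give byte-identical study bundles.

What passing tests show — and don't: the generator emulates censoring,
replicate noise, paired design and a linear spike response. It does not
emulate inter-subject biological variability, isolation-efficiency
differences between samples, PCR inhibition, or non-linear saturation of
highly contaminated samples, so perfect recovery on synthetic data
bounds, but does not guarantee, performance on clinical material.

## Numerical choices and degenerate inputs

* ODs below −0.05 are rejected as corrupt input rather than clamped
  (small negative baselines are instrument drift; large ones are not).
* Spearman ρ of a constant trajectory is defined as 0 (all ties).
* SDs across runs use ddof = 1, with SD = 0 for a single run.
* Fold-change reciprocal, interpolation and tier-nesting identities are
  property-tested (hypothesis, derandomized).
* Out-of-range Cqs are reported with their full (assay, sample,
  replicate, value) coordinates.

## Known limitations

* The per-miRNA enrichment factors are stylized ranges, not fitted to
  any measured RBC miRNA content; absolute synthetic Cqs should not be
  compared to real instruments.
* The dilution "affected" call is a binary threshold rule; it does not
  estimate the enrichment factor itself (a regression of 2^−ΔCq on f
  would, but is out of scope here).
* Hemoglobin OD is never converted to g/l free hemoglobin — no
  calibration is assumed.
* Cohort-level counts from the original profiling experiment cannot be
  recomputed without its raw per-sample Cq tables, which were released
  only as supplementary spreadsheets and are not redistributed; the
  corresponding check in the test suite documents this and fails rather
  than silently passing.
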