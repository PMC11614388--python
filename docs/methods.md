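# Methods

`midtrace` implements the analysis chain of a ¹³C stable-isotope-tracing
GC-MS metabolomics study: natural-abundance correction of isotopologue
peak areas to mass isotopomer distributions (MIDs), experiment-level
labeling summaries, and the two-group differential statistics used for
CSF-style and conditioned-media-style metabolite tables.  A forward-model
synthetic generator makes every stage testable without instrument data.

## Natural-abundance correction

**Fragment composition.** GC-MS metabolites are measured as TBDMS
(tert-butyldimethylsilyl) derivatives on the characteristic M-57 fragment:
each active hydrogen is replaced by a TBDMS group (C6H15Si) and the
monitored ion has lost one tert-butyl radical (C4H9, 57 Da).  The fragment
formula therefore is `parent − n_sites·H + n_sites·C6H15Si − C4H9`.
Underivatized species (LC-MS acylcarnitines) use the parent formula.
Because TBDMS fragments carry silicon, whose heavy isotopes (²⁹Si 4.685%,
³⁰Si 3.092%) contribute strongly at m+1/m+2, correction matrices must be
built from the *derivatized* composition, not the parent metabolite.

**Isotope patterns.** The theoretical pattern of a fragment is the
convolution over all atoms of the single-atom mass-shift distributions,
computed per element by binary exponentiation of the single-atom pattern
(contractually identical to repeated convolution, O(log n) convolutions
per element).  Built-in abundances are IUPAC-style terrestrial values
(¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O/¹⁸O 0.00038/0.00205,
²⁹Si/³⁰Si 0.04685/0.03092, ³³S/³⁴S/³⁶S 0.0075/0.0425/0.0001) and can be
overridden through `IsotopeTable`.

**Correction matrix.** For a fragment with `n` tracer-eligible carbons the
matrix `A` has columns j = 0..n; column j is the theoretical observed
pattern when exactly j tracer carbons carry label: the natural pattern of
the fragment minus j carbons (the remaining n−j tracer positions stay at
natural abundance), convolved with the tracer term.  With tracer purity 1
the tracer term is a delta at shift j and `A` is lower-triangular with
positive diagonal, hence invertible; with purity p < 1 it is the binomial
pmf of j positions at enrichment p.  The default purity is 1.0 (no purity
correction is applied unless requested).  Patterns are truncated at
K = n + 4 extra shifts by default, enough to capture the Si/S/O heavy
tails of TBDMS fragments; truncation only drops tail mass.

**Deconvolution.** Measured areas are corrected by non-negative least
squares (`A·x ≈ raw`, `x ≥ 0`), then renormalized to the MID.  NNLS rather
than direct inversion because channel noise can push a naive inverse
negative; on noise-free data the NNLS solution equals triangular
back-substitution (tested).  The pre-normalization sum of `x` is the
corrected total pool.  Diagnostics: the relative 2-norm residual is stored
per correction and flagged above 5% (default; at 10% channel CV roughly
the upper half of corrections flag, which is informative, not fatal).
Measured vectors shorter than K+1 are zero-padded; longer ones truncated
with a logged warning.  An all-zero vector has no defined MID and raises;
at the table level such (sample, metabolite) pairs are skipped, which is
how multi-compartment tables represent "not measured here".

**Summaries.** Fractional enrichment is Σ j·MIDⱼ / n ∈ [0, 1].  Abundances
are expressed relative to the internal standard (D-myristic acid, spiked
at 750 ng/sample) and per 10⁶ cells: `area / IS_area / cells × 10⁶`.

## Tracing readouts and contrasts

Experiment-level readouts are per-group mean ± SEM of either a MID
fraction or the normalized labeled abundance (`pool × MIDⱼ`, IS- and
cell-normalized) — the latter is the "relative abundance" convention used
for media-release panels.  Group contrasts use the unpaired two-tailed
Student's t-test with pooled variance (df = n₁+n₂−2); Welch's form is
available behind a flag but is not the default because the pooled test is
the stated convention for these designs.  Degenerate zero-variance cases
return (0, 1) for equal means and (±∞, 0) flagged otherwise.  Group sizes
of n=3 are accepted without normality checks, matching the tracing
designs; this is a documented limitation, not an endorsement.
Media-transfer reports join donor-media readouts with recipient-cell
readouts on shared (metabolite, isotopologue) keys; donor-absent keys are
excluded since the donor media defines what could have transferred.

## Differential two-group tables

Per metabolite: FC = mean(treated)/mean(control), log2FC, two-sided p,
−log10 p, optional BH q, and an enrichment call.  Two test back-ends:

* **Student's t** (CSF-style tables, sorted by |log2FC| descending).
* **Wilcoxon rank-sum** (media-style tables, sorted by p ascending, with
  Benjamini–Hochberg FDR over the submitted table's rows).  `exact` mode
  uses the exact permutation null (ties are an error directing to `auto`);
  `normal-approx` applies tie and continuity corrections; `auto` chooses
  exact for tie-free groups up to n=25.  A brute-force enumeration over
  all C(n₁+n₂, n₁) rank assignments is kept as an independent oracle and
  the two agree exhaustively for all n₁, n₂ ≤ 6; the smallest achievable
  two-sided exact p at n=6 per group is 2/924 ≈ 0.00216.

The enrichment rule is |log2FC| > 1 **and** p < 0.05 (both thresholds are
parameters).  This is the unique simple rule consistent with every call in
the bundled CSF reference table — e.g. glutarylcarnitine (p ≈ 0.004 but
log2FC 0.68) is "Not Sig" while hexadecanoic acid (log2FC 1.18, p 0.01)
is enriched.  Zero group means use a pseudo-abundance of half the smallest
nonzero value in the table; all-zero rows are flagged, never fatal.
Rendered tables round FC/log2FC to 2 decimals and p to 2 significant
figures; machine outputs keep full precision (the bundled reference table
itself shows artifacts of independent rounding, e.g. a −log10 p of 2.11
printed beside p 0.01, so recomputation always starts from unrounded
values).

Pooled "Overall" summaries combine group means/SDs exactly as the summary
of the concatenated raw samples:
M = (n₁m₁+n₂m₂)/(n₁+n₂),
s² = [(n₁−1)s₁² + (n₂−1)s₂² + n₁(m₁−M)² + n₂(m₂−M)²]/(n₁+n₂−1).
Note that for two identical groups this gives s·√((2(n−1))/(2n−1)), not s;
that is a property of the concatenation-consistent definition, which is
the one the bundled media reference table verifiably uses.

## Synthetic generator

The generator is the forward model of the correction stage: per sample and
metabolite, raw areas are `pool × (A @ true_MID)` multiplied by independent
per-channel mean-one lognormal noise (lognormal because peak areas are
positive and right-skewed) plus an optional additive baseline, with a
separately noised internal-standard channel.  Ground truth (true MIDs,
pools, effects, noise) is always emitted alongside the data.  A single
seeded PRNG stream drives each run; equal seeds give byte-identical CSVs.

Study designs mirror the emulated experiments: tracing fixtures use
n=3/group (BSA vs palmitate pretreatment), the conditioned-media table
n=6/group, the CSF table n=10/group, with 2×10⁶ cells/sample and an
IS area of 750.  Channel CVs: 15% for cell extracts, 25% for media, 20%
for the CSF abundance table, and 10% for the glucose tracing fixture (its
prescribed calibration).  Bundled fixtures:

* `palmitate_4h` — β-oxidation readouts (palmitoylcarnitine m+16,
  acetylcarnitine/acetylserine m+2), TCA entry (m+2 in α-KG, glutamate,
  succinate, fumarate, malate) and itaconate m+1, cell + media; palmitate
  pretreatment raises the glutamate/itaconate/succinate shunt while
  leaving fumarate/malate unchanged.
* `glucose_6h` — glucose m+6, lactate/pyruvate m+3, m+2 TCA labeling,
  cell + media + recipient neurons whose pools are 0.3× the donor media
  (declared uptake fraction for transfer tests).
* `csf_3dHFD` — 34 metabolites × 2×10 samples whose true fold changes are
  the reference table's printed FCs (2.27 and 2.17 for the two fatty
  acids).
* `media_24h` — 2×6 samples with true group means taken from the media
  reference table (all-zero-mean rows are dropped: a lognormal cannot be
  seeded at zero).

What the generator does *not* emulate: chromatographic artifacts
(retention-time drift, co-elution), detector saturation, missingness,
inter-batch effects, or correlated channel noise.  Passing recovery tests
therefore demonstrates correctness of the correction/statistics chain
under the declared noise model, not robustness to instrument pathology.

The registry of fragment compositions (TBDMS site counts, tracer-carbon
counts) is curated in `data/default_registry.csv` following standard
derivatization chemistry; monitored fragments can be overridden per
metabolite (`fragment_override_formula`) when a non-default ion is used.

## Numerical and design choices

* Scenario truths for labeled fractions are round qualitative values
  chosen once to reflect the emulated biology (strong glycolytic labeling,
  moderate TCA m+2 entry, small itaconate m+1); recovery tests compare
  against the emitted truth, never against figure readings.
* Parameter-recovery is assessed against the ensemble standard error: the
  SE of each group-mean readout is estimated from the replicate ensemble
  (200 replicates), and replicates must fall within 3 SE of truth ≥95% of
  the time.  The per-replicate sample SEM at n=3 is itself so noisy that
  a ±3×(sample SEM) band has only ≈90% coverage (t with 2 df), so it
  cannot certify an unbiased estimator; the ensemble criterion can, and
  fails under a biased correction (e.g. skipping the Si correction).
* Monte-Carlo problem sizes (200 recovery replicates, 1000 null tables of
  20 metabolites, 300-case round-trip sweeps) were chosen to put
  Monte-Carlo error well below the margins being tested while keeping the
  default runs desk-scale.
* The command-line layer is a thin wrapper over the library; every run
  writes a `manifest.json` with config, seed, package/library versions and
  SHA-256 checksums of the inputs.

## Known limitations

* No isotope fine structure or mass-resolution modeling: correction is at
  nominal (unit) mass-shift resolution, appropriate for quadrupole GC-MS.
* FDR q-values are computed over the submitted table only; q-values of a
  published table cannot be re-derived from rounded p-values.
* No batch correction, mixed models, or >2-group designs (two-way ANOVA
  with post hoc tests is out of scope).
* Vendor raw formats (mzML/CDF) are not read; inputs are CSV peak-area
  tables from upstream peak integration.
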