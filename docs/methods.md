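# Methods

This note documents the models, rules and numerical choices behind
`secondhit`, and what the synthetic-data generator does and does not
emulate.

## Read-depth CNV model

Counts for interval *j* of sample *i* in a capture batch are modelled as

    N_ij ~ Poisson( lib_i · e_j · L_j · c_ij / 2 )

where `lib_i` is a per-sample library-size factor, `e_j` a bait-specific
capture efficiency, `L_j` the interval length and `c_ij` the local copy
number (2 unless a CNV overlaps the interval; partial overlaps scale the
dosage step by the overlap fraction).

**Normalization.** Each sample's counts are rescaled so its total equals
the batch mean total. This removes `lib_i` exactly and makes the ratio
matrix invariant to rescaling any one sample's raw counts (verified to
1e-9 in tests). Note one consequence: a very large event changes the
carrier's total itself, shifting all of that sample's ratios by the lost
or gained fraction of the panel. On a realistic multi-gene design
(~1.4 Mb) even a 323 kb homozygous deletion shifts the baseline by ~30%
of the way toward (but not past) the duplication threshold, so calls are
unaffected; on a toy panel dominated by the event the shift can be
material. The simulator therefore includes ballast intervals when
building whole-gene scenarios.

**Reference.** The per-interval reference for a sample is the
leave-one-out *median* of the other samples' rescaled counts. The batch
text only requires comparison "with the other samples"; the median is
chosen so that a CNV-carrying neighbour cannot contaminate a sample's own
reference (a mean would). At least 3 samples are required; intervals
whose reference falls below `min_reference_count` (default 50 rescaled
reads) are flagged uncallable rather than divided.

**Calling.** Per interval, ratio < 0.6 flags a deletion and > 1.40 a
duplication; the inequalities are strict (a ratio exactly at a threshold
is normal dosage). Whether the thresholds apply per interval or to run
means is not specified by the published method; they are applied per
interval, and runs are then summarized by their mean. Runs of
same-direction intervals merge across at most `max_gap` (default 1)
interior unflagged intervals — capture-efficiency dropouts produce
isolated normal-looking intervals inside true events — and runs with
fewer than `min_intervals` (default 2) flagged intervals are dropped to
suppress single-interval noise. Zygosity follows expected dosage with
slack for noise: deletion mean ratio ≤ 0.10 → homozygous, in
[0.35, 0.60) → heterozygous; duplication in (1.40, 1.65] → heterozygous
(three copies); anything else is undetermined. The caller takes whatever
counts it is given; whether duplicates were removed upstream is the
caller's input contract, not something it can verify.

## Breakpoint refinement

Within a contiguously tiled region, the per-base sample/reference depth
ratio is smoothed with a running median (window 51 bases; reference
dropouts are treated as ratio 1, i.e. uninformative). The smoothed track
is scanned for runs of at least `min_crossing_run` (50) consecutive bases
beyond the call's threshold; the first and last such run overlapping the
call span give approximate edges. A median filter preserves a clean step
at its exact base, but at low-contrast steps (1.0 → 1.5 for a
heterozygous duplication) the boundary value of the running median is an
order statistic of the high side, which biases the detected edge by a few
bases. Each edge is therefore polished by a two-segment least-squares
change-point fit on the raw ratio within ±2 smoothing windows — the
classic step-fit estimator, unbiased and, at capture depths of several
hundred X, base-exact with high probability. If no sustained crossing
exists the call is returned unrefined with a warning flag rather than
guessed. Reported breakpoints are 1-based, first to last affected base
(the convention of HGVS-style genomic notation); BED/bedGraph files are
0-based half-open.

## Allele-balance corroboration

In a tandem duplication the duplicated haplotype carries 2 of 3 copies,
so reads at a heterozygous SNP are Binomial(depth, 2/3) for the major
allele. The summarizer folds each SNP to its major-allele fraction
`max(ref, alt)/total` (SNPs under 20 reads are ignored), reports the
fold-biased raw mean plus a noise-corrected estimate
`1/2 + sqrt(mean[(f − 1/2)² − f(1 − f)/(n − 1)])` (the bracketed term is
an unbiased estimate of the squared shift), and issues a verdict:
three copies iff the mean lands in [0.60, 0.75] **and** ≥ 80% of SNPs
individually exceed 0.58; two copies iff the mean lands in [0.45, 0.55];
otherwise inconclusive. The per-SNP condition prevents a couple of
outlier SNPs from carrying the verdict.

## Variant screening

QC retains records with DP ≥ 20 and FS ≤ 60.0 (both boundaries retained;
records missing either field are rejected with reason `missing-qc`, never
silently passed; CNV alleles carry no site-level DP/FS and are exempt).
The frequency screen retains a record iff its MAF is < 0.015 in *every*
database where it is observed — a single common observation disqualifies
a rare-disease allele — and absence everywhere (a novel variant) passes.
A MAF of exactly 0.015 is rejected: the retain rule is `MAF < 0.015`,
and the complementary "filter out > 0.015" phrasing is resolved in favour
of the retain rule. Both filters are idempotent and commute.

## Splice rules

Per tool, a score pair passes iff the *active-site* score meets the tool
minimum and the relative score change exceeds the variation threshold:
MaxEntScan ≥ 2 and > 15%, HSF ≥ 70 and > 10%, NNSPLICE > 0.4 and > 10%.
For loss of a native site the active site is the wild-type one and the
change is computed relative to the wild-type score; for gain of a cryptic
site the new (mutant) site is the active one and the change is relative
to the mutant score — which also keeps the ratio defined when no site
existed before (wild-type 0 ⇒ 100% change). Variation thresholds are
strict. The published protocol does not state how the three tools
combine; the default policy flags a variant when a strict majority of the
tools that produced scores pass (2 of 3, 2 of 2, 1 of 1), matching the
practice of citing multiple concordant predictors; `any`/`all` policies
are available. When a variant affects both a loss and a gain event, each
event is evaluated separately and either can flag it.

## Causality and prioritization

Each screened variant is graded:

* **excluded** — segregation places it in cis with the prior variant
  (does not co-transmit with disease), the gene does not match the
  family phenotype, the database consensus is benign, or there is no
  supporting evidence at all;
* **causal** — phenotype-consistent, segregation (when performed) is
  consistent, and either the databases call it pathogenic/likely
  pathogenic, or it is novel with damaging evidence: a truncating
  consequence (nonsense, frameshift, CNV), a passing splice verdict for
  splice-type consequences, or a majority of protein predictors for
  missense. Database-pathogenic alleles without available relatives are
  *presumed* causal when phenotype-consistent (the presumption rule);
* **candidate** — plausible but incomplete: deep-intronic variants that
  pass the splice rules but lack segregation are capped at candidate, as
  are variants with only partial predictor support or genuinely mixed
  database interpretations.

Conflicting-interpretation database labels satisfy the pathogenicity
criterion only when the recorded submission majority is
pathogenic/likely-pathogenic; labels with benign-majority count against
the variant, and balanced ones grade at most candidate. The criteria
trace records every flag per variant.

The published "(i) segregate, (ii) database-pathogenic or novel,
(iii) phenotype-consistent" criteria are conjoined as
(ii or novel-with-damaging-evidence) AND (iii) AND not-(i fails): many
accepted alleles in the source cohort lack segregation but none were
accepted against it, so failed segregation excludes while absent
segregation merely withholds confirmation.

Genotype models: recessive genes complete with one homozygous causal
allele or ≥ 2 heterozygous causal alleles — unphased double-hets are
assumed in trans with an explicit `phase unconfirmed` note (the source
cohort itself reports compound heterozygotes without parental phasing in
7 of 17 solved families); dominant genes complete with one heterozygous
causal allele only when segregation confirms it. Two homozygous causal
alleles in one gene is contradictory and demotes the family to candidate
with a consistency note. The search evaluates the prior-variant gene
first and other genes afterwards, keeping the first solved model in that
order, then the first candidate model; this makes the fallback a strict
superset search (removing the prior variant can never turn an unsolved
family into a solved one).

Phenotype consistency is an exact lookup in a packaged gene→diagnosis
map (RetNet-style associations). The full 79-gene clinical panel list is
not public; the map covers the genes appearing in the cohort plus a
representative set of well-known IRD genes, and unknown genes are treated
as inconsistent (with a rationale entry).

## Reporting conventions

Diagnostic yield is `100 · solved / families`, rounded half-up to 2
decimals. The mutation spectrum uses the allele-counting convention under
which a homozygous genotype contributes one counted mutation per family
and a recurrent allele counts once per carrying family — the only
convention under which the fixture cohort yields its printed totals (31
occurrences: 18 missense, 4 splicing, 4 frameshift, 3 nonsense, 2 CNV).
"Splicing" pools near-splice intronic and synonymous-splice consequences.
Percentages are reported both raw and rounded half-up to 1 decimal; note
3/31 rounds to 9.7%. Aggregation is deterministic and invariant to input
order, and duplicate family ids are an error.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical structure the analysis relies
on*: Poisson count noise around efficiency × library-size expectations,
lognormal per-sample library variation (default 10–20% CV), embedded
CN 0/1/3 events with fractional dosage at partially overlapped
intervals, binomial allele sampling at heterozygous SNPs (p = 1/2 and
2/3), step-shaped per-base coverage with Poisson noise at a default
800X mean depth (the scale of deep targeted capture), and variant tables
whose MAF spectrum is dominated by common polymorphisms with a
configurable rare fraction (defaults mirror a per-patient load of 2,349
variants of which ~314 are rare). Fixed seeds give byte-identical
outputs.

It deliberately does **not** model read-level artifacts: GC bias,
mappability, duplicate reads, batch effects correlated across intervals,
mosaicism, or copy numbers above 3. Passing tests therefore demonstrate
the correctness of the normalization, calling, refinement and
prioritization logic under the assumed generative model — not robustness
to alignment-level pathologies, which an upstream pipeline must handle.

Worked-example inputs (the two USH2A CNV scenarios) are generated at run
time at the published hg19 coordinates with 1 kb tiles over the gene
region plus ~1.1 Mb of ballast intervals, matching the share the gene
occupies in the real design. Problem sizes throughout the test suite
(batches of 6 samples, 40–60 interval panels, 200-seed sweeps, 100-SNP
spans) are chosen to estimate each property tightly while keeping the
suite fast.

## Known limitations

* Segregation enters as a per-variant status (consistent / inconsistent /
  unavailable) rather than from raw relative genotypes; pedigree-file
  parsing is out of scope.
* The caller reports dosage in {0, 1, 2, 3}; higher amplifications and
  mosaic fractions are out of scope.
* The splice rules score externally produced predictions; the package
  never runs the predictors, and a flagged variant is a *prediction* —
  functional confirmation is outside the analysis.
* CNV population-frequency annotation (DGV/DECIPHER) is carried as
  fields only; no lookups are performed.
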