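# Methods

`plastevo` re-implements, as one tested library, the comparative analyses
routinely applied to plastid genomes: quadripartite structure detection and
IR-boundary comparison, a three-class repeat landscape, simple indel coding,
fixed-topology rate estimation for substitution and indel characters, and
branch dN/dS under a codon model. This note records the models, the defaults
and why, the numerical choices, and what the synthetic-data battery does and
does not demonstrate.

## Coordinates and sequence model

Plastomes are circular; all intervals are 0-based, half-open, and may wrap
the origin (`CircularInterval` stores start + length, making the wrap case
unambiguous). GenBank's 1-based inclusive locations are converted on read.
Sequences are normalized to ACGTN; IUPAC ambiguity codes other than N are
mapped to N because every detector and likelihood below defines behaviour
only over ACGTN.

## Inverted-repeat detection and the quadripartite partition

The IR pair is found exactly at the sequence level: all 31-mers of the
forward strand are indexed; hits against the reverse complement are grouped
by anti-diagonal (for an ungapped inverted match, `startA + endB` is
constant); the largest exact block per diagonal is extended base-by-base
while overall identity stays at or above `1 - max_mismatch_frac`; the
longest disjoint pair wins, ties to the smaller start coordinate with a
logged structural-ambiguity warning.

Defaults: `min_len = 10000` (angiosperm IRs are 20-40 kb; the floor keeps
large dispersed repeats from masquerading as an IR), `max_mismatch_frac =
0.001` (plastome IR copies are homogenized by gene conversion and are
near-identical). With a nonzero budget the maximal pair may absorb a few
coincidentally complementary flanking bases — this is the correct maximal
answer under the stated criterion, not an error; recovery studies that
require exact planted boundaries run with a budget of 0. Limitations: only
substitution differences between copies are handled during extension (no
indels), and the IR copies must not span the sequence origin (published
records conventionally open inside the LSC; rotate first otherwise).

The two arcs between the IR copies become the single-copy regions, the
longer being the LSC; equal arcs fall back to the arc containing *rbcL*,
else the lower coordinate (logged). GC is reported per region and for the
full circle; whole-record comparisons use the full circle. Genes are
assigned to the region containing their midpoint; genes overlapping a
junction are flagged with every region they touch, which keeps the
classification discrete while exposing straddlers such as *rps19* and
*ycf1*. Boundary diffs collapse IRa/IRb to a single "IR" label so an
IR-expansion event (single-copy genes becoming duplicated) is reported once.

## Repeat landscape

**Mononucleotide.** Maximal homopolymer runs of >= 8 bp (regex-equivalent,
verified against a regex oracle), N never extends a run, and runs meeting at
the origin of the circle are merged. The 8 bp threshold is exposed as a
parameter.

**Tandem.** A Tandem-Repeats-Finder-style scan without external binaries:
for each candidate period p (1..500) the sequence is compared with itself at
lag p; match runs separated by at most 5 mismatches are chained; chains are
trimmed to their maximal-scoring stretch (Kadane, +2/-7); a majority-rule
consensus unit is built and the array is scored against the repeated
consensus with TRF's default weights (match +2, mismatch -7, minscore 50,
maxperiod 500). The scan is substitution-aware but ungapped: arrays whose
copies differ by internal indels are reported as shorter or split arrays.
Harmonic collapse: overlapping reports of one locus (overlap > half the
shorter span) keep the best score; scores within 5 % are treated as tied and
the smaller period wins. The tie band exists because a 2-3-copy harmonic
consensus trivially absorbs about half of the copy divergence, inflating its
score by a few mismatch-weights relative to the fundamental; within the
band, and whenever the periods are near-multiples and the fundamental scores
at least 70 % of the harmonic, the fundamental is the more parsimonious
description. Note one consequence of minscore 50: a perfect ungapped array
scores 2 per bp, so arrays spanning under 25 bp (for example, five copies of
a dinucleotide) are below the reporting threshold by definition of the
detector — the planted-array battery therefore sizes its arrays above the
threshold.

**Dispersed.** A native self-scan replacing the external-aligner round trip:
pairs of loci sharing an exact 16-mer, extended along the ungapped diagonal
(direct and inverted orientations) while running identity stays >= 0.95,
reported when longer than 16 bp; trivial self-diagonal and symmetric
duplicates suppressed. The extension rule is deliberately simple and
deterministic — a mismatch run is absorbed if and only if including it and
the next match keeps identity at the threshold — so a quadratic brute-force
diagonal scan reproduces the exact pair set, which the tests exploit. One IR
copy is masked by default before the scan: the IR pair itself is a >25 kb
inverted repeat that would otherwise dominate occupancy.

**Occupancy.** Per class, the union of spans (no double counting of
overlaps); classes are not merged with each other. Mono and tandem repeats
localize to the region containing their start; each dispersed pair
contributes both loci. Because conventions differ on whether a dispersed
pair contributes one or two copies, the summary reports both (`total_bp`
counts both; `dispersed_one_copy_bp` counts one).

## Simple indel coding

Each distinct internal gap extent becomes one binary character: 1 for taxa
with exactly that extent, 0 for taxa with residues across it, missing for
taxa with a different overlapping gap. Terminal gap runs are missing data
throughout (incomplete sequence, not deletion events). Identical gaps in
every taxon yield constant characters, which are retained and flagged
rather than dropped — downstream likelihoods can exclude them if an
ascertainment correction is wanted. Extents are compared within a gene only;
concatenation emits a partition table and fills absent taxa with missing.

## Branch lengths, clade rates, bootstrap test

Substitution matrices are fit under GTR+Γ (4 discrete categories, mean
discretization of Gamma(α, α) normalized to mean 1); indel matrices under a
two-state reversible model with Γ rates. Base/state frequencies are fixed at
their empirical counts (the default behaviour of the standard ML tools for
this analysis); exchangeabilities and α are ML via L-BFGS-B on log
parameters; branch lengths by coordinate-wise Brent with the two-pass
message trick (the likelihood as a function of one branch is an inner
product between the "up" and "down" conditional likelihoods). Convergence:
outer rounds alternate model and branch updates until the log-likelihood
improves by less than 1e-6; everything is deterministic given inputs.
Per-node rescaling keeps 61-state and low-rate mixtures in range. Gaps and N
are missing data in the substitution likelihood.

Clade mean rate: the mean crown-to-tip path length of the clade's MRCA
divided by a fixed calibration age in Ma (substitutions/site/Ma). This is a
deliberate, simple interpretation of "mean clade rate under fixed
calibrations": it uses no rate smoothing, so it is exactly reproducible; a
penalized-likelihood smoother would shift individual branch rates but not
the clade mean on clock-like data. Non-monophyletic clade definitions are an
error, not a warning. Nested clades carry their own ages (e.g. a crown group
at 33.2 Ma inside a family constraint at 59 Ma).

**Absolute vs relative indel rates.** A simple-indel-coded matrix contains
only variable characters (a gap extent nobody has is never coded), so
absolute branch lengths fitted to it without an ascertainment correction
are inflated — roughly an order of magnitude on the synthetic panels.
Padding the matrix with constant-absence characters does not help: it
drives the empirical frequency of the presence state to ~1e-4 and the
normalized two-state process becomes equally distorted. The package
therefore treats the fitted indel tree as a *relative* object (clade-to-
clade contrasts, where the inflation largely cancels) and estimates the
*absolute* per-site indel load by event counting: each coded character is
one indel event, so the per-site indel tree length is simply
`n_characters / n_columns`. On data simulated with the indel rate at 3.6 %
of the substitution rate, this counting estimator recovers the planted
contrast within sampling error, which is what the acceptance script
reports. Model kinds without Γ ("GTR", "BIN") are available alongside
"GTR+G"/"BIN+G".

Bootstrap test: columns of the concatenated matrix are resampled uniformly
with replacement genome-wide (implemented as a multinomial over compressed
site patterns, which is equivalent and fast); branch lengths are refit per
replicate with model parameters held at the original fit; each clade's
bootstrap rate sample is compared with the original estimate by a two-sided
one-sample t-test. A well-specified model yields p near 1 (the original sits
in the middle of its own bootstrap cloud); small p flags instability of the
rate to site resampling. Failed replicates are dropped and counted; more
than 5 % failures aborts. A constant matrix yields a degenerate p of 1,
documented rather than hidden.

## dN/dS

Two estimators, kept strictly independent so each can check the other:

* Nei-Gojobori (1986) counting with Jukes-Cantor correction (plastid =
  bacterial genetic code, translation table 11): site counts averaged over
  the two sequences, multiple-hit codons averaged over substitution
  orderings, stop-codon-crossing paths excluded. dS or dN is undefined
  (NaN) outside the Jukes-Cantor domain (p >= 3/4); very short toys fall in
  this regime, which is reported, not patched.
* A GY94-style ML codon model on 61 sense codons with F3×4 equilibrium
  frequencies (position-specific base frequencies, stops renormalized out),
  κ estimated, and either one global ω (`one_ratio`) or one ω per branch
  (`free_ratio`). Free-ratio is the default for per-branch contrasts because
  terminal and internal branches of accelerated genes differ in ω. Per-branch
  dN and dS follow the codeml convention: expected nonsynonymous
  (synonymous) substitutions per nonsynonymous (synonymous) site, with site
  counts from the ω = 1 version of the fitted matrix; ω is reported missing
  where dS = 0 or the branch carries no resolvable substitutions (t <=
  1e-5). Starting values κ = 2, ω = 0.4; the optimizer is deterministic from
  these, and optional random restarts (`n_restarts`) perturb starting branch
  lengths — on the simulated fixtures a single start reaches the same
  optimum, so the default is 1.

## Synthetic data

The generator produces the conditions the analyses assume, with ground
truth:

* **Plastomes**: LSC + IRa + SSC + revcomp(IRa), default 88/26/18 kb and
  GC ≈ 35.5 % (AT fraction 0.645) to mimic a mimosoid-scale genome; planted
  mono/tandem/dispersed repeats and gene stubs. The bases flanking each
  planted IR copy are forced to mismatch their inverted partners, making
  the planted IR the unique maximal inverted pair — without this, a quarter
  of random genomes extend the "true" IR by a base or more and exact
  boundary recovery is ill-posed.
* **Nucleotide alignments** evolved on a known tree under GTR+Γ (defaults:
  AT-rich frequencies 0.32/0.18/0.18/0.32, transition-biased
  exchangeabilities) with an optional indel process: Poisson events per
  branch at a rate expressed *relative to the substitution rate* (0.036
  mirrors the observed few-percent per-site contribution of indels),
  geometric lengths with mean 3, placed uniformly; insertions create new
  alignment columns, and per-branch event counts are recorded. Within a
  branch, substitutions are applied via the exact transition matrix and
  indels afterwards — event interleaving is not simulated, which is
  immaterial at these rates.
* **Codon alignments** under the same GY94 machinery with known per-branch
  ω.

Everything is bit-reproducible from (spec, seed). What passing on this
battery does *not* show: robustness to annotation errors, to IR copies
diverged by indels, to alignment error in real MACSE output, or to
among-gene rate heterogeneity — real plastome panels exercise all four.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own desk-scale battery: 100 planted genomes
(LSC 50-90 kb, IR 10-40 kb, SSC 5-18 kb) for structural recovery; 1000
random strings for the mono oracle; 100 planted arrays for tandem recovery;
4 kb sequences for the dispersed brute-force comparison; a 20-taxon, 10 kb
clock simulation at 5e-4 subst./site/Ma (age 33.2 Ma) with 100 bootstrap
replicates; 6-taxon codon simulations with 500 codons (global ω) and 50
runs of 300 codons (positive-selection detection).
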