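# Methods

## Scope

`sybodykit` implements the design-and-validation workflow for a
semi-randomized synthetic nanobody (sybody) display library: the positional
amino-acid composition design and its diversity arithmetic, in-silico
construction and verification of the ribosome-display DNA cassette,
synthetic data generation (variant libraries, paired-end amplicon reads,
BLI sensorgrams, two-condition ELISA plates), framework-anchored NGS
composition QC, selection-round statistics, and 1:1 binding-kinetics
fitting. Wet-lab steps (expression, biotinylation, panning, gels,
chromatography) are outside the package's scope.

## Library design model

A design is a scaffold protein, a contiguous region map (FR1–FR4
frameworks and CDR1/2/3, each CDR including its randomized flanking
positions), and per-position compositions. A composition assigns a weight
(design frequency, summing to 1 within 1e-9) to each allowed amino acid at
one 0-based scaffold position. Coordinates are 0-based half-open
internally; a `display_number` field carries 1-based figure-style residue
numbers.

Diversity is counted, not weighted: a fully randomized stretch of `n`
positions over an `a`-letter alphabet encodes `a**n` sequences (computed as
an exact integer), and a semi-randomized design encodes the product of its
allowed-set sizes. Weights change sampling frequencies, never the count, so
diversity is invariant under reweighting and position permutation.
"Fully randomized" positions here use the 18-letter alphabet excluding
cysteine (disulfide risk) and proline (backbone rigidity); the alphabet is
taken from each position's declared set, so 20-letter arithmetic is equally
expressible.

### The packaged S1.0 fixture

`src/sybodykit/data/s1_0.yaml` is a **synthetic reconstruction**: the
scaffold sequence and the individual weights are constructed, not
transcribed from a published figure. It reproduces the design-intrinsic
counts of the S1.0 library: 19 randomized positions; 7 in CDR1+flank with
32 (position, amino-acid) compositions; 5 in CDR2, one of them restricted
to Ser/Tyr/Arg/Glu at 25% each, the other four fully randomized (18
letters); 7 in CDR3+flank with 97 compositions; isoleucine encoded at 20%
at display position 29; theoretical diversity 1.13e18. Where no explicit
weight is dictated, equal weights are used (maximum-entropy default).
Analyses that depend only on these counts and on weight bookkeeping are
therefore exact; analyses that would depend on the authentic residue
identities are illustrative.

## Cassette model

The display cassette is promoter → RBS → ORF → linker → stall spacer →
terminal restriction cassette. The promoter element is the printed 5'
flank containing the T7 core `TAATACGACTCACTATAG`. The RBS and the
tolA-type stall spacer are synthetic placeholders of realistic length (the
authentic vector sequences are not public); the spacer embeds the reverse
complement of the RT primer `CTTCAGTTGCCGCTTTCTTTCTTG` in frame, and the
terminal element is the reverse complement of the TolA-R2 primer with its
minus-strand BspQI site. The coding frame from the start codon through the
spacer is stop-free, as ribosome stalling requires; the terminal element is
not translated. Fixed positions use one preferred E. coli codon per amino
acid; randomized positions carry one codon per allowed letter as slot
alternatives.

Type IIS enzymes are encoded as (recognition site, spacer-to-cut,
overhang length): BsaI GGTCTC/N1/4, BbsI GAAGAC/N2/4, BspQI GCTCTTC/N1/3 —
standard definitions, configurable. Fragments are dsDNA with declared 5'
overhangs present at both ends of the sequence; ligation merges each shared
overhang once, so the assembled length is the fragment-length sum minus one
overhang per junction. Assembly order is dictated by the overhang graph
(unique matches required), making the result deterministic and independent
of input order.

## Synthetic data generators

All generators are pure functions of (parameters, seed) with NumPy
`default_rng`; reruns are byte-identical.

* **Variants** — each randomized position drawn independently from the
  design weights, optionally reshaped by multiplicative bias factors and
  renormalized. Copy counts model PCR duplication.
* **Reads** — PE150 amplicon pairs. The amplicon spans ORF start through
  the linker (396 nt for the fixture), so read 1 covers CDR1, read 2 covers
  CDR3, and CDR2 falls in the unsequenced gap — matching a CDR1/CDR3-only
  analysis. Errors are i.i.d. substitutions; indels and quality decay are
  not modeled (a fixed-length extractor would reject indel reads, and the
  QC targets composition, not quality). Qualities are constant Q40.
  Sampling is proportional to copy count; a replacement-free mode draws
  each read from a distinct molecule ("no PCR duplication").
* **Sensorgrams** — closed-form 1:1 responses (below) plus additive
  Gaussian noise; phase durations default to 300 s association / 600 s
  dissociation (placeholders; real run times are instrument settings).
  An ODE-integration oracle in the tests confirms the closed forms to
  1e-6 relative.
* **ELISA plates** — binder clones draw lognormal calcium/chelator signal
  ratios centered at 3; non-binders a lognormal null centered at 1
  (sd 0.08); chelator signals near 0.3 absorbance units. Defaults model a
  96-well screen with half binders.

What passing tests on these generators show about real data: the QC
pipeline recovers what the generator encodes (frequencies, biases,
uniqueness) under the stated statistical model. Real libraries add PCR
bias with positional structure, indels, chimeras, quality decay and
synthesis artifacts that are not emulated; the discrepancy magnitudes
observed on real data cannot be predicted from these simulations.

## NGS QC

Extraction is framework-anchored: 15-nt DNA anchors immediately flanking
each target region, ≤ 2 mismatches per anchor (pigeonhole-seeded scan with
an exact-match fast path), both strands tried, making extraction
strand-safe. A read yields an extraction iff both anchors match, the
intervening segment has exactly the designed length, and it translates
without stops; otherwise it receives a typed rejection (anchor-miss,
length-miss, frame-stop, low-quality). An optional per-read quality floor
stands in for external read-trimming tools.

Observed frequency at a randomized position is count / extractions covering
the position. Residues outside the designed set are reported as off-design
mass with the same denominator and are excluded from binning. The
discrepancy metric is relative percent, |O − E| / E × 100, chosen because
reported discrepancy ranges for low-weight compositions exceed any
plausible absolute-frequency difference; bins are <10%, [10%, 20%), ≥20%
(left-closed; the prose does not resolve edge ownership). A designed
composition with zero observed reads is "unrepresented" and un-binned, so
bin counts sum to represented compositions per region. Only regions present
in the observed table are compared (CDR2 is never sequenced with this
amplicon). Clonotypes are amino-acid-level (CDR1 residues, CDR3 residues)
pairs joined by read id; nucleotide-level collapsing is not implemented.

## Kinetics

The 1:1 reversible model dR/dt = kon·C·(Rmax − R) − koff·R with R(0) = 0
has closed forms: association R(t) = Req(1 − e^(−kobs t)) with
kobs = kon·C + koff and Req = Rmax·C/(C + KD); dissociation
R(t) = R₀ e^(−koff (t − t₀)); KD = koff/kon. `global_fit` shares one
(kon, koff, Rmax) across all concentrations and both phases, minimizing
unweighted summed squared residuals (no weighting scheme is modeled).

Numerical choices: rates are optimized in log10 space with
`scipy.optimize.least_squares` (TRF, tolerances 1e-15) within bounds
kon ∈ [1e2, 1e9] M⁻¹s⁻¹ and koff ∈ [1e-6, 1] s⁻¹ (configurable);
initialization is deterministic — per-curve kobs from the 63%-of-plateau
time, a kobs-vs-C linear regression seeding (kon, koff), Rmax from the top
plateau scaled by (C + KD)/C. Standard errors come from the local curvature
(JᵀJ)⁻¹ scaled by the residual variance. Data generated with koff = 0 fit
to the lower bound and raise a flatness warning; single-concentration fits
warn. A per-phase constant baseline is the only optional nuisance
parameter; mass-transport limitation, drift and reference subtraction are
not modeled.

## Selection analytics

Enrichment factor is experimental/control recovery; a zero control count is
reported as "no background", not infinity. ELISA positivity is strict
(ratio > threshold, default 1.5, per "exceeded"); clones with non-positive
chelator signal are unevaluable and excluded. The unpaired two-tailed
t-test is a thin convenience hook; exactly-constant groups are guarded
(equal means → t = 0, p = 1; unequal → p = 0 with a note).

## Problem sizes

The package's round-trip checks run at desk scale by choice: 1e5 reads for
composition QC (per-composition binomial z for the rarest weight, 1/18, is
≈ 7.4 at that depth, so the <10% discrepancy bin is expected to be
saturated in the error-free case), 1e4 molecules for the uniqueness
statistic, 20–50 Monte-Carlo replicates for kinetics noise studies.
Library-scale read counts (~1e7–1e8) change only runtime, not the
estimators.

## Known limitations

* The S1.0 fixture is a constructed stand-in (see above); results that
  depend on authentic per-position residue identities are illustrative.
* No indel/chimera/quality error models; no mate merging for overlapping
  amplicons.
* Kinetics covers the 1:1 model only; heterogeneous-ligand and
  conformational-change models are out of scope.
* Kabat/IMGT renumbering and V/D/J-style repertoire annotation are not
  provided.
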