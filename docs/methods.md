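# Methods

`rrbskit` implements a reduced representation bisulfite sequencing (RRBS)
analysis chain and a generative model of the experiment it analyses. This
note documents the model, its assumptions and parameters, the numerical
choices, and what the synthetic data can and cannot show about real data.

## The simulated experiment

### Genome

The toy genome consists of `n_chromosomes` uniform-composition chromosomes
(default 2 × 1 Mb, GC 0.42) carrying three feature classes plus a control
contig:

- **CG islands** — intervals (default ≈30/Mb, 500–2000 bp) rewritten with
  explicitly seeded CG dinucleotides (22 % of positions) on a GC-rich base,
  so they are both CG-dense and MspI-site-dense, as real islands are. A
  configurable fraction of genes (default 0.7) carries an island centred on
  its TSS.
- **Genes** — non-overlapping intervals (default ≈30/Mb, 2–10 kb) with
  strand, TSS, and 2–5 exons; one collapsed transcript per gene.
- **Repeats** — diverged copies (default 10 % substitution) of four family
  consensus sequences (SINE/LINE/LTR/satellite). Divergence keeps 49-mers
  mostly unique so repeats remain mappable at toy scale while still
  exercising the ambiguity path of the aligner.
- **Spike-in** — a fully unmethylated contig with CCGG sites every 200 bp,
  so its fragments always survive size selection and provide conversion-rate
  observations. It carries no other annotation.

MspI digestion cuts C^CGG on the forward strand (the site is its own
reverse complement, so forward scanning is lossless); fragments of
150–400 bp (inclusive) are retained.

### Methylation landscape

Every cytosine on both strands receives a true methylation probability:

- **CG sites** draw from a two-mode Beta mixture (low mode mean 0.08, high
  mode mean 0.85, concentration 30). The *mode* is drawn once per 300-bp
  block, which produces the strong adjacent-CG correlation seen in real
  methylomes; the high-mode weight depends on the compartment: 0.15 inside
  islands, 0.45 in 2-kb shores, 0.75 in background, 0.92 in repeats. CG
  dyads are symmetric by default (both strands share one draw).
- **Non-CG sites** (CHG/CHH) draw from a single low-mean Beta (mean 0.015).
  In *oocyte mode* the non-CG mean is coupled to the local (block) CG level,
  reproducing the genome-wide CG/non-CG correlation characteristic of
  oocytes; somatic mode leaves them independent.
- **Tissue effects** are regional: `n_tissue_regions` windows (default 40;
  half of them gene promoters, the rest random 600-bp windows) have all
  their CG dyads shifted by 0.6 towards the opposite extreme in exactly one
  sample. Regional shifts are deliberate — differential methylation in real
  tissues is clustered (e.g. a promoter island hypomethylated in one
  tissue), and site-level shifts would be diluted to invisibility in
  promoter means.
- **Spike-in** cytosines are exactly 0.

### Reads

Each retained fragment receives Poisson(`depth`, default 30) read pairs;
each pair derives from the top or bottom strand with probability ½ and reads
49 bp in from both fragment ends (truncated and flagged when the fragment is
shorter). Per covered cytosine, the read shows C with probability
`p + (1 − p)(1 − c)` where `p` is the site's true probability and `c` the
per-sample conversion rate (default 0.993; methylated cytosines are never
converted, incomplete conversion leaves unmethylated cytosines as C).
Both mates are emitted 5′→3′ on their bisulfite strand of origin (forward
reference orientation for top-strand reads, reverse complement for
bottom-strand reads); the complementary-to-converted strands of real
library chemistry are not modelled, and downstream counting treats mates
independently with overlap de-duplication. MspI end-repair fill-in
cytosines are not modelled either: fragment-end cytosines carry their
genomic landscape probability. Sequencing errors, adapters, quality
variation and PCR duplicates are all absent; quality trimming is therefore
a pass-through hook.

### Expression

Per gene, `log2(expression) = baseline − coupling × (mean promoter CG
methylation) + N(0, σ)` with baseline 5, coupling 6 and σ = 0.5; the
promoter is the 1500 bp upstream of the TSS. Genes without promoter CG
sites fall back to baseline + noise and are flagged. Expression is exported
as `2^log2` (FPKM-like, non-negative).

## The analysis chain

- **Alignment** is exact-match three-letter mapping: a read is C→T-collapsed
  and matched to the C→T reference (top strand), and reverse-complemented +
  G→A-collapsed against the G→A reference (bottom strand). Only reads with
  exactly one match across both strands are kept; candidates are found by a
  64-bit polynomial rolling hash over all read-length windows and verified
  by full sequence comparison, so hash collisions cannot create false
  alignments. Reads under 20 bp are rejected with a distinct status. The
  ungapped, zero-mismatch design matches the simulator (no indels or
  sequencing errors) and is a documented toy-scale simplification.
- **Calling**: over each unique alignment, reference-C positions (top) or
  reference-G positions (bottom) are tallied as methylated (C/G) or
  unmethylated (T/A); any other base is ignored as an artifact, not counted
  as unmethylated. The two cytosines of a CG dyad are reported as separate
  strand-specific rows (required for cross-strand autocorrelation); an
  optional transform pools dyads. Coordinates are 0-based half-open
  internally and 1-based in exported tables.
- **Filtering** keeps sites with ≥8 reads (the default chosen by the
  cluster-stability scan: filter at 3–10×, restrict to sites shared by all
  samples, keep those with across-sample SD < 0.2 (sample SD, n−1), cluster
  samples by average linkage on 1 − Pearson, and take the smallest threshold
  from which the tree topology — compared as rooted-clade sets, i.e.
  Robinson–Foulds 0 — never changes). Stability between consecutive
  thresholds is reported as 1 for identical topologies, else the cophenetic
  correlation. On noisy desk-scale data the topology may keep drifting, in
  which case the scan honestly recommends the largest threshold.
- **Profiles** use unweighted means of per-site levels throughout (a
  feature's level is the average of its annotated cytosines, not a pooled
  count ratio). Metagene/island profiles use fixed-width flank bins
  (default 50 × 200 bp) and scaled body bins (default 40); minus-strand
  features are flipped so bins read 5′→3′; bodies shorter than the bin
  count are binned fractionally and flagged. Island shores are the 2-kb
  flanks (field convention; assignment precedence island > shore >
  non-island), while repeat and per-contig summaries are computed
  independently of that partition. Autocorrelation uses exact base-pair
  lags with a minimum pair count (default 50) per reported distance.
- **Differential methylation**: the two-sided Fisher exact test is
  implemented by direct hypergeometric enumeration in log-gamma space;
  tables with probability within 1e−12 (relative) of the observed table
  count as ties and are included, and a sum within 1e−9 of 1 is reported as
  exactly 1 (any genuinely excluded table contributes at least the modal
  probability, far above that). q-values are Benjamini–Hochberg within each
  sample-pair family — a deliberate, conservative replacement for
  methylKit's SLIM procedure, keeping the q < 0.01 cutoff semantics.
  Significance requires both q < 0.01 and |Δβ| ≥ 0.25. Islands need ≥5
  detected CG sites (strands counted separately); the island test pools
  counts while the difference cutoff uses the mean of site levels, the
  natural Fisher analogue of an island-level test. Tissue-specific features
  must be significant in all n−1 pairs involving one sample, with a
  consistent sign, and in no other pair (the strict reading of
  one-vs-all).
- **Integration**: promoter = 1500 bp upstream of the TSS, gene body = TSS
  to gene end; cytosines match by position, islands by ≥1 bp overlap;
  promoter takes precedence within a gene and a feature may be tested once
  per overlapping gene. Expression is log2(x + 1)-transformed before
  Pearson correlation (stabilises the FPKM-like scale; the choice is a
  package decision, as is the joint-BH family over all tested pairs).

## Determinism and problem sizes

All randomness flows from one integer seed through per-task
`numpy.random.Generator` streams (per-sample streams keyed by CRC32 of the
sample id, so sample sets can be extended without reshuffling existing
samples). Outputs are byte-stable: gzip members are written with a fixed
mtime and no embedded filename, no output embeds a timestamp, and the run
manifest records content hashes, so two runs with equal seed and
configuration are file-for-file identical.

The shipped demo uses a 2-Mb genome with 10 samples (≈1,200 retained
fragments, ≈73,000 reads per sample) and completes in about a minute on one
CPU; the test suite and the acceptance script use genomes of 10–1,000 kb
with depths 10–200, sized so that each check has adequate statistical
resolution (e.g. ≥50,000 spike-in observations for conversion-rate
recovery, 20,000 sites for error-control checks) while the whole suite
stays fast.

## What passing tests do and do not show

The simulator reproduces the *structure* of an RRBS tissue study — fragment
selection, bisulfite chemistry with realistic conversion rates, bimodal
CG / low non-CG landscapes, island hypomethylation, regional tissue
effects, promoter-repression coupling — so passing tests demonstrate that
the estimators recover known truth under that structure (estimator
calibration, FDR control, power on planted effects). They do not
demonstrate robustness to features the generator omits: sequencing error
and quality variation, indels, PCR duplication, mappability bias beyond
simple repeats, non-CG differential methylation, isoform complexity, or
real genome composition. Levels are reported uncorrected for incomplete
conversion, which inflates low methylation levels by roughly
`(1 − p)(1 − c)` (≈0.007 at the default conversion rate); truth-recovery
tests compare against this expected observable level. Bin means of
metagene profiles built from tens of genes are noisy; dip location is
therefore assessed over bins with a minimum number of site assignments.

## Known limitations

- Exact-match alignment cannot place reads containing any mismatch; it is
  suited only to simulated or error-free reads at toy scale.
- The Fisher/BH design has no replicate handling (one library per tissue);
  replicated designs would need a beta-binomial or logistic model, which is
  out of scope.
- The threshold-stability criterion formalises "stable clustering" as exact
  topology equality; near-ties in tree construction can keep desk-scale
  scans from converging below the maximum threshold.
- `window_correlation_cg_noncg` needs ≥3 windows with both contexts: on
  sub-Mb toy genomes the window size must be reduced below the 1-Mb
  default.
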