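# Methods

## Oligo masses

Masses are neutral average masses assembled from IUPAC standard atomic
weights (H 1.008, C 12.011, N 14.007, O 15.999, P 30.974, S 32.06). A
linear oligo with 5′-OH and 3′-OH is Σ nucleoside masses − (n−1)·M(H₂O) +
(n−1)·M(HPO₃); a 5′-phosphate adds one HPO₃. Reaction-state deltas:
deamination C→U +0.98 Da (nucleoside swap), bisulfite adduct +82.07 Da
(H₂SO₃), 5-methyl +14.03 Da, 4mC→U deamination −13.04 Da (the N4-methyl
leaves with the exocyclic amine). MALDI linear-negative-mode peak labels
track neutral average masses within 1 Da, so the [M−H]⁻ offset is ignored
and peak comparison uses round-half-up to the nearest Da. The published
4mC probe pair shows a −12 Da spacing where the 4mC→U swap predicts
−13.04 Da; since that probe's sequence is not available here, the 4mC pair
is not treated as a golden value and the −13.04 Da swap rule is kept.

## Synthetic libraries

The generator emulates directional bisulfite libraries at toy scale.
Ground truth is a per-C table (reference, position, strand, modification
type, stoichiometry x). Defaults, chosen to mirror the study conditions
at desk scale:

- **DNA mode** — CpG cytosines draw x from a bimodal Beta mixture with
  modes 0.05/0.95 (both strands of a CpG share x, as in symmetric CpG
  methylation); 1 % of non-CpG cytosines carry low-stoichiometry 5mC;
  an unmodified spike-in sequence (λ-DNA stand-in, name `spike`) is
  always available for background and false-positive estimation.
- **RNA mode** — plus-strand transcripts with a configurable number of
  m⁵C sites per transcript (default 10, stoichiometry uniform on
  [0.05, 0.95]); 30 % of sites have the CUCCA motif planted with the
  methylated C in register 1. Reads carry a 5-nt UMI on each side of the
  insert and the inline barcode ATCACG after the 3′ UMI, mirroring the
  small-RNA adapter design.
- **Conversion chemistry** — a molecule is methylated at a site with
  probability x, independently across sites and molecules (an option for
  block correlation is deliberately absent: co-methylation haplotype
  structure is out of scope). Methylated C never converts; unmodified C
  converts with probability 1 − `background_fail` (default 0.006, a
  realistic incomplete-conversion background for a fast protocol);
  4mC converts with probability `fourmC_convert` (1.0 for the ultrafast
  regime, 0.5 for the conventional regime, where 4mC reads ~1:1 C/T).
  Inside configured *structured regions*, all of a fragment's unmodified
  C fail together with probability `structured_fail`, reproducing the
  clustered conversion failures of structured sequence under conventional
  chemistry.
- **Degradation** — a fragment survives with probability
  s_c^(#converted C). The exponential-in-conversions form is this
  package's choice (the underlying chemistry is depyrimidination at
  converted sites, which acts per converted base); s_c defaults to 1
  (off) and the regime presets encode direction, not calibrated
  magnitudes, because the source gel assays are not quantitative.
  Under this model the observed fraction at a site is
  x / (x + (1−x)·S) with S = background-adjusted relative survival of
  unmethylated molecules (S = s_c when background failure is 0);
  simulation agrees with this closed form within Monte-Carlo error
  (verified at ≥10⁴ fragments per point).
- **Sequencing noise** — substitution errors at `error_rate` (default 0),
  applied last; constant Phred 37 qualities (qualities are unused
  downstream); optional simple PCR duplication (one extra copy per
  fragment at `duplication_rate`).
- **cfDNA cohorts** are generated at the site-count level: tiled 1 kb
  windows with ≥22 CpGs each (Poisson-distributed above that floor, so
  every window passes the >20-CpG analysis gate), a shared bimodal base
  methylome, per-sample beta-binomial counts (concentration 100 ≈ mild
  overdispersion, Poisson coverage mean 50). Planted DMR windows redraw
  their baseline with headroom for the requested shift — a region that
  gains 0.30 methylation must start low — and case samples shift by the
  signed effect.

What passing tests on these libraries do *not* show: robustness to indels,
quality-dependent errors, mappability artefacts, copy-number variation, or
co-methylation correlation in real genomes.

## Mapping and counting

Reads are aligned ungapped in collapsed three-base space: the read's C→T
collapse against the C→T-collapsed forward reference, and the reverse
complement's G→A collapse against the G→A-collapsed reference (directional
libraries search exactly these two spaces; reverse-directional swaps them).
Placement is seeded on exact 20-mers (offsets 0 and 20, tolerating one
error in the first seed) with full-length extension and ≤5 %-of-length
mismatches in collapsed space. Ties between distinct best loci are
discarded (strict multi-mapper policy — averaging methylation across
paralogs is worse than losing coverage). An ordered list of reference
groups (e.g. rRNA/tRNA before the genome) lets earlier groups claim reads
first. Deduplication keys are (ref, start, end, strand) for DNA and
(UMI pair, ref, start) for RNA. Pileup counts converted/unconverted reads
per reference C per strand; read bases other than C/T at a C site count as
mismatches and are excluded from both counts. Coordinates are 0-based
half-open internally, 1-based in emitted TSV, 0-based half-open in BED.
Known limitations for real data: no indels, no splicing, no base-quality
weighting.

## Site calling

The background p₀ pools counts over all C sites in one pass (modified
sites included — with sparse modification the contamination is small, and
an iterative mode that re-estimates after excluding called sites is
available but off by default). The binomial upper tail is computed in log
space from log-gamma terms with a stable reverse log-sum accumulation;
it is exact to better than 10 significant digits against arbitrary-
precision direct summation for n ≤ 1000, inclusive (Pr(X ≥ k)), and
monotone in k. Defaults: α = 10⁻⁶, minimum ratio 5 % (inclusive),
minimum coverage 20 for RNA and 10 for DNA (the RNA minimum is this
package's choice; coverage-/ratio-only DNA presets `dna-ed2a` (≥10×,
>10 %) and `dna-fig2c` (≥5×, >25 %) reproduce the figure-level threshold
modes with strict ratio inequalities as printed). The cluster filter's
default is the one-third-of-total rule; the variant bounding unconverted
by half of the converted count is behind `cluster_rule="half"` (the two
appear in different parts of the source description; the total-based rule
is taken as canonical). CUCCA classification uses register 1 (the
methylated C begins C-U-C-C-A), the NSUN6 target register, isolated in
`classify_motif`.

## Comparative statistics

- **Knockdown response**: decreased iff kd ≤ ctrl/3, increased iff
  kd ≥ 3·ctrl (ratio thresholds, hence scale-consistent), with a 1e-9
  relative tolerance so exact-boundary fractions classify stably; sites
  uncalled in the knockdown keep their observed ratio rather than being
  forced to zero.
- **DMRs**: non-overlapping 1 kb windows tiled from 0; per-sample window
  methylation is pooled counts over CpGs (not the mean of site ratios —
  pooling weights by coverage and is stabler at low depth); Welch t-test
  across samples (the unequal-variance form is the safer default when the
  variance homogeneity of the two groups is unknown); report
  |diff| > 0.20 and p < 0.001 on raw p-values (BH optional, off by
  default, matching the raw-threshold convention); windows need > 20 CpG.
- **Coverage evenness**: z-scores over per-window mean depths, IQR of z,
  outliers at |z| > 1.5, plus the raw-scale IQR with 1.5×IQR whiskers.
- **Spike-in FP rate**: fraction of eligible unmodified sites at or above
  a ratio cutoff, plus pooled rate and between-library fold change.
- **Distribution summaries**: counts at ratio thresholds 5/20/33 %,
  sites-per-gene histogram, 5′UTR/CDS/3′UTR assignment, and a
   gene-body metaprofile (100 bins per region, per-gene normalized before
  averaging so highly modified genes do not dominate).

## Problem sizes and determinism

The test suite runs the full chain on references of 0.3–3 kb with
10²–10⁴ fragments per library (10⁶ synthetic null sites for calibration
of the type-I error, ≥10⁴ surviving fragments per point for the
degradation closed form, 6-vs-6 cohorts of 40–100 windows for DMR
checks); these sizes give standard errors well inside the asserted
tolerances while keeping the whole suite under a minute. Every stochastic
component takes an explicit seed (numpy `default_rng`), there is no hidden
global randomness, and fixed seeds give byte-identical FASTQ and tables.
Degenerate inputs are defined, not special-cased: zero-coverage sites are
absent from tables, constant depth yields zero IQR and no outliers,
empty called-site tables give all-zero summaries, and sd = 0 rows in the
DMR z-matrix are left at z = 0.
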