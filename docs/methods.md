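# Methods

## Problem and model

`mirnaeditome` detects mutation/editing (M/E) sites in microRNAs from bulk
small-RNA sequencing and runs the cohort-level analyses that such a study
needs: per-site significance against a sequencing-error null, recurrence
filtering across samples, classification into nine site types, age
correlation, case-versus-control differential editing, divergence of type
compositions, clustering/PCA of editing profiles, and detection of control
samples whose editing profiles resemble cases.

An M/E site is a (hairpin position, alternative base) pair. For one sample,
reads placed on a pre-miRNA hairpin give each position a weighted base
pileup; at a position with total weighted coverage `N` and weighted
alternative count `k`, the editing level is `k/N` and the null hypothesis is
that the alternative reads are sequencing errors:

    p = P(X >= ceil(k)),   X ~ Binomial(round(N), e),   e = 10^(-Q/10)

with `Q` the quality threshold used to gate reads (Q30 gives `e = 0.001`):
a caller that only admits bases claiming quality at least Q should not see
error rates above `10^(-Q/10)` under the instrument's own model. p-values
are Benjamini–Hochberg corrected across all candidate pairs of the sample.
A site is *significant* in a sample when

1. level `k/N >= 5%`,
2. weighted support `k >= 10`,
3. corrected `p < 0.05`,

and a site is *retained* for the cohort when it is significant in at least
`floor(0.10 * n_samples)` samples (minimum 1; 131 samples gives 13). The
weighted counts are rounded to the nearest integer only inside the binomial
test; levels use the unrounded weights. Support uses the cross-mapping
weighted count (whether raw or weighted counts should gate support is
genuinely ambiguous; weighted is the conservative choice and the threshold
is configurable).

## Read processing

*Quality gate.* A read qualifies when each of its first 25 bases has
Phred quality ≥ 30 (shorter reads must qualify over their whole length).
Qualified reads are collapsed to unique sequences with counts; unique reads
shorter than 19 nt are dropped.

*Alignment.* Unique reads are placed on hairpins by bounded ungapped
alignment: at every start, the read splits into a templated body (at most 2
substitutions, no indels) and an untemplated 3′ tail of at most 3 nt.
Candidates are ranked by (mismatch count, then tail length) and only the
global minimizers are kept. Ranking mismatches first means trailing bases
that disagree with the template are attributed to non-templated tailing
rather than to substitutions — which is what 3′ adenylation/uridylation
looks like on a sequencer. A terminal substitution and a 1-nt tail place the
alternative base at the same hairpin position, so site coordinates and
levels do not depend on this tie-break; only the tail/templated bookkeeping
does. Reads are assumed sense-strand relative to the annotated hairpin.

*Genomic loci and cross-mapping correction.* Each aligned read is also
located on the genome: all loci on both strands whose substitution distance
equals the minimum achieved distance (at most 1) are kept — the "best
stratum" contract of a `-a --best -v 1` style aligner. Multi-mapped weight
is then re-allocated iteratively: starting uniform, each read's weight at a
locus is set proportional to that locus's mapped expression
`E(l) = Σ_r count(r)·w(r,l)`, until the largest weight change is below 1e-6
or 100 iterations. Weights per read always sum to 1; symmetric ties are left
symmetric. Genomic loci serve *only* to weight reads: pre-miRNA placement is
authoritative. A read with no genomic locus (typically a tailed read, which
cannot satisfy the 1-mismatch full-read contract) keeps weight 1 at its
hairpin placement; a read whose best stratum excludes this hairpin's locus
contributes weight 0 there. The deficit between raw and weighted support is
the evidence for the Pseudo class below.

## Nine-type classification

Retained sites are labelled in precedence order:

1. **SNP** — a known-SNP table entry matches the site's genomic position and
   both alleles (strand-aware), and the level reaches 100% in at least one
   sample (a homozygous carrier).
2. **Pseudo** — strictly less than half of the site's supporting read weight
   survives cross-mapping correction: the apparent site is explained by
   reads that genuinely originate elsewhere. The 0.5 threshold is exposed in
   the configuration; the strict inequality keeps the symmetric fixed point
   of two identical genomic copies (exactly 0.5) out of the class.
3. **3′-A / 3′-U / 3′-Other** — the site lies past the 3′ end of a mature
   arm (including positions beyond the hairpin), where non-templated tailing
   accrues; the alternative base decides the subclass. The positional
   definition is deliberate: a 1-nt tail may be absorbed as a templated
   mismatch at `arm_end + 1` when the hairpin continues, and both readings
   must land in the same class.
4. **5′-editing** — the site sits exactly at the first templated position of
   a mature arm (the method's 5′ window; such events are rare and no wider
   window is defined).
5. **A-to-I** — internal A→G (inosine reads as G).
6. **C-to-U** — internal C→T/U.
7. **Other** — any other internal substitution.

Sites are named `{premirna}_{position}_{REF}_{alt}` with the reference base
in upper-case RNA and the edited base in lower case (`hsa-mir-497_25_A_g`);
the edited miRNA short form is `{premirna}_{position}{alt}`
(`hsa-mir-497_25g`). The seed region is mature positions 2–8.

## Cohort statistics

*Age correlation.* Within a group, each site's level is correlated with age
at death. The default is rank-based (Spearman ρ) with the two-sided
t-approximation `t = ρ·sqrt((n-2)/(1-ρ²))`; Pearson is available via
`method="pearson"`. Constant sites report an undefined ρ with p = 1. BH
correction is applied within the group; corrected p < 0.05 is age-related.

*Differential editing.* Two-sided Mann–Whitney U per site. When both groups
have at most 8 samples the p-value is exact by full enumeration of
`C(n1+n2, n1)` group assignments (midranks handle ties, so the all-tied case
yields p = 1); otherwise the normal approximation with tie and continuity
corrections. Direction is the sign of the difference of group means.

*Type-composition divergence.* `D(P‖Q) = Σ P_i log2(P_i/Q_i)` in bits over
the nine type labels, after adding a pseudocount of 0.5 per type and
normalizing. Direction, base and pseudocount are configurable; the default
compares the differential-site composition against the full retained set in
the analysis scripts.

*Clustering and PCA.* Levels are transformed as `log2(100·level + 1)` — a
variance-stabilizing map that keeps 0 at 0. Sample distance is 1 − Pearson
correlation between transformed profiles; agglomeration uses Ward's
minimum-variance criterion in its squared-distance (D2) variant. Samples are
canonically ordered by id before linkage, so flat clusterings are invariant
to input order. PCA centers site columns (no unit-variance scaling) and uses
the SVD; each component's sign is fixed so its largest-magnitude loading is
positive. Note that correlation distance is invariant to a *uniform* level
shift across all sites: groups separate only when the effect changes profile
shape, which is why the simulated group effects vary in sign across sites.

*Case-like controls.* With the k = 2 cut of the dendrogram, the cluster
holding the majority of case samples is identified (a tie is an error, by
design — it demands a different k or manual resolution) and the control
samples inside it are reported. This makes algorithmic what a study would
read off a clustering figure.

*Direction-consistent targets.* For an edited miRNA that is up in cases,
targets that are down in cases are kept, and vice versa; target direction
tables are consumed as plain inputs.

## Synthetic data generator

The generator emulates the input side of a brain-cohort editing study:

* a single-chromosome genome carrying each simulated hairpin once, plus
  optional extra identical loci for designated hairpins (multi-mapping),
  with 60-nt random spacers;
* a miRBase-dialect GFF3 (hairpin + mature features, 1-based inclusive,
  strand-aware) and a hairpin FASTA;
* a known-SNP table holding every programmed SNP site;
* per-sample FASTQ files: reads start at the mature 5′ end with probability
  0.9 (else offset ±1 nt), span the mature length (20–23 nt), carry each
  programmed site's alternative base with probability equal to the realized
  level, suffer independent per-base errors at `10^(-Q/10)` for the
  configured quality (Q30 → 0.001, matching the caller's null), and receive
  a 1–3 nt untemplated A/U/other tail with configurable probabilities
  (defaults 0.08/0.08/0.01, making 3′ tailing the most common event class,
  as in real small-RNA data); qualities are constant at the configured Q;
* a ground-truth ledger of every programmed site and each sample's realized
  level.

Realized levels are `base + age_slope·(age − age midpoint) + group_effect`
(the group shift applies to one named group), clipped to [0, 1]; SNP sites
realize 1.0 with probability `base_level`, else 0 (homozygous carriers).
Ages are uniform on the configured range (empirical cohort age distributions
are not modelled). Per-mirna read depth is Poisson around the configured
mean and the realized count is recorded. Everything derives from one integer
seed through spawned generator streams, so identical configurations
reproduce byte-identical outputs.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: realistic expression dispersion across
miRNAs, adapter contamination, 5′ isomiR heterogeneity beyond ±1 nt, quality
heterogeneity along the read, indels, gapped or antisense placements, and
secondary-structure effects on Dicer processing. Results on synthetic
cohorts demonstrate the pipeline's arithmetic and decision rules, not
instrument realism.

## Numerical and design choices

* U/T are normalized to a single DNA alphabet internally; RNA appears only
  in display and site names. Coordinates are hairpin-relative, 1-based,
  5′→3′ everywhere; genomic coordinates appear only at the SNP boundary.
* Candidate sites beyond the hairpin 3′ end carry reference base `-`.
* Zero-coverage positions are skipped, not errors; an empty FASTQ warns.
* The recurrence threshold uses `floor` with a 1e-9 guard against float
  noise and a minimum of 1.
* BH adjustment delegates to `statsmodels` (`fdr_bh`); tests verify it
  against a from-scratch step-up implementation to 1e-12.
* Cross-mapping convergence constants (1e-6, 100 iterations, uniform
  initialization) are fixed points of the method, not tuned values; tests
  compare against a 1e-12/100k-iteration run.
* Problem sizes in the test-bench analyses (12 hairpins, 40 samples, depth
  500; null control at 10 hairpins × 20 samples × depth 1000; 100-replicate
  power runs at the matrix level) were chosen as the smallest designs at
  which the binomial arithmetic, recurrence boundary, and both power
  properties are exercised away from their thresholds.

## Known limitations

* The ungapped aligner cannot place reads over indels; sites are
  substitutions and tail additions only.
* The genome-locus contract allows at most one substitution in the full
  read, so heavily tailed multi-mapped reads are weighted 1 at their hairpin
  placement rather than split; a Pseudo source that is only reachable
  through a tailed read would be missed.
* 5′-editing is restricted to the arm's first templated position; an edit at
  offset −1 (reachable only through the 5% of reads starting 1 nt early)
  would be classed by its substitution instead.
* `find_pd_like` assumes the case group dominates exactly one of the two
  flat clusters; heavily mixed cohorts raise rather than guess.
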