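# mirnaeditome

Detection and cohort analysis of microRNA mutation/editing (M/E) sites from
small-RNA sequencing — with a fully synthetic, ground-truthed test bench.

MicroRNAs are edited during their biogenesis: ADAR enzymes deaminate
adenosine to inosine (read as A→G by sequencers) and APOBEC enzymes
deaminate cytidine (C→U); reads also acquire non-templated 3′ A/U tails.
Calling such sites from bulk small-RNA data means separating low-level
editing (often 5–30%) from sequencing error, from SNPs, and from reads that
merely *look* edited because they originate at another genomic locus. This
package implements that pipeline and the downstream cohort statistics used
to ask whether editing is disrupted in disease — e.g. in prefrontal-cortex
cohorts of Parkinson's disease patients versus controls.

## What it computes

For each sample, each hairpin position × alternative base with weighted
coverage `N` and alternative count `k` is tested against the sequencing-error
null

&nbsp;&nbsp;&nbsp;&nbsp;`p = P(X ≥ ⌈k⌉)`, `X ~ Binomial(⌊N⌉, 10^(−Q/10))`,

with BH correction across the sample's candidates. A site is significant
when its level `k/N ≥ 5%`, its weighted support `k ≥ 10` and corrected
`p < 0.05`; the cohort retains sites significant in ≥ 10% of samples
(131 samples → 13). Retained sites are classified into nine types —
**A-to-I, C-to-U, 3′-A, 3′-U, 3′-Other, 5′-editing, Other, SNP, Pseudo** —
where SNP requires a database match plus a 100%-level sample and Pseudo
marks sites whose read support is reassigned away by cross-mapping
correction of multi-mapped reads. Sites are named
`{premirna}_{position}_{REF}_{alt}` (e.g. `hsa-mir-497_25_A_g`).

Cohort statistics: Spearman/Pearson age correlation with BH correction,
two-sided Mann–Whitney differential editing (exact for small groups),
Kullback–Leibler divergence of type compositions, `log2(100·level+1)`
transformation, Ward-D2 clustering on correlation distance, centered PCA,
and detection of control samples that cluster with cases.

The `simulate` module generates the complete input side — genome, miRBase-
dialect GFF3, SNP table, per-sample FASTQs with programmed editing levels
(optionally age- and group-dependent), base errors, 3′ tails and
multi-mapping loci — together with a ground-truth ledger, so every stage is
testable without downloads.

## Worked example

```bash
python analysis/01_simulate_cohort.py   # 40 samples, 12 pre-miRNAs
python analysis/02_detect_sites.py
python analysis/03_cohort_statistics.py
```

which prints (seed 77):

```
62 sites retained (recurrence threshold 4)
3'-U          27
3'-A          27
A-to-I         3
C-to-U         2
Other          1
5'-editing     1
SNP            1
ground-truth recovery: 8/8
age-related sites in ctl: 1/62
age-related sites in PD: 1/62
differential sites (PD vs ctl): 3 (2 increased, 1 decreased)
KL(differential-site types || all-site types) = 1.751 bits
clustering on 3 differential sites
PC1/PC2 explained variance: 0.95/0.03
case-like control samples: none
```

All eight programmed sites (three A-to-I — one hyper-edited in the case
group, one drifting with age — two C-to-U, one Other, one 5′-editing, one
SNP) are recovered with their correct types; tailing produces the expected
excess of 3′-A/3′-U sites; the three sites programmed with a group effect
are exactly the ones found differential, with the programmed directions; and
clustering on those differential sites cleanly separates the groups, so no
control sample is flagged as case-like (none was planted).

The same steps are available as a CLI
(`mirnaeditome simulate|detect|stats`); the library surface is in
`mirnaeditome` (see `docs/methods.md` for the model and all thresholds).

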