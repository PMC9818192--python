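"""End-to-end orchestration: FASTQ cohort -> retained, classified M/E sites.

Per sample: quality filter and collapse, align unique reads to hairpins,
enumerate genomic loci for the aligned reads, run cross-mapping correction,
assign each hairpin placement the weight of its genomic locus, pile up, and
call candidate sites. Across samples: recurrence filtering, classification
and naming, and the editing matrix for the cohort statistics.

Genomic loci serve only to weight reads: a read with no genomic hit keeps
weight 1 at its hairpin placement, while a read whose best genomic stratum
excludes this hairpin's locus contributes weight 0 there (that deficit is
exactly the Pseudo evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .calling import (
    Pileup,
    call_sample_sites,
    classify_site,
    combine_cohort,
    pileup,
)
from .core import EditingMatrix, GenomeLocus, MESite, PreMiRNA, SampleMetadata
from .reads import (
    align_to_premirna,
    cross_mapping_weights,
    enumerate_genome_loci,
    filter_reads,
)
from .simulate import ReferenceBundle


@dataclass
class DetectionParams:
    """Thresholds of the detection pipeline (defaults follow the method:
    quality gate Q30 over the first 25 nt, reads > 18 nt, binomial null at
    10**(-Q/10), level >= 5%, weighted support >= 10, BH alpha 0.05,
    recurrence in >= 10% of samples)."""

    min_quality: int = 30
    prefix_len: int = 25
    min_len: int = 19
    max_mismatch: int = 2
    max_tail: int = 3
    genome_max_mismatch: int = 1
    error_rate: float | None = None  # None -> 10**(-min_quality/10)
    min_level: float = 0.05
    min_support: float = 10.0
    alpha: float = 0.05
    recurrence: float = 0.10
    pseudo_retained_threshold: float = 0.5

    @property
    def effective_error_rate(self) -> float:
        if self.error_rate is not None:
            return self.error_rate
        return 10.0 ** (-self.min_quality / 10.0)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["error_rate"] = self.effective_error_rate
        return d


def _placement_locus(h: PreMiRNA, start: int, body_length: int) -> GenomeLocus:
    """Genomic locus corresponding to a hairpin placement (full-read window)."""
    if h.strand == "+":
        return GenomeLocus(h.chrom, h.start + start - 1, "+")
    gend = h.end - (start - 1)
    return GenomeLocus(h.chrom, gend - body_length + 1, "-")


def detect_sample(
    fastq_path,
    reference: ReferenceBundle,
    params: DetectionParams | None = None,
) -> pd.DataFrame:
    """Run the per-sample detection stage; returns the candidate-site table."""
    params = params or DetectionParams()
    unique_reads = filter_reads(
        io.read_fastq(fastq_path),
        min_quality=params.min_quality,
        prefix_len=params.prefix_len,
        min_len=params.min_len,
    )
    premirnas = reference.premirnas

    alignments: dict[str, list] = {}
    for read in unique_reads:
        alns = align_to_premirna(
            read, premirnas, max_mismatch=params.max_mismatch, max_tail=params.max_tail
        )
        if alns:
            alignments[read.sequence] = alns

    placements: dict[str, list[GenomeLocus]] = {}
    counts: dict[str, int] = {}
    for seq, alns in alignments.items():
        loci = enumerate_genome_loci(
            alns[0].read, reference.genome, max_mismatch=params.genome_max_mismatch
        )
        counts[seq] = alns[0].read.count
        if loci:
            placements[seq] = loci
    weights = cross_mapping_weights(placements, counts) if placements else {}

    per_hairpin: dict[str, list] = {hid: [] for hid in premirnas}
    for seq, alns in alignments.items():
        has_loci = seq in placements
        for aln in alns:
            h = premirnas[aln.premirna_id]
            if has_loci:
                locus = _placement_locus(h, aln.start, len(seq))
                aln.weight = weights.get((seq, locus), 0.0)
            else:
                aln.weight = 1.0 / len(alns)
            per_hairpin[aln.premirna_id].append(aln)

    pileups: list[Pileup] = [
        pileup(alns, premirnas[hid]) for hid, alns in per_hairpin.items() if alns
    ]
    return call_sample_sites(
        pileups,
        error_rate=params.effective_error_rate,
        min_level=params.min_level,
        min_support=params.min_support,
        alpha=params.alpha,
    )


@dataclass
class CohortResult:
    sites: list[MESite]
    matrix: EditingMatrix
    per_sample_calls: dict[str, pd.DataFrame]
    params: DetectionParams
    threshold: int = 0

    def site_by_name(self, name: str) -> MESite | None:
        for s in self.sites:
            if s.name == name:
                return s
        return None


def detect_cohort(
    cohort_dir,
    params: DetectionParams | None = None,
    reference: ReferenceBundle | None = None,
    metadata: list[SampleMetadata] | None = None,
) -> CohortResult:
    """Run detection over a cohort directory (as laid out by simulate_cohort),
    combine samples, classify and name every retained site."""
    from .calling import recurrence_threshold

    params = params or DetectionParams()
    cohort_dir = Path(cohort_dir)
    if reference is None:
        reference = ReferenceBundle.load(cohort_dir / "reference")
    if metadata is None:
        metadata = io.read_metadata(cohort_dir / "metadata.tsv")

    per_sample: dict[str, pd.DataFrame] = {}
    for meta in metadata:
        per_sample[meta.sample_id] = detect_sample(
            cohort_dir / "reads" / f"{meta.sample_id}.fastq", reference, params
        )

    sites, levels = combine_cohort(per_sample, recurrence=params.recurrence)
    for site in sites:
        classify_site(
            site,
            reference.premirnas[site.premirna_id],
            snp_table=reference.snps,
            pseudo_retained_threshold=params.pseudo_retained_threshold,
        )
    meta_df = pd.DataFrame(
        {"group": [m.group for m in metadata], "age": [m.age for m in metadata]},
        index=[m.sample_id for m in metadata],
    )
    matrix = EditingMatrix(levels, meta_df)
    return CohortResult(
        sites=sites,
        matrix=matrix,
        per_sample_calls=per_sample,
        params=params,
        threshold=recurrence_threshold(len(metadata), params.recurrence),
    )
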