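"""From raw FASTQ to weighted read placements on pre-miRNAs.

Stages: quality gating on the 5' prefix, collapsing to unique reads,
bounded ungapped alignment to hairpins with untemplated 3'-tail splitting,
best-stratum enumeration of genomic loci (both strands, substitutions only),
and iterative cross-mapping correction that re-distributes multi-mapped read
weight in proportion to the locally mapped expression.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomeLocus, PreMiRNA, ReadAlignment, UniqueRead, encode, revcomp
from .io import PHRED_OFFSET


def filter_reads(
    fastq: Iterable[tuple[str, str, str]],
    min_quality: int = 30,
    prefix_len: int = 25,
    min_len: int = 19,
) -> list[UniqueRead]:
    """Quality-gate and collapse a FASTQ stream to unique reads.

    A read is qualified iff every one of its first ``prefix_len`` bases has
    quality >= ``min_quality`` (reads shorter than the prefix must qualify
    over their whole length). Qualified reads are collapsed to unique
    sequences with counts; unique reads shorter than ``min_len`` are dropped.
    """
    min_char = chr(min_quality + PHRED_OFFSET)
    counts: dict[str, int] = {}
    for _name, seq, qual in fastq:
        prefix = qual[:prefix_len]
        if any(c < min_char for c in prefix):
            continue
        counts[seq] = counts.get(seq, 0) + 1
    return [
        UniqueRead(seq, n)
        for seq, n in sorted(counts.items())
        if len(seq) >= min_len
    ]


def _window_mismatches(template: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``template``."""
    m = len(query)
    if len(template) < m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(template, m)
    return (windows != query).sum(axis=1)


def align_to_premirna(
    read: UniqueRead,
    premirnas: Mapping[str, PreMiRNA] | Sequence[PreMiRNA],
    max_mismatch: int = 2,
    max_tail: int = 3,
) -> list[ReadAlignment]:
    """Bounded ungapped placement of a read on a set of hairpins.

    For each hairpin and start, the read is split into a templated body
    (<= ``max_mismatch`` substitutions, no indels) and an untemplated 3' tail
    of length <= ``max_tail``. Trailing bases that do not match the template
    are attributed to non-templated tailing rather than to substitutions:
    candidates are ranked by (mismatch count, then tail length) and only the
    global minimizers are returned. An empty list means no feasible placement.
    """
    if isinstance(premirnas, Mapping):
        premirnas = list(premirnas.values())
    seq = read.sequence
    q = encode(seq)
    n = len(seq)
    best_key: tuple[int, int] | None = None
    best: list[tuple[PreMiRNA, int, int]] = []  # (hairpin, start0, tail_len)
    for h in premirnas:
        t = encode(h.sequence)
        for tail_len in range(0, min(max_tail, n - 1) + 1):
            body = q[: n - tail_len]
            mm = _window_mismatches(t, body)
            feasible = np.nonzero(mm <= max_mismatch)[0]
            for start0 in feasible:
                key = (int(mm[start0]), tail_len)
                if best_key is None or key < best_key:
                    best_key = key
                    best = [(h, int(start0), tail_len)]
                elif key == best_key:
                    best.append((h, int(start0), tail_len))
    alignments = []
    seen = set()
    for h, start0, tail_len in best:
        # a (hairpin, start) pair keeps only its shortest feasible tail
        if (h.id, start0) in seen:
            continue
        seen.add((h.id, start0))
        body = seq[: n - tail_len] if tail_len else seq
        mismatches = [
            (start0 + i + 1, h.sequence[start0 + i], body[i])
            for i in range(len(body))
            if h.sequence[start0 + i] != body[i]
        ]
        alignments.append(
            ReadAlignment(
                read=read,
                premirna_id=h.id,
                start=start0 + 1,
                mismatches=mismatches,
                tail=seq[n - tail_len :] if tail_len else "",
            )
        )
    return alignments


def enumerate_genome_loci(
    read: UniqueRead,
    genome: Mapping[str, str],
    max_mismatch: int = 1,
) -> list[GenomeLocus]:
    """All genomic loci (both strands) in the best substitution-distance
    stratum, provided that minimum distance is <= ``max_mismatch``."""
    q_fwd = encode(read.sequence)
    q_rev = encode(revcomp(read.sequence))
    hits: list[tuple[int, GenomeLocus]] = []
    best = max_mismatch + 1
    for chrom, seq in genome.items():
        t = encode(seq)
        for strand, q in (("+", q_fwd), ("-", q_rev)):
            mm = _window_mismatches(t, q)
            if mm.size == 0:
                continue
            good = np.nonzero(mm <= max_mismatch)[0]
            for start0 in good:
                d = int(mm[start0])
                best = min(best, d)
                hits.append((d, GenomeLocus(chrom, int(start0) + 1, strand)))
    if best > max_mismatch:
        return []
    return [loc for d, loc in hits if d == best]


def cross_mapping_weights(
    placements: Mapping[str, Sequence[GenomeLocus]],
    counts: Mapping[str, int],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> dict[tuple[str, GenomeLocus], float]:
    """Iterative proportional re-allocation of multi-mapped read weight.

    Weights start uniform over each read's loci and are repeatedly set
    proportional to the locus expression E(l) = sum_r count(r) * w(r, l),
    until the largest absolute weight change is below ``tol`` or ``max_iter``
    iterations. Per read, weights always sum to 1.
    """
    for r, loci in placements.items():
        if len(loci) == 0:
            raise ValueError(f"read {r} has an empty locus list")
    weights: dict[tuple[str, GenomeLocus], float] = {}
    for r, loci in placements.items():
        w0 = 1.0 / len(loci)
        for loc in loci:
            weights[(r, loc)] = w0
    multi = [r for r, loci in placements.items() if len(loci) > 1]
    if not multi:
        return weights
    for _ in range(max_iter):
        expression: dict[GenomeLocus, float] = {}
        for (r, loc), w in weights.items():
            expression[loc] = expression.get(loc, 0.0) + counts[r] * w
        max_delta = 0.0
        for r in multi:
            loci = placements[r]
            e = np.array([expression[loc] for loc in loci])
            total = e.sum()
            new = e / total if total > 0 else np.full(len(loci), 1.0 / len(loci))
            for loc, w in zip(loci, new):
                max_delta = max(max_delta, abs(weights[(r, loc)] - w))
                weights[(r, loc)] = float(w)
        if max_delta < tol:
            break
    return weights
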