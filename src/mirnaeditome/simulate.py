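"""Synthetic small-RNA-seq cohorts with known editing ground truth.

The generator emulates the data a brain-cohort miRNA-editing study consumes:
a genome carrying pre-miRNA hairpins (some at multiple identical loci), a
miRBase-dialect annotation, a SNP table, and per-sample FASTQ read sets in
which programmed editing sites are expressed at per-sample levels that may
drift with age or shift with disease group. Every stochastic choice flows
from one integer seed, so a config reproduces byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .core import BASES, PreMiRNA, MatureArm, SampleMetadata, SnpRecord, to_dna
from .calling import name_site


@dataclass
class TruthSite:
    """A programmed mutation/editing site on one hairpin.

    The realized per-sample level is
    ``base_level + age_slope * (age - age midpoint) + group_effect`` (the
    group shift applies only to samples of ``effect_group``), clipped to
    [0, 1]. SNP sites instead realize level 1.0 with probability
    ``base_level`` and 0.0 otherwise (a homozygous carrier draw).
    """

    premirna_id: str
    position: int  # 1-based on the hairpin
    ref_nt: str
    alt_nt: str
    base_level: float
    age_slope: float = 0.0
    group_effect: float = 0.0
    effect_group: str | None = None
    is_snp: bool = False

    def __post_init__(self) -> None:
        self.ref_nt = to_dna(self.ref_nt)
        self.alt_nt = to_dna(self.alt_nt)
        if self.ref_nt == self.alt_nt:
            raise ValueError("ref and alt must differ")
        if not 0.0 <= self.base_level <= 1.0:
            raise ValueError("base_level must be in [0, 1]")

    @property
    def name(self) -> str:
        return name_site(self.premirna_id, self.position, self.ref_nt, self.alt_nt)

    def realized_level(self, age: float, group: str, age_mid: float) -> float:
        level = self.base_level + self.age_slope * (age - age_mid)
        if self.effect_group is not None and group == self.effect_group:
            level += self.group_effect
        return float(np.clip(level, 0.0, 1.0))


@dataclass
class SimConfig:
    """Study-design knobs for a synthetic cohort.

    ``base_error_rate`` defaults to ``10**(-phred_quality/10)`` so the
    generator's noise matches the null model a caller gating reads at that
    quality would assume (Q30 -> 0.001).
    """

    n_premirnas: int = 8
    premirna_length: tuple[int, int] = (80, 110)
    mature_length: tuple[int, int] = (20, 23)
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"case": 5, "control": 5}
    )
    age_range: tuple[float, float] = (55.0, 90.0)
    depth_per_mirna: int = 500
    phred_quality: int = 30
    base_error_rate: float | None = None
    site_specs: list[TruthSite] = field(default_factory=list)
    tail_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.08, "T": 0.08, "other": 0.01}
    )
    multimap_copies: dict[str, int] = field(default_factory=dict)
    rng_seed: int = 0
    spacer_length: int = 60
    start_offset_probs: tuple[float, float, float] = (0.9, 0.05, 0.05)  # 0, -1, +1

    @property
    def error_rate(self) -> float:
        if self.base_error_rate is not None:
            return self.base_error_rate
        return 10.0 ** (-self.phred_quality / 10.0)

    @property
    def age_midpoint(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def validate(self) -> None:
        if self.n_premirnas < 1:
            raise ValueError("need at least one pre-miRNA")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("base error rate must be a probability")
        tp = [self.tail_probs.get(k, 0.0) for k in ("A", "T", "other")]
        if any(p < 0 for p in tp) or sum(tp) > 1.0 + 1e-12:
            raise ValueError("tail probabilities must be >= 0 and sum to <= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("invalid age range")
        for s in self.site_specs:
            if s.position < 1:
                raise ValueError(f"site position must be >= 1 ({s})")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "site_specs" in d:
            d["site_specs"] = [
                s if isinstance(s, TruthSite) else TruthSite(**s) for s in d["site_specs"]
            ]
        for key in ("premirna_length", "mature_length", "age_range", "start_offset_probs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ReferenceBundle:
    """A genome, its annotated hairpins, and the known-SNP table."""

    genome: dict[str, str]
    premirnas: dict[str, PreMiRNA]
    snps: list[SnpRecord]

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.genome, outdir / "genome.fa")
        io.write_fasta(
            {h.id: h.sequence for h in self.premirnas.values()}, outdir / "hairpins.fa"
        )
        io.write_mirbase_gff3(self.premirnas.values(), outdir / "annotation.gff3")
        io.write_snp_table(self.snps, outdir / "snps.tsv")

    @classmethod
    def load(cls, refdir: Path) -> "ReferenceBundle":
        refdir = Path(refdir)
        genome = io.read_fasta(refdir / "genome.fa")
        hairpins = io.read_fasta(refdir / "hairpins.fa")
        premirnas = io.read_mirbase_gff3(
            refdir / "annotation.gff3", hairpin_seqs=hairpins, genome=genome
        )
        snps = io.read_snp_table(refdir / "snps.tsv")
        return cls(genome, premirnas, snps)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def build_reference(config: SimConfig) -> ReferenceBundle:
    """Construct the genome + annotation + SNP table for a config.

    Each hairpin occurs once on the simulated chromosome, with
    ``multimap_copies[id]`` extra identical loci appended after the primary
    block. Truth-site reference bases are written into the hairpin so the
    ledger invariant (ref_nt equals the reference base) holds by construction.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    chrom = "chrS"

    sites_by_hairpin: dict[str, list[TruthSite]] = {}
    for s in config.site_specs:
        sites_by_hairpin.setdefault(s.premirna_id, []).append(s)

    hairpin_seqs: dict[str, str] = {}
    arms: dict[str, MatureArm] = {}
    for i in range(config.n_premirnas):
        hid = f"sim-mir-{i + 1}"
        length = int(rng.integers(config.premirna_length[0], config.premirna_length[1] + 1))
        seq = list(_random_seq(rng, length))
        mlen = int(rng.integers(config.mature_length[0], config.mature_length[1] + 1))
        astart = int(rng.integers(5, max(6, length - mlen - 5)))
        arm = MatureArm(f"{hid}-5p", astart, astart + mlen - 1)
        for s in sites_by_hairpin.get(hid, []):
            if s.position > length:
                raise ValueError(f"site {s.name} beyond hairpin {hid} (length {length})")
            seq[s.position - 1] = s.ref_nt
        hairpin_seqs[hid] = "".join(seq)
        arms[hid] = arm

    # lay hairpins on the chromosome with random spacers
    pieces: list[str] = []
    cursor = 1
    premirnas: dict[str, PreMiRNA] = {}
    extra_loci: list[str] = []
    for hid, seq in hairpin_seqs.items():
        spacer = _random_seq(rng, config.spacer_length)
        pieces.append(spacer)
        cursor += len(spacer)
        premirnas[hid] = PreMiRNA(
            id=hid,
            sequence=seq,
            chrom=chrom,
            start=cursor,
            end=cursor + len(seq) - 1,
            strand="+",
            mature_arms=[arms[hid]],
        )
        pieces.append(seq)
        cursor += len(seq)
        extra_loci.extend([seq] * config.multimap_copies.get(hid, 0))
    for seq in extra_loci:
        spacer = _random_seq(rng, config.spacer_length)
        pieces.append(spacer)
        pieces.append(seq)
    pieces.append(_random_seq(rng, config.spacer_length))
    genome = {chrom: "".join(pieces)}

    snps = []
    for i, s in enumerate(config.site_specs):
        if not s.is_snp:
            continue
        h = premirnas[s.premirna_id]
        snps.append(
            SnpRecord(h.chrom, h.genomic_position(s.position), s.ref_nt, s.alt_nt, f"simrs{i + 1}")
        )
    return ReferenceBundle(genome, premirnas, snps)


def preview_arms(config: SimConfig) -> dict[str, MatureArm]:
    """Mature-arm coordinates the reference will have for this config.

    Hairpin lengths and arm placements depend only on the seed and the size
    parameters, not on ``site_specs`` (sites overwrite single bases after the
    sequence is drawn), so callers can place truth sites inside arms by
    previewing first and then rebuilding with the same seed.
    """
    from dataclasses import replace

    skeleton = build_reference(replace(config, site_specs=[], multimap_copies={}))
    return {hid: h.mature_arms[0] for hid, h in skeleton.premirnas.items()}


def simulate_sample(
    config: SimConfig,
    sample: SampleMetadata,
    reference: ReferenceBundle,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, str]], dict[str, float]]:
    """Draw one sample's FASTQ records and its realized truth levels.

    Reads start at the mature 5' end with probability 0.9 (else offset +-1),
    span the mature length, carry each truth site's alt base with probability
    equal to the realized level, are corrupted per base at the configured
    error rate, and may receive a 1-3 nt untemplated 3' tail.
    """
    records: list[tuple[str, str, str]] = []
    realized: dict[str, float] = {}
    for s in config.site_specs:
        if s.is_snp:
            realized[s.name] = 1.0 if rng.random() < s.base_level else 0.0
        else:
            realized[s.name] = s.realized_level(sample.age, sample.group, config.age_midpoint)

    if config.depth_per_mirna == 0:
        warnings.warn(f"depth 0 for sample {sample.sample_id}: writing empty FASTQ")

    p0, pm, pp = config.start_offset_probs
    pa = config.tail_probs.get("A", 0.0)
    pt = config.tail_probs.get("T", 0.0)
    po = config.tail_probs.get("other", 0.0)
    err = config.error_rate
    read_no = 0
    for hid, h in reference.premirnas.items():
        sites_here = [s for s in config.site_specs if s.premirna_id == hid]
        for arm in h.mature_arms:
            n_reads = int(rng.poisson(config.depth_per_mirna))
            for _ in range(n_reads):
                read_no += 1
                u = rng.random()
                offset = 0 if u < p0 else (-1 if u < p0 + pm else 1)
                start = max(1, arm.start + offset)
                end = min(h.length, start + arm.length - 1)
                seq = list(h.sequence[start - 1 : end])
                for s in sites_here:
                    if start <= s.position <= end and rng.random() < realized[s.name]:
                        seq[s.position - start] = s.alt_nt
                if err > 0:
                    hits = np.nonzero(rng.random(len(seq)) < err)[0]
                    for j in hits:
                        others = [b for b in BASES if b != seq[j]]
                        seq[j] = others[int(rng.integers(0, 3))]
                u = rng.random()
                tail = ""
                if u < pa + pt + po:
                    tlen = int(rng.integers(1, 4))
                    if u < pa:
                        tail = "A" * tlen
                    elif u < pa + pt:
                        tail = "T" * tlen
                    else:
                        tail = "".join("CG"[int(rng.integers(0, 2))] for _ in range(tlen))
                full = "".join(seq) + tail
                qual = chr(config.phred_quality + io.PHRED_OFFSET) * len(full)
                records.append((f"{sample.sample_id}_{hid}_{read_no}", full, qual))
    return records, realized


def simulate_cohort(config: SimConfig, outdir) -> dict:
    """Build the reference and all samples, writing everything under outdir.

    Layout: ``reference/`` (genome.fa, hairpins.fa, annotation.gff3,
    snps.tsv), ``reads/<sample>.fastq``, ``metadata.tsv`` (sample_id, group,
    age, n_reads), ``truth_sites.tsv`` and ``truth_levels.tsv`` (the ledger).
    """
    config.validate()
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    reference = build_reference(config)
    reference.write(outdir / "reference")

    n_samples = sum(config.n_samples_per_group.values())
    seeds = np.random.SeedSequence(config.rng_seed).spawn(1 + n_samples)

    cohort_rng = np.random.default_rng(seeds[0])
    metas: list[SampleMetadata] = []
    for group, n in config.n_samples_per_group.items():
        for j in range(n):
            sid = f"{group}-{j + 1:02d}"
            if any(m.sample_id == sid for m in metas):
                raise ValueError(f"duplicate sample id {sid}")
            age = float(
                np.round(cohort_rng.uniform(config.age_range[0], config.age_range[1]), 2)
            )
            metas.append(SampleMetadata(sid, group, age))

    ledger_rows = []
    n_reads_per_sample = {}
    for k, meta in enumerate(metas):
        rng = np.random.default_rng(seeds[1 + k])
        records, realized = simulate_sample(config, meta, reference, rng)
        io.write_fastq(records, outdir / "reads" / f"{meta.sample_id}.fastq")
        n_reads_per_sample[meta.sample_id] = len(records)
        for site_name, level in realized.items():
            ledger_rows.append((site_name, meta.sample_id, level))

    import pandas as pd

    extra = pd.DataFrame(
        {"sample_id": list(n_reads_per_sample), "n_reads": list(n_reads_per_sample.values())}
    )
    io.write_metadata(metas, outdir / "metadata.tsv", extra=extra)

    truth_sites = pd.DataFrame(
        [
            (
                s.name,
                s.premirna_id,
                s.position,
                s.ref_nt,
                s.alt_nt,
                s.base_level,
                s.age_slope,
                s.group_effect,
                s.effect_group or "",
                int(s.is_snp),
            )
            for s in config.site_specs
        ],
        columns=[
            "name",
            "premirna",
            "position",
            "ref",
            "alt",
            "base_level",
            "age_slope",
            "group_effect",
            "effect_group",
            "is_snp",
        ],
    )
    truth_sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    pd.DataFrame(ledger_rows, columns=["site", "sample_id", "level"]).to_csv(
        outdir / "truth_levels.tsv", sep="\t", index=False
    )
    return {
        "reference": reference,
        "metadata": metas,
        "n_reads": n_reads_per_sample,
        "outdir": outdir,
    }
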