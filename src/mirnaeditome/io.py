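"""Readers and writers for the external formats the pipeline touches.

FASTA/FASTQ go through Biopython; the miRBase GFF3 dialect (features
``miRNA_primary_transcript`` and ``miRNA``, 1-based inclusive coordinates,
mature arms linked to their hairpin by ``Derives_from``/``Parent``) is read
with a small column parser because only those two feature types and four
attributes are consumed. Tables are plain TSV via pandas.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import (
    EditingMatrix,
    MatureArm,
    MESite,
    PreMiRNA,
    SampleMetadata,
    SnpRecord,
    revcomp,
    to_dna,
    to_rna,
)

PHRED_OFFSET = 33


def quality_scores(qual: str) -> list[int]:
    """Decode a Sanger Phred+33 quality string to integer Q scores."""
    return [ord(c) - PHRED_OFFSET for c in qual]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {id: sequence}, upper-cased and U->T normalized.

    Headers are tokenized at the first whitespace.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = to_dna(str(rec.seq))
    if not seqs:
        warnings.warn(f"empty FASTA file: {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (name, sequence, quality) tuples from a Phred+33 FASTQ file.

    Raises ValueError naming the 1-based record index on malformed records.
    """
    n = 0
    with open(path) as fh:
        try:
            for name, seq, qual in FastqGeneralIterator(fh):
                n += 1
                if len(seq) != len(qual):
                    raise ValueError(
                        f"FASTQ record {n} ({name}): sequence and quality "
                        f"lengths differ ({len(seq)} vs {len(qual)})"
                    )
                yield name, to_dna(seq), qual
        except ValueError as err:
            if "FASTQ record" in str(err):
                raise
            raise ValueError(f"malformed FASTQ near record {n + 1}: {err}") from err
    if n == 0:
        warnings.warn(f"empty FASTQ file: {path}")


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# miRBase-dialect GFF3


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_mirbase_gff3(
    path,
    hairpin_seqs: dict[str, str] | None = None,
    genome: dict[str, str] | None = None,
) -> dict[str, PreMiRNA]:
    """Parse a miRBase-dialect GFF3 into PreMiRNA records.

    Hairpin sequences are taken from ``hairpin_seqs`` (keyed by Name or ID)
    or, failing that, sliced from ``genome`` (reverse-complemented on the
    minus strand). Mature-arm coordinates are converted to hairpin-relative
    1-based offsets with strand-aware arithmetic: on the minus strand the
    genomic end of the hairpin is hairpin-relative position 1.
    """
    hairpins: dict[str, dict] = {}
    matures: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _, ftype, start, end, _, strand, _, attr_field = cols
            attrs = _parse_attributes(attr_field)
            rec = {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "id": attrs.get("ID", ""),
                "name": attrs.get("Name", attrs.get("ID", "")),
                "parent": attrs.get("Derives_from", attrs.get("Parent")),
                "line": lineno,
            }
            if ftype == "miRNA_primary_transcript":
                hairpins[rec["id"]] = rec
            elif ftype == "miRNA":
                matures.append(rec)

    by_id: dict[str, PreMiRNA] = {}
    arms_for: dict[str, list[MatureArm]] = {hid: [] for hid in hairpins}
    for m in matures:
        if m["parent"] is None or m["parent"] not in hairpins:
            raise ValueError(
                f"{path}: line {m['line']}: mature feature {m['name']} has no "
                "parent hairpin (Derives_from/Parent)"
            )
        h = hairpins[m["parent"]]
        if m["start"] < h["start"] or m["end"] > h["end"]:
            raise ValueError(
                f"{path}: line {m['line']}: mature arm {m['name']} outside "
                f"hairpin {h['name']} span"
            )
        if h["strand"] == "+":
            rel_start = m["start"] - h["start"] + 1
            rel_end = m["end"] - h["start"] + 1
        else:
            rel_start = h["end"] - m["end"] + 1
            rel_end = h["end"] - m["start"] + 1
        arms_for[h["id"]].append(MatureArm(m["name"], rel_start, rel_end))

    for hid, h in hairpins.items():
        seq = None
        if hairpin_seqs is not None:
            seq = hairpin_seqs.get(h["name"], hairpin_seqs.get(hid))
        if seq is None and genome is not None:
            chrom_seq = genome[h["chrom"]]
            seq = chrom_seq[h["start"] - 1 : h["end"]]
            if h["strand"] == "-":
                seq = revcomp(seq)
        if seq is None:
            raise ValueError(f"no sequence available for hairpin {h['name']}")
        by_id[h["name"]] = PreMiRNA(
            id=h["name"],
            sequence=seq,
            chrom=h["chrom"],
            start=h["start"],
            end=h["end"],
            strand=h["strand"],
            mature_arms=sorted(arms_for[hid], key=lambda a: a.start),
        )
    return by_id


def write_mirbase_gff3(premirnas: Iterable[PreMiRNA], path) -> None:
    """Write hairpins and their mature arms in the miRBase GFF3 dialect."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in premirnas:
            fh.write(
                f"{h.chrom}\t.\tmiRNA_primary_transcript\t{h.start}\t{h.end}\t.\t"
                f"{h.strand}\t.\tID={h.id};Name={h.id}\n"
            )
            for arm in h.mature_arms:
                if h.strand == "+":
                    gstart = h.start + arm.start - 1
                    gend = h.start + arm.end - 1
                else:
                    gstart = h.end - arm.end + 1
                    gend = h.end - arm.start + 1
                fh.write(
                    f"{h.chrom}\t.\tmiRNA\t{gstart}\t{gend}\t.\t{h.strand}\t.\t"
                    f"ID={arm.name};Name={arm.name};Derives_from={h.id}\n"
                )


# ---------------------------------------------------------------------------
# Simple TSV tables


def read_snp_table(path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return [
        SnpRecord(r.chrom, int(r.pos), to_dna(r.ref), to_dna(r.alt), str(r.rsid))
        for r in df.itertuples()
    ]


def write_snp_table(snps: Iterable[SnpRecord], path) -> None:
    rows = [(s.chrom, s.pos, s.ref, s.alt, s.rsid) for s in snps]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "rsid"]).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", comment="#")
    metas = []
    seen = set()
    for r in df.itertuples():
        if r.sample_id in seen:
            raise ValueError(f"duplicate sample id {r.sample_id}")
        seen.add(r.sample_id)
        age = float(r.age) if pd.notna(r.age) else None
        metas.append(SampleMetadata(str(r.sample_id), str(r.group), age))
    return metas


def write_metadata(metas: Iterable[SampleMetadata], path, extra: pd.DataFrame | None = None) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.group, m.age) for m in metas],
        columns=["sample_id", "group", "age"],
    )
    if extra is not None:
        df = df.merge(extra, on="sample_id", how="left")
    df.to_csv(path, sep="\t", index=False)


def _format_percent(level: float) -> str:
    return f"{100.0 * level:.4g}"


def write_site_table(sites: list[MESite], path, thresholds: dict | None = None) -> None:
    """Write the final site table; levels as percentages with 4 significant digits.

    A header comment line records the thresholds used and the tool version.
    """
    from . import __version__

    samples: list[str] = sorted({s for site in sites for s in site.levels})
    with open(path, "w") as fh:
        meta = " ".join(f"{k}={v}" for k, v in (thresholds or {}).items())
        fh.write(f"# mirnaeditome v{__version__} site table; levels in %; {meta}\n")
        cols = ["name", "premirna", "position", "ref", "alt", "type", "n_significant"] + samples
        fh.write("\t".join(cols) + "\n")
        for site in sites:
            row = [
                site.name or "",
                site.premirna_id,
                str(site.position),
                to_rna(site.ref_nt) if site.ref_nt != "-" else "-",
                to_rna(site.alt_nt).lower(),
                site.type_label or "",
                str(site.n_significant),
            ] + [_format_percent(site.levels.get(s, 0.0)) for s in samples]
            fh.write("\t".join(row) + "\n")


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    sample_cols = df.columns[7:]
    df[sample_cols] = df[sample_cols] / 100.0
    return df


def write_matrix(matrix: EditingMatrix, path) -> None:
    """Write an editing matrix (sites x samples) as TSV, levels in percent."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# mirnaeditome v{__version__} editing matrix; levels in %\n")
        fh.write("site\t" + "\t".join(matrix.samples) + "\n")
        for site in matrix.sites:
            vals = [_format_percent(v) for v in matrix.levels.loc[site]]
            fh.write(site + "\t" + "\t".join(vals) + "\n")


def read_matrix(path) -> pd.DataFrame:
    """Read an editing-matrix TSV back to a fraction-scale DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df / 100.0
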