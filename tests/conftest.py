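"""Shared fixtures: a hand-built reference whose read sets exercise all nine
M/E type labels (including a cross-mapping Pseudo construction), plus small
helpers for writing FASTQ files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from mirnaeditome.core import BASES, MatureArm, PreMiRNA, SnpRecord
from mirnaeditome.io import write_fastq, write_metadata, write_snp_table
from mirnaeditome.core import SampleMetadata
from mirnaeditome.simulate import ReferenceBundle


def make_fastq_records(read_counts: dict[str, int], quality_char: str = "I"):
    """Expand {sequence: count} into FASTQ record tuples at constant quality."""
    records = []
    i = 0
    for seq, count in read_counts.items():
        for _ in range(count):
            i += 1
            records.append((f"r{i}", seq, quality_char * len(seq)))
    return records


def _random_seq(rng, length):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def build_nine_type_reference() -> tuple[ReferenceBundle, dict]:
    """Three hairpins plus one unannotated decoy locus.

    fix-mir-1 carries a 5'-editing, an A-to-I, a C-to-U and an Other site in
    its arm and receives 3'-A/3'-U/3'-Other tails; fix-mir-2 carries a
    100%-level SNP; fix-mir-3 receives reads that co-map to the decoy locus,
    whose expression pulls the weight away (the Pseudo construction).
    """
    rng = np.random.default_rng(20240901)
    chrom = "chrF"
    hairpins = {}
    seqs = {}
    for hid in ("fix-mir-1", "fix-mir-2", "fix-mir-3"):
        s = list(_random_seq(rng, 40))
        seqs[hid] = s
    # programmed reference bases
    for pos, base in ((5, "G"), (10, "A"), (14, "C"), (18, "G"), (27, "G")):
        seqs["fix-mir-1"][pos - 1] = base
    seqs["fix-mir-2"][12 - 1] = "A"
    seqs["fix-mir-3"][14 - 1] = "A"
    seqs["fix-mir-3"][20 - 1] = "T"

    pieces = []
    cursor = 1
    for hid in seqs:
        spacer = _random_seq(rng, 30)
        pieces.append(spacer)
        cursor += 30
        seq = "".join(seqs[hid])
        hairpins[hid] = PreMiRNA(
            id=hid,
            sequence=seq,
            chrom=chrom,
            start=cursor,
            end=cursor + 39,
            strand="+",
            mature_arms=[MatureArm(f"{hid}-5p", 5, 26)],
        )
        pieces.append(seq)
        cursor += 40
    # decoy: fix-mir-3's arm with the apparent edit (G at hairpin pos 14)
    # plus one extra substitution (C at hairpin pos 20)
    arm3 = list("".join(seqs["fix-mir-3"])[4:26])
    arm3[14 - 5] = "G"
    decoy = list(arm3)
    decoy[20 - 5] = "C"
    pieces.append(_random_seq(rng, 30))
    pieces.append("".join(decoy))
    pieces.append(_random_seq(rng, 30))
    genome = {chrom: "".join(pieces)}

    h2 = hairpins["fix-mir-2"]
    snps = [SnpRecord(chrom, h2.genomic_position(12), "A", "G", "fixrs1")]

    arm1 = "".join(seqs["fix-mir-1"])[4:26]
    arm2 = "".join(seqs["fix-mir-2"])[4:26]
    arm3_ref = "".join(seqs["fix-mir-3"])[4:26]

    def sub(seq, arm_pos_1based, base):
        s = list(seq)
        s[arm_pos_1based - 1] = base
        return "".join(s)

    read_counts = {
        arm1: 100,
        sub(arm1, 1, "A"): 30,  # 5'-editing at hairpin pos 5
        sub(arm1, 6, "G"): 30,  # A-to-I at pos 10
        sub(arm1, 10, "T"): 30,  # C-to-U at pos 14
        sub(arm1, 14, "T"): 30,  # Other (G->U) at pos 18
        arm1 + "A": 12,  # 3'-A at pos 27
        arm1 + "T": 12,  # 3'-U
        arm1 + "C": 12,  # 3'-Other
        sub(arm2, 8, "G"): 50,  # SNP at pos 12: 100% level
        arm3_ref: 100,
        "".join(arm3): 300,  # co-maps to decoy: Pseudo at pos 14
        "".join(decoy): 900,  # decoy's own expression
    }
    expected_labels = {
        "fix-mir-1_5_G_a": "5'-editing",
        "fix-mir-1_10_A_g": "A-to-I",
        "fix-mir-1_14_C_u": "C-to-U",
        "fix-mir-1_18_G_u": "Other",
        "fix-mir-1_27_G_a": "3'-A",
        "fix-mir-1_27_G_u": "3'-U",
        "fix-mir-1_27_G_c": "3'-Other",
        "fix-mir-2_12_A_g": "SNP",
        "fix-mir-3_14_A_g": "Pseudo",
    }
    return ReferenceBundle(genome, hairpins, snps), {
        "read_counts": read_counts,
        "expected_labels": expected_labels,
    }


@pytest.fixture(scope="session")
def nine_type_bundle():
    return build_nine_type_reference()


@pytest.fixture(scope="session")
def nine_type_cohort(tmp_path_factory, nine_type_bundle):
    """A 4-sample cohort directory with identical reads in every sample."""
    reference, info = nine_type_bundle
    outdir = tmp_path_factory.mktemp("nine_type")
    reference.write(outdir / "reference")
    (outdir / "reads").mkdir()
    metas = []
    for i in range(4):
        sid = f"s{i + 1}"
        metas.append(SampleMetadata(sid, "case" if i < 2 else "control", 70.0 + i))
        write_fastq(
            make_fastq_records(info["read_counts"]), outdir / "reads" / f"{sid}.fastq"
        )
    write_metadata(metas, outdir / "metadata.tsv")
    return outdir, info
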