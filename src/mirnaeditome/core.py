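"""Core domain containers shared across the pipeline.

Conventions used throughout the package:

* sequences are stored in the DNA alphabet (U normalized to T, upper case);
  the RNA alphabet is used only for display and site naming,
* coordinates are hairpin-relative, 1-based, 5'->3' inclusive; genomic
  coordinates appear only at the SNP-matching boundary and in the GFF3,
* editing levels are stored as fractions in [0, 1] and serialized as percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def to_dna(seq: str) -> str:
    """Normalize a sequence to the upper-case DNA alphabet."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Display form: upper-case RNA alphabet."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of byte values (for vector ops)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class MatureArm:
    """A mature miRNA embedded in its hairpin (1-based inclusive offsets)."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PreMiRNA:
    """An annotated hairpin with mature-arm coordinates on it."""

    id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    mature_arms: list[MatureArm] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = to_dna(self.sequence)
        for arm in self.mature_arms:
            if arm.start < 1 or arm.end > len(self.sequence) or arm.start > arm.end:
                raise ValueError(
                    f"mature arm {arm.name} ({arm.start}-{arm.end}) not contained "
                    f"in hairpin {self.id} of length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def arm_sequence(self, arm: MatureArm) -> str:
        return self.sequence[arm.start - 1 : arm.end]

    def base_at(self, position: int) -> str | None:
        """Reference base at a 1-based hairpin position, None beyond the end."""
        if 1 <= position <= self.length:
            return self.sequence[position - 1]
        return None

    def genomic_position(self, position: int) -> int | None:
        """Map a hairpin position to a 1-based genomic coordinate (strand-aware)."""
        if not 1 <= position <= self.length:
            return None
        if self.strand == "+":
            return self.start + position - 1
        return self.end - position + 1

    def arm_containing(self, position: int) -> MatureArm | None:
        for arm in self.mature_arms:
            if arm.start <= position <= arm.end:
                return arm
        return None


@dataclass
class UniqueRead:
    """A collapsed unique read sequence with its raw multiplicity."""

    sequence: str
    count: int
    qualified: bool = True

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("unique read count must be >= 1")
        self.sequence = to_dna(self.sequence)


@dataclass(frozen=True)
class GenomeLocus:
    """A genomic placement of a read: 1-based start of the matched window,
    always in plus-strand coordinates; strand says which strand matched."""

    chrom: str
    start: int
    strand: str


@dataclass
class ReadAlignment:
    """A read's placement on a pre-miRNA.

    ``start`` is the 1-based hairpin position of the read's first templated
    base; ``tail`` is the untemplated 3' suffix (may be empty); ``weight`` is
    the cross-mapping weight of the read at this hairpin's genomic locus.
    """

    read: UniqueRead
    premirna_id: str
    start: int
    mismatches: list[tuple[int, str, str]]
    tail: str
    weight: float = 1.0

    @property
    def body_length(self) -> int:
        return len(self.read.sequence) - len(self.tail)

    @property
    def last_templated(self) -> int:
        return self.start + self.body_length - 1


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str = "."

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
            raise ValueError("SNP alleles must be single distinct bases")


@dataclass
class SampleMetadata:
    sample_id: str
    group: str
    age: float | None = None

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise ValueError(f"negative age for sample {self.sample_id}")


#: the nine M/E type labels
TYPE_LABELS = (
    "A-to-I",
    "C-to-U",
    "3'-A",
    "3'-U",
    "3'-Other",
    "5'-editing",
    "Other",
    "SNP",
    "Pseudo",
)


@dataclass
class MESite:
    """A candidate mutation/editing site aggregated over a cohort."""

    premirna_id: str
    position: int  # 1-based on hairpin; may exceed hairpin length (3' tails)
    ref_nt: str  # DNA alphabet; '-' when beyond the hairpin end
    alt_nt: str
    levels: dict[str, float] = field(default_factory=dict)  # sample -> level
    n_significant: int = 0
    tail_fraction: float = 0.0  # share of alt support contributed by tail bases
    retained_weight_fraction: float = 1.0  # weighted / raw alt support
    type_label: str | None = None
    name: str | None = None

    @property
    def max_level(self) -> float:
        return max(self.levels.values(), default=0.0)


@dataclass
class EditingMatrix:
    """Sites x samples editing levels plus sample metadata.

    ``levels``: DataFrame indexed by site name, columns are sample ids,
    values are fractions in [0, 1] (0 where a site was unobserved).
    ``metadata``: DataFrame indexed by sample id with columns group, age.
    """

    levels: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.levels.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.metadata = self.metadata.loc[list(self.levels.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def sites(self) -> list[str]:
        return list(self.levels.index)

    def group_samples(self, group: str) -> list[str]:
        return list(self.metadata.index[self.metadata["group"] == group])
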