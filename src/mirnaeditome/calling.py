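"""Per-sample M/E site calling, cohort combination, and nine-type classification.

A site is a (hairpin position, alternative base) pair. Per sample, the
alternative's weighted read support is tested against a binomial
sequencing-error null (error rate 10**(-Q/10) for the quality gate Q), with
Benjamini-Hochberg correction across all candidate pairs of the sample. A
site is significant when its level is at least ``min_level``, its weighted
support at least ``min_support``, and its corrected p below ``alpha``; the
cohort keeps sites significant in at least floor(recurrence * n_samples)
samples (minimum one). Retained sites are classified into the nine M/E types
(A-to-I, C-to-U, 3'-A, 3'-U, 3'-Other, 5'-editing, Other, SNP, Pseudo).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    BASES,
    BASE_INDEX,
    EditingMatrix,
    MESite,
    PreMiRNA,
    ReadAlignment,
    SnpRecord,
    to_rna,
)
from .stats import bh_adjust

#: how far beyond the hairpin 3' end tail bases are tracked
TAIL_OVERHANG = 3


@dataclass
class Pileup:
    """Per-position weighted base counts on one hairpin.

    ``templated``/``tail`` hold cross-mapping-weighted counts, the ``*_raw``
    arrays the unweighted read counts (needed for Pseudo evidence). Arrays are
    (hairpin length + TAIL_OVERHANG) x 4, row i is hairpin position i+1.
    """

    premirna: PreMiRNA
    templated: np.ndarray
    tail: np.ndarray
    templated_raw: np.ndarray
    tail_raw: np.ndarray

    @property
    def max_pos(self) -> int:
        return self.templated.shape[0]


def pileup(alignments: list[ReadAlignment], premirna: PreMiRNA) -> Pileup:
    """Accumulate weighted and raw base counts from a sample's alignments."""
    size = premirna.length + TAIL_OVERHANG
    templated = np.zeros((size, 4))
    tail = np.zeros((size, 4))
    templated_raw = np.zeros((size, 4))
    tail_raw = np.zeros((size, 4))
    for aln in alignments:
        if aln.premirna_id != premirna.id:
            raise ValueError(f"alignment on {aln.premirna_id}, expected {premirna.id}")
        if aln.start < 1 or aln.last_templated > premirna.length:
            raise ValueError(
                f"alignment span {aln.start}-{aln.last_templated} outside "
                f"hairpin {premirna.id} (length {premirna.length})"
            )
        w = aln.weight * aln.read.count
        raw = float(aln.read.count)
        body = aln.read.sequence[: aln.body_length]
        for i, base in enumerate(body):
            idx = BASE_INDEX.get(base)
            if idx is None:
                continue
            row = aln.start - 1 + i
            templated[row, idx] += w
            templated_raw[row, idx] += raw
        for j, base in enumerate(aln.tail, start=1):
            idx = BASE_INDEX.get(base)
            if idx is None:
                continue
            row = aln.last_templated - 1 + j
            if row >= size:
                continue
            tail[row, idx] += w
            tail_raw[row, idx] += raw
    return Pileup(premirna, templated, tail, templated_raw, tail_raw)


def binomial_error_pvalue(k: float, n: float, error_rate: float) -> float:
    """P(X >= ceil(k)) for X ~ Binomial(round(n), error_rate)."""
    n_int = int(math.floor(n + 0.5))
    if n_int <= 0:
        return 1.0
    k_int = min(int(math.ceil(k)), n_int)
    if k_int <= 0:
        return 1.0
    return float(sps.binom.sf(k_int - 1, n_int, error_rate))


def call_sample_sites(
    pileups: list[Pileup],
    error_rate: float,
    min_level: float = 0.05,
    min_support: float = 10.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call candidate sites for one sample across its hairpin pileups.

    Returns one row per (hairpin, position, alt) with coverage: weighted alt
    and total counts, level, raw and BH-corrected p (correction spans all of
    the sample's candidates), the significance flag, the share of alt support
    arising from tail bases, and the retained weight fraction (weighted over
    raw alt support; low values are cross-mapping/Pseudo evidence).
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError("error_rate must be in (0, 1)")
    rows = []
    for pu in pileups:
        h = pu.premirna
        total_w = pu.templated + pu.tail
        total_raw = pu.templated_raw + pu.tail_raw
        coverage = total_w.sum(axis=1)
        for row in np.nonzero(coverage > 0)[0]:
            position = row + 1
            ref = h.base_at(position) or "-"
            n_cov = coverage[row]
            for b, idx in BASE_INDEX.items():
                if b == ref:
                    continue
                k = total_w[row, idx]
                if k <= 0 and total_raw[row, idx] <= 0:
                    continue
                k_raw = total_raw[row, idx]
                p = binomial_error_pvalue(k, n_cov, error_rate)
                rows.append(
                    {
                        "premirna": h.id,
                        "position": position,
                        "ref": ref,
                        "alt": b,
                        "alt_weighted": k,
                        "total_weighted": n_cov,
                        "alt_raw": k_raw,
                        "level": k / n_cov if n_cov > 0 else 0.0,
                        "raw_p": p,
                        "tail_alt_weighted": pu.tail[row, idx],
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "premirna",
            "position",
            "ref",
            "alt",
            "alt_weighted",
            "total_weighted",
            "alt_raw",
            "level",
            "raw_p",
            "tail_alt_weighted",
        ],
    )
    if df.empty:
        df["corrected_p"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["corrected_p"] = bh_adjust(df["raw_p"].to_numpy())
    df["significant"] = (
        (df["level"] >= min_level)
        & (df["alt_weighted"] >= min_support)
        & (df["corrected_p"] < alpha)
    )
    return df


def recurrence_threshold(n_samples: int, recurrence: float = 0.10) -> int:
    """Minimum number of significant samples for cohort retention:
    floor(recurrence * n_samples), but at least 1 (131 samples -> 13)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return max(1, int(math.floor(recurrence * n_samples + 1e-9)))


def combine_cohort(
    per_sample_calls: dict[str, pd.DataFrame],
    recurrence: float = 0.10,
) -> tuple[list[MESite], pd.DataFrame]:
    """Combine per-sample calls into cohort-retained sites.

    A site is retained iff significant in >= recurrence_threshold(n) samples.
    Retained sites report levels in all samples (0 where unobserved). Returns
    the retained MESite list and the levels DataFrame (sites x samples; site
    keys are tuples until classification/naming assigns display names).
    """
    n_samples = len(per_sample_calls)
    threshold = recurrence_threshold(n_samples, recurrence)
    samples = list(per_sample_calls)

    agg: dict[tuple, dict] = {}
    for sid, calls in per_sample_calls.items():
        for r in calls.itertuples():
            key = (r.premirna, r.position, r.ref, r.alt)
            a = agg.setdefault(
                key,
                {
                    "n_sig": 0,
                    "levels": {},
                    "alt_w": 0.0,
                    "alt_raw": 0.0,
                    "tail_w": 0.0,
                },
            )
            a["levels"][sid] = r.level
            a["n_sig"] += int(r.significant)
            a["alt_w"] += r.alt_weighted
            a["alt_raw"] += r.alt_raw
            a["tail_w"] += r.tail_alt_weighted

    sites: list[MESite] = []
    for key in sorted(agg):
        a = agg[key]
        if a["n_sig"] < threshold:
            continue
        premirna, position, ref, alt = key
        levels = {sid: float(a["levels"].get(sid, 0.0)) for sid in samples}
        sites.append(
            MESite(
                premirna_id=premirna,
                position=int(position),
                ref_nt=ref,
                alt_nt=alt,
                levels=levels,
                n_significant=int(a["n_sig"]),
                tail_fraction=float(a["tail_w"] / a["alt_w"]) if a["alt_w"] > 0 else 0.0,
                retained_weight_fraction=(
                    float(a["alt_w"] / a["alt_raw"]) if a["alt_raw"] > 0 else 1.0
                ),
                name=name_site(premirna, int(position), ref, alt),
            )
        )
    if sites:
        levels_df = pd.DataFrame({s.name: s.levels for s in sites}).T[samples]
    else:
        levels_df = pd.DataFrame(columns=samples)
    return sites, levels_df


# ---------------------------------------------------------------------------
# Classification and naming


def flag_snps(site: MESite, premirna: PreMiRNA, snp_table: list[SnpRecord]) -> bool:
    """A site is a SNP iff a table entry matches its genomic position and both
    alleles, and its level reaches 100% in at least one sample."""
    gpos = premirna.genomic_position(site.position)
    if gpos is None:
        return False
    ref, alt = site.ref_nt, site.alt_nt
    if premirna.strand == "-":
        from .core import revcomp

        ref, alt = revcomp(ref), revcomp(alt)
    matched = any(
        s.chrom == premirna.chrom and s.pos == gpos and s.ref == ref and s.alt == alt
        for s in snp_table
    )
    return matched and site.max_level >= 1.0 - 1e-9


def classify_site(
    site: MESite,
    premirna: PreMiRNA,
    snp_table: list[SnpRecord] | None = None,
    pseudo_retained_threshold: float = 0.5,
) -> str:
    """Assign one of the nine M/E type labels, in precedence order.

    (1) SNP; (2) Pseudo when strictly less than ``pseudo_retained_threshold``
    of the site's supporting read weight survives cross-mapping correction;
    (3) 3'-A / 3'-U / 3'-Other for sites past the 3' end of a mature arm
    (including positions beyond the hairpin), where non-templated tailing
    accrues; (4) 5'-editing at the first templated position of a mature arm;
    (5) internal A->G = A-to-I; (6) internal C->U = C-to-U; (7) Other.
    """
    pos = site.position
    in_arm = premirna.arm_containing(pos)
    past_three_prime = pos > premirna.length or (
        in_arm is None and any(pos > arm.end for arm in premirna.mature_arms)
    )
    if in_arm is None and not past_three_prime and premirna.base_at(pos) is None:
        raise ValueError(
            f"position {pos} of {premirna.id} is neither templated nor a tail offset"
        )
    if snp_table and flag_snps(site, premirna, snp_table):
        label = "SNP"
    elif site.retained_weight_fraction < pseudo_retained_threshold:
        label = "Pseudo"
    elif past_three_prime:
        label = {"A": "3'-A", "T": "3'-U"}.get(site.alt_nt, "3'-Other")
    elif any(pos == arm.start for arm in premirna.mature_arms):
        label = "5'-editing"
    elif site.ref_nt == "A" and site.alt_nt == "G":
        label = "A-to-I"
    elif site.ref_nt == "C" and site.alt_nt == "T":
        label = "C-to-U"
    else:
        label = "Other"
    site.type_label = label
    return label


def name_site(premirna_id: str, position: int, ref_nt: str, alt_nt: str) -> str:
    """Display name: pre-miRNA, position, reference base (upper-case RNA),
    edited base (lower-case RNA), e.g. ``hsa-mir-497_25_A_g``."""
    ref = to_rna(ref_nt) if ref_nt != "-" else "-"
    return f"{premirna_id}_{position}_{ref}_{to_rna(alt_nt).lower()}"


def name_edited_mirna(premirna_id: str, position: int, alt_nt: str) -> str:
    """Short form naming the edited miRNA itself, e.g. ``hsa-mir-497_25g``."""
    return f"{premirna_id}_{position}{to_rna(alt_nt).lower()}"


_SITE_NAME_RE = re.compile(r"^(?P<id>.+)_(?P<pos>\d+)_(?P<ref>[ACGU\-])_(?P<alt>[acgu])$")


def parse_site_name(name: str) -> tuple[str, int, str, str]:
    """Invert name_site; returns (premirna_id, position, ref, alt) in DNA."""
    m = _SITE_NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a valid site name: {name}")
    from .core import to_dna

    ref = m.group("ref")
    return (
        m.group("id"),
        int(m.group("pos")),
        to_dna(ref) if ref != "-" else "-",
        to_dna(m.group("alt").upper()),
    )


def edited_mature(site: MESite, premirna: PreMiRNA) -> tuple[str, int, str, bool]:
    """Locate a site on its mature arm.

    Returns (arm name, mature-relative 1-based position, edited mature
    sequence, in_seed). The seed region is mature positions 2-8.
    """
    arm = premirna.arm_containing(site.position)
    if arm is None:
        raise ValueError(
            f"site {site.premirna_id}:{site.position} is not within a mature arm"
        )
    rel = site.position - arm.start + 1
    in_seed = 2 <= rel <= 8
    arm_seq = premirna.arm_sequence(arm)
    edited = arm_seq[: rel - 1] + site.alt_nt + arm_seq[rel:]
    return arm.name, rel, edited, in_seed


def context_profile(
    sites: list[MESite], premirnas: dict[str, PreMiRNA]
) -> tuple[pd.Series, pd.Series]:
    """Neighbor-base frequency tables (5' and 3') of internal sites.

    Sites at a hairpin terminus (or beyond) are excluded with a warning.
    Frequencies are over the RNA alphabet and normalized to sum to 1.
    """
    import warnings

    if not sites:
        raise ValueError("empty site list")
    five = {b: 0 for b in BASES}
    three = {b: 0 for b in BASES}
    used = 0
    for site in sites:
        h = premirnas[site.premirna_id]
        if site.position <= 1 or site.position >= h.length:
            warnings.warn(
                f"site {site.premirna_id}:{site.position} at hairpin terminus; excluded"
            )
            continue
        five[h.base_at(site.position - 1)] += 1
        three[h.base_at(site.position + 1)] += 1
        used += 1
    if used == 0:
        raise ValueError("no internal sites to profile")
    idx = [to_rna(b) for b in BASES]
    f = pd.Series([five[b] / used for b in BASES], index=idx)
    t = pd.Series([three[b] / used for b in BASES], index=idx)
    return f, t


def match_conserved_sites(
    sites_a: list[tuple[str, int, str]],
    sites_b: list[tuple[str, int, str]],
    orthology: dict[str, str] | None = None,
) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """Pair sites of equal type at equal mature-relative positions.

    Each site is (arm name, mature-relative position, type). Arm names are
    matched through ``orthology`` (a -> b); identity when omitted. Entries
    whose arm has no orthology mapping are skipped with a warning.
    """
    import warnings

    by_key: dict[tuple[str, int, str], list[tuple[str, int, str]]] = {}
    for b in sites_b:
        by_key.setdefault((b[0], b[1], b[2]), []).append(b)
    pairs = []
    for a in sites_a:
        arm_b = a[0] if orthology is None else orthology.get(a[0])
        if arm_b is None:
            warnings.warn(f"no orthology entry for arm {a[0]}; skipped")
            continue
        for b in by_key.get((arm_b, a[1], a[2]), []):
            pairs.append((a, b))
    return pairs
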