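"""Site calling: pileup arithmetic, the binomial error null, cohort
combination, nine-type classification, SNP flagging, naming, seed logic,
and context/conservation utilities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mirnaeditome.calling import (
    binomial_error_pvalue,
    call_sample_sites,
    classify_site,
    combine_cohort,
    context_profile,
    edited_mature,
    flag_snps,
    match_conserved_sites,
    name_edited_mirna,
    name_site,
    parse_site_name,
    pileup,
    recurrence_threshold,
)
from mirnaeditome.core import (
    MatureArm,
    MESite,
    PreMiRNA,
    ReadAlignment,
    SnpRecord,
    UniqueRead,
)

HP = PreMiRNA(
    "h1",
    "GGGG" + "ACGTACGTACGTACGTACGTAC" + "GGGGGGGGGGGGGG",
    "chr1",
    1001,
    1040,
    "+",
    [MatureArm("h1-5p", 5, 26)],
)
ARM = HP.sequence[4:26]


def _aln(seq, start, weight=1.0, count=1, tail=""):
    body = seq[: len(seq) - len(tail)] if tail else seq
    mismatches = [
        (start + i, HP.sequence[start - 1 + i], c)
        for i, c in enumerate(body)
        if HP.sequence[start - 1 + i] != c
    ]
    return ReadAlignment(UniqueRead(seq, count), "h1", start, mismatches, tail, weight)


def test_pileup_conservation_and_linearity():
    pu = pileup([_aln(ARM, 5, weight=1.0, count=10)], HP)
    for pos in range(5, 27):
        ref = HP.base_at(pos)
        assert pu.templated[pos - 1].sum() == 10
        assert pu.templated[pos - 1]["ACGT".index(ref)] == 10
    pu_half = pileup([_aln(ARM, 5, weight=0.5, count=10)], HP)
    assert np.allclose(pu_half.templated, pu.templated * 0.5)


def test_pileup_disagreement_and_tail_positions():
    alt_read = ARM[:3] + ("G" if ARM[3] != "G" else "A") + ARM[4:]
    pu = pileup([_aln(ARM, 5, count=6), _aln(alt_read, 5, count=4)], HP)
    row = pu.templated[8 - 1]  # hairpin position 8 = arm offset 4
    assert row.sum() == 10 and sorted(row[row > 0]) == [4, 6]
    # a 2-nt tail accumulates at last templated position + 1, + 2
    pu = pileup([_aln(ARM + "AA", 5, count=3, tail="AA")], HP)
    assert pu.tail[27 - 1, 0] == 3 and pu.tail[28 - 1, 0] == 3


def test_pileup_out_of_bounds_errors():
    bad = ReadAlignment(UniqueRead(ARM, 1), "h1", 30, [], "")
    with pytest.raises(ValueError, match="outside"):
        pileup([bad], HP)


def test_binomial_pvalue_null_and_closed_form():
    assert binomial_error_pvalue(0, 100, 0.001) == 1.0
    assert binomial_error_pvalue(10, 10, 0.001) == pytest.approx(1e-30, rel=1e-9)
    # N=1000, k=5: direct pmf summation oracle
    expected = sum(
        math.comb(1000, j) * 0.001**j * 0.999 ** (1000 - j) for j in range(5, 1001)
    )
    assert binomial_error_pvalue(5, 1000, 0.001) == pytest.approx(expected, rel=1e-9)


def test_call_sample_sites_criteria():
    ref = ARM[7]
    alt = "G" if ref != "G" else "A"
    alt_read = ARM[:7] + alt + ARM[8:]
    pu = pileup([_aln(ARM, 5, count=80), _aln(alt_read, 5, count=20)], HP)
    calls = call_sample_sites([pu], error_rate=0.001)
    hit = calls[(calls.position == 12) & (calls.alt == alt)]
    assert len(hit) == 1
    assert bool(hit.significant.iloc[0])
    assert hit.level.iloc[0] == pytest.approx(0.2)
    # support below 10 weighted reads is never significant
    pu2 = pileup([_aln(ARM, 5, count=980), _aln(alt_read, 5, count=9)], HP)
    calls2 = call_sample_sites([pu2], error_rate=0.001)
    hit2 = calls2[(calls2.position == 12) & (calls2.alt == alt)]
    assert not bool(hit2.significant.iloc[0])
    with pytest.raises(ValueError):
        call_sample_sites([pu], error_rate=0.0)


def test_recurrence_threshold_values():
    assert recurrence_threshold(131, 0.10) == 13
    assert recurrence_threshold(10, 0.10) == 1
    assert recurrence_threshold(3, 0.10) == 1  # floor 0 -> minimum 1
    with pytest.raises(ValueError):
        recurrence_threshold(0)


def test_combine_cohort_boundary():
    """Significant in 12 of 131 samples -> dropped; 13 -> kept; retained
    sites report a level for every sample."""

    def calls(significant: bool):
        return pd.DataFrame(
            {
                "premirna": ["h1"],
                "position": [12],
                "ref": ["A"],
                "alt": ["G"],
                "alt_weighted": [20.0],
                "total_weighted": [100.0],
                "alt_raw": [20.0],
                "level": [0.2],
                "raw_p": [1e-20],
                "tail_alt_weighted": [0.0],
                "corrected_p": [1e-19],
                "significant": [significant],
            }
        )

    empty = pd.DataFrame(columns=calls(True).columns)
    per_sample = {f"s{i}": calls(i < 12) if i < 12 else empty for i in range(131)}
    sites, levels = combine_cohort(per_sample)
    assert sites == []
    per_sample = {f"s{i}": calls(i < 13) if i < 13 else empty for i in range(131)}
    sites, levels = combine_cohort(per_sample)
    assert len(sites) == 1 and sites[0].n_significant == 13
    assert levels.shape == (1, 131)
    assert levels.iloc[0].sum() == pytest.approx(0.2 * 13)  # zeros elsewhere


SNPS = [SnpRecord("chr1", HP.genomic_position(12), HP.base_at(12), "G", "rs1")]


def _site(pos, ref, alt, levels, retained=1.0):
    return MESite("h1", pos, ref, alt, levels=levels, retained_weight_fraction=retained)


def test_flag_snps_criteria():
    ref = HP.base_at(12)
    assert flag_snps(_site(12, ref, "G", {"a": 1.0, "b": 0.2}), HP, SNPS)
    # a SNP call needs a 100%-level sample
    assert not flag_snps(_site(12, ref, "G", {"a": 0.97}), HP, SNPS)
    # alleles must match in the stated orientation
    assert not flag_snps(_site(12, "G", ref, {"a": 1.0}), HP, SNPS)


def test_classification_rules_and_precedence():
    ref10 = HP.base_at(10)
    site = _site(10, "A", "G", {"a": 0.3})
    assert classify_site(site, HP, []) == ("A-to-I" if ref10 == "A" else site.type_label)
    assert classify_site(_site(14, "C", "T", {"a": 0.3}), HP, []) == "C-to-U"
    assert classify_site(_site(14, "G", "A", {"a": 0.3}), HP, []) == "Other"
    # SNP beats A-to-I; Pseudo beats positional rules
    assert classify_site(_site(12, HP.base_at(12), "G", {"a": 1.0}), HP, SNPS) == "SNP"
    assert classify_site(_site(10, "A", "G", {"a": 0.3}, retained=0.2), HP, []) == "Pseudo"
    # first templated arm position
    assert classify_site(_site(5, HP.base_at(5), "T", {"a": 0.3}), HP, []) == "5'-editing"
    # past the arm's 3' end, by alternative base; beyond the hairpin too
    assert classify_site(_site(27, HP.base_at(27), "A", {"a": 0.3}), HP, []) == "3'-A"
    assert classify_site(_site(27, HP.base_at(27), "T", {"a": 0.3}), HP, []) == "3'-U"
    assert classify_site(_site(27, HP.base_at(27), "C", {"a": 0.3}), HP, []) == "3'-Other"
    assert classify_site(_site(41, "-", "A", {"a": 0.3}), HP, []) == "3'-A"


def test_site_naming_convention():
    assert name_site("hsa-mir-497", 25, "A", "G") == "hsa-mir-497_25_A_g"
    assert name_site("hsa-mir-1301", 52, "A", "G") == "hsa-mir-1301_52_A_g"
    assert name_site("hsa-mir-125-1", 25, "C", "T") == "hsa-mir-125-1_25_C_u"
    assert name_edited_mirna("hsa-mir-497", 25, "G") == "hsa-mir-497_25g"


@settings(max_examples=50, deadline=None)
@given(
    pos=st.integers(1, 200),
    ref=st.sampled_from("ACGT"),
    alt=st.sampled_from("ACGT"),
    hid=st.sampled_from(["hsa-mir-497", "hsa-let-7a-2", "sim-mir-3"]),
)
def test_naming_round_trip(pos, ref, alt, hid):
    if ref == alt:
        return
    name = name_site(hid, pos, ref, alt)
    assert parse_site_name(name) == (hid, pos, ref, alt)


def test_edited_mature_seed_boundaries():
    arm_start = 5
    site1 = _site(arm_start, HP.base_at(arm_start), "T", {})
    arm, rel, edited, in_seed = edited_mature(site1, HP)
    assert (arm, rel, in_seed) == ("h1-5p", 1, False)
    site2 = _site(arm_start + 1, HP.base_at(arm_start + 1), "T", {})
    _, rel, edited, in_seed = edited_mature(site2, HP)
    assert (rel, in_seed) == (2, True)
    assert sum(a != b for a, b in zip(edited, ARM)) == 1
    _, rel, _, in_seed = edited_mature(_site(13, HP.base_at(13), "T", {}), HP)
    assert (rel, in_seed) == (9, False)
    with pytest.raises(ValueError, match="not within a mature arm"):
        edited_mature(_site(30, HP.base_at(30), "A", {}), HP)


def test_context_profile():
    premirnas = {"h1": HP}
    sites = [_site(p, HP.base_at(p), "G", {}) for p in (10, 14, 18)]
    five, three = context_profile(sites, premirnas)
    assert five.sum() == pytest.approx(1.0, abs=1e-12)
    assert three.sum() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        context_profile([], premirnas)
    with pytest.warns(UserWarning, match="terminus"):
        context_profile([_site(1, HP.base_at(1), "A", {}), sites[0]], premirnas)


def test_match_conserved_sites():
    a = [("mir-1-5p", 4, "A-to-I"), ("mir-2-5p", 7, "C-to-U")]
    assert match_conserved_sites(a, a) == [(x, x) for x in a]
    b = [("mir-1-5p", 4, "C-to-U")]  # same position, different type
    assert match_conserved_sites(a, b) == []
    assert match_conserved_sites(a, [("mir-1-5p", 9, "A-to-I")]) == []
    with pytest.warns(UserWarning, match="orthology"):
        out = match_conserved_sites(a, a, orthology={"mir-1-5p": "mir-1-5p"})
    assert out == [(a[0], a[0])]
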