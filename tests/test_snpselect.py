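import numpy as np
import pytest

from pinesnp import snpselect
from pinesnp.snpselect import (
    INSUFFICIENT_SUPPORT,
    LD_PRUNED,
    LOW_FUNCTIONALITY,
    LOW_POLYBAYES,
    NEIGHBOR_TOO_CLOSE,
    RARE_VARIANT,
    UNIGENE_CAP,
    SnpCandidate,
)

FLANK = "A" * 60 + "G" + "A" * 60


def vitro(snp_id, maf=0.3, func=0.9, gene="g1", frag_pos=None, **kw):
    return SnpCandidate(
        snp_id=snp_id, source="in_vitro", gene_id=gene, flank=FLANK,
        position=61, alleles=("A", "G"), maf=maf, depth=12,
        minor_count=max(1, int(round(maf * 12))),
        functionality_score=func, fragment_pos=frag_pos, **kw,
    )


def silico(snp_id, maf=0.3, depth=5, minor=2, pb=0.995, gene="u1", neigh=()):
    return SnpCandidate(
        snp_id=snp_id, source="in_silico", gene_id=gene, flank=FLANK,
        position=61, alleles=("A", "G"), maf=maf, depth=depth,
        minor_count=minor, polybayes_score=pb,
        neighbor_positions=list(neigh),
    )


def test_functionality_threshold_boundary():
    rep = snpselect.filter_invitro([vitro("a", func=0.39), vitro("b", func=0.4)])
    assert rep.retained == ["b"]
    assert rep.rejected["a"] == [LOW_FUNCTIONALITY]


def test_spacing_drops_lower_maf_member():
    a = vitro("a", maf=0.30, frag_pos=100)
    b = vitro("b", maf=0.10, frag_pos=159)  # 59 nt away: violates 60-nt rule
    rep = snpselect.filter_invitro([a, b])
    assert rep.retained == ["a"]
    assert rep.rejected["b"][0] == NEIGHBOR_TOO_CLOSE


def test_spacing_exhaustive_pairwise_consistency():
    # survivors of the spacing filter must be pairwise >= 60 nt apart
    cands = [
        vitro(f"s{i}", maf=0.1 + 0.02 * i, frag_pos=30 * i) for i in range(10)
    ]
    rep = snpselect.filter_invitro(cands)
    kept = [c for c in cands if c.snp_id in set(rep.retained)]
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            assert abs(a.fragment_pos - b.fragment_pos) >= 60


def test_rare_variant_rejected():
    rep = snpselect.filter_invitro([vitro("a", maf=0.03), vitro("b", maf=0.05, gene="g2")])
    assert rep.retained == ["b"]
    assert rep.rejected["a"] == [RARE_VARIANT]


def test_ld_pruning_drops_downstream_snp():
    a = vitro("a", frag_pos=10)
    b = vitro("b", frag_pos=200)
    h = np.array([0, 1, 0, 1, 1, 0, 0, 1])
    rep = snpselect.filter_invitro([a, b], haplotypes={"a": h, "b": h})
    assert rep.retained == ["a"]
    assert rep.rejected["b"][0] == LD_PRUNED
    # uncorrelated haplotypes: both retained
    h2 = np.array([1, 1, 0, 0, 1, 1, 0, 0])
    rep2 = snpselect.filter_invitro([a, b], haplotypes={"a": h, "b": h2})
    assert sorted(rep2.retained) == ["a", "b"]


def test_invitro_requires_functionality_score():
    c = vitro("a")
    c.functionality_score = None
    with pytest.raises(ValueError, match="functionality"):
        snpselect.filter_invitro([c])


def test_insilico_support_rules():
    rep = snpselect.filter_insilico(
        [
            silico("small_ok", depth=5, minor=2),
            silico("small_bad", depth=5, minor=1),
            silico("large_ok", depth=12, minor=4, maf=0.33),
            silico("large_bad", depth=12, minor=2, maf=0.17),
            silico("low_pb", pb=0.985),
        ]
    )
    assert sorted(rep.retained) == ["large_ok", "small_ok"]
    assert rep.rejected["small_bad"][0] == INSUFFICIENT_SUPPORT
    assert rep.rejected["large_bad"][0] == INSUFFICIENT_SUPPORT
    assert rep.rejected["low_pb"][0] == LOW_POLYBAYES


def test_insilico_clean_flank_and_unigene_cap():
    rep = snpselect.filter_insilico(
        [
            silico("dirty", neigh=(30,)),
            silico("u_a", pb=0.999, gene="u2"),
            silico("u_b", pb=0.998, gene="u2"),
            silico("u_c", pb=0.997, gene="u2"),
        ]
    )
    assert rep.rejected["dirty"][0] == NEIGHBOR_TOO_CLOSE
    assert rep.rejected["u_c"] == [UNIGENE_CAP]
    assert sorted(rep.retained) == ["u_a", "u_b"]


def test_reports_partition_input():
    cands = [vitro("a", func=0.1), vitro("b"), vitro("c", maf=0.01, gene="g3")]
    rep = snpselect.filter_invitro(cands)
    assert set(rep.retained) | set(rep.rejected) == {"a", "b", "c"}
    assert not set(rep.retained) & set(rep.rejected)


def test_format_sequence_dialects_and_parse_roundtrip():
    c = vitro("a")
    iupac = snpselect.format_sequence(c, "iupac")
    assert iupac[60] == "R" and len(iupac) == len(FLANK)
    bracket = snpselect.format_sequence(c, "bracket")
    assert bracket[60:65] == "[A/G]"
    for seq in (iupac, bracket):
        pos, alleles = snpselect.parse_sequence_record(seq)
        assert pos == 61
        assert set(alleles) == {"A", "G"}


def test_candidates_tsv_roundtrip(tmp_path):
    cands = [vitro("a", frag_pos=5), silico("b", neigh=(-10, 40))]
    path = tmp_path / "cands.tsv"
    snpselect.candidates_to_tsv(cands, path)
    back = snpselect.candidates_from_tsv(path)
    assert [c.snp_id for c in back] == ["a", "b"]
    assert back[0].fragment_pos == 5
    assert back[1].neighbor_positions == [-10, 40]
    assert back[1].polybayes_score == pytest.approx(0.995)


def test_candidate_validation():
    with pytest.raises(ValueError, match="MAF"):
        vitro("a", maf=0.7)
    with pytest.raises(ValueError, match="source"):
        SnpCandidate(
            snp_id="x", source="nope", gene_id="g", flank="ACG", position=2,
            alleles=("A", "C"), maf=0.1, depth=4, minor_count=1,
        )
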