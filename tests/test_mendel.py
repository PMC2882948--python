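import numpy as np
import pandas as pd
import pytest

from pinesnp import mendel, simdata
from pinesnp.genotypes import MISSING
from pinesnp.pedigree import Family, Pedigree


def test_duo_rule_opposite_homozygotes_only():
    for p in range(3):
        for c in range(3):
            expect = {p, c} == {0, 2}
            assert mendel.mi_duo(p, c) is expect


def test_trio_rule_examples():
    # AA x AA can only give AA
    assert mendel.mi_trio(0, 0, 1)
    assert mendel.mi_trio(0, 0, 2)
    assert not mendel.mi_trio(0, 0, 0)
    # AA x BB must give AB
    assert not mendel.mi_trio(0, 2, 1)
    assert mendel.mi_trio(0, 2, 0)
    assert mendel.mi_trio(0, 2, 2)
    # AB x AB allows anything
    for c in range(3):
        assert not mendel.mi_trio(1, 1, c)


def test_trio_degrades_to_duo_with_missing_parent():
    assert mendel.mi_trio(MISSING, 0, 2)
    assert not mendel.mi_trio(0, MISSING, 1)
    with pytest.raises(ValueError):
        mendel.mi_trio(MISSING, MISSING, 1)
    with pytest.raises(ValueError):
        mendel.mi_trio(0, 0, MISSING)


def _tiny_pedigree():
    return Pedigree(
        [
            Family("F1", "P1", "P2", ["C1", "C2"]),
            Family("F2", "P3", "P4", ["C3"], mother_genotyped=False),
        ]
    )


def _tiny_gm(values):
    return pd.DataFrame(
        values,
        index=["P1", "P2", "C1", "C2", "P3", "C3"],
        columns=["snpA", "snpB"],
        dtype=np.int8,
    )


def test_tally_planted_inconsistencies():
    # snpA: C1 inconsistent with trio (AA x AA -> AB); snpB: duo MI in F2
    gm = _tiny_gm(
        [
            [0, 1],  # P1
            [0, 1],  # P2
            [1, 0],  # C1: MI at snpA
            [0, 2],  # C2: consistent both
            [0, 0],  # P3
            [0, 2],  # C3: opposite homozygote at snpB
        ]
    )
    report = mendel.tally_mis(_tiny_pedigree(), gm)
    assert report.total_mi == 2
    assert report.per_snp["snpA"] == 1
    assert report.per_snp["snpB"] == 1
    cells = report.cells.set_index(["family_id", "snp_id"])
    assert cells.loc[("F1", "snpA"), "n_children_trio"] == 2
    assert cells.loc[("F2", "snpB"), "n_children_duo"] == 1
    assert report.n_datapoints == 12


def test_tally_handles_missing_calls():
    gm = _tiny_gm(
        [
            [0, MISSING],   # P1: snpB missing -> duo checks vs P2 only
            [0, 0],
            [2, 2],         # C1: MI at snpA (trio), MI at snpB (duo vs P2)
            [MISSING, 0],   # C2: snpA skipped
            [MISSING, 0],   # P3 missing at snpA -> C3 unchecked there
            [2, 0],
        ]
    )
    report = mendel.tally_mis(_tiny_pedigree(), gm)
    cells = report.cells.set_index(["family_id", "snp_id"])
    assert cells.loc[("F1", "snpB"), "n_children_duo"] == 2
    assert cells.loc[("F1", "snpB"), "n_mi"] == 1
    assert cells.loc[("F2", "snpA"), "n_children_trio"] == 0
    assert cells.loc[("F2", "snpA"), "n_children_duo"] == 0
    assert report.n_missing == 3


def test_exclude_pairs_removes_comparisons():
    gm = _tiny_gm(
        [[0, 0], [0, 0], [2, 2], [0, 0], [0, 0], [0, 0]]
    )
    full = mendel.tally_mis(_tiny_pedigree(), gm)
    assert full.total_mi == 2
    excl = mendel.tally_mis(
        _tiny_pedigree(), gm, exclude_pairs={("P1", "C1"), ("P2", "C1")}
    )
    assert excl.total_mi == 0


def test_zero_error_rate_implies_zero_mis(small_genotypes):
    pedigree, gm, _ = small_genotypes
    report = mendel.tally_mis(pedigree, gm)
    assert report.total_mi == 0
    assert (report.pairs["n_mi"] == 0).all()


def test_flag_outlier_pairs():
    pairs = pd.DataFrame(
        {
            "parent_id": ["P1", "P2"],
            "child_id": ["C1", "C2"],
            "family_id": ["F1", "F1"],
            "n_comparisons": [100, 100],
            "n_mi": [6, 0],
        }
    )
    pairs["mi_rate"] = pairs["n_mi"] / pairs["n_comparisons"]
    flagged = mendel.flag_outlier_pairs(pairs)
    assert list(flagged["parent_id"]) == ["P1"]


def test_attribute_outliers_child_when_parent_clean_elsewhere():
    pairs = pd.DataFrame(
        {
            "parent_id": ["P1", "P1"],
            "child_id": ["C1", "C2"],
            "family_id": ["F1", "F2"],
            "n_comparisons": [100, 100],
            "n_mi": [6, 0],
        }
    )
    pairs["mi_rate"] = pairs["n_mi"] / pairs["n_comparisons"]
    flagged = mendel.flag_outlier_pairs(pairs)
    attributed = mendel.attribute_outliers(pairs, flagged)
    assert list(attributed["attributed_to"]) == ["child"]
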