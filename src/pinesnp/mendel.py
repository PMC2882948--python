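"""Mendelian-inconsistency (MI) detection in two-generation families.

Biallelic duo rule: a genotyped parent and child are inconsistent exactly
when they are opposite homozygotes (they share no allele).  Trio rule: the
child is inconsistent when it cannot have received one allele from each
parent.  Tallies are produced per family, per SNP and per parent-offspring
pair; pairs with grossly elevated MI rates are flagged as probable
sample-handling errors and can be excluded from downstream error-rate
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING
from .pedigree import Pedigree

_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}


def _build_tables():
    duo = np.zeros((3, 3), dtype=bool)
    duo[0, 2] = duo[2, 0] = True
    trio = np.zeros((3, 3, 3), dtype=bool)
    for f in range(3):
        for m in range(3):
            possible = {a + b for a in _ALLELES[f] for b in _ALLELES[m]}
            for c in range(3):
                trio[f, m, c] = c not in possible
    return duo, trio


DUO_MI_TABLE, TRIO_MI_TABLE = _build_tables()


def mi_duo(parent_call: int, child_call: int) -> bool:
    """True iff parent and child are opposite homozygotes."""
    if parent_call == MISSING or child_call == MISSING:
        raise ValueError("duo check requires two non-missing calls")
    return bool(DUO_MI_TABLE[parent_call, child_call])


def mi_trio(father: int, mother: int, child: int) -> bool:
    """True iff the child cannot receive one allele from each parent.

    A missing parent degrades to the duo rule against the available parent.
    """
    if child == MISSING:
        raise ValueError("trio check requires a non-missing child call")
    if father == MISSING and mother == MISSING:
        raise ValueError("trio check requires at least one parent call")
    if father == MISSING:
        return mi_duo(mother, child)
    if mother == MISSING:
        return mi_duo(father, child)
    return bool(TRIO_MI_TABLE[father, mother, child])


@dataclass
class MendelReport:
    """All MI tallies for one genotype matrix against one pedigree.

    ``cells`` carries one row per (family, SNP) with the effective
    configuration after missing-data handling: how many children were
    checked against both parents (trio rule) or a single parent (duo rule),
    and the MI count.  Both expected-MI weights are linear in the child
    count, so these two tallies suffice for error-rate estimation even when
    missingness mixes configurations within one family.
    """

    cells: pd.DataFrame          # family_id, snp_id, n_parents_obs, n_children_trio, n_children_duo, n_mi
    pairs: pd.DataFrame          # parent_id, child_id, n_comparisons, n_mi, mi_rate
    per_snp: pd.Series           # snp_id -> total MI count
    n_datapoints: int            # non-missing calls over pedigree individuals
    n_missing: int

    @property
    def total_mi(self) -> int:
        return int(self.cells["n_mi"].sum())


def tally_mis(
    pedigree: Pedigree,
    gm: pd.DataFrame,
    exclude_pairs: set[tuple[str, str]] | None = None,
) -> MendelReport:
    """Count MIs per family, SNP and parent-offspring pair.

    Individuals absent from ``gm`` are treated as un-genotyped.  A child
    with no genotyped parent is excluded (with a warning).  ``exclude_pairs``
    — (parent_id, child_id) tuples, e.g. from :func:`flag_outlier_pairs` —
    removes those comparisons: the child is checked only against its
    remaining parent, or skipped entirely.
    """
    import warnings

    exclude_pairs = exclude_pairs or set()
    snps = gm.columns
    S = len(snps)
    missing_row = np.full(S, MISSING, dtype=np.int8)

    def calls_for(ind: str, genotyped: bool) -> np.ndarray:
        if genotyped and ind in gm.index:
            return gm.loc[ind].to_numpy()
        return missing_row

    cell_rows = []
    pair_rows = []
    per_snp = np.zeros(S, dtype=int)
    n_obs = 0
    n_miss = 0
    for fam in pedigree.families:
        father = calls_for(fam.father_id, fam.father_genotyped)
        mother = calls_for(fam.mother_id, fam.mother_genotyped)
        n_mi = np.zeros(S, dtype=int)
        m_trio = np.zeros(S, dtype=int)
        m_duo = np.zeros(S, dtype=int)
        for ind, row in (
            [(fam.father_id, father), (fam.mother_id, mother)]
            if fam.n_genotyped_parents == 2
            else [(fam.genotyped_parent_ids[0],
                   father if fam.father_genotyped else mother)]
        ):
            n_obs += int((row != MISSING).sum())
            n_miss += int((row == MISSING).sum())
        for cid in fam.child_ids:
            child = calls_for(cid, True)
            n_obs += int((child != MISSING).sum())
            n_miss += int((child == MISSING).sum())
            fa = father if (fam.father_id, cid) not in exclude_pairs else missing_row
            mo = mother if (fam.mother_id, cid) not in exclude_pairs else missing_row
            c_ok = child != MISSING
            f_ok = fa != MISSING
            m_ok = mo != MISSING
            any_parent = f_ok | m_ok
            usable = c_ok & any_parent
            if not usable.any() and not any_parent.any():
                warnings.warn(
                    f"child {cid}: no genotyped parent, excluded from tallies"
                )
            both = usable & f_ok & m_ok
            solo_f = usable & f_ok & ~m_ok
            solo_m = usable & m_ok & ~f_ok
            mi = np.zeros(S, dtype=bool)
            mi[both] = TRIO_MI_TABLE[fa[both], mo[both], child[both]]
            mi[solo_f] = DUO_MI_TABLE[fa[solo_f], child[solo_f]]
            mi[solo_m] = DUO_MI_TABLE[mo[solo_m], child[solo_m]]
            n_mi += mi
            m_trio += both
            m_duo += solo_f | solo_m

            # pairwise duo reports against each genotyped parent
            for pid, prow, ok in (
                (fam.father_id, fa, f_ok),
                (fam.mother_id, mo, m_ok),
            ):
                if not ok.any():
                    continue
                comp = ok & c_ok
                duo = DUO_MI_TABLE[prow[comp], child[comp]]
                pair_rows.append(
                    {
                        "parent_id": pid,
                        "child_id": cid,
                        "family_id": fam.family_id,
                        "n_comparisons": int(comp.sum()),
                        "n_mi": int(duo.sum()),
                    }
                )
        per_snp += n_mi
        # effective parent count per (family, snp)
        f_ok = father != MISSING
        m_ok = mother != MISSING
        npar = f_ok.astype(int) + m_ok.astype(int)
        for j, snp in enumerate(snps):
            cell_rows.append(
                {
                    "family_id": fam.family_id,
                    "snp_id": snp,
                    "n_parents_obs": int(npar[j]),
                    "n_children_trio": int(m_trio[j]),
                    "n_children_duo": int(m_duo[j]),
                    "n_mi": int(n_mi[j]),
                }
            )

    pairs = pd.DataFrame(
        pair_rows,
        columns=["parent_id", "child_id", "family_id", "n_comparisons", "n_mi"],
    )
    if len(pairs):
        pairs["mi_rate"] = pairs["n_mi"] / pairs["n_comparisons"]
    else:
        pairs["mi_rate"] = pd.Series(dtype=float)
    return MendelReport(
        cells=pd.DataFrame(cell_rows),
        pairs=pairs,
        per_snp=pd.Series(per_snp, index=snps, name="n_mi"),
        n_datapoints=n_obs,
        n_missing=n_miss,
    )


def flag_outlier_pairs(
    pairs: pd.DataFrame, rate_threshold: float = 0.04
) -> pd.DataFrame:
    """Parent-offspring pairs whose MI rate signals sample handling errors.

    The default threshold is the lower edge of the elevated band observed
    for probable laboratory mix-ups (MI rates of several percent, far above
    any plausible per-call error rate).
    """
    if (pairs["n_comparisons"] <= 0).any():
        raise ValueError("pairs need at least one comparison")
    return pairs[pairs["mi_rate"] >= rate_threshold].copy()


def attribute_outliers(
    pairs: pd.DataFrame, flagged: pd.DataFrame
) -> pd.DataFrame:
    """Advisory attribution of flagged pairs to the offspring sample.

    A flagged pair's MIs are attributed to the child when the parent looks
    consistent (no flagged pair) in at least one other family; otherwise
    the attribution is left undetermined.
    """
    out = flagged.copy()
    attribution = []
    flagged_keys = set(zip(flagged["parent_id"], flagged["child_id"]))
    for _, row in flagged.iterrows():
        others = pairs[
            (pairs["parent_id"] == row["parent_id"])
            & (pairs["family_id"] != row["family_id"])
        ]
        clean_elsewhere = any(
            (p, c) not in flagged_keys
            for p, c in zip(others["parent_id"], others["child_id"])
        )
        attribution.append("child" if clean_elsewhere else "undetermined")
    out["attributed_to"] = attribution
    return out
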