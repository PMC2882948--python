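"""Two-generation pedigree structures and PLINK-style pedigree file I/O.

The assay's breeding-population data consist of unrelated nuclear families:
a pair of founder parents (one or both of which may be genotyped) and their
full-sib offspring.  Families never share founders, and no deeper pedigree
structure is represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

MISSING_PARENT = "0"


@dataclass
class Family:
    """One nuclear family: two founder parents and their children.

    ``father_genotyped`` / ``mother_genotyped`` record whether the parent was
    assayed; an un-genotyped parent still exists in the mating structure (its
    alleles are drawn from the population) but contributes no genotype calls.
    """

    family_id: str
    father_id: str
    mother_id: str
    child_ids: list[str] = field(default_factory=list)
    father_genotyped: bool = True
    mother_genotyped: bool = True

    @property
    def m(self) -> int:
        """Number of children."""
        return len(self.child_ids)

    @property
    def n_genotyped_parents(self) -> int:
        return int(self.father_genotyped) + int(self.mother_genotyped)

    @property
    def genotyped_parent_ids(self) -> list[str]:
        ids = []
        if self.father_genotyped:
            ids.append(self.father_id)
        if self.mother_genotyped:
            ids.append(self.mother_id)
        return ids


@dataclass
class Pedigree:
    families: list[Family]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_parents: set[str] = set()
        seen_children: set[str] = set()
        for fam in self.families:
            if fam.m < 1:
                raise ValueError(f"family {fam.family_id} has no children")
            if fam.father_id == fam.mother_id:
                raise ValueError(f"family {fam.family_id}: identical parents")
            for pid in (fam.father_id, fam.mother_id):
                if pid in seen_parents:
                    raise ValueError(f"founder {pid} shared between families")
            if set(fam.child_ids) & (seen_parents | seen_children):
                raise ValueError(
                    f"family {fam.family_id}: child id reused elsewhere"
                )
            if set(fam.child_ids) & {fam.father_id, fam.mother_id}:
                raise ValueError(
                    f"family {fam.family_id}: child listed as its own parent"
                )
            seen_parents.update((fam.father_id, fam.mother_id))
            seen_children.update(fam.child_ids)

    @property
    def genotyped_individuals(self) -> list[str]:
        """All individuals expected to carry genotype calls."""
        ids: list[str] = []
        for fam in self.families:
            ids.extend(fam.genotyped_parent_ids)
            ids.extend(fam.child_ids)
        return ids

    @property
    def n_individuals(self) -> int:
        return sum(fam.m + 2 for fam in self.families)

    def to_ped_file(self, path: str | Path) -> None:
        """Write a tab-separated pedigree file.

        Columns: family_id, individual_id, father_id, mother_id, with ``0``
        for an unknown (un-genotyped) parent.  Genotyped parents get their own
        founder rows with both parent slots unknown.
        """
        lines = []
        for fam in self.families:
            if fam.father_genotyped:
                lines.append(
                    (fam.family_id, fam.father_id, MISSING_PARENT, MISSING_PARENT)
                )
            if fam.mother_genotyped:
                lines.append(
                    (fam.family_id, fam.mother_id, MISSING_PARENT, MISSING_PARENT)
                )
            fa = fam.father_id if fam.father_genotyped else MISSING_PARENT
            mo = fam.mother_id if fam.mother_genotyped else MISSING_PARENT
            for cid in fam.child_ids:
                lines.append((fam.family_id, cid, fa, mo))
        Path(path).write_text(
            "\n".join("\t".join(row) for row in lines) + "\n"
        )

    @classmethod
    def from_ped_file(cls, path: str | Path) -> "Pedigree":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed pedigree line: {line!r}")
            rows.append(parts[:4])
        founders = {iid for _, iid, fa, mo in rows
                    if fa == MISSING_PARENT and mo == MISSING_PARENT}
        fams: dict[str, Family] = {}
        for fam_id, iid, fa, mo in rows:
            if fa == MISSING_PARENT and mo == MISSING_PARENT:
                continue  # founder row; attached via its children
            key = (fam_id, fa, mo)
            fam = fams.get(key)
            if fam is None:
                fam = Family(
                    family_id=fam_id,
                    father_id=fa if fa != MISSING_PARENT else f"{fam_id}_UF",
                    mother_id=mo if mo != MISSING_PARENT else f"{fam_id}_UM",
                    child_ids=[],
                    father_genotyped=fa in founders,
                    mother_genotyped=mo in founders,
                )
                fams[key] = fam
            fam.child_ids.append(iid)
        return cls(list(fams.values()))


def make_families(
    spec: Iterable[tuple[int, int]], prefix: str = "FAM"
) -> list[Family]:
    """Build disjoint families from (n_genotyped_parents, n_children) pairs."""
    families = []
    for i, (n_par, m) in enumerate(spec, start=1):
        if m < 1:
            raise ValueError("each family needs at least one child (m >= 1)")
        if n_par not in (1, 2):
            raise ValueError("n_genotyped_parents must be 1 or 2")
        fid = f"{prefix}{i:03d}"
        families.append(
            Family(
                family_id=fid,
                father_id=f"{fid}_P1",
                mother_id=f"{fid}_P2",
                child_ids=[f"{fid}_C{j:02d}" for j in range(1, m + 1)],
                father_genotyped=True,
                mother_genotyped=(n_par == 2),
            )
        )
    return families
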