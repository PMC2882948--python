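"""Candidate-SNP filtering for array design, plus assay-design sequence export.

Two discovery routes feed the array:

* **in vitro** candidates from re-sequenced amplicons (haploid
  megagametophyte panels), filtered on the external design tool's
  functionality score, a 60-nt spacing rule, a minor-allele-frequency floor
  and within-fragment linkage-disequilibrium pruning;
* **in silico** candidates mined from EST assemblies, filtered on the
  PolyBayes posterior, minor-allele support appropriate to the contig depth,
  a clean 60-base flank and a per-unigene cap.

Filters run in a fixed, documented order so that per-stage discard counts
are reproducible.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# rejection reason codes
LOW_FUNCTIONALITY = "LOW_FUNCTIONALITY"
NEIGHBOR_TOO_CLOSE = "NEIGHBOR_TOO_CLOSE"
RARE_VARIANT = "RARE_VARIANT"
LOW_POLYBAYES = "LOW_POLYBAYES"
INSUFFICIENT_SUPPORT = "INSUFFICIENT_SUPPORT"
LD_PRUNED = "LD_PRUNED"
UNIGENE_CAP = "UNIGENE_CAP"

_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_IUPAC_REV = {v: tuple(sorted(k)) for k, v in _IUPAC.items()}


@dataclass
class SnpCandidate:
    """One candidate polymorphism with its flanking sequence and provenance.

    ``position`` is the 1-based offset of the variant inside ``flank``;
    ``fragment_pos`` locates the variant within its gene fragment / contig
    (needed by the spacing rule); ``neighbor_positions`` are signed offsets
    (in bases, relative to the variant) of other known polymorphisms in the
    same fragment.  ``depth`` counts the discovery sequences (haploid samples
    in vitro, ESTs in silico) and ``minor_count`` how many carried the minor
    allele.
    """

    snp_id: str
    source: str                     # "in_vitro" | "in_silico"
    gene_id: str
    flank: str
    position: int
    alleles: tuple[str, str]
    maf: float
    depth: int
    minor_count: int
    functionality_score: float | None = None
    polybayes_score: float | None = None
    neighbor_positions: list[int] = field(default_factory=list)
    fragment_pos: int | None = None

    def __post_init__(self) -> None:
        if self.source not in ("in_vitro", "in_silico"):
            raise ValueError(f"unknown source {self.source!r}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: MAF must be in [0, 0.5]")
        if self.minor_count > self.depth:
            raise ValueError(f"{self.snp_id}: minor_count exceeds depth")
        if not 1 <= self.position <= len(self.flank):
            raise ValueError(f"{self.snp_id}: variant position outside flank")
        a, b = self.alleles
        if a == b:
            raise ValueError(f"{self.snp_id}: alleles must be distinct")


@dataclass
class SelectionReport:
    """Outcome of one filtering pass.

    ``rejected`` maps snp_id to an ordered reason list whose first element is
    the filter that actually removed the SNP in the sequential pass; any
    further elements are other marginally applicable reasons.
    """

    retained: list[str]
    rejected: dict[str, list[str]]

    def first_reason_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for reasons in self.rejected.values():
            out[reasons[0]] = out.get(reasons[0], 0) + 1
        return out

    def reason_counts(self) -> dict[str, int]:
        """Marginal tallies: a SNP may count under several reasons."""
        out: dict[str, int] = {}
        for reasons in self.rejected.values():
            for r in set(reasons):
                out[r] = out.get(r, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"snp_id": s, "retained": True, "reasons": ""} for s in self.retained
        ] + [
            {"snp_id": s, "retained": False, "reasons": ";".join(r)}
            for s, r in self.rejected.items()
        ]
        return pd.DataFrame(rows).sort_values("snp_id", ignore_index=True)


def _check_partition(candidates, report: SelectionReport) -> SelectionReport:
    ids = {c.snp_id for c in candidates}
    assert set(report.retained) | set(report.rejected) == ids
    assert not set(report.retained) & set(report.rejected)
    return report


def filter_invitro(
    candidates: list[SnpCandidate],
    min_functionality: float = 0.4,
    min_spacing: int = 60,
    min_maf: float = 0.05,
    ld_r2_max: float = 0.8,
    haplotypes: dict[str, np.ndarray] | None = None,
) -> SelectionReport:
    """Sequential in vitro filters: functionality, spacing, rarity, LD.

    Spacing: while two surviving SNPs of the same fragment sit fewer than
    ``min_spacing`` nucleotides apart, the lower-MAF member of the closest
    violating pair is dropped (MAF ties: the lexicographically later snp_id).
    LD pruning (only when discovery-panel ``haplotypes`` are supplied, one
    0/1 vector per snp_id with -1 for missing) drops the downstream SNP of
    any within-fragment pair with r-squared above ``ld_r2_max``.
    """
    for c in candidates:
        if c.source != "in_vitro":
            raise ValueError(f"{c.snp_id}: filter_invitro needs in_vitro SNPs")
        if c.functionality_score is None:
            raise ValueError(f"{c.snp_id}: functionality score is mandatory")

    rejected: dict[str, list[str]] = {}

    def reject(c: SnpCandidate, reason: str) -> None:
        rejected[c.snp_id] = [reason]

    alive = []
    for c in candidates:
        if c.functionality_score < min_functionality:
            reject(c, LOW_FUNCTIONALITY)
        else:
            alive.append(c)

    # spacing within fragments
    by_gene: dict[str, list[SnpCandidate]] = {}
    for c in alive:
        by_gene.setdefault(c.gene_id, []).append(c)
    for gene, group in by_gene.items():
        if any(c.fragment_pos is None for c in group):
            if len(group) > 1:
                raise ValueError(
                    f"fragment {gene}: fragment_pos required for spacing filter"
                )
            continue
        group = sorted(group, key=lambda c: (c.fragment_pos, c.snp_id))
        while True:
            pairs = [
                (abs(a.fragment_pos - b.fragment_pos), a, b)
                for i, a in enumerate(group)
                for b in group[i + 1:]
                if abs(a.fragment_pos - b.fragment_pos) < min_spacing
            ]
            if not pairs:
                break
            pairs.sort(key=lambda t: (t[0], t[1].snp_id, t[2].snp_id))
            _, a, b = pairs[0]
            if a.maf != b.maf:
                victim = a if a.maf < b.maf else b
            else:
                victim = max(a, b, key=lambda c: c.snp_id)
            reject(victim, NEIGHBOR_TOO_CLOSE)
            group.remove(victim)
        by_gene[gene] = group
    alive = [c for c in alive if c.snp_id not in rejected]

    survivors = []
    for c in alive:
        if c.maf < min_maf:
            reject(c, RARE_VARIANT)
        else:
            survivors.append(c)

    if haplotypes is not None:
        by_gene = {}
        for c in survivors:
            by_gene.setdefault(c.gene_id, []).append(c)
        for gene, group in by_gene.items():
            group = sorted(
                group, key=lambda c: (c.fragment_pos or 0, c.snp_id)
            )
            kept: list[SnpCandidate] = []
            for c in group:
                pruned = False
                for k in kept:
                    r2 = _r_squared(haplotypes.get(k.snp_id), haplotypes.get(c.snp_id))
                    if r2 is not None and r2 > ld_r2_max:
                        reject(c, LD_PRUNED)
                        pruned = True
                        break
                if not pruned:
                    kept.append(c)
        survivors = [c for c in survivors if c.snp_id not in rejected]

    # append marginally applicable secondary reasons
    by_id = {c.snp_id: c for c in candidates}
    for sid, reasons in rejected.items():
        c = by_id[sid]
        if c.functionality_score < min_functionality and LOW_FUNCTIONALITY not in reasons:
            reasons.append(LOW_FUNCTIONALITY)
        if c.maf < min_maf and RARE_VARIANT not in reasons:
            reasons.append(RARE_VARIANT)

    report = SelectionReport(
        retained=[c.snp_id for c in survivors], rejected=rejected
    )
    return _check_partition(candidates, report)


def _r_squared(h1, h2) -> float | None:
    """Squared correlation between two haploid 0/1 vectors (-1 = missing)."""
    if h1 is None or h2 is None:
        return None
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    ok = (h1 >= 0) & (h2 >= 0)
    if ok.sum() < 2:
        return None
    x, y = h1[ok], h2[ok]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def filter_insilico(
    candidates: list[SnpCandidate],
    min_polybayes: float = 0.99,
    min_depth: int = 4,
    small_panel_max: int = 10,
    min_minor_count: int = 2,
    large_panel_min_maf: float = 0.20,
    clean_flank: int = 60,
    unigene_cap: int | None = 2,
) -> SelectionReport:
    """EST-derived SNP filters.

    A candidate is retained when its PolyBayes posterior reaches
    ``min_polybayes``, its allele support fits the panel size (minor allele
    seen at least ``min_minor_count`` times within ``min_depth`` to
    ``small_panel_max`` ESTs, or MAF above ``large_panel_min_maf`` with more
    than ``small_panel_max`` ESTs), no other polymorphism lies within
    ``clean_flank`` bases, and its unigene has spare capacity (best PolyBayes
    scores first).
    """
    rejected: dict[str, list[str]] = {}
    for c in candidates:
        if c.source != "in_silico":
            raise ValueError(f"{c.snp_id}: filter_insilico needs in_silico SNPs")

    alive = []
    for c in candidates:
        score = c.polybayes_score
        if score is None or score < min_polybayes:
            rejected[c.snp_id] = [LOW_POLYBAYES]
        else:
            alive.append(c)

    survivors = []
    for c in alive:
        if c.depth <= small_panel_max:
            ok = c.depth >= min_depth and c.minor_count >= min_minor_count
        else:
            ok = c.maf > large_panel_min_maf
        if ok:
            survivors.append(c)
        else:
            rejected[c.snp_id] = [INSUFFICIENT_SUPPORT]
    alive, survivors = survivors, []

    for c in alive:
        if any(abs(off) <= clean_flank for off in c.neighbor_positions):
            rejected[c.snp_id] = [NEIGHBOR_TOO_CLOSE]
        else:
            survivors.append(c)

    if unigene_cap is not None:
        by_gene: dict[str, list[SnpCandidate]] = {}
        for c in survivors:
            by_gene.setdefault(c.gene_id, []).append(c)
        survivors = []
        for gene, group in by_gene.items():
            group.sort(key=lambda c: (-(c.polybayes_score or 0), c.snp_id))
            survivors.extend(group[:unigene_cap])
            for c in group[unigene_cap:]:
                rejected[c.snp_id] = [UNIGENE_CAP]

    # secondary marginal reasons
    for c in candidates:
        if c.snp_id not in rejected:
            continue
        reasons = rejected[c.snp_id]
        if (c.polybayes_score is None or c.polybayes_score < min_polybayes) \
                and LOW_POLYBAYES not in reasons:
            reasons.append(LOW_POLYBAYES)
        small = c.depth <= small_panel_max
        supported = (
            c.depth >= min_depth and c.minor_count >= min_minor_count
            if small else c.maf > large_panel_min_maf
        )
        if not supported and INSUFFICIENT_SUPPORT not in reasons:
            reasons.append(INSUFFICIENT_SUPPORT)
        if any(abs(off) <= clean_flank for off in c.neighbor_positions) \
                and NEIGHBOR_TOO_CLOSE not in reasons:
            reasons.append(NEIGHBOR_TOO_CLOSE)

    retained = sorted(c.snp_id for c in survivors)
    report = SelectionReport(retained=retained, rejected=rejected)
    return _check_partition(candidates, report)


# ---------------------------------------------------------------------------
# Assay-design sequence export


def format_sequence(c: SnpCandidate, dialect: str = "iupac") -> str:
    """Flank with the variant site rewritten for the assay-design tool.

    dialect "iupac": the variant base becomes its degenerate IUPAC code;
    dialect "bracket": it becomes ``[X/Y]``.
    """
    a, b = (x.upper() for x in c.alleles)
    i = c.position - 1
    if dialect == "iupac":
        code = _IUPAC.get(frozenset((a, b)))
        if code is None:
            raise ValueError(f"{c.snp_id}: alleles {c.alleles} have no IUPAC code")
        site = code
    elif dialect == "bracket":
        site = f"[{a}/{b}]"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return c.flank[:i] + site + c.flank[i + 1:]


def export_sequence_list(
    candidates: list[SnpCandidate],
    path: str | Path | None = None,
    dialect: str = "iupac",
) -> pd.DataFrame:
    """Assay-design records (Locus_Name, Sequence), optionally written as CSV."""
    rows = [
        {"Locus_Name": c.snp_id, "Sequence": format_sequence(c, dialect)}
        for c in candidates
    ]
    frame = pd.DataFrame(rows, columns=["Locus_Name", "Sequence"])
    if path is not None:
        frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
    return frame


_BRACKET_RE = re.compile(r"\[([ACGT])/([ACGT])\]")


def parse_sequence_record(sequence: str) -> tuple[int, tuple[str, str]]:
    """Recover (1-based variant position, allele pair) from an exported record."""
    m = _BRACKET_RE.search(sequence)
    if m:
        if _BRACKET_RE.search(sequence, m.end()):
            raise ValueError("multiple bracketed variant sites")
        return m.start() + 1, (m.group(1), m.group(2))
    hits = [
        (i, ch) for i, ch in enumerate(sequence) if ch in _IUPAC_REV
    ]
    if len(hits) != 1:
        raise ValueError(
            f"expected exactly one degenerate base, found {len(hits)}"
        )
    i, ch = hits[0]
    return i + 1, _IUPAC_REV[ch]


# ---------------------------------------------------------------------------
# Tabular I/O


def candidates_to_tsv(candidates: list[SnpCandidate], path: str | Path) -> None:
    rows = []
    for c in candidates:
        rows.append(
            {
                "snp_id": c.snp_id, "source": c.source, "gene_id": c.gene_id,
                "flank": c.flank, "position": c.position,
                "allele_a": c.alleles[0], "allele_b": c.alleles[1],
                "maf": c.maf, "depth": c.depth, "minor_count": c.minor_count,
                "functionality_score": c.functionality_score,
                "polybayes_score": c.polybayes_score,
                "neighbor_positions": ",".join(map(str, c.neighbor_positions)),
                "fragment_pos": c.fragment_pos,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def candidates_from_tsv(path: str | Path) -> list[SnpCandidate]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        neigh = (
            [int(x) for x in str(r["neighbor_positions"]).split(",") if x]
            if pd.notna(r.get("neighbor_positions")) else []
        )
        out.append(
            SnpCandidate(
                snp_id=str(r["snp_id"]), source=str(r["source"]),
                gene_id=str(r["gene_id"]), flank=str(r["flank"]),
                position=int(r["position"]),
                alleles=(str(r["allele_a"]), str(r["allele_b"])),
                maf=float(r["maf"]), depth=int(r["depth"]),
                minor_count=int(r["minor_count"]),
                functionality_score=(
                    float(r["functionality_score"])
                    if pd.notna(r["functionality_score"]) else None
                ),
                polybayes_score=(
                    float(r["polybayes_score"])
                    if pd.notna(r["polybayes_score"]) else None
                ),
                neighbor_positions=neigh,
                fragment_pos=(
                    int(r["fragment_pos"]) if pd.notna(r["fragment_pos"]) else None
                ),
            )
        )
    return out
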