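"""Synthetic-data generators for every stage of the array-design pipeline.

The generators emulate the statistical structure of a GoldenGate SNP assay in
an outcrossing conifer breeding population:

* biallelic genotypes in Hardy-Weinberg equilibrium among founders, with
  Mendelian transmission to full-sib offspring in unrelated two-generation
  families;
* genotype-level error injection at a per-call rate ``pi`` (an erroneous call
  is replaced by one of the two other genotypes, uniformly);
* two-channel fluorescence clusters on the normalized theta axis at
  {0, 0.5, 1}, with optional "cluster compression" shifts of the B-homozygote
  cluster and subgroup splits of monomorphic clusters;
* EST contig alignments whose variant columns mix true SNPs with
  sequencing-error pseudo-SNPs.

All randomness flows from a single integer seed; each operation draws from
its own documented substream so that adding one stage never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING
from .pedigree import Family, Pedigree, make_families

# Default family structure: 17 unrelated families with 26 genotyped parents
# (9 families with both parents, 8 with one) and 75 genotyped offspring
# (7 families of 5 children, 10 of 4).
DEFAULT_FAMILY_SPEC: tuple[tuple[int, int], ...] = (
    ((2, 5),) * 7 + ((2, 4),) * 2 + ((1, 4),) * 8
)

# Fixed substream identifiers: operation name -> spawn key.
_STREAMS = {
    "pedigree": 0,
    "genotypes": 1,
    "errors": 2,
    "intensities": 3,
    "est": 4,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, reproducible RNG for one named pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class IntensitySpec:
    """Cluster geometry and noise for two-channel intensity simulation.

    theta_means are the genotype cluster centres for (AA, AB, BB); theta_sd is
    the Gaussian dispersion on the theta axis (truncated to [0, 1]); total
    signal R is log-normal.  ``compression_shift`` moves the BB cluster mean
    toward the A side by that amount; ``subgroup_offset`` splits a monomorphic
    cluster by displacing a fraction of the samples.
    """

    theta_means: tuple[float, float, float] = (0.03, 0.5, 0.97)
    theta_sd: float = 0.03
    r_mean: float = 1.0
    r_sigma: float = 0.2
    compression_shift: float = 0.0
    subgroup_offset: float = 0.0
    subgroup_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.theta_sd < 0 or self.r_sigma < 0:
            raise ValueError("dispersions must be non-negative")
        if not all(0.0 <= t <= 1.0 for t in self.theta_means):
            raise ValueError("theta cluster means must lie in [0, 1]")
        if len(set(self.theta_means)) != 3:
            raise ValueError("cluster means must be distinct")
        if not 0.0 <= self.compression_shift <= 0.5:
            raise ValueError("compression_shift must be in [0, 0.5]")


@dataclass
class EstSpec:
    """EST contig-alignment simulation parameters.

    Depth (reads per contig) is drawn uniformly from ``depth_choices``; true
    SNPs occur independently per reference base with probability
    ``snp_density`` and segregate at minor-allele frequency ``snp_maf``;
    every base of every read is independently mis-read (substituted by a
    uniformly chosen different base) with probability ``base_error_rate``.
    """

    n_contigs: int = 20
    contig_length: int = 500
    depth_choices: tuple[int, ...] = (4, 5, 6, 8, 10)
    base_error_rate: float = 0.001
    snp_density: float = 0.01
    snp_maf: float = 0.3

    def __post_init__(self) -> None:
        if min(self.depth_choices) < 2:
            raise ValueError("non-singleton contigs need depth >= 2")
        for p in (self.base_error_rate, self.snp_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities")
        if not 0.0 <= self.snp_maf <= 0.5:
            raise ValueError("snp_maf must be in [0, 0.5]")


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults reproduce the error-rate analysis conditions: 188 polymorphic
    SNPs, a 212-sample unrelated founder panel for allele-frequency
    estimation, 17 unrelated families (26 genotyped parents, 75 offspring)
    and a per-call genotyping error rate of 0.005.
    """

    n_snps: int = 188
    allele_freq_range: tuple[float, float] = (0.1, 0.5)
    allele_freqs: tuple[float, ...] | None = None
    n_founders: int = 212
    family_spec: tuple[tuple[int, int], ...] = DEFAULT_FAMILY_SPEC
    error_rate: float = 0.005
    intensity_spec: IntensitySpec = field(default_factory=IntensitySpec)
    est_spec: EstSpec = field(default_factory=EstSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.allele_freqs is not None:
            if any(not 0.0 <= p <= 1.0 for p in self.allele_freqs):
                raise ValueError("allele frequencies must be in [0, 1]")
        lo, hi = self.allele_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("allele_freq_range must be within [0, 1]")
        for n_par, m in self.family_spec:
            if m < 1:
                raise ValueError("family children count m must be >= 1")
            if n_par not in (1, 2):
                raise ValueError("genotyped parents per family must be 1 or 2")

    def draw_freqs(self, rng: np.random.Generator) -> np.ndarray:
        if self.allele_freqs is not None:
            if len(self.allele_freqs) != self.n_snps:
                raise ValueError("allele_freqs length must equal n_snps")
            return np.asarray(self.allele_freqs, dtype=float)
        lo, hi = self.allele_freq_range
        return rng.uniform(lo, hi, self.n_snps)


@dataclass
class GenotypeTruth:
    """Ground truth accompanying a simulated genotype matrix."""

    freqs: pd.Series                      # per-SNP true B-allele frequency
    true_genotypes: pd.DataFrame          # all individuals, incl. un-genotyped parents
    errors: pd.DataFrame                  # one row per injected corruption


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Disjoint two-generation families following ``config.family_spec``."""
    if not config.family_spec:
        raise ValueError("family_spec must be non-empty")
    return Pedigree(make_families(config.family_spec))


def snp_ids(n: int) -> list[str]:
    return [f"SNP{i:04d}" for i in range(1, n + 1)]


def _mate(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per SNP from a diploid genotype-code vector."""
    het = parent == 1
    gam = parent // 2
    gam[het] = rng.integers(0, 2, het.sum())
    return gam


def simulate_genotypes(
    pedigree: Pedigree,
    freqs: np.ndarray | pd.Series,
    seed: int = 0,
    n_panel: int = 0,
) -> tuple[pd.DataFrame, GenotypeTruth]:
    """HWE founders, Mendelian transmission, optional unrelated panel.

    Returns the genotype matrix restricted to genotyped individuals (parents
    flagged genotyped, all children, and ``n_panel`` extra unrelated samples
    named ``PANEL###``) plus the full truth table.
    """
    rng = stream_rng(seed, "genotypes")
    p = np.asarray(freqs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    cols = (
        list(freqs.index)
        if isinstance(freqs, pd.Series)
        else snp_ids(len(p))
    )
    S = len(p)

    truth_rows: dict[str, np.ndarray] = {}
    observed_ids: list[str] = []
    for fam in pedigree.families:
        father = rng.binomial(2, p)
        mother = rng.binomial(2, p)
        truth_rows[fam.father_id] = father
        truth_rows[fam.mother_id] = mother
        observed_ids.extend(fam.genotyped_parent_ids)
        for cid in fam.child_ids:
            truth_rows[cid] = _mate(father, rng) + _mate(mother, rng)
            observed_ids.append(cid)
    for i in range(1, n_panel + 1):
        sid = f"PANEL{i:03d}"
        truth_rows[sid] = rng.binomial(2, p)
        observed_ids.append(sid)

    truth = pd.DataFrame.from_dict(truth_rows, orient="index", dtype=np.int8)
    truth.columns = cols
    truth.index.name = "sample_id"
    gm = truth.loc[observed_ids].copy()
    gt = GenotypeTruth(
        freqs=pd.Series(p, index=cols, name="freq"),
        true_genotypes=truth,
        errors=pd.DataFrame(columns=["sample_id", "snp_id", "true", "observed"]),
    )
    return gm, gt


def inject_errors(
    gm: pd.DataFrame,
    pi: float | np.ndarray | pd.Series,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt each non-missing call independently with probability ``pi``.

    ``pi`` may be a scalar or a per-SNP vector aligned with ``gm``'s columns.
    A corrupted call is replaced by one of the two other genotypes with equal
    probability.  Returns the corrupted matrix and a table of corruptions.
    """
    rng = stream_rng(seed, "errors")
    if np.isscalar(pi):
        pi_arr = np.full(gm.shape[1], float(pi))
    else:
        pi_ser = pd.Series(pi)
        pi_arr = (
            pi_ser.reindex(gm.columns).to_numpy(dtype=float)
            if isinstance(pi, pd.Series)
            else np.asarray(pi, dtype=float)
        )
    if np.any((pi_arr < 0) | (pi_arr > 1)) or np.any(np.isnan(pi_arr)):
        raise ValueError("error rate pi must be in [0, 1] for every SNP")

    vals = gm.to_numpy(copy=True)
    hit = (rng.random(vals.shape) < pi_arr[None, :]) & (vals != MISSING)
    # +1 or +2 mod 3 maps a genotype to one of the two others, uniformly
    shift = rng.integers(1, 3, vals.shape)
    corrupted = (vals + shift) % 3
    out = np.where(hit, corrupted, vals).astype(np.int8)

    rows, colix = np.nonzero(hit)
    errors = pd.DataFrame(
        {
            "sample_id": gm.index.to_numpy()[rows],
            "snp_id": gm.columns.to_numpy()[colix],
            "true": vals[rows, colix].astype(int),
            "observed": out[rows, colix].astype(int),
        }
    )
    return pd.DataFrame(out, index=gm.index, columns=gm.columns), errors


# ---------------------------------------------------------------------------
# Two-channel intensities


def theta_r_to_channels(theta: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert theta = (2/pi)*arctan(cy5/cy3), r = cy3 + cy5.

    theta = 0 maps to (r, 0); theta = 1 maps to (0, r).
    """
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    t = np.tan(theta * np.pi / 2.0)
    with np.errstate(over="ignore", invalid="ignore"):
        cy3 = np.where(np.isinf(t), 0.0, r / (1.0 + t))
    cy5 = r - cy3
    return cy3, cy5


def _truncnorm(
    mean: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return mean.astype(float)
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def simulate_intensities(
    gm: pd.DataFrame,
    spec: IntensitySpec | None = None,
    seed: int = 0,
    compression_snps: list[str] | None = None,
    subgroup_snps: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw (theta, R) per call around its genotype cluster, emit (Cy3, Cy5).

    ``compression_snps`` restricts the compression shift to those SNPs (all
    SNPs when None and ``spec.compression_shift > 0``); likewise
    ``subgroup_snps`` for the subgroup split, which displaces a seeded
    fraction of each affected SNP's samples by ``subgroup_offset``.
    Missing calls yield no-signal records (both channels zero).

    Returns a long table (sample_id, snp_id, cy3, cy5) and a truth table with
    the sampled theta and R values.
    """
    spec = spec or IntensitySpec()
    rng = stream_rng(seed, "intensities")
    vals = gm.to_numpy()
    n, S = vals.shape
    means = np.asarray(spec.theta_means)[np.where(vals == MISSING, 0, vals)]

    comp = set(compression_snps) if compression_snps is not None else set(gm.columns)
    sub = set(subgroup_snps) if subgroup_snps is not None else set()
    for j, snp in enumerate(gm.columns):
        if spec.compression_shift > 0 and snp in comp:
            bb = vals[:, j] == 2
            means[bb, j] = spec.theta_means[2] - spec.compression_shift
        if spec.subgroup_offset > 0 and snp in sub:
            pick = rng.random(n) < spec.subgroup_fraction
            means[pick, j] = np.clip(
                means[pick, j] + spec.subgroup_offset, 0.0, 1.0
            )

    theta = _truncnorm(means, spec.theta_sd, rng)
    r = rng.lognormal(math.log(spec.r_mean), spec.r_sigma, size=(n, S))
    missing = vals == MISSING
    theta = np.where(missing, np.nan, theta)
    r = np.where(missing, 0.0, r)
    cy3, cy5 = theta_r_to_channels(np.where(missing, 0.0, theta), r)

    idx = pd.MultiIndex.from_product(
        [gm.index, gm.columns], names=["sample_id", "snp_id"]
    )
    table = pd.DataFrame(
        {"cy3": cy3.ravel(), "cy5": cy5.ravel()}, index=idx
    ).reset_index()
    truth = pd.DataFrame(
        {
            "theta": theta.ravel(),
            "r": np.where(missing, np.nan, r).ravel(),
            "genotype": vals.ravel(),
        },
        index=idx,
    ).reset_index()
    return table, truth


# ---------------------------------------------------------------------------
# EST contigs

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_est_contigs(
    spec: EstSpec | None = None, seed: int = 0
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Ungapped EST contig alignments with true SNPs and sequencing errors.

    Returns ``{contig_id: [read sequences]}`` plus a truth table with one row
    per variant column: contig, position (1-based), depth, minor-allele
    count and whether the column is a true SNP or an error-induced
    pseudo-SNP.  A column that mixes a true SNP with an extra sequencing
    error stays labelled as a true SNP.
    """
    spec = spec or EstSpec()
    rng = stream_rng(seed, "est")
    contigs: dict[str, list[str]] = {}
    rows = []
    for c in range(1, spec.n_contigs + 1):
        cid = f"CTG{c:04d}"
        L = spec.contig_length
        ref = rng.integers(0, 4, L)
        depth = int(rng.choice(spec.depth_choices))
        is_snp = rng.random(L) < spec.snp_density
        alt = (ref + rng.integers(1, 4, L)) % 4
        reads = np.tile(ref, (depth, 1))
        # true SNPs segregate among reads at the specified MAF
        carrier = rng.random((depth, L)) < spec.snp_maf
        snp_cols = np.where(is_snp)[0]
        for j in snp_cols:
            reads[carrier[:, j], j] = alt[j]
        # per-base sequencing errors
        err = rng.random((depth, L)) < spec.base_error_rate
        reads = np.where(err, (reads + rng.integers(1, 4, (depth, L))) % 4, reads)

        seqs = ["".join(_BASES[row].astype(str)) for row in reads]
        contigs[cid] = seqs
        variant = (reads != ref[None, :]).any(axis=0)
        for j in np.where(variant | is_snp)[0]:
            col = reads[:, j]
            counts = np.bincount(col, minlength=4)
            major = int(np.argmax(counts))
            minor_count = int(depth - counts[major])
            rows.append(
                {
                    "contig": cid,
                    "position": int(j + 1),
                    "depth": depth,
                    "minor_count": minor_count,
                    "maf": minor_count / depth,
                    "is_true_snp": bool(is_snp[j]),
                    "is_variant_column": bool(variant[j]),
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "contig", "position", "depth", "minor_count", "maf",
            "is_true_snp", "is_variant_column",
        ],
    )
    return contigs, truth


def write_contigs_fasta(contigs: dict[str, list[str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=f"{cid}_read{i+1}", description="")
        for cid, seqs in contigs.items()
        for i, seq in enumerate(seqs)
    ]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Candidate panels for the selection filters


def _flank(rng: np.random.Generator, half: int = 60) -> tuple[str, int]:
    seq = "".join(rng.choice(list("ACGT"), 2 * half + 1))
    return seq, half + 1


def invitro_accounting_panel(seed: int = 0):
    """448 resequencing-derived candidates with a planned filter accounting.

    Construction: 155 candidates with functionality score below 0.4; 81
    close-spaced pairs whose lower-MAF member falls to the 60-nt spacing rule
    (the higher-MAF member survives); 28 rare variants (MAF < 5%); and 103
    further clean candidates.  Sequential filtering therefore discards
    155 + 81 + 28 and retains 184.
    """
    from .snpselect import SnpCandidate

    rng = np.random.default_rng(seed)
    panel: list[SnpCandidate] = []
    k = 0

    def new_id():
        nonlocal k
        k += 1
        return f"VIT{k:04d}"

    def cand(gene, maf, func, frag_pos):
        flank, pos = _flank(rng)
        return SnpCandidate(
            snp_id=new_id(), source="in_vitro", gene_id=gene, flank=flank,
            position=pos, alleles=("A", "G"), maf=maf, depth=50,
            minor_count=max(1, round(maf * 50)), functionality_score=func,
            fragment_pos=frag_pos,
        )

    for i in range(155):
        panel.append(cand(f"gene_f{i:03d}", 0.25, 0.30, 100))
    for i in range(81):
        g = f"gene_s{i:03d}"
        panel.append(cand(g, 0.30, 0.90, 100))   # survivor
        panel.append(cand(g, 0.10, 0.90, 150))   # 50 nt away, lower MAF
    for i in range(28):
        panel.append(cand(f"gene_r{i:03d}", 0.03, 0.85, 100))
    for i in range(103):
        panel.append(cand(f"gene_c{i:03d}", 0.30, 0.92, 100))
    return panel


def insilico_panel_from_contigs(
    truth: pd.DataFrame,
    polybayes_score: float = 0.995,
    seed: int = 0,
):
    """Turn simulated EST variant columns into in-silico candidates.

    The PolyBayes probability is an external input in the real pipeline; here
    every candidate receives ``polybayes_score`` so that tests can isolate
    the minor-allele-count / MAF support rules.  Neighbour offsets are the
    distances to the other variant columns of the same contig.
    """
    from .snpselect import SnpCandidate

    rng = np.random.default_rng(seed)
    panel = []
    by_contig = truth.groupby("contig")["position"].apply(list).to_dict()
    for i, row in truth.iterrows():
        flank, pos = _flank(rng)
        neighbors = [
            int(q - row["position"])
            for q in by_contig[row["contig"]]
            if q != row["position"]
        ]
        panel.append(
            SnpCandidate(
                snp_id=f"SIL{i+1:05d}",
                source="in_silico",
                gene_id=str(row["contig"]),
                flank=flank,
                position=pos,
                alleles=("C", "T"),
                maf=min(row["maf"], 1 - row["maf"]),
                depth=int(row["depth"]),
                minor_count=int(row["minor_count"]),
                polybayes_score=polybayes_score,
                functionality_score=0.9,
                neighbor_positions=neighbors,
                fragment_pos=int(row["position"]),
            )
        )
    return panel


# ---------------------------------------------------------------------------
# Full-assay composition

#: Assay composition used by default in the end-to-end simulation: category
#: counts (polymorphic / monomorphic / compressed / subgroup-or-abnormal /
#: low-quality) chosen to match the 384-SNP assay outcome: 197 polymorphic,
#: 60 monomorphic, and 127 failures of which 9 show cluster compression,
#: 9 are monomorphic artifacts and the rest fail on cluster separation.
DEFAULT_ASSAY_COMPOSITION = {
    "polymorphic": 197,
    "monomorphic": 60,
    "compressed": 9,
    "subgroup": 9,
    "low_quality": 109,
}


def simulate_assay(
    n_samples: int = 96,
    composition: dict[str, int] | None = None,
    seed: int = 0,
    theta_sd: float = 0.03,
    compression_shift: float = 0.25,
    subgroup_offset: float = 0.18,
    low_quality_sd: float = 0.35,
):
    """Simulate a complete assay's intensity table with per-SNP truth.

    Returns (intensity table, truth DataFrame with columns snp_id,
    true_status, artifact) where true_status is the classification the QC
    stage should recover (``failed`` / ``monomorphic`` / ``polymorphic``).
    """
    comp = dict(DEFAULT_ASSAY_COMPOSITION if composition is None else composition)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    total = sum(comp.values())
    ids = snp_ids(total)
    labels = [lab for lab, n in comp.items() for _ in range(n)]

    tables = []
    truth_rows = []
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    for snp, lab in zip(ids, labels):
        p = rng.uniform(0.1, 0.5)
        if lab == "polymorphic":
            g = rng.binomial(2, p, n_samples)
            # guarantee at least two genotype classes at moderate n
            if len(np.unique(g)) < 2:
                g[0] = 1
            spec = IntensitySpec(theta_sd=theta_sd)
            status, artifact = "polymorphic", "none"
        elif lab == "monomorphic":
            g = np.zeros(n_samples, dtype=int)
            spec = IntensitySpec(theta_sd=theta_sd)
            status, artifact = "monomorphic", "none"
        elif lab == "compressed":
            g = rng.binomial(2, max(p, 0.35), n_samples)
            g[:3] = (0, 1, 2)
            spec = IntensitySpec(
                theta_sd=theta_sd, compression_shift=compression_shift
            )
            status, artifact = "failed", "compression"
        elif lab == "subgroup":
            g = np.zeros(n_samples, dtype=int)
            spec = IntensitySpec(
                theta_sd=theta_sd, subgroup_offset=subgroup_offset
            )
            status, artifact = "failed", "subgroup"
        elif lab == "low_quality":
            g = rng.binomial(2, max(p, 0.3), n_samples)
            spec = IntensitySpec(theta_sd=low_quality_sd)
            status, artifact = "failed", "low_quality"
        else:
            raise ValueError(f"unknown assay category {lab!r}")
        gdf = pd.DataFrame(
            g[:, None], index=pd.Index(samples, name="sample_id"), columns=[snp]
        )
        sub = [snp] if lab == "subgroup" else []
        tab, _ = simulate_intensities(
            gdf, spec, seed=int(rng.integers(2**31)), subgroup_snps=sub
        )
        tables.append(tab)
        truth_rows.append(
            {"snp_id": snp, "true_status": status, "artifact": artifact,
             "source": "in_vitro" if rng.random() < 184 / 384 else "in_silico"}
        )
    return pd.concat(tables, ignore_index=True), pd.DataFrame(truth_rows)
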