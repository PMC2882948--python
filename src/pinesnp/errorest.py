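"""Genotyping-error-rate estimation from Mendelian-inconsistency counts.

Model
-----
Each genotype call is independently wrong with probability ``pi``; an
erroneous call shows one of the two other genotypes with equal probability.
At a biallelic marker with population allele frequency ``p`` (Hardy-Weinberg
founders, Mendelian transmission, q = 1 - p), the expected number of MIs in
a family with m genotyped children is, to first order in ``pi``,
``pi * P_MI`` with

    one genotyped parent:   P_MI = m * (1 - 2 p q)
    both parents genotyped: P_MI = m * (2 - 3 p q)

Both closed forms were derived by exhaustive enumeration of every genotype
configuration and every single-error substitution, and the enumeration is
retained here (:func:`p_mi_oracle`) as an independent check.  The estimator
is method-of-moments: pooled over families and SNPs,

    pi_hat = sum(observed MI counts) / sum(P_MI),

with a per-SNP version of the same ratio; a per-SNP-then-average variant is
exposed behind a flag.  The first-order approximation is accurate in the
regime of interest (pi well below 1%); markers with very high error rates
saturate (some errors mask each other), which biases the pooled mean upward
relative to the error-free majority — identifying and removing such markers
is precisely the point of the per-SNP ranking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mendel import DUO_MI_TABLE, TRIO_MI_TABLE

_ALLELES = {0: (0,), 1: (0, 1), 2: (1,)}


def per_child_weight(p, parents_genotyped: int):
    """Expected-MI weight contributed by one genotyped child.

    ``1 - 2pq`` under the duo rule, ``2 - 3pq`` under the trio rule; the
    family weight is linear in the number of children.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency p must be in [0, 1]")
    pq = p * (1.0 - p)
    if parents_genotyped == 1:
        return 1.0 - 2.0 * pq
    if parents_genotyped == 2:
        return 2.0 - 3.0 * pq
    raise ValueError("parents_genotyped must be 1 or 2")


def p_mi_closed_form(p, m: int, parents_genotyped: int):
    """Closed-form expected-MI weight P_MI for one family at one marker."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return m * per_child_weight(p, parents_genotyped)


def _uniform_error_targets(g: int):
    """(observed genotype, probability) pairs for one erroneous call."""
    return [(h, 0.5) for h in range(3) if h != g]


def p_mi_oracle(
    p: float,
    m: int,
    parents_genotyped: int,
    error_model=None,
    family_event: bool = False,
) -> float:
    """Enumeration oracle for the expected-MI weight.

    Enumerates every true genotype configuration of the family under
    HWE(p) founders and Mendelian transmission, places a single genotyping
    error at each possible position (every genotyped individual) under
    ``error_model`` (a callable genotype -> [(observed, prob), ...];
    default uniform substitution), and accumulates the resulting number of
    detectable MIs.  The result is the first-order coefficient such that
    expected MIs ~ pi * P_MI as pi -> 0.

    ``family_event=True`` instead accumulates the indicator that the family
    shows at least one MI (the per-family event convention); with a single
    parent error several children can be inconsistent simultaneously, so
    the two conventions differ.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1 or m > 8:
        raise ValueError("oracle enumeration supports 1 <= m <= 8")
    if parents_genotyped not in (1, 2):
        raise ValueError("parents_genotyped must be 1 or 2")
    error_model = error_model or _uniform_error_targets

    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])

    def mi_count(f_obs, m_obs, kids_obs) -> int:
        n = 0
        for c in kids_obs:
            if parents_genotyped == 2:
                n += TRIO_MI_TABLE[f_obs, m_obs, c]
            else:
                n += DUO_MI_TABLE[f_obs, c]
        return int(n)

    def contribution(f_obs, m_obs, kids_obs) -> float:
        n = mi_count(f_obs, m_obs, kids_obs)
        return float(n > 0) if family_event else float(n)

    total = 0.0
    for f, mo in itertools.product(range(3), repeat=2):
        w_par = hwe[f] * hwe[mo]
        if w_par == 0.0:
            continue
        # children are i.i.d. given the parents
        child_probs = np.zeros(3)
        for a in _ALLELES[f]:
            for b in _ALLELES[mo]:
                child_probs[a + b] += 1.0 / (len(_ALLELES[f]) * len(_ALLELES[mo]))
        for kids in itertools.product(range(3), repeat=m):
            w_kids = np.prod(child_probs[list(kids)])
            if w_kids == 0.0:
                continue
            w = w_par * w_kids
            # error in the genotyped father
            for obs, q in error_model(f):
                total += w * q * contribution(obs, mo, kids)
            if parents_genotyped == 2:
                for obs, q in error_model(mo):
                    total += w * q * contribution(f, obs, kids)
            # error in one child
            for i in range(m):
                for obs, q in error_model(kids[i]):
                    k = list(kids)
                    k[i] = obs
                    total += w * q * contribution(f, mo, k)
    return total


def p_mi_monte_carlo(
    p: float,
    m: int,
    parents_genotyped: int,
    pi: float = 1e-3,
    n_families: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo slope estimate of P_MI plus its standard error.

    Simulates ``n_families`` independent families at a small error rate and
    returns (mean MI count / pi, standard error on the same scale) — a
    second, fully independent cross-check of the enumeration.
    """
    rng = np.random.default_rng(seed)
    father = rng.binomial(2, p, n_families)
    mother = rng.binomial(2, p, n_families)

    def gametes(parent):
        het = parent == 1
        g = np.repeat(parent[None, :] // 2, m, axis=0)
        g[:, het] = rng.integers(0, 2, (m, het.sum()))
        return g

    kids = gametes(father) + gametes(mother)

    def corrupt(g):
        hit = rng.random(g.shape) < pi
        return np.where(hit, (g + rng.integers(1, 3, g.shape)) % 3, g)

    f_obs = corrupt(father)
    kids_obs = corrupt(kids)
    if parents_genotyped == 2:
        m_obs = corrupt(mother)
        mi = TRIO_MI_TABLE[f_obs[None, :], m_obs[None, :], kids_obs]
    else:
        mi = DUO_MI_TABLE[f_obs[None, :], kids_obs]
    counts = mi.sum(axis=0)
    return float(counts.mean() / pi), float(
        counts.std(ddof=1) / np.sqrt(n_families) / pi
    )


@dataclass
class ErrorRateEstimate:
    pi_global: float
    pi_per_snp: pd.Series          # NaN where the SNP's weight sum is zero
    observed_mi_total: int
    sum_p_mi: float
    n_datapoints: int | None = None

    @property
    def n_zero_mi_snps(self) -> int:
        """SNPs with an estimable, exactly null per-SNP error rate."""
        return int((self.pi_per_snp == 0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pi": self.pi_per_snp}
        ).rename_axis("snp_id").reset_index()


def estimate_pi(
    cells: pd.DataFrame,
    freqs: pd.Series,
    n_datapoints: int | None = None,
    method: str = "pooled",
) -> ErrorRateEstimate:
    """Estimate the genotyping error rate from MI tallies.

    ``cells`` is the per-(family, SNP) tally from :func:`pinesnp.mendel.tally_mis`
    (columns snp_id, n_children_trio, n_children_duo, n_mi) — with outlier
    pairs already excluded when desired — and ``freqs`` the per-SNP allele
    frequency estimated on unrelated founders.  ``method="pooled"`` divides
    total observed MIs by the total expected weight; ``method="per_snp_mean"``
    averages the per-SNP ratios instead (and leaves the per-SNP table
    unchanged).
    """
    if method not in ("pooled", "per_snp_mean"):
        raise ValueError(f"unknown method {method!r}")
    p = pd.Series(freqs).reindex(cells["snp_id"]).to_numpy(dtype=float)
    if np.isnan(p).any():
        missing = sorted(
            set(cells["snp_id"]) - set(pd.Series(freqs).dropna().index)
        )
        raise ValueError(f"no allele frequency for SNPs: {missing[:5]}...")
    pq = p * (1.0 - p)
    w = (
        cells["n_children_trio"].to_numpy() * (2.0 - 3.0 * pq)
        + cells["n_children_duo"].to_numpy() * (1.0 - 2.0 * pq)
    )
    tab = pd.DataFrame(
        {"snp_id": cells["snp_id"], "mi": cells["n_mi"], "w": w}
    )
    grp = tab.groupby("snp_id", sort=True).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = pd.Series(
            np.where(grp["w"] > 0, grp["mi"] / grp["w"], np.nan),
            index=grp.index,
            name="pi",
        )
    sum_w = float(grp["w"].sum())
    total_mi = int(grp["mi"].sum())
    if sum_w == 0:
        raise ValueError(
            "total expected-MI weight is zero: no informative family/SNP cells"
        )
    if method == "pooled":
        pi_global = total_mi / sum_w
    else:
        pi_global = float(per_snp.dropna().mean())
    return ErrorRateEstimate(
        pi_global=float(pi_global),
        pi_per_snp=per_snp,
        observed_mi_total=total_mi,
        sum_p_mi=sum_w,
        n_datapoints=n_datapoints,
    )


def rank_error_prone_snps(
    estimate: ErrorRateEstimate,
    strata: tuple[float, float] = (0.0, 0.05),
) -> pd.DataFrame:
    """Per-SNP error rates ranked descending, with reporting strata.

    Strata: exactly zero, (0, strata[1]] ("low"), and above ("elevated").
    Non-estimable SNPs (zero weight) are listed last with stratum
    "not_estimable".
    """
    lo, hi = strata
    per = estimate.pi_per_snp

    def stratum(x: float) -> str:
        if np.isnan(x):
            return "not_estimable"
        if x <= lo:
            return "zero"
        if x <= hi:
            return "low"
        return "elevated"

    frame = pd.DataFrame({"pi": per})
    frame["stratum"] = [stratum(x) for x in per]
    frame = frame.sort_values(
        ["pi"], ascending=False, na_position="last", kind="mergesort"
    )
    return frame.rename_axis("snp_id").reset_index()
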