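"""Two-channel intensity transform, genotype cluster calling, and SNP QC.

The polar transform maps dye intensities (Cy3, Cy5) to

    theta = (2/pi) * arctan(Cy5 / Cy3),     R = Cy3 + Cy5,

so homozygote A sits near theta = 0, homozygote B near theta = 1 and
heterozygotes near 0.5.  Genotypes are called per SNP from one-dimensional
Gaussian mixtures on theta (1 to 3 components, quantile-initialised,
BIC-selected, hence deterministic).  The vendor's proprietary cluster and
call quality scores are replaced by documented surrogates on the same [0, 1]
scale and the same 0.25 cutoffs: a between-cluster separation score stands
in for the training score, the posterior probability of the assigned
component for the per-call score.  Vendor scores, when supplied, override
the surrogates.

A SNP fails QC when its cluster score is below the cutoff, when a
homozygous cluster mean leaves the [0, 0.1] u [0.9, 1] theta ranges
("cluster compression", a paralog-crosstalk signature), when a monomorphic
SNP's single cluster sits at an abnormal theta, or when a monomorphic
cluster splits into distinct subgroups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .genotypes import MISSING

FAILED = "failed"
MONOMORPHIC = "monomorphic"
POLYMORPHIC = "polymorphic"

LOW_GENTRAIN = "LOW_GENTRAIN"
COMPRESSION = "COMPRESSION"
ABNORMAL_THETA = "ABNORMAL_THETA"
SUBGROUPS = "SUBGROUPS"
OK = "OK"

#: theta ranges a homozygous cluster mean must occupy
HOMOZYGOTE_THETA_RANGES = ((0.0, 0.1), (0.9, 1.0))


def compute_theta_r(cy3, cy5):
    """Polar transform of the two dye channels.

    Returns (theta, r, no_signal).  theta is 0 when Cy5 = 0, exactly 1 when
    Cy3 = 0 and Cy5 > 0 (the limit value).  Records with both channels zero
    are flagged no-signal and get theta = NaN.
    """
    cy3 = np.asarray(cy3, dtype=float)
    cy5 = np.asarray(cy5, dtype=float)
    if np.any(cy3 < 0) or np.any(cy5 < 0):
        raise ValueError("channel intensities must be non-negative")
    no_signal = (cy3 == 0) & (cy5 == 0)
    theta = (2.0 / np.pi) * np.arctan2(cy5, cy3)
    theta = np.where(no_signal, np.nan, theta)
    r = cy3 + cy5
    return theta, r, no_signal


@dataclass
class ClusterModel:
    """Fitted genotype clusters for one SNP plus per-sample calls."""

    snp_id: str
    n_clusters: int
    means: np.ndarray                 # ascending theta order
    sds: np.ndarray
    genotype_map: np.ndarray          # cluster index -> genotype code 0/1/2
    gentrain: float                   # cluster-quality score in [0, 1]
    sample_ids: np.ndarray
    calls: np.ndarray                 # genotype codes, -1 for missing
    gencall: np.ndarray               # per-call confidence in [0, 1]

    @property
    def observed_genotypes(self) -> np.ndarray:
        return np.unique(self.calls[self.calls != MISSING])


@dataclass
class SnpClassification:
    snp_id: str
    status: str
    reason: str

    def __post_init__(self) -> None:
        failing = self.reason in (LOW_GENTRAIN, COMPRESSION, ABNORMAL_THETA, SUBGROUPS)
        if (self.status == FAILED) != failing:
            raise ValueError("status/reason mismatch")


def _fit_gmm(theta: np.ndarray, k: int) -> GaussianMixture:
    # Two deterministic initialisations: quantile placement (robust to
    # unequal cluster sizes when clusters are balanced-ish) and an even
    # spread over the data range (finds small clusters at the extremes that
    # quantile placement starves).  Keep the better fit by likelihood.
    X = theta.reshape(-1, 1)
    inits = [np.quantile(theta, (np.arange(k) + 0.5) / k)]
    if k > 1:
        inits.append(np.linspace(theta.min(), theta.max(), k))
    best = None
    for init in inits:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            means_init=init.reshape(-1, 1),
            n_init=1,
            max_iter=300,
            reg_covar=1e-6,
            random_state=0,
        )
        gm.fit(X)
        if best is None or gm.score(X) > best.score(X):
            best = gm
    return best


def _select_mixture(theta: np.ndarray, k_max: int = 3):
    """BIC-selected 1- to 3-component mixture on theta."""
    k_cap = min(k_max, len(np.unique(np.round(theta, 6))))
    best, best_bic = None, np.inf
    X = theta.reshape(-1, 1)
    for k in range(1, max(k_cap, 1) + 1):
        gm = _fit_gmm(theta, k)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    return best


def _separation_score(means: np.ndarray, sds: np.ndarray) -> float:
    """Surrogate cluster-quality score.

    Multi-cluster SNPs: smallest adjacent-cluster separation in units of the
    summed dispersions, squashed to [0, 1); a well separated clean assay
    scores near 1, overlapping clusters near 0.  Single-cluster SNPs: scored
    on cluster tightness (dispersion relative to a 0.1 theta scale).
    """
    if len(means) == 1:
        return float(np.exp(-sds[0] / 0.1))
    gaps = np.diff(means)
    sep = np.min(gaps / (2.0 * (sds[:-1] + sds[1:]) + 1e-12))
    return float(1.0 - np.exp(-sep / 2.0))


def _assign_genotypes(means: np.ndarray) -> np.ndarray:
    """Map ascending component means to genotype codes (AA=0, AB=1, BB=2).

    Each component takes the nearest canonical theta in {0, 0.5, 1}.  Two
    components may then share a genotype.  A shared homozygote is kept: the
    boundary truncation of a homozygote cloud is often over-fitted by two
    components, and collapsing them restores the single genotype cluster
    (a genuinely split homozygote is caught by the subgroup check).  A
    shared heterozygote cannot arise from truncation — it means an extra
    cluster sits in the interior, e.g. a compressed homozygote riding on
    the het cloud — so the components are reassigned to distinct genotypes
    by minimum total distance, exposing the out-of-range homozygote to the
    compression check.
    """
    canon = np.array([0.0, 0.5, 1.0])
    nearest = np.array([int(np.argmin(np.abs(canon - m))) for m in means])
    if np.count_nonzero(nearest == 1) > 1:
        k = len(means)
        best, best_cost = None, np.inf
        for combo in itertools.combinations(range(3), k):
            cost = sum(abs(means[i] - canon[g]) for i, g in enumerate(combo))
            if cost < best_cost:
                best, best_cost = combo, cost
        return np.array(best)
    return nearest


def _collapse_by_genotype(
    means: np.ndarray, sds: np.ndarray, weights: np.ndarray,
    genotype_map: np.ndarray,
):
    """Merge mixture components assigned to the same genotype.

    Returns moment-matched (means, sds, genotype codes) for the distinct
    genotype-level clusters, in ascending theta order.
    """
    c_means, c_sds, c_map = [], [], []
    for g in sorted(set(genotype_map.tolist())):
        ix = genotype_map == g
        w, m, s = weights[ix], means[ix], sds[ix]
        total = w.sum()
        mu = float((w * m).sum() / total)
        var = float((w * (s**2 + m**2)).sum() / total - mu**2)
        c_means.append(mu)
        c_sds.append(np.sqrt(max(var, 0.0)))
        c_map.append(g)
    order = np.argsort(c_means)
    return (
        np.asarray(c_means)[order],
        np.asarray(c_sds)[order],
        np.asarray(c_map)[order],
    )


def call_genotypes(
    records: pd.DataFrame,
    snp_id: str | None = None,
    gencall_cutoff: float = 0.25,
    gentrain_cutoff: float = 0.25,
    min_samples: int = 10,
) -> ClusterModel:
    """Cluster one SNP's samples on theta and call genotypes.

    ``records`` needs columns sample_id, cy3, cy5 (or precomputed theta);
    optional vendor columns ``gentrain`` and ``gencall`` override the
    surrogate scores.  Calls whose confidence falls below ``gencall_cutoff``
    are set missing.
    """
    snp_id = snp_id or (
        str(records["snp_id"].iloc[0]) if "snp_id" in records else "SNP"
    )
    sample_ids = records["sample_id"].to_numpy()
    if "theta" in records.columns:
        theta = records["theta"].to_numpy(dtype=float)
        no_signal = np.isnan(theta)
    else:
        theta, _, no_signal = compute_theta_r(
            records["cy3"].to_numpy(), records["cy5"].to_numpy()
        )

    n = len(sample_ids)
    calls = np.full(n, MISSING, dtype=np.int8)
    gencall = np.zeros(n)
    good = ~no_signal
    if good.sum() == 0:
        return ClusterModel(
            snp_id=snp_id, n_clusters=0, means=np.array([]), sds=np.array([]),
            genotype_map=np.array([], dtype=int), gentrain=0.0,
            sample_ids=sample_ids, calls=calls, gencall=gencall,
        )
    if good.sum() < min_samples:
        raise ValueError(
            f"{snp_id}: need at least {min_samples} samples with signal"
        )

    th = theta[good]
    gm = _select_mixture(th)
    order = np.argsort(gm.means_.ravel())
    comp_means = gm.means_.ravel()[order]
    comp_sds = np.sqrt(gm.covariances_.ravel()[order])
    comp_weights = gm.weights_.ravel()[order]
    post = gm.predict_proba(th.reshape(-1, 1))[:, order]
    comp_map = _assign_genotypes(comp_means)

    # genotype-level clusters: components sharing a genotype merge, and the
    # per-call confidence is the posterior mass of the assigned genotype
    means, sds, genotype_map = _collapse_by_genotype(
        comp_means, comp_sds, comp_weights, comp_map
    )
    geno_post = np.column_stack(
        [post[:, comp_map == g].sum(axis=1) for g in genotype_map]
    )
    cluster_ix = np.argmax(geno_post, axis=1)
    conf = geno_post[np.arange(len(th)), cluster_ix]

    gentrain = _separation_score(means, sds)
    if "gentrain" in records.columns and records["gentrain"].notna().any():
        gentrain = float(records["gentrain"].dropna().iloc[0])
    if "gencall" in records.columns and records["gencall"].notna().all():
        conf = records["gencall"].to_numpy(dtype=float)[good]

    g = genotype_map[cluster_ix].astype(np.int8)
    g[conf < gencall_cutoff] = MISSING
    calls[good] = g
    gencall[good] = conf
    return ClusterModel(
        snp_id=snp_id, n_clusters=len(means), means=means, sds=sds,
        genotype_map=genotype_map, gentrain=gentrain,
        sample_ids=sample_ids, calls=calls, gencall=gencall,
    )


def _in_homozygote_range(theta_mean: float) -> bool:
    return any(lo <= theta_mean <= hi for lo, hi in HOMOZYGOTE_THETA_RANGES)


def detect_compression(model: ClusterModel) -> str:
    """Compression / abnormal-theta check on the fitted cluster means.

    Polymorphic patterns: any homozygote-assigned cluster mean outside
    [0, 0.1] u [0.9, 1] signals cluster compression.  Monomorphic patterns
    (single cluster): a mean outside those ranges is an abnormal-theta
    failure.
    """
    if model.n_clusters == 0:
        return OK
    if model.n_clusters == 1:
        return OK if _in_homozygote_range(model.means[0]) else ABNORMAL_THETA
    for mean, g in zip(model.means, model.genotype_map):
        if g in (0, 2) and not _in_homozygote_range(mean):
            return COMPRESSION
    return OK


def detect_subgroups(
    theta: np.ndarray, min_gap: float = 0.1
) -> str:
    """Subgroup check within a monomorphic SNP's single cluster.

    Fits 1- versus 2-component mixtures on theta; reports SUBGROUPS when the
    2-component fit wins on BIC *and* the subcluster means sit more than
    ``min_gap`` apart (the separation floor keeps noise-driven splits out).
    """
    theta = np.asarray(theta, dtype=float)
    theta = theta[~np.isnan(theta)]
    if len(theta) < 4 or len(np.unique(theta)) < 2:
        return OK
    X = theta.reshape(-1, 1)
    g1 = _fit_gmm(theta, 1)
    g2 = _fit_gmm(theta, 2)
    if g2.bic(X) < g1.bic(X):
        means = np.sort(g2.means_.ravel())
        if means[1] - means[0] > min_gap:
            return SUBGROUPS
    return OK


def classify_snp(
    model: ClusterModel,
    compression: str = OK,
    subgroup: str = OK,
    gentrain_cutoff: float = 0.25,
) -> SnpClassification:
    """Combine the QC checks into failed / monomorphic / polymorphic."""
    if model.n_clusters == 0 or model.gentrain < gentrain_cutoff:
        return SnpClassification(model.snp_id, FAILED, LOW_GENTRAIN)
    if subgroup != OK:
        return SnpClassification(model.snp_id, FAILED, subgroup)
    if compression != OK:
        return SnpClassification(model.snp_id, FAILED, compression)
    observed = model.observed_genotypes
    if len(observed) <= 1:
        return SnpClassification(model.snp_id, MONOMORPHIC, OK)
    return SnpClassification(model.snp_id, POLYMORPHIC, OK)


def classify_assay(
    intensities: pd.DataFrame,
    gencall_cutoff: float = 0.25,
    gentrain_cutoff: float = 0.25,
    subgroup_min_gap: float = 0.1,
):
    """Run the full QC pipeline over a long intensity table.

    Returns (classification frame, genotype matrix, cluster summary).  The
    genotype matrix keeps calls only for successfully genotyped SNPs.
    """
    class_rows, summary_rows, call_cols = [], [], {}
    sample_index = None
    for snp, grp in intensities.groupby("snp_id", sort=True):
        grp = grp.reset_index(drop=True)
        model = call_genotypes(
            grp, snp_id=str(snp),
            gencall_cutoff=gencall_cutoff, gentrain_cutoff=gentrain_cutoff,
        )
        compression = detect_compression(model)
        subgroup = OK
        if model.n_clusters >= 1 and len(model.observed_genotypes) <= 1:
            if "theta" in grp.columns:
                theta = grp["theta"].to_numpy(dtype=float)
            else:
                theta, _, _ = compute_theta_r(
                    grp["cy3"].to_numpy(), grp["cy5"].to_numpy()
                )
            subgroup = detect_subgroups(theta, min_gap=subgroup_min_gap)
        cls = classify_snp(
            model, compression, subgroup, gentrain_cutoff=gentrain_cutoff
        )
        class_rows.append(
            {"snp_id": cls.snp_id, "status": cls.status, "reason": cls.reason}
        )
        summary_rows.append(
            {
                "snp_id": model.snp_id,
                "n_clusters": model.n_clusters,
                "means": ",".join(f"{m:.4f}" for m in model.means),
                "gentrain": model.gentrain,
                "call_rate": float(np.mean(model.calls != MISSING)),
            }
        )
        if cls.status != FAILED:
            if sample_index is None:
                sample_index = model.sample_ids
            call_cols[model.snp_id] = pd.Series(
                model.calls, index=model.sample_ids
            )
    classifications = pd.DataFrame(class_rows)
    summary = pd.DataFrame(summary_rows)
    gm = pd.DataFrame(call_cols)
    gm.index.name = "sample_id"
    return classifications, gm.astype(np.int8) if len(gm) else gm, summary


def call_rates(gm: pd.DataFrame):
    """Per-SNP and per-sample call rates (1 minus the missing fraction)."""
    obs = gm != MISSING
    return obs.mean(axis=0).rename("snp_call_rate"), obs.mean(axis=1).rename(
        "sample_call_rate"
    )


def plot_clusters(intensities: pd.DataFrame, snp_id: str, path: str | Path):
    """Scatter of (theta, R) for one SNP, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grp = intensities[intensities["snp_id"] == snp_id]
    theta, r, _ = compute_theta_r(grp["cy3"].to_numpy(), grp["cy5"].to_numpy())
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(theta, r, s=12, alpha=0.7)
    ax.set_xlim(-0.02, 1.02)
    ax.set_xlabel("normalized theta")
    ax.set_ylabel("normalized R")
    ax.set_title(snp_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
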