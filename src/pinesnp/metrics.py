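"""Assay-level statistics: success/conversion rates, contrasts, MAF spectra,
and sequencing-vs-genotyping allele-frequency concordance.

Definitions (per the GoldenGate QC vocabulary):

* **success rate** = 100 * (monomorphic + polymorphic) / total SNPs;
* **conversion rate** = 100 * polymorphic / total SNPs.

Group contrasts use the chi-square test on 2x2 tables with Yates continuity
correction by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .clusterqc import FAILED, MONOMORPHIC, POLYMORPHIC

_STATUSES = (FAILED, MONOMORPHIC, POLYMORPHIC)


@dataclass
class GroupCounts:
    n_failed: int
    n_monomorphic: int
    n_polymorphic: int

    @property
    def n_total(self) -> int:
        return self.n_failed + self.n_monomorphic + self.n_polymorphic

    @property
    def n_successful(self) -> int:
        return self.n_monomorphic + self.n_polymorphic

    def success_rate(self) -> float:
        return 100.0 * self.n_successful / self.n_total

    def conversion_rate(self) -> float:
        return 100.0 * self.n_polymorphic / self.n_total

    def monomorphic_among_successful(self) -> float:
        return 100.0 * self.n_monomorphic / self.n_successful

    # exact rational forms, for callers that must not lose precision
    def success_rate_exact(self) -> Fraction:
        return Fraction(100 * self.n_successful, self.n_total)

    def conversion_rate_exact(self) -> Fraction:
        return Fraction(100 * self.n_polymorphic, self.n_total)


@dataclass
class AssayRates:
    """Per-category counts and rates, overall and per SNP source."""

    overall: GroupCounts
    per_source: dict[str, GroupCounts]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name, g in [("overall", self.overall)] + sorted(self.per_source.items()):
            rows.append(
                {
                    "group": name,
                    "n_total": g.n_total,
                    "n_failed": g.n_failed,
                    "n_monomorphic": g.n_monomorphic,
                    "n_polymorphic": g.n_polymorphic,
                    "success_rate_pct": round(g.success_rate(), 1),
                    "conversion_rate_pct": round(g.conversion_rate(), 1),
                }
            )
        return pd.DataFrame(rows)


def assay_rates(
    statuses: pd.Series | dict, sources: pd.Series | dict
) -> AssayRates:
    """Tally classifications into success and conversion rates.

    ``statuses`` maps snp_id to failed/monomorphic/polymorphic and
    ``sources`` to its discovery route (in_vitro / in_silico).
    """
    st = pd.Series(statuses)
    src = pd.Series(sources).reindex(st.index)
    bad = set(st.unique()) - set(_STATUSES)
    if bad:
        raise ValueError(f"unknown status labels: {sorted(bad)}")
    if src.isna().any():
        raise ValueError("every SNP needs a source label")
    bad_src = set(src.unique()) - {"in_vitro", "in_silico"}
    if bad_src:
        raise ValueError(f"unknown source labels: {sorted(bad_src)}")

    def counts(mask) -> GroupCounts:
        sub = st[mask]
        return GroupCounts(
            n_failed=int((sub == FAILED).sum()),
            n_monomorphic=int((sub == MONOMORPHIC).sum()),
            n_polymorphic=int((sub == POLYMORPHIC).sum()),
        )

    return AssayRates(
        overall=counts(np.ones(len(st), dtype=bool)),
        per_source={s: counts((src == s).to_numpy()) for s in src.unique()},
    )


@dataclass
class ContrastResult:
    table: np.ndarray
    chi2: float
    p_value: float
    correction: bool


def contrast_2x2(
    a: int, b: int, c: int, d: int, correction: bool = True
) -> ContrastResult:
    """Chi-square test on the 2x2 table [[a, b], [c, d]], 1 df, two-sided.

    Yates continuity correction is applied by default.  Zero margins make
    the test undefined and raise.
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0) or table.dtype.kind not in "iu":
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 test undefined with a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return ContrastResult(table=table, chi2=float(chi2), p_value=float(p), correction=correction)


@dataclass
class MafSpectrum:
    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]          # per source label
    rare_fraction_pct: dict[str, float]    # % of SNPs with MAF <= rare_cutoff
    rare_cutoff: float

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for src, cnt in sorted(self.counts.items()):
            for lo, hi, n in zip(self.bin_edges[:-1], self.bin_edges[1:], cnt):
                rows.append(
                    {"source": src, "bin_low": lo, "bin_high": hi, "count": int(n)}
                )
        return pd.DataFrame(rows)


def maf_spectrum(
    freqs: pd.Series | np.ndarray,
    sources: pd.Series | np.ndarray | None = None,
    bin_width: float = 0.05,
    rare_cutoff: float = 0.10,
) -> MafSpectrum:
    """Histogram of minor-allele frequencies, per discovery source.

    Frequencies above 0.5 are folded to the minor-allele convention with a
    warning.  The rare-variant flag reports the percentage of SNPs at
    MAF <= ``rare_cutoff``.
    """
    f = pd.Series(freqs, dtype=float)
    if (f > 0.5).any():
        warnings.warn("frequencies above 0.5 folded to minor-allele scale")
        f = np.minimum(f, 1.0 - f)
    if (f < 0).any() or (f > 0.5).any():
        raise ValueError("minor-allele frequencies must lie in [0, 0.5]")
    src = (
        pd.Series(sources).reindex(f.index)
        if sources is not None
        else pd.Series("all", index=f.index)
    )
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    counts, rare = {}, {}
    for s in src.unique():
        vals = f[src == s].to_numpy()
        counts[s], _ = np.histogram(vals, bins=edges)
        rare[s] = (
            100.0 * float((vals <= rare_cutoff).mean()) if len(vals) else float("nan")
        )
    return MafSpectrum(
        bin_edges=edges, counts=counts, rare_fraction_pct=rare,
        rare_cutoff=rare_cutoff,
    )


@dataclass
class ConcordanceResult:
    pearson_r: float
    n: int
    ci_band: pd.DataFrame   # nominal freq x panel size -> 95% interval


def freq_concordance(
    freq_a,
    freq_b,
    panel_sizes: tuple[int, ...] = (20, 50),
    n_boot: int = 2000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> ConcordanceResult:
    """Concordance of two allele-frequency estimates of the same SNPs.

    Returns the Pearson correlation of the paired vectors plus, for each
    nominal frequency on ``grid`` and each diploid panel size, the 95%
    interval of the frequency estimated from ``n_boot`` binomial resamples
    of 2 * panel_size alleles.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired frequency vectors must have equal length")
    r = float(stats.pearsonr(a, b).statistic)

    rng = np.random.default_rng(seed)
    grid = np.round(np.arange(0.0, 1.0001, 0.05), 4) if grid is None else grid
    rows = []
    for n_samples in panel_sizes:
        n_alleles = 2 * n_samples
        for p in grid:
            draws = rng.binomial(n_alleles, p, size=n_boot) / n_alleles
            lo, hi = np.quantile(draws, (0.025, 0.975))
            rows.append(
                {
                    "panel_size": n_samples, "nominal_freq": float(p),
                    "ci_low": float(lo), "ci_high": float(hi),
                }
            )
    return ConcordanceResult(pearson_r=r, n=len(a), ci_band=pd.DataFrame(rows))
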