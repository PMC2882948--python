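import numpy as np
import pandas as pd
import pytest

from pinesnp import errorest


def test_per_child_weight_values():
    # p = 0.5: pq = 0.25 -> duo 0.5, trio 1.25
    assert errorest.per_child_weight(0.5, 1) == pytest.approx(0.5)
    assert errorest.per_child_weight(0.5, 2) == pytest.approx(1.25)
    # fixed allele: every error is detectable against homozygous parents
    assert errorest.per_child_weight(0.0, 1) == pytest.approx(1.0)
    assert errorest.per_child_weight(0.0, 2) == pytest.approx(2.0)


def test_per_child_weight_validation():
    with pytest.raises(ValueError):
        errorest.per_child_weight(1.2, 1)
    with pytest.raises(ValueError):
        errorest.per_child_weight(0.3, 3)


def test_closed_form_matches_oracle_spot_checks():
    for p in (0.1, 0.3, 0.5):
        for m in (1, 3):
            for cfg in (1, 2):
                closed = errorest.p_mi_closed_form(p, m, cfg)
                oracle = errorest.p_mi_oracle(p, m, cfg)
                assert closed == pytest.approx(oracle, abs=1e-9)


def test_oracle_family_event_convention_differs_for_trios():
    # a single parent error can hit several children at once, so the
    # per-family event coefficient is below the per-child count coefficient
    count = errorest.p_mi_oracle(0.3, 4, 2, family_event=False)
    event = errorest.p_mi_oracle(0.3, 4, 2, family_event=True)
    assert event < count


def test_monte_carlo_cross_check():
    est, se = errorest.p_mi_monte_carlo(0.3, 2, 2, pi=1e-3, n_families=100_000, seed=1)
    closed = errorest.p_mi_closed_form(0.3, 2, 2)
    assert abs(est - closed) < max(4 * se, 0.05)


def test_estimate_pi_exact_arithmetic():
    # one SNP, p = 0.5, one family with 10 trio children, 2 observed MIs:
    # pi = 2 / (10 * 1.25) = 0.16
    cells = pd.DataFrame(
        {
            "family_id": ["F1"],
            "snp_id": ["s1"],
            "n_children_trio": [10],
            "n_children_duo": [0],
            "n_mi": [2],
        }
    )
    est = errorest.estimate_pi(cells, pd.Series({"s1": 0.5}))
    assert est.pi_global == pytest.approx(0.16)
    assert est.pi_per_snp["s1"] == pytest.approx(0.16)
    assert est.observed_mi_total == 2


def test_estimate_pi_mixes_duo_and_trio_weights():
    cells = pd.DataFrame(
        {
            "family_id": ["F1", "F2"],
            "snp_id": ["s1", "s1"],
            "n_children_trio": [4, 0],
            "n_children_duo": [0, 6],
            "n_mi": [1, 1],
        }
    )
    est = errorest.estimate_pi(cells, pd.Series({"s1": 0.5}))
    expected = 2 / (4 * 1.25 + 6 * 0.5)
    assert est.pi_global == pytest.approx(expected)


def test_estimate_pi_method_variants_and_errors():
    cells = pd.DataFrame(
        {
            "family_id": ["F1", "F1"],
            "snp_id": ["s1", "s2"],
            "n_children_trio": [10, 10],
            "n_children_duo": [0, 0],
            "n_mi": [0, 5],
        }
    )
    freqs = pd.Series({"s1": 0.5, "s2": 0.5})
    pooled = errorest.estimate_pi(cells, freqs, method="pooled")
    per_snp = errorest.estimate_pi(cells, freqs, method="per_snp_mean")
    assert pooled.pi_global == pytest.approx(5 / 25)
    assert per_snp.pi_global == pytest.approx((0 + 0.4) / 2)
    assert pooled.n_zero_mi_snps == 1
    with pytest.raises(ValueError):
        errorest.estimate_pi(cells, freqs, method="bogus")
    with pytest.raises(ValueError, match="frequency"):
        errorest.estimate_pi(cells, pd.Series({"s1": 0.5}))


def test_rank_error_prone_snps_strata():
    est = errorest.ErrorRateEstimate(
        pi_global=0.01,
        pi_per_snp=pd.Series({"a": 0.0, "b": 0.02, "c": 0.3, "d": np.nan}),
        observed_mi_total=10,
        sum_p_mi=100.0,
    )
    ranked = errorest.rank_error_prone_snps(est)
    assert list(ranked["snp_id"]) == ["c", "b", "a", "d"]
    assert list(ranked["stratum"]) == ["elevated", "low", "zero", "not_estimable"]
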