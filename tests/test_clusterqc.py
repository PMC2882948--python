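import numpy as np
import pandas as pd
import pytest

from pinesnp import clusterqc, simdata
from pinesnp.clusterqc import (
    ABNORMAL_THETA,
    COMPRESSION,
    FAILED,
    LOW_GENTRAIN,
    MONOMORPHIC,
    OK,
    POLYMORPHIC,
    SUBGROUPS,
)
from pinesnp.genotypes import MISSING


def _records(theta, r=1.0, snp="S", gentrain=None, gencall=None):
    theta = np.asarray(theta, dtype=float)
    cy3, cy5 = simdata.theta_r_to_channels(theta, np.full(len(theta), r))
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(theta))],
            "snp_id": snp,
            "cy3": cy3,
            "cy5": cy5,
        }
    )
    if gentrain is not None:
        df["gentrain"] = gentrain
    if gencall is not None:
        df["gencall"] = gencall
    return df


def test_theta_special_values():
    theta, r, no_sig = clusterqc.compute_theta_r(
        np.array([100.0, 100.0, 0.0, 0.0]), np.array([100.0, 0.0, 50.0, 0.0])
    )
    assert theta[0] == pytest.approx(0.5)
    assert theta[1] == 0.0
    assert theta[2] == 1.0  # cy3 = 0 maps to the limit value exactly
    assert no_sig[3] and np.isnan(theta[3])
    assert r[0] == 200.0


def test_theta_known_value():
    theta, r, _ = clusterqc.compute_theta_r(np.array([100.0]), np.array([300.0]))
    assert theta[0] == pytest.approx((2 / np.pi) * np.arctan(3.0), abs=1e-15)
    assert r[0] == 400.0


def test_negative_intensities_raise():
    with pytest.raises(ValueError):
        clusterqc.compute_theta_r(np.array([-1.0]), np.array([1.0]))


def test_three_cluster_calling_correct():
    rng = np.random.default_rng(0)
    truth = np.repeat([0, 1, 2], [30, 25, 20])
    theta = np.concatenate(
        [
            rng.normal(0.03, 0.02, 30).clip(0, 1),
            rng.normal(0.5, 0.02, 25),
            rng.normal(0.97, 0.02, 20).clip(0, 1),
        ]
    )
    model = clusterqc.call_genotypes(_records(theta))
    assert model.n_clusters == 3
    assert model.gentrain >= 0.53
    np.testing.assert_array_equal(model.calls, truth)


def test_monomorphic_single_cluster():
    rng = np.random.default_rng(1)
    theta = rng.normal(0.02, 0.015, 40).clip(0, 1)
    model = clusterqc.call_genotypes(_records(theta))
    assert model.n_clusters == 1
    assert (model.calls == 0).all()


def test_vendor_scores_override_surrogates():
    rng = np.random.default_rng(2)
    theta = np.concatenate(
        [rng.normal(0.03, 0.02, 20).clip(0, 1), rng.normal(0.97, 0.02, 20).clip(0, 1)]
    )
    rec = _records(theta, gentrain=0.11, gencall=np.full(40, 0.2))
    model = clusterqc.call_genotypes(rec)
    assert model.gentrain == pytest.approx(0.11)
    # all confidences below the 0.25 cutoff: every call missing
    assert (model.calls == MISSING).all()


def test_min_samples_enforced():
    with pytest.raises(ValueError, match="at least"):
        clusterqc.call_genotypes(_records(np.linspace(0, 1, 5)))


def test_all_no_signal_fails_low_gentrain():
    rec = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(12)],
            "snp_id": "S",
            "cy3": 0.0,
            "cy5": 0.0,
        }
    )
    model = clusterqc.call_genotypes(rec)
    cls = clusterqc.classify_snp(model)
    assert cls.status == FAILED and cls.reason == LOW_GENTRAIN


def test_compression_detection():
    rng = np.random.default_rng(3)
    theta = np.concatenate(
        [
            rng.normal(0.05, 0.02, 30).clip(0, 1),
            rng.normal(0.40, 0.02, 20),
            rng.normal(0.75, 0.02, 15),  # BB homozygote compressed off [0.9, 1]
        ]
    )
    model = clusterqc.call_genotypes(_records(theta))
    assert clusterqc.detect_compression(model) == COMPRESSION


def test_abnormal_theta_single_cluster():
    rng = np.random.default_rng(4)
    theta = rng.normal(0.5, 0.02, 30)
    model = clusterqc.call_genotypes(_records(theta))
    assert clusterqc.detect_compression(model) == ABNORMAL_THETA


def test_subgroup_detection():
    rng = np.random.default_rng(5)
    tight = rng.normal(0.02, 0.01, 40).clip(0, 1)
    assert clusterqc.detect_subgroups(tight) == OK
    split = np.concatenate(
        [rng.normal(0.02, 0.01, 25).clip(0, 1), rng.normal(0.18, 0.01, 15)]
    )
    assert clusterqc.detect_subgroups(split) == SUBGROUPS


def test_classify_assay_clean_is_perfect(clean_assay):
    intensities, truth = clean_assay
    cls, gm, summary = clusterqc.classify_assay(intensities)
    merged = cls.merge(truth, on="snp_id")
    assert (merged["status"] == merged["true_status"]).all()
    # status partition: every SNP classified exactly once
    assert len(cls) == len(truth)
    assert cls["status"].isin([FAILED, MONOMORPHIC, POLYMORPHIC]).all()
    # genotype matrix only keeps successful SNPs
    ok = set(cls.loc[cls["status"] != FAILED, "snp_id"])
    assert set(gm.columns) == ok


def test_compression_shift_always_fails():
    # compression_shift > 0.15 on the BB homozygote => failed classification.
    # Shifts are kept below ~0.35: beyond that the compressed homozygote
    # lands within the heterozygote cloud and the pattern is statistically
    # indistinguishable from a clean two-genotype SNP.
    for shift in (0.16, 0.25, 0.33):
        inten, truth = simdata.simulate_assay(
            n_samples=50,
            composition={"compressed": 5},
            seed=31,
            compression_shift=shift,
        )
        cls, _, _ = clusterqc.classify_assay(inten)
        assert (cls["status"] == FAILED).all()


def test_call_rates():
    gm = pd.DataFrame(
        {"a": [0, 1, MISSING, 2], "b": [1, 1, 1, 1]},
        index=["s1", "s2", "s3", "s4"],
    )
    snp_rates, sample_rates = clusterqc.call_rates(gm)
    assert snp_rates["a"] == 0.75 and snp_rates["b"] == 1.0
    assert sample_rates["s3"] == 0.5


def test_plot_clusters_writes_file(tmp_path, clean_assay):
    intensities, truth = clean_assay
    snp = truth["snp_id"].iloc[0]
    out = tmp_path / "clusters.png"
    clusterqc.plot_clusters(intensities, snp, out)
    assert out.stat().st_size > 0
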