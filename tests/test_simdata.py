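import numpy as np
import pandas as pd
import pytest

from pinesnp import simdata
from pinesnp.genotypes import MISSING


def test_simulate_genotypes_deterministic(small_pedigree):
    config, ped = small_pedigree
    freqs = np.full(config.n_snps, 0.3)
    gm1, _ = simdata.simulate_genotypes(ped, freqs, seed=5)
    gm2, _ = simdata.simulate_genotypes(ped, freqs, seed=5)
    assert gm1.equals(gm2)
    gm3, _ = simdata.simulate_genotypes(ped, freqs, seed=6)
    assert not gm1.equals(gm3)


def test_fixed_allele_forces_monomorphic(small_pedigree):
    _, ped = small_pedigree
    gm, _ = simdata.simulate_genotypes(ped, np.zeros(5), seed=1, n_panel=20)
    assert (gm.to_numpy() == 0).all()
    gm, _ = simdata.simulate_genotypes(ped, np.ones(5), seed=1)
    assert (gm.to_numpy() == 2).all()


def test_founder_genotype_frequencies_hwe():
    # p = 0.5, 10,000 founders: genotype frequencies within 3 SE of (1/4, 1/2, 1/4)
    config = simdata.SimConfig(n_snps=1, family_spec=((2, 1),))
    ped = simdata.simulate_pedigree(config)
    gm, _ = simdata.simulate_genotypes(ped, np.array([0.5]), seed=3, n_panel=10_000)
    panel = gm.loc[[s for s in gm.index if s.startswith("PANEL")], :].to_numpy().ravel()
    n = len(panel)
    for code, expect in ((0, 0.25), (1, 0.5), (2, 0.25)):
        obs = np.mean(panel == code)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(obs - expect) < 3 * se


def test_children_consistent_with_true_parents(small_genotypes):
    ped, gm, truth = small_genotypes
    tg = truth.true_genotypes
    for fam in ped.families:
        f = tg.loc[fam.father_id].to_numpy()
        m = tg.loc[fam.mother_id].to_numpy()
        for cid in fam.child_ids:
            c = tg.loc[cid].to_numpy()
            # child allele count bounded by what the parents can transmit
            assert (c >= f // 2 + m // 2).all()
            assert (c <= (f + 1) // 2 + (m + 1) // 2 + 0).all()


def test_inject_errors_limits(small_genotypes):
    _, gm, _ = small_genotypes
    same, errs = simdata.inject_errors(gm, 0.0, seed=2)
    assert same.equals(gm)
    assert len(errs) == 0
    flipped, errs = simdata.inject_errors(gm, 1.0, seed=2)
    obs = gm.to_numpy() != MISSING
    assert (flipped.to_numpy()[obs] != gm.to_numpy()[obs]).all()
    assert len(errs) == obs.sum()


def test_inject_errors_binomial_count():
    rng = np.random.default_rng(7)
    gm = pd.DataFrame(
        rng.integers(0, 3, (1000, 100)),
        index=[f"s{i}" for i in range(1000)],
        columns=[f"snp{j}" for j in range(100)],
    )
    _, errs = simdata.inject_errors(gm, 0.005, seed=7)
    n_calls = gm.size
    expect = 0.005 * n_calls
    se = np.sqrt(n_calls * 0.005 * 0.995)
    assert abs(len(errs) - expect) < 3 * se
    # every recorded corruption is a real difference onto another genotype
    assert (errs["true"] != errs["observed"]).all()
    assert errs["observed"].isin([0, 1, 2]).all()


def test_theta_r_channel_roundtrip():
    theta = np.array([0.0, 0.1, 0.5, 0.9, 1.0])
    r = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
    cy3, cy5 = simdata.theta_r_to_channels(theta, r)
    from pinesnp.clusterqc import compute_theta_r

    t2, r2, no_sig = compute_theta_r(cy3, cy5)
    assert not no_sig.any()
    np.testing.assert_allclose(t2, theta, atol=1e-12)
    np.testing.assert_allclose(r2, r, atol=1e-12)


def test_simulate_intensities_truth_alignment(small_genotypes):
    _, gm, _ = small_genotypes
    sub = gm.iloc[:20, :5]
    table, truth = simdata.simulate_intensities(sub, seed=9)
    assert len(table) == sub.size
    assert set(table.columns) >= {"sample_id", "snp_id", "cy3", "cy5"}
    merged = table.merge(truth, on=["sample_id", "snp_id"])
    assert len(merged) == len(table)


def test_est_contigs_error_free_all_true_snps():
    spec = simdata.EstSpec(base_error_rate=0.0)
    _, truth = simdata.simulate_est_contigs(spec, seed=4)
    assert truth["is_true_snp"].all()


def test_est_contigs_pseudo_variant_expectation():
    # no true SNPs: every variant column is error-induced; a column is
    # variant iff >= 1 of its depth-d bases is misread, P = 1 - (1-e)^d
    spec = simdata.EstSpec(
        n_contigs=20,
        contig_length=500,
        depth_choices=(5,),
        base_error_rate=0.01,
        snp_density=0.0,
    )
    _, truth = simdata.simulate_est_contigs(spec, seed=8)
    n_positions = 20 * 500
    p_var = 1.0 - (1.0 - 0.01) ** 5
    expect = n_positions * p_var
    se = np.sqrt(n_positions * p_var * (1 - p_var))
    assert abs(len(truth) - expect) < 3 * se
    assert not truth["is_true_snp"].any()


def test_invitro_accounting_panel_composition():
    panel = simdata.invitro_accounting_panel(seed=1)
    assert len(panel) == 448
    low_func = [c for c in panel if c.functionality_score < 0.4]
    assert len(low_func) == 155
    rare = [c for c in panel if c.functionality_score >= 0.4 and c.maf < 0.05]
    assert len(rare) == 28


def test_simulate_assay_partition_and_determinism():
    comp = {"polymorphic": 8, "monomorphic": 4, "low_quality": 3}
    inten1, truth1 = simdata.simulate_assay(n_samples=30, composition=comp, seed=13)
    inten2, truth2 = simdata.simulate_assay(n_samples=30, composition=comp, seed=13)
    assert inten1.equals(inten2) and truth1.equals(truth2)
    assert len(truth1) == 15
    assert truth1["true_status"].value_counts().to_dict() == {
        "polymorphic": 8, "monomorphic": 4, "failed": 3
    }


def test_stream_rngs_are_independent():
    a = simdata.stream_rng(5, "genotypes").random(4)
    b = simdata.stream_rng(5, "errors").random(4)
    a2 = simdata.stream_rng(5, "genotypes").random(4)
    np.testing.assert_array_equal(a, a2)
    assert not np.allclose(a, b)
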