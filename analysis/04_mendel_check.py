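"""Stage 4 — Mendelian-inconsistency screen on the family material.

Simulates the study's family design — 17 two-generation families (26
genotyped parents, 75 offspring) plus a 212-sample unrelated founder panel —
genotyped at 188 polymorphic SNPs with a 0.5% per-call error rate, then
tallies Mendelian inconsistencies per family, SNP and parent-offspring pair
and flags pairs whose MI rate indicates a sample-handling error rather than
genotyping noise.  Writes the tally tables consumed by the error-rate stage.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from pinesnp import genotypes, mendel, simdata


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--error-rate", type=float, default=0.005)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    config = simdata.SimConfig(error_rate=args.error_rate, seed=args.seed)
    pedigree = simdata.simulate_pedigree(config)
    freqs = config.draw_freqs(simdata.stream_rng(args.seed, "genotypes"))
    gm_true, truth = simdata.simulate_genotypes(
        pedigree, freqs, seed=args.seed, n_panel=config.n_founders
    )
    gm_obs, injected = simdata.inject_errors(
        gm_true, config.error_rate, seed=args.seed
    )

    pedigree.to_ped_file(args.out_dir / "families.ped")
    genotypes.write_genotypes(gm_obs, args.out_dir / "family_genotypes.tsv")

    # allele frequencies from the unrelated panel (family-free estimate)
    panel = [s for s in gm_obs.index if s.startswith("PANEL")]
    freq_panel = genotypes.allele_frequencies(gm_obs, panel)
    freq_panel.rename_axis("snp_id").to_frame().to_csv(
        args.out_dir / "panel_freqs.tsv", sep="\t"
    )

    report = mendel.tally_mis(pedigree, gm_obs)
    flagged = mendel.flag_outlier_pairs(report.pairs)
    report.cells.to_csv(args.out_dir / "mendel_cells.tsv", sep="\t", index=False)
    report.pairs.to_csv(args.out_dir / "mendel_pairs.tsv", sep="\t", index=False)
    flagged.to_csv(args.out_dir / "mendel_outlier_pairs.tsv", sep="\t", index=False)

    summary = {
        "n_families": len(pedigree.families),
        "n_snps": gm_obs.shape[1],
        "n_datapoints": report.n_datapoints,
        "total_mi": report.total_mi,
        "n_injected_errors": len(injected),
        "n_outlier_pairs": len(flagged),
        "snps_with_mi": int((report.per_snp > 0).sum()),
    }
    (args.out_dir / "mendel_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
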