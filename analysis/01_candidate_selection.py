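"""Stage 1 — candidate SNP selection for the genotyping array.

Two discovery routes feed the assay: resequencing-derived candidates
("in vitro"), filtered on amplicon functionality, 60-nt flank spacing and
minor-allele frequency; and EST-alignment-derived candidates ("in silico"),
filtered on detection probability, depth and minor-allele support.  This
script runs both filters on simulated candidate panels whose construction
mirrors the real accounting (448 resequencing candidates reduced to 184)
and writes the per-candidate outcomes plus a summary.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from pinesnp import simdata, snpselect


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    # resequencing route: 448 candidates -> 184 retained
    invitro = simdata.invitro_accounting_panel(seed=args.seed)
    rep_vitro = snpselect.filter_invitro(invitro)
    rep_vitro.to_frame().to_csv(
        args.out_dir / "selection_invitro.tsv", sep="\t", index=False
    )

    # EST route: simulate contig alignments, extract variant columns, filter
    contigs, est_truth = simdata.simulate_est_contigs(seed=args.seed)
    simdata.write_contigs_fasta(contigs, args.out_dir / "est_contigs.fasta")
    insilico = simdata.insilico_panel_from_contigs(est_truth, seed=args.seed)
    rep_silico = snpselect.filter_insilico(insilico)
    rep_silico.to_frame().to_csv(
        args.out_dir / "selection_insilico.tsv", sep="\t", index=False
    )

    # assay design sheet for the retained candidates
    retained = [c for c in invitro if c.snp_id in set(rep_vitro.retained)]
    snpselect.export_sequence_list(
        retained, args.out_dir / "assay_sequences.tsv", dialect="iupac"
    )

    summary = {
        "invitro": {
            "n_candidates": len(invitro),
            "n_retained": len(rep_vitro.retained),
            "first_reason_counts": rep_vitro.first_reason_counts(),
        },
        "insilico": {
            "n_candidates": len(insilico),
            "n_retained": len(rep_silico.retained),
            "first_reason_counts": rep_silico.first_reason_counts(),
            "n_true_snps_among_candidates": int(est_truth["is_true_snp"].sum()),
        },
    }
    (args.out_dir / "selection_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
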