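"""Stage 3 — success / conversion rates and source contrasts.

Reads the classification and truth tables written by ``02_assay_qc.py`` and
computes: success rate (monomorphic + polymorphic over all SNPs) and
conversion rate (polymorphic over all SNPs) overall and per discovery
source; the chi-square contrast of the two sources on both rates; and the
minor-allele-frequency spectrum of the polymorphic SNPs per source with the
rare-variant (MAF <= 0.10) fraction.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from pinesnp import genotypes, metrics


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cls = pd.read_csv(args.in_dir / "assay_classifications.tsv", sep="\t")
    truth = pd.read_csv(args.in_dir / "assay_truth.tsv", sep="\t")
    gm = genotypes.read_genotypes(args.in_dir / "assay_genotypes.tsv")

    merged = cls.merge(truth[["snp_id", "source"]], on="snp_id")
    statuses = merged.set_index("snp_id")["status"]
    sources = merged.set_index("snp_id")["source"]
    rates = metrics.assay_rates(statuses, sources)
    rates.as_frame().to_csv(args.out_dir / "assay_rates.tsv", sep="\t", index=False)

    # 2x2 contrasts between the two discovery sources
    vit = rates.per_source["in_vitro"]
    sil = rates.per_source["in_silico"]
    success = metrics.contrast_2x2(
        vit.n_successful, vit.n_failed, sil.n_successful, sil.n_failed
    )
    conversion = metrics.contrast_2x2(
        vit.n_polymorphic,
        vit.n_total - vit.n_polymorphic,
        sil.n_polymorphic,
        sil.n_total - sil.n_polymorphic,
    )

    # MAF spectrum of the polymorphic SNPs (frequencies from called genotypes)
    poly = merged[merged["status"] == "polymorphic"]["snp_id"]
    maf = genotypes.minor_allele_frequencies(gm[list(poly)])
    spectrum = metrics.maf_spectrum(
        maf, sources.reindex(poly.to_numpy()), rare_cutoff=0.10
    )
    spectrum.as_frame().to_csv(
        args.out_dir / "maf_spectrum.tsv", sep="\t", index=False
    )

    summary = {
        "success_rate_pct": {
            "overall": rates.overall.success_rate(),
            "in_vitro": vit.success_rate(),
            "in_silico": sil.success_rate(),
        },
        "conversion_rate_pct": {
            "overall": rates.overall.conversion_rate(),
            "in_vitro": vit.conversion_rate(),
            "in_silico": sil.conversion_rate(),
        },
        "success_contrast": {"chi2": success.chi2, "p": success.p_value},
        "conversion_contrast": {"chi2": conversion.chi2, "p": conversion.p_value},
        "rare_fraction_pct": spectrum.rare_fraction_pct,
    }
    (args.out_dir / "assay_metrics_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
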