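# pinesnp

Design, quality control and error-rate analysis for a medium-throughput SNP
genotyping array in maritime pine, built around simulated data. The package
covers the full workflow:

1. **Candidate selection** — filter resequencing-derived (in vitro) and
   EST-contig-derived (in silico) SNP candidates down to an assay design.
2. **Cluster QC** — transform two-channel intensities to polar coordinates,
   call genotypes with a Gaussian-mixture model, score clusters, and classify
   each SNP as failed / monomorphic / polymorphic with a failure reason
   (low cluster quality, cluster compression, abnormal theta, subgroups).
3. **Assay metrics** — success and conversion rates per candidate source,
   2×2 contrasts (Yates-corrected chi-square), minor-allele-frequency
   spectra and allele-frequency concordance.
4. **Mendelian checks** — tally Mendelian inconsistencies (MIs) in
   parent–offspring families, flag outlier parent–child pairs.
5. **Error-rate estimation** — a method-of-moments estimator for the
   per-datapoint genotyping error rate Π based on expected-MI weights
   (`P_MI`), plus per-SNP ranking to identify error-prone markers.

## Layout

```
src/pinesnp/          library
  simdata.py          simulated pedigrees, genotypes, intensities, EST contigs
  snpselect.py        in vitro / in silico candidate filters, sequence export
  clusterqc.py        theta/R transform, genotype calling, SNP classification
  metrics.py          assay rates, contrasts, MAF spectrum, concordance
  mendel.py           MI tallying and outlier parent-child pairs
  errorest.py         P_MI closed forms + enumeration oracle, Π estimator
  pedigree.py         family structures, PED I/O
  genotypes.py        genotype-matrix conventions and TSV I/O
  cli.py              `pinesnp` command-line interface
analysis/             numbered pipeline drivers (01 → 05)
scripts/acceptance.py end-to-end report of the headline quantities
tests/                unit + acceptance tests
docs/methods.md       statistical methods note
```

## Running the analysis pipeline

Each driver writes into `results/` and can be run independently:

```bash
python analysis/01_candidate_selection.py   # 448 -> 184 in vitro panel + in silico panel
python analysis/02_assay_qc.py              # simulate assay, cluster QC, classifications
python analysis/03_assay_metrics.py         # success/conversion rates, contrasts, MAF
python analysis/04_mendel_check.py          # family simulation, MI tally, outlier pairs
python analysis/05_error_rate.py            # Π estimate, per-SNP ranking, two-stratum experiment
```

## Command-line interface

```bash
pinesnp simulate-assay --seed 1 --out-prefix out/assay
pinesnp cluster-qc --intensities out/assay_intensities.tsv --out-prefix out/qc
pinesnp select --candidates candidates.tsv --mode invitro --out-prefix out/sel
pinesnp mendel-check --ped fam.ped --genotypes geno.tsv --out-prefix out/mendel
pinesnp error-rate --cells out/mendel_cells.tsv --freqs freqs.tsv --out out/pi.tsv
```

## Tests and acceptance report

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline quantities (filter accounting,
assay success/conversion rates, contrast p-values, P_MI closed-form vs
enumeration agreement, Π recovery, elevated-SNP identification, polar
roundtrip error, rare-variant fraction) and writes them as JSON.

See `docs/methods.md` for the statistical model behind `P_MI` and the
estimator, and the cluster-QC decision rules.
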