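# Methods

## Error model

Each genotype datapoint is mis-called independently with probability Π. An
error replaces the true genotype (coded 0 = AA, 1 = AB, 2 = BB by B-allele
count) with one of the two other genotypes, each with probability Π/2
(uniform substitution).

## Mendelian-inconsistency (MI) rules

For a child and one genotyped parent, the pair is inconsistent when they are
opposite homozygotes (AA vs BB). With both parents genotyped, the child is
checked against the full trio transmission table (e.g. AA × AA cannot
produce AB or BB; AA × BB must produce AB). A missing parent call falls back
to the duo rule against the remaining parent. `mendel.tally_mis` counts, per
family × SNP cell, the number of inconsistent child checks.

## Expected-MI weights (P_MI)

Let p be the B-allele frequency, q = 1 − p, and m the number of genotyped
offspring in a family. To first order in Π, the expected number of MIs in a
family × SNP cell caused by genotyping error is Π · P_MI with

- one genotyped parent:  `P_MI = m (1 − 2pq)`
- two genotyped parents: `P_MI = m (2 − 3pq)`

Derivation sketch: a single error (in a parent or a child) is detected with
a probability that depends on the Hardy–Weinberg genotype distribution of
the family; summing the detection probabilities over the m + 1 (duo) or
m + 2 (trio) genotyped individuals, each erring with rate Π, and counting
the expected number of inconsistent child checks gives the forms above.
Both are verified to machine precision against a brute-force enumeration
oracle (`errorest.p_mi_oracle`) that sums over all parental and child
genotypes and all error channels, and against Monte-Carlo slopes in Π.

The convention is expected MI **count** (number of inconsistent child
checks), not the probability of at least one MI per family; the two agree to
first order for duos but differ when a single parental error invalidates
several children at once. The count convention keeps the pooled estimator
unbiased to first order in Π.

## Error-rate estimator

Method of moments, pooled over all family × SNP cells with estimable
weights:

```
Π̂ = Σ observed MIs / Σ P_MI(p̂, m, parents genotyped)
```

with p̂ the plug-in allele frequency from an unrelated founder panel.
A per-SNP version uses the same ratio restricted to one SNP; ranking SNPs by
their per-SNP ratio identifies error-prone markers (strata: zero /
low / elevated by configurable cutoffs). Removing flagged SNPs and
re-estimating quantifies their contribution to the global rate.

Validity checks built into the test-suite: with errors injected at Π =
0.005 over a 17-family design (26 genotyped parents, 75 offspring, 188
SNPs), the mean of 100 replicate estimates is within 10% of the truth and
the empirical 95% interval covers it; with a two-stratum design (4 SNPs at
Π = 0.3, the rest at Π = 0.0005) the 4 elevated SNPs rank top-4 in ≥95% of
replicates and removing them drops the pooled estimate ≥10-fold.

## Intensity model and cluster QC

Two-channel intensities are summarised by polar coordinates

```
theta = (2/π) · arctan2(cy5, cy3)        R = cy3 + cy5
```

so clean genotype clusters sit near theta ≈ 0.03 (AA), 0.5 (AB) and 0.97
(BB). The transform is exactly invertible (`simdata.theta_r_to_channels`).

Genotype calling fits 1–3-component spherical Gaussian mixtures on theta,
each with two deterministic EM initialisations (quantile means and an even
spread over the data range; the better-likelihood fit is kept) and selects
the component count by BIC. Components map to genotypes by nearest canonical
theta with two collision rules:

- two components nearest the same **homozygote** are merged
  (moment-matched) — the signature of an over-split truncated cluster at the
  axis;
- two components nearest the **heterozygote** are forced onto distinct
  genotypes by minimum-total-distance assignment — the signature of cluster
  compression, where a homozygote cluster is dragged toward 0.5.

Cluster quality is scored by a separation-based surrogate (gentrain-like,
per SNP) and a per-call posterior confidence (gencall-like); vendor scores,
when present in the input, take precedence. Calls below the confidence
cutoff (0.25) are set missing; SNPs below the cluster-quality cutoff (0.25)
fail with reason LOW_GENTRAIN.

Failure classification, in precedence order: LOW_GENTRAIN → SUBGROUPS
(monomorphic-by-calls SNPs whose theta distribution splits into two
well-separated subclusters, indicating a second polymorphism under the
probe) → COMPRESSION / ABNORMAL_THETA (any homozygote-assigned cluster mean
outside [0, 0.1] ∪ [0.9, 1]; a single out-of-range cluster is ABNORMAL_THETA).

Identifiability caveat: a compressed homozygote is only detectable while it
remains resolvable from the heterozygote cloud; once the compression shift
places its mean within ≈0.1 of 0.5 the data are statistically equivalent to
a clean two-genotype SNP and no caller can flag it.

## Assay metrics

Success rate = (monomorphic + polymorphic) / designed; conversion rate =
polymorphic / designed, reported overall and per candidate source. Source
contrasts use 2×2 chi-square with Yates continuity correction
(`scipy.stats.chi2_contingency`). MAF spectra fold frequencies above 0.5 and
report the rare-variant fraction below a cutoff. Allele-frequency
concordance reports Pearson r plus binomial bootstrap confidence bands as a
function of discovery-panel size.

## Candidate filters

In vitro (resequencing) candidates pass, in order: amplicon functionality
score ≥ 0.4; pairwise spacing ≥ 60 nt (iteratively dropping the
lower-MAF member of the closest violating pair); MAF ≥ 0.05; optional LD
pruning at r² > 0.8. In silico (EST contig) candidates pass: detection
probability ≥ 0.99; read support (depth 4–10 with ≥2 minor-allele reads, or
depth > 10 with MAF > 0.20); clean flanking sequence within 60 nt; at most
2 SNPs per unigene (best detection score first).
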