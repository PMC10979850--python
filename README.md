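# locindex

Nucleo-cytosolic RNA localization from matched whole-cell, nuclear and
cytosolic RNA-seq.

## The problem

RNA-seq abundances (FPKM, TPM) are relative to the total RNA of the library
sequenced. After cellular fractionation, the nuclear and cytosolic libraries
measure pools of very different — and usually unknown — total RNA volume, so
their FPKMs cannot be compared directly: the ratio
FPKM<sub>c</sub>/(FPKM<sub>n</sub> + FPKM<sub>c</sub>) (the *naive
localization index*) misstates where a transcript's molecules actually are,
and can even flip its apparent compartment preference.

If a matched **whole-cell** library is also available, the missing scale
becomes estimable. Writing β for the fraction of the total cellular RNA
volume (nucleotides summed over all molecules) that resides in the cytosol,
per-transcript abundances obey

```
FPKM_w(i) = (1 − β)·FPKM_n(i) + β·FPKM_c(i) + ε(i),    ε(i) ~ t(ν, 0, σ)
```

`locindex` estimates β by Bayesian robust linear regression across all
expressed transcripts (Student-t errors for robustness to outlying
transcripts; priors ν ~ Γ(2, 0.1), σ ~ Exponential(mean s) with s the
whole-cell FPKM standard deviation, β ~ Beta(2, 2)), taking the posterior
mode (MAP) as the point estimate. Given β, the **localization index**

```
LI(i) = β·FPKM_c(i) / ((1 − β)·FPKM_n(i) + β·FPKM_c(i))
```

is the fraction of transcript *i*'s molecules in the cytosol — the quantity
the naive index only recovers when β = 0.5.

The package is aimed at anyone with matched fractionated RNA-seq
quantifications (bulk replicates, or pseudo-bulked fractionated single-cell
data): it reads RSEM-style isoform quantification tables, applies the
standard preprocessing (CPM ≥ 1 detection filter, mitochondrial exclusion,
replicate consensus), estimates β per sample with QC (samples with β > 0.95
are flagged as likely fractionation failures), computes localization tables,
and summarizes cross-condition consistency and splicing-feature enrichment
(hypergeometric test, Bonferroni). A ground-truth simulator of fractionated
counts supports benchmarking the whole pipeline.

## Worked example

Simulate a matched triplet whose true cytosolic volume fraction is 0.8, then
estimate β from the tables alone:

```sh
$ locindex simulate --n 2000 --molecules 100000 --beta 0.8 --depth 1000000 \
      --mode multinomial --seed 42 --out-dir demo
realized_beta   0.799852

$ locindex estimate-beta --whole demo/whole.tsv --nuclear demo/nuclear.tsv \
      --cytosolic demo/cytosolic.tsv --out-dir demo_beta --fast --seed 1
beta_map        0.800851
qc              pass
```

The estimate (0.8009) recovers the realized volume fraction (0.7999) to
about 10⁻³; `qc pass` means it is below the 0.95 exclusion threshold.
(`--fast` uses the deterministic MAP optimizer; omit it for full MCMC with
R-hat/ESS diagnostics.) Localization indices then follow:

```sh
$ locindex localize --whole demo/whole.tsv --nuclear demo/nuclear.tsv \
      --cytosolic demo/cytosolic.tsv --out-dir demo_loc --beta 0.8009
$ head -4 demo_loc/localization.tsv
transcript_id   li       naive_li  label         beta_used  sample_id
TX000001        0.5805   0.2598    intermediate  0.8009     sample
TX000002        1.0      1.0       cytosolic     0.8009     sample
TX000003        0.0      0.0       nuclear       0.8009     sample
```

For TX000001 the naive index (0.26) would call the transcript nuclear; the
β-corrected index (0.58) shows its molecules actually lean cytosolic — the
exact failure mode of fraction-only comparisons at β far from 0.5.

From Python the estimator is scikit-learn shaped:

```python
import numpy as np
from locindex import BetaTRegressor

est = BetaTRegressor(method="map").fit(np.column_stack([fpkm_n, fpkm_c]), fpkm_w)
est.beta_map_, est.qc_status_
```

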