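# repshare

Cross-compartment clonal-sharing analysis for UMI-quantified B-cell
receptor (BCR) heavy-chain repertoires.

## The problem

In inflammatory joint disease, the same expanded B-cell clones can appear
in synovial tissue (ST) at different biopsy sites, in synovial fluid (SF)
and in peripheral blood (PB) of one patient. Quantifying that sharing
requires a chain of careful steps: collapsing PCR duplicates by unique
molecular identifier (UMI), calling clonotypes from the CDR3 sequence plus
V/J gene use, standardizing sequencing depth so richness and overlap
statistics are comparable, and estimating between-sample similarity in a
way that is robust to clones missed by incomplete sampling. `repshare`
implements that chain as a tested, reusable library and CLI for anyone
working with AIRR-style rearrangement tables, plus a calibrated synthetic
cohort generator so every stage can be validated against known ground
truth.

## Core statistics

* **Clonotype**: molecules sharing one clone key (CDR3 nucleotide or
  amino-acid sequence + V gene + J gene within a sample; CDR3 only for
  cross-sample comparison). Quantification is per UMI-collapsed molecule.
* **Depth standardization**: every sample is reduced to a common depth
  (default *N* = 9,736 molecules) by uniform draws without replacement —
  clone counts are multivariate hypergeometric.
* **Highly expanded clones (HECs)**: clones at frequency ≥ 0.5%
  (inclusive); *HEC impact* is their summed frequency in percent.
* **Top-N clonal retrieval**: percentage of the *N* (default 25) most
  expanded clones of each sample found in both samples' top-*N* lists.
* **Chao-modified Sørensen index** `L = 2UV/(U+V)` where, over shared
  clones with counts `X_i` (of `n`) and `Y_i` (of `m`),

  ```
  U = Σ X_i/n + ((m−1)/m) · f+1/(2·f+2) · Σ_{Y_i=1} X_i/n     (capped at 1)
  V = Σ Y_i/m + ((n−1)/n) · f1+/(2·f2+) · Σ_{X_i=1} Y_i/m     (capped at 1)
  ```

  with `f+1`/`f+2` the shared clones that are singletons/doubletons in the
  partner sample (zero doubleton counts are replaced by 1). The correction
  terms estimate the relative abundance of shared clones that sampling
  missed; `L` ranges from 0 (no overlap) to 1 (identical repertoires).

## Worked example

Generate a two-patient synthetic cohort (two knee joints with
suprapatellar + infrapatellar ST biopsies, SF, PB per patient), run the
full pipeline, and compare estimates with the generator's ground truth:

```bash
repshare simulate --seed 7 --patients 2 --out cohort/
repshare run --config run.yaml       # manifest/data_dir/out_dir point at cohort/
repshare recover --cohort-dir cohort/ --overlap-table results/overlap.tsv \
                 --out recovery.tsv
```

or in Python:

```python
from repshare import (SyntheticCohortConfig, generate_cohort, DepthConfig)
from repshare.pipeline import analyze_records

cohort = generate_cohort(SyntheticCohortConfig(n_patients=2, master_seed=7))
summary, results, overlap = analyze_records(
    cohort.records, cohort.manifest, DepthConfig(depth=9736, seed=7))
print(summary.groupby("compartment")[["n_clones", "n_hecs", "hec_impact"]].mean())
print(overlap.groupby("comparison_class")[["topn_retrieval_pct", "chao_sorensen"]].mean())
```

which prints (seed 7):

```
             n_clones  n_hecs  hec_impact
compartment
PB             5132.5    5.00    4.570666
SF             1655.5   27.50   46.631060
ST_IP          1196.5   31.50   48.975452
ST_SP          1153.0   26.25   51.461072
                      topn_retrieval_pct  chao_sorensen
comparison_class
SF_PB                                0.0       0.005624
ST_PB                                1.5       0.007649
ST_SF                                3.0       0.072060
ST_ST_between_joints                 3.0       0.055400
ST_ST_within_joint                  12.0       0.197150
```

Reading: each standardized sample holds 9,736 molecules. ST samples carry
~1,200 clones of which ~30 are HECs covering ~50% of all molecules, while
blood is far richer (~5,100 clones) with almost no expanded clones — the
expected tissue/blood contrast. Sharing of dominant clones is strongest
between two biopsy sites of the same joint (top-25 retrieval 12%,
Sørensen 0.20), weaker between contralateral joints and between tissue
and fluid, and nearly absent versus blood.

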