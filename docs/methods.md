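# Methods

This note documents the models and numerical choices behind `repshare`:
what each stage assumes, which parameters matter, what the synthetic
cohort generator does and does not emulate, and where the design was
genuinely open.

## Clonotype model

A clonotype is defined by the CDR3 sequence together with the V and J
gene calls; within a sample this triple is the clone key, while all
cross-sample comparisons use the CDR3 sequence alone. The rationale for
dropping V/J across samples is somatic hypermutation: mutated lineage
variants can receive different gene calls and fragment one biological
clone into several keys, deflating every overlap statistic. CDR3-only
matching across samples is the more conservative choice for similarity
analysis, at a small cost in specificity.

Two open choices are exposed as flags rather than resolved:

* **Gene-call resolution.** Clone keys use gene-level calls
  (allele suffix `*NN` stripped) by default; allele-level keying is
  available via `strip_alleles=False` at read time.
* **CDR3 level.** Nucleotide CDR3 is the default comparison sequence;
  amino-acid mode (`mode="aa"`) merges synonymous variants and yields
  slightly higher overlap values.

Quantification is molecule-based. Reads sharing a UMI and a clone key
collapse into one molecule; a UMI observed with two different clone keys
is treated as two molecules (a collision resolved by key, not by
majority vote — order-independent and conservative). No UMI error
correction (e.g. one-mismatch merging) is applied; the collapser is a
single function that can be swapped if error modelling is needed.
Raw-read multiplicities are retained as `duplicate_count` but never
weight clone sizes: with linear amplification the molecule count is the
quantity proportional to input transcripts.

## Depth standardization

Richness, HEC counts and both overlap statistics are strongly
depth-dependent, so all statistics are computed after reducing every
sample to one fixed depth, default 9,736 molecules. The draw is uniform
without replacement over the sample's molecules, making post-draw clone
counts exactly multivariate hypergeometric and the per-clone expected
frequency equal to the pre-draw frequency (verified by a 200-seed
simulation test). Samples below the target depth abort the run by
default (`shallow_policy="error"`); keeping them at native depth is
possible but flagged, because unequal depths bias every comparison.

Seeding: one master seed; each sample's draw is seeded by
`sha256(master_seed:sample_id)`, so adding or removing samples never
perturbs the other samples' draws, and the whole pipeline is
reproducible bit-for-bit.

The HEC rule (frequency ≥ 0.5%, boundary inclusive) is applied after
standardization; at depth 9,736 it corresponds to a floor of
ceil(0.005·9736) = 49 molecules, which is recorded in output metadata.
A flag allows detection before standardization for sensitivity
analyses.

## Overlap statistics

**Top-N clonal retrieval** takes exactly N top-ranked CDR3 keys from
each sample (ties broken deterministically: count descending, then CDR3
lexicographic) and reports `100·|intersection|/N`. With equal list
sizes the definition is symmetric. If a sample holds fewer than N
clones, the effective N is `min(N, clone counts)` and is recorded.

**Chao-modified Sørensen.** The abundance-based two-assemblage
estimator with the bias-correction term for shared clones missed by
sampling (see README for the formula). Numerical conventions, all
surfaced in the returned `ChaoComponents` so alternates can be audited:

* zero doubleton counts (`f+2` or `f2+`) are replaced by 1 before
  dividing — the convention used by the standard biodiversity software
  implementations of these estimators;
* `U` and `V` are capped at 1 (they estimate total relative abundances);
* no shared clones gives index 0 without evaluating `2UV/(U+V)`.

An `uncorrected` variant (correction terms dropped) is available behind
a flag because published analyses do not always state which form was
used; the bias-corrected form is the default. The implementation is
validated three ways: a frozen hand-computed example, a brute-force
from-the-formula oracle on random count tables (agreement to 1e-12),
and R/vegan's independent implementation of the Jaccard-type form,
which shares the U and V terms.

Comparison classes for pairs within a patient: ST–ST within joint,
ST–ST between joints, ST–SF, ST–PB, SF–PB. Pairs are never formed
across patients.

## Group statistics

The module maps study comparisons onto standard tests — unpaired
two-sided Mann–Whitney U, paired t, one-way ANOVA with Tukey's
multiple-comparison test — delegating computation to scipy/statsmodels.
Sample SD uses the n−1 denominator and is reported as undefined (not 0)
for single-observation groups. Zero-variance paired differences are
flagged degenerate with no p-value rather than a fabricated one. All
tests are two-sided by default with an `alternative` override; a
one-tailed option exists because published repertoire comparisons
occasionally use it, and the choice is deliberately explicit rather
than silent. No multiple-testing correction is applied beyond Tukey
within an ANOVA family.

## Synthetic cohort generator

The generator emulates a paired-compartment arthritis cohort — per
patient: two knee joints, each biopsied at suprapatellar (SP) and
infrapatellar (IP) sites, synovial fluid from one joint, peripheral
blood — so that the full pipeline can be tested against known sharing
structure. Key modelling decisions:

* **Abundance model.** Each sample's clone pool has a deterministic
  rank-abundance profile: rank-quantile lognormal for ST/SF (flatter
  head: many moderately expanded clones) or Zipf for PB (power-law with
  a rich flat tail). The shape parameter is solved by grid search so
  that the expected number of pool clones at ≥ 0.5% equals the
  configured HEC target; the HEC mass then emerges from the profile.
* **Default calibration.** Pool richness and HEC targets per
  compartment (ST 4,000/30, SF 8,000/23, PB 12,000/5; 20,000 molecules
  per sample) were chosen numerically so that at depth 9,736 the
  generated clone counts, HEC counts and HEC impact match the
  per-compartment profiles typical of inflamed-joint BCR data: ST
  ≈1,100–1,300 clones with ~28 HECs covering ~50%, SF ≈1,700–2,200
  clones with ~25 HECs covering ~40%, PB ≈5,100 clones with ~5 HECs of
  small total impact.
* **Sharing model.** Clone identities are patient-private; sharing is
  modelled at the identity level. When sample B is paired to sample A
  with probability rho, each rank of B carries the same clone identity
  as that rank of A with probability rho, otherwise a fresh identity —
  i.e. shared clones have correlated dominance, which is precisely the
  inference target of the overlap statistics. Defaults:
  rho(within joint)=0.25 > rho(ST–SF)=0.20 > rho(between joints)=0.15 ≫
  rho(blood)=0.03, reproducing the qualitative ordering of tissue
  versus blood sharing. Chained pairs (e.g. SP of joint 1 vs IP of
  joint 2) share transitively and therefore less.
* **Plasma-cell amplification.** BCR mRNA expression differs roughly
  5–50-fold between plasma cells and B cells, so a random 2% of tissue
  and fluid clones get their abundance multiplied by a factor drawn
  uniformly from [5, 50] before normalization, independently per
  sample. This realistically decouples observed dominance from
  identity sharing and is the main reason observed top-25 retrieval
  sits well below 100·rho.
* **Sequencing.** `molecules` molecules are drawn multinomially; each
  gets a unique 12-nt UMI (collision-free within a sample) and a
  raw-read multiplicity 1 + Poisson(mean−1). CDR3s are random 30–60-mers
  with an 8-nt patient barcode prefix so cross-patient collisions — which
  would corrupt chance-overlap baselines — are structurally impossible.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: somatic hypermutation and clonal lineage
structure, sequencing and PCR errors (including UMI errors), isotypes
and light chains, biological correlation between abundance and sharing
beyond the rank-preserving copy, and inter-patient biological
variability (all patients share one compartment profile). Calibration
checks therefore validate the *pipeline* under realistic repertoire
shapes, not biological conclusions.

## Problem sizes in tests and the acceptance script

Simulation-based checks use cohorts of 2 patients at 20,000 molecules
per sample over 20 seeds (calibration and ordering checks) and
single-joint SP/IP pairs at 12,000 molecules over 20 seeds per sharing
level (rho sweep) — sizes chosen so that Monte-Carlo means are stable
against the tested tolerances while the whole suite stays comfortably
interactive. The rho = 0 chance bound for top-25 retrieval is
100·25/4,000 = 0.625%; with patient-private barcoded CDR3s the true
chance overlap is exactly zero, so the bound is conservative.

## Known limitations

* The Chao–Sørensen variance is not estimated (no bootstrap CIs); the
  index is reported as a point estimate per pair, as in typical use.
* Repertoires are held as in-memory pandas tables; samples of tens of
  millions of molecules would need chunked readers.
* The manifest model fixes one compartment per sample and one joint per
  tissue sample; longitudinal designs are representable only via
  `collection_day`.
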