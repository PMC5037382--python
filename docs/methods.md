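# Methods

## The prediction task and model

`acpkit` frames anticancer-peptide recognition as binary classification of
short amino-acid sequences (positive = anticancer). Each peptide is mapped
to a fixed-length numeric vector by up to three encoders, the vectors are
min-max scaled, and an RBF-kernel support-vector machine separates the
classes. The modelling assumptions are those of any composition-based
predictor: the discriminative signal is carried by residue usage (AAC),
coarse-grained local ordering (reduced-alphabet dipeptides), and a proxy
for local structural propensity (chemical-shift autocovariance); no
alignment, motif model or positional profile is used.

## Encoders

**AAC.** Frequencies *n_i / L* over the fixed residue order
`ACDEFGHIKLMNPQRSTVWY`. Always sums to 1; invariant under sequence
permutation.

**RAAC.** The sequence is rewritten over 6 hydropathy groups
(1 = {R,D,E,N,Q,K,H}, 2 = {L,I,V,A,M,F}, 3 = {S,T,Y,W}, 4 = {P}, 5 = {G},
6 = {C}) and the 36 ordered dipeptide counts over the overlapping width-2
window are divided by **L** (the literal definition; the vector then sums
to (L−1)/L). Dividing by L−1, which normalizes to 1, is available as
`raac_normalization="by_L_minus_1"`. Feature order is row-major over group
pairs (`raac:1-1`, `raac:1-2`, …). Requires L ≥ 2.

**acACS.** Each atom type (¹Hα, ¹H_N, ¹⁵N, ¹³Cα; tags `HA`, `HN`, `N15`,
`CA13`, always in that order) contributes a per-position series s(p) of
standardized reference shifts, and for lags d = 1..λ the correlation factor

    θ(d) = (1/(L−d)) · Σ_{p=1..L−d} (s_p − s_{p+d})²

is appended. The mean-squared-lagged-difference form is the standard
choice in this descriptor family; a centered autocovariance form
(`acacs_form="autocov"`) is provided as an alternative. Both are exactly 0
on homopolymers, and θ is reversal-invariant (up to floating-point
summation order). Requires L ≥ λ + 1. Default λ = 5 and all four atoms,
i.e. 20 features; both are configurable because the optimal lag/atom
combination is a plain grid a caller can scan.

**Chemical-shift table.** Reference shifts are not a modelling choice we
can derive, so the packaged table
(`acpkit/data/chemical_shifts_synthetic_default.tsv`) is a synthetic
compilation of typical random-coil protein chemical-shift statistics; it
is clearly labelled in its provenance header (proline's amide-proton entry
is a placeholder — proline has none) and is fully replaceable via
`--scale-file` / `EncoderConfig.scale_file`. Scales are z-scored per atom
(population variance) before use; standardization is idempotent and errors
on a constant column. All tests that check θ values numerically use
explicit toy scales, never the packaged table.

**Hybrid vectors** are plain concatenations in the order the parts are
requested, with encoder-prefixed feature names (`aac:G`, `raac:1-2`,
`acacs:N15:d3`) so column identity is reproducible across runs. No
weighting between blocks is applied.

## Classifier

Min-max scaling to [0, 1] is fit on training rows only; applying the
scaler never clips, and a feature that was constant in training maps to 0.
(C, γ) are chosen by exhaustive search over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵},
γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}, maximizing mean stratified k-fold accuracy
(k = 5 by default) with scaling re-fit inside every inner fold; ties break
toward the smallest C, then the smallest γ, so the search is deterministic
given the fold seed. The decision threshold is 0 with the tie at exactly 0
assigned to the positive class (arbitrary but documented). No class
weighting and no probability calibration are applied.

## Evaluation

Metrics: Sn, Sp, Q_A (percent) and MCC from pooled cross-validation
counts; Q_A equals the prevalence-weighted mean of Sn and Sp exactly on
unrounded values. Percentages are rounded half-up to 2 decimals and MCC to
3 (the precision such tables are printed at); unrounded values are always
reported alongside. When an MCC denominator factor is 0 the coefficient is
reported as 0 with a degenerate flag and a warning.

Schemes: jackknife (leave-one-out; n folds for n records) and stratified
k-fold with seed-controlled shuffling. Hyperparameter tuning is either
`global` (once on the full dataset before CV — the cheaper protocol, which
leaks each test record into tuning; the report carries an explicit
leakage note) or `per_fold` (re-searched inside every training split).
`global` is the default; neither mode is claimed to be what any particular
published protocol used.

`recover_confusion` inverts printed (Sn, Sp) and class sizes to integer
counts via half-up rounding. Because printed percentages are quantized,
two readings of an overall accuracy coexist: counts-based Q_A and the
weighted mean of the rounded Sn/Sp (`qa_weighted`); they can differ by one
unit in the last decimal, and recovered MCC values are only reliable to
about one printed ulp. Both readings are exposed.

`class_mean_composition` returns, per class, the unweighted mean of the
per-peptide AAC vectors (each class column sums to 1) — the computation
behind the usual residue-usage comparison plot.

## Synthetic data

The generator emulates the *structure* of an ACP benchmark, not its
biology: two class-separated sets (defaults 138 positive / 206 negative),
lengths uniform on 12–50, residues i.i.d. Negatives follow a background
distribution (uniform by default; a natural-frequency background is
available), positives the background with mass δ moved uniformly onto an
enriched set (default {K, L, F, G}, echoing the cationic/hydrophobic
character of real ACPs). The uniform background keeps expectations
analytic: the enriched-set frequency excess in positives is
δ·(1 − background mass of the set) = 0.24 at δ = 0.3.

Because residues are i.i.d., the signal is compositional only: RAAC adds
little beyond AAC and acACS carries almost none, so pipeline tests score
the AAC encoder and treat the hybrid's extra blocks as noise robustness.
Passing these tests therefore demonstrates correct mechanics and
chance-level honesty, not real-data accuracy: real ACP discrimination
depends on positional and structural regularities this generator does not
produce.

## Problem sizes and statistical tolerances

* Strong-signal check: δ = 0.30, 60+60 peptides, stratified 5-fold,
  grid-searched SVM; Q_A ≥ 90% at the fixed test seed. The acceptance
  script reports the mean over 5 replicate datasets, since a single
  60+60 draw has a Q_A sampling sd of roughly 2–3 points.
* Chance-level check: δ = 0, 100+100 peptides per seed, jackknife, fixed
  mid-grid (C, γ) = (8, 2⁻³), 20 seeds. At n = 200 the per-seed MCC
  sampling sd is ≈ 0.07, so the asserted per-seed band of ±0.25 is a
  3.5σ statement and the mean-within-±0.1 band is ≈ 6σ; smaller per-seed
  datasets would make these bands fail by chance.
* Monotonicity: mean 5-fold Q_A over seeds 1–10 at δ ∈ {0, 0.1, 0.2, 0.3}
  must be non-decreasing, allowing one inversion ≤ 1 point.

These sizes keep the full suite under a minute on one CPU while leaving
the asserted bands statistically comfortable.

## Numerical and design notes

* Rounding is decimal half-up (never banker's), applied only at the
  reporting boundary.
* Validation is strict by default: sequences must be over the canonical
  20-letter alphabet; the ambiguity codes B/J/O/U/X/Z can instead be
  dropped per record or deleted per residue by explicit policy; all other
  characters are always errors.
* Encoding precedes fold splitting (encoders are purely per-record, so no
  information crosses records); scaling, which does pool rows, is fit
  strictly inside each training split, and fold diagnostics expose the
  scaler parameters so this is testable.
* Duplicating every training row leaves the fitted decision function
  unchanged only in the hard-margin regime (no bounded support vectors);
  with active slack it effectively rescales C. The stability test runs in
  the former regime.
* Known limitations: no sequence-redundancy filtering, no length filter,
  no probability outputs, no descriptor families beyond the three
  encoders, and no attempt to reproduce any external benchmark's accuracy
  — external datasets are deliberately out of scope.
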