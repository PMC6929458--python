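# Methods

## Scope and prediction unit

The package predicts the b/y fragment-ion intensity vector of a tryptic
peptide (canonical 20-letter alphabet, length 9–19, precursor charge 2+
or 3+) from a physico-chemical encoding of the peptide and its fragment
sequences. One model is trained per (length, charge) slot, so each model
sees a homogeneous feature dimension `30 + 20(L−1)` and output dimension
`4(L−1)`; a merged-charge "mix" model trains on the union of the 2+ and
3+ rows at one length and is evaluated per charge.

## Masses and the ion grid

Monoisotopic residue masses, proton (1.007276 Da) and water
(18.010565 Da) are shipped as a versioned TSV. b ions are residue sum +
charge·proton; y ions and precursors additionally carry one water. The
intensity grid covers both fragment series at fragment charges 1+ and 2+
(order: b 1+ block, y 1+ block, b 2+ block, y 2+ block, each indexed
1..L−1). Hosting 2+ fragments for both precursor charges is a deliberate
choice: high-resolution HCD libraries of 3+ precursors carry substantial
doubly charged fragments, and a grid that cannot host them cannot score
them. Peaks are assigned to grid ions by nearest m/z with a one-to-one
greedy match (smallest |Δm/z| first), default tolerance 0.05 Th —
appropriate for Orbitrap-class accuracy and configurable.

## Descriptors

Nine descriptors are computed for the whole peptide and for each of the
2(L−1) fragment sequences:

| descriptor | definition | default source |
|---|---|---|
| isoelectric point | zero of the Bjellqvist/Henderson–Hasselbalch net-charge model, bisected on pH 0–14 to < 1e−6 pH | Biopython charge model |
| instability index | (10/L)·Σ DIWV(xᵢ, xᵢ₊₁), Guruprasad dipeptide weights | Biopython |
| aromaticity | fraction of F/W/Y | in-package |
| ss class fractions | fractions of {V,I,Y,F,W,L}, {N,P,G,S}, {E,M,A,L} | in-package |
| helicity | mean Chou–Fasman α-helix propensity | data file |
| hydrophobicity | mean Kyte–Doolittle hydropathy | data file |
| basicity | mean Harrison gas-phase basicity (kcal/mol) | data file |

The bisection runs in-package because library pI solvers stop at a
looser precision than the |net charge| < 0.01 contract we test; the
class fractions are computed in-package to pin the (class1, class2,
class3) output order, since library conventions for the same three
residue classes differ in ordering across versions. The three residue
scales are intentionally configurable (`scale_mean` accepts any complete
residue→value map); the shipped defaults are published scales, and a
single-residue sequence has instability 0 (no dipeptides). The
descriptor profile is defined down to length-1 fragments so that b₁/y₁
slots are populated.

Note one deliberate non-goal: modifications, non-canonical residues and
a/c/x/z or neutral-loss ions are out of scope.

## Feature layout

`[precursor m/z | composition A..Y | peptide physchem ×9 | b₁..b₍L−1₎
then y₁..y₍L−1₎: fragment m/z + physchem ×9]`. The precursor m/z slot
uses the declared precursor charge; fragment m/z slots use 1+ so each
fragment sequence contributes one canonical mass value — the
fragment-charge structure lives in the target vector instead. The layout
is versioned (`feature-layout-version: 1` in persisted matrices and
model bundles) because trained weights are only meaningful against a
fixed slot order.

## Consensus deduplication

Replicate spectra of one (peptide, charge) are max-normalized, projected
on the ion grid (absent ion = 0), and reduced by the per-ion median;
even replicate counts use the mean of the two central values. Counting
an absent ion as 0 rather than skipping it keeps one-off noise
annotations from inflating the consensus. The consensus is not
re-normalized by default (its maximum can fall below 1); COS is
scale-invariant and PCC location/scale-invariant, so this affects only
exported peak lists. Dataset filters keep charges {2, 3} and lengths
9–19; slots with fewer than 5000 peptides are flagged as below the
training threshold rather than dropped, so small synthetic runs remain
usable (`train` refuses flagged slots without `--allow-small`).

## Network and training protocol

Architecture per slot: n × (Conv1D, 10 filters, kernel 3, stride 1,
zero same-padding → ReLU → max-pool width 2, floor semantics) on the
feature vector as a 1-channel signal, then flatten → dense 2·4(L−1) with
ReLU → linear output 4(L−1), predictions clipped at 0 post hoc (the
output layer itself is linear; clipping keeps intensities physical
without saturating gradients). Depth n defaults to 4 and may range 2–7;
a spec whose repeated floor-halving would reach signal length 0 is
rejected with the maximum feasible depth named. With floor pooling every
depth up to 7 is feasible for all lengths 9–19 (190 slots pool to 1
after 7 halvings). All layers and Adam are implemented on numpy with
hand-written backpropagation; initialization is He-scaled normal driven
by a single user seed that also fixes split shuffling and batch order,
making validation traces bit-reproducible.

Training: MSE loss, Adam (lr 1e−3), batch 64, epoch cap 200. Early
stopping monitors mean validation COS (configurable to loss) with
min-delta 0.001 and patience 1 — training ends at the first epoch that
fails to beat its predecessor by 0.001 — and the returned parameters are
those of the best-validation epoch. Passing `min_delta=None` disables
early stopping for controlled experiments. Cross validation is
five-fold with a three-way split: per fold, 20% test (untouched by
training and model selection), 10% of the remaining training rows as
validation; an audit helper verifies the test/train+validation
intersection is empty per fold.

## Synthetic data

The generator emulates what a curated HCD library looks like *to this
pipeline*: uniform-random tryptic peptides (terminal K/R), per-peptide
replicate spectra at theoretical m/z with arbitrary raw intensity units,
multiplicative log-normal ion noise (σ, default 0.1), and
Poisson-distributed unannotated noise peaks (default mean 2/spectrum).
Defaults: 500 peptides, lengths 9–19, charges {2, 3}, 3 replicates. The
ground-truth law (`basicity-v1`) makes y ions dominate with a
mid-sequence positional bell, scales intensity with the fragment's mean
gas-phase basicity, and makes 2+ fragments weak for 2+ precursors but
substantial for 3+ precursors — deterministic, smooth, and built from
descriptor families the feature vector carries, so the regression task
is well-posed by construction and training-recovery tests measure the
learner, not extrapolation. A separate `noise_seed` lets two libraries
share peptides with independent noise, which is what the upper-bound
analysis needs. What the generator does **not** emulate: mobile-proton
fragmentation chemistry, peak-intensity correlations between ions,
retention time, isotope envelopes, or realistic peptide composition
bias; passing tests therefore demonstrate pipeline and learner
correctness, not spectrum-prediction accuracy on real instruments.

## Evaluation

COS and PCC are computed on full grid vectors including zeros. A
zero-prediction vector (possible after clipping) scores COS 0 and PCC
NaN with a flag instead of raising, so batch evaluation completes.
Summaries weight peptides equally within a (length, charge) slot. The
replicate upper bound pairs consensus vectors of peptides shared by two
libraries and averages per slot — with identical libraries it is exactly
1, and it decreases with replicate noise. The Wilcoxon signed-rank test
uses the zero-drop convention, exact null for ≤ 25 nonzero differences
and the normal approximation above.

## Problem sizes and determinism

The test suite and reference runs use desk-scale problems chosen to
exercise every code path: up to 2000 peptides for training recovery
(held-out median COS ≥ 0.85 at σ = 0 with the default 4-layer model),
40–100 peptides for protocol and upper-bound checks, 1000 random
peptides for mass-oracle sweeps, and 10 000 random vector pairs for
metric-oracle equivalence. Every stochastic step is seeded; library
generation is byte-reproducible from its config.

## Known limitations

* Slot models do not share parameters across lengths or charges, so a
  length missing from training has no model (transfer across slots is
  out of scope).
* Fragment m/z collisions within one peptide (rare near-isobaric b/y
  coincidences) resolve by nearest-match order, which can in principle
  swap two near-identical annotations.
* The "mix" model concatenates charges without a charge indicator
  feature beyond precursor m/z; charge-specific fragmentation structure
  must be inferred from that single slot.
* Real `.msp` dialect coverage is limited to the peptide-library
  conventions documented in `spectra_io`; exotic header keys are
  tolerated but ignored.
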