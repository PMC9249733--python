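# Methods

## Label assignment from sorted-library sequencing

Labels are pure functions of read presence (count ≥ `min_count`, default 1)
across the 12 samples; no abundance threshold is applied beyond that.
Antigen binding: positive iff present in both antigen-positive samples;
sequences in exactly one are discarded (irreproducible between replicates);
negative iff absent from both but present in an input sample. Non-specific
binding: positive iff present in ≥3 of the 4 positive samples (PSR/OVA ×
2 replicates) and in none of the 4 negatives, mirrored for negative;
anything else is unlabeled. Variants absent from the antigen samples and
from every input carry no information and are dropped.

Two frequency notions coexist and both are implemented: the *occurrence
fraction* (samples containing the variant / samples considered), which
drives master-dataset ranking, and the per-sample *relative abundance*
(count / total reads), the only reading under which the enrichment ratio
ER = log₂(f_out/f_in) is well defined. ER is computed per replicate and
averaged over replicates with a defined value; a replicate with a zero
count on either side contributes nothing unless a pseudocount (+0.5 reads,
off by default) is configured. A variant absent from all inputs yields a
missing value, not an error.

Master-dataset selection stratifies evenly by specificity (n/2 positive,
n/2 negative); within each stratum all antigen-positive variants are taken
first (they are the scarcer, more informative class), then remaining slots
fill by descending occurrence frequency with ties broken by sequence id —
a deterministic codification of a selection the original protocol described
only loosely.

## Feature encodings

*One-hot*: per-position indicator columns with categories learned from the
fitting set. This mirrors a label-encode-then-one-hot flow: a residue never
seen at a position during fitting has no column and no model weight, so
transforming it raises — the designed behaviour that makes one-hot models
unable to score novel mutations.

*PhysChem (26 descriptors)*: residue counts in alphabetical one-letter
order (features 1–20); counts of hydrophobic {A,I,L,F,V}, amphipathic
{W,Y,M}, polar {Q,N,S,T,C,M} and charged {K,R,D,E,H} residues (21–24; note
M deliberately belongs to two classes); isoelectric point (25); mean
Kyte–Doolittle hydropathy (26). The pI is the root of the net-charge
function under Bjellqvist/ExPASy pKa constants (N-term 7.5, C-term 3.55,
K 10.0, R 12.0, H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0), found by bisection
on pH ∈ [0, 14] to |charge| < 1e-4; net charge is strictly decreasing in
pH, so the root is unique. Terminal-residue-specific pKa refinements used
by some other solvers are not applied; tests tolerate the resulting
sub-0.5-pH-unit differences.

*Embedding*: the mean over positions of the 64-unit hidden state of a
multiplicative LSTM (m_t = (W_mx x_t) ⊙ (W_mh h_{t−1}) feeding the gates)
run over the sequence. The cell parameterization is defined by a weight
file; without one, seeded random weights give a deterministic,
order-sensitive embedding suitable only for structural tests — it carries
no learned information, and the test suite asserts only shape, determinism
and order sensitivity.

## Projection models

The central object is the continuous 1-D projection of a two-class
classifier, used as a surrogate metric for a binding property. For the LDA
model (SVD solver, tolerant of the rank deficiency one-hot matrices always
have), the projection is the raw affine score wᵀx and the threshold is
where the fitted posterior flips (−intercept) — generally not zero. The
sign convention is fixed so the positive class (high affinity / high
non-specific binding) has the higher mean projection. On full-rank data
the fitted direction agrees with the closed-form pooled-covariance solution
S_w⁻¹(μ₁ − μ₀) to 1e-6 relative tolerance (verified in tests, where the
closed form is an independent oracle, not the implementation).

The neural projector is a numpy MLP: two ReLU hidden layers (32, 8 by
default; widths are a repo choice), a single linear node whose activation
*is* the projection, and a 2-way softmax prediction layer, trained with
categorical cross-entropy, Adam (lr 1e-3), batch size 50, 50 epochs by
default (250 recommended for embedding features). Because the prediction
layer is affine in the scalar projection, classification reduces exactly to
`projection > threshold`, with the threshold at the logit crossing.
All randomness (init, batch order) flows from one seed; identical data and
seed give bitwise-identical parameters.

Cross-validation is a plain shuffled (unstratified) k-fold: with n = 4000
and 5 folds this yields 3200/800 train/test splits; the final model is
refit on all n. The kNN baseline reports mean 5-fold CV accuracy for
k = 1…25 (Euclidean, majority vote, ties toward the smaller label index).

## Pareto design

The property plane is (affinity metric, maximize) × (non-specificity
metric, minimize); the non-specificity axis stays in higher-is-worse
orientation throughout. `pareto_front` returns all non-dominated points by
a sort-and-sweep (duplicates of a frontier point are all retained);
`near_frontier` adds the non-frontier points closest to the frontier in
z-scored metric space, deterministically. The single-mutant scan covers
HCDR2 and HCDR3 (HCDR1 is excluded: the library design barely samples it),
skips cysteine, and keeps substitutions with BLOSUM62 ≥ 0 — conservative
mutations, the regime where projection models extrapolate usefully.
`select_designs` prioritizes candidates not dominated by the library
frontier (first pick: the candidate dominating the most library points),
then spreads picks by greedy max–min distance in z-scored space. The
near-frontier and design-selection rules are deterministic stand-ins for
judgment calls a practitioner would make by eye; their parameters are
logged.

## Statistics

Spearman correlations (average-rank ties) are always reported, with
two-sided p from t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom. Pearson
correlations are added only when both variables pass a Shapiro–Wilk
normality gate at α = 0.05 (the gate is skipped, and Pearson omitted, when
n is outside the test's 3–5000 validity range). Group comparisons use
Welch's two-sided t-test; two zero-variance groups with equal means return
p = 1 by convention. The leave-one-residue-out analysis trains on all
sequences lacking a given residue at a given site (capped by the
master-selection rule when the pool exceeds the cap) and evaluates on every
sequence bearing it; one-hot encoders raise on the held-out residue, which
is the expected negative control, while physicochemical and embedding
encoders generalize.

## The simulator and what it does (not) show

The simulator emulates one FACS round of the campaign (the preceding
magnetic pre-enrichment rounds are not simulated; labeling consumes only
the FACS round plus input):

* **Library**: the 8-site × 6-residue design on a synthetic 115-residue
  parent VH (the real parent is not public; the stand-in carries the
  wild-type residues implied by the site labels). 5,000 distinct variants
  are sampled uniformly — sparse relative to the 1.7 × 10⁶ theoretical
  diversity, as in a real campaign. Initial abundances are log-normal
  (σ = 1.0).
* **Truth**: per-(site, residue) effect pairs are bivariate normal with
  sd 1.0 and correlation 0.6 between the affinity and non-specificity
  effects, so residues that raise affinity tend to raise non-specific
  binding — the tradeoff the method exists to resolve. Parent residues are
  the zero reference. Variant latents are additive plus N(0, 0.3) noise;
  no epistasis by default (a sparse pairwise hook exists).
* **Sorting**: per replicate, a variant's gate signal is its latent plus
  N(0, 0.3) display noise, drawn independently per reagent — the two
  non-specificity pseudo-reagents (PSR- and OVA-like) share the latent and
  differ only in this noise, so the 3-of-4 labeling rule is meaningfully
  exercised. Gates keep the top 50% (antigen), top 25% and bottom 10%
  (non-specificity) of the abundance-weighted signal distribution.
  Sequencing draws multinomial counts at depth 10⁵ per sample.

Noise scales (0.3 against a latent sd of ≈2.6) reflect a library whose
behaviour is dominated by additive residue effects — the regime the linear
analysis targets. The simulator omits sequencing error, PCR bias, chimeras,
cell-level gate stochasticity and off-design mutations; passing tests
therefore demonstrate correctness of the pipeline and recoverability of
additive ground truth under realistic sort/sequencing sampling, not
performance on real campaigns.

**Scale choices.** At the 5,000-variant simulated scale the bottom-10%
gate yields only a few hundred specificity-negative variants, so the
master dataset is 800 variants (400/400 by specificity) rather than the
4,000 used at full campaign scale; the end-to-end recovery workflow trains
each property model on *all* variants labeled for that property (80/20
train/holdout split) and uses the master subset where the downstream
analysis needs it (the Pareto plane). Training on the master subset alone
is supported but, at this scale, its selection-biased composition costs
accuracy on the affinity axis.

## Numerical and degenerate-input conventions

Rank-deficient feature matrices are handled by the SVD route's
singular-value cutoff; a feature with zero within-class variance is
discarded by that route (inherited, documented behaviour). Enrichment of a
variant unseen in output or input is missing, not ±∞. Constant vectors
yield an undefined (NaN) Spearman ρ. Empty scan regions yield empty
candidate lists; a sequencing depth of zero yields valid empty samples.
Pareto inputs must be finite. All tie-breaks (master selection,
near-frontier, design selection, kNN votes) are deterministic and
documented at the call site.

## Known limitations

* The simulator's additive truth favours linear models; it cannot reveal
  regimes where the neural projector would outperform LDA.
* The random-weight embedder tests the embedding *interface*; scientific
  use requires pretrained weights supplied as a file.
* Replication against the deposited campaign datasets requires obtaining
  those files separately; only their dialects and the evaluation wiring
  ship here.
* Single-mutant scans do not compose mutations; combinatorial design is
  out of scope.
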