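# Methods

## Model

Each of the n sequences r_1..r_n over a K-letter alphabet may carry two
binding events, recorded by binary labels w_i (first binding) and g_i
(second binding). Each event, when present, occupies a contiguous
window: length J starting at a_i1 ∈ [1, L_i−J+1] for the first, length
J̃ starting at b_i1 for the second. Windows are described by
column-stochastic position-specific probability matrices Θ (K×J) and Θ̃
(K×J̃); non-window residues follow a background distribution θ0. The
defining hierarchical assumption is *dominance of the downstream event*:
when both windows cover a position, its residue is emitted by the Θ̃
column of the second window. In the (w=1, g=1) case the Θ column used
for a surviving first-window position is indexed by that position's rank
within the first window (column j for position a_ij), not re-ranked over
the surviving positions. Positions are 1-based and inclusive throughout
the library; conversion happens only at I/O boundaries. All likelihood
arithmetic is in log space — a 30-mer under a 20-letter background
underflows linear-space doubles.

The four label cases give the per-sequence likelihood: background only
(0,0); first window under Θ (1,0); second window under Θ̃ (0,1); both
windows with Θ̃ dominating overlaps (1,1). Labels can be unobserved
(`NA`); the sets of unknown w and g indices are fixed at input time and
only those entries are ever resampled.

## Priors and full conditionals

Conjugate priors: Dirichlet(α0), Dirichlet(α_j), Dirichlet(α̃_j) on θ0
and the motif columns (symmetric, all-ones by default — flat), uniform
categorical priors on window starts, Bernoulli(p0) on unknown labels
with p0 = 0.5 by default. The Gibbs full conditionals are:

- Θ_j | − ~ Dirichlet(H_{A_j} + α_j), where H_{A_j} counts the letter at
  first-window position j over sequences with w=1 — excluding, when
  g=1, positions covered by the second window. Likewise Θ̃_j with
  H_{B_j} (all g=1 sequences, full window) and θ0 with H_0 (every
  residue not claimed by a motif). All columns j = 1..J are updated,
  including the boundary columns.
- Unknown labels: two-point posteriors, the case likelihood of the one
  affected sequence under each hypothetical value times the Bernoulli
  prior, normalised by log-sum-exp. When both labels of a sequence are
  unknown they are updated one at a time, each conditioned on the
  other's current value (systematic scan).
- Window starts: rows are conditionally independent; the conditional for
  a_i1 enumerates every valid start, evaluating the case likelihood
  (which accounts for overlap with the current b_i), and draws
  categorically. When the relevant label is 0 the conditional reduces to
  the uniform prior — those rows are still resampled so the state keeps
  a fixed shape.

One sweep updates, in order: unknown w, unknown g, all a-starts, all
b-starts, Θ, Θ̃, θ0.

## Grouped shift moves

A position sampler that moves one window at a time gets trapped in
shifted modes: windows sitting uniformly one position off the truth are
self-consistent with a correspondingly shifted motif matrix, and no
single-row update is accepted against the other n−1 rows. Two grouped
Metropolis–Hastings moves escape this: draw δ ∈ {−1, +1} with equal
probability, translate *all* starts of one motif by δ, regenerate the
motif matrix from Dirichlet(H*+α) computed at the shifted windows, and
regenerate the unknown labels from their two-point conditionals under
the shifted matrix; accept or reject the whole group with the standard
ratio (posterior ratio × reverse/forward proposal densities, computed in
log space; the reverse density regenerates the current matrix from
counts at the current windows with the proposed labels in place, then
the current labels under the current matrix). The first move (A, Θ,
unknown w) runs every 5 iterations, the second (B, Θ̃, unknown g) every
10, first before second when both fall due.

**Boundary handling.** The translation is cyclic within each sequence's
valid-start range: a start at the range edge wraps to the opposite end.
A cyclic shift is a bijection on the joint start space, so the proposal
stays symmetric in δ and exactly reversible, and the q-ratio needs no
correction. The alternative — rejecting any proposal that pushes a row
out of range — is available (`boundary="reject"`) but is useless at
realistic sizes: with hundreds of sequences whose irrelevant (label-0)
rows are uniformly placed over a handful of valid starts, some row sits
at a boundary with probability near 1 and the move never fires. Wrapped
rows with label 0 cost nothing (their conditional is uniform); wrapped
relevant rows are priced in by the likelihood ratio.

## Initialisation, estimation, prediction

Initial state: unknown labels ~ Bernoulli(1/2), starts uniform over
valid ranges, all parameter blocks ~ Dirichlet(1). The chain runs 100
iterations with the first 50 discarded as burn-in (both configurable).
The point estimate is MAP over the collected samples: the post-burn-in
snapshot with the highest joint log-posterior (likelihood plus Dirichlet
prior densities plus Bernoulli label priors; uniform position priors are
a constant and are dropped). Masked-label prediction reads the held-out
g values off the MAP snapshot and scores exact agreement.

Motif-length selection fixes J, masks a fraction (default 20%) of the
known g labels — the *same* masked subset for every candidate, for
variance reduction — runs a chain per candidate J̃, and keeps the length
with the highest masked-label accuracy, breaking ties toward the
smaller (more parsimonious) length.

## Synthetic-data generator

The generator draws from the model itself: θ0 ~ Dirichlet(1), motif
columns from symmetric Dirichlets with concentrations η (first motif)
and γ (second), window starts uniform, labels Bernoulli(label_prob),
residues emitted per the four cases with Θ̃ dominating overlaps.
Defaults define the benchmark regime used across the test suite and the
acceptance script: n = 200 equal-length 15-mers over the 20-letter
alphabet, J = 9, J̃ = 5, η = γ = 0.05 (strongly conserved columns —
small concentrations put most mass on one or two letters),
label_prob = 0.3. After generation the g label is hidden with
probability 0.1 where w = 1 and λ where w = 0 (default λ = 1: the
downstream assay is never run on sequences that failed the upstream
step — the hardest, and most realistic, missingness regime). w is never
masked by default; an optional exact-fraction w mask exists for
generality. The separate `mask_labels` operation hides an exact
⌈fraction·known⌉-subset of known g labels (sampling without
replacement) and returns the held-out truths for scoring.

What the generator does *not* emulate: variable peptide lengths, amino
acid composition biases of real proteomes, correlated positions within
motifs, or multiple TCR clones mixing distinct motifs. Passing the
recovery benchmarks therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to real
biological misspecification.

## Numerical choices

- Log-sum-exp for every categorical/Bernoulli normalisation; Dirichlet
  log-densities via gammaln with xlogy so that α = 1 components tolerate
  zero coordinates.
- Categorical draws by inverse-CDF on the cumulative sum; ties broken by
  the draw itself.
- Motif columns written to disk are renormalised and must be within
  1e-6 of the simplex; dataset validation enforces alphabet membership
  and window bounds.
- Determinism: every routine takes a `numpy.random.Generator` or a seed;
  identical seeds give bit-identical traces and byte-identical output
  files.

## Experiment design in the acceptance script

- *Recovery*: the benchmark regime above, one chain of 100 iterations —
  reports final normalised L1 errors (mean absolute error per matrix
  element) for θ0, Θ, Θ̃, masked-g accuracy over the originally hidden
  entries, and exact-start window accuracies counted over sequences
  whose true label makes the window identifiable (w = 1 for A, g = 1
  for B).
- *Shifted-mode rescue*: 40 sequences with one strongly conserved
  planted motif, chain started in the self-consistent +1-shifted mode
  (windows shifted, matrix drawn from the shifted-window counts);
  reports best window accuracy over 50 iterations with and without the
  shift move.
- *Length scan*: benchmark generator with fully observed labels
  (λ = 0), candidates 2..9 against a true J̃ = 5. Scoring masked
  predictions requires known labels, hence the fully labelled regime
  here. Accuracy differences between neighbouring lengths are of the
  order of the binomial noise of the ~40 held-out labels, so the
  selected length can land on 4 or 6 rather than exactly 5; the scan is
  a model-selection heuristic, not a consistent estimator of length at
  this sample size.

## Known limitations

- Single motif per binding event; no gaps, no mixture of motifs, no
  higher-order background. Windows are contiguous by assumption.
- MAP over visited samples is a noisy maximiser; with 50 post-burn-in
  samples the selected snapshot varies between seeds even when the
  posterior is well concentrated.
- The alignment diagnostic (`alignment_diagnostic`) reports when a ±1
  column shift of an estimated matrix would fit the truth better; the
  headline errors are always computed unshifted, trusting the shift
  moves to resolve alignment.
- Label-0 rows of the position state are resampled from their uniform
  conditional each sweep; this keeps state dimensions fixed but means
  those rows carry no information.
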