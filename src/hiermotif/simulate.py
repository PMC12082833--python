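"""Synthetic-data generator with planted hierarchical motifs.

Generates sequence sets from the model itself: a background distribution
drawn from a flat Dirichlet, two planted motifs whose columns come from
symmetric Dirichlets with small concentration (small values give highly
conserved columns), uniform window placement, Bernoulli binding labels,
and partial masking of the second label to mimic assays in which the
downstream binding outcome is unobserved for many sequences — in
particular for sequences that failed the upstream binding step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    DNA_ALPHABET,
    PROTEIN_ALPHABET,
    UNKNOWN,
    LabelState,
    MotifModel,
    PositionState,
    SequenceDataset,
)

__all__ = ["SimConfig", "SimTruth", "generate_dataset", "mask_labels"]


@dataclass
class SimConfig:
    """Parameters of the generating process.

    Defaults reproduce the benchmark regime used throughout the test
    suite: 200 peptide-like sequences of length 15 over the 20-letter
    alphabet, a length-9 first motif and length-5 second motif with
    strongly conserved columns (concentration 0.05), Bernoulli(0.3)
    binding labels, and the second label hidden for 10% of upstream-bound
    sequences and for a fraction ``lam`` (default all) of upstream-unbound
    sequences.
    """

    n: int = 200
    L: int = 15
    K: int = 20
    J: int = 9
    J_tilde: int = 5
    eta: float = 0.05
    gamma: float = 0.05
    label_prob: float = 0.3
    lam: float = 1.0
    missing_w1: float = 0.1
    mask_w_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.gamma <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        for name in ("label_prob", "lam", "missing_w1", "mask_w_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.L < max(self.J, self.J_tilde):
            raise ValueError("sequences must be at least as long as the longer motif")
        if self.K not in (4, 20) and self.K < 2:
            raise ValueError("alphabet size must be >= 2")

    @property
    def alphabet(self) -> str:
        if self.K == 20:
            return PROTEIN_ALPHABET
        if self.K == 4:
            return DNA_ALPHABET
        return PROTEIN_ALPHABET[: self.K]


@dataclass
class SimTruth:
    """Ground truth kept aside for parameter-recovery evaluation."""

    model: MotifModel
    positions: PositionState
    labels_full: LabelState
    labels_masked: LabelState
    masked_g: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    masked_w: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def _draw_columns(K: int, width: int, conc: float, rng: np.random.Generator) -> np.ndarray:
    cols = rng.dirichlet(np.full(K, conc), size=width).T
    # guard against all-zero underflow at tiny concentrations
    cols = np.maximum(cols, 0.0)
    cols /= cols.sum(axis=0, keepdims=True)
    return cols


def generate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SequenceDataset, SimTruth]:
    """Draw a dataset and its generating truth from the hierarchical model.

    Residues are drawn per the four label cases, with the second motif
    governing any position covered by both windows.  After generation the
    second label is masked to unknown with probability ``missing_w1``
    where ``w=1`` and ``lam`` where ``w=0``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    K, L, n = config.K, config.L, config.n
    J, Jt = config.J, config.J_tilde

    theta0 = rng.dirichlet(np.ones(K))
    Theta = _draw_columns(K, J, config.eta, rng)
    ThetaTilde = _draw_columns(K, Jt, config.gamma, rng)
    model = MotifModel(theta0, Theta, ThetaTilde)

    w = (rng.random(n) < config.label_prob).astype(np.int64)
    g = (rng.random(n) < config.label_prob).astype(np.int64)
    a_start = rng.integers(1, L - J + 2, size=n)
    b_start = rng.integers(1, L - Jt + 2, size=n)

    alphabet = config.alphabet
    seqs = []
    for i in range(n):
        codes = np.array([_categorical(theta0, rng) for _ in range(L)])
        if w[i] == 1:
            for j in range(J):
                codes[a_start[i] - 1 + j] = _categorical(Theta[:, j], rng)
        if g[i] == 1:  # second binding dominates overlapped positions
            for j in range(Jt):
                codes[b_start[i] - 1 + j] = _categorical(ThetaTilde[:, j], rng)
        seqs.append("".join(alphabet[k] for k in codes))
    data = SequenceDataset(seqs, alphabet)

    labels_full = LabelState(w.copy(), g.copy())
    g_masked = g.copy()
    mask_prob = np.where(w == 1, config.missing_w1, config.lam)
    hide = rng.random(n) < mask_prob
    g_masked[hide] = UNKNOWN
    w_masked = w.copy()
    hidden_w = np.empty(0, dtype=np.int64)
    if config.mask_w_fraction > 0:
        hidden_w = rng.choice(n, size=int(np.ceil(config.mask_w_fraction * n)), replace=False)
        w_masked[hidden_w] = UNKNOWN
    labels_masked = LabelState(w_masked, g_masked)

    truth = SimTruth(
        model=model,
        positions=PositionState(a_start, b_start, J, Jt),
        labels_full=labels_full,
        labels_masked=labels_masked,
        masked_g=np.flatnonzero(hide),
        masked_w=np.sort(hidden_w),
    )
    return data, truth


def _categorical(p: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))


def mask_labels(
    labels: LabelState, fraction: float, rng: np.random.Generator
) -> tuple[LabelState, list[tuple[int, int]]]:
    """Hide a random subset of the known second-binding labels.

    Exactly ``ceil(fraction * #known)`` known g entries become unknown
    (sampling without replacement).  Returns the masked labels together
    with the held-out ``(index, true value)`` pairs for later scoring.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    known = np.flatnonzero(labels.g != UNKNOWN)
    m = int(np.ceil(fraction * known.size))
    chosen = np.sort(rng.choice(known, size=m, replace=False)) if m else np.empty(0, int)
    held_out = [(int(i), int(labels.g[i])) for i in chosen]
    g_new = labels.g.copy()
    g_new[chosen] = UNKNOWN
    return LabelState(labels.w.copy(), g_new, labels.p0), held_out
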