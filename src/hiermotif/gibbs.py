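"""Full-conditional Gibbs updates.

Each update samples one block of the state from its exact full
conditional: motif columns and the background from conjugate Dirichlet
posteriors built on residue counts, unknown binding labels from two-point
(Bernoulli) posteriors, and binding-window starts from categorical
posteriors enumerated over every valid start.  All normalisation happens
in log space via log-sum-exp.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import logsumexp

from .model import (
    UNKNOWN,
    LabelState,
    MotifModel,
    PositionState,
    SequenceDataset,
    _case_loglik_codes,
)

__all__ = [
    "MotifCounts",
    "accumulate_motif_counts",
    "sample_theta",
    "label_posterior_w",
    "label_posterior_g",
    "sample_label_w",
    "sample_label_g",
    "position_posterior_a",
    "position_posterior_b",
    "sample_position_a",
    "sample_position_b",
    "gibbs_sweep",
]


class MotifCounts(NamedTuple):
    """Residue counts feeding the Dirichlet full conditionals.

    ``H_A`` (K x J) counts letters attributable to the first motif,
    ``H_B`` (K x J~) to the second motif, and ``H_0`` (K,) to the
    background.
    """

    H_A: np.ndarray
    H_B: np.ndarray
    H_0: np.ndarray


def _log_tables(model: MotifModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        return np.log(model.theta0), np.log(model.Theta), np.log(model.ThetaTilde)


def accumulate_motif_counts(
    data: SequenceDataset,
    labels: LabelState,
    positions: PositionState,
) -> MotifCounts:
    """Tally residues by the distribution that governs them.

    Column ``j`` of ``H_A`` counts the letter at the ``j``-th position of
    the first window for sequences with ``w=1`` — excluding, when
    ``g=1``, positions overlapped by the second window.  ``H_B`` counts
    second-window letters for every ``g=1`` sequence.  ``H_0`` counts all
    remaining residues, including entire ``w=g=0`` sequences.
    """
    if (labels.w == UNKNOWN).any() or (labels.g == UNKNOWN).any():
        raise ValueError("labels must be fully instantiated")
    K, J, Jt = data.K, positions.J, positions.J_tilde
    H_A = np.zeros((K, J), dtype=np.int64)
    H_B = np.zeros((K, Jt), dtype=np.int64)
    H_0 = np.zeros(K, dtype=np.int64)
    for i in range(data.n):
        codes = data.codes[i]
        w, g = int(labels.w[i]), int(labels.g[i])
        motif_mask = np.zeros(codes.size, dtype=bool)
        if g == 1:
            b0 = int(positions.b_start[i]) - 1
            for j in range(Jt):
                H_B[codes[b0 + j], j] += 1
            motif_mask[b0:b0 + Jt] = True
        if w == 1:
            a0 = int(positions.a_start[i]) - 1
            for j in range(J):
                if not motif_mask[a0 + j]:  # not claimed by the second motif
                    H_A[codes[a0 + j], j] += 1
            motif_mask[a0:a0 + J] = True
        H_0 += np.bincount(codes[~motif_mask], minlength=K)
    return MotifCounts(H_A, H_B, H_0)


def sample_theta(H: np.ndarray, alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a probability vector from Dirichlet(H + alpha)."""
    H = np.asarray(H, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if (alpha <= 0).any():
        raise ValueError("Dirichlet hyperparameters must be strictly positive")
    if (H < 0).any():
        raise ValueError("counts must be non-negative")
    return rng.dirichlet(H + alpha)


def _two_point_log_posterior(
    i: int,
    data: SequenceDataset,
    labels: LabelState,
    positions: PositionState,
    model: MotifModel,
    which: str,
) -> float:
    """log P(label=1 | -) for the w (``which='w'``) or g label of sequence i."""
    lt0, lT, lTt = _log_tables(model)
    codes = data.codes[i]
    a0, b0 = int(positions.a_start[i]), int(positions.b_start[i])
    if which == "w":
        other = int(labels.g[i])
        f1 = _case_loglik_codes(codes, 1, other, a0, b0, lt0, lT, lTt)
        f0 = _case_loglik_codes(codes, 0, other, a0, b0, lt0, lT, lTt)
    else:
        other = int(labels.w[i])
        f1 = _case_loglik_codes(codes, other, 1, a0, b0, lt0, lT, lTt)
        f0 = _case_loglik_codes(codes, other, 0, a0, b0, lt0, lT, lTt)
    lp1 = f1 + np.log(labels.p0)
    lp0 = f0 + np.log(1.0 - labels.p0)
    return lp1 - logsumexp([lp1, lp0])


def label_posterior_w(i, data, labels, positions, model) -> float:
    """Posterior probability that sequence ``i`` carries the first binding."""
    return float(np.exp(_two_point_log_posterior(i, data, labels, positions, model, "w")))


def label_posterior_g(i, data, labels, positions, model) -> float:
    """Posterior probability that sequence ``i`` carries the second binding."""
    return float(np.exp(_two_point_log_posterior(i, data, labels, positions, model, "g")))


def sample_label_w(i, data, labels, positions, model, rng: np.random.Generator) -> int:
    """Resample the unknown first-binding label of sequence ``i``."""
    if i not in labels.U:
        raise ValueError(f"w label of sequence {i} is observed; refusing to resample")
    p = label_posterior_w(i, data, labels, positions, model)
    return int(rng.random() < p)


def sample_label_g(i, data, labels, positions, model, rng: np.random.Generator) -> int:
    """Resample the unknown second-binding label of sequence ``i``."""
    if i not in labels.U_tilde:
        raise ValueError(f"g label of sequence {i} is observed; refusing to resample")
    p = label_posterior_g(i, data, labels, positions, model)
    return int(rng.random() < p)


def position_posterior_a(i, data, labels, positions, model) -> np.ndarray:
    """Categorical posterior over first-window starts for sequence ``i``.

    When ``w_i = 0`` the likelihood does not involve the first window and
    the posterior reduces to the uniform prior over valid starts.
    """
    L = data.codes[i].size
    n_starts = L - positions.J + 1
    if int(labels.w[i]) == 0:
        return np.full(n_starts, 1.0 / n_starts)
    lt0, lT, lTt = _log_tables(model)
    g = int(labels.g[i])
    b0 = int(positions.b_start[i])
    logf = np.array([
        _case_loglik_codes(data.codes[i], 1, g, x, b0, lt0, lT, lTt)
        for x in range(1, n_starts + 1)
    ])
    return np.exp(logf - logsumexp(logf))


def position_posterior_b(i, data, labels, positions, model) -> np.ndarray:
    """Categorical posterior over second-window starts for sequence ``i``."""
    L = data.codes[i].size
    n_starts = L - positions.J_tilde + 1
    if int(labels.g[i]) == 0:
        return np.full(n_starts, 1.0 / n_starts)
    lt0, lT, lTt = _log_tables(model)
    w = int(labels.w[i])
    a0 = int(positions.a_start[i])
    logf = np.array([
        _case_loglik_codes(data.codes[i], w, 1, a0, x, lt0, lT, lTt)
        for x in range(1, n_starts + 1)
    ])
    return np.exp(logf - logsumexp(logf))


def _draw_categorical(p: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))


def sample_position_a(i, data, labels, positions, model, rng: np.random.Generator) -> int:
    """Draw a new 1-based first-window start for sequence ``i``."""
    return 1 + _draw_categorical(position_posterior_a(i, data, labels, positions, model), rng)


def sample_position_b(i, data, labels, positions, model, rng: np.random.Generator) -> int:
    """Draw a new 1-based second-window start for sequence ``i``."""
    return 1 + _draw_categorical(position_posterior_b(i, data, labels, positions, model), rng)


def gibbs_sweep(
    data: SequenceDataset,
    labels: LabelState,
    positions: PositionState,
    model: MotifModel,
    rng: np.random.Generator,
) -> None:
    """One systematic-scan sweep, updating state in place.

    Update order: unknown w labels, unknown g labels, first-window
    starts, second-window starts, Theta columns, ThetaTilde columns,
    background.  Known labels are never touched.
    """
    for i in labels.U:
        labels.w[i] = sample_label_w(int(i), data, labels, positions, model, rng)
    for i in labels.U_tilde:
        labels.g[i] = sample_label_g(int(i), data, labels, positions, model, rng)
    for i in range(data.n):
        positions.a_start[i] = sample_position_a(i, data, labels, positions, model, rng)
    for i in range(data.n):
        positions.b_start[i] = sample_position_b(i, data, labels, positions, model, rng)
    counts = accumulate_motif_counts(data, labels, positions)
    for j in range(positions.J):
        model.Theta[:, j] = sample_theta(counts.H_A[:, j], model.alpha[:, j], rng)
    for j in range(positions.J_tilde):
        model.ThetaTilde[:, j] = sample_theta(counts.H_B[:, j], model.alpha_tilde[:, j], rng)
    model.theta0[:] = sample_theta(counts.H_0, model.alpha0, rng)
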