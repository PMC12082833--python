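"""Grouped Metropolis-Hastings shift moves.

Position samplers that move one window at a time get trapped in shifted
local modes: every window sitting one position off the true motif is
self-consistent with a correspondingly shifted PSPM.  The two moves here
escape such modes by jointly proposing (i) all binding starts translated
by delta in {-1, +1}, (ii) a motif matrix regenerated from the counts at
the shifted windows, and (iii) unknown labels regenerated under the
shifted matrix, then accepting or rejecting the whole group with the
usual MH ratio.  The first move acts on (A, Theta, unknown w); the
second on (B, ThetaTilde, unknown g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp, xlogy

from .model import (
    LabelState,
    MotifModel,
    PositionState,
    SequenceDataset,
    _case_loglik_codes,
    joint_log_likelihood,
)
from .gibbs import accumulate_motif_counts, _log_tables

__all__ = ["ShiftProposal", "dirichlet_logpdf", "shift_move_first", "shift_move_second"]


def dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    """Log-density of a Dirichlet distribution (0 * log 0 treated as 0)."""
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum() + xlogy(alpha - 1.0, x).sum())


@dataclass
class ShiftProposal:
    """Record of one grouped shift proposal and its MH bookkeeping."""

    delta: int
    valid: bool
    accepted: bool = False
    log_alpha: float = -np.inf
    log_q_forward: float = np.nan
    log_q_reverse: float = np.nan
    proposed_starts: np.ndarray | None = field(default=None, repr=False)
    proposed_matrix: np.ndarray | None = field(default=None, repr=False)
    proposed_labels: np.ndarray | None = field(default=None, repr=False)

    @property
    def alpha(self) -> float:
        return float(np.exp(min(0.0, self.log_alpha)))


def _two_point_proposal_logprobs(
    codes, w, g, a0, b0, tables, p0, which: str
) -> np.ndarray:
    """Normalised log-probabilities [log f*(0), log f*(1)] for one label."""
    lt0, lT, lTt = tables
    if which == "w":
        f = [_case_loglik_codes(codes, z, g, a0, b0, lt0, lT, lTt) for z in (0, 1)]
    else:
        f = [_case_loglik_codes(codes, w, z, a0, b0, lt0, lT, lTt) for z in (0, 1)]
    logf = np.array([f[0] + np.log(1.0 - p0), f[1] + np.log(p0)])
    return logf - logsumexp(logf)


def _log_label_prior(values: np.ndarray, p0: float) -> float:
    k = int(values.sum())
    return k * np.log(p0) + (values.size - k) * np.log(1.0 - p0)


def _shift_move(
    data: SequenceDataset,
    labels: LabelState,
    positions: PositionState,
    model: MotifModel,
    rng: np.random.Generator,
    first: bool,
    boundary: str = "wrap",
) -> ShiftProposal:
    lengths = data.lengths
    delta = int(rng.integers(0, 2)) * 2 - 1
    prop = ShiftProposal(delta=delta, valid=True)

    if first:
        starts, width = positions.a_start, positions.J
        unknown = labels.U
    else:
        starts, width = positions.b_start, positions.J_tilde
        unknown = labels.U_tilde

    if boundary == "wrap":
        # Cyclic translation within each sequence's valid-start range: a
        # bijection, so the proposal stays symmetric in delta and the
        # reverse shift -delta maps the proposal back exactly.
        n_starts = lengths - width + 1
        new_starts = (starts - 1 + delta) % n_starts + 1
    elif boundary == "reject":
        new_starts = starts + delta
        if (new_starts < 1).any() or (new_starts + width - 1 > lengths).any():
            prop.valid = False  # out-of-range for some sequence: auto-reject
            return prop
    else:
        raise ValueError("boundary must be 'wrap' or 'reject'")

    # --- Step 1: propose shifted starts, regenerated matrix, regenerated labels.
    pos_star = positions.copy()
    if first:
        pos_star.a_start = new_starts
    else:
        pos_star.b_start = new_starts
    counts_star = accumulate_motif_counts(data, labels, pos_star)

    model_star = model.copy()
    log_q_fwd = np.log(0.5)
    if first:
        H_star, alpha_cols = counts_star.H_A, model.alpha
    else:
        H_star, alpha_cols = counts_star.H_B, model.alpha_tilde
    matrix_star = np.empty((data.K, width))
    for j in range(width):
        params = H_star[:, j] + alpha_cols[:, j]
        matrix_star[:, j] = rng.dirichlet(params)
        log_q_fwd += dirichlet_logpdf(matrix_star[:, j], params)
    if first:
        model_star.Theta = matrix_star
    else:
        model_star.ThetaTilde = matrix_star

    tables_star = _log_tables(model_star)
    labels_star = labels.copy()
    which = "w" if first else "g"
    cur_vals = labels.w if first else labels.g
    star_vals = labels_star.w if first else labels_star.g
    a_star = pos_star.a_start
    b_star = pos_star.b_start
    for u in unknown:
        u = int(u)
        lp = _two_point_proposal_logprobs(
            data.codes[u], int(labels.w[u]), int(labels.g[u]),
            int(a_star[u]), int(b_star[u]), tables_star, labels.p0, which,
        )
        z = int(np.log(rng.random()) < lp[1])
        star_vals[u] = z
        log_q_fwd += lp[z]

    # --- Step 2: MH acceptance ratio, all in log space.
    # Target: joint likelihood x label prior x matrix prior (uniform position
    # prior is a constant because the valid-start range is shift-invariant).
    log_pi_star = joint_log_likelihood(data, labels_star, pos_star, model_star)
    log_pi_cur = joint_log_likelihood(data, labels, positions, model)
    log_pi_star += _log_label_prior(star_vals[unknown], labels.p0)
    log_pi_cur += _log_label_prior(cur_vals[unknown], labels.p0)
    cur_matrix = model.Theta if first else model.ThetaTilde
    for j in range(width):
        log_pi_star += dirichlet_logpdf(matrix_star[:, j], alpha_cols[:, j])
        log_pi_cur += dirichlet_logpdf(cur_matrix[:, j], alpha_cols[:, j])

    # Reverse proposal: from the proposed state, the shift -delta regenerates
    # the current matrix from counts at the current windows (labels as in the
    # proposed state), then the current labels under the current matrix.
    counts_rev = accumulate_motif_counts(data, labels_star, positions)
    H_rev = counts_rev.H_A if first else counts_rev.H_B
    log_q_rev = np.log(0.5)
    for j in range(width):
        log_q_rev += dirichlet_logpdf(cur_matrix[:, j], H_rev[:, j] + alpha_cols[:, j])
    tables_cur = _log_tables(model)
    for u in unknown:
        u = int(u)
        lp = _two_point_logprobs_for_state(
            data, labels_star, positions, tables_cur, u, which
        )
        log_q_rev += lp[int(cur_vals[u])]

    prop.log_alpha = (log_pi_star - log_pi_cur) + (log_q_rev - log_q_fwd)
    prop.log_q_forward = float(log_q_fwd)
    prop.log_q_reverse = float(log_q_rev)
    prop.proposed_starts = new_starts
    prop.proposed_matrix = matrix_star
    prop.proposed_labels = star_vals[unknown].copy()

    if rng.random() <= prop.alpha:
        prop.accepted = True
        starts[:] = new_starts
        if first:
            model.Theta[:] = matrix_star
            labels.w[unknown] = star_vals[unknown]
        else:
            model.ThetaTilde[:] = matrix_star
            labels.g[unknown] = star_vals[unknown]
    return prop


def _two_point_logprobs_for_state(data, labels, positions, tables, u, which):
    """Reverse-move label proposal log-probabilities at the current windows.

    The conditioning labels (the other binding's label of sequence u) come
    from ``labels``, i.e. the state the reverse move would start from.
    """
    return _two_point_proposal_logprobs(
        data.codes[u], int(labels.w[u]), int(labels.g[u]),
        int(positions.a_start[u]), int(positions.b_start[u]),
        tables, labels.p0, which,
    )


def shift_move_first(
    data: SequenceDataset,
    labels: LabelState,
    positions: PositionState,
    model: MotifModel,
    rng: np.random.Generator,
    boundary: str = "wrap",
) -> ShiftProposal:
    """Grouped shift of all first-binding windows with Theta and unknown w.

    ``boundary`` chooses how starts at the edge of their valid range are
    handled: ``"wrap"`` (default) translates cyclically within each
    sequence's valid-start range, ``"reject"`` discards the whole group
    proposal if any row would leave its range.  Mutates
    ``positions.a_start``, ``model.Theta`` and the unknown entries of
    ``labels.w`` in place when the proposal is accepted; otherwise the
    state is left bit-identical.
    """
    return _shift_move(data, labels, positions, model, rng, first=True, boundary=boundary)


def shift_move_second(
    data: SequenceDataset,
    labels: LabelState,
    positions: PositionState,
    model: MotifModel,
    rng: np.random.Generator,
    boundary: str = "wrap",
) -> ShiftProposal:
    """Grouped shift of all second-binding windows with ThetaTilde and unknown g."""
    return _shift_move(data, labels, positions, model, rng, first=False, boundary=boundary)
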