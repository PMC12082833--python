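"""Core domain types and the observed-data likelihood.

The model assumes each sequence may carry up to two binding events.  The
first event (label ``w``) places a length-``J`` motif described by a
position-specific probability matrix (PSPM) ``Theta``; the second event
(label ``g``) places a length-``J~`` motif described by ``ThetaTilde``.
Binding windows are contiguous and may overlap; residues at positions
covered by the second binding are always governed by the second motif
(the second event sits downstream in the biological hierarchy and its
selection dominates).  Residues outside every binding window follow a
background distribution ``theta0``.

All coordinates are 1-based and inclusive.  All likelihoods are handled
in log space: a length-30 peptide under a 20-letter background already
underflows in linear space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

UNKNOWN = -1  # sentinel for an unobserved binary label

__all__ = [
    "PROTEIN_ALPHABET",
    "DNA_ALPHABET",
    "UNKNOWN",
    "AlphabetError",
    "SequenceDataset",
    "LabelState",
    "PositionState",
    "MotifModel",
    "count_letters",
    "case_log_likelihood",
    "joint_log_likelihood",
]


class AlphabetError(ValueError):
    """A residue is not a member of the declared alphabet."""


def _encode(sequence: str, alphabet: str) -> np.ndarray:
    lookup = {c: k for k, c in enumerate(alphabet)}
    try:
        return np.array([lookup[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - message formatting
        raise AlphabetError(
            f"residue {exc.args[0]!r} not in alphabet {alphabet!r}"
        ) from None


@dataclass
class SequenceDataset:
    """A set of residue strings over a fixed ordered alphabet.

    Parameters
    ----------
    sequences:
        The ``n`` residue strings.
    alphabet:
        Ordered string of the ``K`` distinct letters; defaults to the
        20-letter amino-acid alphabet.
    ids:
        Optional per-sequence identifiers (FASTA headers).
    """

    sequences: list[str]
    alphabet: str = PROTEIN_ALPHABET
    ids: list[str] | None = None
    codes: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise ValueError("need at least one sequence")
        if len(set(self.alphabet)) != len(self.alphabet) or len(self.alphabet) < 2:
            raise ValueError("alphabet must contain at least 2 distinct letters")
        if self.ids is None:
            self.ids = [f"seq{i + 1}" for i in range(len(self.sequences))]
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        self.codes = [_encode(s, self.alphabet) for s in self.sequences]

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def K(self) -> int:
        return len(self.alphabet)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.sequences], dtype=np.int64)


@dataclass
class LabelState:
    """Per-sequence binary binding labels, possibly unobserved.

    ``w`` and ``g`` are int arrays with entries in {0, 1, -1}; ``-1``
    marks an unknown label.  ``U`` / ``U_tilde`` are the index sets of
    unknown ``w`` / ``g``, frozen at construction: samplers overwrite the
    values at those indices in place, while known labels stay immutable.
    """

    w: np.ndarray
    g: np.ndarray
    p0: float = 0.5
    U: np.ndarray | None = None
    U_tilde: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.int64)
        self.g = np.asarray(self.g, dtype=np.int64)
        if self.w.shape != self.g.shape:
            raise ValueError("w and g must have equal length")
        for name, arr in (("w", self.w), ("g", self.g)):
            if not np.isin(arr, (0, 1, UNKNOWN)).all():
                raise ValueError(f"{name} entries must be 0, 1 or {UNKNOWN} (unknown)")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie strictly in (0, 1)")
        if self.U is None:
            self.U = np.flatnonzero(self.w == UNKNOWN)
        if self.U_tilde is None:
            self.U_tilde = np.flatnonzero(self.g == UNKNOWN)
        self.U = np.asarray(self.U, dtype=np.int64)
        self.U_tilde = np.asarray(self.U_tilde, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.w.size

    @property
    def l(self) -> int:
        """Number of unknown first-binding labels."""
        return self.U.size

    @property
    def l_tilde(self) -> int:
        """Number of unknown second-binding labels."""
        return self.U_tilde.size

    def copy(self) -> "LabelState":
        return LabelState(self.w.copy(), self.g.copy(), self.p0,
                          self.U.copy(), self.U_tilde.copy())


@dataclass
class PositionState:
    """Binding-window start positions (1-based, contiguous windows).

    The first binding occupies positions ``a_start[i] .. a_start[i]+J-1``
    of sequence ``i``; the second occupies
    ``b_start[i] .. b_start[i]+J_tilde-1``.
    """

    a_start: np.ndarray
    b_start: np.ndarray
    J: int
    J_tilde: int

    def __post_init__(self) -> None:
        self.a_start = np.asarray(self.a_start, dtype=np.int64)
        self.b_start = np.asarray(self.b_start, dtype=np.int64)
        if self.J < 1 or self.J_tilde < 1:
            raise ValueError("motif lengths must be positive")

    def validate(self, lengths: np.ndarray) -> None:
        if (self.a_start < 1).any() or (self.a_start + self.J - 1 > lengths).any():
            raise IndexError("first-binding window outside sequence bounds")
        if (self.b_start < 1).any() or (self.b_start + self.J_tilde - 1 > lengths).any():
            raise IndexError("second-binding window outside sequence bounds")

    def copy(self) -> "PositionState":
        return PositionState(self.a_start.copy(), self.b_start.copy(), self.J, self.J_tilde)


@dataclass
class MotifModel:
    """Background distribution, the two PSPMs, and their Dirichlet priors.

    ``Theta`` is ``K x J`` and ``ThetaTilde`` is ``K x J_tilde``; every
    column is a probability vector.  ``alpha0``, ``alpha`` and
    ``alpha_tilde`` are the (strictly positive) Dirichlet hyperparameters
    of the background and of each motif column.
    """

    theta0: np.ndarray
    Theta: np.ndarray
    ThetaTilde: np.ndarray
    alpha0: np.ndarray | None = None
    alpha: np.ndarray | None = None
    alpha_tilde: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta0 = np.asarray(self.theta0, dtype=float)
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.ThetaTilde = np.asarray(self.ThetaTilde, dtype=float)
        K = self.theta0.size
        if self.Theta.shape[0] != K or self.ThetaTilde.shape[0] != K:
            raise ValueError("Theta/ThetaTilde rows must match alphabet size")
        if self.alpha0 is None:
            self.alpha0 = np.ones(K)
        if self.alpha is None:
            self.alpha = np.ones_like(self.Theta)
        if self.alpha_tilde is None:
            self.alpha_tilde = np.ones_like(self.ThetaTilde)
        self.alpha0 = np.asarray(self.alpha0, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.alpha_tilde = np.asarray(self.alpha_tilde, dtype=float)
        if (self.alpha0 <= 0).any() or (self.alpha <= 0).any() or (self.alpha_tilde <= 0).any():
            raise ValueError("Dirichlet hyperparameters must be strictly positive")
        for name, arr in (("theta0", self.theta0[:, None]),
                          ("Theta", self.Theta), ("ThetaTilde", self.ThetaTilde)):
            if not np.allclose(arr.sum(axis=0), 1.0, atol=1e-8):
                raise ValueError(f"columns of {name} must sum to 1")

    @property
    def K(self) -> int:
        return self.theta0.size

    @property
    def J(self) -> int:
        return self.Theta.shape[1]

    @property
    def J_tilde(self) -> int:
        return self.ThetaTilde.shape[1]

    def copy(self) -> "MotifModel":
        return MotifModel(self.theta0.copy(), self.Theta.copy(), self.ThetaTilde.copy(),
                          self.alpha0.copy(), self.alpha.copy(), self.alpha_tilde.copy())


def count_letters(sequence: str, positions: Iterable[int], alphabet: str) -> np.ndarray:
    """Count letters of ``sequence`` at the given 1-based positions.

    Returns a length-``K`` integer vector whose ``k``-th entry is the
    number of listed positions holding letter ``alphabet[k]``.
    """
    codes = _encode(sequence, alphabet)
    counts = np.zeros(len(alphabet), dtype=np.int64)
    for p in positions:
        if not 1 <= p <= codes.size:
            raise IndexError(f"position {p} outside sequence of length {codes.size}")
        counts[codes[p - 1]] += 1
    return counts


def _window(start: int, width: int) -> np.ndarray:
    """0-based indices of a 1-based contiguous window."""
    return np.arange(start - 1, start - 1 + width)


def _case_loglik_codes(
    codes: np.ndarray,
    w: int,
    g: int,
    a_start: int,
    b_start: int,
    log_theta0: np.ndarray,
    log_Theta: np.ndarray,
    log_ThetaTilde: np.ndarray,
) -> float:
    """Log-likelihood of one encoded sequence under one label case.

    Residues covered by the second binding are scored under
    ``ThetaTilde``; residues of the first window outside the second
    window are scored under the ``Theta`` column matching their rank in
    the first window; everything else is background.
    """
    L = codes.size
    J = log_Theta.shape[1]
    Jt = log_ThetaTilde.shape[1]
    bgl = log_theta0[codes]
    ll = float(bgl.sum())
    if g == 1:
        if not 1 <= b_start <= L - Jt + 1:
            raise IndexError("second-binding start out of range")
        b_idx = _window(b_start, Jt)
        ll += float(log_ThetaTilde[codes[b_idx], np.arange(Jt)].sum() - bgl[b_idx].sum())
    if w == 1:
        if not 1 <= a_start <= L - J + 1:
            raise IndexError("first-binding start out of range")
        a_idx = _window(a_start, J)
        j = np.arange(J)
        if g == 1:
            # Column j of Theta keeps the rank of the position within the
            # first window; overlapped positions contribute nothing.
            outside = (a_idx < b_start - 1) | (a_idx > b_start + Jt - 2)
            a_idx, j = a_idx[outside], j[outside]
        ll += float(log_Theta[codes[a_idx], j].sum() - bgl[a_idx].sum())
    return ll


def case_log_likelihood(
    sequence: str,
    w: int,
    g: int,
    a_start: int,
    b_start: int,
    model: MotifModel,
    alphabet: str = PROTEIN_ALPHABET,
) -> float:
    """Observed-data log-likelihood of one sequence under labels (w, g).

    The four cases are: (0,0) all residues background; (1,0) first
    window under ``Theta``; (0,1) second window under ``ThetaTilde``;
    (1,1) second window under ``ThetaTilde``, non-overlapped first-window
    positions under their ``Theta`` columns, rest background.
    """
    if w not in (0, 1) or g not in (0, 1):
        raise ValueError("labels must be 0 or 1")
    codes = _encode(sequence, alphabet)
    with np.errstate(divide="ignore"):
        return _case_loglik_codes(
            codes, w, g, a_start, b_start,
            np.log(model.theta0), np.log(model.Theta), np.log(model.ThetaTilde),
        )


def joint_log_likelihood(
    data: SequenceDataset,
    labels: LabelState,
    positions: PositionState,
    model: MotifModel,
) -> float:
    """Sum of per-sequence case log-likelihoods over the whole dataset.

    Every label must be instantiated to 0/1 (unknown entries filled with
    their current sampled values).
    """
    if (labels.w == UNKNOWN).any() or (labels.g == UNKNOWN).any():
        raise ValueError("all labels must be instantiated before evaluating the likelihood")
    with np.errstate(divide="ignore"):
        lt0 = np.log(model.theta0)
        lT = np.log(model.Theta)
        lTt = np.log(model.ThetaTilde)
    total = 0.0
    for i in range(data.n):
        total += _case_loglik_codes(
            data.codes[i], int(labels.w[i]), int(labels.g[i]),
            int(positions.a_start[i]), int(positions.b_start[i]), lt0, lT, lTt,
        )
    return total
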