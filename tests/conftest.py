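"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own likelihood code:
they walk each residue, decide which distribution governs it, and
multiply probabilities directly, so they can arbitrate the vectorised
implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hiermotif.model import MotifModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def oracle_loglik(seq, w, g, a_start, b_start, theta0, Theta, ThetaTilde, alphabet):
    """Per-residue product oracle for the observed-data likelihood.

    Walks the sequence once, assigns each residue its governing
    distribution (second motif wins on overlap; first-motif column index
    is the position's rank within the first window), and sums logs.
    """
    J = np.asarray(Theta).shape[1]
    Jt = np.asarray(ThetaTilde).shape[1]
    idx = {c: k for k, c in enumerate(alphabet)}
    a_pos = set(range(a_start, a_start + J)) if w == 1 else set()
    b_pos = set(range(b_start, b_start + Jt)) if g == 1 else set()
    ll = 0.0
    for p, c in enumerate(seq, start=1):
        k = idx[c]
        if p in b_pos:
            ll += math.log(ThetaTilde[k][p - b_start])
        elif p in a_pos:
            ll += math.log(Theta[k][p - a_start])
        else:
            ll += math.log(theta0[k])
    return ll


def random_model(K, J, Jt, rng, conc=1.0):
    """A motif model with all blocks drawn from symmetric Dirichlets."""
    return MotifModel(
        theta0=rng.dirichlet(np.full(K, conc)),
        Theta=rng.dirichlet(np.full(K, conc), size=J).T,
        ThetaTilde=rng.dirichlet(np.full(K, conc), size=Jt).T,
    )


def spiked_columns(K, letters, alphabet, spike=0.5):
    """PSPM whose column j puts ``spike`` on letters[j], rest spread evenly."""
    M = np.full((K, len(letters)), (1.0 - spike) / (K - 1))
    for j, c in enumerate(letters):
        M[alphabet.index(c), j] = spike
    return M
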