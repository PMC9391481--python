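"""Pseudo-inverse (orthogonalized) storage of limit-cycle attractors.

Given the K*L embedded states xi(mu, lam), the synaptic matrix is

    w_ij = sum_{mu, lam} xi_i(mu, lam+1) * adj_xi_j(mu, lam)

where the adjoint (dual) vectors

    adj_xi(mu, lam) = sum_{alpha, beta} (o^-1)[mu lam, alpha beta] xi(alpha, beta)

are built from the inverse of the pattern overlap (Gram) matrix
o[mu lam, alpha beta] = xi(mu, lam) . xi(alpha, beta) and satisfy the
biorthonormality adj_xi(a) . xi(b) = delta_ab.  Phases wrap cyclically
(the successor of the last phase is the first), so in exact arithmetic
w maps every embedded state to the next state of its cycle: the cycles
are exact attractor orbits of the sign dynamics.

Adjoints are computed over the full concatenated N-vectors — a single
global pseudo-inverse, from which the nine inter/intra-module blocks
w^(kappa, eta) are read off.  This is what makes the embedded cycles
exact states of the coupled three-module system.  Invertibility of the
overlap matrix is generic for random ±1 patterns with K*L << N;
ill-conditioning is reported as an error rather than regularized away.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .errors import ConsistencyError, DegeneracyError
from .patterns import MODULES, PatternSet

#: Condition-number ceiling above which the overlap matrix is treated as
#: degenerate (patterns too close to linear dependence).
CONDITION_LIMIT = 1e8


@dataclass
class AdjointSet:
    """Adjoint vectors and the overlap matrix they derive from."""

    dagger_xi: np.ndarray  # (K*L, N) real adjoint vectors
    overlap: np.ndarray  # (K*L, K*L) Gram matrix of the patterns
    overlap_inverse: np.ndarray
    condition_number: float
    pattern_fingerprint: str = ""

    def orthonormality_error(self, ps: PatternSet) -> float:
        """Max absolute deviation of adj_xi(a) . xi(b) from delta_ab."""
        gram = self.dagger_xi @ ps.xi.T.astype(np.float64)
        return float(np.abs(gram - np.eye(gram.shape[0])).max())


@dataclass
class WeightMatrix:
    """Dense N x N synaptic matrix with the module block partition."""

    w: np.ndarray
    block_index: dict[tuple[str, str], tuple[slice, slice]]
    source_patterns: PatternSet

    def block(self, target: str, source: str) -> np.ndarray:
        """View of the block w^(target, source) (target rows, source cols)."""
        rows, cols = self.block_index[(target, source)]
        return self.w[rows, cols]


def _fingerprint(ps: PatternSet) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(ps.xi).tobytes())
    h.update(f"{ps.K},{ps.L},{ps.layout.N}".encode())
    return h.hexdigest()


def compute_adjoints(ps: PatternSet) -> AdjointSet:
    """Compute adjoint vectors via a dense solve of the overlap system.

    Raises :class:`DegeneracyError` if the overlap matrix condition
    number exceeds ``CONDITION_LIMIT`` (retry with a different pattern
    seed rather than regularizing).
    """
    X = ps.xi.astype(np.float64)
    overlap = X @ X.T
    cond = float(np.linalg.cond(overlap))
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise DegeneracyError(
            f"overlap matrix condition number {cond:.3g} exceeds "
            f"{CONDITION_LIMIT:.0e}; the patterns are too close to linear "
            "dependence — regenerate with a different seed"
        )
    eye = np.eye(overlap.shape[0])
    overlap_inverse = scipy.linalg.solve(overlap, eye, assume_a="sym")
    dagger = overlap_inverse @ X
    return AdjointSet(
        dagger_xi=dagger,
        overlap=overlap,
        overlap_inverse=overlap_inverse,
        condition_number=cond,
        pattern_fingerprint=_fingerprint(ps),
    )


def build_weights(ps: PatternSet, adj: AdjointSet) -> WeightMatrix:
    """Assemble w = sum over states of xi(successor) outer adj_xi(state).

    The phase successor is cyclic, so each embedded state advances one
    phase per update and each cycle closes after L steps.
    """
    if adj.pattern_fingerprint and adj.pattern_fingerprint != _fingerprint(ps):
        raise ConsistencyError(
            "adjoint set was not computed from this pattern set"
        )
    X_next = ps.xi[ps.successor_rows()].astype(np.float64)
    w = X_next.T @ adj.dagger_xi
    lay = ps.layout
    block_index = {
        (tgt, src): (lay.block(tgt), lay.block(src))
        for tgt in MODULES
        for src in MODULES
    }
    return WeightMatrix(w=w, block_index=block_index, source_patterns=ps)


# ---------------------------------------------------------------------------
# Optional persistence: portable binary container + JSON sidecar.


def save_weights(wm: WeightMatrix, path: str | Path) -> Path:
    """Persist the weight matrix (.npz) with a JSON sidecar for integrity."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.parent / (path.name + ".npz")
    np.savez_compressed(path, w=wm.w)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "shape": list(wm.w.shape),
                "pattern_fingerprint": _fingerprint(wm.source_patterns),
            }
        )
    )
    return path


def load_weights(path: str | Path, ps: PatternSet) -> WeightMatrix:
    """Load a persisted weight matrix, verifying it matches ``ps``."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    if meta["pattern_fingerprint"] != _fingerprint(ps):
        raise ConsistencyError(
            f"{path}: stored weights were built from a different pattern set"
        )
    w = np.load(path)["w"]
    lay = ps.layout
    block_index = {
        (tgt, src): (lay.block(tgt), lay.block(src))
        for tgt in MODULES
        for src in MODULES
    }
    return WeightMatrix(w=w, block_index=block_index, source_patterns=ps)
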