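"""Synchronous binary dynamics of the three-module network.

All living neurons update in lockstep:

    s_i(t+1) = sgn( sum_j eps_ij * w_ij * s_j(t) + q_i * [i in V] - theta_i(t) )

with sgn(u) = +1 for u >= 0 and -1 otherwise.  External input q acts on
the visual module only; theta is the (module-uniform) threshold.  Dead
neurons are clamped to -1 (quiet): with zero fan-in their update would
reduce to sgn(-theta), a threshold-sign artifact with no physiological
meaning.

States are exactly ±1, so attractor entry and cycle period are detected
by exact state repetition — no tolerance is involved.  The overlap
order parameter m(mu, lam) = (1/N_living) * sum_i s_i xi_i(mu, lam),
restricted to one module's living neurons, quantifies proximity to each
embedded state.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .errors import ConsistencyError, PasimError
from .learning import WeightMatrix
from .pathology import ConnectivityMask, ThresholdSchedule, threshold_at
from .patterns import ModuleLayout, PatternSet


@dataclass
class NetworkState:
    """Instantaneous network state: a ±1 vector at discrete time t."""

    s: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.int8)
        if self.s.ndim != 1:
            raise ConsistencyError(f"state must be 1-D, got shape {self.s.shape}")
        if not np.isin(self.s, (-1, 1)).all():
            raise ConsistencyError("state entries must be exactly ±1")


@dataclass
class InputSignal:
    """External drive to the visual module.

    ``mode='init'`` (default): the probe pattern is written into the
    initial state and q plays no role during the run.
    ``mode='persistent'``: ``strength * q`` is added to the visual
    field for the first ``duration`` update steps.
    """

    q: np.ndarray
    mode: str = "init"
    strength: float = 1.0
    duration: int = 0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64)
        if self.mode not in ("init", "persistent"):
            raise ConsistencyError(f"unknown input mode {self.mode!r}")

    def padded(self, layout: ModuleLayout) -> np.ndarray:
        """q zero-padded to the full N-vector (nonzero on V only)."""
        if self.q.size != layout.n_visual:
            raise ConsistencyError(
                f"input length {self.q.size} != n_visual {layout.n_visual}"
            )
        full = np.zeros(layout.N)
        full[layout.block("V")] = self.q
        return full


@dataclass
class Trajectory:
    """A simulated orbit: states[k] is the state at time t0 + k."""

    states: np.ndarray  # (steps+1, N) int8
    t0: int = 0
    mask: ConnectivityMask | None = None
    threshold_schedule: ThresholdSchedule | None = None
    input_signal: InputSignal | None = None
    detected_period: int | None = None
    convergence_step: int | None = None

    def __len__(self) -> int:
        return self.states.shape[0]

    def state(self, k: int) -> NetworkState:
        return NetworkState(s=self.states[k], t=self.t0 + k)


def masked_weights(
    w: WeightMatrix, eps: ConnectivityMask | None
) -> np.ndarray:
    """Effective synaptic matrix eps * w (elementwise); w itself if no mask."""
    if eps is None:
        return w.w
    if eps.eps.shape != w.w.shape:
        raise ConsistencyError(
            f"mask shape {eps.eps.shape} != weight shape {w.w.shape}"
        )
    return w.w * eps.eps


def _sgn(field_values: np.ndarray) -> np.ndarray:
    # sgn(0) = +1 by convention
    return np.where(field_values >= 0.0, 1, -1).astype(np.int8)


def step_states(
    S: np.ndarray,
    W_eff: np.ndarray,
    dead: np.ndarray | None = None,
    theta: np.ndarray | None = None,
    q: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous update of a batch of states.

    ``S`` is (B, N) ±1; ``theta`` may be (N,) shared or (B, N) per
    batch member; ``q`` likewise.  Returns the updated (B, N) int8
    batch with dead neurons clamped to -1.
    """
    field_values = S.astype(np.float64) @ W_eff.T
    if q is not None:
        field_values += q
    if theta is not None:
        field_values -= theta
    S_new = _sgn(field_values)
    if dead is not None and len(dead):
        S_new[:, dead] = -1
    return S_new


def update_state(
    state: NetworkState,
    w: WeightMatrix,
    eps: ConnectivityMask | None = None,
    theta: np.ndarray | None = None,
    q: np.ndarray | None = None,
) -> NetworkState:
    """One synchronous update of all living neurons.

    ``theta`` and ``q`` are full-length vectors (or None for zero).
    For repeated stepping prefer :func:`run_simulation`, which applies
    the connectivity mask to the weights once instead of per call.
    """
    N = w.w.shape[0]
    if state.s.size != N:
        raise ConsistencyError(f"state length {state.s.size} != N {N}")
    for name, vec in (("theta", theta), ("q", q)):
        if vec is not None and np.asarray(vec).size != N:
            raise ConsistencyError(f"{name} length != N {N}")
    W_eff = masked_weights(w, eps)
    dead = eps.dead if eps is not None else None
    s_new = step_states(state.s[None, :], W_eff, dead, theta, q)[0]
    return NetworkState(s=s_new, t=state.t + 1)


def run_simulation(
    initial: NetworkState,
    steps: int,
    w: WeightMatrix,
    eps: ConnectivityMask | None = None,
    threshold_schedule: ThresholdSchedule | None = None,
    input_signal: InputSignal | None = None,
) -> Trajectory:
    """Iterate the synchronous update for ``steps`` steps.

    The update at step k uses thresholds evaluated at the pre-update
    time t0 + k.  Persistent input is added for its first ``duration``
    steps.  Fully deterministic given its arguments.
    """
    if steps < 1:
        raise ConsistencyError("steps must be >= 1")
    layout = w.source_patterns.layout
    W_eff = masked_weights(w, eps)
    dead = eps.dead if eps is not None else None
    q_full = None
    if input_signal is not None and input_signal.mode == "persistent":
        q_full = input_signal.strength * input_signal.padded(layout)
    states = np.empty((steps + 1, initial.s.size), dtype=np.int8)
    s = initial.s.copy()
    if dead is not None and len(dead):
        s[dead] = -1
    states[0] = s
    for k in range(steps):
        t = initial.t + k
        theta = (
            threshold_at(threshold_schedule, t, layout)
            if threshold_schedule is not None
            else None
        )
        q = (
            q_full
            if q_full is not None and k < input_signal.duration
            else None
        )
        states[k + 1] = step_states(
            states[k][None, :], W_eff, dead, theta, q
        )[0]
    return Trajectory(
        states=states,
        t0=initial.t,
        mask=eps,
        threshold_schedule=threshold_schedule,
        input_signal=input_signal,
    )


def detect_cycle(
    traj: Trajectory, max_period: int
) -> tuple[int, int] | None:
    """Smallest exact period p <= max_period and its earliest onset.

    Returns (p, onset) such that states[k] == states[k + p] for every
    recorded k >= onset, with at least one such comparison available;
    None if no period fits.
    """
    states = traj.states
    T = states.shape[0]
    for p in range(1, max_period + 1):
        if p >= T:
            break
        mismatch = (states[: T - p] != states[p:]).any(axis=1)
        bad = np.nonzero(mismatch)[0]
        onset = 0 if bad.size == 0 else int(bad[-1]) + 1
        if onset <= T - 1 - p:
            return p, onset
    return None


def overlap(
    state: NetworkState,
    ps: PatternSet,
    module: str,
    eps: ConnectivityMask | None = None,
) -> np.ndarray:
    """Overlap of one module's living neurons with every embedded state.

    Returns the length-K*L vector m(mu, lam) in pattern-row order;
    m = 1 means exact match on the module's living neurons.
    """
    sl = ps.layout.block(module)
    living = (
        eps.living(ps.layout.N)[sl]
        if eps is not None
        else np.ones(sl.stop - sl.start, dtype=bool)
    )
    n_living = int(living.sum())
    if n_living == 0:
        raise PasimError(
            f"overlap undefined: no living neurons in module {module}"
        )
    s_block = state.s[sl][living].astype(np.float64)
    xi_block = ps.xi[:, sl][:, living].astype(np.float64)
    return xi_block @ s_block / n_living


def noisy_probe(
    ps: PatternSet,
    mu: int,
    lam: int,
    noise_fraction: float,
    rng: np.random.Generator,
) -> NetworkState:
    """Embedded state (mu, lam) with a fraction of visual bits flipped.

    Exactly ``round(noise_fraction * n_visual)`` visual-module bits,
    chosen uniformly without replacement, are sign-flipped; the memory
    and perceiving blocks are left intact.  Models a noisy or deformed
    stimulus arriving at an otherwise coherent network state.
    """
    if not 0.0 <= noise_fraction <= 1.0:
        raise ConsistencyError("noise_fraction must lie in [0, 1]")
    s = ps.state(mu, lam).copy()
    n_flip = int(round(noise_fraction * ps.layout.n_visual))
    if n_flip:
        sl = ps.layout.block("V")
        idx = rng.choice(
            np.arange(sl.start, sl.stop), size=n_flip, replace=False
        )
        s[idx] = -s[idx]
    return NetworkState(s=s, t=0)


def stimulus_onset_probe(
    ps: PatternSet,
    mu: int,
    lam: int,
    noise_fraction: float,
    rng: np.random.Generator,
) -> NetworkState:
    """A fresh-stimulus initial condition for perception experiments.

    The visual block carries the noisy stimulus (a fraction of bits of
    xi(mu, lam)'s visual pattern flipped), the memory block holds the
    recalled context (intact), and the perceiving block is uniformly
    random: at stimulus onset the percept has not yet formed and must
    be assembled from bottom-up drive.  This is the probe the outcome
    classifiers are meant for — an intact network re-forms the percept
    within a step or two, while impaired bottom-up projections delay or
    misdirect it.
    """
    probe = noisy_probe(ps, mu, lam, noise_fraction, rng)
    sl = ps.layout.block("P")
    probe.s[sl] = rng.choice(
        np.array([-1, 1], dtype=np.int8), size=ps.layout.n_perceiving
    )
    return probe
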