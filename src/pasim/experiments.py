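"""Scenario runners: probe the (lesioned) network and classify outcomes.

A probe presents a noisy version of an embedded state to the network
and the perceiving module's trajectory is scored against the K fixed
perceiving patterns.  Outcomes:

* ``veridical`` — the perceiving module settles on the probed cycle's
  pattern and stays there for the final ``sustain`` steps, with no
  sustained earlier error.
* ``transient-error-then-veridical`` — veridical at the end, but some
  earlier stretch of >= ``sustain`` consecutive steps did not match the
  probed cycle (erroneous perception that self-corrects).
* ``hallucination-like`` — the perceiving module holds the pattern of a
  *different* cycle for >= ``sustain`` consecutive steps (at the end or
  transiently): a stable percept of something that was not presented.
* ``non-convergent`` — none of the above within the run.

The sweep runners repeat this over many random lesion configurations
("typical case" protocol): a fixed severity, e.g. a fixed necrosis
count or fan-in budget, is realized many times with different random
configurations, and outcome frequencies per severity are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .dynamics import Trajectory, step_states, stimulus_onset_probe
from .learning import WeightMatrix
from .pathology import (
    ConnectivityMask,
    LesionConfig,
    ThresholdSchedule,
    full_mask,
    make_lesion,
)
from .patterns import PatternSet

LABELS = (
    "veridical",
    "transient-error-then-veridical",
    "hallucination-like",
    "non-convergent",
)

#: Perceiving-module overlap above which the state counts as matching a
#: stored percept.  High enough that exact orbit entry always matches
#: and two random patterns essentially never do.
DEFAULT_MATCH_THRESHOLD = 0.95


@dataclass
class OutcomeReport:
    """Classification of one probe trajectory."""

    label: str
    input_cycle: int
    final_cycle: int | None
    match_index: np.ndarray  # per-step best matching cycle, -1 = none
    match_overlap: np.ndarray  # per-step overlap of the best match
    convergence_step: int | None


@dataclass
class SweepResult:
    """Outcome records and per-cell frequencies of a sweep.

    ``records`` has one row per (cell, config, probe); ``frequencies``
    one row per cell with a column per outcome label (rows sum to 1).
    """

    records: pd.DataFrame
    frequencies: pd.DataFrame
    seeds: dict
    typical: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Match series and classification


def perceiving_match_series(
    states: np.ndarray,
    ps: PatternSet,
    eps: ConnectivityMask | None = None,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-matching perceiving pattern per step.

    ``states`` is (T, N) or (T, B, N).  Returns (index, overlap) of the
    same leading shape; index is the best cycle or -1 when its overlap
    is below ``match_threshold``.  Overlaps are computed over living
    perceiving neurons only.
    """
    sl = ps.layout.block("P")
    living = (
        eps.living(ps.layout.N)[sl]
        if eps is not None
        else np.ones(sl.stop - sl.start, dtype=bool)
    )
    n_living = int(living.sum())
    if n_living == 0:
        raise ConsistencyError("no living perceiving neurons")
    P = ps.perceiving_patterns[:, living].astype(np.float64)  # (K, n_liv)
    S = states[..., sl][..., living].astype(np.float64)
    m = S @ P.T / n_living  # (..., K)
    best = np.argmax(m, axis=-1)
    best_overlap = np.take_along_axis(m, best[..., None], axis=-1)[..., 0]
    index = np.where(best_overlap >= match_threshold, best, -1)
    return index.astype(np.int64), best_overlap


def _run_lengths(flags: np.ndarray) -> int:
    """Length of the longest run of True in a boolean vector."""
    if not flags.any():
        return 0
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[::2]).max())


def _max_wrong_run(match: np.ndarray, mu: int) -> int:
    """Longest run of consecutive steps matching one same cycle != mu."""
    best = 0
    run = 0
    prev = None
    for v in match:
        if v != -1 and v != mu and v == prev:
            run += 1
        elif v != -1 and v != mu:
            run = 1
        else:
            run = 0
        prev = v
        best = max(best, run)
    return best


def classify_series(
    match: np.ndarray, input_cycle: int, sustain: int
) -> tuple[str, int | None, int | None]:
    """Label one per-step match-index series.

    Returns (label, final_cycle, convergence_step).  ``sustain`` is the
    number of consecutive steps a percept must persist to count.
    """
    T = match.shape[0]
    if T < sustain:
        raise ConsistencyError(
            f"trajectory of {T} recorded states is shorter than "
            f"sustain={sustain}"
        )
    tail = match[-sustain:]
    final_cycle = (
        int(tail[0]) if tail[0] != -1 and (tail == tail[0]).all() else None
    )
    convergence_step = None
    if final_cycle is not None:
        off = np.flatnonzero(match != final_cycle)
        convergence_step = int(off[-1]) + 1 if off.size else 0
    end_veridical = final_cycle == input_cycle
    if end_veridical:
        if _run_lengths(match != input_cycle) >= sustain:
            return LABELS[1], final_cycle, convergence_step
        return LABELS[0], final_cycle, convergence_step
    if _max_wrong_run(match, input_cycle) >= sustain:
        return LABELS[2], final_cycle, convergence_step
    return LABELS[3], final_cycle, convergence_step


def classify_outcome(
    traj: Trajectory,
    ps: PatternSet,
    input_cycle: int,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
    sustain: int | None = None,
) -> OutcomeReport:
    """Classify a trajectory against the probed cycle.

    ``sustain`` defaults to the cycle period L, so exact orbit entry is
    always veridical and one-or-two-step excursions never flip a label.
    """
    if sustain is None:
        sustain = ps.L
    match, m = perceiving_match_series(
        traj.states, ps, traj.mask, match_threshold
    )
    label, final_cycle, conv = classify_series(match, input_cycle, sustain)
    return OutcomeReport(
        label=label,
        input_cycle=input_cycle,
        final_cycle=final_cycle,
        match_index=match,
        match_overlap=m,
        convergence_step=conv,
    )


# ---------------------------------------------------------------------------
# Batched probe execution (shared by the sweep runners)


def _simulate_batch(
    S0: np.ndarray,
    steps: int,
    W_eff: np.ndarray,
    dead: np.ndarray,
    theta_fn=None,
) -> np.ndarray:
    """Run B probes in lockstep; returns (steps+1, B, N) int8 history."""
    B, N = S0.shape
    states = np.empty((steps + 1, B, N), dtype=np.int8)
    S = S0.astype(np.int8).copy()
    if len(dead):
        S[:, dead] = -1
    states[0] = S
    for k in range(steps):
        theta = theta_fn(k) if theta_fn is not None else None
        states[k + 1] = step_states(states[k], W_eff, dead, theta)
    return states


def _probe_states(
    ps: PatternSet,
    n_probe: int,
    noise_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """n_probe stimulus-onset probes cycling through the cycles."""
    mus = np.arange(n_probe) % ps.K
    S0 = np.stack(
        [
            stimulus_onset_probe(ps, int(mu), 0, noise_fraction, rng).s
            for mu in mus
        ]
    )
    return S0, mus


def _classify_batch(
    states: np.ndarray,
    ps: PatternSet,
    mask: ConnectivityMask | None,
    mus: np.ndarray,
    match_threshold: float,
    sustain: int,
) -> list[tuple[str, int | None, int | None]]:
    match, _ = perceiving_match_series(states, ps, mask, match_threshold)
    return [
        classify_series(match[:, b], int(mus[b]), sustain)
        for b in range(states.shape[1])
    ]


def _frequencies(records: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    freq = (
        records.groupby(by)["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(LABELS), fill_value=0.0)
        .reset_index()
    )
    return freq


# ---------------------------------------------------------------------------
# Scenario runners


def run_bottom_up_impairment(
    ps: PatternSet,
    w: WeightMatrix,
    budget: int,
    n_config: int = 20,
    n_probe: int | None = None,
    seed: int = 0,
    noise_fraction: float = 0.05,
    steps: int | None = None,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
    sustain: int | None = None,
) -> SweepResult:
    """Impaired bottom-up drive to the perceiving module.

    The perceiving module's pooled fan-in from the visual and memory
    modules is cut to ``budget`` surviving connections per neuron
    (out of n_visual + n_memory), realized ``n_config`` times with
    independent random configurations; each realization is probed with
    ``n_probe`` noisy inputs (one per cycle by default).
    """
    layout = ps.layout
    if n_probe is None:
        n_probe = ps.K
    if steps is None:
        steps = 10 * ps.L
    if sustain is None:
        sustain = ps.L
    pool = layout.n_visual + layout.n_memory
    if not 0 <= budget <= pool:
        raise ConfigurationError(
            f"pooled budget {budget} infeasible (pool size {pool})"
        )
    cfg = LesionConfig(fan_in={("P", ("V", "M")): budget})
    root = np.random.SeedSequence(seed)
    rows = []
    for c, child in enumerate(root.spawn(n_config)):
        lesion_seed, noise_seed = child.spawn(2)
        mask = (
            full_mask(layout)
            if budget == pool
            else make_lesion(cfg, layout, seed=lesion_seed)
        )
        W_eff = w.w * mask.eps
        rng = np.random.default_rng(noise_seed)
        S0, mus = _probe_states(ps, n_probe, noise_fraction, rng)
        states = _simulate_batch(S0, steps, W_eff, mask.dead)
        for b, (label, final_cycle, conv) in enumerate(
            _classify_batch(states, ps, mask, mus, match_threshold, sustain)
        ):
            rows.append(
                {
                    "budget": budget,
                    "config": c,
                    "probe": b,
                    "input_cycle": int(mus[b]),
                    "label": label,
                    "final_cycle": final_cycle,
                    "convergence_step": conv,
                }
            )
    records = pd.DataFrame(rows)
    return SweepResult(
        records=records,
        frequencies=_frequencies(records, ["budget"]),
        seeds={"seed": seed, "n_config": n_config, "n_probe": n_probe},
    )


def run_threshold_fluctuation(
    ps: PatternSet,
    w: WeightMatrix,
    sched: ThresholdSchedule,
    n_probe: int = 1,
    seed: int = 0,
    lesion: LesionConfig | None = None,
    phases: Sequence[int] | None = None,
    noise_fraction: float = 0.05,
    steps: int | None = None,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
    sustain: int | None = None,
) -> SweepResult:
    """Sinusoidal threshold fluctuation, probed at every onset phase.

    Each probe is launched with the schedule advanced by a phase offset
    (default: every integer phase of the longest scheduled period), so
    outcomes are recorded as a function of where in the slow
    neuromodulatory cycle the stimulus arrives.  An optional lesion is
    applied once (single random configuration from ``seed``).
    """
    layout = ps.layout
    if steps is None:
        steps = 10 * ps.L
    if sustain is None:
        sustain = ps.L
    if phases is None:
        longest = max(
            (spec.period for spec in sched.entries.values()), default=1
        )
        phases = range(longest)
    phases = np.asarray(list(phases), dtype=np.int64)
    root = np.random.SeedSequence(seed)
    lesion_seed, noise_seed = root.spawn(2)
    mask = (
        make_lesion(lesion, layout, seed=lesion_seed)
        if lesion is not None
        else full_mask(layout)
    )
    W_eff = w.w * mask.eps
    rng = np.random.default_rng(noise_seed)
    S0_probe, mus_probe = _probe_states(ps, n_probe, noise_fraction, rng)
    # batch = phases x probes, sharing time but offset in schedule phase
    B = len(phases) * n_probe
    S0 = np.repeat(S0_probe[None, :, :], len(phases), axis=0).reshape(B, -1)
    mus = np.tile(mus_probe, len(phases))
    phase_of = np.repeat(phases, n_probe)

    def theta_fn(k: int) -> np.ndarray | None:
        if not sched.entries:
            return None
        theta = np.zeros((B, layout.N))
        for module, spec in sched.entries.items():
            vals = spec.value(k + phase_of)
            theta[:, layout.block(module)] = vals[:, None]
        return theta

    states = _simulate_batch(S0, steps, W_eff, mask.dead, theta_fn)
    rows = []
    for b, (label, final_cycle, conv) in enumerate(
        _classify_batch(states, ps, mask, mus, match_threshold, sustain)
    ):
        rows.append(
            {
                "phase": int(phase_of[b]),
                "probe": b % n_probe,
                "input_cycle": int(mus[b]),
                "label": label,
                "final_cycle": final_cycle,
                "convergence_step": conv,
            }
        )
    records = pd.DataFrame(rows)
    return SweepResult(
        records=records,
        frequencies=_frequencies(records, ["phase"]),
        seeds={"seed": seed, "n_probe": n_probe},
    )


def run_combined_necrosis(
    ps: PatternSet,
    w: WeightMatrix,
    grid: Sequence[tuple[str, LesionConfig]],
    n_config: int = 10,
    n_probe: int | None = None,
    seed: int = 0,
    noise_fraction: float = 0.05,
    steps: int | None = None,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
    sustain: int | None = None,
    typical_fraction: float = 0.5,
) -> SweepResult:
    """Grid sweep over combined necrosis/pruning lesion configurations.

    ``grid`` is a sequence of (cell name, LesionConfig).  Each cell is
    realized ``n_config`` times with independent random configurations
    at the same severity, each probed ``n_probe`` times.  A (cell,
    label) pair reaching frequency >= ``typical_fraction`` is flagged
    as a "typical case" of that outcome at that severity.
    """
    layout = ps.layout
    if n_probe is None:
        n_probe = ps.K
    if steps is None:
        steps = 10 * ps.L
    if sustain is None:
        sustain = ps.L
    root = np.random.SeedSequence(seed)
    rows = []
    for (cell, cfg), cell_seed in zip(grid, root.spawn(len(grid))):
        for c, child in enumerate(cell_seed.spawn(n_config)):
            lesion_seed, noise_seed = child.spawn(2)
            mask = make_lesion(cfg, layout, seed=lesion_seed)
            W_eff = w.w * mask.eps
            rng = np.random.default_rng(noise_seed)
            S0, mus = _probe_states(ps, n_probe, noise_fraction, rng)
            states = _simulate_batch(S0, steps, W_eff, mask.dead)
            for b, (label, final_cycle, conv) in enumerate(
                _classify_batch(
                    states, ps, mask, mus, match_threshold, sustain
                )
            ):
                rows.append(
                    {
                        "cell": cell,
                        "config": c,
                        "probe": b,
                        "input_cycle": int(mus[b]),
                        "label": label,
                        "final_cycle": final_cycle,
                        "convergence_step": conv,
                    }
                )
    records = pd.DataFrame(rows)
    freq = _frequencies(records, ["cell"])
    typical = freq.melt(
        id_vars=["cell"], var_name="label", value_name="frequency"
    )
    typical = typical[typical["frequency"] >= typical_fraction].reset_index(
        drop=True
    )
    return SweepResult(
        records=records,
        frequencies=freq,
        seeds={"seed": seed, "n_config": n_config, "n_probe": n_probe},
        typical=typical,
    )
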