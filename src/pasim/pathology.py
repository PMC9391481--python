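"""Disease encoding: necrosis, fan-in pruning, threshold fluctuation.

Three pathological factors act on the network:

* **Necrosis** — a dead neuron's entire row and column of the binary
  connectivity matrix eps are zeroed: it neither receives input nor
  influences anyone.  Its state is clamped to -1 (quiet) by the
  dynamics and excluded from overlap normalization.
* **Fan-in pruning** — for each living neuron of a target module, only
  r incoming connections from a specified source-module group survive,
  chosen uniformly without replacement.  Only incoming (fan-in)
  connectivity is pruned.  A pooled group (e.g. the perceiving module's
  joint input from visual and memory) shares one budget drawn from the
  pooled candidate set, so the per-source split fluctuates around the
  source-size proportions.
* **Threshold fluctuation** — a module-wide slow sinusoid
  theta_kappa(t) = A * sin(2*pi*(t + phase)/T), a symbolic stand-in for
  impaired neuromodulator (acetylcholine) release regulating the
  activity level of a whole module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .errors import ConfigurationError
from .patterns import MODULES, ModuleLayout

#: Canonical key of a fan-in constraint: (target module, source modules).
FanInKey = tuple[str, tuple[str, ...]]


def parse_projection(key: "str | FanInKey") -> FanInKey:
    """Normalize a projection key.

    Accepts ``("P", ("V", "M"))`` or the arrow form ``"P<-V+M"``
    (target, then the pooled source group joined by '+').
    """
    if isinstance(key, str):
        try:
            target, sources = key.split("<-")
        except ValueError as exc:
            raise ConfigurationError(
                f"projection {key!r} is not of the form 'P<-V+M'"
            ) from exc
        parsed = (target.strip(), tuple(s.strip() for s in sources.split("+")))
    else:
        target, srcs = key
        parsed = (target, tuple(srcs))
    tgt, srcs_t = parsed
    if tgt not in MODULES or any(s not in MODULES for s in srcs_t):
        raise ConfigurationError(f"projection {key!r} names unknown modules")
    if len(set(srcs_t)) != len(srcs_t):
        raise ConfigurationError(f"projection {key!r} repeats a source module")
    return parsed


@dataclass
class LesionConfig:
    """Declarative description of a lesion.

    ``dead_counts`` maps module -> number of neurons killed (chosen
    uniformly at random within the module).  ``fan_in`` maps a
    projection — single source or pooled group — to the surviving
    incoming-connection count per living target neuron.  Projections
    not listed stay fully connected (apart from dead rows/columns).
    """

    dead_counts: dict[str, int] = field(default_factory=dict)
    fan_in: dict["str | FanInKey", int] = field(default_factory=dict)
    seed: int | None = None

    def normalized_fan_in(self) -> dict[FanInKey, int]:
        out: dict[FanInKey, int] = {}
        for key, budget in self.fan_in.items():
            pkey = parse_projection(key)
            if pkey in out:
                raise ConfigurationError(f"duplicate projection {key!r}")
            out[pkey] = int(budget)
        # a source module may not appear in two constraints with the
        # same target: the budgets would fight over the same columns
        for (tgt_a, srcs_a) in out:
            for (tgt_b, srcs_b) in out:
                if (tgt_a, srcs_a) < (tgt_b, srcs_b) and tgt_a == tgt_b:
                    if set(srcs_a) & set(srcs_b):
                        raise ConfigurationError(
                            f"projections {(tgt_a, srcs_a)} and "
                            f"{(tgt_b, srcs_b)} overlap"
                        )
        return out


@dataclass
class ConnectivityMask:
    """Realized binary connectivity: eps[i, j] = 1 iff j feeds i."""

    eps: np.ndarray  # (N, N) uint8
    dead: np.ndarray  # sorted indices of dead neurons
    fan_in_spec: dict[FanInKey, int]
    seed: int | None = None

    def living(self, N: int | None = None) -> np.ndarray:
        """Boolean mask of living neurons."""
        n = self.eps.shape[0] if N is None else N
        mask = np.ones(n, dtype=bool)
        mask[self.dead] = False
        return mask

    def realized_fan_in(
        self, layout: ModuleLayout, target: str, sources: tuple[str, ...]
    ) -> np.ndarray:
        """Incoming-connection counts of the target module's living
        neurons from the (living part of the) given source modules."""
        living = self.living()
        rows = np.arange(layout.N)[layout.block(target)]
        rows = rows[living[rows]]
        cols = np.concatenate(
            [np.arange(layout.N)[layout.block(s)] for s in sources]
        )
        cols = cols[living[cols]]
        return self.eps[np.ix_(rows, cols)].sum(axis=1)


def full_mask(layout: ModuleLayout) -> ConnectivityMask:
    """The no-lesion mask: all connections present, nobody dead."""
    return ConnectivityMask(
        eps=np.ones((layout.N, layout.N), dtype=np.uint8),
        dead=np.array([], dtype=np.int64),
        fan_in_spec={},
    )


def make_lesion(
    cfg: LesionConfig, layout: ModuleLayout, seed: int | None = None
) -> ConnectivityMask:
    """Realize a lesion configuration as a connectivity mask.

    Dead neurons are drawn uniformly within each module; for each
    fan-in constraint every living target neuron keeps exactly the
    budgeted number of incoming connections, drawn uniformly without
    replacement from the living pooled sources.  Deterministic for a
    fixed (cfg, seed); ``seed`` overrides ``cfg.seed``.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    N = layout.N
    eps = np.ones((N, N), dtype=np.uint8)

    dead_parts = []
    for module, count in cfg.dead_counts.items():
        if module not in MODULES:
            raise ConfigurationError(f"unknown module {module!r} in dead_counts")
        n_mod = layout.count(module)
        if not 0 <= count <= n_mod:
            raise ConfigurationError(
                f"cannot kill {count} of {n_mod} neurons in module {module}"
            )
        idx = np.arange(N)[layout.block(module)]
        dead_parts.append(rng.choice(idx, size=count, replace=False))
    dead = (
        np.sort(np.concatenate(dead_parts))
        if dead_parts
        else np.array([], dtype=np.int64)
    )
    eps[dead, :] = 0
    eps[:, dead] = 0
    living = np.ones(N, dtype=bool)
    living[dead] = False

    fan_in_spec = cfg.normalized_fan_in()
    for (target, sources), budget in fan_in_spec.items():
        rows = np.arange(N)[layout.block(target)]
        rows = rows[living[rows]]
        cand = np.concatenate(
            [np.arange(N)[layout.block(s)] for s in sources]
        )
        cand = cand[living[cand]]
        C = cand.size
        if not 0 <= budget <= C:
            raise ConfigurationError(
                f"fan-in budget {budget} for {target}<-{'+'.join(sources)} "
                f"infeasible: only {C} living source neurons"
            )
        if budget == C or rows.size == 0:
            continue
        eps[np.ix_(rows, cand)] = 0
        if budget > 0:
            # per-target uniform sample without replacement: keep the
            # `budget` smallest of i.i.d. uniform keys per row
            keys = rng.random((rows.size, C))
            keep = np.argpartition(keys, budget - 1, axis=1)[:, :budget]
            eps[np.repeat(rows, budget), cand[keep].ravel()] = 1
    return ConnectivityMask(
        eps=eps, dead=dead, fan_in_spec=fan_in_spec, seed=seed
    )


# ---------------------------------------------------------------------------
# Threshold schedules


@dataclass(frozen=True)
class SineSpec:
    """One module's threshold sinusoid: A * sin(2*pi*(t + phase)/T)."""

    amplitude: float
    period: int
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ConfigurationError(
                f"threshold period must be >= 1, got {self.period}"
            )

    def value(self, t: "float | np.ndarray") -> "float | np.ndarray":
        return self.amplitude * np.sin(
            2.0 * np.pi * (np.asarray(t, dtype=float) + self.phase)
            / self.period
        )


@dataclass
class ThresholdSchedule:
    """Per-module sinusoidal threshold schedules (uniform within module).

    Modules without an entry have zero threshold at all times.
    """

    entries: dict[str, SineSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for module in self.entries:
            if module not in MODULES:
                raise ConfigurationError(
                    f"unknown module {module!r} in threshold schedule"
                )

    @classmethod
    def perceiving(
        cls, amplitude: float, period: int, phase: float = 0.0
    ) -> "ThresholdSchedule":
        """Convenience: sinusoid on the perceiving module only."""
        return cls({"P": SineSpec(amplitude, period, phase)})


def threshold_at(
    sched: ThresholdSchedule | None, t: float, layout: ModuleLayout
) -> np.ndarray:
    """Length-N threshold vector theta(t); zero where unscheduled."""
    theta = np.zeros(layout.N)
    if sched is None:
        return theta
    for module, spec in sched.entries.items():
        theta[layout.block(module)] = spec.value(t)
    return theta
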