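"""Attractor pattern sets for the three-module network.

The network stores K limit cycles of period L.  Each embedded state
xi(mu, lam) is a concatenated ±1 vector over the visual (V), memory (M)
and perceiving (P) modules.  Within a cycle the V and M blocks step
through L distinct patterns while the P block stays fixed — the
many-to-one ("ten-to-one" at the default L=10) correspondence that
stands in for concept formation: many retinal images, one percept.

Patterns are i.i.d. equiprobable ±1.  The dynamics depend only on the
linear-algebraic structure of the pattern set, not on pictorial
content, so random bit patterns replace meaningful bitmaps; bit-pattern
images supplied as plain PBM files can be substituted via
:func:`read_patterns`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CapacityError, ConfigurationError, FormatError
from .pbm import read_pbm, write_pbm

MODULES = ("V", "M", "P")

#: Standard network size: 900 visual + 1200 memory + 900 perceiving neurons.
DEFAULT_COUNTS = {"V": 900, "M": 1200, "P": 900}
DEFAULT_GRIDS = {"V": (30, 30), "M": (30, 40), "P": (30, 30)}


@dataclass(frozen=True)
class ModuleLayout:
    """Neuron counts and visualization grids of the three modules.

    Module order in every concatenated state vector is V, M, P.
    """

    n_visual: int = DEFAULT_COUNTS["V"]
    n_memory: int = DEFAULT_COUNTS["M"]
    n_perceiving: int = DEFAULT_COUNTS["P"]
    visual_grid: tuple[int, int] = DEFAULT_GRIDS["V"]
    memory_grid: tuple[int, int] = DEFAULT_GRIDS["M"]
    perceiving_grid: tuple[int, int] = DEFAULT_GRIDS["P"]

    def __post_init__(self) -> None:
        for name, count, grid in (
            ("visual", self.n_visual, self.visual_grid),
            ("memory", self.n_memory, self.memory_grid),
            ("perceiving", self.n_perceiving, self.perceiving_grid),
        ):
            if grid[0] * grid[1] != count:
                raise ConfigurationError(
                    f"{name} grid {grid} has {grid[0] * grid[1]} cells "
                    f"but the module holds {count} neurons"
                )
        if self.N <= 0:
            raise ConfigurationError("total neuron count must be positive")

    @property
    def N(self) -> int:
        """Total number of neurons."""
        return self.n_visual + self.n_memory + self.n_perceiving

    def count(self, module: str) -> int:
        return {
            "V": self.n_visual,
            "M": self.n_memory,
            "P": self.n_perceiving,
        }[module]

    def grid(self, module: str) -> tuple[int, int]:
        return {
            "V": self.visual_grid,
            "M": self.memory_grid,
            "P": self.perceiving_grid,
        }[module]

    def block(self, module: str) -> slice:
        """Index range of a module inside a concatenated state vector."""
        if module == "V":
            return slice(0, self.n_visual)
        if module == "M":
            return slice(self.n_visual, self.n_visual + self.n_memory)
        if module == "P":
            return slice(self.n_visual + self.n_memory, self.N)
        raise ConfigurationError(f"unknown module {module!r}")


@dataclass
class PatternSet:
    """The K*L embedded attractor states.

    ``xi`` has shape (K*L, N) with int8 entries ±1, stored row-major by
    (cycle, phase): row ``mu * L + lam`` holds xi(mu, lam) for 0-based
    cycle ``mu`` and phase ``lam``.  The cyclic successor of phase lam
    is ``(lam + 1) % L``.
    """

    layout: ModuleLayout
    K: int
    L: int
    xi: np.ndarray
    seed: int | None = None

    def row(self, mu: int, lam: int) -> int:
        """Flat row index of state (mu, lam), phases taken cyclically."""
        if not 0 <= mu < self.K:
            raise IndexError(f"cycle index {mu} out of range 0..{self.K - 1}")
        return mu * self.L + lam % self.L

    def state(self, mu: int, lam: int) -> np.ndarray:
        """Full N-vector of state (mu, lam)."""
        return self.xi[self.row(mu, lam)]

    def block(self, mu: int, lam: int, module: str) -> np.ndarray:
        """One module's block of state (mu, lam)."""
        return self.xi[self.row(mu, lam), self.layout.block(module)]

    def successor_rows(self) -> np.ndarray:
        """Row indices of each state's cyclic successor, same ordering."""
        idx = np.arange(self.K * self.L)
        mu, lam = divmod(idx, self.L)
        return mu * self.L + (lam + 1) % self.L

    @property
    def perceiving_patterns(self) -> np.ndarray:
        """(K, n_perceiving) array: each cycle's fixed perceiving pattern."""
        sl = self.layout.block("P")
        return self.xi[:: self.L, sl]

    def validate(self) -> None:
        """Check every structural invariant, raising on violation."""
        K, L, N = self.K, self.L, self.layout.N
        if self.xi.shape != (K * L, N):
            raise ConfigurationError(
                f"xi shape {self.xi.shape} != ({K * L}, {N})"
            )
        if not np.isin(self.xi, (-1, 1)).all():
            raise ConfigurationError("pattern entries must be exactly ±1")
        _check_capacity(K, L, N)
        p_sl = self.layout.block("P")
        for mu in range(K):
            cyc = self.xi[mu * L : (mu + 1) * L]
            if not (cyc[:, p_sl] == cyc[0, p_sl]).all():
                raise ConfigurationError(
                    f"cycle {mu}: perceiving block varies along the cycle"
                )
            for module in ("V", "M"):
                blocks = cyc[:, self.layout.block(module)]
                if len(np.unique(blocks, axis=0)) != L:
                    raise ConfigurationError(
                        f"cycle {mu}: {module} blocks are not pairwise distinct"
                    )
        if len(np.unique(self.perceiving_patterns, axis=0)) != K:
            raise ConfigurationError(
                "perceiving patterns are not pairwise distinct across cycles"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatternSet):
            return NotImplemented
        return (
            self.layout == other.layout
            and self.K == other.K
            and self.L == other.L
            and np.array_equal(self.xi, other.xi)
        )


def _check_capacity(K: int, L: int, N: int) -> None:
    # Exact cycle storage needs K*L << N; N/4 is the enforced ceiling.
    if K * L > N // 4:
        raise CapacityError(
            f"K*L = {K * L} exceeds the capacity bound N/4 = {N // 4}"
        )


def _draw_distinct(rng: np.random.Generator, n: int, width: int) -> np.ndarray:
    """n pairwise-distinct random ±1 rows, by rejection resampling."""
    if width < 64 and n > 2**width:
        raise ConfigurationError(
            f"cannot draw {n} distinct patterns of {width} bits"
        )
    rows = rng.choice((-1, 1), size=(n, width)).astype(np.int8)
    while True:
        _, first = np.unique(rows, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(n), first)
        if dup.size == 0:
            return rows
        rows[dup] = rng.choice((-1, 1), size=(dup.size, width))


def generate_patterns(
    layout: ModuleLayout, K: int, L: int, seed: int
) -> PatternSet:
    """Generate a random pattern set with the embedded-cycle structure.

    Entries are i.i.d. equiprobable ±1; the L visual and memory blocks
    of each cycle are pairwise distinct, the K perceiving patterns are
    pairwise distinct (colliding draws are resampled), and each cycle's
    perceiving block is constant.  Deterministic for a fixed seed.
    """
    if K < 1 or L < 1:
        raise ConfigurationError(f"K and L must be >= 1, got K={K}, L={L}")
    _check_capacity(K, L, layout.N)
    rng = np.random.default_rng(seed)
    xi = np.empty((K * L, layout.N), dtype=np.int8)
    p_patterns = _draw_distinct(rng, K, layout.n_perceiving)
    for mu in range(K):
        v = _draw_distinct(rng, L, layout.n_visual)
        m = _draw_distinct(rng, L, layout.n_memory)
        rows = slice(mu * L, (mu + 1) * L)
        xi[rows, layout.block("V")] = v
        xi[rows, layout.block("M")] = m
        xi[rows, layout.block("P")] = p_patterns[mu]
    ps = PatternSet(layout=layout, K=K, L=L, xi=xi, seed=seed)
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# Serialization: one plain PBM per module pattern plus a JSON manifest.

MANIFEST_NAME = "patterns.json"


def _pattern_files(ps: PatternSet) -> dict[str, list[list[str]]]:
    files: dict[str, list[list[str]]] = {"V": [], "M": [], "P": []}
    for mu in range(ps.K):
        files["V"].append(
            [f"cycle{mu:02d}_phase{lam:02d}_visual.pbm" for lam in range(ps.L)]
        )
        files["M"].append(
            [f"cycle{mu:02d}_phase{lam:02d}_memory.pbm" for lam in range(ps.L)]
        )
        # one file per cycle: the perceiving block is phase-invariant
        files["P"].append([f"cycle{mu:02d}_perceiving.pbm"])
    return files


def write_patterns(ps: PatternSet, path: str | Path) -> Path:
    """Write a pattern set as PBM bitmaps plus a JSON manifest.

    Returns the manifest path.  ``read_patterns(write_patterns(ps))``
    reproduces ``ps`` bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lay = ps.layout
    files = _pattern_files(ps)
    for mu in range(ps.K):
        for module in ("V", "M"):
            for lam in range(ps.L):
                grid = ps.block(mu, lam, module).reshape(lay.grid(module))
                write_pbm(path / files[module][mu][lam], grid)
        p_grid = ps.block(mu, 0, "P").reshape(lay.grid("P"))
        write_pbm(path / files["P"][mu][0], p_grid)
    manifest = {
        "n_visual": lay.n_visual,
        "n_memory": lay.n_memory,
        "n_perceiving": lay.n_perceiving,
        "grids": {m: list(lay.grid(m)) for m in MODULES},
        "K": ps.K,
        "L": ps.L,
        "seed": ps.seed,
        "files": files,
    }
    manifest_path = path / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_patterns(path: str | Path) -> PatternSet:
    """Read a pattern set written by :func:`write_patterns`.

    ``path`` may be the manifest file or its directory.  Bitmap
    dimensions are validated against the manifest; mismatches raise
    :class:`FormatError`.
    """
    path = Path(path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    try:
        manifest = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read manifest {path}: {exc}") from exc
    try:
        layout = ModuleLayout(
            n_visual=manifest["n_visual"],
            n_memory=manifest["n_memory"],
            n_perceiving=manifest["n_perceiving"],
            visual_grid=tuple(manifest["grids"]["V"]),
            memory_grid=tuple(manifest["grids"]["M"]),
            perceiving_grid=tuple(manifest["grids"]["P"]),
        )
        K, L = manifest["K"], manifest["L"]
        files = manifest["files"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"manifest {path} missing field: {exc}") from exc
    base = path.parent
    xi = np.empty((K * L, layout.N), dtype=np.int8)

    def load(name: str, module: str) -> np.ndarray:
        grid = read_pbm(base / name)
        if grid.shape != layout.grid(module):
            raise FormatError(
                f"{name}: bitmap shape {grid.shape} does not match "
                f"manifest grid {layout.grid(module)}"
            )
        return grid.ravel()

    for mu in range(K):
        for lam in range(L):
            row = mu * L + lam
            xi[row, layout.block("V")] = load(files["V"][mu][lam], "V")
            xi[row, layout.block("M")] = load(files["M"][mu][lam], "M")
            xi[row, layout.block("P")] = load(files["P"][mu][0], "P")
    ps = PatternSet(layout=layout, K=K, L=L, xi=xi, seed=manifest.get("seed"))
    ps.validate()
    return ps
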