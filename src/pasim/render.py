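"""Bit-pattern visualization of module activity.

A network state is shown as three grids (30x30, 30x40, 30x30 at the
default layout): active (+1) neurons dark, quiet (-1) neurons light.
PBM output is plain text; PNG output marks dead neurons in red and can
be magnified for inspection.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError
from .dynamics import NetworkState
from .patterns import MODULES, ModuleLayout
from .pbm import write_pbm

_MODULE_NAMES = {"V": "visual", "M": "memory", "P": "perceiving"}

ACTIVE_RGB = (0, 0, 0)
QUIET_RGB = (255, 255, 255)
DEAD_RGB = (220, 40, 40)


def render_state(
    state: NetworkState,
    layout: ModuleLayout,
    out_prefix: "str | Path",
    fmt: str = "pbm",
    dead: np.ndarray | None = None,
    scale: int = 8,
) -> list[Path]:
    """Write one grid image per module; returns the created paths.

    ``fmt`` is ``'pbm'`` (plain text, +1 -> 1) or ``'png'`` (dead
    neurons rendered red, image magnified ``scale`` times).
    """
    if state.s.size != layout.N:
        raise ConfigurationError(
            f"state length {state.s.size} != layout N {layout.N}"
        )
    if fmt not in ("pbm", "png"):
        raise ConfigurationError(f"unknown render format {fmt!r}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    dead_mask = np.zeros(layout.N, dtype=bool)
    if dead is not None:
        dead_mask[np.asarray(dead, dtype=np.int64)] = True
    paths = []
    for module in MODULES:
        sl = layout.block(module)
        grid = state.s[sl].reshape(layout.grid(module))
        path = Path(f"{out_prefix}_{_MODULE_NAMES[module]}.{fmt}")
        if fmt == "pbm":
            write_pbm(path, grid)
        else:
            rgb = np.where(
                (grid > 0)[..., None], ACTIVE_RGB, QUIET_RGB
            ).astype(np.uint8)
            rgb[dead_mask[sl].reshape(grid.shape)] = DEAD_RGB
            img = Image.fromarray(rgb, mode="RGB")
            if scale > 1:
                img = img.resize(
                    (grid.shape[1] * scale, grid.shape[0] * scale),
                    resample=Image.NEAREST,
                )
            img.save(path)
        paths.append(path)
    return paths
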