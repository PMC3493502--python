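"""Rendering of map states: orientation hue, OD contours, pinwheel markers."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import hsv_to_rgb  # noqa: E402

from .grid import GridSpec
from .model import FieldState
from .pinwheels import PinwheelSet, orientation_and_selectivity


def map_image(z: np.ndarray, selectivity_brightness: bool = False) -> np.ndarray:
    """RGB image of an OP map: θ as cyclic hue, optionally |z| as brightness."""
    theta, sel = orientation_and_selectivity(z)
    h = np.nan_to_num(theta) / np.pi
    s = np.ones_like(h)
    if selectivity_brightness:
        v = sel / sel.max() if sel.max() > 0 else np.zeros_like(sel)
    else:
        v = np.ones_like(h)
    return hsv_to_rgb(np.stack([h, s, v], axis=-1))


def render_map(state: FieldState, grid: GridSpec, path=None,
               pinwheels: PinwheelSet | None = None,
               od_contours: bool = True,
               selectivity_brightness: bool = False):
    """Render an OP map with optional OD zero contours and pinwheel markers.

    Orientation is shown as cyclic hue; zero contours of the first real
    field are overlaid in black; pinwheels are drawn as star markers,
    upright for charge +½ and rotated for −½. Pure function: the state is
    not modified. Returns the matplotlib figure; saves PNG when ``path``
    is given.
    """
    fig, ax = plt.subplots(figsize=(5, 5 * grid.ly / grid.lx))
    extent = (0, grid.lx, 0, grid.ly)
    ax.imshow(map_image(state.z, selectivity_brightness), origin="lower",
              extent=extent, interpolation="nearest")
    if od_contours and state.os:
        x, y = grid.coords()
        ax.contour(x, y, state.os[0], levels=[0.0], colors="k",
                   linewidths=1.2)
    if pinwheels is not None and len(pinwheels):
        pos = pinwheels.positions
        q = pinwheels.charges
        plus = q > 0
        ax.plot(pos[plus, 0], pos[plus, 1], "w*", mec="k", ms=9)
        ax.plot(pos[~plus, 0], pos[~plus, 1], "k*", mec="w", ms=9)
    ax.set_xlabel("x / Λ")
    ax.set_ylabel("y / Λ")
    ax.set_title(f"t = {state.t:.3g}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
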