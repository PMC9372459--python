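"""Overlay drawing for localization results.

The 3D box is drawn in the image as its projected front face (blue),
back face (red) and the four connecting side edges (yellow); under
perspective the far face appears smaller and nested inside the near one.
"""

from __future__ import annotations

import numpy as np

from .geometry import Localization3D


def draw_box3d(ax, loc: Localization3D) -> None:
    """Draw the projected 3D box of one fruit onto a matplotlib axes."""
    p = np.asarray(loc.projections)  # p1..p8; 0..3 back face, 4..7 front face
    back, front = p[:4], p[4:]
    for face, color in ((front, "tab:blue"), (back, "tab:red")):
        ring = np.vstack([face, face[:1]])
        ax.plot(ring[:, 0], ring[:, 1], color=color, linewidth=1.5)
    for i in range(4):
        ax.plot([back[i, 0], front[i, 0]], [back[i, 1], front[i, 1]],
                color="gold", linewidth=1.0)


def save_overlay(image: np.ndarray, locs: list[Localization3D], path) -> None:
    """Write the RGB image with every fruit's projected 3D box drawn on it."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(image.shape[1] / 100, image.shape[0] / 100), dpi=100)
    ax.imshow(image)
    for loc in locs:
        draw_box3d(ax, loc)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
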