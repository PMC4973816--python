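"""Transcriptome display tile plots in CMY colour space.

Each homoeologue triplet x accession becomes one coloured tile: the
A, B and D copies drive the cyan, magenta and yellow channels.  For
each homoeologue, expression is min-max normalized across the panel to
a value v in [0, 1] where 1 marks the accession with the LOWEST
expression and 0 the highest.  The RGB hexcode is then R = round(255
v_A), G = round(255 v_B), B = round(255 v_D) -- equivalently ink
channels C = 1 - v_A, M = 1 - v_B, Y = 1 - v_D with RGB = 1 - CMY.
Under this mapping all three homoeologues at their panel maxima give a
black tile, all at minima white, a lone high A-copy cyan, and equal
channels a grey; the diploid/tetraploid control rows of a plot render
cyan/magenta/yellow and blue/green/red respectively.

Tiles are rendered pixel-exactly (PNG via Pillow, or a plain SVG of
rectangles), one row per accession and one column per triplet in
pseudomolecule order.
"""

from __future__ import annotations



import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "TileColour",
    "normalize_panel",
    "to_hex",
    "hex_to_rgb",
    "colour_matrix",
    "render_tileplot",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class TileColour:
    """Normalized channel values of one tile and their RGB hexcode."""

    v_a: float
    v_b: float
    v_d: float

    def __post_init__(self):
        for v in (self.v_a, self.v_b, self.v_d):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"normalized value {v} outside [0, 1]")

    @property
    def hexcode(self) -> str:
        return to_hex(self.v_a, self.v_b, self.v_d)


def normalize_panel(values) -> np.ndarray:
    """Min-max normalize across the panel, inverted: 1 = lowest value.

    ``v = (max - x) / (max - min)``; a constant series (max == min) is
    mapped to 0.5 everywhere (no expression contrast to display).
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.full(x.shape, 0.5)
    return (hi - x) / (hi - lo)


def _channel(v: float) -> int:
    # round-half-up to an 8-bit channel
    return int(np.floor(255.0 * v + 0.5))


def to_hex(v_a: float, v_b: float, v_d: float) -> str:
    """RGB hexcode from normalized channel values."""
    for v in (v_a, v_b, v_d):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"normalized value {v} outside [0, 1]")
    return f"{_channel(v_a):02X}{_channel(v_b):02X}{_channel(v_d):02X}"


def hex_to_rgb(hexcode: str) -> tuple[int, int, int]:
    h = hexcode.lstrip("#")
    return tuple(int(h[i : i + 2], 16) for i in (0, 2, 4))


def colour_matrix(
    rpkm_a: pd.DataFrame,
    rpkm_b: pd.DataFrame,
    rpkm_d: pd.DataFrame,
) -> pd.DataFrame:
    """Hexcode per accession x triplet from three RPKM tables.

    Inputs are (triplet x accession) tables sharing index and columns;
    normalization runs per homoeologue across the panel (rows of the
    output are accessions, matching the plot layout).
    """
    if not (rpkm_a.shape == rpkm_b.shape == rpkm_d.shape):
        raise ValueError("the three matrices must share shape")
    v = {}
    for key, df in (("A", rpkm_a), ("B", rpkm_b), ("D", rpkm_d)):
        v[key] = np.apply_along_axis(normalize_panel, 1, df.to_numpy(dtype=float))
    hexes = np.empty(rpkm_a.shape, dtype=object)
    for t in range(rpkm_a.shape[0]):
        for a in range(rpkm_a.shape[1]):
            hexes[t, a] = to_hex(v["A"][t, a], v["B"][t, a], v["D"][t, a])
    return pd.DataFrame(
        hexes.T, index=rpkm_a.columns, columns=rpkm_a.index
    )


def _as_rgb_array(matrix) -> np.ndarray:
    if isinstance(matrix, pd.DataFrame):
        rows = matrix.to_numpy(dtype=object)
    else:
        rows = matrix
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError("ragged colour matrix")
        rows = np.asarray([list(r) for r in rows], dtype=object)
    if rows.ndim != 2 or rows.size == 0:
        raise ValueError("colour matrix must be 2-D and non-empty")
    rgb = np.zeros((rows.shape[0], rows.shape[1], 3), dtype=np.uint8)
    for i in range(rows.shape[0]):
        for j in range(rows.shape[1]):
            rgb[i, j] = hex_to_rgb(str(rows[i, j]))
    return rgb


def render_tileplot(
    matrix,
    path=None,
    tile_width: int = 4,
    tile_height: int = 12,
) -> Image.Image:
    """Render a hexcode matrix (rows = accessions/controls) as tiles.

    Returns the PIL image; writes PNG or SVG when ``path`` is given
    (format chosen by extension).  Tile colours are pixel-exact.
    """
    rgb = _as_rgb_array(matrix)
    img_arr = np.repeat(np.repeat(rgb, tile_height, axis=0), tile_width, axis=1)
    img = Image.fromarray(img_arr, mode="RGB")
    if path is not None:
        p = str(path)
        if p.lower().endswith(".svg"):
            _write_svg(matrix, p, tile_width, tile_height)
        else:
            img.save(p)
    return img


def _write_svg(matrix, path: str, tw: int, th: int) -> None:
    rgb = _as_rgb_array(matrix)
    n_rows, n_cols = rgb.shape[:2]
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{n_cols * tw}" height="{n_rows * th}">'
    ]
    for i in range(n_rows):
        for j in range(n_cols):
            r, g, b = rgb[i, j]
            parts.append(
                f'<rect x="{j * tw}" y="{i * th}" width="{tw}" height="{th}" '
                f'fill="#{r:02X}{g:02X}{b:02X}"/>'
            )
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
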