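"""Color indices computed from leaf mean channel values.

Twenty-eight indices are derived from the region-of-interest channel
means (R, G, B on the 0–255 scale): the raw channels, their pairwise
differences and ratios, a family of algebraic chlorophyll-sensitive
combinations such as (G+B-R)/(2G), and the brightness-normalised
chromaticities r = R/(R+G+B), g, b with their pairwise differences.
Green/blue-dominant indices track chlorophyll absorption (blue and red
light are absorbed, green reflected), which is why they correlate with
SPAD readings.

Indices are evaluated on the per-leaf mean color, one vector per leaf.
A ratio whose denominator is exactly zero yields NaN (flagged missing,
never silently zero); that cannot occur for a real leaf photograph.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .imaging import MeanChannelColor

__all__ = ["FEATURE_NAMES", "CANONICAL_FEATURES", "compute_features", "feature_table"]


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0.0 else float("nan")


def _feature_dict(R: float, G: float, B: float) -> dict[str, float]:
    s = R + G + B
    r = _safe_div(R, s)
    g = _safe_div(G, s)
    b = _safe_div(B, s)
    return {
        "R": R,
        "G": G,
        "B": B,
        "R-G": R - G,
        "R-B": R - B,
        "G-B": G - B,
        "R/G": _safe_div(R, G),
        "R/B": _safe_div(R, B),
        "G/B": _safe_div(G, B),
        "(G-R)/(G+R)": _safe_div(G - R, G + R),
        "(G+B-R)/(2R)": _safe_div(G + B - R, 2 * R),
        "(G+B-R)/(2G)": _safe_div(G + B - R, 2 * G),
        "(G+B-R)/(2B)": _safe_div(G + B - R, 2 * B),
        "(R-G-B)/(R+B)": _safe_div(R - G - B, R + B),
        "(R-G-B)/(R+G)": _safe_div(R - G - B, R + G),
        "(R-G-B)/(G+B)": _safe_div(R - G - B, G + B),
        "(B-G-R)/(R+B)": _safe_div(B - G - R, R + B),
        "(B-G-R)/(B+G)": _safe_div(B - G - R, B + G),
        "(B-G-R)/(G+R)": _safe_div(B - G - R, G + R),
        "(2G-R-B)/(2G+R+B)": _safe_div(2 * G - R - B, 2 * G + R + B),
        "(G-B)/(G+B)": _safe_div(G - B, G + B),
        "(G-B)B/(R+G)": _safe_div((G - B) * B, R + G),
        "r": r,
        "g": g,
        "b": b,
        "r-g": r - g,
        "r-b": r - b,
        "g-b": g - b,
    }


#: Canonical ordering of the 28 color indices (22 RGB-derived, 6 normalised).
FEATURE_NAMES: tuple[str, ...] = tuple(_feature_dict(1.0, 1.0, 1.0))

#: The 21 indices retained after correlation screening against SPAD,
#: in their published order.
CANONICAL_FEATURES: tuple[str, ...] = (
    "R", "G", "r", "g", "b", "r-b", "g-b", "R-B", "G-B", "R/B", "G/B",
    "(G+B-R)/(2R)", "(G+B-R)/(2G)",
    "(R-G-B)/(R+B)", "(R-G-B)/(R+G)", "(R-G-B)/(G+B)",
    "(B-G-R)/(R+B)", "(B-G-R)/(B+G)", "(B-G-R)/(G+R)",
    "(2G-R-B)/(2G+R+B)", "(G-B)/(G+B)",
)


def compute_features(color: MeanChannelColor) -> pd.Series:
    """Evaluate all 28 color indices on one leaf's mean channel values.

    Returns a Series indexed by :data:`FEATURE_NAMES`.  Degenerate
    denominators (possible only for pathological inputs such as a pure
    black region) produce NaN entries.
    """
    vals = _feature_dict(float(color.mean_R), float(color.mean_G), float(color.mean_B))
    return pd.Series(vals, index=list(FEATURE_NAMES), dtype=float)


def feature_table(
    colors: Sequence[MeanChannelColor],
    spad: Sequence[float],
    index: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble an n×28 feature matrix with an aligned ``spad`` column.

    ``index`` (e.g. image filenames) must be unique when given.  Row
    order follows the input order.
    """
    if len(colors) != len(spad):
        raise AlignmentError(f"{len(colors)} color vectors but {len(spad)} SPAD values")
    if index is not None:
        if len(index) != len(colors):
            raise AlignmentError(f"{len(index)} index labels but {len(colors)} samples")
        dup = pd.Index(index)[pd.Index(index).duplicated()].unique().tolist()
        if dup:
            raise AlignmentError(f"duplicate sample identifiers: {dup}")
    rows = [compute_features(c) for c in colors]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES), dtype=float)
    if index is not None:
        df.index = pd.Index(index, name="filename")
    df["spad"] = np.asarray(spad, dtype=float)
    return df
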