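"""Radial Coordinate Visualization (RadViz) projection.

RadViz maps an n-dimensional point to the equilibrium position of a point
attached by springs to n anchors on the unit circle, with spring constants
equal to the (min-max normalised) attribute values:

    u = sum_j y'_j (cos a_j, sin a_j) / sum_j y'_j

Rows whose attribute sum is zero map to the origin.  The projection always
lands inside the convex hull of the anchors and is invariant to a common
positive rescaling of an un-normalised row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .classify import FeatureTable

#: the four level-5 attributes covering the Cat2 -> Max3 neighbourhood
SEGMENT_ATTRS = ("w5coef24", "w5coef25", "w5coef26", "w5coef27")


@dataclass
class RadVizLayout:
    """Circular anchors: one angle (radians) per projected attribute."""

    attribute_names: list[str]
    anchor_angles: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.attribute_names)
        if self.anchor_angles is None:
            self.anchor_angles = 2.0 * np.pi * np.arange(n) / n
        self.anchor_angles = np.asarray(self.anchor_angles, dtype=float)
        if len(self.anchor_angles) != n:
            raise ParameterError("one anchor angle per attribute required")
        if len(np.unique(np.mod(self.anchor_angles, 2 * np.pi))) != n:
            raise ParameterError("anchor angles must be distinct")

    @property
    def anchors(self) -> np.ndarray:
        return np.column_stack([np.cos(self.anchor_angles),
                                np.sin(self.anchor_angles)])


def project(points: np.ndarray, layout: RadVizLayout,
            normalize: bool = True) -> np.ndarray:
    """Project n-dim rows onto the plane of the layout's anchors."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] != len(layout.attribute_names):
        raise ParameterError(
            f"points have {pts.shape[1]} columns, layout expects "
            f"{len(layout.attribute_names)}")
    if normalize:
        lo = pts.min(axis=0)
        rng = pts.max(axis=0) - lo
        rng[rng == 0.0] = 1.0
        pts = (pts - lo) / rng
    weights = pts.sum(axis=1)
    out = np.zeros((len(pts), 2))
    nz = weights != 0.0
    out[nz] = (pts[nz] @ layout.anchors) / weights[nz, None]
    return out


def project_wavelet_subset(table: FeatureTable,
                           attrs: tuple[str, ...] = SEGMENT_ATTRS,
                           normalize: bool = True) -> pd.DataFrame:
    """Project selected wavelet attributes; returns u1, u2 plus labels."""
    if table.mode != "wavelet32":
        raise ParameterError("RadViz subset projection requires wavelet32 mode")
    missing = [a for a in attrs if a not in table.frame.columns]
    if missing:
        raise ParameterError(f"missing attributes {missing}")
    layout = RadVizLayout(list(attrs))
    uv = project(table.frame[list(attrs)].to_numpy(), layout, normalize)
    return pd.DataFrame({
        "tissue": table.frame["tissue"].to_numpy(),
        "subject": table.frame["subject"].to_numpy(),
        "replicate": table.frame["replicate"].to_numpy(),
        "u1": uv[:, 0], "u2": uv[:, 1],
    })
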