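"""A small knee/elbow locator for monotone curves (Kneedle-style).

Normalizes the curve to the unit square, flips it onto an increasing concave
reference shape, and returns the x at the maximum vertical distance from the
diagonal.  Sufficient for the two curves this package needs: a decreasing
convex within-cluster-sum-of-squares curve (elbow for K) and an increasing
convex sorted k-distance curve (epsilon for DBSCAN).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np


def find_knee(x, y, curve: str = "convex",
              direction: str = "decreasing") -> Optional[Tuple[float, float]]:
    """Locate the point of maximum curvature on a monotone curve.

    Returns ``(x_knee, y_knee)`` or None when the curve has no knee (e.g. a
    straight line, or fewer than 3 points).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        return None
    x_range = x[-1] - x[0]
    y_range = y.max() - y.min()
    if x_range == 0 or y_range == 0:
        return None
    xn = (x - x[0]) / x_range
    yn = (y - y.min()) / y_range

    if curve == "convex" and direction == "decreasing":
        diff = (1.0 - yn) - xn
    elif curve == "convex" and direction == "increasing":
        diff = xn - yn
    elif curve == "concave" and direction == "increasing":
        diff = yn - xn
    elif curve == "concave" and direction == "decreasing":
        diff = yn - (1.0 - xn)
    else:
        raise ValueError(f"unknown curve/direction: {curve}/{direction}")

    i = int(np.argmax(diff))
    if diff[i] <= 1e-9 or i == 0 or i == x.size - 1:
        return None
    return float(x[i]), float(y[i])
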