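"""Observation windows and planar point patterns.

Coordinates are Cartesian (x right, y up) in micrometres.  A pattern is a
finite set of cell-centre locations observed inside a rectangular window;
the window matters because every summary statistic downstream (K, L, the
Geyer pseudolikelihood) is defined relative to the observed region and
needs its area and boundary for edge correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Window", "PointPattern"]


@dataclass(frozen=True)
class Window:
    """Rectangular observation region [x_min, x_max] x [y_min, y_max] in um."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def shorter_side(self) -> float:
        return min(self.width, self.height)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of rows of ``points`` (n, 2) lying inside the window."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= self.x_min)
            & (pts[:, 0] <= self.x_max)
            & (pts[:, 1] >= self.y_min)
            & (pts[:, 1] <= self.y_max)
        )

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest window edge."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return np.minimum.reduce(
            [
                pts[:, 0] - self.x_min,
                self.x_max - pts[:, 0],
                pts[:, 1] - self.y_min,
                self.y_max - pts[:, 1],
            ]
        )

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Window":
        return cls(d["x_min"], d["x_max"], d["y_min"], d["y_max"])


class PointPattern:
    """A finite planar point pattern with its observation window.

    Parameters
    ----------
    points : array-like, shape (n, 2)
        Cell-centre coordinates (x, y) in micrometres.
    window : Window
        Observation region.  All points must lie inside it.
    """

    def __init__(self, points, window: Window):
        pts = np.asarray(points, dtype=float).reshape(-1, 2).copy()
        if pts.size and not window.contains(pts).all():
            raise ValueError("all points must lie inside the window")
        self.points = pts
        self.window = window

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def intensity(self) -> float:
        """Empirical intensity beta-hat = n / |W| (cells per um^2)."""
        return self.n / self.window.area

    def pairwise_distances(self) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        if self.n < 2:
            return np.zeros((self.n, self.n))
        return squareform(pdist(self.points))

    def nearest_neighbour_distances(self) -> np.ndarray:
        """Distance from each point to its nearest other point."""
        if self.n < 2:
            return np.full(self.n, np.nan)
        d = self.pairwise_distances()
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)

    def min_nn_distance(self) -> float:
        d = self.nearest_neighbour_distances()
        return float(np.nanmin(d)) if self.n >= 2 else np.inf

    def scaled(self, c: float) -> "PointPattern":
        """Pattern with all coordinates and the window scaled by ``c``."""
        w = Window(
            self.window.x_min * c,
            self.window.x_max * c,
            self.window.y_min * c,
            self.window.y_max * c,
        )
        return PointPattern(self.points * c, w)

    # --- persistence: CSV with x,y header + JSON sidecar for the window ---

    def to_csv(self, path) -> None:
        import json

        path = Path(path)
        pd.DataFrame(self.points, columns=["x", "y"]).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".window.json")
        sidecar.write_text(json.dumps(self.window.to_dict()))

    @classmethod
    def from_csv(cls, path, window: Window | None = None) -> "PointPattern":
        import json

        path = Path(path)
        df = pd.read_csv(path)
        if window is None:
            sidecar = path.with_suffix(path.suffix + ".window.json")
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"no window given and sidecar {sidecar} not found"
                )
            window = Window.from_dict(json.loads(sidecar.read_text()))
        return cls(df[["x", "y"]].to_numpy(), window)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PointPattern(n={self.n}, window=[{self.window.x_min:g}, "
            f"{self.window.x_max:g}] x [{self.window.y_min:g}, {self.window.y_max:g}])"
        )
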