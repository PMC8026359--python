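"""Sulcus-aligned stimulation-grid geometry.

The mapping grid is anchored to the gyrus–sulcus border of the precentral
hand knob: a digitized 3D polyline (:class:`SulcusCurve`).  The first grid
line is laid on that curve with equidistant targets (default 5 mm on-line
spacing, 7 targets); four further lines are offset anteriorly in 5 mm steps,
each following the local shape of the curve, for 5 × 7 = 35 targets.  At every
target the coil orientation is the local in-plane anterior normal — the
direction of the second-phase induced current, posterior→anterior and
perpendicular to the local line tangent.

Coordinates are continuous millimetres in an MNI-like frame (x lateral,
y anterior, z superior); there is no voxel indexing anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError

ANTERIOR = np.array([0.0, 1.0, 0.0])


@dataclass
class SulcusCurve:
    """Ordered 3D polyline (mm) tracing the precentral gyrus–sulcus border."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise GeometryError("curve needs an (n>=2, 3) array of points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise GeometryError("consecutive curve points must be distinct")
        self.points = pts

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @classmethod
    def from_csv(cls, path) -> "SulcusCurve":
        df = pd.read_csv(path)
        missing = {"x", "y", "z"} - set(df.columns)
        if missing:
            raise GeometryError(f"curve CSV lacks columns {sorted(missing)}")
        return cls(df[["x", "y", "z"]].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.points, columns=["x", "y", "z"]).to_csv(path, index=False)


@dataclass
class TargetSite:
    """One stimulation target: grid indices, position, coil orientation."""

    line_index: int      # 1..n_lines, 1 = most posterior (on the sulcus border)
    target_index: int    # 1..n_targets along the line
    position: np.ndarray
    orientation: np.ndarray  # unit vector, anterior-pointing, ⟂ local tangent


@dataclass
class StimulationGrid:
    """The full sulcus-aligned grid: positions/orientations as (lines, targets, 3)."""

    positions: np.ndarray
    orientations: np.ndarray
    spacing_on_line: float
    interline_spacing: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.orientations = np.asarray(self.orientations, float)
        if self.positions.shape != self.orientations.shape or self.positions.ndim != 3:
            raise GeometryError("positions/orientations must both be (lines, targets, 3)")

    @property
    def n_lines(self) -> int:
        return self.positions.shape[0]

    @property
    def n_targets(self) -> int:
        return self.positions.shape[1]

    @property
    def n_sites(self) -> int:
        return self.n_lines * self.n_targets

    def site(self, line_index: int, target_index: int) -> TargetSite:
        """1-based access mirroring the mapping protocol's numbering."""
        if not (1 <= line_index <= self.n_lines and 1 <= target_index <= self.n_targets):
            raise GeometryError("site index out of range")
        return TargetSite(
            line_index, target_index,
            self.positions[line_index - 1, target_index - 1].copy(),
            self.orientations[line_index - 1, target_index - 1].copy(),
        )

    def flat_positions(self) -> np.ndarray:
        return self.positions.reshape(-1, 3)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k in range(self.n_lines):
            for i in range(self.n_targets):
                p, o = self.positions[k, i], self.orientations[k, i]
                rows.append((k + 1, i + 1, *p, *o))
        return pd.DataFrame(rows, columns=["line_index", "target_index",
                                           "x", "y", "z", "ox", "oy", "oz"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def arc_length_resample(curve: SulcusCurve, n: int) -> np.ndarray:
    """Resample a polyline at ``n`` equal arc-length steps (endpoints included)."""
    if n < 2:
        raise GeometryError("need at least 2 resampled points")
    pts = curve.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("degenerate curve with zero arc length")
    targets = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(targets, s, pts[:, j]) for j in range(3)])


def _tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents of a polyline: central differences inside, one-sided at the ends."""
    t = np.empty_like(points)
    t[1:-1] = points[2:] - points[:-2]
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise GeometryError("zero-length tangent")
    return t / norms


def anterior_normals(points: np.ndarray, anterior: np.ndarray = ANTERIOR) -> np.ndarray:
    """In-plane anterior normal at each point of a polyline.

    The normal is the component of the anterior axis orthogonal to the local
    tangent (i.e. the unit vector ⟂ tangent within the tangent–anterior
    plane, pointing anteriorly).  Undefined where the tangent is parallel to
    the anterior axis.
    """
    tan = _tangents(np.asarray(points, float))
    a = np.asarray(anterior, float)
    a = a / np.linalg.norm(a)
    n = a[None, :] - (tan @ a)[:, None] * tan
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(norms < 1e-8):
        raise GeometryError("anterior normal undefined: tangent parallel to anterior axis")
    return n / norms


def offset_line(base_points: np.ndarray, offset: float,
                anterior: np.ndarray = ANTERIOR) -> np.ndarray:
    """Displace each point of a polyline by ``offset`` along its local anterior normal."""
    if offset < 0:
        raise GeometryError("offset must be >= 0")
    base = np.asarray(base_points, float)
    if offset == 0.0:
        return base.copy()
    return base + offset * anterior_normals(base, anterior)


def _smooth_tangents(points: np.ndarray, window: int) -> np.ndarray:
    """Unit tangents from symmetric chords over ±``window`` samples.

    On a digitized (piecewise-linear) curve the pointwise central-difference
    tangent kinks at every original vertex; offsetting a 5 mm-spaced grid line
    by up to 20 mm along such kinked normals folds the offset polyline.  A
    chord over a few millimetres of arc smooths across digitization kinks
    while staying exact for straight segments and symmetric arcs.
    """
    n = len(points)
    w = max(1, min(window, n - 1))
    hi = np.minimum(np.arange(n) + w, n - 1)
    lo = np.maximum(np.arange(n) - w, 0)
    t = points[hi] - points[lo]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise GeometryError("zero-length tangent")
    return t / norms


def _smooth_normals(points: np.ndarray, window: int,
                    anterior: np.ndarray = ANTERIOR) -> np.ndarray:
    tan = _smooth_tangents(points, window)
    a = np.asarray(anterior, float)
    a = a / np.linalg.norm(a)
    nrm = a[None, :] - (tan @ a)[:, None] * tan
    norms = np.linalg.norm(nrm, axis=1, keepdims=True)
    if np.any(norms < 1e-8):
        raise GeometryError("anterior normal undefined: tangent parallel to anterior axis")
    return nrm / norms


def _resample_span(points: np.ndarray, span: float, n: int) -> np.ndarray:
    """``n`` equal-arc targets over a ``span``-long window centred on a polyline.

    When the polyline is shorter than ``span`` (anterior offset lines of a
    bowed curve shrink toward the centre of curvature) it is extended
    tangentially at both ends so the targets still cover the full
    longitudinal extent at the nominal spacing.
    """
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("degenerate line with zero arc length")
    deficit = span - total
    if deficit > span:  # would be more extension than line
        raise GeometryError("offset line too short to carry the target span")
    if deficit > 1e-9:
        ext = deficit / 2.0 + 1e-9
        t0 = (pts[1] - pts[0]) / np.linalg.norm(pts[1] - pts[0])
        t1 = (pts[-1] - pts[-2]) / np.linalg.norm(pts[-1] - pts[-2])
        pts = np.vstack([pts[0] - ext * t0, pts, pts[-1] + ext * t1])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
    mid = total / 2.0
    targets = np.linspace(mid - span / 2.0, mid + span / 2.0, n)
    return np.column_stack([np.interp(targets, s, pts[:, j]) for j in range(3)])


def build_grid(curve: SulcusCurve, n_lines: int = 5, n_targets: int = 7,
               spacing: float | None = 5.0, interline: float = 5.0,
               anterior: np.ndarray = ANTERIOR) -> StimulationGrid:
    """Build the sulcus-aligned stimulation grid.

    Line 1 lies on the curve itself (the gyrus–sulcus border); lines 2..n are
    offset anteriorly in steps of ``interline`` mm, each following the local
    curve shape.  With ``spacing`` given (default 5 mm) targets sit at fixed
    arc-length steps from the curve start, which requires the curve to be at
    least ``(n_targets−1)·spacing`` long; with ``spacing=None`` the spacing is
    derived from the curve length so the targets span the whole curve.

    Per-site coil orientations are the local anterior normals.
    """
    if n_lines < 1 or n_targets < 2:
        raise GeometryError("need n_lines >= 1 and n_targets >= 2")
    # densely resample first so offsets follow the curve, then pick targets
    dense_n = max(1024, 32 * n_targets)
    dense = arc_length_resample(curve, dense_n)
    total = SulcusCurve(dense).arc_length
    if spacing is None:
        spacing = total / (n_targets - 1)
        base_dense = dense
    else:
        span_ = (n_targets - 1) * spacing
        if span_ > total * (1 + 1e-9):
            raise GeometryError(
                f"curve of length {total:.2f} mm too short for {n_targets} targets "
                f"at {spacing:g} mm spacing")
        # restrict to the first `span_` of arc length
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        keep = np.linspace(0.0, span_, dense_n)
        base_dense = np.column_stack([np.interp(keep, s, dense[:, j]) for j in range(3)])
    span = (n_targets - 1) * spacing

    # tangent-smoothing window: ~2 mm of arc of the dense base
    h = SulcusCurve(base_dense).arc_length / (len(base_dense) - 1)
    window = max(1, int(round(2.0 / h)))

    positions = np.empty((n_lines, n_targets, 3))
    orientations = np.empty_like(positions)
    for k in range(n_lines):
        if k == 0:
            line_dense = base_dense
        else:
            # one direct offset from the base; iterating offsets amplifies
            # discretization kinks into folds on digitized curves
            line_dense = base_dense + (k * interline) * _smooth_normals(
                base_dense, window, anterior)
        line_pts = _resample_span(line_dense, span, n_targets)
        positions[k] = line_pts
        orientations[k] = _smooth_normals(line_pts, 1, anterior)
    return StimulationGrid(positions, orientations, float(spacing), float(interline))
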