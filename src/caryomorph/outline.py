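"""Grain outlines: extraction from masks, calibration, resampling, size indices, I/O.

An outline is a closed, ordered polygon describing one view of one grain.
Two views are used throughout: *lateral* (grain seen in its thickness) and
*ventral* (furrow facing up).  Coordinates are pixels straight after mask
tracing and millimetres after calibration against a two-point scale bar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label

logger = logging.getLogger(__name__)

VIEWS = ("lateral", "ventral")
ROW_TYPES = ("2-row", "6-row")
HULL_TYPES = ("hulled", "naked")
SOWING_LEVELS = ("spring", "winter", "alternative")

#: default number of arc-length resampling points
DEFAULT_K = 360


class OutlineError(ValueError):
    """Raised for invalid outlines, masks or metadata."""


# ---------------------------------------------------------------------------
# basic polygon helpers
# ---------------------------------------------------------------------------

def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive if CCW)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(points: np.ndarray) -> float:
    """Perimeter of the closed polygon through ``points``."""
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _ensure_ccw(points: np.ndarray) -> np.ndarray:
    if signed_area(points) < 0:
        points = points[::-1]
    return np.ascontiguousarray(points)


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of points to their centroid."""
    c = points.mean(axis=0)
    return float(np.sqrt(((points - c) ** 2).sum()))


def principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and 2x2 rotation whose rows are (major, minor) axes.

    The major axis is the eigenvector of the point covariance with the
    larger eigenvalue; signs are fixed so the rotation is deterministic
    (major axis has nonnegative x, ties broken toward positive y; minor
    axis completes a right-handed frame).
    """
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    vals, vecs = np.linalg.eigh(cov)
    major = vecs[:, int(np.argmax(vals))]
    if major[0] < 0 or (major[0] == 0 and major[1] < 0):
        major = -major
    minor = np.array([-major[1], major[0]])
    return c, np.vstack([major, minor])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Outline:
    """Closed 2D outline of one view of one grain.

    ``points`` is an (k, 2) array; the first point is not repeated at the
    end (closure is implicit).  ``unit`` is ``"px"`` before calibration,
    ``"mm"`` after, and ``"norm"`` after shape normalization.
    Stored orientation is counter-clockwise.
    """

    points: np.ndarray
    view: str = "lateral"
    grain_id: str = ""
    unit: str = "px"
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise OutlineError("outline needs an (k>=3, 2) point array")
        if np.allclose(pts[0], pts[-1]) and len(pts) > 3:
            pts = pts[:-1]
        self.points = _ensure_ccw(pts)
        if self.view not in VIEWS:
            raise OutlineError(f"unknown view {self.view!r}; expected one of {VIEWS}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        return perimeter(self.points)

    @property
    def centroid_size(self) -> float:
        return centroid_size(self.points)

    def is_simple(self) -> bool:
        """True if the closed polygon does not self-intersect."""
        from shapely.geometry import LinearRing

        try:
            return LinearRing(self.points).is_valid
        except Exception:
            return False


@dataclass
class ScalePair:
    """Two scale-bar landmarks a known physical distance apart (1 cm here)."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    known_distance_mm: float = 10.0

    def __post_init__(self) -> None:
        if np.allclose(self.p1, self.p2):
            raise OutlineError("scale landmarks coincide: zero separation")
        if self.known_distance_mm <= 0:
            raise OutlineError("known distance must be positive")

    @property
    def pixel_distance(self) -> float:
        return float(np.hypot(self.p1[0] - self.p2[0], self.p1[1] - self.p2[1]))


@dataclass
class SizeIndices:
    """The five size measurements of one grain (all in mm).

    Length and width are the extents of the ventral outline along its
    principal major/minor axes; thickness is the minor-axis extent of the
    lateral outline; the two centroid sizes are per-view.
    """

    length_mm: float
    width_mm: float
    thickness_mm: float
    cs_lateral: float
    cs_ventral: float

    def as_dict(self) -> dict[str, float]:
        return {
            "length_mm": self.length_mm,
            "width_mm": self.width_mm,
            "thickness_mm": self.thickness_mm,
            "cs_lateral": self.cs_lateral,
            "cs_ventral": self.cs_ventral,
        }


@dataclass
class GrainMetadata:
    accession_id: str
    variety: str
    row_type: str
    hull_type: str
    sowing: str
    year: int

    def __post_init__(self) -> None:
        if self.row_type not in ROW_TYPES:
            raise OutlineError(f"unknown row_type {self.row_type!r}")
        if self.hull_type not in HULL_TYPES:
            raise OutlineError(f"unknown hull_type {self.hull_type!r}")
        if self.sowing not in SOWING_LEVELS:
            raise OutlineError(f"unknown sowing {self.sowing!r}")

    @property
    def category(self) -> str:
        """Four-group label, e.g. ``'2-row hulled'``."""
        return f"{self.row_type} {self.hull_type}"


@dataclass
class GrainRecord:
    """Two calibrated outlines of one grain plus its accession metadata."""

    grain_id: str
    lateral: Outline
    ventral: Outline
    metadata: GrainMetadata
    sizes: SizeIndices | None = None

    def __post_init__(self) -> None:
        for view, o in (("lateral", self.lateral), ("ventral", self.ventral)):
            if o.view != view:
                raise OutlineError(f"{view} slot holds a {o.view!r} outline")


# ---------------------------------------------------------------------------
# mask tracing
# ---------------------------------------------------------------------------

# Moore neighbourhood in clockwise order, (row, col) offsets starting at W
_MOORE = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
)


def trace_mask(mask: np.ndarray) -> Outline:
    """Trace the pixel-centre boundary of the single grain in a binary mask.

    The largest 8-connected foreground component is traced with the
    Moore-neighbour algorithm; the result is the ordered loop of boundary
    pixel centres, in (x, y) = (col, row) pixel coordinates, oriented
    counter-clockwise in image coordinates.  Holes are ignored.

    Raises :class:`OutlineError` on an empty mask, a component smaller
    than 20 px, or a second component larger than 10% of the largest
    (which signals a segmentation problem rather than one grain).
    """
    fg = np.asarray(mask) != 0
    if not fg.any():
        raise OutlineError("empty mask: no foreground pixels")
    lab, n_comp = sk_label(fg, connectivity=2, return_num=True)
    areas = np.bincount(lab.ravel())[1:]
    order = np.argsort(areas)[::-1]
    if len(areas) > 1 and areas[order[1]] > 0.1 * areas[order[0]]:
        sizes = ", ".join(str(a) for a in sorted(areas, reverse=True))
        raise OutlineError(
            f"multiple comparable components (areas: {sizes}); expected one grain"
        )
    comp = lab == (order[0] + 1)
    if comp.sum() < 20:
        raise OutlineError(f"component too small ({int(comp.sum())} px < 20 px)")

    padded = np.pad(comp, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    boundary = [start]
    # backtrack is the W neighbour of the start (background by construction)
    backtrack_dir = 0
    cur = start
    max_steps = 4 * int(comp.sum()) + 8
    for _ in range(max_steps):
        found = False
        for j in range(8):
            k = (backtrack_dir + j) % 8
            nb = (cur[0] + int(_MOORE[k][0]), cur[1] + int(_MOORE[k][1]))
            if padded[nb]:
                # next backtrack: direction of the last background pixel,
                # seen from the new current pixel
                prev = (backtrack_dir + j - 1) % 8
                prev_pix = (cur[0] + int(_MOORE[prev][0]), cur[1] + int(_MOORE[prev][1]))
                backtrack_dir = _direction_from(nb, prev_pix)
                cur = nb
                found = True
                break
        if not found:  # isolated pixel
            break
        if cur == start and len(boundary) > 1:
            break
        boundary.append(cur)
    arr = np.array(boundary, dtype=float) - 1.0  # undo padding
    pts = np.column_stack([arr[:, 1], arr[:, 0]])  # (x, y) = (col, row)
    return Outline(points=pts, unit="px")


def _direction_from(origin: tuple[int, int], target: tuple[int, int]) -> int:
    off = (target[0] - origin[0], target[1] - origin[1])
    for i, (r, c) in enumerate(_MOORE):
        if (int(r), int(c)) == off:
            return i
    return 0


# ---------------------------------------------------------------------------
# calibration and resampling
# ---------------------------------------------------------------------------

def calibrate(outline: Outline, scale: ScalePair) -> Outline:
    """Convert a pixel-unit outline to millimetres using the scale pair."""
    if outline.unit != "px":
        raise OutlineError(
            f"outline already in {outline.unit!r}; calibration applies exactly once"
        )
    factor = scale.known_distance_mm / scale.pixel_distance
    return replace(outline, points=outline.points * factor, unit="mm")


def resample(outline: Outline, k: int = DEFAULT_K, set_start: bool = True) -> Outline:
    """Resample the closed outline to ``k`` points equally spaced by arc length.

    With ``set_start=True`` the sampling starts where the outline crosses
    the positive principal major axis (the crossing of largest major-axis
    coordinate, i.e. the apex end).  This anchor is a continuous function
    of the outline geometry and independent of where the stored traversal
    begins, so the resampled point sequence — and hence downstream
    harmonic coefficient signs — is reproducible and stable under small
    shape perturbations.
    """
    if k < 3:
        raise OutlineError("k must be >= 3")
    pts = outline.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise OutlineError("degenerate outline: zero perimeter")
    t0 = _start_offset(closed, cum, total) if set_start else 0.0
    t = (t0 + np.arange(k) * (total / k)) % total
    x = np.interp(t, cum, closed[:, 0])
    y = np.interp(t, cum, closed[:, 1])
    return replace(outline, points=np.column_stack([x, y]))


def _start_offset(closed: np.ndarray, cum: np.ndarray, total: float,
                  k_probe: int = 720) -> float:
    """Arc-length position of the apex anchor of a closed polygon.

    The anchor is where the (lightly smoothed) outline crosses its
    positive principal major axis.  Smoothing makes the anchor a stable,
    nearly unbiased function of the underlying shape in the presence of
    outline noise, which a raw max-coordinate vertex is not.
    """
    from scipy.ndimage import uniform_filter1d

    tp = np.arange(k_probe) * (total / k_probe)
    P = np.column_stack(
        [np.interp(tp, cum, closed[:, 0]), np.interp(tp, cum, closed[:, 1])]
    )
    w = max(3, k_probe // 36)
    Ps = uniform_filter1d(P, size=w, axis=0, mode="wrap")
    c, rot = principal_axes(Ps)
    proj = (Ps - c) @ rot.T
    u, v = proj[:, 0], proj[:, 1]
    un, vn = np.roll(u, -1), np.roll(v, -1)
    cross = (v <= 0) & (vn > 0)  # upward crossings of the major axis
    if cross.any():
        idx = np.flatnonzero(cross)
        frac = -v[idx] / (vn[idx] - v[idx])
        u_cross = u[idx] + frac * (un[idx] - u[idx])
        best = int(np.argmax(u_cross))
        return float((idx[best] + frac[best]) * (total / k_probe) % total)
    # degenerate (e.g. collinear) outline: fall back to the max-u vertex
    return float(tp[int(np.lexsort((v, -u))[0])])


# ---------------------------------------------------------------------------
# size indices
# ---------------------------------------------------------------------------

def size_indices(lateral: Outline, ventral: Outline, k: int = DEFAULT_K) -> SizeIndices:
    """Compute the five size indices from calibrated two-view outlines.

    Each view is aligned to its own principal axes; length and width are
    the ventral major/minor extents, thickness the lateral minor extent.
    Centroid sizes are computed on the k-point resampled outlines, so they
    are comparable across grains.
    """
    for o in (lateral, ventral):
        if o.unit != "mm":
            raise OutlineError("size indices require mm-calibrated outlines")
    lat = resample(lateral, k).points
    ven = resample(ventral, k).points

    def extents(pts: np.ndarray) -> tuple[float, float]:
        c, rot = principal_axes(pts)
        proj = (pts - c) @ rot.T
        return (
            float(proj[:, 0].max() - proj[:, 0].min()),
            float(proj[:, 1].max() - proj[:, 1].min()),
        )

    length, width = extents(ven)
    _, thickness = extents(lat)
    return SizeIndices(
        length_mm=length,
        width_mm=width,
        thickness_mm=thickness,
        cs_lateral=centroid_size(lat),
        cs_ventral=centroid_size(ven),
    )


# ---------------------------------------------------------------------------
# I/O: outline CSV + metadata TSV, and the TPS dialect
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "grain_id", "accession_id", "variety", "row_type", "hull_type",
    "sowing", "year",
]


def write_outlines(records: list[GrainRecord], outline_path, meta_path) -> None:
    """Write records as outline CSV + metadata TSV (lossless round-trip)."""
    rows = []
    for rec in records:
        for view, o in (("lateral", rec.lateral), ("ventral", rec.ventral)):
            for i, (x, y) in enumerate(o.points):
                rows.append((rec.grain_id, view, i, repr(float(x)), repr(float(y))))
    pd.DataFrame(
        rows, columns=["grain_id", "view", "point_index", "x_mm", "y_mm"]
    ).to_csv(outline_path, index=False)

    meta = pd.DataFrame(
        [
            {
                "grain_id": rec.grain_id,
                "accession_id": rec.metadata.accession_id,
                "variety": rec.metadata.variety,
                "row_type": rec.metadata.row_type,
                "hull_type": rec.metadata.hull_type,
                "sowing": rec.metadata.sowing,
                "year": rec.metadata.year,
            }
            for rec in records
        ]
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_outlines(outline_path, meta_path) -> list[GrainRecord]:
    """Read records written by :func:`write_outlines`.

    Raises :class:`OutlineError` on missing metadata columns, duplicated
    (grain_id, view) pairs, or category tokens outside the closed
    vocabularies, naming the offending row.
    """
    df = pd.read_csv(outline_path)
    meta = pd.read_csv(meta_path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise OutlineError(f"metadata missing columns: {missing}")
    for i, row in meta.iterrows():
        for col, vocab in (
            ("row_type", ROW_TYPES), ("hull_type", HULL_TYPES), ("sowing", SOWING_LEVELS)
        ):
            if row[col] not in vocab:
                raise OutlineError(
                    f"metadata row {i} (grain {row['grain_id']}): "
                    f"{col}={row[col]!r} not in {vocab}"
                )
    pair_counts = df.groupby(["grain_id", "view", "point_index"]).size()
    if (pair_counts > 1).any():
        bad = pair_counts[pair_counts > 1].index[0]
        raise OutlineError(f"duplicated grain_id+view rows: {bad[:2]}")

    meta = meta.set_index("grain_id")
    records = []
    for gid, sub in df.groupby("grain_id", sort=False):
        outlines = {}
        for view, vsub in sub.groupby("view"):
            vsub = vsub.sort_values("point_index")
            outlines[view] = Outline(
                points=vsub[["x_mm", "y_mm"]].to_numpy(float),
                view=view, grain_id=str(gid), unit="mm",
            )
        if set(outlines) != set(VIEWS):
            raise OutlineError(f"grain {gid}: expected both views, got {sorted(outlines)}")
        m = meta.loc[gid]
        md = GrainMetadata(
            accession_id=str(m["accession_id"]), variety=str(m["variety"]),
            row_type=str(m["row_type"]), hull_type=str(m["hull_type"]),
            sowing=str(m["sowing"]), year=int(m["year"]),
        )
        rec = GrainRecord(
            grain_id=str(gid), lateral=outlines["lateral"],
            ventral=outlines["ventral"], metadata=md,
        )
        rec.sizes = size_indices(rec.lateral, rec.ventral)
        records.append(rec)
    return records


def write_tps(outlines: list[Outline], path, scale: float | None = None) -> None:
    """Write outlines in the tpsDig outline dialect (LM=0, OUTLINES=1)."""
    with open(path, "w") as fh:
        for i, o in enumerate(outlines):
            fh.write("LM=0\n")
            fh.write("OUTLINES=1\n")
            fh.write(f"POINTS={len(o.points)}\n")
            for x, y in o.points:
                fh.write(f"{x:.9f} {y:.9f}\n")
            fh.write(f"ID={o.grain_id or i}\n")
            if scale is not None:
                fh.write(f"SCALE={scale}\n")


def read_tps(path, view: str = "lateral", unit: str = "mm") -> list[Outline]:
    """Read outlines from a tpsDig-dialect file.

    Records with ``LM=0`` and outline points are parsed as outline-only
    records; an optional ``SCALE=`` factor is applied to the coordinates.
    """
    outlines: list[Outline] = []
    points: list[list[float]] = []
    n_expected = 0
    cur_id = ""
    scale = 1.0

    def flush():
        nonlocal points, cur_id, scale, n_expected
        if points:
            pts = np.array(points) * scale
            outlines.append(Outline(points=pts, view=view, grain_id=cur_id, unit=unit))
        points, cur_id, scale, n_expected = [], "", 1.0, 0

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("LM="):
                flush()
            elif up.startswith("OUTLINES="):
                continue
            elif up.startswith("POINTS="):
                n_expected = int(line.split("=", 1)[1])
            elif up.startswith("ID="):
                cur_id = line.split("=", 1)[1]
            elif up.startswith("SCALE="):
                scale = float(line.split("=", 1)[1])
            else:
                parts = line.split()
                if len(parts) == 2:
                    points.append([float(parts[0]), float(parts[1])])
    flush()
    return outlines
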