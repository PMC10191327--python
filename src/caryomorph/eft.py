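"""Elliptic Fourier analysis of closed outlines.

The outline (x(t), y(t)), parameterized by cumulative arc length t over
one traversal of the closed polygon, is expanded as

    x(t) = A0 + sum_n [ a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T) ]
    y(t) = C0 + sum_n [ c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T) ]

with T the traversal period.  Because every analysed outline is first
resampled to k points equally spaced by arc length, the coefficients are
obtained as the discrete Fourier cosine/sine coefficients of the sampled
x and y sequences, which is exact at the sample points.  The power of
harmonic n is P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2 and drives the
choice of how many harmonics describe a grain view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from caryomorph.outline import Outline, OutlineError, centroid_size

__all__ = [
    "EFTCoefficients", "MeanShapePair", "normalize", "eft_forward",
    "eft_inverse", "harmonic_power", "harmonic_power_rank",
    "align_first_ellipse", "mean_shapes", "records_to_coefficients",
    "select_harmonics", "write_coefficients", "read_coefficients",
]

#: per-view default harmonic counts for grain outlines
DEFAULT_HARMONICS = {"lateral": 5, "ventral": 7}


@dataclass
class EFTCoefficients:
    """Per-harmonic quadruples (a_n, b_n, c_n, d_n) of one outline.

    ``coeffs`` has shape (H, 4) with columns a, b, c, d.  ``centred`` and
    ``scaled`` record which normalization steps were applied to the source
    outline; when ``scaled`` the coefficient vector is invariant to
    uniform scaling of the source.
    """

    coeffs: np.ndarray
    view: str = "lateral"
    grain_id: str = ""
    centred: bool = False
    scaled: bool = False
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.coeffs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
            raise ValueError("coeffs must be an (H>=1, 4) array")
        self.coeffs = arr

    @property
    def n_harmonics(self) -> int:
        return int(self.coeffs.shape[0])

    def flat(self) -> np.ndarray:
        """Row-major flattening (a1, b1, c1, d1, a2, ...)."""
        return self.coeffs.ravel().copy()

    @classmethod
    def from_flat(cls, vec: np.ndarray, **kw) -> "EFTCoefficients":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 4:
            raise ValueError("flat coefficient vector length must be divisible by 4")
        return cls(coeffs=vec.reshape(-1, 4), **kw)


def normalize(outline: Outline) -> Outline:
    """Centre an outline on its centroid and scale it to centroid size 1.

    No rotation is applied: grains are assumed photographed in a
    controlled orientation and the start-point convention set at
    resampling already fixes the parameterization origin.
    """
    pts = outline.points
    c = pts.mean(axis=0)
    cs = centroid_size(pts)
    if cs <= 0:
        raise OutlineError("degenerate outline: zero centroid size")
    return replace(outline, points=(pts - c) / cs, unit="norm")


def eft_forward(outline: Outline, H: int) -> EFTCoefficients:
    """Elliptic Fourier expansion of a closed k-point outline, H harmonics.

    The k vertices are taken as equally spaced samples of the closed curve
    in its traversal parameter: a_n and b_n are the discrete Fourier
    cosine/sine coefficients of the x samples, c_n and d_n those of the y
    samples.  Outlines produced by :func:`~caryomorph.outline.resample`
    are equally spaced by arc length, so for them the parameter is
    (normalized) arc length, the standard outline-morphometrics
    convention; a circle of radius r sampled this way yields exactly
    (a1, b1, c1, d1) = (r, 0, 0, r).
    """
    pts = outline.points
    k = len(pts)
    if not 1 <= H <= k // 2:
        raise ValueError(f"H={H} out of range 1..{k // 2} for a {k}-point outline")

    n = np.arange(1, H + 1)[:, None]  # (H, 1)
    t = np.arange(k)[None, :] / k
    phi = 2.0 * np.pi * n * t  # (H, k)
    cos, sin = np.cos(phi), np.sin(phi)
    a = (2.0 / k) * (cos @ pts[:, 0])
    b = (2.0 / k) * (sin @ pts[:, 0])
    c = (2.0 / k) * (cos @ pts[:, 1])
    dd = (2.0 / k) * (sin @ pts[:, 1])

    A0 = float(pts[:, 0].mean())
    C0 = float(pts[:, 1].mean())

    return EFTCoefficients(
        coeffs=np.column_stack([a, b, c, dd]),
        view=outline.view,
        grain_id=outline.grain_id,
        centred=outline.unit == "norm",
        scaled=outline.unit == "norm",
        offset=(A0, C0),
    )


def eft_inverse(
    coeffs: EFTCoefficients, k: int, include_offset: bool = False
) -> Outline:
    """Reconstruct a k-point outline at equally spaced parameter values."""
    H = coeffs.n_harmonics
    if k < 2 * H:
        raise ValueError(f"k={k} must be >= 2H = {2 * H}")
    t = np.arange(k) / k
    n = np.arange(1, H + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(phi), np.sin(phi)
    a, b, c, d = coeffs.coeffs.T
    x = a @ cos + b @ sin
    y = c @ cos + d @ sin
    if include_offset:
        x = x + coeffs.offset[0]
        y = y + coeffs.offset[1]
    pts = np.column_stack([x, y])
    if np.allclose(pts, pts[0]):
        raise OutlineError("zero coefficients reconstruct to a single point")
    return Outline(points=pts, view=coeffs.view, grain_id=coeffs.grain_id, unit="norm")


def harmonic_power(coeffs: EFTCoefficients | np.ndarray) -> np.ndarray:
    """Per-harmonic power P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2."""
    arr = coeffs.coeffs if isinstance(coeffs, EFTCoefficients) else np.asarray(coeffs)
    return (arr**2).sum(axis=1) / 2.0


def harmonic_power_rank(
    outline: Outline, threshold: float = 0.99, H_max: int = 32
) -> int:
    """Smallest harmonic count whose cumulative power reaches ``threshold``.

    Power fractions are taken relative to the total over ``H_max``
    harmonics (H_max is capped at k/2 for a k-point outline).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    H_max = min(H_max, len(outline.points) // 2)
    power = harmonic_power(eft_forward(outline, H_max))
    total = power.sum()
    if total <= 0:
        raise OutlineError("total harmonic power is zero")
    frac = np.cumsum(power) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def align_first_ellipse(coeffs: EFTCoefficients) -> EFTCoefficients:
    """Normalize rotation and phase against the first harmonic ellipse.

    Optional step (off by default throughout the package): rotates the
    outline so the first ellipse's major axis lies along x and shifts the
    parameter origin to that axis, after which (b1, c1) vanish.
    """
    a, b, c, d = coeffs.coeffs[0]
    theta = 0.5 * np.arctan2(2 * (a * b + c * d), a**2 + c**2 - b**2 - d**2)
    n = np.arange(1, coeffs.n_harmonics + 1)
    out = np.empty_like(coeffs.coeffs)
    for i, nn in enumerate(n):
        ct, st = np.cos(nn * theta), np.sin(nn * theta)
        rot_t = np.array([[ct, -st], [st, ct]])
        out[i] = (coeffs.coeffs[i].reshape(2, 2) @ rot_t).ravel()
    a1 = out[0]
    psi = np.arctan2(a1[2], a1[0])
    cp, sp = np.cos(psi), np.sin(psi)
    rot_xy = np.array([[cp, sp], [-sp, cp]])
    for i in range(len(out)):
        out[i] = (rot_xy @ out[i].reshape(2, 2)).ravel()
    return replace(coeffs, coeffs=out)


@dataclass
class MeanShapePair:
    """Mean shapes of two groups with per-point deviations between them."""

    group_a: str
    group_b: str
    mean_a: EFTCoefficients
    mean_b: EFTCoefficients
    outline_a: Outline
    outline_b: Outline
    deviation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.deviation is None:
            self.deviation = np.hypot(
                *(self.outline_a.points - self.outline_b.points).T
            )


def mean_shapes(
    features,
    group_a: str,
    group_b: str,
    k: int = 360,
    view: str | None = None,
    grouping: str = "category",
) -> MeanShapePair:
    """Mean-shape contrast between two groups of grains.

    ``features`` is a :class:`~caryomorph.morphostats.FeatureMatrix` whose
    view blocks hold per-harmonic coefficient quadruples.  The two group
    mean coefficient vectors are inverse-transformed at matched parameter
    values; ``deviation[i]`` is the distance between matched points and is
    what mean-shape difference maps colour.
    """
    view_candidates = [b for b in features.view_blocks if b in ("lateral", "ventral")]
    if view is None:
        if not view_candidates:
            raise ValueError("feature matrix has no per-view coefficient block")
        view = view_candidates[0]
    if view not in features.view_blocks:
        raise ValueError(f"feature matrix has no {view!r} block")
    sl = features.view_blocks[view]
    labels = np.asarray(features.labels[grouping])
    means: dict[str, EFTCoefficients] = {}
    for g in (group_a, group_b):
        rows = features.values[labels == g][:, sl]
        if rows.shape[0] == 0:
            raise ValueError(f"empty group {g!r} for grouping {grouping!r}")
        means[g] = EFTCoefficients.from_flat(
            rows.mean(axis=0), view=view, centred=True, scaled=True
        )
    return MeanShapePair(
        group_a=group_a,
        group_b=group_b,
        mean_a=means[group_a],
        mean_b=means[group_b],
        outline_a=eft_inverse(means[group_a], k),
        outline_b=eft_inverse(means[group_b], k),
    )


# ---------------------------------------------------------------------------
# dataset-level helpers and coefficient-table I/O
# ---------------------------------------------------------------------------

def select_harmonics(
    records, threshold: float = 0.99, H_max: int = 32, k: int = 360,
    sample: int | None = 50, seed: int = 0,
):
    """Per-view harmonic counts by the harmonic-power criterion.

    The rank is computed per grain on (a sample of) the dataset and the
    per-view maximum is kept, so the chosen count describes every grain
    at the threshold.
    """
    import numpy as _np

    from caryomorph.outline import resample as _resample

    idx = _np.arange(len(records))
    if sample is not None and len(idx) > sample:
        idx = _np.random.default_rng(seed).choice(idx, size=sample, replace=False)
    out = {}
    for view in ("lateral", "ventral"):
        ranks = []
        for i in idx:
            o = getattr(records[i], view)
            ranks.append(harmonic_power_rank(normalize(_resample(o, k)), threshold, H_max))
        out[view] = int(max(ranks))
    return out


def records_to_coefficients(records, harmonics=None, k: int = 360):
    """Long coefficient table (grain_id, view, n, a, b, c, d) for a dataset.

    Each outline is resampled to k points, normalized (centred, centroid
    size 1), and expanded to the per-view harmonic count (defaults:
    lateral 5, ventral 7).
    """
    import pandas as pd

    from caryomorph.outline import resample as _resample

    harmonics = dict(DEFAULT_HARMONICS if harmonics is None else harmonics)
    rows = []
    for rec in records:
        for view in ("lateral", "ventral"):
            o = getattr(rec, view)
            cf = eft_forward(normalize(_resample(o, k)), harmonics[view])
            for n, (a, b, c, d) in enumerate(cf.coeffs, start=1):
                rows.append((rec.grain_id, view, n, a, b, c, d))
    return pd.DataFrame(rows, columns=["grain_id", "view", "n", "a", "b", "c", "d"])


def write_coefficients(table, path, sidecar: bool = True) -> None:
    """Write the long coefficient table as CSV (+ normalization sidecar JSON)."""
    import json
    from pathlib import Path

    table.to_csv(path, index=False)
    if sidecar:
        meta = {
            "centred": True, "scaled": True, "rotation_aligned": False,
            "harmonics": {
                v: int(table[table["view"] == v]["n"].max()) for v in table["view"].unique()
            },
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_coefficients(path):
    import pandas as pd

    df = pd.read_csv(path)
    required = {"grain_id", "view", "n", "a", "b", "c", "d"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coefficient table missing columns: {sorted(missing)}")
    return df
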