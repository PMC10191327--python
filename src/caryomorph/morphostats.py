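"""Descriptive and inferential statistics on grain size and shape.

Size indices (length, width, thickness, per-view centroid sizes) are
compared between groups with Kruskal-Wallis rank tests and pairwise
Wilcoxon rank-sum tests; shape (harmonic coefficient) matrices with
MANOVA (Pillai's trace) and pairwise permutational MANOVA on Euclidean
distances; and the adequacy of a per-accession sample size with a
rarefaction curve of captured variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix", "TestResult", "PCAResult", "size_correlations", "pca",
    "manova", "pairwise_permanova", "kruskal_wallis", "wilcoxon_pairs",
    "rarefaction_sufficiency",
]

SIZE_INDEX_NAMES = ["length_mm", "width_mm", "thickness_mm", "cs_lateral", "cs_ventral"]


@dataclass
class FeatureMatrix:
    """Grains x features matrix with group labels and view-block layout.

    ``view_blocks`` maps a block name ("lateral", "ventral", "size") to
    the slice of columns it occupies; classification and mean-shape code
    rely on it to address one view's coefficients.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: pd.DataFrame  # index: grain_id; columns incl. variety, category, ...
    view_blocks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2:
            raise ValueError("values must be 2-D")
        if V.shape[0] < 2:
            raise ValueError("need at least 2 grains")
        if V.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must equal column count")
        if not np.isfinite(V).all():
            raise ValueError("feature matrix contains missing/non-finite values")
        if len(self.labels) != V.shape[0]:
            raise ValueError("labels must align with rows")
        self.values = V

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def groups(self, grouping: str) -> np.ndarray:
        if grouping not in self.labels.columns:
            raise KeyError(f"no grouping column {grouping!r}")
        return self.labels[grouping].astype(str).to_numpy()

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[mask],
            feature_names=list(self.feature_names),
            labels=self.labels.iloc[mask].copy(),
            view_blocks=dict(self.view_blocks),
        )


@dataclass
class TestResult:
    """One test outcome in the tidy layout used by result tables."""

    statistic_name: str  # KW_chi2 | wilcoxon_W | pillai_F | pseudo_F | mantel_r
    statistic: float
    p_value: float
    df: tuple | None = None
    permutations: int | None = None
    adjusted_p: float | None = None
    adjust_method: str | None = None
    contrast: str | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def as_row(self) -> dict:
        return {
            "contrast": self.contrast,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p": self.p_value,
            "p_adjusted": self.adjusted_p,
            "adjust_method": self.adjust_method,
            "df": str(self.df) if self.df else "",
            "B": self.permutations,
            "note": self.note,
        }


def results_table(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


# ---------------------------------------------------------------------------
# size correlations
# ---------------------------------------------------------------------------

def size_correlations(sizes) -> pd.DataFrame:
    """Pearson correlation matrix of the five size indices.

    ``sizes`` is a list of :class:`~caryomorph.outline.SizeIndices` or a
    DataFrame with the five index columns.
    """
    if not isinstance(sizes, pd.DataFrame):
        sizes = pd.DataFrame([s.as_dict() for s in sizes])
    sizes = sizes[SIZE_INDEX_NAMES]
    if len(sizes) < 3:
        raise ValueError("need at least 3 grains")
    sd = sizes.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance size index: {zero}")
    return sizes.corr(method="pearson")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (p, n_comp), columns are component vectors
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca(features: FeatureMatrix | np.ndarray) -> PCAResult:
    """Centred (not re-scaled) PCA via singular value decomposition.

    Scores reproduce the centred data exactly through the loadings; the
    explained-variance fractions sum to one over the retained (nonzero)
    components.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.shape[0] < 2:
        raise ValueError("need more than one row")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    signs = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    ev = s**2
    total = ev.sum()
    ratio = ev / total if total > 0 else ev
    return PCAResult(
        scores=U * s, loadings=Vt.T, explained_variance_ratio=ratio, mean=mu
    )


def _pca_reduce(X: np.ndarray, var_threshold: float, max_rank: int) -> np.ndarray:
    """Centred scores capturing >= var_threshold variance, rank-guarded."""
    res = pca(X)
    frac = np.cumsum(res.explained_variance_ratio)
    n_comp = int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
    nonzero = int((res.explained_variance_ratio > 1e-12).sum())
    n_comp = max(1, min(n_comp, max_rank, nonzero))
    return res.scores[:, :n_comp]


# ---------------------------------------------------------------------------
# MANOVA (Pillai's trace)
# ---------------------------------------------------------------------------

def manova(
    features: FeatureMatrix,
    grouping: str,
    var_threshold: float = 0.99,
    min_group_size: int = 2,
) -> TestResult:
    """One-way MANOVA on (possibly PCA-reduced) shape features.

    Reports Pillai's trace V with its standard F approximation.  When
    the feature matrix is rank-deficient for the available degrees of
    freedom, features are replaced by leading principal component scores
    capturing ``var_threshold`` of total variance (the standard guard
    for harmonic-coefficient matrices).
    """
    y = features.groups(grouping)
    levels, counts = np.unique(y, return_counts=True)
    g = len(levels)
    if g < 2:
        raise ValueError("MANOVA needs at least 2 groups")
    if counts.min() < min_group_size:
        small = levels[counts < min_group_size].tolist()
        raise ValueError(f"groups below minimum size {min_group_size}: {small}")
    n = features.n
    X = features.values
    max_rank = n - g
    if features.p > max_rank or np.linalg.matrix_rank(X - X.mean(axis=0)) < features.p:
        X = _pca_reduce(X, var_threshold, max_rank)
    p = X.shape[1]

    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lev in levels:
        Xg = X[y == lev]
        d = (Xg.mean(axis=0) - grand)[:, None]
        H += len(Xg) * (d @ d.T)
        Xc = Xg - Xg.mean(axis=0)
        E += Xc.T @ Xc
    try:
        V = float(np.trace(np.linalg.solve(H + E, H)))  # Pillai's trace
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular within-group scatter; reduce features (PCA) or add grains"
        )
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    nn = (n - g - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or s <= 0 or V >= s:
        V = min(V, s - 1e-12)
    F = (df2 / df1) * (V / (s - V))
    pval = float(sps.f.sf(F, df1, df2))
    return TestResult(
        statistic_name="pillai_F", statistic=float(F), p_value=pval,
        df=(float(df1), float(df2)), contrast=grouping,
        note=f"pillai_V={V:.6f}, features={p}",
    )


# ---------------------------------------------------------------------------
# permutational MANOVA (pairwise)
# ---------------------------------------------------------------------------

def _permanova_stat(d2: np.ndarray, y: np.ndarray, levels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a squared Euclidean distance matrix."""
    n = len(y)
    a = len(levels)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for lev in levels:
        idx = np.flatnonzero(y == lev)
        if len(idx) < 1:
            continue
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    features: FeatureMatrix | np.ndarray,
    y: np.ndarray | str,
    B: int = 999,
    seed: int = 0,
) -> TestResult:
    """One-way PERMANOVA on Euclidean distances with seeded permutations."""
    if isinstance(features, FeatureMatrix):
        X = features.values
        y = features.groups(y) if isinstance(y, str) else np.asarray(y).astype(str)
    else:
        X = np.asarray(features, float)
        y = np.asarray(y).astype(str)
    if B < 99:
        raise ValueError("B must be >= 99")
    levels, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each group needs >= 2 members for a pseudo-F")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    f_obs = _permanova_stat(sq, y, levels)
    rng = np.random.default_rng(seed)
    count = 0
    yy = y.copy()
    for _ in range(B):
        rng.shuffle(yy)
        count += _permanova_stat(sq, yy, levels) >= f_obs
    p = (1.0 + count) / (1.0 + B)
    return TestResult(
        statistic_name="pseudo_F", statistic=float(f_obs), p_value=p,
        permutations=B,
    )


def pairwise_permanova(
    features: FeatureMatrix,
    grouping: str,
    B: int = 999,
    adjust: str = "bonferroni",
    seed: int = 0,
) -> list[TestResult]:
    """All pairwise PERMANOVA comparisons with multiplicity adjustment.

    The multilevel analogue of pairwise post-hoc tests: for each pair of
    group levels a two-group PERMANOVA is run on the Euclidean distances
    of their grains; p-values are adjusted with ``adjust`` (bonferroni,
    holm, or fdr_bh).
    """
    from statsmodels.stats.multitest import multipletests

    y = features.groups(grouping)
    levels = sorted(set(y))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    results = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            mask = (y == la) | (y == lb)
            res = permanova(features.values[mask], y[mask], B=B, seed=seed)
            res.contrast = f"{la} vs {lb}"
            results.append(res)
    raw = [r.p_value for r in results]
    _, adj, _, _ = multipletests(raw, method=adjust)
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
        r.adjust_method = adjust
    return results


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p-value."""
    values = np.asarray(values, float)
    groups = np.asarray(groups).astype(str)
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == lev] for lev in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.ptp(values) == 0:
        return TestResult(
            statistic_name="KW_chi2", statistic=0.0, p_value=1.0,
            df=(len(levels) - 1,), note="all values identical; H undefined",
        )
    H, p = sps.kruskal(*samples)
    return TestResult(
        statistic_name="KW_chi2", statistic=float(H), p_value=float(p),
        df=(len(levels) - 1,),
    )


def wilcoxon_pairs(
    values: np.ndarray,
    groups: np.ndarray,
    adjust: str = "bonferroni",
) -> list[TestResult]:
    """Pairwise two-sided Wilcoxon rank-sum tests with adjustment.

    The reported W is the Mann-Whitney U of the first group (the
    convention of common statistical software).
    """
    from statsmodels.stats.multitest import multipletests

    values = np.asarray(values, float)
    groups = np.asarray(groups).astype(str)
    levels = sorted(set(groups))
    results = []
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            va, vb = values[groups == la], values[groups == lb]
            if len(va) == 0 or len(vb) == 0:
                raise ValueError(f"empty group in pair {la} vs {lb}")
            stat, p = sps.mannwhitneyu(va, vb, alternative="two-sided")
            results.append(
                TestResult(
                    statistic_name="wilcoxon_W", statistic=float(stat),
                    p_value=float(p), contrast=f"{la} vs {lb}",
                )
            )
    raw = [r.p_value for r in results]
    if raw:
        _, adj, _, _ = multipletests(raw, method=adjust)
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
            r.adjust_method = adjust
    return results


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefaction_sufficiency(
    features: FeatureMatrix,
    accession: str,
    n_grid: list[int],
    B: int = 100,
    seed: int = 0,
    target: float = 0.95,
    accession_column: str = "accession_id",
) -> tuple[pd.DataFrame, int | None]:
    """Variance-captured rarefaction curve for one accession.

    For each n in ``n_grid``, draws B random subsamples (without
    replacement) of n grains and records the ratio of total feature
    variance in the subsample to the full-accession total variance
    (maximum-likelihood variances, so the ratio measures the share of
    the population's variation a sample of n grains records and rises
    towards 1 with n).  Returns the per-n curve (mean and sd of the
    ratio) and the smallest n whose mean ratio reaches ``target`` (None
    if never reached).  This is the calculation behind "how many grains
    per accession are enough".
    """
    mask = features.labels[accession_column].astype(str).to_numpy() == str(accession)
    X = features.values[mask]
    n_full = X.shape[0]
    if n_full == 0:
        raise ValueError(f"unknown accession {accession!r}")
    if max(n_grid) > n_full:
        raise ValueError(f"n_grid exceeds accession size {n_full}")
    total_full = X.var(axis=0, ddof=0).sum()
    rng = np.random.default_rng(seed)
    rows = []
    for n in sorted(n_grid):
        ratios = np.empty(B)
        for b in range(B):
            idx = rng.choice(n_full, size=n, replace=False)
            ratios[b] = X[idx].var(axis=0, ddof=0).sum() / total_full if n > 1 else 0.0
        rows.append({"n": n, "mean_ratio": ratios.mean(), "sd_ratio": ratios.std(ddof=1) if B > 1 else 0.0})
    curve = pd.DataFrame(rows)
    reached = curve[curve["mean_ratio"] >= target]
    recommended = int(reached["n"].iloc[0]) if len(reached) else None
    return curve, recommended
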