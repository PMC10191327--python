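"""Discriminant classification of grains with leave-one-out cross-validation.

Grains are classified into a chosen label (variety, four-group category,
row-number type, hulled/naked type, or sowing period) from a chosen
feature block: a single size index, one view's harmonic coefficients
("shape"), or shape plus log centroid size ("form"), per view or with
both views combined.  Accuracy is the cross-validation percentage (CVP):
the share of grains assigned to their true class when each is held out
and the linear discriminant model is refit on the remainder.  A
stratified bootstrap over grains yields the confidence interval on CVP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from caryomorph.morphostats import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_SETS", "CVReport", "build_features", "lda_loocv",
    "cvp_confidence_interval", "contrast_suite", "LDAModel",
]

FEATURE_SETS = (
    "length", "width", "thickness",
    "lateral_shape", "ventral_shape", "combined_shape",
    "lateral_form", "ventral_form", "combined_form",
)

CONTRASTS = ("variety", "four_group", "row_type", "hull_type", "sowing")


# ---------------------------------------------------------------------------
# linear discriminant model (pooled covariance, proportional priors)
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Classic Gaussian linear discriminant: pooled within-class covariance,
    class priors proportional to training counts."""

    classes: np.ndarray
    means: np.ndarray  # (c, p)
    cov_inv: np.ndarray  # (p, p)
    log_priors: np.ndarray  # (c,)

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, ridge: float = 1e-8) -> "LDAModel":
        classes, counts = np.unique(y, return_counts=True)
        n, p = X.shape
        if len(classes) < 2:
            raise ValueError("need >= 2 classes")
        means = np.array([X[y == c].mean(axis=0) for c in classes])
        S = np.zeros((p, p))
        for c, mu in zip(classes, means):
            Xc = X[y == c] - mu
            S += Xc.T @ Xc
        S /= max(n - len(classes), 1)
        try:
            cov_inv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            lam = ridge * float(np.mean(np.diag(S)))
            logger.warning("singular pooled covariance; adding ridge %.3g", lam)
            cov_inv = np.linalg.inv(S + lam * np.eye(p))
        return cls(
            classes=classes, means=means, cov_inv=cov_inv,
            log_priors=np.log(counts / n),
        )

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores delta_k(x), one column per class."""
        A = self.means @ self.cov_inv  # (c, p)
        const = -0.5 * np.einsum("cp,cp->c", A, self.means) + self.log_priors
        return X @ A.T + const

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision(X), axis=1)]


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def build_features(
    coeffs: pd.DataFrame,
    sizes: pd.DataFrame,
    meta: pd.DataFrame,
    feature_set: str,
) -> FeatureMatrix:
    """Assemble the grains x features matrix for one feature set.

    ``coeffs`` is the long coefficient table (columns grain_id, view, n,
    a, b, c, d); ``sizes`` and ``meta`` are indexed by grain_id.  Shape
    sets concatenate per-view coefficient quadruples; form sets append
    the log centroid size of the corresponding view(s); size sets are a
    single index column.  Grains missing a required block are dropped
    with a logged count.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    if sizes is not None and "grain_id" in sizes.columns:
        sizes = sizes.set_index("grain_id")
    if "grain_id" in meta.columns:
        meta = meta.set_index("grain_id")

    if feature_set in ("length", "width", "thickness"):
        col = {"length": "length_mm", "width": "width_mm", "thickness": "thickness_mm"}[feature_set]
        ids = sizes.index.astype(str)
        values = sizes[[col]].to_numpy(float)
        names = [col]
        blocks = {"size": slice(0, 1)}
        return _finalize(values, names, blocks, ids, meta)

    views = {
        "lateral_shape": ["lateral"], "ventral_shape": ["ventral"],
        "combined_shape": ["lateral", "ventral"],
        "lateral_form": ["lateral"], "ventral_form": ["ventral"],
        "combined_form": ["lateral", "ventral"],
    }[feature_set]
    with_size = feature_set.endswith("_form")

    wide = {}
    for view in views:
        sub = coeffs[coeffs["view"] == view].sort_values(["grain_id", "n"])
        if sub.empty:
            raise ValueError(f"no coefficients for view {view!r}")
        piv = sub.pivot_table(
            index="grain_id", columns="n", values=["a", "b", "c", "d"], sort=True
        )
        H = sub["n"].max()
        cols = []
        for n in range(1, H + 1):
            for q in ("a", "b", "c", "d"):
                cols.append((q, n))
        wide[view] = piv.reindex(columns=pd.MultiIndex.from_tuples(cols))

    ids = wide[views[0]].index
    for view in views[1:]:
        ids = ids.intersection(wide[view].index)
    for view in views:
        complete = wide[view].loc[ids].dropna().index
        ids = ids.intersection(complete)
    if with_size:
        ids = ids.intersection(sizes.index)
    ids = ids.intersection(meta.index)
    n_dropped = len(set().union(*[set(w.index) for w in wide.values()]) - set(ids))
    if n_dropped:
        logger.info("dropped %d grains missing a required block", n_dropped)

    parts, names, blocks = [], [], {}
    col0 = 0
    for view in views:
        block = wide[view].loc[ids]
        parts.append(block.to_numpy(float))
        names.extend(f"{view[:3]}_{q}{n}" for (q, n) in block.columns)
        blocks[view] = slice(col0, col0 + block.shape[1])
        col0 += block.shape[1]
    if with_size:
        cs_cols = []
        for view in views:
            cs = np.log(sizes.loc[ids, f"cs_{view}"].to_numpy(float))
            cs_cols.append(cs[:, None])
            names.append(f"log_cs_{view}")
        parts.append(np.hstack(cs_cols))
        blocks["size"] = slice(col0, col0 + len(views))
    values = np.hstack(parts)
    return _finalize(values, names, blocks, ids, meta)


def _finalize(values, names, blocks, ids, meta) -> FeatureMatrix:
    if len(ids) == 0:
        raise ValueError("no grains left after dropping incomplete records")
    labels = meta.loc[ids].copy()
    labels.index = labels.index.astype(str)
    if "category" not in labels.columns and {"row_type", "hull_type"} <= set(labels.columns):
        labels["category"] = labels["row_type"].astype(str) + " " + labels["hull_type"].astype(str)
    return FeatureMatrix(
        values=values, feature_names=names, labels=labels, view_blocks=blocks
    )


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Leave-one-out classification summary for one (label, feature set)."""

    label_name: str
    feature_set: str
    cvp: float  # percent correct
    ci_low: float | None
    ci_high: float | None
    confusion: pd.DataFrame
    per_class_recall: dict
    n_grains: int
    assignments: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    seed: int | None = None
    B_bootstrap: int | None = None
    ci_method: str | None = None

    def as_row(self) -> dict:
        return {
            "contrast": self.label_name, "feature_set": self.feature_set,
            "cvp": self.cvp, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n": self.n_grains, "B": self.B_bootstrap, "seed": self.seed,
            "ci_method": self.ci_method,
        }


def _loocv_assign(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Predicted class for each grain with that grain held out."""
    n = len(y)
    out = np.empty(n, dtype=y.dtype)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        model = LDAModel.fit(X[mask], y[mask])
        out[i] = model.predict(X[i : i + 1])[0]
    return out


def lda_loocv(features: FeatureMatrix, label: str) -> CVReport:
    """Leave-one-out linear discriminant classification.

    Each grain is classified by a model fit on all other grains; the CVP
    is the percentage of correct assignments and the confusion matrix
    tabulates true class (rows) against assigned class (columns).
    Deterministic: no randomness is involved.
    """
    X = features.values
    y = features.groups(label)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        small = classes[counts < 3].tolist()
        raise ValueError(f"classes with < 3 members: {small}")
    assigned = _loocv_assign(X, y)
    return _report_from_assignments(y, assigned, classes, label, features)


def _report_from_assignments(y, assigned, classes, label, features, feature_set="custom"):
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, a in zip(y, assigned):
        conf.loc[t, a] += 1
    n = len(y)
    cvp = 100.0 * np.trace(conf.to_numpy()) / n
    recall = {
        c: float(conf.loc[c, c] / conf.loc[c].sum()) if conf.loc[c].sum() else np.nan
        for c in classes
    }
    return CVReport(
        label_name=label, feature_set=feature_set, cvp=float(cvp),
        ci_low=None, ci_high=None, confusion=conf, per_class_recall=recall,
        n_grains=n, assignments=assigned,
    )


def cvp_confidence_interval(
    features: FeatureMatrix,
    label: str,
    B: int = 100,
    seed: int = 0,
    method: str = "bootstrap",
) -> tuple[float, float]:
    """95% confidence interval for the CVP.

    ``bootstrap``: percentile interval of the CVP over B stratified
    bootstrap resamples of grains (each class resampled with replacement
    to its own size), re-running the full LOOCV on every resample.
    ``wilson``: the Wilson score interval of the observed proportion
    (no resampling).
    """
    X = features.values
    y = features.groups(label)
    if method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        assigned = _loocv_assign(X, y)
        k = int((assigned == y).sum())
        lo, hi = proportion_confint(k, len(y), alpha=0.05, method="wilson")
        return 100.0 * float(lo), 100.0 * float(hi)
    if B < 20:
        raise ValueError("B must be >= 20 for a bootstrap interval")
    rng = np.random.default_rng(seed)
    classes = np.unique(y)
    cvps = np.empty(B)
    for b in range(B):
        parts = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            parts.append(rng.choice(idx, size=len(idx), replace=True))
        take = np.concatenate(parts)
        yb = y[take]
        assigned = _loocv_assign(X[take], yb)
        cvps[b] = 100.0 * np.mean(assigned == yb)
    lo, hi = np.percentile(cvps, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# contrast suite
# ---------------------------------------------------------------------------

def contrast_suite(
    coeffs: pd.DataFrame,
    sizes: pd.DataFrame,
    meta: pd.DataFrame,
    contrasts: list[str] = ("four_group", "row_type", "hull_type", "sowing"),
    feature_sets: list[str] = FEATURE_SETS,
    ci: bool = True,
    B: int = 100,
    seed: int = 0,
) -> list[CVReport]:
    """One CVReport per (contrast, feature set).

    The ``sowing`` contrast is evaluated within each four-group category
    separately (a sowing difference is only meaningful among varieties
    of the same taxonomic type); contrast levels absent from the data
    are skipped with a log entry.
    """
    reports: list[CVReport] = []
    for contrast in contrasts:
        if contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {contrast!r}")
        for fs in feature_sets:
            fm = build_features(coeffs, sizes, meta, fs)
            if contrast == "four_group":
                runs = [("four_group", fm, "category")]
            elif contrast == "sowing":
                runs = []
                for cat in sorted(fm.labels["category"].unique()):
                    sub = fm.subset((fm.labels["category"] == cat).to_numpy())
                    if sub.labels["sowing"].nunique() < 2:
                        logger.info("skipping sowing within %s: single level", cat)
                        continue
                    runs.append((f"sowing[{cat}]", sub, "sowing"))
            else:
                runs = [(contrast, fm, contrast)]
            for name, mat, label_col in runs:
                counts = mat.labels[label_col].value_counts()
                if (counts < 3).any() or len(counts) < 2:
                    logger.info("skipping %s / %s: class too small or single class", name, fs)
                    continue
                rep = lda_loocv(mat, label_col)
                rep.label_name = name
                rep.feature_set = fs
                if ci:
                    lo, hi = cvp_confidence_interval(mat, label_col, B=B, seed=seed)
                    # widen the percentile interval to bracket the observed
                    # CVP (it is a resampling interval for the procedure)
                    rep.ci_low, rep.ci_high = min(lo, rep.cvp), max(hi, rep.cvp)
                    rep.B_bootstrap, rep.seed, rep.ci_method = B, seed, "bootstrap"
                reports.append(rep)
    return reports


def reports_table(reports: list[CVReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports])


def plot_cvp_bars(reports: list[CVReport], path=None):
    """Grouped bar chart of CVPs per contrast and feature set, with
    confidence-interval whiskers where available."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = reports_table(reports)
    contrasts = list(dict.fromkeys(df["contrast"]))
    feature_sets = list(dict.fromkeys(df["feature_set"]))
    width = 0.8 / max(len(feature_sets), 1)
    fig, ax = plt.subplots(figsize=(1.8 * len(contrasts) + 2, 4))
    x = np.arange(len(contrasts))
    for j, fs in enumerate(feature_sets):
        sub = df[df["feature_set"] == fs].set_index("contrast").reindex(contrasts)
        err = None
        if sub["ci_low"].notna().any():
            err = np.vstack([
                (sub["cvp"] - sub["ci_low"]).fillna(0),
                (sub["ci_high"] - sub["cvp"]).fillna(0),
            ])
        ax.bar(x + j * width, sub["cvp"], width=width, label=fs, yerr=err, capsize=2)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(contrasts, rotation=20, ha="right")
    ax.set_ylabel("CVP (%)")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
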