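"""Synthetic two-view grain datasets with hierarchical effect structure.

The generator emulates a varietal collection of barley caryopses: four
taxonomic categories (2-row/6-row x hulled/naked), varieties nested in
categories, accessions (variety x harvest year), ~30 grains per
accession, and two correlated outline views per grain.  Grain shape is
modelled in normalized elliptic Fourier coefficient space as

    template(view) + category effect + sowing effect
                   + variety effect + year effect + grain noise,

inverse-transformed to outlines and scaled to sizes drawn lognormally
around category-independent base dimensions, with spring accessions
uniformly enlarged relative to winter ones.

The taxonomic effects are anisotropic across views on purpose: the
row-number contrast (a spike-architecture constraint) loads mainly on
the ventral outline and the hulled/naked contrast (a husk-adherence
effect) mainly on the lateral outline, so downstream classification
should find the row signal in the ventral view and the hull signal in
the lateral view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from caryomorph._templates import TEMPLATE_COEFFS, TEMPLATE_EXTENTS
from caryomorph.eft import EFTCoefficients, eft_inverse
from caryomorph.outline import (
    Outline,
    OutlineError,
    GrainMetadata,
    GrainRecord,
    ScalePair,
    size_indices,
)
from caryomorph.distnet import SNPMatrix

__all__ = [
    "SynthConfig", "SynthTruth", "generate_dataset", "generate_snp_matrix",
    "rasterize_outline",
]

#: harmonics used by the generator (the template depth)
N_HARMONICS = 10
#: fraction of the grain-noise variance shared between the two views
#: of one grain (the within-grain view coupling; see SynthConfig)
_DEFAULT_VIEW_COUPLING = 0.3

# cross-view loading of the two taxonomic contrasts: (ventral, lateral)
_ROW_LOADING = {"ventral": 1.0, "lateral": 0.3}
_HULL_LOADING = {"ventral": 0.3, "lateral": 1.0}

_DEFAULT_CATEGORIES = (
    ("2-row", "hulled"),
    ("2-row", "naked"),
    ("6-row", "hulled"),
    ("6-row", "naked"),
)

_DEFAULT_EFFECT_SCALES = {
    "category_shape": 1.3e-3,
    "sowing_shape": 4.5e-4,
    "variety_shape": 4.5e-4,
    "year_shape": 3.0e-4,
    "grain_noise": 1.8e-3,
}

#: per-harmonic decay of effect standard deviations (smooth variation:
#: low harmonics vary most, as in real outline data)
_HARMONIC_DECAY = 1.0 / np.arange(1, N_HARMONICS + 1)

_DEFAULT_SIZE_PARAMS = {
    "base_length_mm": 8.5,
    "base_width_mm": 3.4,
    "base_thickness_mm": 2.8,
    "spring_size_multiplier": 1.06,
    "lognormal_cv": 0.05,
}


@dataclass
class SynthConfig:
    """Configuration of the synthetic grain-collection generator.

    Effect scales are standard deviations per coefficient in normalized
    (centroid-size-1) elliptic Fourier space.  ``view_noise_correlation``
    is the share of grain-noise variance common to the two views of a
    grain; within-accession view covariance is not documented for real
    material, so this is an explicit modelling knob.
    """

    n_varieties_per_category: int = 14
    grains_per_accession: int = 30
    categories: tuple = _DEFAULT_CATEGORIES
    sowing_levels: tuple = ("spring", "winter")
    effect_scales: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECT_SCALES))
    size_params: dict = field(default_factory=lambda: dict(_DEFAULT_SIZE_PARAMS))
    n_years: int = 1
    n_snps: int = 784
    genetic_morpho_coupling: float = 0.0
    view_noise_correlation: float = _DEFAULT_VIEW_COUPLING
    seed: int = 0
    k_points: int = 360

    def __post_init__(self) -> None:
        scales = dict(_DEFAULT_EFFECT_SCALES)
        scales.update(self.effect_scales)
        self.effect_scales = scales
        sizes = dict(_DEFAULT_SIZE_PARAMS)
        sizes.update(self.size_params)
        self.size_params = sizes
        if any(v < 0 for v in self.effect_scales.values()):
            raise ValueError("effect scales must be nonnegative")
        if self.grains_per_accession < 3:
            raise ValueError("grains_per_accession must be >= 3")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.genetic_morpho_coupling <= 1.0:
            raise ValueError("genetic_morpho_coupling must be in [0, 1]")
        if not 0.0 <= self.view_noise_correlation <= 1.0:
            raise ValueError("view_noise_correlation must be in [0, 1]")
        for row, hull in self.categories:
            if row not in ("2-row", "6-row") or hull not in ("hulled", "naked"):
                raise ValueError(f"unknown category ({row}, {hull})")
        for s in self.sowing_levels:
            if s not in ("spring", "winter", "alternative"):
                raise ValueError(f"unknown sowing level {s!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["categories"] = [list(c) for c in self.categories]
        d["sowing_levels"] = list(self.sowing_levels)
        return d


@dataclass
class SynthTruth:
    """Ground truth of one generated dataset, for parameter-recovery tests."""

    variety_means: dict  # variety -> {view: (H, 4) array, analysis space
    #                       (normalized coefficients of the noise-free mean)}
    year_offsets: dict  # (variety, year) -> {view: (H, 4) array}
    row_effects: dict  # view -> (H, 4) array (2-row minus 6-row direction)
    hull_effects: dict  # view -> (H, 4) array
    sowing_effects: dict  # view -> (H, 4) array (spring minus winter direction)
    variety_table: "object" = None  # pandas DataFrame of variety metadata
    snp_allele_freqs: np.ndarray | None = None

    def to_json(self, path) -> None:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            return obj

        payload = {
            "variety_means": conv(self.variety_means),
            "year_offsets": conv({f"{v}|{y}": d for (v, y), d in self.year_offsets.items()}),
            "row_effects": conv(self.row_effects),
            "hull_effects": conv(self.hull_effects),
            "sowing_effects": conv(self.sowing_effects),
            "snp_allele_freqs": conv(self.snp_allele_freqs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _normalized_template(view: str) -> np.ndarray:
    return np.asarray(TEMPLATE_COEFFS[view], dtype=float)


def _aspect_scales(view: str, size_params: dict) -> tuple[float, float]:
    """Per-view (x, y) coefficient multipliers mapping the normalized
    template to the configured base dimensions (before the per-grain
    uniform size factor)."""
    ext_major, ext_minor = TEMPLATE_EXTENTS[view]
    minor_key = "base_width_mm" if view == "ventral" else "base_thickness_mm"
    return (
        size_params["base_length_mm"] / ext_major,
        size_params[minor_key] / ext_minor,
    )


def _analysis_space_mean(
    coeffs: np.ndarray, view: str, size_params: dict, k: int = 360
) -> np.ndarray:
    """Express a mean coefficient vector the way the analysis sees grains:
    aspect-scaled, reconstructed, resampled with the start-point
    convention, normalized to centroid size 1, and re-expanded."""
    from caryomorph.eft import eft_forward, normalize
    from caryomorph.outline import resample

    sx, sy = _aspect_scales(view, size_params)
    scaled = coeffs.copy()
    scaled[:, :2] *= sx
    scaled[:, 2:] *= sy
    o = eft_inverse(EFTCoefficients(coeffs=scaled, view=view), k)
    o.unit = "mm"
    return eft_forward(normalize(resample(o, k)), N_HARMONICS).coeffs


def _draw_effect(rng: np.random.Generator, scale: float) -> dict[str, np.ndarray]:
    return {
        v: rng.normal(0.0, scale, size=(N_HARMONICS, 4)) * _HARMONIC_DECAY[:, None]
        for v in ("lateral", "ventral")
    }


def _scaled_effect(effect: dict, loading: dict) -> dict:
    return {v: effect[v] * loading[v] for v in effect}


def generate_dataset(config: SynthConfig) -> tuple[list[GrainRecord], SynthTruth]:
    """Generate grain records and their ground truth.

    Randomness is structured so that every accession (variety x year) has
    its own RNG stream derived from ``(seed, variety_index, year)``:
    enlarging the collection never perturbs already-generated accessions.
    Global taxonomic and sowing effect vectors come from a dedicated
    stream derived from the seed alone.
    """
    import pandas as pd

    es = config.effect_scales
    sp = config.size_params

    g_rng = np.random.default_rng([config.seed, 0])
    row_eff = _scaled_effect(_draw_effect(g_rng, es["category_shape"]), _ROW_LOADING)
    hull_eff = _scaled_effect(_draw_effect(g_rng, es["category_shape"]), _HULL_LOADING)
    sow_eff = _draw_effect(g_rng, es["sowing_shape"])

    sow_sign = {"spring": 0.5, "winter": -0.5, "alternative": 0.0}

    records: list[GrainRecord] = []
    variety_means: dict = {}
    year_offsets: dict = {}
    variety_rows = []

    variety_idx = 0
    for row_type, hull_type in config.categories:
        r_sign = 0.5 if row_type == "2-row" else -0.5
        h_sign = 0.5 if hull_type == "hulled" else -0.5
        for v in range(config.n_varieties_per_category):
            variety = f"V{variety_idx:03d}"
            sowing = config.sowing_levels[v % len(config.sowing_levels)]
            v_rng = np.random.default_rng([config.seed, 10_000 + variety_idx])
            var_eff = _draw_effect(v_rng, es["variety_shape"])
            means = {}
            for view in ("lateral", "ventral"):
                means[view] = (
                    _normalized_template(view)
                    + r_sign * row_eff[view]
                    + h_sign * hull_eff[view]
                    + sow_sign[sowing] * sow_eff[view]
                    + var_eff[view]
                )
            variety_means[variety] = {
                view: _analysis_space_mean(means[view], view, sp, config.k_points)
                for view in ("lateral", "ventral")
            }
            variety_rows.append(
                {"variety": variety, "row_type": row_type, "hull_type": hull_type,
                 "sowing": sowing, "category": f"{row_type} {hull_type}"}
            )
            for year_i in range(config.n_years):
                year = 2000 + year_i
                a_rng = np.random.default_rng(
                    [config.seed, 10_000 + variety_idx, year_i]
                )
                y_off = _draw_effect(a_rng, es["year_shape"])
                year_offsets[(variety, year)] = y_off
                acc_id = f"{variety}-{year}"
                meta = GrainMetadata(
                    accession_id=acc_id, variety=variety, row_type=row_type,
                    hull_type=hull_type, sowing=sowing, year=year,
                )
                for g in range(config.grains_per_accession):
                    gid = f"{acc_id}-g{g:03d}"
                    rec = _make_grain(
                        gid, meta, means, y_off, sowing, a_rng, config
                    )
                    records.append(rec)
            variety_idx += 1

    truth = SynthTruth(
        variety_means=variety_means,
        year_offsets=year_offsets,
        row_effects=row_eff,
        hull_effects=hull_eff,
        sowing_effects=sow_eff,
        variety_table=pd.DataFrame(variety_rows).set_index("variety"),
    )
    return records, truth


def _make_grain(
    gid: str,
    meta: GrainMetadata,
    means: dict,
    y_off: dict,
    sowing: str,
    rng: np.random.Generator,
    config: SynthConfig,
) -> GrainRecord:
    es, sp = config.effect_scales, config.size_params
    rho = config.view_noise_correlation
    mult = sp["spring_size_multiplier"] if sowing == "spring" else 1.0
    cv = sp["lognormal_cv"]
    sigma = np.sqrt(np.log1p(cv**2))

    for _attempt in range(100):
        shared = rng.normal(0.0, 1.0, size=(N_HARMONICS, 4)) * _HARMONIC_DECAY[:, None]
        # lognormal with unit mean: exp(N(-sigma^2/2, sigma^2))
        s = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        outlines = {}
        ok = True
        for view in ("lateral", "ventral"):
            own = rng.normal(0.0, 1.0, size=(N_HARMONICS, 4)) * _HARMONIC_DECAY[:, None]
            noise = es["grain_noise"] * (
                np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
            )
            coeffs = means[view] + y_off[view] + noise
            ext_major, ext_minor = TEMPLATE_EXTENTS[view]
            major_target = sp["base_length_mm"] * s * mult
            minor_key = "base_width_mm" if view == "ventral" else "base_thickness_mm"
            minor_target = sp[minor_key] * s * mult
            scaled = coeffs.copy()
            scaled[:, :2] *= major_target / ext_major
            scaled[:, 2:] *= minor_target / ext_minor
            o = eft_inverse(
                EFTCoefficients(coeffs=scaled, view=view, grain_id=gid),
                config.k_points,
            )
            o.unit = "mm"
            if not o.is_simple():
                ok = False
                break
            outlines[view] = o
        if ok:
            rec = GrainRecord(
                grain_id=gid, lateral=outlines["lateral"],
                ventral=outlines["ventral"], metadata=meta,
            )
            rec.sizes = size_indices(rec.lateral, rec.ventral)
            return rec
    raise OutlineError(
        f"grain {gid}: no simple outline in 100 draws; "
        "effect scales are too large for the template"
    )


# ---------------------------------------------------------------------------
# SNP genotypes
# ---------------------------------------------------------------------------

def generate_snp_matrix(config: SynthConfig, truth: SynthTruth) -> SNPMatrix:
    """Binary variety x marker genotypes, optionally coupled to shape.

    With ``genetic_morpho_coupling = 0`` genotypes are independent
    Bernoulli draws per marker (morphometric and genetic distances are
    then unrelated, the situation the Mantel test probes).  With
    coupling 1, every marker is a thresholded random projection of the
    variety's true mean coefficient vector, so genotype clusters follow
    shape clusters.  Intermediate values mix the two marker types in
    proportion.
    """
    rng = np.random.default_rng([config.seed, 2])
    varieties = list(truth.variety_means)
    n_v = len(varieties)
    latent = np.array(
        [
            np.concatenate(
                [truth.variety_means[v][view].ravel() for view in ("lateral", "ventral")]
            )
            for v in varieties
        ]
    )
    latent = latent - latent.mean(axis=0)

    p = rng.uniform(0.1, 0.9, size=config.n_snps)
    rand_bits = (rng.random((n_v, config.n_snps)) < p).astype(np.int8)
    w = rng.normal(size=(latent.shape[1], config.n_snps))
    proj = latent @ w
    shape_bits = (proj > np.median(proj, axis=0)).astype(np.int8)
    use_shape = rng.random(config.n_snps) < config.genetic_morpho_coupling
    geno = np.where(use_shape[None, :], shape_bits, rand_bits)

    truth.snp_allele_freqs = p
    return SNPMatrix(varieties=varieties, genotypes=geno)


# ---------------------------------------------------------------------------
# rasterization (inverse of mask tracing, for end-to-end outline tests)
# ---------------------------------------------------------------------------

def rasterize_outline(
    outline: Outline, px_per_cm: float
) -> tuple[np.ndarray, ScalePair]:
    """Render a calibrated outline as a binary mask plus scale landmarks.

    The outline (mm) is drawn as a filled polygon at ``px_per_cm``
    resolution; the returned :class:`ScalePair` holds two pixel
    coordinates exactly 1 cm apart, mimicking the manually placed scale
    landmarks of an imaging protocol.  Round-tripping through
    ``trace_mask`` -> ``calibrate`` recovers the outline to sub-pixel
    accuracy, which is how outline extraction is tested end to end.
    """
    from skimage.draw import polygon as sk_polygon

    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    if outline.unit != "mm":
        raise OutlineError("rasterization expects a mm-calibrated outline")
    px_per_mm = px_per_cm / 10.0
    if outline.perimeter * px_per_mm < 20:
        raise OutlineError(
            "resolution too low: fewer than 20 boundary pixels for this outline"
        )
    pts = outline.points * px_per_mm
    margin = 8.0
    pts = pts - pts.min(axis=0) + margin
    width = int(np.ceil(max(pts[:, 0].max() + margin, px_per_cm + 2 * margin)))
    height = int(np.ceil(pts[:, 1].max() + margin + 12))
    mask = np.zeros((height, width), dtype=bool)
    rr, cc = sk_polygon(pts[:, 1], pts[:, 0], shape=mask.shape)
    mask[rr, cc] = True
    y_bar = height - 4.0
    scale = ScalePair(p1=(4.0, y_bar), p2=(4.0 + px_per_cm, y_bar))
    return mask, scale
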