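import numpy as np
import pandas as pd
import pytest

import caryomorph as cm


def circle(r=1.0, k=360, phase=0.0):
    """Circle of radius r sampled CCW from (r, 0), uniformly in angle."""
    th = 2 * np.pi * np.arange(k) / k + phase
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def ellipse(A=2.0, B=1.0, k=360):
    """Axis-aligned ellipse sampled uniformly in the angular parameter."""
    th = 2 * np.pi * np.arange(k) / k
    return np.column_stack([A * np.cos(th), B * np.sin(th)])


def grain_outline(view="lateral", seed=0, k=360, noise=0.0):
    """One synthetic grain-like outline (mm units), optionally noisy."""
    from caryomorph._templates import TEMPLATE_COEFFS, TEMPLATE_EXTENTS
    from caryomorph.eft import EFTCoefficients, eft_inverse

    coeffs = np.array(TEMPLATE_COEFFS[view], dtype=float)
    if noise:
        rng = np.random.default_rng(seed)
        decay = 1.0 / np.arange(1, len(coeffs) + 1)
        coeffs = coeffs + rng.normal(0, noise, coeffs.shape) * decay[:, None]
    ext = TEMPLATE_EXTENTS[view]
    coeffs[:, :2] *= 8.5 / ext[0]
    coeffs[:, 2:] *= (3.4 if view == "ventral" else 2.8) / ext[1]
    o = eft_inverse(EFTCoefficients(coeffs=coeffs, view=view), k)
    o.unit = "mm"
    return o


def tables_from_records(records):
    """(coeffs, sizes, meta) DataFrames for a list of GrainRecords."""
    from caryomorph.eft import records_to_coefficients

    coeffs = records_to_coefficients(records)
    sizes = pd.DataFrame(
        [{"grain_id": r.grain_id, **r.sizes.as_dict()} for r in records]
    )
    meta = pd.DataFrame(
        [
            {
                "grain_id": r.grain_id,
                "accession_id": r.metadata.accession_id,
                "variety": r.metadata.variety,
                "row_type": r.metadata.row_type,
                "hull_type": r.metadata.hull_type,
                "sowing": r.metadata.sowing,
                "year": r.metadata.year,
            }
            for r in records
        ]
    )
    return coeffs, sizes, meta


@pytest.fixture(scope="session")
def small_dataset():
    """4 categories x 2 varieties x 8 grains, with ground truth."""
    cfg = cm.SynthConfig(
        n_varieties_per_category=2, grains_per_accession=8, n_snps=60, seed=11
    )
    records, truth = cm.generate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_tables(small_dataset):
    _, records, _ = small_dataset
    return tables_from_records(records)


@pytest.fixture(scope="session")
def medium_tables():
    """4 categories x 3 varieties x 30 grains (the study's per-accession
    sample size): enough rows for the 48-column combined-shape block."""
    cfg = cm.SynthConfig(
        n_varieties_per_category=3, grains_per_accession=30, n_snps=80, seed=23
    )
    records, _ = cm.generate_dataset(cfg)
    return tables_from_records(records)
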