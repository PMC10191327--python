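"""End-to-end orchestration: simulate/load -> coefficients -> statistics ->
classification -> networks -> Mantel -> report.

A run is driven by a single :class:`RunConfig` (constructible from a
YAML file with full defaulting); every stage writes its outputs under
the run directory and the manifest records the package version, a hash
of the fully-defaulted configuration, per-stage seeds and row counts,
so a bare config re-runs to identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

import caryomorph
from caryomorph import classify as _classify
from caryomorph import distnet as _distnet
from caryomorph import eft as _eft
from caryomorph import morphostats as _stats
from caryomorph import outline as _outline
from caryomorph import synthdata as _synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully-defaulted configuration of one pipeline run."""

    out_dir: str = "caryomorph_run"
    # input: either simulate, or load outlines+meta from files
    simulate: bool = True
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    outlines_csv: str | None = None
    meta_tsv: str | None = None
    snps_tsv: str | None = None
    # analysis settings
    harmonics: dict | None = None  # e.g. {"lateral": 5, "ventral": 7}; None = auto
    harmonic_threshold: float = 0.99
    k_points: int = 360
    contrasts: tuple = ("four_group", "row_type", "hull_type", "sowing")
    feature_sets: tuple = ("combined_shape", "lateral_shape", "ventral_shape")
    permutations: int = 999
    bootstrap: int = 100
    ci_method: str = "bootstrap"
    adjust_method: str = "bonferroni"
    network_grouping: str = "variety"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contrasts"] = list(self.contrasts)
        d["feature_sets"] = list(self.feature_sets)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis settings (the output directory does not
        change what is computed, so it is excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json).

    On a stage failure the outputs produced so far are moved under
    ``<out_dir>/failed/`` and a :class:`PipelineError` naming the stage
    is raised; nothing downstream of the failure is written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": caryomorph.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    stage = "init"
    try:
        # ------------------------------------------------ input stage
        stage = "simulate" if config.simulate else "extract"
        snps = None
        truth = None
        if config.simulate:
            synth_cfg = _synth.SynthConfig(**{"seed": config.seed, **config.synth})
            records, truth = _synth.generate_dataset(synth_cfg)
            snps = _synth.generate_snp_matrix(synth_cfg, truth)
            _outline.write_outlines(records, out / "outlines.csv", out / "meta.tsv")
            snps.to_tsv(out / "snps.tsv")
            truth.to_json(out / "truth.json")
        else:
            if not config.outlines_csv or not config.meta_tsv:
                raise ValueError("outlines_csv and meta_tsv required when simulate=false")
            records = _outline.read_outlines(config.outlines_csv, config.meta_tsv)
            if not records:
                raise ValueError("no grains found in input outline file")
            if config.snps_tsv:
                snps = _distnet.SNPMatrix.from_tsv(config.snps_tsv)
        manifest["stages"][stage] = {"rows_out": len(records), "seed": config.seed}

        # ------------------------------------------------ eft stage
        stage = "eft"
        harmonics = config.harmonics
        if harmonics is None:
            harmonics = _eft.select_harmonics(
                records, threshold=config.harmonic_threshold, k=config.k_points,
                seed=config.seed,
            )
        coeffs = _eft.records_to_coefficients(records, harmonics, k=config.k_points)
        _eft.write_coefficients(coeffs, out / "coeffs.csv")
        sizes = pd.DataFrame(
            [{"grain_id": r.grain_id, **r.sizes.as_dict()} for r in records]
        )
        sizes.to_csv(out / "sizes.csv", index=False)
        meta = pd.read_csv(out / "meta.tsv", sep="\t") if config.simulate else pd.read_csv(
            config.meta_tsv, sep="\t"
        )
        manifest["stages"]["eft"] = {
            "harmonics": {k: int(v) for k, v in harmonics.items()},
            "rows_out": int(len(coeffs)),
        }

        # ------------------------------------------------ stats stage
        stage = "stats"
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        _stats.size_correlations(sizes.drop(columns=["grain_id"])).to_csv(
            stats_dir / "size_correlations.csv"
        )
        meta_idx = meta.set_index("grain_id")
        meta_idx["category"] = meta_idx["row_type"] + " " + meta_idx["hull_type"]
        results = []
        sz = sizes.set_index("grain_id").loc[meta_idx.index]
        for index_col in ("length_mm", "width_mm", "thickness_mm"):
            res = _stats.kruskal_wallis(sz[index_col].to_numpy(), meta_idx["category"].to_numpy())
            res.contrast = f"category:{index_col}"
            results.append(res)
            results.extend(
                _w_with_contrast(sz[index_col].to_numpy(), meta_idx["category"].to_numpy(),
                                 config.adjust_method, index_col)
            )
        fm = _classify.build_features(coeffs, sizes, meta, "combined_shape")
        res = _stats.manova(fm, "category")
        results.append(res)
        pw = _stats.pairwise_permanova(
            fm, "category", B=config.permutations, adjust=config.adjust_method,
            seed=config.seed,
        )
        results.extend(pw)
        _stats.results_table(results).to_csv(stats_dir / "tests.csv", index=False)
        manifest["stages"]["stats"] = {
            "tests": len(results), "B": config.permutations, "seed": config.seed,
        }

        # ------------------------------------------------ classify stage
        stage = "classify"
        cv_dir = out / "cv"
        cv_dir.mkdir(exist_ok=True)
        reports = _classify.contrast_suite(
            coeffs, sizes, meta, contrasts=config.contrasts,
            feature_sets=config.feature_sets, ci=True, B=config.bootstrap,
            seed=config.seed,
        )
        _classify.reports_table(reports).to_csv(cv_dir / "cv_reports.csv", index=False)
        conf = {
            f"{r.label_name}|{r.feature_set}": r.confusion.to_dict()
            for r in reports
        }
        (cv_dir / "confusions.json").write_text(json.dumps(conf, indent=2))
        manifest["stages"]["classify"] = {
            "reports": len(reports), "B_bootstrap": config.bootstrap,
            "seed": config.seed,
        }

        # ------------------------------------------------ network stage
        stage = "network"
        net_dir = out / "net"
        net_dir.mkdir(exist_ok=True)
        group_col = config.network_grouping
        dm = _distnet.mahalanobis_groups(fm, group_col)
        dm.to_csv(net_dir / f"mahalanobis_{group_col}.csv")
        dm.to_phylip(net_dir / f"mahalanobis_{group_col}.phy")
        if len(dm.labels) >= 3:
            tree = _distnet.neighbor_joining(dm)
            _distnet.export_newick(tree, net_dir / f"nj_{group_col}.nwk")
        manifest["stages"]["network"] = {"groups": len(dm.labels)}

        # ------------------------------------------------ mantel stage
        stage = "mantel"
        if snps is not None:
            gen_dm = _distnet.sokal_michener(snps)
            morpho_vars = [v for v in gen_dm.labels if v in set(fm.labels["variety"])]
            fm_v = fm.subset(fm.labels["variety"].isin(morpho_vars).to_numpy())
            morpho_dm = _distnet.mahalanobis_groups(fm_v, "variety")
            gen_dm = gen_dm.reorder(morpho_dm.labels)
            mres = _distnet.mantel(
                morpho_dm, gen_dm, B=config.permutations, seed=config.seed
            )
            (out / "mantel.json").write_text(
                json.dumps({"r": mres.statistic, "p": mres.p_value,
                            "B": mres.permutations}, indent=2)
            )
            manifest["stages"]["mantel"] = {
                "r": mres.statistic, "p": mres.p_value, "B": config.permutations,
            }
        else:
            manifest["stages"]["mantel"] = "not run (no SNP input)"

        # ------------------------------------------------ report stage
        stage = "report"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        make_report(out)
        return manifest
    except Exception as exc:  # noqa: BLE001 - fail-fast with stage context
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for item in list(out.iterdir()):
            if item.name != "failed":
                shutil.move(str(item), failed / item.name)
        (failed / "manifest_partial.json").write_text(
            json.dumps(manifest, indent=2, default=str)
        )
        raise PipelineError(stage, exc) from exc


def _w_with_contrast(values, groups, adjust, index_name):
    results = _stats.wilcoxon_pairs(values, groups, adjust=adjust)
    for r in results:
        r.contrast = f"{index_name}:{r.contrast}"
    return results


def make_report(run_dir) -> str:
    """Assemble a plain-text summary of a completed run.

    Lists size-index test tables, the CVP table with confidence
    intervals, Newick strings of the dissimilarity networks and the
    Mantel result; stages whose outputs are missing are listed as such.
    The text is also written to ``report.txt`` in the run directory.
    """
    run_dir = Path(run_dir)
    lines = ["caryomorph run report", "=" * 40]
    missing = []

    man_path = run_dir / "manifest.json"
    if man_path.exists():
        man = json.loads(man_path.read_text())
        lines.append(f"package version: {man['package_version']}")
        lines.append(f"config hash: {man['config_hash']}")
        eft_stage = man["stages"].get("eft", {})
        if isinstance(eft_stage, dict) and "harmonics" in eft_stage:
            lines.append(f"harmonics: {eft_stage['harmonics']}")
    else:
        missing.append("manifest")

    tests_path = run_dir / "stats" / "tests.csv"
    if tests_path.exists():
        lines.append("\n-- group tests (size: Kruskal-Wallis/Wilcoxon; shape: MANOVA/PERMANOVA) --")
        lines.append(pd.read_csv(tests_path).to_string(index=False, max_rows=60))
    else:
        missing.append("stats")

    cv_path = run_dir / "cv" / "cv_reports.csv"
    if cv_path.exists():
        cv = pd.read_csv(cv_path)
        lines.append("\n-- leave-one-out cross-validation percentages --")
        for _, row in cv.iterrows():
            ci = ""
            if pd.notna(row.get("ci_low")):
                ci = f" (CI: {row['ci_low']:.1f}-{row['ci_high']:.1f}%)"
            lines.append(
                f"{row['contrast']:<28} {row['feature_set']:<16} "
                f"CVP {row['cvp']:.1f}%{ci}  n={row['n']}"
            )
    else:
        missing.append("classify")

    net_dir = run_dir / "net"
    if net_dir.exists() and any(net_dir.glob("*.nwk")):
        lines.append("\n-- neighbor-joining networks --")
        for nwk in sorted(net_dir.glob("*.nwk")):
            lines.append(f"{nwk.name}: {nwk.read_text().strip()}")
    else:
        missing.append("network")

    mantel_path = run_dir / "mantel.json"
    if mantel_path.exists():
        m = json.loads(mantel_path.read_text())
        lines.append(
            f"\nMantel (morphometric vs genetic): r={m['r']:.4f}, p={m['p']:.4f} (B={m['B']})"
        )
    else:
        lines.append("\nMantel: not run")

    if missing:
        lines.append("\nmissing stages: " + ", ".join(missing))
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
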