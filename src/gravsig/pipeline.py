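"""End-to-end orchestration: synthesize -> DE -> persistence -> signature -> lipids.

A run is configured by :class:`RunConfig` (stage toggles, thresholds, one
top-level seed, output directory), validated fail-fast before any stage
executes, and produces per-stage artifacts plus a JSON run report.  All
randomness flows from the top-level seed through per-stage seeds derived as
``sha256("{seed}:{stage}") mod 2**31`` so stages are individually
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import calibration, io
from .diffexpr import call_degs, call_expressed_ncrna, cluster_samples, test_differential_expression
from .lipidomics import compare_species, replicate_qc
from .persistence import compute_persistence
from .signature import build_signature
from .simulate import generate_expression, generate_lipid_panel, generate_overlap_lists

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

STAGES = ("expression", "overlap", "lipid", "clinostat")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed: sha256 of '{seed}:{stage}', reduced mod 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


@dataclass
class RunConfig:
    outdir: str | Path = "run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    fc_threshold: float = 2.0
    alpha: float = 0.05
    ncrna_cutoff: float = 24.7
    r2_threshold: float = 0.9
    # optional real inputs; when absent the calibrated generators are used
    expression_matrix: str | None = None
    expression_design: str | None = None
    lipid_panel: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be non-negative")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in (0, 1]")
        paired = (self.expression_matrix is None) == (self.expression_design is None)
        if not paired:
            raise ValueError("expression_matrix and expression_design go together")
        for p in (self.expression_matrix, self.expression_design, self.lipid_panel):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _run_expression(cfg: RunConfig, outdir: Path) -> dict:
    seed = stage_seed(cfg.seed, "expression")
    if cfg.expression_matrix:
        matrix = io.read_expression_matrix(cfg.expression_matrix, cfg.expression_design)
        truth = None
    else:
        matrix, truth = generate_expression(calibration.expression_config(seed))
        io.write_expression_matrix(
            matrix, outdir / "expression_matrix.tsv", outdir / "expression_design.tsv"
        )
        io.write_json(truth.to_jsonable(), outdir / "expression_truth.json")
    conditions = matrix.conditions
    gc, contrasts = conditions[0], conditions[1:]
    tables = {}
    deg_counts = {}
    for cond in contrasts:
        stats = test_differential_expression(matrix, cond, gc)
        table = call_degs(
            stats, treatment=cond, control=gc,
            fc_threshold=cfg.fc_threshold, alpha=cfg.alpha,
        )
        tables[cond] = table
        deg_counts[cond] = {"up": len(table.up_ids), "down": len(table.down_ids)}
        io.write_deg_table(table, outdir / f"degs_{cond}_vs_{gc}.tsv")
    dendro = cluster_samples(matrix)
    (outdir / "sample_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    summary: dict = {"deg_counts": deg_counts, "conditions": conditions}
    if len(contrasts) >= 2:
        report = compute_persistence(tables[contrasts[0]], [tables[c] for c in contrasts[1:]])
        io.write_json(report.to_jsonable(), outdir / "persistence.json")
        summary["maintained_fraction_overall"] = {
            tp.timepoint: tp.overall_fraction for tp in report.timepoints
        }
    return summary


def _run_overlap(cfg: RunConfig, outdir: Path) -> dict:
    seed = stage_seed(cfg.seed, "overlap")
    ocfg = calibration.overlap_config(seed)
    table_a, table_b = generate_overlap_lists(ocfg)
    io.write_deg_table(table_a, outdir / "overlap_study_a.tsv")
    io.write_deg_table(table_b, outdir / "overlap_study_b.tsv")
    result = build_signature(table_a, table_b, universe_size=ocfg.universe_size)
    io.write_json(result.to_jsonable(), outdir / "signature.json")
    (outdir / "signature_genes.txt").write_text(
        "\n".join(sorted(result.signature_ids)) + "\n"
    )
    return {
        "n_common": len(result.common_ids),
        "n_conflicting": len(result.conflicting_ids),
        "n_signature": len(result.signature_ids),
        "overlap_p_value": result.overlap_test.p_value,
    }


def _run_lipid(cfg: RunConfig, outdir: Path) -> dict:
    seed = stage_seed(cfg.seed, "lipid")
    if cfg.lipid_panel:
        panel = io.read_ceramide_panel(cfg.lipid_panel)
    else:
        panel, truth = generate_lipid_panel(calibration.lipid_config(seed))
        io.write_ceramide_panel(panel, outdir / "ceramide_panel.tsv")
        io.write_json(truth.to_jsonable(), outdir / "lipid_truth.json")
    panel = replicate_qc(panel, r2_threshold=cfg.r2_threshold)
    io.write_json(
        {rid: {"status": s, "mean_r2": r} for rid, (s, r) in panel.qc_status.items()},
        outdir / "lipid_qc.json",
    )
    stats = compare_species(panel, alpha=cfg.alpha)
    stats.to_csv(outdir / "lipid_stats.tsv", sep="\t", index=False)
    excluded = [r for r, (s, _) in panel.qc_status.items() if s == "excluded"]
    return {
        "excluded_replicates": excluded,
        "n_significant": int(stats["significant"].sum()),
        "fold_changes": {
            r.species: {"fold": r.fold_change, "direction": r.direction}
            for r in stats.itertuples()
        },
    }


def _run_clinostat(cfg: RunConfig, outdir: Path) -> dict:
    from .clinostat import radius_curve, steady_state_radius, radial_drift_rate

    system = calibration.clinostat_system(omega=1.0)
    omegas = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
    curve = radius_curve(system, omegas, vt_sd=calibration.CLINOSTAT_VT_SD)
    curve.to_csv(outdir / "radius_curve.tsv", sep="\t", index=False)
    return {
        "orbit_radius_m": steady_state_radius(system),
        "radial_drift_rate_per_s": radial_drift_rate(system),
        "v_terminal_m_s": system.v_terminal,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Validate, run enabled stages in order, write artifacts and a report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "thresholds": {
            "fc_threshold": config.fc_threshold,
            "alpha": config.alpha,
            "ncrna_cutoff": config.ncrna_cutoff,
            "r2_threshold": config.r2_threshold,
        },
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES
                        if config.stages.get(s, False)},
        "stages": {},
    }
    runners = {
        "expression": _run_expression,
        "overlap": _run_overlap,
        "lipid": _run_lipid,
        "clinostat": _run_clinostat,
    }
    for stage in STAGES:
        if not config.stages.get(stage, False):
            continue
        try:
            report["stages"][stage] = runners[stage](config, outdir)
        except Exception as exc:
            io.write_json(report, outdir / "run_report.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        p.name: _sha256_file(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in ("run_report.json", "manifest.json")
    }
    io.write_json(manifest, outdir / "manifest.json")
    io.write_json(report, outdir / "run_report.json")
    return report
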