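"""Shipped study-calibrated synthetic configurations.

These configs hold the effect structure of the study the package models:

* expression: 5 conditions (ground control, 4-day simulated-microgravity
  exposure, and returns at 4/8/12 days), 3 replicates, 5000 genes, 10% DE at
  exposure; 75% of exposure effects retained at the first return, and at the
  third return 16% of upregulated and (essentially) none of the downregulated
  effects remain;
* a transcription-factor variant designating a 20-gene upregulated TF panel
  whose upregulation is retained at 90% / 75% / 15% across the three returns;
* lipid panel: the eleven sphingolipid species with their reported
  treatment/control fold changes (LacCer up 27-fold, HexCer down 3.6-fold,
  d18:1-C20 up 3.7-fold, ...), three replicates per group, and one
  decorrelated ground-control replicate for the QC stage to catch;
* overlap: 134 shared DEGs between the two studies, 16 of them
  sign-conflicting, over a 20000-gene universe;
* clinostat: the validation microspheres (5.6 um melamine, 1.51 g/cm^3) at
  1 rad/s with the measured terminal velocity 3.2 +- 0.2 um/s.

Functions return fresh config objects so callers may override the seed.
"""

from __future__ import annotations

from .clinostat import ClinostatSystem
from .simulate import ExpressionSimConfig, LipidSimConfig, OverlapSimConfig

__all__ = [
    "expression_config",
    "tf_expression_config",
    "lipid_config",
    "overlap_config",
    "clinostat_system",
    "CLINOSTAT_VT_SD",
]

#: measured terminal velocity of the validation microspheres, m/s (mean, SD)
CLINOSTAT_VT = 3.2e-6
CLINOSTAT_VT_SD = 0.2e-6


def expression_config(seed: int = 0) -> ExpressionSimConfig:
    """Expression design calibrated to the study's persistence structure."""
    return ExpressionSimConfig(
        n_genes=5000,
        conditions=("GC", "MG", "R1_GC", "R2_GC", "R3_GC"),
        n_replicates=3,
        baseline_log2_mean=9.0,
        baseline_log2_sd=2.0,
        nb_dispersion=0.02,
        frac_de=0.10,
        de_log2fc_magnitude=3.5,
        frac_up=0.6,
        de_min_baseline_log2=9.0,
        persistence={
            "R1_GC": 0.75,
            "R2_GC": {"up": 0.70, "down": 0.55},
            "R3_GC": {"up": 0.16, "down": 0.0},
        },
        seed=seed,
    )


def tf_expression_config(seed: int = 0) -> ExpressionSimConfig:
    """Expression design with a designated 20-gene upregulated TF panel.

    The panel's retention (90/75/15% across the returns) overrides the global
    persistence; a strong effect size keeps per-gene calling power near one
    so the 20-gene percentages are recoverable.
    """
    cfg = expression_config(seed)
    tf_ids = tuple(cfg.gene_ids()[:20])
    return ExpressionSimConfig(
        **{
            **cfg.__dict__,
            "de_log2fc_magnitude": 4.0,
            "tf_gene_ids": tf_ids,
            "subset_force_de": {"tf": "up"},
            "subset_persistence": {
                "tf": {"R1_GC": 0.90, "R2_GC": 0.75, "R3_GC": 0.15}
            },
        }
    )


#: species -> (control mean ng/ml, treatment/control fold change).
#: Species with fold 1.0 are quantified by the panel but unaffected by the
#: exposure; they anchor the replicate-correlation QC the way the full MRM
#: analyte list does in a real run.
LIPID_SPECIES: dict[str, tuple[float, float]] = {
    "total ceramide": (1500.0, 1 / 1.5),
    "HexCer": (300.0, 1 / 3.6),
    "LacCer": (2.0, 27.0),
    "SB": (40.0, 1 / 1.9),
    "d18:1 sphingosine": (25.0, 1 / 1.4),
    "d18:1-C14": (12.0, 1.0),
    "d18:1-C16": (150.0, 1 / 2.8),
    "d18:1-C18": (90.0, 1 / 1.6),
    "d18:1-C18:1": (20.0, 1.0),
    "d18:1-C20": (8.0, 3.7),
    "d18:1-C22": (30.0, 1.5),
    "d18:1-C22:1": (15.0, 1.0),
    "d18:1-C24": (400.0, 1 / 1.2),
    "d18:1-C24:1": (60.0, 1 / 3.2),
    "d18:1-C26": (5.0, 1.0),
    "d18:1-C26:1": (3.0, 1.0),
    "d18:0-C16": (35.0, 1.0),
    "d18:0-C18": (18.0, 1.0),
    "d18:0-C24": (80.0, 1.0),
    "d18:0 sphinganine": (10.0, 1.0),
}


def lipid_config(seed: int = 0, outlier_replicate: bool = True) -> LipidSimConfig:
    """Ceramide panel calibrated to the reported species fold changes."""
    return LipidSimConfig(
        species=tuple(LIPID_SPECIES),
        n_replicates=3,
        control_mean={s: m for s, (m, _) in LIPID_SPECIES.items()},
        fold_change={s: f for s, (_, f) in LIPID_SPECIES.items()},
        cv=0.22,
        outlier_replicate=outlier_replicate,
        seed=seed,
    )


def overlap_config(seed: int = 0) -> OverlapSimConfig:
    """Cross-study DEG overlap with the reported shared/conflicting counts."""
    return OverlapSimConfig(
        universe_size=20000,
        n_degs_study_a=600,
        n_degs_study_b=300,
        n_shared=134,
        n_conflicting=16,
        seed=seed,
    )


def clinostat_system(omega: float = 1.0) -> ClinostatSystem:
    """The validation-microsphere system at the given rotation rate."""
    return ClinostatSystem(
        omega=omega,
        particle_radius=2.8e-6,  # 5.6 um diameter
        particle_density=1510.0,
        fluid_density=1000.0,
        terminal_velocity=CLINOSTAT_VT,
    )
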