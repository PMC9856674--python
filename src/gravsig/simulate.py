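"""Seeded synthetic-data generators for every stage of the pipeline.

Three generators emit inputs carrying the statistical structure the analysis
assumes, together with the ground truth used by recovery tests:

* :func:`generate_expression` — negative-binomial count matrices for a
  ground-control / exposure / return design with a configurable fraction of
  truly differentially expressed genes and decaying persistence of their
  effects at the return timepoints;
* :func:`generate_lipid_panel` — lognormal replicate panels of lipid species
  concentrations with configured per-species fold changes and an optional
  decorrelated control replicate for QC testing;
* :func:`generate_overlap_lists` — two signed DEG tables with an exact number
  of shared gene ids, an exact number of which have conflicting signs.

Everything integer-countable (which genes are DE, how many are retained at a
return timepoint, shared/conflicting id counts) is realized exactly as
configured; only the noise around effects is random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .diffexpr import DEGTable, ExpressionMatrix
from .lipidomics import CeramidePanel

__all__ = [
    "ExpressionSimConfig",
    "ExpressionGroundTruth",
    "LipidSimConfig",
    "LipidGroundTruth",
    "OverlapSimConfig",
    "generate_expression",
    "generate_lipid_panel",
    "generate_overlap_lists",
]


def _round_half_even(x: float) -> int:
    """Nearest integer, ties to even (Python's round)."""
    return int(round(x))


Persistence = float | Mapping[str, float]


def _persistence_for(p: Persistence, direction: str) -> float:
    if isinstance(p, Mapping):
        return float(p[direction])
    return float(p)


@dataclass
class ExpressionSimConfig:
    """Design of a synthetic expression experiment.

    ``conditions`` is ordered: the first label is the ground control, the
    second the exposure, the rest are return timepoints.  ``persistence``
    maps each return condition to the fraction of exposure-DE genes whose
    effect is retained there, either as one number or split by direction
    (``{"up": 0.16, "down": 0.0}``).  ``subset_force_de`` forces a designated
    subset (by label) to be DE in a given direction at exposure, and
    ``subset_persistence`` overrides retention for that subset — this is how
    a transcription-factor panel with its own maintenance profile is built.
    """

    n_genes: int = 5000
    conditions: tuple[str, ...] = ("GC", "MG", "R1_GC", "R2_GC", "R3_GC")
    n_replicates: int = 3
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    nb_dispersion: float = 0.05
    frac_de: float = 0.1
    de_log2fc_magnitude: float = 3.0
    frac_up: float = 0.6
    de_min_baseline_log2: float | None = None
    persistence: Mapping[str, Persistence] = field(default_factory=dict)
    tf_gene_ids: tuple[str, ...] | None = None
    ncrna_gene_ids: tuple[str, ...] | None = None
    subset_force_de: Mapping[str, str] = field(default_factory=dict)
    subset_persistence: Mapping[str, Mapping[str, Persistence]] = field(
        default_factory=dict
    )
    output: str = "counts"
    seed: int = 0

    def gene_ids(self) -> list[str]:
        width = max(5, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def subsets(self) -> dict[str, tuple[str, ...]]:
        out = {}
        if self.tf_gene_ids is not None:
            out["tf"] = tuple(self.tf_gene_ids)
        if self.ncrna_gene_ids is not None:
            out["ncrna"] = tuple(self.ncrna_gene_ids)
        return out

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.conditions) < 2:
            raise ValueError("need at least a ground control and an exposure condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.n_replicates < 2:
            raise ValueError(
                "n_replicates must be >= 2 (downstream tests need variance)"
            )
        for name, frac in (("frac_de", self.frac_de), ("frac_up", self.frac_up)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.de_log2fc_magnitude <= 0:
            raise ValueError("de_log2fc_magnitude must be positive")
        returns = set(self.conditions[2:])
        for tp, p in self.persistence.items():
            if tp not in returns:
                raise ValueError(f"persistence timepoint {tp!r} is not a return condition")
            for d in ("up", "down"):
                f = _persistence_for(p, d)
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"persistence fraction for {tp!r} must lie in [0, 1]")
        universe = set(self.gene_ids())
        for label, ids in self.subsets().items():
            extra = set(ids) - universe
            if extra:
                raise ValueError(
                    f"subset {label!r} contains ids outside the gene universe: "
                    f"{sorted(extra)[:5]}"
                )
        for label, direction in self.subset_force_de.items():
            if label not in self.subsets():
                raise ValueError(f"subset_force_de refers to unknown subset {label!r}")
            if direction not in ("up", "down"):
                raise ValueError("forced direction must be 'up' or 'down'")
        for label in self.subset_persistence:
            if label not in self.subsets():
                raise ValueError(f"subset_persistence refers to unknown subset {label!r}")
        if self.output not in ("counts", "fpkm"):
            raise ValueError("output must be 'counts' or 'fpkm'")


@dataclass
class ExpressionGroundTruth:
    """True DE structure of a generated expression matrix.

    ``effects`` maps each non-control condition to {gene_id: 'up'/'down'}
    for the genes truly differentially expressed there (relative to ground
    control).  Retained genes keep the exposure log2 fold change unchanged;
    non-retained genes revert to baseline.
    """

    exposure: str
    returns: tuple[str, ...]
    effects: dict[str, dict[str, str]]
    log2fc_magnitude: float

    def de_ids(self, condition: str, direction: str | None = None) -> set[str]:
        eff = self.effects[condition]
        if direction is None:
            return set(eff)
        return {g for g, d in eff.items() if d == direction}

    def to_jsonable(self) -> dict:
        return {
            "exposure": self.exposure,
            "returns": list(self.returns),
            "log2fc_magnitude": self.log2fc_magnitude,
            "effects": {c: dict(sorted(e.items())) for c, e in self.effects.items()},
        }


def generate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, ExpressionGroundTruth]:
    """Generate a seeded negative-binomial expression matrix with ground truth.

    Gene baselines are lognormal (normal on the log2 scale); counts are drawn
    negative-binomial with variance mu + dispersion * mu^2 via the
    gamma–Poisson mixture.  DE genes at exposure shift their mean by
    ``2**(+-de_log2fc_magnitude)``; at each return timepoint the configured
    fraction of exposure-DE genes (rounded half-to-even, per direction)
    retains the identical effect, with retained sets nested across timepoints
    so that monotone persistence configs produce progressive reversion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    n = config.n_genes

    baseline_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)

    # forced subsets come from the expressed (upper) part of the baseline
    # distribution: curated panels are biased toward detectable genes
    forced: dict[str, str] = {}
    for label, direction in config.subset_force_de.items():
        for g in config.subsets()[label]:
            forced[g] = direction
    floor = config.de_min_baseline_log2
    if forced:
        lo = 0.0 if floor is None else max(
            0.0, (floor - config.baseline_log2_mean) / config.baseline_log2_sd
        )
        tn = _st.truncnorm(  # truncated below at the baseline mean (or the DE floor)
            lo, np.inf, loc=config.baseline_log2_mean, scale=config.baseline_log2_sd
        )
        draws = tn.rvs(size=len(forced), random_state=rng)
        for (g, _), v in zip(sorted(forced.items()), draws):
            baseline_log2[gene_index[g]] = v

    n_de = _round_half_even(config.frac_de * n)
    if len(forced) > n_de:
        raise ValueError(
            f"{len(forced)} forced-DE genes exceed the configured DE count {n_de}"
        )

    exposure = config.conditions[1]
    returns = tuple(config.conditions[2:])

    if floor is None:
        free_pool = [g for g in genes if g not in forced]
    else:
        # DE effects land on detectably expressed genes only
        free_pool = [
            g for g in genes
            if g not in forced and baseline_log2[gene_index[g]] >= floor
        ]
    n_free = n_de - len(forced)
    if len(free_pool) < n_free:
        raise ValueError(
            f"only {len(free_pool)} genes at or above the DE baseline floor "
            f"for {n_free} required DE genes; lower de_min_baseline_log2"
        )
    chosen_free = list(rng.choice(free_pool, size=n_free, replace=False))
    n_up = _round_half_even(config.frac_up * n_de)
    n_up_forced = sum(1 for d in forced.values() if d == "up")
    n_up_free = int(np.clip(n_up - n_up_forced, 0, n_free))
    shuffled = list(rng.permutation(chosen_free))
    directions: dict[str, str] = dict(forced)
    for g in shuffled[:n_up_free]:
        directions[g] = "up"
    for g in shuffled[n_up_free:]:
        directions[g] = "down"

    effects: dict[str, dict[str, str]] = {exposure: dict(directions)}

    # retention: one random permutation per (group, direction); the retained
    # set at each timepoint is its leading slice, so sets are nested whenever
    # the configured fractions are non-increasing
    override_groups: dict[str, set[str]] = {}
    claimed: set[str] = set()
    for label in config.subset_persistence:
        members = set(config.subsets()[label]) & set(directions)
        override_groups[label] = members - claimed
        claimed |= members
    base_group = set(directions) - claimed

    orders: dict[tuple[str, str], list[str]] = {}
    for gname, members in [("__base__", base_group)] + list(override_groups.items()):
        for d in ("up", "down"):
            pool = sorted(g for g in members if directions[g] == d)
            orders[(gname, d)] = list(rng.permutation(pool)) if pool else []

    for tp in returns:
        eff_tp: dict[str, str] = {}
        for (gname, d), order in orders.items():
            if gname == "__base__":
                p = config.persistence.get(tp, 0.0)
            else:
                p = config.subset_persistence[gname].get(
                    tp, config.persistence.get(tp, 0.0)
                )
            f = _persistence_for(p, d)
            keep = _round_half_even(f * len(order))
            for g in order[:keep]:
                eff_tp[g] = d
        effects[tp] = eff_tp

    # mean matrix and NB sampling
    mu_base = 2.0 ** baseline_log2
    shift = 2.0 ** config.de_log2fc_magnitude
    columns: list[str] = []
    design: dict[str, tuple[str, int]] = {}
    data = np.empty((n, len(config.conditions) * config.n_replicates))
    col = 0
    for cond in config.conditions:
        mu = mu_base.copy()
        if cond != config.conditions[0]:
            for g, d in effects.get(cond, {}).items():
                i = gene_index[g]
                mu[i] = mu_base[i] * (shift if d == "up" else 1.0 / shift)
        for rep in range(1, config.n_replicates + 1):
            lam = rng.gamma(
                shape=1.0 / config.nb_dispersion,
                scale=mu * config.nb_dispersion,
            )
            counts = rng.poisson(lam).astype(float)
            sample = f"{cond}_r{rep}"
            columns.append(sample)
            design[sample] = (cond, rep)
            data[:, col] = counts
            col += 1

    if config.output == "fpkm":
        # fixed pseudo-length of 1 kb: FPKM = counts / (libsize / 1e6)
        libsize = data.sum(axis=0)
        libsize[libsize == 0] = 1.0
        data = data / (libsize / 1e6)

    values = pd.DataFrame(data, index=genes, columns=columns)
    matrix = ExpressionMatrix(values=values, design=design)
    truth = ExpressionGroundTruth(
        exposure=exposure,
        returns=returns,
        effects=effects,
        log2fc_magnitude=config.de_log2fc_magnitude,
    )
    return matrix, truth


@dataclass
class LipidSimConfig:
    """Design of a synthetic lipid concentration panel (ng/ml scale).

    ``fold_change`` is treatment over control per species (values < 1 are
    decreases).  ``cv`` is log-space noise common to both groups.  With
    ``outlier_replicate`` set, the last control replicate's log profile is
    rebuilt so its sample correlation with the true species profile equals
    ``sqrt(outlier_target_r2)`` exactly (Gram–Schmidt against a random
    direction), so the QC stage sees a decorrelated replicate with R^2 near
    the configured target rather than merely low in expectation.
    """

    species: tuple[str, ...]
    n_replicates: int = 3
    control_mean: Mapping[str, float] = field(default_factory=dict)
    fold_change: Mapping[str, float] = field(default_factory=dict)
    cv: float = 0.25
    outlier_replicate: bool = False
    outlier_target_r2: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if not self.species:
            raise ValueError("species list must be non-empty")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for s in self.species:
            m = self.control_mean.get(s)
            f = self.fold_change.get(s)
            if m is None or f is None:
                raise ValueError(f"species {s!r} lacks a control mean or fold change")
            if m <= 0 or f <= 0:
                raise ValueError(
                    f"means and fold changes must be strictly positive (species {s!r})"
                )
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if not 0.0 < self.outlier_target_r2 < 1.0:
            raise ValueError("outlier_target_r2 must lie in (0, 1)")
        if self.outlier_replicate and len(self.species) < 3:
            raise ValueError("outlier injection needs at least 3 species")


@dataclass
class LipidGroundTruth:
    fold_change: dict[str, float]
    outlier_replicate: str | None

    def to_jsonable(self) -> dict:
        return {
            "fold_change": dict(self.fold_change),
            "outlier_replicate": self.outlier_replicate,
        }


def generate_lipid_panel(
    config: LipidSimConfig,
) -> tuple[CeramidePanel, LipidGroundTruth]:
    """Generate a two-group lognormal concentration panel with ground truth.

    Concentrations are lognormal around the configured species means (with
    the usual -sigma^2/2 offset so expected concentrations equal the means
    exactly); treatment means are control means times the configured fold
    change before noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = list(config.species)
    n_sp = len(species)
    sigma = config.cv
    log_mu = np.log([config.control_mean[s] for s in species])
    folds = np.array([config.fold_change[s] for s in species])

    columns: list[str] = []
    groups: dict[str, str] = {}
    cols: list[np.ndarray] = []
    outlier_id: str | None = None
    for group, group_mu in (("control", log_mu), ("treatment", log_mu + np.log(folds))):
        for rep in range(1, config.n_replicates + 1):
            rid = f"{group}_r{rep}"
            profile = group_mu
            if (
                config.outlier_replicate
                and group == "control"
                and rep == config.n_replicates
            ):
                # exact-correlation construction: standardize the true log
                # profile, mix with an orthogonalized random direction
                x = group_mu - group_mu.mean()
                x_hat = x / np.linalg.norm(x)
                y = rng.normal(size=n_sp)
                y = y - y.mean()
                y = y - (y @ x_hat) * x_hat
                y_hat = y / np.linalg.norm(y)
                r0 = np.sqrt(config.outlier_target_r2)
                mixed = r0 * x_hat + np.sqrt(1.0 - r0**2) * y_hat
                profile = group_mu.mean() + mixed * np.linalg.norm(x)
                outlier_id = rid
            eps = rng.normal(0.0, sigma, n_sp)
            cols.append(np.exp(profile - sigma**2 / 2.0 + eps))
            columns.append(rid)
            groups[rid] = group

    conc = pd.DataFrame(np.column_stack(cols), index=species, columns=columns)
    panel = CeramidePanel(concentrations=conc, groups=groups)
    truth = LipidGroundTruth(
        fold_change={s: float(f) for s, f in zip(species, folds)},
        outlier_replicate=outlier_id,
    )
    return panel, truth


@dataclass
class OverlapSimConfig:
    """Two signed DEG lists over a shared universe with exact overlap structure."""

    universe_size: int = 20000
    n_degs_study_a: int = 600
    n_degs_study_b: int = 300
    n_shared: int = 134
    n_conflicting: int = 16
    seed: int = 0

    def validate(self) -> None:
        for name in ("universe_size", "n_degs_study_a", "n_degs_study_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_shared < 0 or self.n_conflicting < 0:
            raise ValueError("counts must be non-negative")
        if self.n_shared > min(self.n_degs_study_a, self.n_degs_study_b):
            raise ValueError(
                f"n_shared={self.n_shared} exceeds the smaller DEG list "
                f"({min(self.n_degs_study_a, self.n_degs_study_b)})"
            )
        if self.n_conflicting > self.n_shared:
            raise ValueError(
                f"n_conflicting={self.n_conflicting} exceeds n_shared={self.n_shared}"
            )
        union = self.n_degs_study_a + self.n_degs_study_b - self.n_shared
        if self.universe_size < union:
            raise ValueError(
                f"universe_size={self.universe_size} smaller than the DEG union ({union})"
            )


def _deg_table_from_signs(
    label: str, signs: dict[str, int], rng: np.random.Generator
) -> DEGTable:
    ids = sorted(signs)
    sgn = np.array([signs[g] for g in ids], dtype=float)
    log2fc = sgn * (2.5 + rng.uniform(0.0, 2.0, len(ids)))
    p_adj = rng.uniform(1e-8, 1e-3, len(ids))
    rec = pd.DataFrame(
        {
            "gene_id": ids,
            "log2fc": log2fc,
            "p_raw": p_adj / 2.0,
            "p_adj": p_adj,
            "call": np.where(sgn > 0, "up", "down"),
        }
    )
    return DEGTable(treatment=label, control="GC", records=rec)


def generate_overlap_lists(
    config: OverlapSimConfig,
) -> tuple[DEGTable, DEGTable]:
    """Emit two signed DEG tables with exactly the configured overlap structure.

    The shared ids number exactly ``n_shared``; exactly ``n_conflicting`` of
    them carry opposite signs between the two tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(5, len(str(config.universe_size)))
    universe = [f"g{i:0{width}d}" for i in range(1, config.universe_size + 1)]
    union = config.n_degs_study_a + config.n_degs_study_b - config.n_shared
    picked = list(rng.choice(universe, size=union, replace=False))
    shared = picked[: config.n_shared]
    a_only = picked[config.n_shared : config.n_degs_study_a]
    b_only = picked[config.n_degs_study_a :]

    signs_a: dict[str, int] = {}
    signs_b: dict[str, int] = {}
    base_signs = rng.choice([-1, 1], size=config.n_shared)
    conflict_ids = set(
        rng.choice(shared, size=config.n_conflicting, replace=False)
        if config.n_conflicting
        else []
    )
    for g, s in zip(shared, base_signs):
        signs_a[g] = int(s)
        signs_b[g] = -int(s) if g in conflict_ids else int(s)
    for g, s in zip(a_only, rng.choice([-1, 1], size=len(a_only))):
        signs_a[g] = int(s)
    for g, s in zip(b_only, rng.choice([-1, 1], size=len(b_only))):
        signs_b[g] = int(s)

    table_a = _deg_table_from_signs("study_a", signs_a, rng)
    table_b = _deg_table_from_signs("study_b", signs_b, rng)
    return table_a, table_b
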