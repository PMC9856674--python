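"""Ceramide panel statistics: replicate QC, equal-variance check, mean comparison.

The workflow mirrors a standard targeted-lipidomics analysis: replicates are
screened by cross-replicate Pearson correlation (mean pairwise R^2, computed
on log10 concentrations so no single abundant species dominates), equal
variances are checked per species with the classic mean-centered Levene test,
and group means are compared with a two-tailed pooled-variance Student t-test.
Fold changes are ratios of group means, reported as a positive magnitude with
an explicit increase/decrease direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CeramidePanel",
    "replicate_qc",
    "levene_test",
    "compare_species",
]

GROUPS = ("control", "treatment")


@dataclass
class CeramidePanel:
    """Lipid species x replicate concentrations with per-replicate QC status.

    ``concentrations`` has species as the index and replicate ids as columns;
    ``groups`` maps replicate id -> 'control'/'treatment'.  ``qc_status``
    maps replicate id -> (status, mean_r_squared) once QC has run; before QC
    every replicate is implicitly 'kept'.
    """

    concentrations: pd.DataFrame
    groups: Mapping[str, str]
    qc_status: dict[str, tuple[str, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.concentrations.index.has_duplicates:
            raise ValueError("duplicate species labels")
        if self.concentrations.columns.has_duplicates:
            raise ValueError("duplicate replicate ids")
        missing = [c for c in self.concentrations.columns if c not in self.groups]
        if missing:
            raise ValueError(f"replicates missing a group label: {missing}")
        bad = {g for g in self.groups.values()} - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        arr = self.concentrations.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("concentrations must be finite and strictly positive")

    @property
    def species(self) -> list[str]:
        return list(self.concentrations.index)

    def replicates_for(self, group: str, kept_only: bool = True) -> list[str]:
        out = []
        for rid in self.concentrations.columns:
            if self.groups[rid] != group:
                continue
            if kept_only and self.qc_status.get(rid, ("kept", None))[0] != "kept":
                continue
            out.append(rid)
        return out

    def kept_values(self, group: str) -> pd.DataFrame:
        return self.concentrations[self.replicates_for(group, kept_only=True)]


def _mean_pairwise_r2(log_conc: np.ndarray) -> np.ndarray:
    """Per-replicate mean of squared Pearson r against each other replicate."""
    n_rep = log_conc.shape[1]
    r = np.corrcoef(log_conc.T)
    r2 = r**2
    np.fill_diagonal(r2, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(r2, axis=1)


def replicate_qc(panel: CeramidePanel, r2_threshold: float = 0.9) -> CeramidePanel:
    """Screen replicates by cross-replicate correlation; exclude at most one per group.

    For each replicate, Pearson r against every other same-group replicate is
    computed across species (on log10 concentrations), squared, and averaged.
    The single worst replicate in a group is excluded if its mean R^2 falls
    below ``r2_threshold``; one exclusion per group per pass.  Excluded
    replicates stay in the panel with status ``excluded``.
    """
    status: dict[str, tuple[str, float | None]] = {}
    for group in GROUPS:
        rids = panel.replicates_for(group, kept_only=False)
        if not rids:
            continue
        if len(rids) < 3:
            raise ValueError(
                f"group {group!r} has {len(rids)} replicates; need >= 3 to screen"
            )
        log_conc = np.log10(panel.concentrations[rids].to_numpy(dtype=float))
        mean_r2 = _mean_pairwise_r2(log_conc)
        worst = int(np.argmin(mean_r2))
        for i, rid in enumerate(rids):
            status[rid] = ("kept", float(mean_r2[i]))
        if mean_r2[worst] < r2_threshold:
            if len(rids) - 1 < 2:
                raise ValueError(
                    f"excluding {rids[worst]!r} would leave fewer than 2 kept "
                    f"replicates in group {group!r}; nothing excluded"
                )
            status[rids[worst]] = ("excluded", float(mean_r2[worst]))
    return replace(panel, qc_status=status)


def levene_test(group_a, group_b) -> tuple[float, float]:
    """Classic mean-centered Levene test for equality of variances.

    W is the one-way ANOVA F statistic on absolute deviations from the group
    means, referred to F(1, n-2).  Degenerate inputs with zero within-group
    spread of the deviations return (0, 1) when the deviation means agree and
    (inf, 0) when they do not.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    within = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    if within <= 1e-300:
        return (0.0, 1.0) if np.isclose(za.mean(), zb.mean()) else (np.inf, 0.0)
    w, p = stats.levene(a, b, center="mean")
    return float(w), float(p)


@dataclass
class LipidStatsRow:
    species: str
    control_mean: float
    treatment_mean: float
    fold_change: float
    direction: str  # 'increase' or 'decrease' (treatment relative to control)
    levene_p: float
    t_p: float
    significant: bool


def compare_species(panel: CeramidePanel, alpha: float = 0.05) -> pd.DataFrame:
    """Per-species fold change and two-tailed mean comparison on kept replicates.

    The location test is Student's pooled-variance t-test, gated on the
    Levene equal-variance check (the workflow confirms equal variances
    first); when Levene rejects at ``alpha`` the test falls back to Welch
    with a logged warning.  Fold change is the ratio of the larger to the
    smaller group mean, with the direction reported separately.

    Returns a DataFrame with one row per species: species, control_mean,
    treatment_mean, fold_change, direction, levene_p, t_p, significant.
    """
    ctrl = panel.kept_values("control")
    trt = panel.kept_values("treatment")
    for label, df in (("control", ctrl), ("treatment", trt)):
        if df.shape[1] < 2:
            raise ValueError(f"group {label!r} has fewer than 2 kept replicates")
    rows: list[LipidStatsRow] = []
    for sp in panel.species:
        a = trt.loc[sp].to_numpy(dtype=float)
        c = ctrl.loc[sp].to_numpy(dtype=float)
        lev_w, lev_p = levene_test(a, c)
        if lev_p < alpha:
            warnings.warn(
                f"Levene rejects equal variances for {sp!r} (p={lev_p:.3g}); "
                "falling back to Welch t-test",
                RuntimeWarning,
                stacklevel=2,
            )
            _, t_p = stats.ttest_ind(a, c, equal_var=False)
        else:
            _, t_p = stats.ttest_ind(a, c, equal_var=True)
        if np.isnan(t_p):  # zero variance in both groups
            t_p = 1.0 if np.isclose(a.mean(), c.mean()) else 0.0
        mc, mt = float(c.mean()), float(a.mean())
        direction = "increase" if mt >= mc else "decrease"
        fold = max(mc, mt) / min(mc, mt)
        rows.append(
            LipidStatsRow(
                species=sp,
                control_mean=mc,
                treatment_mean=mt,
                fold_change=float(fold),
                direction=direction,
                levene_p=float(lev_p),
                t_p=float(t_p),
                significant=bool(t_p < alpha),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
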