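"""Persistence of exposure-induced expression changes after return to ground.

A gene counts as *maintained* at a return timepoint when it is called DE
there in the same direction as at exposure; a gene called DE in the opposite
direction is *conflicting* (tracked separately, not merged into *lost*).
Fractions are maintained counts over the exposure DEG set of the matching
direction, and the same bookkeeping is applied to designated gene subsets
(transcription factors, ncRNAs) when provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .diffexpr import DEGTable

__all__ = [
    "DirectionPersistence",
    "TimepointPersistence",
    "PersistenceReport",
    "compute_persistence",
    "ncrna_persistence",
]


@dataclass
class DirectionPersistence:
    """Fate of the exposure DEGs of one direction at one return timepoint."""

    exposure_ids: frozenset[str]
    maintained: frozenset[str]
    lost: frozenset[str]
    conflicting: frozenset[str]

    @property
    def fraction(self) -> float | None:
        """Maintained fraction; None when there were no exposure DEGs (n/a)."""
        if not self.exposure_ids:
            return None
        return len(self.maintained) / len(self.exposure_ids)


@dataclass
class TimepointPersistence:
    timepoint: str
    up: DirectionPersistence
    down: DirectionPersistence
    newly_de: frozenset[str]

    @property
    def overall_fraction(self) -> float | None:
        exposure = self.up.exposure_ids | self.down.exposure_ids
        if not exposure:
            return None
        maintained = self.up.maintained | self.down.maintained
        return len(maintained) / len(exposure)


@dataclass
class PersistenceReport:
    exposure_contrast: str
    timepoints: list[TimepointPersistence]
    subset_reports: dict[str, "PersistenceReport"] = field(default_factory=dict)

    def timepoint(self, label: str) -> TimepointPersistence:
        for tp in self.timepoints:
            if tp.timepoint == label:
                return tp
        raise KeyError(f"unknown timepoint {label!r}")

    def to_jsonable(self) -> dict:
        def frac(x: float | None):
            return None if x is None else round(x, 3)

        out = {
            "exposure_contrast": self.exposure_contrast,
            "timepoints": [
                {
                    "timepoint": tp.timepoint,
                    "maintained_up": sorted(tp.up.maintained),
                    "maintained_down": sorted(tp.down.maintained),
                    "lost_up": sorted(tp.up.lost),
                    "lost_down": sorted(tp.down.lost),
                    "conflicting_up": sorted(tp.up.conflicting),
                    "conflicting_down": sorted(tp.down.conflicting),
                    "newly_de": sorted(tp.newly_de),
                    "maintained_fraction_up": frac(tp.up.fraction),
                    "maintained_fraction_down": frac(tp.down.fraction),
                    "maintained_fraction_overall": frac(tp.overall_fraction),
                }
                for tp in self.timepoints
            ],
        }
        if self.subset_reports:
            out["subsets"] = {
                label: rep.to_jsonable() for label, rep in self.subset_reports.items()
            }
        return out


def _direction_fate(
    exposure_ids: set[str], same_dir: set[str], opposite_dir: set[str]
) -> DirectionPersistence:
    maintained = exposure_ids & same_dir
    conflicting = exposure_ids & opposite_dir
    lost = exposure_ids - maintained - conflicting
    return DirectionPersistence(
        exposure_ids=frozenset(exposure_ids),
        maintained=frozenset(maintained),
        lost=frozenset(lost),
        conflicting=frozenset(conflicting),
    )


def _build_report(
    exposure: DEGTable,
    returns: Sequence[DEGTable],
    restrict: set[str] | None,
) -> PersistenceReport:
    def limit(ids: set[str]) -> set[str]:
        return ids if restrict is None else ids & restrict

    exp_up = limit(exposure.up_ids)
    exp_down = limit(exposure.down_ids)
    tps = []
    for table in returns:
        up_t = limit(table.up_ids)
        down_t = limit(table.down_ids)
        tps.append(
            TimepointPersistence(
                timepoint=table.treatment,
                up=_direction_fate(exp_up, up_t, down_t),
                down=_direction_fate(exp_down, down_t, up_t),
                newly_de=frozenset((up_t | down_t) - (exp_up | exp_down)),
            )
        )
    return PersistenceReport(exposure_contrast=exposure.contrast, timepoints=tps)


def compute_persistence(
    exposure: DEGTable,
    returns: Sequence[DEGTable],
    subsets: Mapping[str, Iterable[str]] | None = None,
) -> PersistenceReport:
    """Classify every exposure DEG as maintained / lost / conflicting per timepoint.

    All tables must share one gene universe; ``returns`` are ordered by time.
    ``subsets`` restricts the same bookkeeping to designated gene sets and
    attaches the results as ``subset_reports``.
    """
    universe = exposure.gene_ids
    for table in returns:
        if table.gene_ids != universe:
            diff = sorted(table.gene_ids ^ universe)
            raise ValueError(
                f"gene universe of {table.contrast!r} differs from the exposure "
                f"table; symmetric difference starts with {diff[:10]}"
            )
    report = _build_report(exposure, returns, restrict=None)
    if subsets:
        for label, ids in subsets.items():
            report.subset_reports[label] = _build_report(
                exposure, returns, restrict=set(ids)
            )
    return report


def ncrna_persistence(
    expressed_sets: Mapping[str, set[str]],
    ground_control: str,
    exposed_conditions: Sequence[str],
) -> tuple[set[str], set[str], dict[str, int]]:
    """ncRNAs induced or silenced throughout exposure and every return.

    ``induced_throughout``: expressed in the exposure condition and every
    return but not in the ground control.  ``silenced_throughout``: expressed
    in the ground control but in none of exposure/returns.  Also returns the
    per-condition expressed counts.
    """
    if ground_control not in expressed_sets:
        raise KeyError(f"ground control {ground_control!r} missing from expressed sets")
    if len(exposed_conditions) < 1:
        raise ValueError("need at least one exposed condition")
    missing = [c for c in exposed_conditions if c not in expressed_sets]
    if missing:
        raise KeyError(f"conditions missing from expressed sets: {missing}")
    gc = expressed_sets[ground_control]
    exposed = [expressed_sets[c] for c in exposed_conditions]
    induced = set.intersection(*exposed) - gc
    silenced = gc - set.union(*exposed)
    counts = {c: len(expressed_sets[c]) for c in expressed_sets}
    return induced, silenced, counts
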