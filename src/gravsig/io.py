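"""Plain-text readers and writers for the pipeline's data currencies.

Formats: expression matrix TSV (first column gene id, remaining columns
sample ids) with a sidecar design TSV (sample, condition, replicate); DEG
table TSV; GMT gene sets; ceramide panel TSV with a leading group header
row; JSON reports.  Parse -> serialize -> parse is the identity for all of
them, and malformed input is reported with line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .diffexpr import DEGTable, ExpressionMatrix
from .lipidomics import CeramidePanel

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_deg_table",
    "write_deg_table",
    "read_gmt",
    "write_gmt",
    "read_ceramide_panel",
    "write_ceramide_panel",
    "write_json",
]


def _check_unique_first_column(path: Path, skip: int = 1) -> None:
    """Reject duplicate ids in a TSV's first column, naming both line numbers."""
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= skip or not line.strip():
                continue
            key = line.split("\t", 1)[0].strip()
            if key in seen:
                raise ValueError(
                    f"{path}: duplicate id {key!r} on lines {seen[key]} and {lineno}"
                )
            seen[key] = lineno


def write_expression_matrix(
    matrix: ExpressionMatrix, matrix_path: str | Path, design_path: str | Path
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    rows = [
        {"sample": s, "condition": c, "replicate": r}
        for s, (c, r) in matrix.design.items()
    ]
    pd.DataFrame(rows).to_csv(design_path, sep="\t", index=False)


def read_expression_matrix(
    matrix_path: str | Path, design_path: str | Path
) -> ExpressionMatrix:
    matrix_path = Path(matrix_path)
    _check_unique_first_column(matrix_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    design_df = pd.read_csv(design_path, sep="\t")
    required = {"sample", "condition", "replicate"}
    if not required <= set(design_df.columns):
        raise ValueError(
            f"{design_path}: design file needs columns {sorted(required)}"
        )
    design = {
        str(r["sample"]): (str(r["condition"]), int(r["replicate"]))
        for _, r in design_df.iterrows()
    }
    return ExpressionMatrix(values=values, design=design)


DEG_COLUMNS = ["gene_id", "log2fc", "p_raw", "p_adj", "call"]


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# contrast={table.treatment}\t{table.control}"
            f"\tfc_threshold={table.fc_threshold!r}\talpha={table.alpha!r}\n"
        )
        table.records[DEG_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_deg_table(path: str | Path) -> DEGTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("# contrast="):
        raise ValueError(f"{path}: line 1: missing '# contrast=' header")
    fields = header[2:].strip().split("\t")
    treatment = fields[0].split("=", 1)[1]
    control = fields[1]
    meta = dict(f.split("=", 1) for f in fields[2:])
    _check_unique_first_column(path, skip=2)
    rec = pd.read_csv(path, sep="\t", skiprows=1)
    missing = set(DEG_COLUMNS) - set(rec.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rec["gene_id"] = rec["gene_id"].astype(str)
    return DEGTable(
        treatment=treatment,
        control=control,
        records=rec,
        fc_threshold=float(meta.get("fc_threshold", 2.0)),
        alpha=float(meta.get("alpha", 0.05)),
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, tab-separated gene ids."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description, "
                    "and at least one gene id"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, ids in sets.items():
            fh.write("\t".join([name, description, *sorted(ids)]) + "\n")


def write_ceramide_panel(panel: CeramidePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        cols = list(panel.concentrations.columns)
        fh.write("\t".join(["group", *(panel.groups[c] for c in cols)]) + "\n")
        panel.concentrations.to_csv(fh, sep="\t", index_label="species")


def read_ceramide_panel(path: str | Path) -> CeramidePanel:
    path = Path(path)
    with open(path) as fh:
        group_line = fh.readline().rstrip("\n").split("\t")
    if not group_line or group_line[0] != "group":
        raise ValueError(f"{path}: line 1: expected a 'group' header row")
    _check_unique_first_column(path, skip=2)
    conc = pd.read_csv(path, sep="\t", skiprows=1, index_col=0)
    conc.index = conc.index.astype(str)
    conc.index.name = None
    if len(group_line) - 1 != conc.shape[1]:
        raise ValueError(
            f"{path}: line 1: {len(group_line) - 1} group labels for "
            f"{conc.shape[1]} replicate columns"
        )
    groups = {str(c): g for c, g in zip(conc.columns, group_line[1:])}
    return CeramidePanel(concentrations=conc, groups=groups)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
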