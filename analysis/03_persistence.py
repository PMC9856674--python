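#!/usr/bin/env python
"""Quantify how exposure-induced DEGs persist across the return timepoints.

Reads DEG tables from 02_differential_expression.py; writes persistence
reports (overall and for the TF panel) and prints the maintained percentages.
"""

import argparse
from pathlib import Path

from gravsig import io
from gravsig.persistence import compute_persistence


def pct(x):
    return "n/a" if x is None else f"{round(100 * x)}%"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/diffexpr"))
    ap.add_argument("--synthdir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--outdir", type=Path, default=Path("results/persistence"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    exposure = io.read_deg_table(args.indir / "degs_MG_vs_GC.tsv")
    returns = [
        io.read_deg_table(args.indir / f"degs_{c}_vs_GC.tsv")
        for c in ("R1_GC", "R2_GC", "R3_GC")
    ]
    report = compute_persistence(exposure, returns)
    io.write_json(report.to_jsonable(), args.outdir / "persistence.json")
    print("main run (exposure DEGs:", len(exposure.de_ids), "):")
    for tp in report.timepoints:
        print(f"  {tp.timepoint}: overall {pct(tp.overall_fraction)}, "
              f"up {pct(tp.up.fraction)}, down {pct(tp.down.fraction)}")

    tf_exposure = io.read_deg_table(args.indir / "tf_degs_MG_vs_GC.tsv")
    tf_returns = [
        io.read_deg_table(args.indir / f"tf_degs_{c}_vs_GC.tsv")
        for c in ("R1_GC", "R2_GC", "R3_GC")
    ]
    subsets = io.read_gmt(args.synthdir / "tf_panel.gmt")
    tf_report = compute_persistence(tf_exposure, tf_returns, subsets=subsets)
    io.write_json(tf_report.to_jsonable(), args.outdir / "tf_persistence.json")
    print("TF panel maintained-up:")
    for tp in tf_report.subset_reports["tf_panel"].timepoints:
        print(f"  {tp.timepoint}: {pct(tp.up.fraction)}")


if __name__ == "__main__":
    main()
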