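#!/usr/bin/env python
"""Ceramide panel analysis: replicate QC, then per-species statistics.

Reads the synthetic panel, screens replicates by cross-replicate correlation,
runs Levene-gated pooled t-tests per species, and writes the statistics table.
"""

import argparse
import warnings
from pathlib import Path

from gravsig import io
from gravsig.lipidomics import compare_species, replicate_qc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--outdir", type=Path, default=Path("results/lipidomics"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    panel = io.read_ceramide_panel(args.indir / "ceramide_panel.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screened = replicate_qc(panel)
        stats = compare_species(screened)
    io.write_json(
        {r: {"status": s, "mean_r2": round(v, 3)}
         for r, (s, v) in screened.qc_status.items()},
        args.outdir / "qc_report.json",
    )
    stats.to_csv(args.outdir / "lipid_stats.tsv", sep="\t", index=False)

    excluded = [r for r, (s, _) in screened.qc_status.items() if s == "excluded"]
    print(f"QC: excluded {excluded or 'none'} "
          f"(mean R^2 {[round(screened.qc_status[r][1], 2) for r in excluded]})")
    sig = stats[stats["significant"]]
    print(f"{len(sig)} of {len(stats)} species significant at alpha=0.05:")
    for r in sig.itertuples():
        print(f"  {r.species}: {r.fold_change:.2f}-fold {r.direction} "
              f"(t p={r.t_p:.3g}, Levene p={r.levene_p:.2f})")


if __name__ == "__main__":
    main()
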