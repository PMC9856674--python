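#!/usr/bin/env python
"""Build the cross-study microgravity-responsive signature.

Reads the two synthetic study DEG tables, intersects them, tests the overlap
against a 20000-gene universe, removes sign conflicts, and writes the
signature gene list.
"""

import argparse
from pathlib import Path

from gravsig import io
from gravsig.signature import build_signature

UNIVERSE_SIZE = 20000


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--outdir", type=Path, default=Path("results/signature"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    a = io.read_deg_table(args.indir / "overlap_study_a.tsv")
    b = io.read_deg_table(args.indir / "overlap_study_b.tsv")
    result = build_signature(a, b, universe_size=UNIVERSE_SIZE)
    io.write_json(result.to_jsonable(), args.outdir / "signature.json")
    (args.outdir / "signature_genes.txt").write_text(
        "\n".join(sorted(result.signature_ids)) + "\n"
    )
    t = result.overlap_test
    print(f"common DEGs: {len(result.common_ids)}")
    print(f"sign-conflicting (discarded): {len(result.conflicting_ids)}")
    print(f"signature genes: {len(result.signature_ids)}")
    print(f"overlap test: k={t.overlap} of K={t.set_a_size} x n={t.draw_size} "
          f"in N={t.universe_size}; upper-tail p = {t.p_value:.3g}")


if __name__ == "__main__":
    main()
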