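#!/usr/bin/env python
"""Optional driver for re-analysing the published cassava trials.

The original field files and genomic relationship matrix are distributed
separately (the manuscripts section of the CassavaBase FTP archive) and are
not bundled here.  After downloading them, point this script at
one trial's field CSV (columns ``clone``, ``Range``, ``Column`` and the
trait columns DM/FYLD/SHTWT/HI) and the kinship CSV; it runs the full
cross-validated model selection for each requested trait and writes one
output bundle per trait.

Example:
    python scripts/replicate_real_data.py field.csv kinship.csv out/ \
        --traits DM FYLD --plot-width 1 --plot-length 4
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from interplot.pipeline import RunConfig, run_pipeline


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("field_csv", type=Path)
    parser.add_argument("kinship_csv", type=Path)
    parser.add_argument("outdir", type=Path)
    parser.add_argument("--traits", nargs="+", required=True)
    parser.add_argument("--plot-width", type=float, default=1.0)
    parser.add_argument("--plot-length", type=float, default=4.0)
    parser.add_argument("--long-edge", choices=("ranges", "columns"), default="ranges")
    parser.add_argument("--folds", type=int, default=10)
    parser.add_argument("--repeats", type=int, default=5)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    for path in (args.field_csv, args.kinship_csv):
        if not path.exists():
            print(f"error: {path} not found (download the published datasets first)",
                  file=sys.stderr)
            return 2
    for trait in args.traits:
        config = RunConfig(
            field_csv=str(args.field_csv),
            trait=trait,
            kinship_csv=str(args.kinship_csv),
            outdir=str(args.outdir / trait),
            plot_width=args.plot_width,
            plot_length=args.plot_length,
            long_edge=args.long_edge,
            folds=args.folds,
            repeats=args.repeats,
            seed=args.seed,
        )
        paths = run_pipeline(config)
        print(f"{trait}: selection report at {paths['selection_report']}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
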