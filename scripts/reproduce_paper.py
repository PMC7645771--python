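#!/usr/bin/env python
"""Re-run the full published analysis protocol on an exported cohort.

Given a data directory in the package's CSV dialects (``metadata.csv`` plus
``scans/<sample>_r<rep>_<polarity>.csv``; convert an instrument export with
``faimsvoc.io.write_scan`` / ``write_metadata`` first), this script runs the
complete protocol - replicate 2, background threshold, tenfold CV with
in-fold rank-sum selection, all four classifier families at k in
{100, 50, 20} - for the eleven clinical comparisons, and prints the best
pooled AUC per comparison next to the value published for this study
design.  Because fold seeds and classifier hyperparameters were not part of
the published record, agreement is expected only within stochastic
tolerance (about +/-0.10 in AUC).

Usage:
    python scripts/reproduce_paper.py --data <cohort_dir> [--out table.csv]
        [--families f1,f2] [--ks 100,50,20] [--n-folds 10] [--seed 0]
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import pandas as pd

from faimsvoc.crossval import CLASSIFIER_FAMILIES
from faimsvoc.pipeline import RunConfig, analyze, load_cohort, sample_vectors

# best-model AUC per comparison as published for this study design
PUBLISHED_AUC = {
    "mortality_vs_survival": 0.71,
    "early_mortality_vs_survival": 0.73,
    "late_mortality_vs_survival": 0.82,
    "early_vs_late_mortality": 0.80,
    "sam_vs_healthy_controls": 0.99,
    "waz_le_minus3": 0.70,
    "oedema_vs_no_oedema": 0.71,
    "diarrhoea_vs_no_diarrhoea": 0.66,
    "pneumonia_vs_no_pneumonia": 0.63,
    "hiv_pos_vs_neg": 0.73,
    "age_le_2y_vs_gt_2y": 0.79,
}


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--data", required=True, help="cohort directory")
    ap.add_argument("--out", default=None, help="write the table as CSV")
    ap.add_argument("--families", default=",".join(CLASSIFIER_FAMILIES))
    ap.add_argument("--ks", default="100,50,20")
    ap.add_argument("--n-folds", type=int, default=10)
    ap.add_argument("--replicate", type=int, default=2)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args(argv)

    samples, metadata = load_cohort(args.data, replicate=args.replicate)
    vectors = sample_vectors(samples)
    cfg = RunConfig(
        families=tuple(args.families.split(",")),
        ks=tuple(int(k) for k in args.ks.split(",")),
        n_folds=args.n_folds,
        n_boot=200,
        n_perm=1000,
        seed=args.seed,
    )
    out = analyze(vectors, metadata, cfg)

    rows = []
    for rep in out.reports:
        if not rep.best:
            continue
        pub = PUBLISHED_AUC.get(rep.comparison_id)
        rows.append(
            {
                "comparison": rep.comparison_id,
                "best_family": rep.family,
                "k": rep.k,
                "auc": round(rep.auc, 3),
                "published_auc": pub,
                "delta": None if pub is None else round(rep.auc - pub, 3),
            }
        )
    table = pd.DataFrame(rows)
    print(table.to_string(index=False))
    for entry in out.log:
        print(f"# {entry}", file=sys.stderr)
    if args.out:
        table.to_csv(args.out, index=False)
    deltas = table["delta"].dropna()
    if len(deltas):
        print(f"\nmax |delta| vs published: {deltas.abs().max():.3f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
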