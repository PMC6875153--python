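"""Optional: refit the archived 10x10x10 study grids at the full optimizer
budget.

The deposited sector data for the seven post-mortem specimens lives in a
figshare share (https://figshare.com/s/aee5a09da245058504a9) whose internal
file layout is not documented; this script therefore expects the data to
have been downloaded and converted by hand into the package's canonical CSV
sector-table schema (specimen,marker,i,j,k,x1,x2,x3,y,included).  It then
runs outlier exclusion and the full four-model comparison (differential
evolution, population 20x the parameter count, up to 5000 generations) per
(specimen, marker) — roughly 84 x 4 fits, hours of CPU — and writes the
preference table plus the exclusion fraction.

Not run by the test suite: it needs a network download and a full-budget
optimization run.

Usage:
    python scripts/refit_deposit.py --table deposit_sectors.csv --out results/
"""

import argparse
import json
from pathlib import Path

import numpy as np

from stngrad import FitOptions, compare_models, exclude_outliers, read_sector_table
from stngrad.fitting import build_preference_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--table", required=True,
                    help="deposited grids converted to the canonical CSV schema")
    ap.add_argument("--out", default="deposit_results")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--de-iters", type=int, default=5000)
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    grids = read_sector_table(args.table)
    n_total = sum(len(g.records) for g in grids)
    grids = [exclude_outliers(g) for g in grids]
    n_excl = n_total - sum(g.n_included for g in grids)

    opts = FitOptions(maxiter=args.de_iters)
    ss = np.random.SeedSequence(args.seed)
    results = []
    for g, sub in zip(grids, ss.spawn(len(grids))):
        print(f"fitting {g.specimen_id}/{g.marker} ...", flush=True)
        results.append(compare_models(
            g, seed=int(sub.generate_state(1)[0] % 2 ** 31), options=opts))
    table = build_preference_table(results)
    table.rows.to_csv(out / "preferences.csv", index=False)
    (out / "summary.json").write_text(json.dumps({
        "n_sectors": n_total,
        "n_excluded": n_excl,
        "excluded_pct": 100.0 * n_excl / n_total,
    }, indent=1))
    print(f"excluded {n_excl}/{n_total} sectors "
          f"({100.0 * n_excl / n_total:.3f}%)")


if __name__ == "__main__":
    main()
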