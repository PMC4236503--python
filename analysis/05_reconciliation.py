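"""The full-vs-pruned divergence-time reconciliation experiment.

For each of 20 seeds: simulate a fast (mito-like) and a slow (nuclear-like)
dataset on a shared 44-taxon, 390 Ma chronogram; screen and prune saturated
partitions; estimate branch lengths under a deliberately underparameterized
model (HKY, no rate heterogeneity); date the tree by a least-squares strict
clock with the root fixed; and compare node-age RMSE against the known true
ages.  Finding: pruning lowers the saturated dataset's RMSE in the large
majority of seeds (median improvement tens of Ma), while the slow dataset
is nearly unaffected — the synthetic analogue of the mitochondrial/nuclear
age reconciliation.

Runtime: ~10 minutes single-threaded at the default 20 seeds.  Pass a
comma-separated seed list as the first argument to run fewer.
"""

import json
import sys
from pathlib import Path

from saturascreen.experiment import (DEFAULT_SEEDS, run_reconciliation,
                                     summarize_reconciliation)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)


def main():
    seeds = ([int(s) for s in sys.argv[1].split(",")]
             if len(sys.argv) > 1 else DEFAULT_SEEDS)
    df = run_reconciliation(seeds, progress=True)
    summary = summarize_reconciliation(df)
    df.to_csv(RESULTS / "reconciliation.csv", index=False)
    with open(RESULTS / "reconciliation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))
    print(f"wrote {RESULTS / 'reconciliation.csv'} and summary")


if __name__ == "__main__":
    main()
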