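#!/usr/bin/env python
"""Cluster the treatments by their standardised property profiles.

Reads results/quality_metrics.csv, builds the "physical" and "overall"
feature sets, clusters with Ward linkage on z-scored features, writes one
Newick dendrogram per feature set plus the flat two-way cluster assignment
from a cut at half the root height, and reports which treatments cluster
together.
"""

from pathlib import Path

import pandas as pd

from rehydkin.pipeline import DEFAULT_FEATURE_SETS, cluster_quality

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    quality = pd.read_csv(OUT / "quality_metrics.csv")
    newicks, assignments = cluster_quality(
        quality, DEFAULT_FEATURE_SETS, linkage="ward", distance="euclidean",
        cut_fraction=0.5,
    )
    for name, nwk in newicks.items():
        (OUT / f"dendrogram_{name}.nwk").write_text(nwk + "\n", encoding="utf-8")
        print(f"wrote dendrogram_{name}.nwk")
    assignments.to_csv(OUT / "cluster_assignments.csv", index=False)
    for name in newicks:
        sub = assignments[assignments.feature_set == name]
        print(f"\n{name} feature set, cut at 50% of root height:")
        for cid, grp in sub.groupby("cluster"):
            print(f"  cluster {cid}: {', '.join(sorted(grp.treatment))}")


if __name__ == "__main__":
    main()
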