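#!/usr/bin/env python
"""Cluster the bacterial community fingerprints.

For each enzyme: normalize profiles, drop peaks under 0.3% of the profile
total, bin into 2-bp bins in four frames offset by 0.5 bp, take the
max-over-frames Whittaker similarity, cluster by group average (UPGMA),
and set the significance threshold from 50 Monte Carlo replicates of the
duplicate-run noise model (+/-46 rfu at 18,000 rfu; +/-0.08 bp).  Nodes
merging at or above the worst replicate similarity are not distinguishable
from replicate error.
"""

import json
from pathlib import Path

import chemocline as cc

SEED = 1
BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    peaks = BASE / "synthetic" / "peak_table.tsv"
    if not peaks.exists():
        raise SystemExit("run analysis/01_simulate_dataset.py first")
    profiles = cc.read_peak_table(peaks)
    enzymes = sorted({p.enzyme for p in profiles})
    report = {}
    for enzyme in enzymes:
        enz_profiles = [p for p in profiles if p.enzyme == enzyme]
        result = cc.monte_carlo_significance(
            enz_profiles, cc.NoiseModel(), n_replicates=50, seed=SEED
        )
        result.resemblance.to_frame().to_csv(
            BASE / f"resemblance_{enzyme}.tsv", sep="\t", float_format="%.4f"
        )
        (BASE / f"dendrogram_{enzyme}.nwk").write_text(result.dendrogram.to_newick() + "\n")
        n_ns = sum(1 for n in result.dendrogram.nodes if n.significant is False)
        report[enzyme] = {
            "n_samples": len(enz_profiles),
            "mc_threshold_pct": result.threshold,
            "replicate_similarity_mean_pct": float(result.replicate_similarities.mean()),
            "nodes_within_replicate_error": n_ns,
        }
        print(
            f"{enzyme}: {len(enz_profiles)} samples; replicate-similarity floor "
            f"{result.threshold:.1f}% (mean {result.replicate_similarities.mean():.1f}%); "
            f"{n_ns} of {len(result.dendrogram.nodes)} nodes within replicate error"
        )
    with open(BASE / "fingerprint_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"wrote resemblance matrices, newick dendrograms and {BASE/'fingerprint_report.json'}")


if __name__ == "__main__":
    main()
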