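#!/usr/bin/env python
"""Predict terminal restriction fragment lengths for the phylotype set.

Runs the in-silico digest over the synthetic phylotype stand-ins (clone
sequences beginning at the priming site; HaeIII, Hpy188I, MspI, MnlI) and
compares against the expected integer fragment lengths that were planted
into the stand-ins from the published per-phylotype signature table.
"""

from pathlib import Path

import pandas as pd

import chemocline as cc

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fasta = BASE / "synthetic" / "synthetic_phylotypes.fasta"
    expected_path = BASE / "synthetic" / "synthetic_phylotypes_expected.tsv"
    if not fasta.exists():
        raise SystemExit("run analysis/01_simulate_dataset.py first")
    table = cc.digest_table(fasta)
    expected = pd.read_csv(expected_path, sep="\t")
    merged = table.drop(columns=["primer_set", "accession"]).merge(
        expected, on=["phylotype", "enzyme"], suffixes=("_pred", "_exp")
    )
    merged["match"] = merged["fragment_bp_pred"].astype(str) == merged["fragment_bp_exp"].astype(str)
    out = BASE / "digest_predictions.tsv"
    merged.to_csv(out, sep="\t", index=False)

    n_cut = (merged["fragment_bp_exp"] != "uncut").sum()
    print(f"{len(merged)} phylotype x enzyme predictions ({n_cut} with a planted site)")
    print(f"concordance with expected table: {merged['match'].mean():.0%}")
    wide = merged.pivot(index="phylotype", columns="enzyme", values="fragment_bp_pred")
    print(wide.to_string())
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
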