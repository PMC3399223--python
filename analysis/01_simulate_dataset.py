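#!/usr/bin/env python
"""Generate the synthetic study dataset.

Emulates the field design: five stations (three central-gyre style, two
mixing-zone style) sampled across the oxycline with three restriction
enzymes at 18,000 rfu total peak height and duplicate-run noise; Black
Sea-like chemical profiles for both scenarios; and 15NO3- incubations at
four densities spanning the sulfide onset.  Everything downstream
(analysis/02-05) reads from results/synthetic/.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

import chemocline as cc

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = cc.default_community_spec(seed=SEED)
    sim = cc.simulate_community(spec, cc.NoiseModel())
    all_profiles = [p for profs in sim.profiles.values() for p in profs]
    cc.write_peak_table(all_profiles, OUT / "peak_table.tsv")
    sim.truth_abundance.to_csv(OUT / "truth_abundance.tsv", sep="\t", float_format="%.5f")
    pd.Series(sim.group_labels, name="group").rename_axis("sample_id").to_csv(
        OUT / "group_labels.tsv", sep="\t"
    )
    n_samples = len(sim.profiles["MspI"])
    print(
        f"community: {len(spec.stations)} stations x {len(spec.depths)} depths "
        f"= {n_samples} samples, enzymes {spec.enzymes}, "
        f"{len(spec.otus)} OTUs, total height {spec.total_height:g} rfu"
    )

    for scenario in ("central_gyre", "mixing_zone"):
        prof = cc.simulate_env_profiles(scenario, seed=SEED)
        prof.samples.to_csv(OUT / f"env_{scenario}.tsv", sep="\t", index=False)
        print(f"chemistry [{scenario}]: {len(prof.samples)} levels, analytes {prof.analytes}")

    # incubations: non-sulfidic control depth plus three sulfidic depths,
    # rates increasing with depth as in the incubation experiments
    rows = []
    for rate, sigma, depth in [(0.0, 16.26, 178.0), (4.0, 16.4, 192.0),
                               (10.0, 16.46, 197.0), (78.0, 16.52, 212.0)]:
        inc = cc.simulate_incubation(
            rate, label_fraction=0.9, duration=2.0, noise_sd=0.5,
            seed=SEED + int(sigma * 100), sigma_theta=sigma, depth_m=depth,
        )
        rows.append(vars(inc) | {"true_rate_nM_N_day": rate})
    pd.DataFrame(rows).to_csv(OUT / "incubations.tsv", sep="\t", index=False)
    print(f"incubations: {len(rows)} endpoints (true rates 0-78 nM N/day)")

    records, expected = cc.standin_phylotypes(seed=SEED)
    SeqIO.write(records, OUT / "synthetic_phylotypes.fasta", "fasta")
    expected.to_csv(OUT / "synthetic_phylotypes_expected.tsv", sep="\t", index=False)
    print(f"phylotype stand-ins: {len(records)} sequences with planted restriction sites")
    print(f"wrote dataset to {OUT}")


if __name__ == "__main__":
    main()
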