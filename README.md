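# chemocline

Community fingerprinting and geochemistry across a stratified marine
chemocline.

In permanently stratified basins like the Black Sea, the transition from
oxic surface water through the suboxic zone into sulfidic deep water
structures the microbial community, and lateral intrusions of oxygenated
water can bring nitrate and sulfide close enough together to fuel
autotrophic denitrification. This package implements the computational
side of that kind of study for researchers working with TRFLP community
fingerprints and depth-resolved chemistry:

* **TRFLP profile processing** — normalization by total peak height,
  removal of peaks under 0.3% of the profile total, and frame-shifted
  binning (2-bp bins in four frames offset by 0.5 bp) so sub-bp
  electrophoresis drift cannot split one fragment across a bin edge in
  every frame at once.
* **Resemblance and clustering** — the Whittaker index of association
  `S = 100 (1 − ½ Σᵢ |pᵢ − qᵢ|)` on relative abundances (identically
  `100 (1 − Bray–Curtis)`), taking the maximum similarity over the four
  frames; group-average (UPGMA) clustering on `100 − S`; and a Monte
  Carlo significance threshold from replicate-run noise (heights ±46 rfu
  at 18,000 rfu total, sizes ±0.08 bp): cluster nodes merging at or above
  the worst original-vs-perturbed replicate similarity cannot be called
  different.
* **Community–environment statistics** — ANOSIM
  `R = (r̄_between − r̄_within)/(M/2)` with permutation p-values, global
  and pairwise; BEST/BIOENV selection of the environmental-variable
  subset whose z-scored Euclidean distances best Spearman-correlate with
  the community dissimilarities; single-fragment depth profiles with
  multi-enzyme concordance checks (heights of *different* fragments are
  never compared — PCR bias differs per template).
* **In-silico digest** — predicted lengths of the 5′-labeled terminal
  restriction fragment from a sequence, primer pair and enzyme (HaeIII,
  Hpy188I, MspI, MnlI registry built in, user-overridable), with IUPAC
  degenerate matching and the first-cut rule.
* **Geochemistry** — piecewise-linear profile interpolation on depth or
  potential density (σθ), Fick's-law diffusive fluxes
  `F = K |ΔC/Δz| · 86 400` (µmol m⁻² day⁻¹), detection of density
  intervals where NOx⁻ and sulfide overlap (or nearly overlap within
  detection limits), and conversion of ¹⁵NO₃⁻-incubation δ³⁰N₂ / δ²⁹N₂
  enrichments into N₂ production rates (nM N day⁻¹), with the ²⁹N₂
  (anammox-type) signal always flagged as ambiguous.
* **Synthetic data** — generators for sequences with planted restriction
  sites, depth-structured multi-enzyme communities with planted oxygen-
  regime groups, Black Sea-like chemical profiles (central-gyre and
  mixing-zone intrusion scenarios), and isotope incubations; each returns
  its ground truth so every pipeline stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate_dataset.py
python analysis/02_digest_predictions.py
python analysis/03_fingerprint_clustering.py
python analysis/04_community_stats.py
python analysis/05_geochem_rates.py
```

`04_community_stats.py` prints:

```
ANOSIM (oxygen regime, MspI): R = 0.987, p = 0.001
  pairwise <4 uM O2 vs >4 uM O2: R = 1.000, p = 0.001
  pairwise <4 uM O2 vs sulfidic: R = 0.938, p = 0.001
  pairwise >4 uM O2 vs sulfidic: R = 1.000, p = 0.001
BEST: 63 subsets; best ('NO3', 'NH4') rho = 0.822
sulfur-oxidizer fragment HaeIII/MnlI: rho = 0.932 (supported)
```

meaning the oxygen regime planted into the synthetic community (>4 µM O₂
/ <4 µM O₂ / sulfidic) is recovered almost perfectly by the rank-based
test (R near 1 means all between-group dissimilarities outrank the
within-group ones; p = 0.001 is the floor of a 999-permutation test), 63
= 2⁶ − 1 environmental subsets were screened, and the sulfur-oxidizer
OTU's depth profile is corroborated across restriction enzymes.
`05_geochem_rates.py` converts the incubation endpoints back to rates:

```
mixing_zone: NOx and sulfide overlap at sigma 16.40-16.47
sigma 16.4:  excess d30N2 = 483 per mil -> 4.0 nM N/day (true 4); ...
sigma 16.52: excess d30N2 = 9418 per mil -> 78.0 nM N/day (true 78); ...
```

recovering the simulated denitrification rates exactly, inside the
density interval where nitrate and sulfide co-occur.

A `chemocline` console script exposes the same pipeline as subcommands
(`simulate`, `digest`, `fingerprint`, `geochem`), each writing a run
manifest so identical configs reproduce identical outputs.

## Layout

```
src/chemocline/     library: digest, profiles, similarity, stats, geochem, synth, cli
analysis/           numbered narrative drivers writing to results/
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     models, parameters, numerical choices, limitations
```
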