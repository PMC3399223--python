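# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic-data generators, and the numerical
and design choices made where the design was genuinely open. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## TRFLP profile model

A profile is the set of (fragment length in bp, peak height in rfu) pairs
one restriction enzyme produced for one sample. Fragment lengths are kept
fractional — they come from electrophoresis calibration, not sequence —
and are never rounded before binning.

**Normalization and filtering.** Heights are divided by the profile
total; peaks below a threshold fraction of that same profile's total
(default 0.003, i.e. 0.3%) are removed and the survivors re-normalized.
Because the threshold is relative to the profile's own total, filtering
raw heights and filtering normalized heights are algebraically identical
(tested as a property). Filtering is applied before binning.

**Frame-shifted binning.** Peaks are binned into half-open bins
`[offset + k·w, offset + (k+1)·w)` with width `w = 2.0` bp in four frames
offset by 0, 0.5, 1.0 and 1.5 bp. The width is the number of frames times
the frame interval, the value consistent with each frame tiling the axis;
both width and offsets are configurable. A peak exactly on a boundary
goes to the upper bin. Mass is conserved per sample in every frame.

**Resemblance.** For two relative-abundance vectors on a common bin axis
the Whittaker index of association is `S = 100 (1 − ½ Σ|pᵢ − qᵢ|)`
percent, identical to `100 (1 − Bray–Curtis)` on relativized data (tested
against `scipy.spatial.distance.braycurtis`). Each sample pair's
similarity is the maximum over the four frames, which absorbs sub-bp
sizing drift: two labs' 100.9 and 101.1 bp calls split across a bin edge
in some frames but share a bin in at least one.

**Clustering.** Group-average (UPGMA) agglomeration on dissimilarity
`100 − S`. Ties are broken toward the cluster pair containing the
smallest leaf indices, making the merge order deterministic. Node heights
are recorded as merge similarities; the newick export uses ultrametric
branch lengths (`(100 − S)/2`) and carries significance flags as node
comments. The implementation is cross-checked against
`scipy.cluster.hierarchy.linkage(method="average")` and a brute-force
oracle that explores every tie-compatible merge order on ≤6 leaves.

**Monte Carlo significance.** The duplicate-run noise model has three
parameters: height sd at a reference total (default ±46 rfu at 18,000
rfu; the height sd scales proportionally with the profile total), and a
fragment-size sd (default ±0.08 bp). A Planctomycetes-run variant (±83
rfu at 15,000 rfu, ±0.06 bp) ships as `PLANCTOMYCETES_NOISE`. For each of
`n_replicates` draws (default 50) every profile is perturbed once and the
similarity of each original to its own perturbed replicate is computed
through the full filter → bin → max-over-frames pipeline. The
significance threshold defaults to the minimum replicate similarity (a
percentile option is provided); dendrogram nodes merging at or above it
are flagged as not significantly different. The original-vs-perturbed
("self-replicate") definition was chosen because the noise model is an
estimate of replicate reproducibility; a perturbed-vs-perturbed variant
would conflate two draws of the same error. Zero noise gives a threshold
of exactly 100%; the threshold is stochastically non-increasing in the
noise sd (tested over paired seeds).

## Community–environment statistics

**ANOSIM.** Dissimilarities `100 − S` are ranked with average ranks for
ties; `R = (r̄_between − r̄_within)/(M/2)` with `M = n(n−1)/2`, so
`R ∈ [−1, 1]` and is invariant to monotone transformation of the
dissimilarities. p-values permute the group labels with the +1
correction; the default 999 permutations put the attainable floor at
p = 0.001. Pairwise tests restrict the matrix to each pair of categories.
Cross-checked against scikit-bio's `anosim` on random matrices.

**BEST / BIOENV.** Every variable is z-scored (population sd), so
results are invariant to affine rescaling of any variable; zero-variance
variables are excluded with a warning. For each of the `2ᵏ − 1` non-empty
subsets (guard at k ≤ 15), Euclidean distances between samples are
Spearman-correlated with the community dissimilarities over the unfolded
upper triangles, and subsets are ranked by rho. Whether the original
procedure z-scored and used Euclidean distance is an inference — it is
the standard BIOENV construction — and is stated here as this package's
definition.

**Single-fragment statistics.** `otu_depth_profile` sums the normalized
height of peaks within ±tolerance of a target length per sample; heights
of different fragments are never compared to each other, since PCR bias
differs per template. Cross-enzyme concordance Spearman-correlates two
enzymes' depth profiles over shared samples (≥3 required) and calls the
OTU "supported" above a configurable rho threshold (default 0.7); an
all-zero vector leaves rho undefined and the pair unsupported.
`abundance_env_correlation` defaults to rank correlation (the linear
option is provided because the original choice is not documented), with
an exact-permutation p-value available at n ≤ 8 — at n = 5 a perfect
monotone association has p = 2/120.

## In-silico terminal fragment prediction

The labeled fragment runs from the 5′ (fluorophore-carrying) base of the
forward primer to the first top-strand cut. The built-in registry holds
standard recognition/cut data — HaeIII GG^CC (offset 2), MspI C^CGG
(offset 1), MnlI CCTC with the top-strand cut 7 nt past the motif end
(offset 11), Hpy188I TCN^GA (offset 3) — as data, user-overridable.
Fragment length counts from the first primer base inclusive, matching
how labeled fragments are detected; the anchor can instead be the
sequence start for clone sequences that begin at the priming site.
Degenerate codes match as base sets (intersection non-empty), the
permissive convention of digest tools. Only the forward strand's labeled
fragment is reported; the reverse primer bounds the amplicon, and a site
at or past it leaves the prediction "uncut".

*Limitation:* recognition is restricted to top-strand-oriented motifs.
A real digest with a non-palindromic enzyme (MnlI here) also cuts at
reverse-orientation sites; users who need that behavior can register the
reverse-complement motif with its own offset as an additional enzyme.
Published fractional fragment lengths are electrophoresis-calibrated
observations and are out of scope for sequence-based prediction.

## Geochemistry

**Interpolation and fluxes.** Profiles carry both depth (m) and
potential density σθ; chemistry aligns on density in stratified basins,
so σθ is the default ordinate for alignment and reporting, while
gradients and fluxes are computed on depth because flux units are per
metre. Interpolation is piecewise linear and refuses to extrapolate.
Fick's-law flux is `F = K |ΔC/Δz| · 86 400` in µmol m⁻² day⁻¹ with ΔC
converted from µM to µmol m⁻³; the turbulent diffusivity K (m² s⁻¹) is
user-supplied per density layer, since appropriate values are
basin-specific. Flux direction follows the gradient sign (toward
decreasing concentration).

**NOx/sulfide overlap.** Both profiles are interpolated onto a common σθ
grid (default step 0.005). Overlap intervals are where any NOx species
and sulfide are simultaneously above their detection limits (defaults:
H₂S 3, NO₃⁻ 0.05, NO₂⁻ 0.02, O₂ 1, NH₄⁺ 0.1 µM). When there is no
overlap, the gap between the deepest NOx detection and the shallowest
sulfide detection is reported, and a "possible overlap" flag is set when
that gap is narrower than a configurable width (default 0.15 σθ units) —
below-detection concentrations could then co-occur.

**Incubation rates.** Adding ¹⁵NO₃⁻ to an anoxic sample lets
denitrification of the labeled pool produce ³⁰N₂ while anammox-type
pairing with unlabeled N produces ²⁹N₂. Per-mil excesses over killed
controls convert to concentrations via the natural isotopologue ratios
of the background N₂ pool: with atom fraction x = 0.003663 (air
standard, overridable), R₃₀ = x² and R₂₉ = 2x(1−x)/(1−x)². R₃₀ is
defined on the atom-fraction square rather than the strict ³⁰/²⁸ ratio
(x/(1−x))²; the two differ by 0.7%, far below isotope-ratio measurement
precision, and the simpler form is kept as the package's convention.
Then `excess [³⁰N₂] = (excess δ³⁰N₂ / 1000) · R₃₀ · [N₂]` and the rate
counts N atoms: `rate = 2 · excess [³⁰N₂] / duration` in nM N day⁻¹.
The background [N₂] is a required constant the user controls (default
500 µM, a typical deep-basin value). In `pairing_corrected` mode the
³⁰N₂ rate is divided by F² and the ²⁹N₂ rate by F, where F is the
labeled fraction of the NO₃⁻ pool after spiking, assuming random isotope
pairing. Raw mode reports labeled-pair production as-is. Negative
excesses are floored at zero with a warning rather than modeled — there
is no isotopologue-consumption model. The ²⁹N₂ signal always carries an
ambiguity flag: it can equally come from denitrification of small
amounts of unlabeled NOx⁻. A full 29/30 isotope-pairing solve is out of
scope.

## Synthetic data

The generators define the study conditions and return their ground
truth, so every analysis stage has an exact round-trip test.

* **Sequences.** Random ACGT backgrounds with recognition motifs planted
  at fixed positions; accidental occurrences of any registry motif are
  scrubbed from the background, so the truth table (first motif position
  plus top-strand offset, by direct string scan) is exact. Overlapping
  planted motifs that disagree raise an error. The phylotype stand-ins
  (`standin_phylotypes`) are built this way: synthetic sequences, one per
  phylotype, with sites planted so the digest must reproduce the
  published integer fragment lengths. They are stand-ins, not the real
  GenBank records; fractional/ambiguous table cells get no planted site
  and predict "uncut".
* **Communities.** Each OTU has a Gaussian (or boxcar) abundance response
  over σθ with optional per-station multipliers; the same relative
  abundances drive every enzyme's profile (cross-enzyme concordance holds
  by construction), and pre-noise heights sum exactly to the total
  (default 18,000 rfu). Height/size noise reuses the replicate noise
  model: Gaussian, truncated at zero — a choice, since no distributional
  form for replicate error is documented. The default five-station,
  three-enzyme design places oxic, low-oxygen and sulfidic guilds across
  the oxycline and boosts the sulfur-oxidizer guild 8× at the two
  mixing-zone stations. `three_group_spec` uses boxcar guilds so that
  within-group mixtures are identical pre-noise, giving a clean
  planted-group recovery target.
* **Chemistry.** Piecewise-linear profiles in σθ with scenario-specific
  breakpoints (only qualitative shapes are constrained): the
  central-gyre scenario has O₂ reaching detection near σθ 15.8 and
  sulfide onset near 16.05; the mixing-zone scenario keeps O₂/NOx
  measurable to ~16.3 with sulfide onset ~16.4, so the overlap detector
  finds a non-empty interval there by construction. Small multiplicative
  noise (sd 2%) leaves exact zeros at zero.
* **Incubations.** The forward model is the exact inverse of the rate
  calculation (fraction F² of produced N₂ to ³⁰N₂, 2F(1−F) to ²⁹N₂), so
  zero-noise recovery is exact and noisy recovery is unbiased (checked
  within 3 SE over 100 replicates).

What passing these tests does **not** show about real data: the
generators contain no PCR or primer bias, no electropherogram baseline
or size-calibration error beyond a Gaussian bp jitter, no OTUs sharing a
fragment length by coincidence (beyond what the community design plants), and
chemical profiles are smooth piecewise-linear idealizations. Recovery
rates on synthetic data are upper bounds on what field data supports.

## Problem sizes and defaults

The analysis drivers use 5 stations × 8 depths × 3 enzymes (40 samples
per enzyme), 50 Monte Carlo replicates, 999 ANOSIM permutations, and a
σθ grid step of 0.005 — small enough that the full pipeline runs in
seconds on one core while every statistic keeps its intended resolution
(p-floor 0.001, threshold from 2,000 replicate similarities). The
acceptance script scales the driver-recovery simulation to 100 runs of
15 samples with 4 candidate variables.

## Known limitations

* Per-enzyme resemblance only; no cross-enzyme averaging of matrices.
* No SIMPROF-style multi-level significance testing; the single
  replicate-error threshold flags nodes globally.
* The BEST procedure reports the rank correlation, not a permutation
  p-value for it.
* Reverse-orientation restriction sites of non-palindromic enzymes are
  not searched (see above).
* No reaction-transport modeling; fluxes are local two-point gradients.
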