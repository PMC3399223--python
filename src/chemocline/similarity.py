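"""Whittaker-index resemblance, UPGMA clustering, and Monte Carlo
significance of cluster nodes.

The Whittaker index of association between two relative-abundance vectors
p and q is ``S = 100 * (1 - 0.5 * sum|p_i - q_i|)`` percent — identically
``100 * (1 - Bray-Curtis)`` on relativized data.  Pairwise similarity is
computed in each of the four binning frames and the maximum over frames is
used, which absorbs sub-bp sizing drift.  Samples are clustered by
group-average (UPGMA) agglomeration on dissimilarity ``100 - S``, and the
significance of cluster nodes is judged against the reproducibility of
replicate fingerprints: each profile is perturbed with the duplicate-run
noise model, the original-vs-perturbed similarity is computed through the
full binning pipeline, and nodes that merge at or above the worst replicate
similarity cannot be called different.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    BinnedMatrix,
    NoiseModel,
    Peak,
    TRFLPProfile,
    bin_frames,
    filter_minor_peaks,
)


def whittaker_similarity(p: np.ndarray, q: np.ndarray, atol: float = 1e-6) -> float:
    """Whittaker index of association, in percent.

    Both vectors must be relative abundances on a common bin axis (each
    summing to 1).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must share a bin axis")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > atol:
            raise ValueError(f"{name} is not normalized (sums to {v.sum():.6g})")
    return float(100.0 * (1.0 - 0.5 * np.abs(p - q).sum()))


@dataclass(frozen=True)
class ResemblanceMatrix:
    sample_ids: tuple[str, ...]
    similarity: np.ndarray  # symmetric, percent
    enzyme: str = ""

    def __post_init__(self) -> None:
        sim = np.asarray(self.similarity, dtype=float)
        n = len(self.sample_ids)
        if sim.shape != (n, n):
            raise ValueError("similarity matrix shape does not match sample ids")
        if not np.allclose(sim, sim.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        if sim.min() < -1e-9 or sim.max() > 100 + 1e-9:
            raise ValueError("similarities must lie in [0, 100]")
        object.__setattr__(self, "similarity", sim)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.similarity, index=self.sample_ids, columns=self.sample_ids)

    def pair(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.similarity[i, j])


def resemblance(frames: Sequence[BinnedMatrix], enzyme: str = "") -> ResemblanceMatrix:
    """Max-over-frames Whittaker similarity between every sample pair."""
    if not frames:
        raise ValueError("no frames given")
    ids = frames[0].sample_ids
    for fr in frames[1:]:
        if fr.sample_ids != ids:
            raise ValueError("frames were built from different profile sets")
    n = len(ids)
    sim = np.zeros((n, n))
    per_frame = []
    for fr in frames:
        mat = fr.abundance.to_numpy(dtype=float)
        s = np.zeros((n, n))
        for i in range(n):
            s[i, i] = 100.0
            for j in range(i + 1, n):
                val = 100.0 * (1.0 - 0.5 * np.abs(mat[i] - mat[j]).sum())
                s[i, j] = s[j, i] = val
        per_frame.append(s)
    sim = np.maximum.reduce(per_frame)
    np.fill_diagonal(sim, 100.0)
    return ResemblanceMatrix(tuple(ids), np.clip(sim, 0.0, 100.0), enzyme=enzyme)


def resemblance_from_profiles(
    profiles: Sequence[TRFLPProfile],
    minor_peak_threshold: float = 0.003,
    bin_width: float = 2.0,
    offsets: Sequence[float] = (0.0, 0.5, 1.0, 1.5),
) -> ResemblanceMatrix:
    """Full pipeline: filter minor peaks, bin in four frames, max-frame Whittaker."""
    filtered = [filter_minor_peaks(p, minor_peak_threshold)[0] for p in profiles]
    frames = bin_frames(filtered, bin_width=bin_width, offsets=offsets)
    enzyme = profiles[0].enzyme if profiles else ""
    return resemblance(frames, enzyme=enzyme)


@dataclass
class MergeNode:
    """One agglomeration step: ``members`` of the two children merged at
    ``similarity`` percent."""

    left: int  # node index: 0..n-1 leaves, then n, n+1, ... internal
    right: int
    similarity: float
    members: tuple[int, ...]
    significant: bool | None = None  # False => within replicate error


@dataclass
class Dendrogram:
    leaves: tuple[str, ...]
    nodes: list[MergeNode]

    @property
    def merge_similarities(self) -> list[float]:
        return [n.similarity for n in self.nodes]

    def flag_significance(self, threshold: float) -> None:
        """Nodes merging at or above *threshold* are within replicate error."""
        for node in self.nodes:
            node.significant = node.similarity < threshold

    def to_newick(self) -> str:
        """Newick string; branch lengths are half the merge dissimilarity
        (ultrametric heights), significance flags as node comments."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        label: dict[int, str] = {i: self.leaves[i] for i in range(n)}
        for k, node in enumerate(self.nodes):
            h = (100.0 - node.similarity) / 2.0
            bl_left = h - height[node.left]
            bl_right = h - height[node.right]
            comment = ""
            if node.significant is not None:
                comment = "[&significant=%s]" % ("true" if node.significant else "false")
            label[n + k] = (
                f"({label[node.left]}:{bl_left:.6g},{label[node.right]}:{bl_right:.6g}){comment}"
            )
            height[n + k] = h
        return label[n + len(self.nodes) - 1] + ";"


def upgma_cluster(matrix: ResemblanceMatrix) -> Dendrogram:
    """Group-average (UPGMA) agglomeration on dissimilarity ``100 - S``.

    Ties are broken toward the cluster pair whose smallest leaf indices are
    smallest, making the merge order deterministic.
    """
    n = len(matrix.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    d = 100.0 - matrix.similarity.astype(float)
    # active clusters: node index -> (members tuple, min leaf index)
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    nodes: list[MergeNode] = []
    next_id = n
    active = list(range(n))

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    while len(active) > 1:
        best = None
        for idx_a in range(len(active)):
            for idx_b in range(idx_a + 1, len(active)):
                a, b = active[idx_a], active[idx_b]
                dd = dist[key(a, b)]
                ma, mb = min(members[a]), min(members[b])
                tie = (min(ma, mb), max(ma, mb))
                cand = (dd, tie, a, b)
                if best is None or cand < best:
                    best = cand
        dd, _, a, b = best
        new_members = tuple(sorted(members[a] + members[b]))
        nodes.append(MergeNode(left=a, right=b, similarity=100.0 - dd, members=new_members))
        # average linkage update weighted by cluster sizes
        na, nb = len(members[a]), len(members[b])
        for c in active:
            if c in (a, b):
                continue
            dac = dist[key(a, c)]
            dbc = dist[key(b, c)]
            dist[key(next_id, c)] = (na * dac + nb * dbc) / (na + nb)
        members[next_id] = new_members
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(leaves=tuple(matrix.sample_ids), nodes=nodes)


def perturb_profiles(
    profiles: Sequence[TRFLPProfile],
    noise: NoiseModel,
    seed: int | np.random.Generator,
) -> list[TRFLPProfile]:
    """Jitter every peak's height and fragment length per the noise model.

    Height sd scales with the profile total (``sigma_height *
    total/reference_total``); heights are truncated at zero; fragment
    lengths get independent Gaussian jitter of sd ``sigma_bp``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for prof in profiles:
        total = prof.total_height
        sd_h = noise.sigma_height * total / noise.reference_total
        peaks = []
        for peak in prof.peaks:
            h = peak.height_rfu + (rng.normal(0.0, sd_h) if sd_h > 0 else 0.0)
            bp = peak.fragment_bp + (rng.normal(0.0, noise.sigma_bp) if noise.sigma_bp > 0 else 0.0)
            peaks.append(Peak(max(bp, 1e-9), max(h, 0.0)))
        out.append(prof.with_peaks(peaks))
    return out


def replicate_similarity(
    original: TRFLPProfile,
    perturbed: TRFLPProfile,
    minor_peak_threshold: float = 0.003,
    bin_width: float = 2.0,
    offsets: Sequence[float] = (0.0, 0.5, 1.0, 1.5),
) -> float:
    """Similarity of a profile to its perturbed replicate, through the full
    filter -> bin -> max-over-frames pipeline."""
    twin = TRFLPProfile(
        sample_id=original.sample_id + "__replicate",
        enzyme=original.enzyme,
        peaks=perturbed.peaks,
        station=original.station,
        year=original.year,
        sigma_theta=original.sigma_theta,
    )
    mat = resemblance_from_profiles(
        [original, twin],
        minor_peak_threshold=minor_peak_threshold,
        bin_width=bin_width,
        offsets=offsets,
    )
    return float(mat.similarity[0, 1])


@dataclass
class SignificanceResult:
    threshold: float
    replicate_similarities: np.ndarray  # samples x replicates
    dendrogram: Dendrogram
    resemblance: ResemblanceMatrix
    n_replicates: int


def monte_carlo_significance(
    profiles: Sequence[TRFLPProfile],
    noise: NoiseModel,
    n_replicates: int = 50,
    seed: int | np.random.Generator = 0,
    minor_peak_threshold: float = 0.003,
    bin_width: float = 2.0,
    offsets: Sequence[float] = (0.0, 0.5, 1.0, 1.5),
    threshold_mode: str = "min",
    percentile: float = 5.0,
) -> SignificanceResult:
    """Replicate-noise significance threshold for the cluster diagram.

    For each of ``n_replicates`` Monte Carlo draws, every profile is
    perturbed once with the duplicate-run noise model and the similarity of
    each original to its own perturbed replicate is computed through the
    full pipeline.  The threshold is the minimum such similarity (or the
    ``percentile``-th percentile with ``threshold_mode="percentile"``);
    dendrogram nodes merging at or above it are flagged as not
    significantly different.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sims = np.empty((len(profiles), n_replicates))
    for r in range(n_replicates):
        perturbed = perturb_profiles(profiles, noise, rng)
        for i, (orig, pert) in enumerate(zip(profiles, perturbed)):
            sims[i, r] = replicate_similarity(
                orig,
                pert,
                minor_peak_threshold=minor_peak_threshold,
                bin_width=bin_width,
                offsets=offsets,
            )
    if threshold_mode == "min":
        threshold = float(sims.min())
    elif threshold_mode == "percentile":
        threshold = float(np.percentile(sims, percentile))
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    mat = resemblance_from_profiles(
        profiles,
        minor_peak_threshold=minor_peak_threshold,
        bin_width=bin_width,
        offsets=offsets,
    )
    dendro = upgma_cluster(mat)
    dendro.flag_significance(threshold)
    return SignificanceResult(
        threshold=threshold,
        replicate_similarities=sims,
        dendrogram=dendro,
        resemblance=mat,
        n_replicates=n_replicates,
    )
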