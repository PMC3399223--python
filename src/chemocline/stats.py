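"""Community-environment statistics.

ANOSIM contrasts between- vs within-group dissimilarity ranks; the BEST /
BIOENV procedure finds the subset of (z-scored) environmental variables
whose Euclidean inter-sample distances best rank-correlate with the
community dissimilarities; OTU-level helpers extract the depth profile of
one terminal fragment and check it is supported by multiple enzymes.

A core constraint of peak-height fingerprinting is honoured throughout:
relative abundances of the *same* fragment are comparable across samples,
but heights of *different* fragments are never compared to each other
(PCR bias differs per template).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata, spearmanr

from .profiles import TRFLPProfile, normalize
from .similarity import ResemblanceMatrix


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    groups: tuple[str, ...]


def _anosim_r(dissim_ranks: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    m = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    ranks = dissim_ranks
    r_within = ranks[same].mean()
    r_between = ranks[~same].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    matrix: ResemblanceMatrix,
    labels: Mapping[str, str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> AnosimResult:
    """Analysis of similarities on dissimilarity ``100 - S``.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 and average ranks for ties; the p-value counts permuted
    R >= observed with the +1 correction.
    """
    ids = matrix.sample_ids
    missing = [s for s in ids if s not in labels]
    if missing:
        raise ValueError(f"labels missing for samples {missing}")
    lab = np.array([labels[s] for s in ids])
    cats, counts = np.unique(lab, return_counts=True)
    if len(cats) < 2:
        raise ValueError("need >= 2 categories")
    if (counts < 2).any():
        small = cats[counts < 2].tolist()
        raise ValueError(f"groups with < 2 samples: {small}")
    n = len(ids)
    d = 100.0 - matrix.similarity
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])  # average ranks for ties
    observed = _anosim_r(ranks, lab)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        if _anosim_r(ranks, perm) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return AnosimResult(r=observed, p_value=p, n_permutations=n_perm, groups=tuple(cats))


def anosim_pairwise(
    matrix: ResemblanceMatrix,
    labels: Mapping[str, str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[str, str], AnosimResult]:
    """ANOSIM restricted to every pair of categories."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lab = {s: labels[s] for s in matrix.sample_ids}
    cats = sorted(set(lab.values()))
    results = {}
    for a, b in combinations(cats, 2):
        keep = [s for s in matrix.sample_ids if lab[s] in (a, b)]
        idx = [matrix.sample_ids.index(s) for s in keep]
        sub = ResemblanceMatrix(
            tuple(keep), matrix.similarity[np.ix_(idx, idx)], enzyme=matrix.enzyme
        )
        results[(a, b)] = anosim(sub, lab, n_perm=n_perm, seed=rng)
    return results


def best_env_subset(
    env: pd.DataFrame,
    matrix: ResemblanceMatrix,
    max_vars: int = 15,
) -> pd.DataFrame:
    """BIOENV/BEST: rank all variable subsets by Spearman rho.

    ``env`` is a samples x variables table (index = sample ids).  Every
    variable is z-scored, Euclidean distances are computed per subset, and
    the Spearman rank correlation between the unfolded upper triangles of
    the environmental distance and the community dissimilarity is
    recorded.  Returns a DataFrame with columns ``variables`` (tuple) and
    ``rho``, sorted best first.  Zero-variance variables are excluded with
    a warning.
    """
    ids = list(matrix.sample_ids)
    missing = [s for s in ids if s not in env.index]
    if missing:
        raise ValueError(f"environment table missing samples {missing}")
    env = env.loc[ids]
    keep = []
    for col in env.columns:
        if env[col].std(ddof=0) == 0:
            warnings.warn(f"excluding zero-variance variable {col!r}")
        else:
            keep.append(col)
    if not keep:
        raise ValueError("no variable with non-zero variance")
    if len(keep) > max_vars:
        raise ValueError(f"{len(keep)} variables exceed the enumeration guard ({max_vars})")
    z = (env[keep] - env[keep].mean()) / env[keep].std(ddof=0)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    comm = (100.0 - matrix.similarity)[iu]
    rows = []
    for k in range(1, len(keep) + 1):
        for subset in combinations(keep, k):
            ed = pdist(z[list(subset)].to_numpy(), metric="euclidean")
            rho = spearmanr(ed, comm).statistic
            rows.append({"variables": subset, "rho": float(rho)})
    out = pd.DataFrame(rows).sort_values("rho", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)


def otu_depth_profile(
    profiles: Sequence[TRFLPProfile],
    target_bp: float,
    tolerance_bp: float = 0.5,
) -> pd.Series:
    """Normalized height of one fragment across samples.

    Per sample, the summed normalized height of peaks within
    ``+/- tolerance_bp`` of ``target_bp`` (0 when the fragment is absent).
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance must be non-negative")
    values = {}
    for prof in profiles:
        norm = normalize(prof)
        total = sum(
            p.height_rfu
            for p in norm.peaks
            if abs(p.fragment_bp - target_bp) <= tolerance_bp
        )
        values[prof.sample_id] = total
    return pd.Series(values, name=f"trf_{target_bp:g}")


def otu_depth_profiles(
    profiles: Sequence[TRFLPProfile],
    targets: Sequence[float],
    tolerance_bp: float = 0.5,
) -> pd.DataFrame:
    """Depth profiles for several target fragments; warns on overlapping
    target windows (peaks could be double-counted)."""
    for a, b in combinations(sorted(targets), 2):
        if b - a <= 2 * tolerance_bp:
            warnings.warn(f"target windows {a} and {b} overlap at tolerance {tolerance_bp}")
    return pd.DataFrame(
        {f"trf_{t:g}": otu_depth_profile(profiles, t, tolerance_bp) for t in targets}
    )


@dataclass(frozen=True)
class ConcordanceResult:
    rho: float | None
    supported: bool
    enzymes: tuple[str, str]
    n_samples: int


def cross_enzyme_concordance(
    profiles_by_enzyme: Mapping[str, Sequence[TRFLPProfile]],
    target_bp_by_enzyme: Mapping[str, float],
    tolerance_bp: float = 0.5,
    support_threshold: float = 0.7,
) -> list[ConcordanceResult]:
    """Check an OTU's depth profile is supported by multiple enzymes.

    For every pair of enzymes, the Spearman correlation between the two
    depth-profile vectors over the shared samples; a pair is "supported"
    when rho exceeds ``support_threshold``.  An all-zero (or otherwise
    constant) vector leaves rho undefined and the pair unsupported.
    """
    enzymes = sorted(profiles_by_enzyme)
    if len(enzymes) < 2:
        raise ValueError("need profiles from >= 2 enzymes")
    vectors = {}
    for enz in enzymes:
        vec = otu_depth_profile(
            profiles_by_enzyme[enz], target_bp_by_enzyme[enz], tolerance_bp
        )
        vectors[enz] = vec
    results = []
    for a, b in combinations(enzymes, 2):
        shared = vectors[a].index.intersection(vectors[b].index)
        if len(shared) < 3:
            raise ValueError(f"enzymes {a}/{b} share only {len(shared)} samples (need >= 3)")
        va = vectors[a].loc[shared].to_numpy()
        vb = vectors[b].loc[shared].to_numpy()
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            results.append(ConcordanceResult(None, False, (a, b), len(shared)))
            continue
        rho = float(spearmanr(va, vb).statistic)
        results.append(ConcordanceResult(rho, rho > support_threshold, (a, b), len(shared)))
    return results


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    method: str
    sign: int
    n: int


def abundance_env_correlation(
    otu_values: Sequence[float],
    env_values: Sequence[float],
    method: str = "spearman",
    p_method: str = "asymptotic",
) -> CorrelationResult:
    """Correlation between one OTU's abundance and one environmental rate
    or concentration across stations.

    ``method`` is "spearman" (rank, default) or "pearson" (linear);
    ``p_method="exact"`` enumerates all permutations of one vector (n <= 8)
    for a two-sided permutation p-value.
    """
    x = np.asarray(otu_values, dtype=float)
    y = np.asarray(env_values, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")

    def coef(a: np.ndarray, b: np.ndarray) -> float:
        if method == "spearman":
            return float(spearmanr(a, b).statistic)
        if method == "pearson":
            return float(pearsonr(a, b).statistic)
        raise ValueError(f"unknown method {method!r}")

    obs = coef(x, y)
    if p_method == "asymptotic":
        if method == "spearman":
            p = float(spearmanr(x, y).pvalue)
        else:
            p = float(pearsonr(x, y).pvalue)
    elif p_method == "exact":
        if len(x) > 8:
            raise ValueError("exact permutation p limited to n <= 8")
        count = 0
        total = 0
        for perm in permutations(y):
            total += 1
            if abs(coef(x, np.array(perm))) >= abs(obs) - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CorrelationResult(
        coefficient=obs, p_value=p, method=method, sign=int(np.sign(obs)), n=len(x)
    )
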