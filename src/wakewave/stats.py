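"""Electrode-level contrasts and cluster-based permutation inference.

Per electrode, a within-subject two-level contrast is summarized by a
paired t statistic across subjects (each subject contributes the mean
difference between condition levels); any richer per-electrode model can be
plugged in through a callback. Family-wise error over the montage is
controlled non-parametrically: electrodes with one-tailed p below the
cluster-forming alpha (0.025 per tail) are grouped into sign-consistent
clusters of spatial neighbours, each cluster is scored by the sum of its t
values (cluster mass), and the observed masses are compared with the
distribution of the maximal absolute mass over within-subject sign
permutations. The Monte Carlo cluster p value is declared significant below
0.05, Bonferroni-divided by the number of map families tested together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import channel_positions

__all__ = [
    "ElectrodeStatMap",
    "ClusterResult",
    "build_adjacency",
    "electrode_stat_map",
    "cluster_permutation",
]

DEFAULT_ADJACENCY_THRESHOLD = 0.045  # metres; ~1.5x nearest-neighbour spacing


@dataclass
class ElectrodeStatMap:
    contrast: str
    channels: list[str]
    t: np.ndarray
    p: np.ndarray
    n_subjects: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "t": self.t, "p": self.p})


@dataclass
class ClusterResult:
    channels: tuple[str, ...]
    mass: float
    sign: int
    p_cluster: float
    significant: bool


def build_adjacency(montage: list[str] | tuple[str, ...],
                    distance_threshold: float = DEFAULT_ADJACENCY_THRESHOLD
                    ) -> np.ndarray:
    """Boolean channel adjacency: edge iff inter-electrode distance (3-D,
    standard template positions) is at or below the threshold. Symmetric,
    no self-edges."""
    pos = channel_positions(tuple(montage))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d <= distance_threshold) & ~np.eye(len(montage), dtype=bool)
    return adj


# ---------------------------------------------------------------------------
# per-electrode statistics
# ---------------------------------------------------------------------------

def _subject_difference_maps(features: np.ndarray, subjects: np.ndarray,
                             labels: np.ndarray, contrast: tuple, ) -> np.ndarray:
    """Collapse per-observation features to per-subject mean(A) - mean(B)
    maps; subjects lacking either level are dropped with a warning."""
    level_a, level_b = contrast
    diffs = []
    dropped = []
    for s in pd.unique(subjects):
        sel = subjects == s
        in_a = sel & (labels == level_a)
        in_b = sel & (labels == level_b)
        if not in_a.any() or not in_b.any():
            dropped.append(s)
            continue
        diffs.append(features[in_a].mean(axis=0) - features[in_b].mean(axis=0))
    if dropped:
        warnings.warn(f"subjects without both contrast levels dropped: {dropped}",
                      stacklevel=3)
    if len(diffs) < 2:
        raise ValueError("fewer than 2 subjects with both contrast levels")
    return np.asarray(diffs)


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sem = diffs.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sem > 0, mean / sem, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    return t, np.clip(p, np.finfo(float).tiny, 1.0)


def electrode_stat_map(features: np.ndarray, subjects: np.ndarray,
                       labels: np.ndarray, contrast: tuple,
                       channels: list[str],
                       stat_fn=None) -> ElectrodeStatMap:
    """Per-electrode t and p values for a two-level within-subject contrast.

    Parameters
    ----------
    features : ndarray, shape (n_observations, n_channels)
        One row per probe/trial (e.g. pre-probe wave density per channel).
    subjects, labels : arrays of length n_observations
    contrast : (level_a, level_b)
        Positive t means level_a > level_b.
    stat_fn : callable, optional
        ``stat_fn(diffs) -> (t, p)`` on the (n_subjects, n_channels)
        difference maps; defaults to the paired t across subjects.
    """
    features = np.asarray(features, dtype=float)
    diffs = _subject_difference_maps(features, np.asarray(subjects),
                                     np.asarray(labels), contrast)
    t, p = (stat_fn or _paired_t)(diffs)
    return ElectrodeStatMap(contrast=f"{contrast[0]}>{contrast[1]}",
                            channels=list(channels), t=np.asarray(t),
                            p=np.asarray(p), n_subjects=diffs.shape[0])


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def _neighbor_lists(adjacency: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(adjacency[i]) for i in range(adjacency.shape[0])]


def _clusters_from_t(t: np.ndarray, t_crit: float,
                     neighbors: list[np.ndarray]) -> list[tuple[list[int], float, int]]:
    """Sign-consistent connected components of supra-threshold electrodes."""
    out = []
    for sign in (1, -1):
        supra = (sign * t) > t_crit
        seen = np.zeros(t.size, dtype=bool)
        for start in np.flatnonzero(supra):
            if seen[start]:
                continue
            stack = [start]
            seen[start] = True
            members = []
            while stack:
                i = stack.pop()
                members.append(i)
                for j in neighbors[i]:
                    if supra[j] and not seen[j]:
                        seen[j] = True
                        stack.append(j)
            out.append((members, float(t[members].sum()), sign))
    return out


def _max_cluster_mass(t: np.ndarray, t_crit: float,
                      neighbors: list[np.ndarray]) -> float:
    clusters = _clusters_from_t(t, t_crit, neighbors)
    if not clusters:
        return 0.0
    return max(abs(c[1]) for c in clusters)


def _perm_t(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized paired t over sign-flip permutations.

    Exploits sum((s_i d_i)^2) == sum(d_i^2): only the mean changes under a
    sign flip, so the whole permutation block is two matrix products.
    """
    n = diffs.shape[0]
    mean = signs @ diffs / n                        # (P, C)
    ss = (diffs**2).sum(axis=0)[None, :]            # (1, C)
    var = (ss - n * mean**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def cluster_permutation(features: np.ndarray, subjects: np.ndarray,
                        labels: np.ndarray, contrast: tuple,
                        adjacency: np.ndarray, channels: list[str],
                        cluster_alpha: float = 0.025,
                        n_perm: int = 1000,
                        mc_threshold: float = 0.05,
                        n_comparisons: int = 1,
                        seed: int | np.random.Generator = 0,
                        ) -> tuple[list[ClusterResult], ElectrodeStatMap]:
    """Cluster-based permutation test of a two-level within-subject contrast.

    The null distribution is the maximal absolute cluster mass under
    within-subject condition-label permutations, realized as sign flips of
    the per-subject difference maps. With ``2^n_subjects <= n_perm`` the
    sign-flip space is enumerated exhaustively; otherwise ``n_perm`` random
    flips are drawn and ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    A cluster is significant iff ``p < mc_threshold / n_comparisons``
    (Bonferroni across map families).
    """
    if n_perm < 200:
        raise ValueError("n_perm must be at least 200")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    features = np.asarray(features, dtype=float)
    diffs = _subject_difference_maps(features, np.asarray(subjects),
                                     np.asarray(labels), contrast)
    n = diffs.shape[0]
    t_obs, _ = _paired_t(diffs)
    # one-tailed cluster-forming threshold per tail (p < cluster_alpha)
    t_crit = float(sps.t.ppf(1.0 - cluster_alpha, df=n - 1))
    neighbors = _neighbor_lists(adjacency)
    clusters = _clusters_from_t(t_obs, t_crit, neighbors)

    exhaustive = 2**n <= n_perm
    if exhaustive:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    t_perm = _perm_t(diffs, signs)
    null = np.array([_max_cluster_mass(t_perm[i], t_crit, neighbors)
                     for i in range(t_perm.shape[0])])

    alpha = mc_threshold / n_comparisons
    results = []
    for members, mass, sign in clusters:
        if exhaustive:
            p = float((null >= abs(mass) - 1e-12).mean())
        else:
            p = float((1 + (null >= abs(mass) - 1e-12).sum()) / (1 + n_perm))
        results.append(ClusterResult(
            channels=tuple(channels[i] for i in members),
            mass=mass, sign=sign, p_cluster=p, significant=p < alpha))
    results.sort(key=lambda c: -abs(c.mass))
    stat_map = ElectrodeStatMap(contrast=f"{contrast[0]}>{contrast[1]}",
                                channels=list(channels), t=t_obs,
                                p=_paired_t(diffs)[1], n_subjects=n)
    return results, stat_map
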