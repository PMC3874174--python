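"""Optimal k-best minimum-distance bipartite matching.

Each observed element (an eQTL class, or a domain sequence summarised by
its conditioning statistics) carries a feature vector of confounders.
Matching pairs every observed element with its k best random counterparts
so that the *total* Euclidean distance over all pairs is minimal, with
every candidate used at most once.  This is the matched case-control
device used by all resampling tests in the package: comparing observed
elements with near-identical random counterparts removes confounding by
the matched features.

The k-best semantics replicate each observed element k times and solve a
single rectangular min-cost assignment (scipy's Jonker-Volgenant solver),
so the k matches per element are jointly optimal rather than greedy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr


class InsufficientCandidatesError(ValueError):
    pass


@dataclass
class MatchResult:
    """Assignment of each observed index to k candidate indices.

    ``assignments`` rows are (observed_index, candidate_index, rank,
    distance) with rank 1 the closest of the k matches.
    """

    observed_index: np.ndarray
    candidate_index: np.ndarray
    rank: np.ndarray
    distance: np.ndarray
    total_distance: float
    k: int

    def rank1_candidates(self, n_observed: int) -> np.ndarray:
        """Candidate index matched at rank 1 for each observed element."""
        out = np.full(n_observed, -1, dtype=np.int64)
        sel = self.rank == 1
        out[self.observed_index[sel]] = self.candidate_index[sel]
        return out

    @property
    def assignments(self) -> list[tuple[int, int, int, float]]:
        return list(zip(self.observed_index.tolist(),
                        self.candidate_index.tolist(),
                        self.rank.tolist(), self.distance.tolist()))


def _as_matrix(vectors) -> np.ndarray:
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature vectors must be finite")
    return arr


def match(observed, candidates, k: int = 1, scale: bool = False) -> MatchResult:
    """Optimal k-best matching minimising summed Euclidean distance.

    Parameters
    ----------
    observed, candidates
        Arrays of shape (n, f) and (m, f) with a shared feature schema.
    k
        Number of distinct candidates assigned to each observed element.
    scale
        If True, z-scale each feature (over observed and candidates
        pooled) before computing distances.  Off by default: features
        enter the distance unscaled.
    """
    obs = _as_matrix(observed)
    cand = _as_matrix(candidates)
    if obs.shape[1] != cand.shape[1]:
        raise ValueError("feature schemas differ between observed and candidates")
    n, m = obs.shape[0], cand.shape[0]
    if m < k * n:
        raise InsufficientCandidatesError(
            f"need {k * n} candidates ({n} observed x k={k}), have {m}")
    if scale:
        pooled = np.vstack([obs, cand])
        mu, sd = pooled.mean(axis=0), pooled.std(axis=0)
        sd[sd == 0] = 1.0
        obs = (obs - mu) / sd
        cand = (cand - mu) / sd
    dist = cdist(obs, cand)
    cost = np.repeat(dist, k, axis=0)  # rows (i, replica) in lexicographic order
    rows, cols = linear_sum_assignment(cost)
    obs_idx = rows // k
    d = cost[rows, cols]
    # assign ranks 1..k per observed element by increasing distance,
    # ties broken by candidate index for determinism
    order = np.lexsort((cols, d, obs_idx))
    obs_idx = obs_idx[order]
    cand_idx = cols[order]
    d = d[order]
    ranks = np.empty_like(obs_idx)
    for i in range(n):
        sel = obs_idx == i
        ranks[sel] = np.arange(1, k + 1)
    return MatchResult(observed_index=obs_idx, candidate_index=cand_idx,
                       rank=ranks, distance=d, total_distance=float(d.sum()),
                       k=k)


def match_quality(result: MatchResult, observed, candidates) -> np.ndarray:
    """Per-feature Pearson correlation between observed values and their
    rank-1 matched candidate values.

    Zero-variance features yield NaN rather than raising.
    """
    obs = _as_matrix(observed)
    cand = _as_matrix(candidates)
    sel = result.rank == 1
    x = obs[result.observed_index[sel]]
    y = cand[result.candidate_index[sel]]
    rhos = np.full(obs.shape[1], np.nan)
    for f in range(obs.shape[1]):
        if np.std(x[:, f]) == 0 or np.std(y[:, f]) == 0:
            continue
        rhos[f] = pearsonr(x[:, f], y[:, f]).statistic
    return rhos


def match_table(result: MatchResult, observed, candidates,
                feature_names: list[str] | None = None):
    """Flat match table: observed_id, candidate_id, rank, distance and the
    feature values on both sides."""
    import pandas as pd

    obs = _as_matrix(observed)
    cand = _as_matrix(candidates)
    names = feature_names or [f"f{i}" for i in range(obs.shape[1])]
    df = pd.DataFrame({"observed_id": result.observed_index,
                       "candidate_id": result.candidate_index,
                       "rank": result.rank, "distance": result.distance})
    for j, nm in enumerate(names):
        df[f"obs_{nm}"] = obs[result.observed_index, j]
        df[f"cand_{nm}"] = cand[result.candidate_index, j]
    return df
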