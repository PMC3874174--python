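"""Matched-pair spatial-proximity tests and boundary-enrichment statistics.

The central question: are eQTL SNP bins in unusually frequent Hi-C
contact with their target-gene bins?  Each observed eQTL class is paired
(k = 1 optimal matching on the confounder vector d, g, t_hat, m) with a
random class of near-identical genomic geometry and coverage, and the
paired proximity difference is tested with the Wilcoxon signed-rank test.
Rank-sum comparisons of per-bin total frequencies and empirical
boundary-window enrichment over shuffled domains complete the picture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .eqtl_mapping import EqtlClass, classify_many
from .hic_graph import CROSSING, DomainSequence
from .matching import MatchResult, match
from .null_models import RandomEqtlSpace, ShuffledDomainSet

logger = logging.getLogger(__name__)

DEFAULT_PROXIMITY_BIN_EDGES = (0.0, 1.0, 5.0, 10.0, 30.0)
DEFAULT_BOUNDARY_WINDOW = 250_000

EXACT_RANKSUM_MAX_N = 50


@dataclass
class MatchedPairTest:
    n_pairs: int
    statistic: float
    p_value: float
    direction: str  # "observed", "random" or "none"
    per_bin_counts: dict[str, tuple[int, int]]
    match_quality: np.ndarray | None = None
    subset: str = "all"


def _feature_matrix(classes: list[EqtlClass]) -> np.ndarray:
    feats = np.array([c.properties.as_array() for c in classes])
    if feats.size and not np.all(np.isfinite(feats)):
        raise ValueError("class properties contain non-finite values")
    return feats


def _proximity_bins(values: np.ndarray, edges) -> np.ndarray:
    """Bin index per value; the last bin is open-ended [edges[-1], inf)."""
    return np.clip(np.searchsorted(edges, values, side="right") - 1,
                   0, len(edges) - 1)


def _bin_label(edges, i) -> str:
    if i == len(edges) - 1:
        return f"[{edges[i]:g},inf)"
    return f"[{edges[i]:g},{edges[i + 1]:g})"


def proximity_matched_test(observed_classes: list[EqtlClass],
                           random_space: RandomEqtlSpace,
                           subset: str = "all",
                           domains: DomainSequence | None = None,
                           proximity_bin_edges=DEFAULT_PROXIMITY_BIN_EDGES,
                           ) -> MatchedPairTest:
    """Wilcoxon signed-rank test on matched observed vs random proximities.

    Each observed class (optionally restricted to the ``crossing`` or
    ``noncrossing`` subset, which requires ``domains``) is matched k = 1
    to the random space on (d, g, t_hat, m); the test is two-sided on the
    paired differences p_obs - p_rand with zero differences dropped and
    average ranks for ties.  ``per_bin_counts`` tallies observed and
    random proximity values per bin for the enrichment-direction display.
    """
    classes = list(observed_classes)
    if subset != "all":
        if domains is None:
            raise ValueError(f"subset={subset!r} requires domains")
        labels = classify_many(classes, domains)
        keep = (labels == CROSSING) if subset == "crossing" else (labels != CROSSING)
        classes = [c for c, k in zip(classes, keep) if k]
    if not classes:
        raise ValueError(f"no classes in subset {subset!r}")
    feats = _feature_matrix(classes)
    result = match(feats, random_space.features, k=1)
    rank1 = result.rank1_candidates(len(classes))
    p_obs = np.array([c.properties.p for c in classes])
    p_rand = random_space.proximity[rank1]
    quality = None
    diffs = p_obs - p_rand
    if np.all(diffs == 0):
        stat, pval, direction = 0.0, 1.0, "none"
    else:
        res = stats.wilcoxon(p_obs, p_rand, zero_method="wilcox",
                             alternative="two-sided", method="auto")
        stat, pval = float(res.statistic), float(res.pvalue)
        med = np.median(diffs[diffs != 0])
        direction = ("observed" if diffs[diffs != 0].mean() > 0 else "random") \
            if med == 0 else ("observed" if med > 0 else "random")
    from .matching import match_quality as _mq
    quality = _mq(result, feats, random_space.features)
    edges = list(proximity_bin_edges)
    ob = _proximity_bins(p_obs, edges)
    rb = _proximity_bins(p_rand, edges)
    per_bin = {_bin_label(edges, i): (int((ob == i).sum()), int((rb == i).sum()))
               for i in range(len(edges))}
    return MatchedPairTest(n_pairs=len(classes), statistic=stat, p_value=pval,
                           direction=direction, per_bin_counts=per_bin,
                           match_quality=quality, subset=subset)


def total_frequency_ranksum(group_a, group_b,
                            alternative: str = "two-sided") -> float:
    """Two-sample Wilcoxon rank-sum p-value on total frequencies.

    Exact null when both groups are small (n <= 50) and tie-free,
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = ("exact" if tie_free and max(a.size, b.size) <= EXACT_RANKSUM_MAX_N
              else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def boundary_window_enrichment(classes: list[EqtlClass],
                               domains: DomainSequence,
                               shuffle_set: ShuffledDomainSet,
                               window: int = DEFAULT_BOUNDARY_WINDOW,
                               ) -> tuple[float, float]:
    """Fraction of distinct SNP fragments within ``window`` bp of a domain
    boundary, with an add-one empirical p-value over shuffled domains.

    p = (1 + #{shuffles with fraction >= observed}) / (1 + n_d).
    """
    if len(shuffle_set) == 0:
        raise ValueError("empty shuffle set")
    mids = np.unique([c.midpoint_snp() for c in classes])

    def frac(dom: DomainSequence) -> float:
        return float(np.mean(np.abs(dom.signed_boundary_distance(mids)) <= window))

    observed = frac(domains)
    shuffled = np.array([frac(d) for d in shuffle_set.sequences])
    p = (1 + int((shuffled >= observed).sum())) / (1 + len(shuffled))
    return observed, p


@dataclass
class SizeStratifiedResult:
    size: int
    n_domains: int
    n_snps: int
    chi2: float
    p_raw: float
    p_bonferroni: float
    underpowered: bool
    histogram: np.ndarray


def size_stratified_boundary_test(classes: list[EqtlClass],
                                  domains: DomainSequence,
                                  sizes=(500_000, 1_000_000, 2_000_000),
                                  tolerance: float = 0.2,
                                  n_bins: int = 10,
                                  ) -> list[SizeStratifiedResult]:
    """Chi-squared uniformity test of boundary offsets, per domain size.

    For each size class s (domains with length within s*(1 +/- tolerance)),
    SNP fragments within s/2 of a boundary of such a domain are
    histogrammed by |offset| into ``n_bins`` equal-width bins over
    [0, s/2] and tested against uniformity; p-values are Bonferroni
    multiplied by the number of size classes.  Strata with fewer than
    5 * n_bins SNPs are flagged underpowered.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes is empty")
    mids = np.unique([c.midpoint_snp() for c in classes])
    out = []
    for s in sizes:
        lo, hi = s * (1 - tolerance), s * (1 + tolerance)
        sel = (domains.lengths >= lo) & (domains.lengths <= hi)
        sub_starts, sub_ends = domains.starts[sel], domains.ends[sel]
        bnd = np.sort(np.concatenate([sub_starts, sub_ends])) if sel.any() else \
            np.array([])
        if bnd.size:
            pos = np.searchsorted(bnd, mids)
            left = np.where(pos > 0, np.abs(mids - bnd[np.clip(pos - 1, 0, None)]),
                            np.inf)
            right = np.where(pos < bnd.size,
                             np.abs(bnd[np.clip(pos, 0, bnd.size - 1)] - mids),
                             np.inf)
            offsets = np.minimum(left, right)
            offsets = offsets[offsets <= s / 2]
        else:
            offsets = np.array([])
        hist, _ = np.histogram(offsets, bins=n_bins, range=(0, s / 2))
        under = offsets.size < 5 * n_bins
        if offsets.size:
            chi2, p_raw = stats.chisquare(hist)
            chi2, p_raw = float(chi2), float(p_raw)
        else:
            chi2, p_raw = 0.0, 1.0
        if under:
            logger.warning("size class %d: only %d SNPs (< %d); "
                           "chi-squared test underpowered", s, offsets.size,
                           5 * n_bins)
        out.append(SizeStratifiedResult(
            size=int(s), n_domains=int(sel.sum()), n_snps=int(offsets.size),
            chi2=chi2, p_raw=p_raw,
            p_bonferroni=float(min(1.0, p_raw * len(sizes))),
            underpowered=bool(under), histogram=hist))
    return out


def regulatory_proximity_test(reg_classes: list[EqtlClass],
                              other_classes: list[EqtlClass]) -> float:
    """One-sided rank-sum: regulatory-element classes have larger
    proximity than the rest (caller restricts both lists to non-crossing)."""
    if not reg_classes or not other_classes:
        raise ValueError("both class lists must be non-empty")
    a = [c.properties.p for c in reg_classes]
    b = [c.properties.p for c in other_classes]
    return total_frequency_ranksum(a, b, alternative="greater")
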