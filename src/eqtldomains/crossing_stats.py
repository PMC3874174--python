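"""Domain-crossing counts and the conditioned empirical p-value.

The number of eQTL classes whose SNP-gene interval crosses a domain is
compared against the same count over shuffled domain sequences.  Because
the raw crossing count co-varies with how many distinct genes (N_G) and
SNP fragments (N_S) cross, the empirical p-value is *conditioned*: the
shuffle set is restricted to sequences whose (N_G, N_S) lie within ranges
derived from the k shuffles best matching the observed values, and the
observed sequence is always included, so the p-value is in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .eqtl_mapping import EqtlClass
from .hic_graph import CROSSING, DomainSequence
from .matching import match
from .null_models import ShuffledDomainSet


@dataclass
class CrossingStats:
    n: int                      # observed crossing class count
    n_genes: int                # distinct genes among crossing classes (N_G)
    n_snp_fragments: int        # distinct SNP bins among crossing classes (N_S)
    gamma_range: tuple[int, int]
    sigma_range: tuple[int, int]
    conditioned_space_size: int
    p_value: float
    shuffle_counts: np.ndarray | None = None  # N per shuffle (diagnostics)


def _class_arrays(classes: list[EqtlClass]):
    """Precompute interval endpoints, gene ids and SNP bins for speed."""
    ab = np.array([c.snp_gene_interval() for c in classes], dtype=float)
    gene_names = {}
    gene_ids = np.array([gene_names.setdefault(c.gene_name, len(gene_names))
                         for c in classes], dtype=np.int64)
    snp_bins = np.array([c.snp_fragment for c in classes], dtype=np.int64)
    return ab[:, 0], ab[:, 1], gene_ids, snp_bins


def _counts_for(domains: DomainSequence, a, b, gene_ids, snp_bins):
    labels = domains.classify_intervals(a, b)
    mask = labels == CROSSING
    n = int(mask.sum())
    ng = int(np.unique(gene_ids[mask]).size)
    ns = int(np.unique(snp_bins[mask]).size)
    return n, ng, ns


def crossing_counts(classes: list[EqtlClass],
                    domains: DomainSequence) -> tuple[int, int, int]:
    """(n, N_G, N_S): crossing classes, distinct genes and distinct SNP
    fragments among them."""
    if not classes:
        return (0, 0, 0)
    a, b, gene_ids, snp_bins = _class_arrays(classes)
    return _counts_for(domains, a, b, gene_ids, snp_bins)


def conditioned_pvalue(classes: list[EqtlClass],
                       observed_domains: DomainSequence,
                       shuffle_set: ShuffledDomainSet,
                       k_cond: int = 100) -> CrossingStats:
    """Conditioned empirical p-value for the observed crossing count.

    Procedure: compute (N, N_G, N_S) for every shuffled sequence; find the
    ``k_cond`` shuffles whose (N_G, N_S) are nearest (Euclidean) the
    observed values; set the gamma (genes) and sigma (SNP fragments)
    ranges to the min/max over those shuffles, widened to include the
    observed values; the conditioned space is every shuffle with both
    statistics in range, plus the observed sequence; the p-value is the
    fraction of the conditioned space with N >= n (the observed sequence
    contributes to numerator and denominator, so p > 0 always).
    """
    if len(shuffle_set) == 0:
        raise ValueError("empty shuffle set")
    if k_cond > len(shuffle_set):
        raise ValueError(f"k_cond={k_cond} exceeds {len(shuffle_set)} shuffles")
    if not classes:
        raise ValueError("no eQTL classes")
    a, b, gene_ids, snp_bins = _class_arrays(classes)
    n, ng, ns = _counts_for(observed_domains, a, b, gene_ids, snp_bins)
    stats = np.array([_counts_for(d, a, b, gene_ids, snp_bins)
                      for d in shuffle_set.sequences], dtype=np.int64)
    N, NG, NS = stats[:, 0], stats[:, 1], stats[:, 2]
    res = match([[ng, ns]], stats[:, 1:3].astype(float), k=k_cond)
    # widen the matched set to every shuffle tied with the k-th best
    # distance, so the ranges do not depend on solver tie-breaking
    dists = np.hypot(NG - ng, NS - ns)
    best = dists <= res.distance.max()
    gamma = (int(min(NG[best].min(), ng)), int(max(NG[best].max(), ng)))
    sigma = (int(min(NS[best].min(), ns)), int(max(NS[best].max(), ns)))
    in_space = ((NG >= gamma[0]) & (NG <= gamma[1])
                & (NS >= sigma[0]) & (NS <= sigma[1]))
    size = int(in_space.sum()) + 1  # + observed sequence
    n_ge = int((N[in_space] >= n).sum()) + 1  # observed attains N >= n
    return CrossingStats(n=n, n_genes=ng, n_snp_fragments=ns,
                         gamma_range=gamma, sigma_range=sigma,
                         conditioned_space_size=size,
                         p_value=n_ge / size,
                         shuffle_counts=N)


def per_chromosome_correction(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment across chromosomes."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
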