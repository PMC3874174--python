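"""Null sample spaces: random eQTL classes and shuffled domain sequences.

Two resampling nulls back the statistical tests:

* **Random eQTL classes** — synthetic SNP-gene pairs built by resampling
  the observed gene-length and SNP-gene-distance empirical distributions
  and placing the SNP uniformly in the admissible interval, so the random
  set mirrors the observed set's genomic geometry while being blind to
  Hi-C structure.  The space is made ``n_p`` times larger than the
  observed set so that close confounder matches exist.

* **Shuffled domain sequences** — permutations of the observed domain
  tiling that preserve the multiset of domain lengths, the multiset of
  non-domain (gap) lengths, and the alternating domain/non-domain label
  pattern, destroying only the ordering of lengths along the chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .eqtl_mapping import EqtlClass, EqtlGenePair, gene_fragments_of
from .hic_graph import BinnedContactGraph, DomainSequence, total_frequencies

logger = logging.getLogger(__name__)

MAX_SAMPLER_ITERATIONS = 10_000_000


class SamplerExhaustedError(RuntimeError):
    """Target sample-space size not reached within the iteration cap."""


@dataclass
class RandomEqtlSpace:
    """A sampled space of random eQTL equivalence classes.

    Stored columnarly for speed; ``features`` holds (d, g, t_hat, m) in
    the matching schema and ``proximity`` the spatial-proximity values.
    """

    chrom: str
    bin_size: int
    snp_fragment: np.ndarray
    gene_first: np.ndarray
    gene_last: np.ndarray
    features: np.ndarray  # (n, 4): d, g, t_hat, m
    proximity: np.ndarray
    n_p: int
    seed: int | None

    def __len__(self) -> int:
        return len(self.snp_fragment)

    def as_classes(self) -> list[EqtlClass]:
        out = []
        for i in range(len(self)):
            out.append(EqtlClass(
                chrom=self.chrom, snp_fragment=int(self.snp_fragment[i]),
                gene_name=f"rand_{i}",
                gene_fragments=np.arange(self.gene_first[i], self.gene_last[i] + 1),
                bin_size=self.bin_size))
        return out


@dataclass
class ShuffledDomainSet:
    sequences: list[DomainSequence]
    n_d: int
    seed: int | None

    def __len__(self) -> int:
        return len(self.sequences)


def _empirical_draws(pairs: list[EqtlGenePair]):
    """Observed (gene length, SNP-to-boundary distance, downstream flag)."""
    l = np.array([p.gene_end - p.gene_start for p in pairs], dtype=np.int64)
    d = np.empty(len(pairs), dtype=np.int64)
    down = np.empty(len(pairs), dtype=bool)
    for i, p in enumerate(pairs):
        if p.snp_pos >= p.gene_end:  # SNP downstream of the gene
            d[i] = p.snp_pos - p.gene_end
            down[i] = True
        else:
            d[i] = p.gene_start - p.snp_pos
            down[i] = False
    return l, d, down


def sample_random_eqtls(observed: list[EqtlClass], pairs: list[EqtlGenePair],
                        chrom_length: int, graph: BinnedContactGraph,
                        n_p: int = 100, seed: int | None = None,
                        joint: bool = False) -> RandomEqtlSpace:
    """Sample ``n_p * len(observed)`` random eQTL equivalence classes.

    For each draw: a gene length ``l`` and a SNP-gene distance ``d`` are
    resampled (independently unless ``joint``) from the observed pairs,
    the SNP is placed up- or downstream of the gene with the observed
    probability, and the SNP position is uniform over positions for which
    the implied gene fits on the chromosome.  Draws that exactly reproduce
    an observed class (same SNP bin and gene-fragment set) are discarded;
    duplicates *within* the random space are allowed.
    """
    if not observed:
        raise ValueError("observed class list is empty")
    if n_p < 1:
        raise ValueError("n_p must be >= 1")
    l_obs, d_obs, down_obs = _empirical_draws(pairs)
    if np.all(l_obs + d_obs + 1 > chrom_length):
        raise SamplerExhaustedError(
            "chromosome shorter than every observed gene length + distance")
    p_down = float(np.mean(down_obs))
    observed_keys = {(c.snp_fragment, int(c.gene_fragments[0]),
                      int(c.gene_fragments[-1])) for c in observed}
    target = n_p * len(observed)
    rng = np.random.default_rng(seed)
    totals = total_frequencies(graph).t
    bs = graph.bin_size

    snp_bins, g_firsts, g_lasts, snps, gstarts, gends = [], [], [], [], [], []
    n_drawn = 0
    got = 0
    while got < target:
        batch = min(max(2 * (target - got), 1000), 2_000_000)
        if n_drawn + batch > MAX_SAMPLER_ITERATIONS:
            batch = MAX_SAMPLER_ITERATIONS - n_drawn
            if batch <= 0:
                raise SamplerExhaustedError(
                    f"iteration cap {MAX_SAMPLER_ITERATIONS} reached with "
                    f"{got} of {target} classes sampled")
        n_drawn += batch
        idx = rng.integers(0, len(l_obs), size=batch)
        l = l_obs[idx]
        if joint:
            d = d_obs[idx]
            down = down_obs[idx]
        else:
            d = d_obs[rng.integers(0, len(d_obs), size=batch)]
            down = rng.random(batch) < p_down
        span = l + d
        ok = span + 1 <= chrom_length
        l, d, down, span = l[ok], d[ok], down[ok], span[ok]
        # downstream SNP: gene = [s - d - l, s - d), s in [d + l, c)
        # upstream SNP:   gene = [s + d, s + d + l), s in [0, c - d - l)
        width = chrom_length - span
        s = rng.integers(0, np.maximum(width, 1))
        s = np.where(down, s + span, s)
        gs = np.where(down, s - span, s + d)
        ge = gs + l
        sb = s // bs
        gf = gs // bs
        gl = (ge - 1) // bs
        for j in range(len(s)):
            key = (int(sb[j]), int(gf[j]), int(gl[j]))
            if key in observed_keys:
                continue
            snp_bins.append(sb[j]); g_firsts.append(gf[j]); g_lasts.append(gl[j])
            snps.append(s[j]); gstarts.append(gs[j]); gends.append(ge[j])
            got += 1
            if got == target:
                break

    sb = np.array(snp_bins, dtype=np.int64)
    gf = np.array(g_firsts, dtype=np.int64)
    gl = np.array(g_lasts, dtype=np.int64)
    feats = np.empty((target, 4))
    prox = np.empty(target)
    mid_s = (sb + 0.5) * bs
    # closest gene fragment: SNP is outside the gene so it is first or last
    mid_first = (gf + 0.5) * bs
    mid_last = (gl + 0.5) * bs
    d_first = np.abs(mid_first - mid_s)
    d_last = np.abs(mid_last - mid_s)
    feats[:, 0] = np.minimum(d_first, d_last)
    feats[:, 1] = mid_last - mid_first
    feats[:, 2] = totals[sb]
    for i in range(target):
        gbins = slice(gf[i], gl[i] + 1)
        feats[i, 3] = totals[gbins].max()
        prox[i] = graph.freq[sb[i], gbins].max()
    return RandomEqtlSpace(chrom=graph.chrom, bin_size=bs, snp_fragment=sb,
                           gene_first=gf, gene_last=gl, features=feats,
                           proximity=prox, n_p=n_p, seed=seed)


def shuffle_domains(domains: DomainSequence,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> DomainSequence:
    """Shuffle a domain sequence preserving lengths and label pattern.

    The chromosome's alternating domain / non-domain tiling is decomposed
    into two length lists, each list is permuted independently, and the
    tiling is reassembled by traversing the original label sequence and
    drawing lengths from the permuted lists; start positions follow by
    cumulative sum.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tiling = domains.label_intervals()
    dom_lens = [e - s for lab, s, e in tiling if lab == "domain"]
    gap_lens = [e - s for lab, s, e in tiling if lab == "non-domain"]
    dom_perm = list(rng.permutation(dom_lens)) if dom_lens else []
    gap_perm = list(rng.permutation(gap_lens)) if gap_lens else []
    starts, ends = [], []
    cursor = 0
    di = gi = 0
    for lab, _, _ in tiling:
        if lab == "domain":
            length = int(dom_perm[di]); di += 1
            starts.append(cursor)
            ends.append(cursor + length)
        else:
            length = int(gap_perm[gi]); gi += 1
        cursor += length
    return DomainSequence(chrom=domains.chrom, starts=np.array(starts),
                         ends=np.array(ends), chrom_length=domains.chrom_length)


def build_shuffle_set(domains: DomainSequence, n_d: int = 10_000,
                      seed: int | None = None) -> ShuffledDomainSet:
    """``n_d`` independent shuffles with per-sequence seeds derived from
    one master seed, so the whole set is reproducible bit-for-bit."""
    if n_d < 1:
        raise ValueError("n_d must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_d)
    seqs = [shuffle_domains(domains, rng=np.random.default_rng(c))
            for c in children]
    return ShuffledDomainSet(sequences=seqs, n_d=n_d, seed=seed)
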