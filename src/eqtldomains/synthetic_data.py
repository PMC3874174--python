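"""Synthetic chromosomes with controllable planted eQTL-domain structure.

The generator emulates, at desk scale, the data regime the analysis was
designed for: a chromosome tiled by alternating topological domains and
gaps, a binned contact matrix with power-law genomic-distance decay plus
within-domain contact enrichment, genes as non-overlapping intervals, and
distal eQTL-gene pairs.  Three independent planting knobs control the
effects the statistical tests target:

lambda (proximity_planting >= 0)
    SNP placement weight proportional to (1 + f(snp_bin, gene_bin))**lambda;
    0 means placement uniform over admissible positions.
rho (boundary_planting in [0, 1])
    probability that a SNP is re-drawn uniformly among admissible
    positions within 250 kb of a domain boundary.
kappa (crossing_planting in [0, 1])
    probability that the SNP is forced to a position whose SNP-gene
    interval crosses a domain.

``lambda = rho = kappa = 0`` is the global null: eQTL placement is then
independent of both contact structure and domain structure.

Contact counts are Poisson around mu(u, v) = A * (|u - v| + 1)**(-alpha),
multiplied by beta when u and v lie in the same domain (a negative
binomial option adds overdispersion).  Defaults — a 20-Mb chromosome of
500 40-kb bins, ~800-kb domains, 60 genes, 200 eQTLs, alpha = 1,
beta = 5 — give realistic decay, clear domain blocks and boundary
fractions comparable to genome-scale domain calls.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .eqtl_mapping import EqtlGenePair, gene_fragments_of
from .hic_graph import (
    CROSSING,
    BinnedContactGraph,
    DomainSequence,
    write_domains,
    write_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    chrom: str = "chrS"
    chrom_length: int = 20_000_000
    bin_size: int = 40_000
    domain_length_mean: int = 800_000
    domain_length_sd: int = 400_000
    gap_fraction: float = 0.15
    decay_exponent: float = 1.0       # alpha
    within_domain_boost: float = 5.0  # beta
    base_intensity: float = 10.0      # A
    nb_dispersion: float | None = None  # None => Poisson counts
    n_genes: int = 60
    gene_length_mean: int = 60_000
    gene_length_sd: int = 40_000
    n_eqtls: int = 200
    min_snp_gene_dist: int = 50_000
    max_snp_gene_dist: int = 1_000_000
    proximity_planting: float = 0.0   # lambda
    boundary_planting: float = 0.0    # rho
    crossing_planting: float = 0.0    # kappa
    boundary_window: int = 250_000
    allow_gene_overlap: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.domain_length_mean < 2 * self.bin_size:
            raise ValueError("mean domain length must be >= 2 bins")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")
        for name in ("boundary_planting", "crossing_planting"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.proximity_planting < 0:
            raise ValueError("proximity_planting must be >= 0")

    @property
    def is_null(self) -> bool:
        return (self.proximity_planting == 0 and self.boundary_planting == 0
                and self.crossing_planting == 0)


@dataclass
class SyntheticDataset:
    graph: BinnedContactGraph
    domains: DomainSequence
    genes: list[tuple[int, int, str]]  # (start, end, name)
    pairs: list[EqtlGenePair]
    reg_elements: list[tuple[int, int]]
    truth: dict
    config: SyntheticConfig


def _trunc_normal_lengths(rng, n, mean, sd, minimum):
    out = rng.normal(mean, sd, size=n)
    return np.maximum(np.round(out).astype(np.int64), minimum)


def generate_domains(cfg: SyntheticConfig,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> DomainSequence:
    """Alternating domain/gap tiling filling the chromosome.

    Domain lengths are truncated normal (minimum two bins); gap lengths
    are truncated normal with mean set so gaps occupy ``gap_fraction`` of
    the chromosome in expectation; the final interval is truncated at the
    chromosome end.  ``gap_fraction = 0`` tiles the chromosome exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    gap_mean = (cfg.gap_fraction / (1 - cfg.gap_fraction)) * cfg.domain_length_mean
    starts, ends = [], []
    cursor = 0
    while cursor < cfg.chrom_length:
        length = int(_trunc_normal_lengths(rng, 1, cfg.domain_length_mean,
                                           cfg.domain_length_sd,
                                           2 * cfg.bin_size)[0])
        end = min(cursor + length, cfg.chrom_length)
        if end - cursor >= cfg.bin_size:
            starts.append(cursor)
            ends.append(end)
        cursor = end
        if cursor >= cfg.chrom_length:
            break
        if cfg.gap_fraction > 0:
            gap = int(_trunc_normal_lengths(rng, 1, gap_mean, gap_mean / 2,
                                            cfg.bin_size)[0])
            cursor += gap
    return DomainSequence(chrom=cfg.chrom, starts=np.array(starts),
                         ends=np.array(ends), chrom_length=cfg.chrom_length)


def _domain_id_per_bin(domains: DomainSequence, n_bins: int,
                       bin_size: int) -> np.ndarray:
    """Domain index of each bin midpoint, -1 for gap bins."""
    mids = (np.arange(n_bins) + 0.5) * bin_size
    return domains.contains_points(mids)


def generate_contacts(domains: DomainSequence, cfg: SyntheticConfig,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> BinnedContactGraph:
    """Poisson (or negative-binomial) contact matrix with distance decay
    and within-domain enrichment."""
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    n = -(-cfg.chrom_length // cfg.bin_size)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    mu = cfg.base_intensity * np.power(sep + 1.0, -cfg.decay_exponent)
    dom = _domain_id_per_bin(domains, n, cfg.bin_size)
    same = (dom[:, None] == dom[None, :]) & (dom[:, None] >= 0)
    mu = np.where(same, mu * cfg.within_domain_boost, mu)
    if cfg.nb_dispersion is None:
        counts = rng.poisson(mu)
    else:
        r = cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    upper = np.triu(counts)
    freq = upper + np.triu(upper, 1).T
    return BinnedContactGraph(chrom=cfg.chrom, bin_size=cfg.bin_size,
                              chrom_length=cfg.chrom_length,
                              freq=freq.astype(float))


def generate_genes(cfg: SyntheticConfig,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> list[tuple[int, int, str]]:
    """Place ``n_genes`` genes uniformly, non-overlapping by default."""
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    lengths = _trunc_normal_lengths(rng, cfg.n_genes, cfg.gene_length_mean,
                                    cfg.gene_length_sd, 2_000)
    genes: list[tuple[int, int, str]] = []
    taken: list[tuple[int, int]] = []
    for i, l in enumerate(lengths):
        for _ in range(200):
            s = int(rng.integers(0, cfg.chrom_length - l))
            e = int(s + l)
            if cfg.allow_gene_overlap or not any(s < te and e > ts
                                                 for ts, te in taken):
                genes.append((s, e, f"gene{i:03d}"))
                taken.append((s, e))
                break
        else:
            logger.warning("could not place gene %d without overlap", i)
    genes.sort()
    return genes


def _admissible_positions(gene_start, gene_end, cfg) -> list[tuple[int, int]]:
    """Half-open bp intervals where a SNP for this gene may fall."""
    iv = []
    lo = max(0, gene_start - cfg.max_snp_gene_dist)
    hi = gene_start - cfg.min_snp_gene_dist + 1  # inclusive threshold
    if hi > lo:
        iv.append((lo, hi))
    lo = gene_end + cfg.min_snp_gene_dist
    hi = min(cfg.chrom_length, gene_end + cfg.max_snp_gene_dist + 1)
    if hi > lo:
        iv.append((lo, hi))
    return iv


def _sample_uniform(intervals, rng, size) -> np.ndarray:
    widths = np.array([e - s for s, e in intervals], dtype=np.int64)
    total = widths.sum()
    u = rng.integers(0, total, size=size)
    edges = np.cumsum(widths)
    which = np.searchsorted(edges, u, side="right")
    offset = u - np.concatenate([[0], edges])[which]
    starts = np.array([s for s, _ in intervals])
    return starts[which] + offset


def generate_eqtls(domains: DomainSequence, genes, graph: BinnedContactGraph,
                   cfg: SyntheticConfig,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> list[EqtlGenePair]:
    """Generate eQTL-gene pairs with the configured planted preferences.

    Per eQTL: a gene is chosen uniformly; candidate SNP positions are
    sampled uniformly over the admissible set (distal, within
    ``max_snp_gene_dist``, on-chromosome); one candidate is selected with
    weight (1 + f)**lambda; with probability rho the SNP is re-drawn
    uniformly among boundary-proximal candidates, and with probability
    kappa among candidates whose SNP-gene interval crosses a domain.
    Genes with no admissible position are skipped with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    if not genes:
        raise ValueError("no genes to associate eQTLs with")
    bs = cfg.bin_size
    pairs: list[EqtlGenePair] = []
    n_candidates = 200
    attempts = 0
    while len(pairs) < cfg.n_eqtls and attempts < 50 * cfg.n_eqtls:
        attempts += 1
        gs, ge, name = genes[rng.integers(0, len(genes))]
        intervals = _admissible_positions(gs, ge, cfg)
        if not intervals:
            logger.warning("gene %s has no admissible SNP position; skipped",
                           name)
            continue
        cand = _sample_uniform(intervals, rng, n_candidates)
        cbin = cand // bs
        # nearest gene bin per candidate (SNP is outside the gene body)
        gf, gl = gs // bs, (ge - 1) // bs
        near = np.where(cand < gs, gf, gl)
        if cfg.proximity_planting > 0:
            w = np.power(1.0 + graph.freq[cbin, near], cfg.proximity_planting)
            pos = int(cand[rng.choice(n_candidates, p=w / w.sum())])
        else:
            pos = int(cand[rng.integers(0, n_candidates)])
        if cfg.boundary_planting > 0 and rng.random() < cfg.boundary_planting:
            offs = np.abs(domains.signed_boundary_distance(cand))
            sel = np.flatnonzero(offs <= cfg.boundary_window)
            if sel.size:
                pos = int(cand[sel[rng.integers(0, sel.size)]])
        if cfg.crossing_planting > 0 and rng.random() < cfg.crossing_planting:
            mid_c = (cbin + 0.5) * bs
            mid_g = (near + 0.5) * bs
            labels = domains.classify_intervals(np.minimum(mid_c, mid_g),
                                                np.maximum(mid_c, mid_g))
            sel = np.flatnonzero(labels == CROSSING)
            if sel.size == 0:
                continue  # try another gene so kappa=1 yields only crossings
            pos = int(cand[sel[rng.integers(0, sel.size)]])
        pairs.append(EqtlGenePair(cfg.chrom, pos, cfg.chrom, gs, ge, name))
    if len(pairs) < cfg.n_eqtls:
        warnings.warn(f"generated only {len(pairs)} of {cfg.n_eqtls} eQTLs")
    return pairs


def generate_regulatory_elements(pairs: list[EqtlGenePair],
                                 graph: BinnedContactGraph,
                                 cfg: SyntheticConfig,
                                 rng: np.random.Generator | None = None,
                                 seed: int | None = None,
                                 fraction: float = 0.2,
                                 planted: bool = True,
                                 element_length: int = 2_000,
                                 ) -> list[tuple[int, int]]:
    """Short intervals covering a subset of SNP positions.

    With ``planted=True`` the covered subset is the top ``fraction`` of
    SNPs by contact frequency with their nearest gene bin (emulating
    regulatory elements in high-contact loci); otherwise a uniform random
    subset of the same size.
    """
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    if not pairs:
        return []
    bs = graph.bin_size
    snp = np.array([p.snp_pos for p in pairs])
    near = np.array([p.gene_start // bs if p.snp_pos < p.gene_start
                     else (p.gene_end - 1) // bs for p in pairs])
    k = max(1, int(round(fraction * len(pairs))))
    if planted:
        f = graph.freq[snp // bs, near]
        chosen = np.argsort(f, kind="stable")[-k:]
    else:
        chosen = rng.choice(len(pairs), size=k, replace=False)
    half = element_length // 2
    return [(max(0, int(snp[i]) - half),
             min(cfg.chrom_length, int(snp[i]) + half)) for i in chosen]


def generate_dataset(cfg: SyntheticConfig,
                     seed: int | None = None,
                     with_regulatory: bool = False) -> SyntheticDataset:
    """Full synthetic dataset from one master seed.

    Per-component generators draw from independent child streams of the
    master seed, so each stage is individually reproducible.
    """
    master = seed if seed is not None else cfg.seed
    ss = np.random.SeedSequence(master)
    r_dom, r_con, r_gene, r_eqtl, r_reg = (np.random.default_rng(c)
                                           for c in ss.spawn(5))
    domains = generate_domains(cfg, rng=r_dom)
    graph = generate_contacts(domains, cfg, rng=r_con)
    genes = generate_genes(cfg, rng=r_gene)
    pairs = generate_eqtls(domains, genes, graph, cfg, rng=r_eqtl)
    reg = (generate_regulatory_elements(pairs, graph, cfg, rng=r_reg)
           if with_regulatory else [])
    truth = {"seed": master, **{k: v for k, v in asdict(cfg).items()}}
    return SyntheticDataset(graph=graph, domains=domains, genes=genes,
                            pairs=pairs, reg_elements=reg, truth=truth,
                            config=cfg)


# ---------------------------------------------------------------------------
# parameter-recovery estimators (used to validate the generator itself)


def estimate_decay_exponent(graph: BinnedContactGraph,
                            max_separation: int = 100) -> float:
    """Estimate alpha by regressing log mean contact on log(separation + 1).

    Intended for beta = 1 matrices, where the mean depends on separation
    only.
    """
    n = graph.n_bins
    seps = np.arange(1, min(max_separation, n - 1) + 1)
    means = np.array([np.mean(np.diagonal(graph.freq, k)) for k in seps])
    ok = means > 0
    slope = np.polyfit(np.log(seps[ok] + 1.0), np.log(means[ok]), 1)[0]
    return float(-slope)


def estimate_domain_boost(graph: BinnedContactGraph, domains: DomainSequence,
                          max_separation: int = 10) -> float:
    """Estimate beta from within- vs cross-domain mean contacts at fixed
    bin separation, averaged over separations with both strata present."""
    dom = _domain_id_per_bin(domains, graph.n_bins, graph.bin_size)
    ratios = []
    for k in range(1, max_separation + 1):
        diag = np.diagonal(graph.freq, k)
        a, b = dom[:-k], dom[k:]
        within = (a == b) & (a >= 0)
        cross = ~within
        if within.sum() >= 20 and cross.sum() >= 20:
            mc = diag[cross].mean()
            if mc > 0:
                ratios.append(diag[within].mean() / mc)
    if not ratios:
        raise ValueError("no separation stratum with both within- and "
                         "cross-domain pairs")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# deterministic hand-checkable fixture


def _fixture_freq(n_bins: int, domains: DomainSequence,
                  bin_size: int) -> np.ndarray:
    """Deterministic contact rule: f(u, v) = max(0, 8 - |u - v|) plus 4
    when both bin midpoints fall in the same domain."""
    idx = np.arange(n_bins)
    sep = np.abs(idx[:, None] - idx[None, :])
    freq = np.maximum(0, 8 - sep).astype(float)
    dom = _domain_id_per_bin(domains, n_bins, bin_size)
    same = (dom[:, None] == dom[None, :]) & (dom[:, None] >= 0)
    return freq + 4.0 * same


def fixture_small() -> SyntheticDataset:
    """Deterministic 50-bin dataset with hand-checkable values.

    2-Mb chromosome, 40-kb bins, three domains, five genes, nine eQTL
    pairs covering every crossing label, a multi-gene SNP fragment and a
    duplicate-SNP equivalence class.  Identical on every call.
    """
    cfg = SyntheticConfig(chrom="chrF", chrom_length=2_000_000,
                          bin_size=40_000, n_genes=5, n_eqtls=9, seed=0)
    domains = DomainSequence(
        chrom="chrF",
        starts=np.array([200_000, 680_000, 1_400_000]),
        ends=np.array([600_000, 1_200_000, 1_800_000]),
        chrom_length=2_000_000)
    freq = _fixture_freq(50, domains, 40_000)
    graph = BinnedContactGraph(chrom="chrF", bin_size=40_000,
                               chrom_length=2_000_000, freq=freq)
    genes = [
        (400_000, 480_000, "geneA"),      # bins 10-11, inside domain 0
        (800_000, 900_000, "geneB"),      # bins 20-22, inside domain 1
        (1_300_000, 1_360_000, "geneE"),  # bins 32-33, inside the gap
        (1_440_000, 1_500_000, "geneC"),  # bins 36-37, inside domain 2
        (1_840_000, 1_880_000, "geneD"),  # bin 46, past the last domain
    ]
    gmap = {name: (s, e) for s, e, name in genes}
    mk = lambda pos, name: EqtlGenePair("chrF", pos, "chrF",
                                        gmap[name][0], gmap[name][1], name)
    pairs = [
        mk(250_000, "geneA"),    # bin 6; within domain 0
        mk(255_000, "geneA"),    # same bin + gene => same class
        mk(250_000, "geneB"),    # bin 6 -> geneB crosses domain boundary
        mk(340_000, "geneA"),    # bin 8, 60 kb upstream of geneA; within
        mk(1_250_000, "geneE"),  # bin 31; interval inside the gap
        mk(1_600_000, "geneC"),  # bin 40; within domain 2
        mk(1_950_000, "geneD"),  # bin 48; entirely past the last domain
        mk(1_700_000, "geneD"),  # bin 42; crosses domain-2 end
        mk(700_000, "geneA"),    # bin 17; crosses boundary at 600/680 kb
    ]
    reg = [(240_000, 242_000)]  # covers bin 6
    truth = {"seed": 0, "fixture": "small", "planted": "none"}
    return SyntheticDataset(graph=graph, domains=domains, genes=genes,
                            pairs=pairs, reg_elements=reg, truth=truth,
                            config=cfg)


# ---------------------------------------------------------------------------
# on-disk emission in the pipeline's input dialects


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write matrix, domains, eQTL table, regulatory BED and truth JSON."""
    from pathlib import Path

    from .eqtl_mapping import write_eqtl_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": str(out / f"{ds.graph.chrom}.matrix.txt"),
        "domains": str(out / f"{ds.graph.chrom}.domains.bed"),
        "eqtls": str(out / f"{ds.graph.chrom}.eqtls.tsv"),
        "truth": str(out / f"{ds.graph.chrom}.truth.json"),
    }
    write_matrix(ds.graph, paths["matrix"])
    write_domains(ds.domains, paths["domains"])
    write_eqtl_table(ds.pairs, paths["eqtls"])
    if ds.reg_elements:
        paths["regulatory"] = str(out / f"{ds.graph.chrom}.regulatory.bed")
        pd.DataFrame([(ds.graph.chrom, s, e) for s, e in ds.reg_elements]
                     ).to_csv(paths["regulatory"], sep="\t", header=False,
                              index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=2, default=str)
    return paths
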