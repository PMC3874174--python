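"""Per-chromosome analysis orchestration and machine-readable reports.

``run_chromosome_data`` sequences the full analysis for one chromosome —
filter pairs, build equivalence classes, compute properties, generate
both null spaces, run the matched-proximity, boundary and crossing tests
— and returns a JSON-serialisable block.  ``run_genome`` runs every
chromosome present in the eQTL table, isolates per-chromosome failures,
and BH-adjusts the crossing p-values across chromosomes.

One master seed derives per-stage seeds through ``numpy``'s
``SeedSequence`` spawning, so any stage can be re-run in isolation and
the whole report is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossing_stats import conditioned_pvalue, crossing_counts, \
    per_chromosome_correction
from .eqtl_mapping import (
    attach_properties,
    build_classes,
    classes_to_table,
    classify_many,
    filter_pairs,
    multi_gene_partition,
    read_eqtl_table,
    regulatory_subset,
)
from .hic_graph import CROSSING, NON_DOMAIN_GAP, WITHIN_DOMAIN, load_domains, \
    load_matrix, total_frequencies
from .null_models import build_shuffle_set, sample_random_eqtls
from .proximity_stats import (
    boundary_window_enrichment,
    proximity_matched_test,
    regulatory_proximity_test,
    size_stratified_boundary_test,
    total_frequency_ranksum,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    matrix: dict = field(default_factory=dict)   # chrom -> path
    domains: dict = field(default_factory=dict)  # chrom -> path
    eqtls: str = ""
    regulatory: str | None = None
    chrom_lengths: dict = field(default_factory=dict)
    bin_size: int = 40_000
    min_dist: int = 50_000
    n_p: int = 100
    n_d: int = 10_000
    k_match: int = 1
    k_cond: int = 100
    window: int = 250_000
    proximity_bin_edges: tuple = (0.0, 1.0, 5.0, 10.0, 30.0)
    sizes: tuple = (500_000, 1_000_000, 2_000_000)
    size_tolerance: float = 0.2
    size_n_bins: int = 10
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name in ("n_p", "n_d", "k_match", "k_cond"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("proximity_bin_edges", "sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_seeds(master: int, chrom: str) -> dict[str, int]:
    """Deterministic per-stage child seeds for one chromosome."""
    chrom_key = int(hashlib.sha256(chrom.encode()).hexdigest()[:8], 16) % (2 ** 31)
    base = np.random.SeedSequence([master, chrom_key])
    names = ("random_eqtls", "shuffles")
    states = [int(c.generate_state(1)[0] % (2 ** 31)) for c in base.spawn(len(names))]
    return dict(zip(names, states))


def run_chromosome_data(graph, domains, pairs, reg_elements, cfg: RunConfig,
                        seed_override: int | None = None) -> dict:
    """Full analysis for one chromosome on in-memory inputs."""
    seeds = _stage_seeds(cfg.seed if seed_override is None else seed_override,
                         graph.chrom)
    totals = total_frequencies(graph)
    filtered = filter_pairs(pairs, min_dist=cfg.min_dist)
    classes = attach_properties(build_classes(filtered, graph), graph, totals)
    if not classes:
        raise ValueError(f"{graph.chrom}: no equivalence classes after filtering")
    labels = classify_many(classes, domains)
    label_counts = {lab: int((labels == lab).sum())
                    for lab in (CROSSING, WITHIN_DOMAIN, NON_DOMAIN_GAP)}

    logger.info("%s: %d pairs -> %d filtered -> %d classes", graph.chrom,
                len(pairs), len(filtered), len(classes))

    # null spaces
    space = sample_random_eqtls(classes, filtered, graph.chrom_length, graph,
                                n_p=cfg.n_p, seed=seeds["random_eqtls"])
    shuffles = build_shuffle_set(domains, n_d=cfg.n_d, seed=seeds["shuffles"])

    # matched proximity tests on all classes and the crossing subsets
    prox = {}
    for subset in ("all", "crossing", "noncrossing"):
        try:
            t = proximity_matched_test(classes, space, subset=subset,
                                       domains=domains,
                                       proximity_bin_edges=cfg.proximity_bin_edges)
            prox[subset] = {
                "n_pairs": t.n_pairs, "statistic": t.statistic,
                "p_value": t.p_value, "direction": t.direction,
                "per_bin_counts": t.per_bin_counts,
                "match_quality": [None if np.isnan(r) else float(r)
                                  for r in t.match_quality],
            }
        except ValueError as exc:
            prox[subset] = {"error": str(exc)}

    # total-frequency rank sums: eQTL bins vs all, boundary bins vs all,
    # eQTL-and-boundary bins vs eQTL bins
    snp_bins = np.unique([c.snp_fragment for c in classes])
    bnd_bins = np.unique(domains.boundaries // graph.bin_size)
    bnd_bins = bnd_bins[bnd_bins < graph.n_bins]
    all_t = totals.t
    eqtl_t = totals.t[snp_bins]
    ranksums = {
        "eqtl_vs_all": total_frequency_ranksum(eqtl_t, all_t),
        "boundary_vs_all": total_frequency_ranksum(totals.t[bnd_bins], all_t),
    }
    both = np.intersect1d(snp_bins, bnd_bins)
    ranksums["eqtl_boundary_vs_eqtl"] = (
        total_frequency_ranksum(totals.t[both], eqtl_t) if both.size else None)

    frac, bp = boundary_window_enrichment(classes, domains, shuffles,
                                          window=cfg.window)
    size_tests = [
        {"size": r.size, "n_domains": r.n_domains, "n_snps": r.n_snps,
         "chi2": r.chi2, "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni,
         "underpowered": r.underpowered}
        for r in size_stratified_boundary_test(
            classes, domains, sizes=cfg.sizes, tolerance=cfg.size_tolerance,
            n_bins=cfg.size_n_bins)
    ]

    cross = conditioned_pvalue(classes, domains, shuffles, k_cond=cfg.k_cond)
    partition = multi_gene_partition(classes, domains)

    reg_block = None
    if reg_elements:
        reg_cls = regulatory_subset(classes, reg_elements,
                                    min_dist=cfg.min_dist)
        reg_ids = {id(c) for c in reg_cls}
        noncross = [c for c, lab in zip(classes, labels) if lab != CROSSING]
        reg_nc = [c for c in noncross if id(c) in reg_ids]
        other_nc = [c for c in noncross if id(c) not in reg_ids]
        reg_block = {"n_regulatory_classes": len(reg_cls),
                     "n_noncrossing_regulatory": len(reg_nc)}
        if reg_nc and other_nc:
            reg_block["p_value"] = regulatory_proximity_test(reg_nc, other_nc)

    return {
        "chrom": graph.chrom,
        "seeds": seeds,
        "counts": {
            "pairs_raw": len(pairs), "pairs_filtered": len(filtered),
            "classes": len(classes), **label_counts,
        },
        "crossing": {
            "n": cross.n, "n_genes": cross.n_genes,
            "n_snp_fragments": cross.n_snp_fragments,
            "gamma_range": list(cross.gamma_range),
            "sigma_range": list(cross.sigma_range),
            "conditioned_space_size": cross.conditioned_space_size,
            "p_value": cross.p_value,
        },
        "proximity": prox,
        "ranksums": ranksums,
        "boundary_window": {"window": cfg.window, "fraction_within": frac,
                            "empirical_p": bp},
        "size_stratified": size_tests,
        "multi_gene_partition": partition,
        "regulatory": reg_block,
    }


def run_chromosome(cfg: RunConfig, chrom: str) -> dict:
    """Load inputs for ``chrom`` from the configured paths and analyse."""
    length = cfg.chrom_lengths.get(chrom)
    graph = load_matrix(cfg.matrix[chrom], bin_size=cfg.bin_size, chrom=chrom,
                        chrom_length=length)
    domains = load_domains(cfg.domains[chrom], chrom_length=graph.chrom_length,
                           chrom=chrom)
    pairs = [p for p in read_eqtl_table(cfg.eqtls) if p.snp_chrom == chrom]
    reg = None
    if cfg.regulatory:
        bed = pd.read_csv(cfg.regulatory, sep="\t", header=None,
                          usecols=[0, 1, 2], names=["chrom", "start", "end"])
        reg = [(int(r.start), int(r.end)) for r in
               bed[bed["chrom"] == chrom].itertuples(index=False)]
    return run_chromosome_data(graph, domains, pairs, reg, cfg)


def run_genome(cfg: RunConfig) -> dict:
    """Analyse every configured chromosome and BH-correct crossing
    p-values across chromosomes; failures are isolated per chromosome."""
    chroms = sorted(cfg.matrix)
    blocks, failures = {}, {}
    for chrom in chroms:
        try:
            blocks[chrom] = run_chromosome(cfg, chrom)
        except Exception as exc:  # noqa: BLE001 - isolate and report
            logger.error("%s failed: %s", chrom, exc)
            failures[chrom] = str(exc)
    ok = [c for c in chroms if c in blocks]
    if ok:
        adjusted = per_chromosome_correction(
            [blocks[c]["crossing"]["p_value"] for c in ok])
        for c, adj in zip(ok, adjusted):
            blocks[c]["crossing"]["p_adjusted"] = float(adj)
    return {
        "provenance": {"version": __version__, "seed": cfg.seed,
                       "config_hash": cfg.config_hash()},
        "chromosomes": blocks,
        "failures": failures,
    }


# ---------------------------------------------------------------------------
# minimal structural schema validation for reports

REPORT_SCHEMA = {
    "provenance": {"version": str, "seed": int, "config_hash": str},
    "chromosomes": dict,
    "failures": dict,
}

BLOCK_SCHEMA = {
    "chrom": str,
    "counts": dict,
    "crossing": dict,
    "proximity": dict,
    "ranksums": dict,
    "boundary_window": dict,
    "size_stratified": list,
    "multi_gene_partition": dict,
}


def validate_report(report: dict) -> None:
    """Raise ValueError when the report deviates from the shipped schema."""
    def check(obj, schema, where):
        for key, expected in schema.items():
            if key not in obj:
                raise ValueError(f"report missing {where}.{key}")
            if isinstance(expected, dict):
                if not isinstance(obj[key], dict):
                    raise ValueError(f"{where}.{key} must be an object")
                if any(isinstance(v, type) for v in expected.values()):
                    check(obj[key], expected, f"{where}.{key}")
            elif not isinstance(obj[key], expected):
                raise ValueError(f"{where}.{key} has type "
                                 f"{type(obj[key]).__name__}")

    check(report, REPORT_SCHEMA, "report")
    for chrom, block in report["chromosomes"].items():
        check(block, BLOCK_SCHEMA, f"chromosomes.{chrom}")


def write_report(report: dict, path) -> None:
    validate_report(report)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
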