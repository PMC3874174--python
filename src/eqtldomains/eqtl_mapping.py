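"""eQTL-gene pairs, equivalence classes and per-class properties.

A distal eQTL is a SNP associated with the expression of a gene at least
50 kb away.  At Hi-C resolution, all SNPs falling in one 40-kb bin that
target the same gene are indistinguishable, so pairs are collapsed into
*equivalence classes* keyed by (SNP bin, gene name).  Each class carries
five properties used as confounders and test statistics downstream:

d      SNP-gene distance: |midpoint(SNP bin) - midpoint(closest gene bin)|
g      gene length: midpoint(last gene bin) - midpoint(first gene bin)
m      maximum total frequency t(v) over bins overlapping the gene
t_hat  total frequency t(s) of the SNP bin
p      spatial proximity: max contact frequency between the SNP bin and
       any gene bin (0 when no contact exists)

The *SNP-gene interval* spans from the SNP-bin midpoint to the midpoint
of the closest gene bin; a class whose interval overlaps a domain without
being contained in it *crosses* that domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hic_graph import (
    CROSSING,
    NON_DOMAIN_GAP,
    WITHIN_DOMAIN,
    BinnedContactGraph,
    DomainSequence,
    DomainValidationError,
    FragmentTotals,
)

logger = logging.getLogger(__name__)

MIN_SNP_GENE_DIST = 50_000


@dataclass
class EqtlGenePair:
    """One SNP paired with the gene whose expression it associates with."""

    snp_chrom: str
    snp_pos: int
    gene_chrom: str
    gene_start: int
    gene_end: int
    gene_name: str

    def __post_init__(self) -> None:
        if self.gene_start >= self.gene_end:
            raise ValueError(f"{self.gene_name}: gene_start >= gene_end")
        if self.snp_pos < 0 or self.gene_start < 0:
            raise ValueError("negative coordinates")


@dataclass
class PropertyVector:
    d: float
    g: float
    m: float
    t_hat: float
    p: float

    def as_array(self) -> np.ndarray:
        """Feature order used for matching: (d, g, t_hat, m)."""
        return np.array([self.d, self.g, self.t_hat, self.m])


@dataclass
class EqtlClass:
    """Equivalence class of eQTL-gene pairs sharing one SNP bin and gene."""

    chrom: str
    snp_fragment: int
    gene_name: str
    gene_fragments: np.ndarray  # contiguous bin indices overlapping the gene
    bin_size: int
    members: list = field(default_factory=list)
    properties: PropertyVector | None = None

    def __post_init__(self) -> None:
        self.gene_fragments = np.asarray(self.gene_fragments, dtype=np.int64)
        if self.gene_fragments.size == 0:
            raise ValueError("gene_fragments is empty")

    def midpoint_snp(self) -> float:
        return (self.snp_fragment + 0.5) * self.bin_size

    def closest_gene_fragment(self) -> int:
        """Gene bin whose midpoint is nearest the SNP bin midpoint.

        Ties are broken toward the lower bin index.
        """
        mids = (self.gene_fragments + 0.5) * self.bin_size
        return int(self.gene_fragments[np.argmin(np.abs(mids - self.midpoint_snp()))])

    def snp_gene_interval(self) -> tuple[float, float]:
        """Closed [a, b] from SNP-bin midpoint to closest-gene-bin midpoint."""
        a = self.midpoint_snp()
        b = (self.closest_gene_fragment() + 0.5) * self.bin_size
        return (min(a, b), max(a, b))


# ---------------------------------------------------------------------------
# table I/O

EQTL_COLUMNS = ["snp_chrom", "snp_pos", "gene_chrom", "gene_start", "gene_end",
                "gene_name"]


def read_eqtl_table(path) -> list[EqtlGenePair]:
    """Read a headered TSV of eQTL-gene pairs (0-based bp coordinates)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EQTL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [EqtlGenePair(r.snp_chrom, int(r.snp_pos), r.gene_chrom,
                         int(r.gene_start), int(r.gene_end), r.gene_name)
            for r in df.itertuples(index=False)]


def write_eqtl_table(pairs: list[EqtlGenePair], path) -> None:
    pd.DataFrame([[p.snp_chrom, p.snp_pos, p.gene_chrom, p.gene_start,
                   p.gene_end, p.gene_name] for p in pairs],
                 columns=EQTL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering and class construction


def pair_gene_distance(pair: EqtlGenePair) -> int:
    """Distance from the SNP position to the nearest gene boundary (bp).

    This is the quantity thresholded by the distal filter; it is distinct
    from the class property d, which is measured between bin midpoints.
    """
    return min(abs(pair.snp_pos - pair.gene_start),
               abs(pair.snp_pos - pair.gene_end))


def filter_pairs(pairs: list[EqtlGenePair],
                 min_dist: int = MIN_SNP_GENE_DIST) -> list[EqtlGenePair]:
    """Keep intra-chromosomal pairs with a distal SNP.

    A pair survives when the SNP and gene share a chromosome, the SNP lies
    outside the gene body, and the SNP is at least ``min_dist`` (inclusive)
    from the nearest gene boundary.  Dropped records are counted by reason
    and logged.
    """
    kept: list[EqtlGenePair] = []
    drops = {"interchromosomal": 0, "snp_in_gene": 0, "too_close": 0}
    for p in pairs:
        if p.snp_chrom != p.gene_chrom:
            drops["interchromosomal"] += 1
        elif p.gene_start <= p.snp_pos < p.gene_end:
            drops["snp_in_gene"] += 1
        elif pair_gene_distance(p) < min_dist:
            drops["too_close"] += 1
        else:
            kept.append(p)
    logger.info("filter_pairs: kept %d of %d (dropped %s)",
                len(kept), len(pairs), drops)
    return kept


def gene_fragments_of(gene_start: int, gene_end: int, bin_size: int) -> np.ndarray:
    """All bin indices overlapping the half-open gene interval."""
    return np.arange(gene_start // bin_size, (gene_end - 1) // bin_size + 1)


def build_classes(pairs: list[EqtlGenePair],
                  graph: BinnedContactGraph) -> list[EqtlClass]:
    """Collapse pairs into equivalence classes keyed by (SNP bin, gene name).

    Gene names must map to a unique interval; names carrying conflicting
    intervals are dropped entirely with a warning.  A gene extending past
    the chromosome end is a validation error.
    """
    gene_iv: dict[str, tuple[int, int]] = {}
    conflicted: set[str] = set()
    for p in pairs:
        iv = (p.gene_start, p.gene_end)
        if gene_iv.setdefault(p.gene_name, iv) != iv:
            conflicted.add(p.gene_name)
    if conflicted:
        logger.warning("dropping %d gene(s) with conflicting intervals: %s",
                       len(conflicted), sorted(conflicted)[:5])

    groups: dict[tuple[int, str], list[EqtlGenePair]] = {}
    for p in pairs:
        if p.gene_name in conflicted:
            continue
        if p.gene_end > graph.chrom_length:
            raise DomainValidationError(
                f"gene {p.gene_name} ends at {p.gene_end} beyond chromosome "
                f"length {graph.chrom_length}")
        key = (int(p.snp_pos // graph.bin_size), p.gene_name)
        groups.setdefault(key, []).append(p)

    classes = []
    for (snp_bin, gene_name), members in sorted(groups.items()):
        g0, g1 = gene_iv[gene_name]
        classes.append(EqtlClass(
            chrom=graph.chrom, snp_fragment=snp_bin, gene_name=gene_name,
            gene_fragments=gene_fragments_of(g0, g1, graph.bin_size),
            bin_size=graph.bin_size, members=members))
    return classes


def compute_properties(cls: EqtlClass, graph: BinnedContactGraph,
                       totals: FragmentTotals) -> PropertyVector:
    """Compute the five-property vector (d, g, m, t_hat, p) of a class."""
    gf = cls.gene_fragments
    mid_snp = cls.midpoint_snp()
    mids = (gf + 0.5) * cls.bin_size
    d = float(np.min(np.abs(mids - mid_snp)))
    g = float(mids[-1] - mids[0])
    m = float(np.max(totals.t[gf]))
    t_hat = float(totals.t[cls.snp_fragment])
    p = float(np.max(graph.freq[cls.snp_fragment, gf]))
    return PropertyVector(d=d, g=g, m=m, t_hat=t_hat, p=p)


def attach_properties(classes: list[EqtlClass], graph: BinnedContactGraph,
                      totals: FragmentTotals) -> list[EqtlClass]:
    for c in classes:
        c.properties = compute_properties(c, graph, totals)
    return classes


# ---------------------------------------------------------------------------
# domain-relative classification


def classify_crossing(cls: EqtlClass, domains: DomainSequence) -> str:
    """Label a class {crossing, within_domain, non_domain_gap}."""
    a, b = cls.snp_gene_interval()
    return str(domains.classify_intervals([a], [b])[0])


def classify_many(classes: list[EqtlClass], domains: DomainSequence) -> np.ndarray:
    """Vectorised crossing labels for a list of classes."""
    if not classes:
        return np.array([], dtype=object)
    ab = np.array([c.snp_gene_interval() for c in classes])
    return domains.classify_intervals(ab[:, 0], ab[:, 1])


def boundary_offset(cls: EqtlClass, domains: DomainSequence) -> float:
    """Signed bp distance from the SNP-bin midpoint to the nearest
    domain boundary: positive inside a domain, negative outside."""
    if len(domains) == 0:
        raise DomainValidationError("empty domain sequence")
    return float(domains.signed_boundary_distance([cls.midpoint_snp()])[0])


def multi_gene_partition(classes: list[EqtlClass],
                         domains: DomainSequence) -> dict[str, int]:
    """Crossing exclusivity of SNP fragments targeting >= 2 distinct genes.

    Within-domain and gap classes are merged as non-crossing.  Returns
    counts {exclusively_crossing, exclusively_noncrossing, both} summing to
    the number of multi-gene SNP fragments.
    """
    labels = classify_many(classes, domains)
    by_snp: dict[int, list[bool]] = {}
    genes_by_snp: dict[int, set[str]] = {}
    for c, lab in zip(classes, labels):
        by_snp.setdefault(c.snp_fragment, []).append(lab == CROSSING)
        genes_by_snp.setdefault(c.snp_fragment, set()).add(c.gene_name)
    counts = {"exclusively_crossing": 0, "exclusively_noncrossing": 0, "both": 0}
    for snp, flags in by_snp.items():
        if len(genes_by_snp[snp]) < 2:
            continue
        if all(flags):
            counts["exclusively_crossing"] += 1
        elif not any(flags):
            counts["exclusively_noncrossing"] += 1
        else:
            counts["both"] += 1
    return counts


def regulatory_subset(classes: list[EqtlClass], reg_elements,
                      min_dist: int = MIN_SNP_GENE_DIST) -> list[EqtlClass]:
    """Classes whose SNP bin overlaps a regulatory element.

    ``reg_elements`` is a list of (start, end) bp intervals.  Members are
    restricted to those passing the distal filter at ``min_dist``; classes
    with no surviving members are dropped.
    """
    if not classes:
        return []
    reg = np.asarray(list(reg_elements), dtype=np.int64).reshape(-1, 2)
    out = []
    for c in classes:
        bs, be = c.snp_fragment * c.bin_size, (c.snp_fragment + 1) * c.bin_size
        if not np.any((reg[:, 0] < be) & (reg[:, 1] > bs)):
            continue
        members = [m for m in c.members if pair_gene_distance(m) >= min_dist]
        if c.members and not members:
            continue
        out.append(c)
    return out


def classes_to_table(classes: list[EqtlClass], graph: BinnedContactGraph,
                     totals: FragmentTotals,
                     domains: DomainSequence | None = None) -> pd.DataFrame:
    """Flat per-class table (TSV-ready) with properties and domain labels."""
    rows = []
    labels = (classify_many(classes, domains) if domains is not None
              else [None] * len(classes))
    for c, lab in zip(classes, labels):
        pv = c.properties or compute_properties(c, graph, totals)
        rows.append({
            "chrom": c.chrom, "snp_fragment": c.snp_fragment,
            "gene_name": c.gene_name, "n_members": len(c.members),
            "d": pv.d, "g": pv.g, "m": pv.m, "t_hat": pv.t_hat, "p": pv.p,
            "crossing_label": lab,
            "boundary_offset": (boundary_offset(c, domains)
                                if domains is not None and len(domains) else None),
        })
    return pd.DataFrame(rows)
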