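"""Binned Hi-C contact graphs and topological-domain sequences.

A chromosome's intra-chromosomal Hi-C contacts are represented as a
symmetric, non-negative matrix over fixed-width bins (default 40 kb),
the node unit at which all downstream eQTL analysis operates.  Domain
calls are ordered, non-overlapping ``[start, end)`` intervals that induce
an alternating domain / non-domain labelling of the chromosome.

Coordinates are 0-based, half-open throughout.  A position ``pos`` maps
to bin ``pos // bin_size``; the midpoint of bin ``v`` is
``(v + 0.5) * bin_size``.  Self-contacts ``f(v, v)`` are retained and
contribute once to the per-bin total frequency ``t(v)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 40_000

#: crossing labels used throughout the package
CROSSING = "crossing"
WITHIN_DOMAIN = "within_domain"
NON_DOMAIN_GAP = "non_domain_gap"


class ContactInputError(ValueError):
    """A read-pair or record falls outside the declared chromosome."""


class MatrixFormatError(ValueError):
    """A dense matrix file is not a valid symmetric contact matrix."""


class DomainValidationError(ValueError):
    """Domain intervals overlap or exceed the chromosome."""


@dataclass
class BinnedContactGraph:
    """Symmetric binned contact-frequency matrix for one chromosome."""

    chrom: str
    bin_size: int
    chrom_length: int
    freq: np.ndarray  # dense (n_bins, n_bins), symmetric, >= 0

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[0] != self.freq.shape[1]:
            raise MatrixFormatError("contact matrix must be square")
        expected = -(-self.chrom_length // self.bin_size)  # ceil division
        if self.freq.shape[0] != expected:
            raise MatrixFormatError(
                f"matrix has {self.freq.shape[0]} bins, expected {expected} "
                f"for chrom_length={self.chrom_length}, bin_size={self.bin_size}"
            )
        if np.any(self.freq < 0):
            raise MatrixFormatError("negative contact frequencies")
        if not np.allclose(self.freq, self.freq.T):
            raise MatrixFormatError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.freq.shape[0]

    def midpoint(self, v) -> np.ndarray | float:
        """Genomic midpoint of bin ``v`` (bp)."""
        return (np.asarray(v) + 0.5) * self.bin_size

    def bin_of(self, pos) -> np.ndarray | int:
        return np.asarray(pos) // self.bin_size

    @property
    def flagged_bins(self) -> np.ndarray:
        """Bins with zero total frequency (unmappable / uncovered regions)."""
        return np.flatnonzero(self.freq.sum(axis=0) == 0)


@dataclass
class FragmentTotals:
    """Per-bin total contact frequency t(v) = sum_u f(u, v)."""

    t: np.ndarray

    def __getitem__(self, v):
        return self.t[v]


@dataclass
class DomainSequence:
    """Ordered non-overlapping topological-domain intervals on one chromosome."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    chrom_length: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        order = np.argsort(self.starts, kind="stable")
        self.starts = self.starts[order]
        self.ends = self.ends[order]
        if np.any(self.starts >= self.ends):
            raise DomainValidationError("domain with start >= end")
        if np.any(self.starts < 0) or np.any(self.ends > self.chrom_length):
            raise DomainValidationError("domain interval outside chromosome")
        if len(self.starts) > 1:
            bad = np.flatnonzero(self.starts[1:] < self.ends[:-1])
            if bad.size:
                i = bad[0]
                raise DomainValidationError(
                    f"overlapping domains: "
                    f"[{self.starts[i]}, {self.ends[i]}) and "
                    f"[{self.starts[i + 1]}, {self.ends[i + 1]})"
                )

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def boundaries(self) -> np.ndarray:
        """All domain start and end coordinates, sorted."""
        return np.sort(np.concatenate([self.starts, self.ends]))

    def label_intervals(self) -> list[tuple[str, int, int]]:
        """Alternating (label, start, end) tiling of the whole chromosome.

        Leading and trailing segments outside any domain are non-domain
        intervals; zero-length segments are omitted.
        """
        out: list[tuple[str, int, int]] = []
        cursor = 0
        for s, e in zip(self.starts, self.ends):
            if s > cursor:
                out.append(("non-domain", cursor, int(s)))
            out.append(("domain", int(s), int(e)))
            cursor = int(e)
        if cursor < self.chrom_length:
            out.append(("non-domain", cursor, self.chrom_length))
        return out

    def gap_lengths(self) -> np.ndarray:
        return np.array(
            [e - s for lab, s, e in self.label_intervals() if lab == "non-domain"],
            dtype=np.int64,
        )

    # -- vectorised geometry used by the eQTL classifiers -------------------

    def contains_points(self, points) -> np.ndarray:
        """Index of the domain containing each point (-1 if in a gap)."""
        pts = np.asarray(points, dtype=float)
        idx = np.searchsorted(self.starts, pts, side="right") - 1
        ok = (idx >= 0) & (pts < self.ends[np.clip(idx, 0, None)])
        return np.where(ok, idx, -1)

    def classify_intervals(self, a, b) -> np.ndarray:
        """Label closed intervals [a, b] against the domain tiling.

        Returns an array of {crossing, within_domain, non_domain_gap}.
        An interval is *within_domain* when some domain [s, e) satisfies
        s <= a and b <= e (an endpoint exactly on a boundary coordinate
        counts as contained); *crossing* when it overlaps a domain
        (a < e and b > s, strictly) without being contained; otherwise it
        lies entirely in a non-domain gap.
        """
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        # containment: candidate domain is the last with start <= a
        idx = np.searchsorted(self.starts, a, side="right") - 1
        contained = (idx >= 0) & (b <= self.ends[np.clip(idx, 0, None)])
        # overlap: any domain with start < b and end > a; domains are sorted
        # and disjoint so ends are sorted too
        j = np.searchsorted(self.starts, b, side="left")
        overlaps = (j > 0) & (self.ends[np.clip(j - 1, 0, None)] > a)
        labels = np.where(
            contained, WITHIN_DOMAIN, np.where(overlaps, CROSSING, NON_DOMAIN_GAP)
        )
        return labels

    def signed_boundary_distance(self, points) -> np.ndarray:
        """Signed distance from each point to its nearest boundary coordinate.

        Positive inside a domain, negative outside, zero on a boundary.
        """
        pts = np.asarray(points, dtype=float)
        bnd = self.boundaries
        pos = np.searchsorted(bnd, pts)
        left = np.where(pos > 0, np.abs(pts - bnd[np.clip(pos - 1, 0, None)]), np.inf)
        right = np.where(
            pos < len(bnd), np.abs(bnd[np.clip(pos, 0, len(bnd) - 1)] - pts), np.inf
        )
        dist = np.minimum(left, right)
        inside = self.contains_points(pts) >= 0
        sign = np.where(dist == 0, 0.0, np.where(inside, 1.0, -1.0))
        return sign * dist


def bin_contacts(
    read_pairs,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_length: int | None = None,
    chrom: str = "chr",
) -> BinnedContactGraph:
    """Bin intra-chromosomal read-pair positions into a contact graph.

    ``read_pairs`` is an iterable of (pos1, pos2) bp positions.  Each pair
    increments f(u, v) for the bins u, v of its two positions; a pair with
    both ends in one bin increments the diagonal once.
    """
    pairs = np.asarray(list(read_pairs), dtype=np.int64).reshape(-1, 2)
    if chrom_length is None:
        raise ValueError("chrom_length is required")
    if pairs.size:
        bad = np.flatnonzero((pairs < 0).any(axis=1) | (pairs >= chrom_length).any(axis=1))
        if bad.size:
            i = bad[0]
            raise ContactInputError(
                f"read pair #{i} ({pairs[i, 0]}, {pairs[i, 1]}) outside "
                f"[0, {chrom_length})"
            )
    n_bins = -(-chrom_length // bin_size)
    freq = np.zeros((n_bins, n_bins))
    if pairs.size:
        b = pairs // bin_size
        lo = np.minimum(b[:, 0], b[:, 1])
        hi = np.maximum(b[:, 0], b[:, 1])
        np.add.at(freq, (lo, hi), 1.0)
        freq = freq + np.triu(freq, 1).T
    return BinnedContactGraph(chrom=chrom, bin_size=bin_size,
                              chrom_length=chrom_length, freq=freq)


def load_matrix(
    path,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom: str = "chr",
    chrom_length: int | None = None,
) -> BinnedContactGraph:
    """Load a whitespace-separated dense N x N contact matrix.

    Asymmetric input is symmetrised as (A + A.T) / 2 with a warning;
    negative or non-finite entries and non-square shapes are rejected.
    """
    A = np.loadtxt(path, ndmin=2)
    if A.shape[0] != A.shape[1]:
        raise MatrixFormatError(f"{path}: matrix is {A.shape[0]}x{A.shape[1]}, not square")
    if not np.all(np.isfinite(A)):
        raise MatrixFormatError(f"{path}: non-finite entries")
    if np.any(A < 0):
        raise MatrixFormatError(f"{path}: negative entries")
    if not np.allclose(A, A.T):
        warnings.warn(f"{path}: asymmetric matrix symmetrised as (A + A.T)/2")
        A = (A + A.T) / 2.0
    n = A.shape[0]
    if chrom_length is None:
        chrom_length = n * bin_size
    return BinnedContactGraph(chrom=chrom, bin_size=bin_size,
                              chrom_length=chrom_length, freq=A)


def write_matrix(graph: BinnedContactGraph, path) -> None:
    np.savetxt(path, graph.freq, fmt="%.10g")


def total_frequencies(graph: BinnedContactGraph) -> FragmentTotals:
    """t(v) = sum_u f(u, v), the self-contact counted once."""
    return FragmentTotals(t=graph.freq.sum(axis=0))


def load_domains(path, chrom_length: int, chrom: str | None = None) -> DomainSequence:
    """Load BED3 (chrom, start, end; 0-based half-open) domain calls."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    if chrom is not None:
        df = df[df["chrom"] == chrom]
        label = chrom
    else:
        uniq = df["chrom"].unique()
        if len(uniq) != 1:
            raise DomainValidationError(
                f"{path}: multiple chromosomes {list(uniq)}; pass chrom= to select one"
            )
        label = uniq[0]
    return DomainSequence(chrom=label,
                          starts=df["start"].to_numpy(),
                          ends=df["end"].to_numpy(),
                          chrom_length=chrom_length)


def write_domains(domains: DomainSequence, path) -> None:
    pd.DataFrame({"chrom": domains.chrom,
                  "start": domains.starts,
                  "end": domains.ends}).to_csv(path, sep="\t",
                                               header=False, index=False)
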