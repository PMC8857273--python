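"""Scanner for the class-A flexible DNA pattern with indel-tolerant gaps.

The pattern is a series of fixed literals (default TT ... G ... T ... TT,
i.e. periodic repeats of Ts roughly one helical turn apart) separated by
non-conserved regions of nominal length whose realised length may deviate
by a bounded number of insertions/deletions.  The default spec is
``TTxxxGxxxTxxxxxxxxxxTT`` with at most one indel in each of the first
two gaps and at most two in the third; each gap carries its own budget.

Matching is exact on the literals (N never matches), every feasible start
position is reported once per strand, and the lexicographically smallest
feasible gap realisation is recorded for that start.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from silencerscope.genome_io import GeneModel, reverse_complement


@dataclass
class FlexPatternSpec:
    """Literal blocks and gap-length tolerances of a flexible pattern."""

    literal_blocks: list[str] = field(
        default_factory=lambda: ["TT", "G", "T", "TT"]
    )
    gap_lengths: list[int] = field(default_factory=lambda: [3, 3, 10])
    gap_tolerances: list[int] = field(default_factory=lambda: [1, 1, 2])

    def __post_init__(self) -> None:
        if len(self.gap_lengths) != len(self.literal_blocks) - 1:
            raise ValueError("need one gap per adjacent literal pair")
        if len(self.gap_tolerances) != len(self.gap_lengths):
            raise ValueError("one tolerance per gap required")
        for blk in self.literal_blocks:
            if not blk or set(blk) - set("ACGT"):
                raise ValueError(f"literal block {blk!r} must be non-empty ACGT")
        for g, t in zip(self.gap_lengths, self.gap_tolerances):
            if t < 0 or g < t:
                raise ValueError("tolerances must satisfy 0 <= tol <= nominal")

    @property
    def literal_length(self) -> int:
        return sum(len(b) for b in self.literal_blocks)

    def gap_choices(self) -> list[tuple[int, ...]]:
        """All feasible gap-length combinations, lexicographic order."""
        ranges = [
            range(g - t, g + t + 1)
            for g, t in zip(self.gap_lengths, self.gap_tolerances)
        ]
        return list(itertools.product(*ranges))

    def span_range(self) -> tuple[int, int]:
        lit = self.literal_length
        lo = lit + sum(g - t for g, t in zip(self.gap_lengths, self.gap_tolerances))
        hi = lit + sum(g + t for g, t in zip(self.gap_lengths, self.gap_tolerances))
        return lo, hi


@dataclass
class MotifMatch:
    """One occurrence of the pattern (coordinates on the forward axis)."""

    replicon_id: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    strand: str
    gap_realization: tuple[int, ...]

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def _literal_offsets(
    spec: FlexPatternSpec, gaps: Sequence[int]
) -> list[tuple[int, str]]:
    """(offset, literal) pairs for one gap realisation, offsets from start."""
    out = []
    pos = 0
    for i, blk in enumerate(spec.literal_blocks):
        out.append((pos, blk))
        pos += len(blk)
        if i < len(gaps):
            pos += gaps[i]
    return out


def _scan_one_strand(seq: str, spec: FlexPatternSpec) -> dict[int, tuple[int, ...]]:
    """Map of 0-based start -> smallest feasible gap realisation.

    Vectorised: for each gap combination the match condition is a
    conjunction of shifted base-equality arrays; combinations are applied
    in lexicographic order so the first hit at a start is the smallest.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    base_masks = {b: arr == ord(b) for b in "ACGT"}
    found: dict[int, tuple[int, ...]] = {}
    for gaps in spec.gap_choices():
        offsets = _literal_offsets(spec, gaps)
        span = offsets[-1][0] + len(offsets[-1][1])
        limit = n - span + 1
        if limit <= 0:
            continue
        ok = np.ones(limit, dtype=bool)
        for off, blk in offsets:
            for j, b in enumerate(blk):
                ok &= base_masks[b][off + j : off + j + limit]
                if not ok.any():
                    break
            else:
                continue
            break
        for start in np.flatnonzero(ok):
            found.setdefault(int(start), tuple(gaps))
    return found


def scan_flexible(
    seq: str,
    spec: FlexPatternSpec | None = None,
    strand_mode: str = "both",
    replicon_id: str = "",
) -> list[MotifMatch]:
    """Scan a sequence for the flexible pattern.

    ``strand_mode`` is "forward" or "both".  Minus-strand matches are
    found by scanning the reverse complement and reporting coordinates on
    the forward axis.  Matches may overlap; each (start, strand) is
    reported once.
    """
    spec = spec or FlexPatternSpec()
    if strand_mode not in ("forward", "both"):
        raise ValueError("strand_mode must be 'forward' or 'both'")
    seq = seq.upper()
    matches: list[MotifMatch] = []
    lit = spec.literal_length
    for start, gaps in sorted(_scan_one_strand(seq, spec).items()):
        span = lit + sum(gaps)
        matches.append(
            MotifMatch(replicon_id, start + 1, start + span, "+", gaps)
        )
    if strand_mode == "both":
        n = len(seq)
        rc = reverse_complement(seq)
        for start, gaps in sorted(_scan_one_strand(rc, spec).items()):
            span = lit + sum(gaps)
            # map the rc interval back to forward-axis coordinates
            fwd_start = n - (start + span) + 1
            matches.append(
                MotifMatch(replicon_id, fwd_start, fwd_start + span - 1, "-", gaps)
            )
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


def count_in_regions(
    matches: Iterable[MotifMatch],
    regions: Sequence[tuple[int, int]],
) -> list[int]:
    """Count matches whose midpoint lies in each [start, end] region.

    Midpoints are real-valued (half-integers for even spans) and compared
    without rounding.
    """
    mids = sorted(m.midpoint for m in matches)
    counts = []
    for lo, hi in regions:
        if lo > hi:
            raise ValueError(f"invalid region [{lo}, {hi}]")
        i = int(np.searchsorted(mids, lo, side="left"))
        j = int(np.searchsorted(mids, hi, side="right"))
        counts.append(j - i)
    return counts


def motif_gene_distances(
    matches: Sequence[MotifMatch],
    genes: Sequence[GeneModel],
    upstream_bound: int = 500,
    coding_bound: int = 2000,
) -> list[tuple[str, float]]:
    """Signed motif-to-gene-start distances, strand-oriented.

    Distance = motif midpoint minus the first nucleotide of the gene,
    positive into the coding region.  Motifs are kept when the distance
    lies in [-upstream_bound, +coding_bound]; for genes shorter than
    ``coding_bound`` positive distances beyond the stop codon are dropped
    so that downstream intergenic sequence never contaminates the
    intragenic signal.
    """
    by_rep: dict[str, list[MotifMatch]] = {}
    for m in matches:
        by_rep.setdefault(m.replicon_id, []).append(m)
    out: list[tuple[str, float]] = []
    for gene in genes:
        for m in by_rep.get(gene.replicon_id, []):
            if gene.strand == "+":
                dist = m.midpoint - gene.start
            else:
                dist = gene.end - m.midpoint
            if not (-upstream_bound <= dist <= coding_bound):
                continue
            if dist > 0 and dist > gene.length - 1:
                continue  # downstream intergenic region of a short gene
            out.append((gene.gene_id, dist))
    return out


def positional_density(
    distances: Sequence[float],
    bandwidth: float | None = None,
    grid_range: tuple[float, float] = (-500.0, 2000.0),
    n_grid: int = 501,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of motif/summit positions relative to gene
    starts, evaluated on a fixed grid.

    Bandwidth defaults to Silverman's rule (scipy's ``silverman``); a
    positive float overrides it as an absolute bandwidth in bp.
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 distances for a density estimate")
    if bandwidth is None:
        kde = gaussian_kde(x, bw_method="silverman")
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        kde = gaussian_kde(x, bw_method=bandwidth / x.std(ddof=1))
    grid = np.linspace(*grid_range, n_grid)
    dens = kde(grid)
    # renormalise over the analysis window so the curve is a proper
    # probability density on the grid regardless of edge mass loss
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("degenerate density (no mass on the grid)")
    return grid, dens / area
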