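"""ChIP-seq peak consolidation and target-gene assignment.

Peaks called per condition/replicate are merged by single-linkage
clustering of summit positions (summits closer than a threshold get the
same peak id), classified as shared or condition-specific, and assigned
to target genes whose regulation window (default -500..+100 bp around
the start codon) contains a consensus summit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from silencerscope.genome_io import GeneModel, Genome, RegionSeq

CONDITIONS = ("FC", "BC")  # free-living cells / bacteroid cells


@dataclass
class PeakRecord:
    """One called peak from one sample (condition x replicate)."""

    replicon_id: str
    summit: int  # 1-based
    enrichment_fold: float
    q_value: float
    condition: str
    replicate: str = "combined"

    def __post_init__(self) -> None:
        if self.enrichment_fold <= 0:
            raise ValueError("enrichment_fold must be positive")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError("q_value must lie in [0, 1]")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")


@dataclass
class MergedPeak:
    """A consolidated peak: all sample peaks linked by summit proximity."""

    peak_id: str
    replicon_id: str
    consensus_summit: int
    members: list[PeakRecord] = field(default_factory=list)
    per_condition_enrichment: dict[str, float] = field(default_factory=dict)
    shared_flag: str = "shared"  # shared | FC_only | BC_only

    @property
    def max_enrichment(self) -> float:
        return max(self.per_condition_enrichment.values())


@dataclass
class TargetAssignment:
    """A (gene, peak) pair with the summit inside the regulation window."""

    gene_id: str
    peak_id: str
    summit_offset: int  # bp relative to start codon; negative = upstream


def _consensus_summit(summits: Sequence[int]) -> int:
    """Median summit; for even counts take the lower middle (leftmost)."""
    s = sorted(summits)
    return s[(len(s) - 1) // 2]


def merge_peaks(
    peak_sets: Iterable[Iterable[PeakRecord]],
    max_summit_distance: int = 200,
    genome: Genome | None = None,
) -> list[MergedPeak]:
    """Single-linkage merge of peak records across samples.

    Two peaks on the same replicon are linked when their summit distance
    is strictly below ``max_summit_distance``; linkage is transitive.
    The consensus summit is the median member summit (ties -> smaller
    coordinate) and per-condition enrichment is the maximum member fold
    for that condition.  The result is independent of input order.
    """
    if max_summit_distance < 0:
        raise ValueError("max_summit_distance must be >= 0")
    records = [p for ps in peak_sets for p in ps]
    if genome is not None:
        for p in records:
            if p.replicon_id not in genome:
                raise ValueError(f"peak on unknown replicon {p.replicon_id!r}")
            if not (1 <= p.summit <= len(genome[p.replicon_id])):
                raise ValueError(
                    f"summit {p.summit} out of bounds on {p.replicon_id!r}"
                )
    records.sort(key=lambda p: (p.replicon_id, p.summit, p.condition, p.replicate))

    merged: list[MergedPeak] = []
    chain: list[PeakRecord] = []

    def _flush() -> None:
        if not chain:
            return
        conds = sorted({p.condition for p in chain})
        per_cond = {
            c: max(p.enrichment_fold for p in chain if p.condition == c)
            for c in conds
        }
        flag = "shared" if len(conds) == 2 else f"{conds[0]}_only"
        merged.append(
            MergedPeak(
                peak_id="",  # assigned after the full pass, in genomic order
                replicon_id=chain[0].replicon_id,
                consensus_summit=_consensus_summit([p.summit for p in chain]),
                members=list(chain),
                per_condition_enrichment=per_cond,
                shared_flag=flag,
            )
        )
        chain.clear()

    for rec in records:
        if (
            chain
            and rec.replicon_id == chain[-1].replicon_id
            and rec.summit - chain[-1].summit < max_summit_distance
        ):
            chain.append(rec)
        else:
            _flush()
            chain.append(rec)
    _flush()

    width = max(4, len(str(len(merged))))
    for i, mp in enumerate(merged, start=1):
        mp.peak_id = f"peak_{i:0{width}d}"
    return merged


def central_region(
    peak: MergedPeak, genome: Genome, width: int = 200
) -> RegionSeq:
    """Forward-strand window of ``width`` bp centred on the summit.

    The window is [summit - width/2 + 1, summit + width/2]; windows that
    would run off a replicon end are truncated and flagged.
    """
    if width < 2 or width % 2:
        raise ValueError("width must be even and >= 2")
    rep = genome[peak.replicon_id]
    if not (1 <= peak.consensus_summit <= len(rep)):
        raise ValueError(
            f"summit {peak.consensus_summit} out of bounds on "
            f"{peak.replicon_id!r}"
        )
    lo = peak.consensus_summit - width // 2 + 1
    hi = peak.consensus_summit + width // 2
    trunc = lo < 1 or hi > len(rep)
    lo, hi = max(1, lo), min(len(rep), hi)
    return RegionSeq(
        replicon_id=peak.replicon_id,
        start=lo,
        end=hi,
        sequence=rep.sequence[lo - 1 : hi],
        truncated=trunc,
    )


def regulation_window(
    gene: GeneModel, upstream: int = 500, downstream: int = 100
) -> tuple[int, int]:
    """Forward-axis regulation window around the start codon, inclusive.

    For a '+' gene with start s the window is [s - upstream, s + downstream];
    for a '-' gene (start codon at its end coordinate e) it is
    [e - downstream, e + upstream].  Windows may extend past position 1;
    callers clip when intersecting with actual coordinates.
    """
    if gene.strand == "+":
        return gene.start - upstream, gene.start + downstream
    return gene.end - downstream, gene.end + upstream


def assign_targets(
    peaks: Sequence[MergedPeak],
    genes: Sequence[GeneModel],
    upstream: int = 500,
    downstream: int = 100,
) -> list[TargetAssignment]:
    """Assign each merged peak to every gene whose regulation window
    contains its consensus summit.

    A peak may target several genes (divergent promoters) and a gene may
    carry several peaks.  ``summit_offset`` is signed, strand-oriented:
    negative = upstream of the start codon, and always lies in
    [-upstream, +downstream].
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be non-negative")
    by_rep: dict[str, list[MergedPeak]] = {}
    for p in peaks:
        by_rep.setdefault(p.replicon_id, []).append(p)
    for ps in by_rep.values():
        ps.sort(key=lambda p: p.consensus_summit)

    out: list[TargetAssignment] = []
    for gene in genes:
        ps = by_rep.get(gene.replicon_id)
        if not ps:
            continue
        lo, hi = regulation_window(gene, upstream, downstream)
        summits = [p.consensus_summit for p in ps]
        i = int(np.searchsorted(summits, lo, side="left"))
        j = int(np.searchsorted(summits, hi, side="right"))
        for p in ps[i:j]:
            if gene.strand == "+":
                offset = p.consensus_summit - gene.start
            else:
                offset = gene.end - p.consensus_summit
            out.append(
                TargetAssignment(
                    gene_id=gene.gene_id, peak_id=p.peak_id, summit_offset=offset
                )
            )
    return out


def classify_condition_specific(
    peaks: Sequence[MergedPeak], low_fold_threshold: float = 5.0
) -> dict[str, int]:
    """Count shared vs condition-specific merged peaks.

    Among condition-specific peaks, also count those whose (single)
    enrichment fold is below ``low_fold_threshold`` — condition-specific
    binding is typically weak.
    """
    shared = sum(1 for p in peaks if p.shared_flag == "shared")
    specific = [p for p in peaks if p.shared_flag != "shared"]
    low = sum(1 for p in specific if p.max_enrichment < low_fold_threshold)
    return {
        "total": len(peaks),
        "shared": shared,
        "condition_specific": len(specific),
        "condition_specific_low_fold": low,
    }


# --------------------------------------------------------------------------
# tabular I/O

PEAK_COLUMNS = [
    "replicon_id",
    "summit",
    "enrichment_fold",
    "q_value",
    "condition",
    "replicate",
]


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a TSV of peak records (columns as in ``PEAK_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate": str})
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns {sorted(missing)}")
    return [
        PeakRecord(
            replicon_id=str(r.replicon_id),
            summit=int(r.summit),
            enrichment_fold=float(r.enrichment_fold),
            q_value=float(r.q_value),
            condition=str(r.condition),
            replicate=str(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


def read_narrowpeak_summits(
    narrowpeak_path: str | Path, condition: str, replicate: str = "combined"
) -> list[PeakRecord]:
    """Read MACS2 narrowPeak (0-based half-open; summit offset in col 10).

    Coordinates are converted to the 1-based summit convention used here.
    """
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "signalValue", "pValue", "qValue", "peak",
    ]
    df = pd.read_csv(narrowpeak_path, sep="\t", header=None, names=cols)
    out = []
    for r in df.itertuples(index=False):
        summit = int(r.start) + int(r.peak) + 1  # 0-based -> 1-based
        q = 10 ** (-float(r.qValue)) if r.qValue >= 0 else 1.0
        out.append(
            PeakRecord(
                replicon_id=str(r.chrom),
                summit=summit,
                enrichment_fold=float(r.signalValue),
                q_value=min(1.0, q),
                condition=condition,
                replicate=replicate,
            )
        )
    return out


def merged_peaks_frame(peaks: Sequence[MergedPeak]) -> pd.DataFrame:
    rows = []
    for p in peaks:
        rows.append(
            {
                "peak_id": p.peak_id,
                "replicon_id": p.replicon_id,
                "consensus_summit": p.consensus_summit,
                "n_members": len(p.members),
                "shared_flag": p.shared_flag,
                "fold_FC": p.per_condition_enrichment.get("FC", np.nan),
                "fold_BC": p.per_condition_enrichment.get("BC", np.nan),
                "max_fold": p.max_enrichment,
            }
        )
    return pd.DataFrame(rows)


def assignments_frame(assignments: Sequence[TargetAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": a.gene_id, "peak_id": a.peak_id,
             "summit_offset": a.summit_offset}
            for a in assignments
        ]
    )
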