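"""Promoter element prediction and spacer composition analysis.

Position-specific scoring matrices (PSSMs) for the -35 and -10 elements
of a sigma factor are built from aligned training sites, the genome is
scanned on both strands for element pairs whose spacer length falls in
the sigma factor's allowed range, hits are classified intergenic vs
intragenic, and spacer AT% is compared between hits associated with
target vs non-target genes.  AT-rich spacers enhance RNA-polymerase
engagement, so silencer targets are expected to carry hotter spacers.

Spacer-length defaults per sigma factor are explicit configuration, not
literature values: RpoD 15-19 bp, RpoN 4-6 bp (between its -24/-12-style
elements), the remaining factors 14-20 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from silencerscope.composition import at_percent
from silencerscope.genome_io import GeneModel, Genome, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SIGMA_LABELS = ("RpoD", "RpoH1", "RpoH2", "RpoE2", "RpoN", "custom")
DEFAULT_SPACER_RANGES: dict[str, tuple[int, int]] = {
    "RpoD": (15, 19),
    "RpoH1": (14, 20),
    "RpoH2": (14, 20),
    "RpoE2": (14, 20),
    "RpoN": (4, 6),
    "custom": (14, 20),
}


def build_pssm(
    aligned_sites: Sequence[str],
    pseudocount: float = 0.5,
    background: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Log-odds PSSM (4 x w) from equal-length aligned ACGT sites.

    Column probability = (count + pseudocount) / (n + 4 * pseudocount);
    score = log2(probability / background).  Rows are A, C, G, T.
    """
    if len(aligned_sites) < 2:
        raise ValueError("need at least 2 training sites")
    w = len(aligned_sites[0])
    for s in aligned_sites:
        if len(s) != w:
            raise ValueError("training sites must have equal length")
        if set(s.upper()) - set(BASES):
            raise ValueError(f"non-ACGT symbol in training site {s!r}")
    bg = background or {b: 0.25 for b in BASES}
    n = len(aligned_sites)
    counts = np.zeros((4, w))
    for s in aligned_sites:
        for j, b in enumerate(s.upper()):
            counts[_BASE_INDEX[b], j] += 1
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg_col = np.array([bg[b] for b in BASES])[:, None]
    return np.log2(probs / bg_col)


def score_sites(pssm: np.ndarray, sites: Sequence[str]) -> np.ndarray:
    """PSSM score of each site (must match matrix width)."""
    w = pssm.shape[1]
    out = np.empty(len(sites))
    for i, s in enumerate(sites):
        if len(s) != w:
            raise ValueError("site length does not match matrix width")
        out[i] = sum(pssm[_BASE_INDEX[b], j] for j, b in enumerate(s.upper()))
    return out


@dataclass
class PromoterModel:
    """Paired -35/-10 scoring model for one sigma factor."""

    sigma_label: str
    pssm_35: np.ndarray
    pssm_10: np.ndarray
    spacer_range: tuple[int, int]
    threshold_35: float
    threshold_10: float

    def __post_init__(self) -> None:
        if self.sigma_label not in SIGMA_LABELS:
            raise ValueError(f"unknown sigma label {self.sigma_label!r}")
        if self.spacer_range[0] > self.spacer_range[1]:
            raise ValueError("invalid spacer_range")

    @classmethod
    def from_training_sites(
        cls,
        sigma_label: str,
        sites_35: Sequence[str],
        sites_10: Sequence[str],
        spacer_range: tuple[int, int] | None = None,
        score_percentile: float = 90.0,
        pseudocount: float = 0.5,
        background: Mapping[str, float] | None = None,
    ) -> "PromoterModel":
        """Build both PSSMs and set per-element thresholds at a percentile
        of the training sites' own scores (default: 90th)."""
        pssm_35 = build_pssm(sites_35, pseudocount, background)
        pssm_10 = build_pssm(sites_10, pseudocount, background)
        thr_35 = float(np.percentile(score_sites(pssm_35, sites_35), score_percentile))
        thr_10 = float(np.percentile(score_sites(pssm_10, sites_10), score_percentile))
        if spacer_range is None:
            spacer_range = DEFAULT_SPACER_RANGES[sigma_label]
        return cls(sigma_label, pssm_35, pssm_10, spacer_range, thr_35, thr_10)


@dataclass
class PromoterHit:
    """A paired -35/-10 hit with its spacer, on forward-axis coordinates."""

    replicon_id: str
    strand: str
    pos_35: tuple[int, int]  # 1-based inclusive interval
    pos_10: tuple[int, int]
    spacer_seq: str
    spacer_at: float
    score_35: float
    score_10: float
    sigma_label: str
    context: str = "unclassified"  # intergenic | intragenic
    associated_gene: str | None = None


def _scan_strand_scores(seq_idx: np.ndarray, pssm: np.ndarray) -> np.ndarray:
    """Score every window of the matrix width along an index-encoded
    sequence (N encoded as 4 scores -inf)."""
    w = pssm.shape[1]
    n = len(seq_idx) - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.vstack([pssm, np.full((1, w), -np.inf)])
    scores = np.zeros(n)
    for j in range(w):
        scores += padded[seq_idx[j : j + n], j]
    return scores


_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_paired(genome: Genome, model: PromoterModel) -> list[PromoterHit]:
    """Scan both strands for -35/-10 element pairs within spacer range.

    On each strand, every position scoring at or above the per-element
    threshold is an element hit; a promoter hit is a -35 hit followed
    downstream (in strand orientation) by a -10 hit with a spacer whose
    length lies in the model's range.  All overlapping pairs are
    reported.  Coordinates are reported on the forward axis; the spacer
    sequence is strand-oriented.
    """
    lo_sp, hi_sp = model.spacer_range
    if lo_sp < 0 or lo_sp > hi_sp:
        raise ValueError("invalid spacer_range")
    w35, w10 = model.pssm_35.shape[1], model.pssm_10.shape[1]
    hits: list[PromoterHit] = []
    for rep in genome.values():
        n = len(rep)
        for strand in "+-":
            seq = rep.sequence if strand == "+" else reverse_complement(rep.sequence)
            idx = _encode(seq)
            s35 = _scan_strand_scores(idx, model.pssm_35)
            s10 = _scan_strand_scores(idx, model.pssm_10)
            pos35 = np.flatnonzero(s35 >= model.threshold_35)
            good10 = s10 >= model.threshold_10
            for p35 in pos35:  # 0-based on the strand-oriented sequence
                for sp in range(lo_sp, hi_sp + 1):
                    p10 = p35 + w35 + sp
                    if p10 + w10 > n or not good10[p10]:
                        continue
                    spacer = seq[p35 + w35 : p10]
                    if strand == "+":
                        iv35 = (p35 + 1, p35 + w35)
                        iv10 = (p10 + 1, p10 + w10)
                    else:
                        iv35 = (n - (p35 + w35) + 1, n - p35)
                        iv10 = (n - (p10 + w10) + 1, n - p10)
                    hits.append(
                        PromoterHit(
                            replicon_id=rep.id,
                            strand=strand,
                            pos_35=iv35,
                            pos_10=iv10,
                            spacer_seq=spacer,
                            spacer_at=at_percent(spacer) if spacer else float("nan"),
                            score_35=float(s35[p35]),
                            score_10=float(s10[p10]),
                            sigma_label=model.sigma_label,
                        )
                    )
    hits.sort(key=lambda h: (h.replicon_id, h.pos_35, h.strand))
    return hits


def classify_context(
    hits: Sequence[PromoterHit],
    genes: Sequence[GeneModel],
    association_window: int = 500,
) -> list[PromoterHit]:
    """Label hits intergenic/intragenic and associate a downstream gene.

    A hit is intragenic iff the 3' end of its -10 element lies inside any
    gene body (either strand); the associated gene is the nearest gene
    start downstream on the hit strand within ``association_window`` bp.
    Hits are modified in place and returned.
    """
    trees: dict[str, IntervalTree] = {}
    starts: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for g in genes:
        trees.setdefault(g.replicon_id, IntervalTree()).addi(
            g.start, g.end + 1, g.gene_id
        )
        starts.setdefault((g.replicon_id, g.strand), []).append(
            (g.start_codon_pos, g.gene_id)
        )
    for key in starts:
        starts[key].sort()

    for h in hits:
        three_prime = h.pos_10[1] if h.strand == "+" else h.pos_10[0]
        tree = trees.get(h.replicon_id)
        h.context = (
            "intragenic" if tree is not None and tree.overlaps(three_prime)
            else "intergenic"
        )
        cand = starts.get((h.replicon_id, h.strand), [])
        h.associated_gene = None
        best = None
        for pos, gid in cand:
            dist = pos - three_prime if h.strand == "+" else three_prime - pos
            if 0 <= dist <= association_window and (best is None or dist < best[0]):
                best = (dist, gid)
        if best is not None:
            h.associated_gene = best[1]
    return list(hits)


def spacer_at_comparison(
    hits: Sequence[PromoterHit], target_gene_ids: set[str]
) -> pd.DataFrame:
    """Welch t-test of spacer AT% between target- and non-target-associated
    hits, per (sigma factor, context) stratum.

    Returns one row per stratum with group means, standard errors, group
    sizes, t and p.  Strata with fewer than 2 hits in either group are
    skipped (flagged in the ``skipped`` column of a sentinel row-free
    result; they simply do not appear).
    """
    rows = []
    df = pd.DataFrame(
        [
            {
                "sigma": h.sigma_label,
                "context": h.context,
                "spacer_at": h.spacer_at,
                "is_target": h.associated_gene in target_gene_ids
                if h.associated_gene is not None
                else False,
            }
            for h in hits
            if h.associated_gene is not None and not np.isnan(h.spacer_at)
        ]
    )
    if df.empty:
        return pd.DataFrame(
            columns=["sigma", "context", "n_target", "n_nontarget",
                     "mean_target", "mean_nontarget", "se_target",
                     "se_nontarget", "t_stat", "p_value"]
        )
    for (sigma, context), grp in df.groupby(["sigma", "context"]):
        tgt = grp.loc[grp.is_target, "spacer_at"].to_numpy()
        non = grp.loc[~grp.is_target, "spacer_at"].to_numpy()
        if len(tgt) < 2 or len(non) < 2:
            continue
        t, p = stats.ttest_ind(tgt, non, equal_var=False)
        rows.append(
            {
                "sigma": sigma,
                "context": context,
                "n_target": len(tgt),
                "n_nontarget": len(non),
                "mean_target": float(tgt.mean()),
                "mean_nontarget": float(non.mean()),
                "se_target": float(tgt.std(ddof=1) / np.sqrt(len(tgt))),
                "se_nontarget": float(non.std(ddof=1) / np.sqrt(len(non))),
                "t_stat": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
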