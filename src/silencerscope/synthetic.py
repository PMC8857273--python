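"""Synthetic multi-replicon genomes with planted silencer-targetome structure.

The generator emulates the statistical structure the analysis pipeline
assumes in a GC-rich multipartite bacterial genome:

* replicons of differing GC% with AT-rich islands (horizontally acquired
  sequence is AT-rich relative to the backbone);
* genes in four hierarchical conservation subsets with subset-dependent
  GC% (genus core GC-richest, strain-specific genes markedly AT-rich)
  and island genes forced strain-specific;
* a flexible T-repeat binding motif planted at elevated density inside
  islands and at a background rate elsewhere;
* ChIP peaks whose enrichment fold follows
  ``fold = max(1 + eps, b0 + b_at * AT% + b_motif * motifs + b_ta * z + N(0, sigma))``
  computed on the true 200-bp central region, with ``z`` an optional
  per-peak TpA-step planting intensity;
* shared vs condition-specific peaks (specific ones attenuated, hence
  mostly weak);
* lognormal expression with subset-decreasing means, a multiplicative
  boost for target genes, and a further up-shift of targets in the
  silencer-mutant condition;
* promoter element pairs planted upstream of target and non-target genes
  with controlled spacer length and AT% (targets hotter by a configured
  shift).

Every planted feature is recorded in a :class:`GroundTruthLedger`
sufficient to recompute the expected value of each pipeline summary
without re-running the generator.  Generation is fully deterministic
given the seed: one root ``SeedSequence`` is spawned into named
per-component streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from silencerscope.composition import at_percent
from silencerscope.genome_io import (
    GeneModel,
    Genome,
    Replicon,
    reverse_complement,
    write_annotation,
    write_genome,
)
from silencerscope.peaks import PeakRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
SUBSETS = ("I", "II", "III", "IV")

_STREAMS = (
    "backbone", "genes", "islands", "motifs", "peaks",
    "expression", "promoters", "clusters",
)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    # (id, length bp, GC%): chromosome + chromid + symbiosis plasmid,
    # GC%s of a rhizobial genome; lengths scaled to about a third of the
    # real multipartite genome so the default peak set covers roughly the
    # same fraction of genes as in the study (~20% of genes targeted)
    replicons: list[tuple[str, int, float]] = field(
        default_factory=lambda: [
            ("chromosome", 1_000_000, 62.0),
            ("chromid", 700_000, 61.0),
            ("symbiosis_plasmid", 500_000, 59.0),
        ]
    )
    gene_length_range: tuple[int, int] = (600, 1500)
    intergenic_range: tuple[int, int] = (120, 400)
    subset_proportions: tuple[float, float, float, float] = (0.45, 0.15, 0.10, 0.30)
    # GC offset (points) of gene sequence vs replicon backbone, I..IV
    subset_gc_offsets: tuple[float, float, float, float] = (2.0, 0.0, -3.0, -9.0)
    n_islands_per_replicon: int = 6
    island_length: int = 3000
    island_gc_delta: float = -18.0
    island_motif_per_kb: float = 0.8
    background_motif_per_kb: float = 0.06
    # peak model
    n_peaks: int = 500
    gene_peak_fraction: float = 0.6  # peaks placed in gene regulation regions
    min_peak_spacing: int = 400
    beta0: float = -12.0
    beta_at: float = 0.4  # fold per AT point
    beta_motif: float = 2.0  # fold per planted motif in the central region
    beta_ta: float = 7.0  # fold per unit of TpA usage deviation above 1
    sigma: float = 2.0
    fold_floor_eps: float = 0.01
    max_extra_ta: int = 25  # TpA steps planted in a region at z = 1
    motif_in_peak_prob: float = 0.5
    motif_in_peak_mean: float = 1.2  # Poisson mean when planting
    shared_fraction: float = 0.646  # share of peaks present in both conditions
    # condition-specific binding is weak: attenuation chosen so the large
    # majority of specific peaks fall below fold 5
    specific_attenuation: float = 0.25
    # relative propensity of subsets I..IV to receive a peak: the
    # silencer is drawn to AT-rich, poorly conserved (foreign) genes
    subset_target_weights: tuple[float, float, float, float] = (0.6, 0.9, 1.2, 2.4)
    condition_jitter_sd: float = 0.05  # lognormal sd of per-condition fold jitter
    summit_jitter: int = 30  # bp between the FC and BC summit of a shared peak
    # expression model
    subset_expr_means: tuple[float, float, float, float] = (100.0, 70.0, 50.0, 30.0)
    expr_sigma: float = 0.7  # lognormal sigma (log-space)
    target_boost: float = 1.6
    mutant_shift: float = 1.8
    conditions: tuple[str, str] = ("wild_type", "mucr_mutant")
    # promoters
    sigma_factors: tuple[str, ...] = ("RpoD",)
    consensus_35: str = "TTGACA"
    consensus_10: str = "TATAAT"
    n_training_sites: int = 40
    training_mut_rate: float = 0.12
    n_promoters: int = 200
    spacer_length: int = 17
    spacer_at_target: float = 72.0
    spacer_at_nontarget: float = 64.0
    promoter_gap: int = 20  # bp between -10 3' end and the start codon
    # pangenome strain universe: 12 genus, 5 species, 3 close, focal S01
    n_genus: int = 12
    n_species: int = 5
    n_close: int = 3
    missing_cluster_fraction: float = 0.02

    def __post_init__(self) -> None:
        if abs(sum(self.subset_proportions) - 1.0) > 1e-9:
            raise ValueError("subset_proportions must sum to 1")
        if any(length < 10_000 for _, length, _ in self.replicons):
            raise ValueError("replicon lengths must be >= 10 kb")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def strain_groups(self):
        from silencerscope.pangenome import StrainGroups

        names = [f"S{i:02d}" for i in range(1, self.n_genus + 1)]
        return StrainGroups(
            genus=frozenset(names),
            species=frozenset(names[: self.n_species]),
            close=frozenset(names[: self.n_close]),
            focal=names[0],
        )


@dataclass
class GroundTruthLedger:
    """Planted features and model draws, one record per feature."""

    genes: pd.DataFrame  # gene_id, replicon, coords, subset, is_target, expr means
    peaks: pd.DataFrame  # true peak id, summit, AT%, motif count, z, noise, fold
    motifs: pd.DataFrame  # planted motif coordinates (1-based, strand)
    islands: pd.DataFrame  # island intervals
    promoters: pd.DataFrame  # planted promoter positions, group, spacer AT
    config: SyntheticConfig


@dataclass
class SyntheticDataset:
    genome: Genome
    genes: list[GeneModel]
    peak_records: list[PeakRecord]
    expression: pd.DataFrame
    clusters: dict[str, tuple[str, frozenset[str]]]
    training_sites: dict[str, tuple[list[str], list[str]]]  # sigma -> (-35, -10)
    ledger: GroundTruthLedger


def _draw_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    gc = min(max(gc, 5.0), 95.0) / 100.0
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p)


def _at_biased_seq(rng: np.random.Generator, n: int, at: float) -> str:
    at = min(max(at, 0.0), 100.0) / 100.0
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def _allocate_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation so counts sum to n exactly."""
    raw = [p * n for p in proportions]
    counts = [int(x) for x in raw]
    order = np.argsort([c - x for c, x in zip(counts, raw)])
    for i in range(n - sum(counts)):
        counts[order[i]] += 1
    return counts


def _canonical_motif(rng: np.random.Generator) -> str:
    """One concrete instance of the flexible pattern at nominal gaps,
    with AT-biased gap filler."""
    g = lambda n: _at_biased_seq(rng, n, 70.0)
    return "TT" + g(3) + "G" + g(3) + "T" + g(10) + "TT"


def generate(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate the full synthetic dataset (optionally writing files).

    Deterministic given ``config.seed``: running twice yields identical
    in-memory objects and byte-identical files.
    """
    root = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, root.spawn(len(_STREAMS)))
    }

    # ---------------- backbone + islands -------------------------------
    seqs: dict[str, np.ndarray] = {}
    protected: dict[str, np.ndarray] = {}  # planted spans never overwritten
    island_rows = []
    for rep_id, length, gc in config.replicons:
        seqs[rep_id] = _draw_seq(rngs["backbone"], length, gc)
        protected[rep_id] = np.zeros(length, dtype=bool)
        span = length // config.n_islands_per_replicon
        for i in range(config.n_islands_per_replicon):
            lo = i * span + int(
                rngs["islands"].integers(0, max(1, span - config.island_length))
            )
            hi = min(length, lo + config.island_length)
            island_rows.append(
                {"replicon_id": rep_id, "start": lo + 1, "end": hi, "gc":
                 gc + config.island_gc_delta}
            )
    islands = pd.DataFrame(island_rows)

    def in_island(rep_id: str, pos: int) -> bool:
        sub = islands[islands.replicon_id == rep_id]
        return bool(((sub.start <= pos) & (pos <= sub.end)).any())

    # ---------------- genes --------------------------------------------
    gene_rows = []
    rng_g = rngs["genes"]
    counter = 0
    for rep_id, length, gc in config.replicons:
        pos = int(rng_g.integers(*config.intergenic_range))
        while True:
            glen = int(rng_g.integers(*config.gene_length_range))
            if pos + glen + 3 > length - 200:
                break
            counter += 1
            gene_rows.append(
                {
                    "gene_id": f"gene_{counter:05d}",
                    "replicon_id": rep_id,
                    "start": pos + 1,
                    "end": pos + glen,
                    "strand": "+" if rng_g.random() < 0.5 else "-",
                }
            )
            pos += glen + int(rng_g.integers(*config.intergenic_range))
    genes_df = pd.DataFrame(gene_rows)
    n_genes = len(genes_df)

    # subset labels: exact configured counts, shuffled, then island genes
    # swapped to IV (foreign genes cluster in AT-rich islands)
    counts = _allocate_counts(n_genes, config.subset_proportions)
    labels = np.array(
        [s for s, c in zip(SUBSETS, counts) for _ in range(c)], dtype=object
    )
    rng_g.shuffle(labels)
    genes_df["subset"] = labels
    mid = (genes_df.start + genes_df.end) // 2
    is_island_gene = np.array(
        [in_island(r, m) for r, m in zip(genes_df.replicon_id, mid)]
    )
    non_island_iv = list(genes_df.index[(genes_df.subset == "IV") & ~is_island_gene])
    rng_g.shuffle(non_island_iv)
    for idx in genes_df.index[is_island_gene]:
        if genes_df.at[idx, "subset"] != "IV" and non_island_iv:
            donor = non_island_iv.pop()
            genes_df.at[donor, "subset"] = genes_df.at[idx, "subset"]
            genes_df.at[idx, "subset"] = "IV"

    # overwrite gene spans with subset-dependent GC; island intergenic
    # stretches with island GC
    gc_of_rep = {rid: gc for rid, _, gc in config.replicons}
    offsets = dict(zip(SUBSETS, config.subset_gc_offsets))
    for row in islands.itertuples(index=False):
        seqs[row.replicon_id][row.start - 1 : row.end] = _draw_seq(
            rngs["islands"], row.end - row.start + 1, row.gc
        )
    for r in genes_df.itertuples(index=False):
        base_gc = gc_of_rep[r.replicon_id] + offsets[r.subset]
        if in_island(r.replicon_id, (r.start + r.end) // 2):
            base_gc += config.island_gc_delta / 2
        seqs[r.replicon_id][r.start - 1 : r.end] = _draw_seq(
            rngs["genes"], r.end - r.start + 1, base_gc
        )

    # ---------------- motif plants -------------------------------------
    rng_m = rngs["motifs"]
    motif_rows = []

    def plant_motif(rep_id: str, start0: int) -> bool:
        """Plant one canonical-instance motif at 0-based start; False if
        the span is already occupied."""
        inst = _canonical_motif(rng_m)
        strand = "+"
        if rng_m.random() < 0.5:
            inst, strand = reverse_complement(inst), "-"
        end0 = start0 + len(inst)
        if end0 > len(seqs[rep_id]) or protected[rep_id][start0:end0].any():
            return False
        seqs[rep_id][start0:end0] = np.frombuffer(inst.encode(), dtype=np.uint8)
        protected[rep_id][start0:end0] = True
        motif_rows.append(
            {
                "replicon_id": rep_id,
                "start": start0 + 1,
                "end": end0,
                "strand": strand,
                "context": "planned",
            }
        )
        return True

    for rep_id, length, _ in config.replicons:
        isl = islands[islands.replicon_id == rep_id]
        island_bp = int((isl.end - isl.start + 1).sum())
        n_island = rng_m.poisson(config.island_motif_per_kb * island_bp / 1000)
        n_back = rng_m.poisson(
            config.background_motif_per_kb * (length - island_bp) / 1000
        )
        placed = 0
        attempts = 0
        while placed < n_island and attempts < 20 * max(1, n_island):
            attempts += 1
            row = isl.iloc[int(rng_m.integers(len(isl)))]
            pos = int(rng_m.integers(row.start - 1, row.end - 30))
            if plant_motif(rep_id, pos):
                placed += 1
        placed = 0
        attempts = 0
        while placed < n_back and attempts < 20 * max(1, n_back):
            attempts += 1
            pos = int(rng_m.integers(0, length - 30))
            if plant_motif(rep_id, pos):
                placed += 1

    # ---------------- peaks --------------------------------------------
    rng_p = rngs["peaks"]
    taken: dict[str, list[int]] = {rid: [] for rid, _, _ in config.replicons}

    def far_enough(rep_id: str, pos: int) -> bool:
        return all(abs(pos - s) >= config.min_peak_spacing for s in taken[rep_id])

    n_gene_peaks = int(round(config.n_peaks * config.gene_peak_fraction))
    # weighted order without replacement (exponential-sort trick), biased
    # toward strain-specific genes
    w_of = dict(zip(SUBSETS, config.subset_target_weights))
    w = np.array([w_of[s] for s in genes_df.subset])
    keys = rng_p.random(len(genes_df)) ** (1.0 / w)
    gene_order = list(genes_df.index[np.argsort(-keys)])
    peak_sites: list[tuple[str, int, str | None]] = []  # (replicon, summit, gene)
    for idx in gene_order:
        if len(peak_sites) >= n_gene_peaks:
            break
        g = genes_df.loc[idx]
        off = int(rng_p.integers(-300, 51))
        summit = (g.start + off) if g.strand == "+" else (g.end - off)
        length = len(seqs[g.replicon_id])
        if not (200 < summit < length - 200) or not far_enough(g.replicon_id, summit):
            continue
        taken[g.replicon_id].append(int(summit))
        peak_sites.append((g.replicon_id, int(summit), g.gene_id))
    attempts = 0
    rep_ids = [rid for rid, _, _ in config.replicons]
    rep_weights = np.array([ln for _, ln, _ in config.replicons], dtype=float)
    rep_weights /= rep_weights.sum()
    while len(peak_sites) < config.n_peaks and attempts < 50 * config.n_peaks:
        attempts += 1
        rid = rep_ids[int(rng_p.choice(len(rep_ids), p=rep_weights))]
        pos = int(rng_p.integers(200, len(seqs[rid]) - 200))
        if far_enough(rid, pos):
            taken[rid].append(pos)
            peak_sites.append((rid, pos, None))

    # per-peak TpA intensity and extra motif plants inside the central region
    peak_meta = []
    for i, (rid, summit, gene_id) in enumerate(peak_sites):
        lo0 = summit - 100  # 0-based window start of the 200-bp region
        z = float(rng_p.random())
        n_extra = (
            int(rng_p.poisson(config.motif_in_peak_mean))
            if rng_p.random() < config.motif_in_peak_prob
            else 0
        )
        planted = 0
        for _ in range(4 * max(1, n_extra)):
            if planted >= n_extra:
                break
            pos = int(rng_p.integers(lo0, lo0 + 200 - 26))
            if plant_motif(rid, pos):
                motif_rows[-1]["context"] = "peak"
                planted += 1
        peak_meta.append(
            {"true_peak_id": f"tp_{i + 1:04d}", "replicon_id": rid,
             "summit": summit, "target_gene": gene_id, "z": z,
             "n_motifs_peak_planted": planted}
        )

    # TpA planting (avoid protected spans so planted motifs stay intact).
    # The planted count scales with the region's expected TA count (which
    # grows with AT%^2) so the usage-deviation gain is composition-neutral
    # and the TpA signal is not confounded with plain AT content.
    ta = np.frombuffer(b"TA", dtype=np.uint8)
    for meta in peak_meta:
        rid, summit, z = meta["replicon_id"], meta["summit"], meta["z"]
        lo0 = summit - 100
        region_now = seqs[rid][lo0 : lo0 + 200].tobytes().decode()
        at_scale = (at_percent(region_now) / 50.0) ** 2
        n_ta = int(round(z * config.max_extra_ta * at_scale))
        placed = 0
        for _ in range(6 * max(1, n_ta)):
            if placed >= n_ta:
                break
            pos = int(rng_p.integers(lo0, lo0 + 199))
            if protected[rid][pos : pos + 2].any():
                continue
            seqs[rid][pos : pos + 2] = ta
            placed += 1
        meta["n_ta_planted"] = placed

    # ---------------- promoters ----------------------------------------
    rng_pr = rngs["promoters"]
    target_genes = {m["target_gene"] for m in peak_meta if m["target_gene"]}

    def mutate(site: str, rate: float) -> str:
        out = []
        for b in site:
            if rng_pr.random() < rate:
                out.append("ACGT"[int(rng_pr.integers(4))])
            else:
                out.append(b)
        return "".join(out)

    training_sites = {
        sf: (
            [mutate(config.consensus_35, config.training_mut_rate)
             for _ in range(config.n_training_sites)],
            [mutate(config.consensus_10, config.training_mut_rate)
             for _ in range(config.n_training_sites)],
        )
        for sf in config.sigma_factors
    }

    promoter_rows = []
    tgt_pool = [g for g in genes_df.itertuples(index=False) if g.gene_id in target_genes]
    non_pool = [g for g in genes_df.itertuples(index=False) if g.gene_id not in target_genes]
    rng_pr.shuffle(tgt_pool)
    rng_pr.shuffle(non_pool)
    half = config.n_promoters // 2
    elem_len = len(config.consensus_35) + config.spacer_length + len(config.consensus_10)
    for group, pool, spacer_at in (
        ("target", tgt_pool[:half], config.spacer_at_target),
        ("nontarget", non_pool[: config.n_promoters - half], config.spacer_at_nontarget),
    ):
        for g in pool:
            spacer = _at_biased_seq(rng_pr, config.spacer_length, spacer_at)
            element = config.consensus_35 + spacer + config.consensus_10
            length = len(seqs[g.replicon_id])
            if g.strand == "+":
                start0 = g.start - 1 - config.promoter_gap - elem_len
                written = element
            else:
                start0 = g.end + config.promoter_gap
                written = reverse_complement(element)
            end0 = start0 + elem_len
            if start0 < 0 or end0 > length or protected[g.replicon_id][start0:end0].any():
                continue
            seqs[g.replicon_id][start0:end0] = np.frombuffer(
                written.encode(), dtype=np.uint8
            )
            protected[g.replicon_id][start0:end0] = True
            promoter_rows.append(
                {
                    "replicon_id": g.replicon_id,
                    "start": start0 + 1,
                    "end": end0,
                    "strand": g.strand,
                    "gene_id": g.gene_id,
                    "group": group,
                    "spacer_len": config.spacer_length,
                    "spacer_at": at_percent(spacer),
                }
            )
    promoters_df = pd.DataFrame(promoter_rows)

    # ---------------- finalise sequences, compute peak folds -----------
    role_of = {
        "chromosome": "chromosome",
        "chromid": "chromid",
        "symbiosis_plasmid": "symbiosis_plasmid",
    }
    genome: Genome = {
        rid: Replicon(
            rid, seqs[rid].tobytes().decode(), role_of.get(rid, "unspecified")
        )
        for rid, _, _ in config.replicons
    }
    motifs_df = pd.DataFrame(motif_rows)

    from silencerscope.composition import oligo_deviation

    peak_records: list[PeakRecord] = []
    for meta in peak_meta:
        rid, summit = meta["replicon_id"], meta["summit"]
        region = genome[rid].sequence[summit - 100 : summit + 100]
        at = at_percent(region)
        ta_dev = oligo_deviation(region, 2).values["TA"]
        if motifs_df.empty:
            m_count = 0
        else:
            mmid = (motifs_df.start + motifs_df.end) / 2.0
            m_count = int(
                (
                    (motifs_df.replicon_id == rid)
                    & (mmid >= summit - 99)
                    & (mmid <= summit + 100)
                ).sum()
            )
        noise = float(rng_p.normal(0, config.sigma))
        # TpA coupling acts through the realised usage deviation of the
        # final region (the planting intensity z only creates its spread)
        fold = (
            config.beta0
            + config.beta_at * at
            + config.beta_motif * m_count
            + config.beta_ta * max(0.0, ta_dev - 1.0)
            + noise
        )
        shared = bool(rng_p.random() < config.shared_fraction)
        if not shared:
            fold *= config.specific_attenuation
        fold = max(1 + config.fold_floor_eps, fold)
        meta.update(
            {"at_percent": at, "ta_deviation": ta_dev,
             "n_motifs_region": m_count, "noise": noise,
             "fold": fold, "shared": shared}
        )
        if shared:
            jit = int(rng_p.integers(-config.summit_jitter, config.summit_jitter + 1))
            for cond, s in (("FC", summit), ("BC", summit + jit)):
                f = fold * float(
                    rng_p.lognormal(0, config.condition_jitter_sd)
                )
                peak_records.append(
                    PeakRecord(rid, s, max(1 + config.fold_floor_eps, f),
                               q_value=1e-4, condition=cond)
                )
        else:
            cond = "FC" if rng_p.random() < 0.5 else "BC"
            peak_records.append(
                PeakRecord(rid, summit, fold, q_value=1e-4, condition=cond)
            )
    peaks_df = pd.DataFrame(peak_meta)

    # ---------------- expression ---------------------------------------
    rng_e = rngs["expression"]
    mean_of = dict(zip(SUBSETS, config.subset_expr_means))
    wt, mut = [], []
    is_target = genes_df.gene_id.isin(target_genes).to_numpy()
    for i, r in enumerate(genes_df.itertuples(index=False)):
        mu = mean_of[r.subset] * (config.target_boost if is_target[i] else 1.0)
        w = float(rng_e.lognormal(np.log(mu), config.expr_sigma))
        shift = config.mutant_shift if is_target[i] else 1.0
        m = float(
            w * shift * rng_e.lognormal(0, 0.1)
        )
        wt.append(w)
        mut.append(m)
    expression = pd.DataFrame(
        {config.conditions[0]: wt, config.conditions[1]: mut},
        index=pd.Index(genes_df.gene_id, name="gene_id"),
    )
    genes_df["is_target"] = is_target

    # ---------------- cluster table ------------------------------------
    rng_c = rngs["clusters"]
    groups = config.strain_groups()
    genus = sorted(groups.genus)
    species = sorted(groups.species)
    close = sorted(groups.close)
    non_species = [s for s in genus if s not in groups.species]
    species_minus_close = [s for s in species if s not in groups.close]
    non_close = [s for s in genus if s not in groups.close]
    clusters: dict[str, tuple[str, frozenset[str]]] = {}
    for i, r in enumerate(genes_df.itertuples(index=False)):
        cid = f"clu_{i + 1:05d}"
        if r.subset == "I":
            strains = set(genus)
        elif r.subset == "II":
            k = int(rng_c.integers(0, len(non_species)))  # never all of them
            strains = set(species) | set(rng_c.choice(non_species, k, replace=False))
        elif r.subset == "III":
            k = int(rng_c.integers(0, 5))
            strains = set(close) | set(rng_c.choice(non_species, k, replace=False))
        else:
            strains = {groups.focal}
            if rng_c.random() < 0.3:
                strains |= set(rng_c.choice(non_close, 1))
        if r.subset == "IV" and rng_c.random() < config.missing_cluster_fraction:
            continue  # gene absent from the table: strain-specific by absence
        clusters[r.gene_id] = (cid, frozenset(strains))

    genes = [
        GeneModel(r.gene_id, r.replicon_id, int(r.start), int(r.end), r.strand,
                  subset=r.subset)
        for r in genes_df.itertuples(index=False)
    ]
    ledger = GroundTruthLedger(
        genes=genes_df,
        peaks=peaks_df,
        motifs=motifs_df,
        islands=islands,
        promoters=promoters_df,
        config=config,
    )
    ds = SyntheticDataset(
        genome=genome,
        genes=genes,
        peak_records=peak_records,
        expression=expression,
        clusters=clusters,
        training_sites=training_sites,
        ledger=ledger,
    )
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SyntheticDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_genome(ds.genome, out_dir / "genome.fa")
    write_annotation(ds.genes, out_dir / "annotation.gff3")
    pd.DataFrame(
        [
            {
                "replicon_id": p.replicon_id,
                "summit": p.summit,
                "enrichment_fold": p.enrichment_fold,
                "q_value": p.q_value,
                "condition": p.condition,
                "replicate": p.replicate,
            }
            for p in ds.peak_records
        ]
    ).to_csv(out_dir / "peaks.tsv", sep="\t", index=False)
    ds.expression.to_csv(out_dir / "expression.tsv", sep="\t")
    pd.DataFrame(
        [
            {"gene_id": g, "cluster_id": cid, "strains": ",".join(sorted(strains))}
            for g, (cid, strains) in ds.clusters.items()
        ]
    ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    for sf, (s35, s10) in ds.training_sites.items():
        for tag, sites in (("35", s35), ("10", s10)):
            with open(out_dir / f"promoters_{sf}_minus{tag}.fa", "w") as fh:
                for i, s in enumerate(sites, 1):
                    fh.write(f">{sf}_m{tag}_{i:03d}\n{s}\n")
    for name in ("genes", "peaks", "motifs", "islands", "promoters"):
        getattr(ds.ledger, name).to_csv(
            out_dir / f"ledger_{name}.tsv", sep="\t", index=False
        )


def ledger_expectations(ledger: GroundTruthLedger) -> dict:
    """Closed-form / bookkeeping expectations for pipeline summaries."""
    cfg = ledger.config
    exp: dict = {
        "subset_counts": dict(
            zip(SUBSETS, _allocate_counts(len(ledger.genes),
                                          cfg.subset_proportions))
        ),
        "slope_fold_on_at": cfg.beta_at,
        "shared_fraction": cfg.shared_fraction,
        "target_boost": cfg.target_boost,
        "mutant_shift": cfg.mutant_shift,
        "spacer_at_shift": cfg.spacer_at_target - cfg.spacer_at_nontarget,
        "n_planted_motifs": len(ledger.motifs),
        "n_true_peaks": len(ledger.peaks),
        "n_target_genes_planted": int(ledger.genes.is_target.sum()),
    }
    if not ledger.peaks.empty:
        exp["empirical_shared_fraction"] = float(ledger.peaks.shared.mean())
    if not ledger.promoters.empty:
        grp = ledger.promoters.groupby("group").spacer_at.mean()
        exp["spacer_at_means"] = grp.to_dict()
    return exp
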