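"""Genome and annotation I/O plus interval sequence extraction.

Coordinates follow GFF3 convention throughout the public surface:
1-based, inclusive on both ends.  Sequences are uppercase ACGTN; N is
tolerated everywhere but never matches a motif literal and is excluded
from composition statistics (see :func:`silencerscope.composition.at_percent`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")
ROLE_LABELS = frozenset(
    {"chromosome", "chromid", "plasmid", "symbiosis_plasmid", "unspecified"}
)
SUBSET_LABELS = ("I", "II", "III", "IV", "unassigned")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Replicon:
    """One replicon of a (possibly multipartite) genome.

    Bacterial genomes of the rhizobia studied here are multipartite:
    a chromosome plus chromids and (symbiosis) plasmids.  The role label
    is biological knowledge supplied by the user, never inferred.
    """

    id: str
    sequence: str
    role_label: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"replicon {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.role_label not in ROLE_LABELS:
            raise ValueError(f"unknown replicon role {self.role_label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene with conservation-subset annotation.

    ``subset`` is one of the hierarchical pangenome conservation classes
    (I genus core, II species core, III near-strain shared, IV
    strain-specific) or ``unassigned`` before classification.
    """

    gene_id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    subset: str = "unassigned"
    product: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid coordinates "
                f"{self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.subset not in SUBSET_LABELS:
            raise ValueError(f"gene {self.gene_id!r}: bad subset {self.subset!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def start_codon_pos(self) -> int:
        """Position of the first nucleotide of the gene on the forward axis."""
        return self.start if self.strand == "+" else self.end


Genome = dict[str, Replicon]


def read_genome(
    fasta_path: str | Path, roles: Mapping[str, str] | None = None
) -> Genome:
    """Read a multi-FASTA genome into a dict of Replicons keyed by id.

    Sequences are uppercased; N is allowed.  ``roles`` optionally maps
    replicon id -> role label (chromosome/chromid/plasmid/...).
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    roles = roles or {}
    genome: Genome = {}
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records found")
    for rec in records:
        if rec.id in genome:
            raise ValueError(f"{fasta_path}: duplicate replicon id {rec.id!r}")
        genome[rec.id] = Replicon(
            id=rec.id,
            sequence=str(rec.seq),
            role_label=roles.get(rec.id, "unspecified"),
        )
    return genome


def write_genome(genome: Genome, fasta_path: str | Path, width: int = 70) -> None:
    """Write the genome as multi-FASTA (fixed line width, stable order)."""
    records = [
        SeqRecord(Seq(rep.sequence), id=rep.id, description="")
        for rep in genome.values()
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_annotation(gff_path: str | Path, genome: Genome) -> list[GeneModel]:
    """Read gene models from GFF3, validating against the genome.

    Accepts ``gene`` and ``CDS`` features carrying an ID attribute; when a
    gene and its CDS share an ID the gene feature wins.  Coordinates are
    checked against replicon lengths; a feature on an unknown replicon or
    running past the replicon end is an error.
    """
    gff_path = Path(gff_path)
    if not gff_path.exists():
        raise FileNotFoundError(gff_path)
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    for ftype in ("gene", "CDS"):
        for feat in db.features_of_type(ftype, order_by=("seqid", "start")):
            gid = feat.attributes.get("ID", [feat.id])[0]
            if gid in genes:
                continue  # gene feature seen first takes precedence
            if feat.seqid not in genome:
                raise ValueError(
                    f"{gff_path}: feature {gid!r} on unknown replicon "
                    f"{feat.seqid!r}"
                )
            rep_len = len(genome[feat.seqid])
            if feat.end > rep_len:
                raise ValueError(
                    f"{gff_path}: feature {gid!r} end {feat.end} exceeds "
                    f"replicon {feat.seqid!r} length {rep_len}"
                )
            product = feat.attributes.get("product", [""])[0]
            genes[gid] = GeneModel(
                gene_id=gid,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                product=product,
            )
    return list(genes.values())


def write_annotation(genes: Iterable[GeneModel], gff_path: str | Path) -> None:
    """Write gene models as GFF3 (one ``gene`` feature per model)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.replicon_id}\tsilencerscope\tgene\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_expression(tsv_path: str | Path | io.StringIO) -> pd.DataFrame:
    """Read a gene x condition expression matrix.

    First column: gene_id; header row: condition labels.  All values must
    be non-negative.
    """
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("expression table contains negative values")
    return df


def extract_interval(
    genome: Genome, replicon_id: str, start: int, end: int, strand: str = "+"
) -> str:
    """Extract the sequence of [start, end] (1-based inclusive).

    Returns the forward-strand substring for '+', its reverse complement
    for '-'.  Out-of-bounds coordinates raise; nothing is clamped here.
    """
    if replicon_id not in genome:
        raise KeyError(f"unknown replicon {replicon_id!r}")
    rep = genome[replicon_id]
    if not (1 <= start <= end <= len(rep)):
        raise ValueError(
            f"interval {start}..{end} out of bounds for replicon "
            f"{replicon_id!r} (length {len(rep)})"
        )
    sub = rep.sequence[start - 1 : end]
    return sub if strand == "+" else reverse_complement(sub)


@dataclass
class RegionSeq:
    """A sequence extracted with edge truncation bookkeeping."""

    replicon_id: str
    start: int
    end: int
    sequence: str
    truncated: bool = False
    extras: dict = field(default_factory=dict)
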