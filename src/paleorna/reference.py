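"""Toy reference construction: genome, gene models, transcripts, tissue arrays.

The downstream statistics (composition, junction straddling, damage,
tissue scoring) only assume a genome with spliced gene models of three
biotypes (mRNA / rRNA / tRNA) and a multi-tissue expression array that
assigns most genes a clearly most-associated tissue.  This module builds
such a reference deterministically from a seed, at a scale where every
stage of the pipeline runs in seconds.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Ten tissue labels in the style of a multi-tissue normal-tissue array.
DEFAULT_TISSUES = (
    "cartilage",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "pancreas",
    "skin",
    "spleen",
    "testis",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """One gene: ordered, disjoint exon intervals on the genome (0-based,
    half-open) plus strand and biotype."""

    gene_id: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    biotype: str  # 'mRNA' | 'rRNA' | 'tRNA'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.biotype not in ("mRNA", "rRNA", "tRNA"):
            raise ValueError(f"bad biotype {self.biotype!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval ({s}, {e})")
            if s <= prev_end:
                raise ValueError("exons must be ordered and disjoint")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    def splice(self, genome: str) -> str:
        """Transcript sequence: concatenated exons, reverse-complemented
        for minus-strand genes."""
        seq = "".join(genome[s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclasses.dataclass
class ReferenceBundle:
    """Everything the pipeline needs to know about the (toy) organism.

    Attributes
    ----------
    genome:
        Single toy chromosome as an ACGT string.
    genes:
        Gene models in genome order.
    transcripts:
        gene_id -> spliced transcript sequence.
    tissue_profiles:
        genes x tissues DataFrame; each tissue column is a probability
        vector over mRNA genes (relative transcript abundance).
    array_matrix:
        mRNA genes x tissues DataFrame of nonnegative expression-array
        values; most genes have one strictly maximal (marker) tissue.
    """

    genome: str
    genes: list[GeneModel]
    transcripts: dict[str, str]
    tissue_profiles: pd.DataFrame
    array_matrix: pd.DataFrame

    @property
    def tissues(self) -> list[str]:
        return list(self.array_matrix.columns)

    def genes_by_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == biotype]

    def transcript_lengths(self) -> dict[str, int]:
        return {gid: len(seq) for gid, seq in self.transcripts.items()}

    def reference_sequences(self, reference_class: str) -> dict[str, str]:
        """Sequences to map against for one reference class
        ('genome', 'mRNA', 'rRNA' or 'tRNA')."""
        if reference_class == "genome":
            return {"chr1": self.genome}
        if reference_class in ("mRNA", "rRNA", "tRNA"):
            return {
                g.gene_id: self.transcripts[g.gene_id]
                for g in self.genes
                if g.biotype == reference_class
            }
        raise ValueError(f"unknown reference class {reference_class!r}")


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
    return "".join(BASES[i] for i in idx)


def build_reference(
    n_genes: int,
    n_tissues: int = 10,
    seed: int = 0,
    *,
    marker_fraction: float = 0.9,
    tissues: Sequence[str] | None = None,
) -> ReferenceBundle:
    """Build a deterministic toy reference bundle.

    Parameters
    ----------
    n_genes:
        Total gene count (>= 10); at least one rRNA and one tRNA gene are
        always included, the rest are spliced mRNAs with 1-8 exons and
        introns of at least 40 nt.
    n_tissues:
        Number of tissues in the expression array (default 10, matching a
        ten-tissue normal-tissue array).
    marker_fraction:
        Fraction of mRNA genes given one strongly dominant (marker) tissue
        in the array matrix; the rest get near-flat background values.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    rng = np.random.default_rng(seed)

    if tissues is None:
        tissues = list(DEFAULT_TISSUES[:n_tissues])
        while len(tissues) < n_tissues:
            tissues.append(f"tissue{len(tissues)}")
    else:
        tissues = list(tissues)
        if len(tissues) != n_tissues:
            raise ValueError("len(tissues) must equal n_tissues")

    n_rrna = max(1, n_genes // 25)
    n_trna = max(1, n_genes // 25)
    n_mrna = n_genes - n_rrna - n_trna

    chunks: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0

    def _spacer() -> None:
        nonlocal cursor
        n = int(rng.integers(100, 400))
        chunks.append(_random_seq(rng, n))
        cursor += n

    biotype_plan = (
        ["mRNA"] * n_mrna + ["rRNA"] * n_rrna + ["tRNA"] * n_trna
    )
    rng.shuffle(biotype_plan)

    i_m = i_r = i_t = 0
    for biotype in biotype_plan:
        _spacer()
        strand = "+" if rng.random() < 0.5 else "-"
        if biotype == "mRNA":
            gene_id = f"gene{i_m:04d}"
            i_m += 1
            n_exons = int(rng.integers(1, 9))
            exons = []
            for j in range(n_exons):
                if j > 0:
                    intron = int(rng.integers(40, 300))
                    cursor += intron
                    chunks.append(_random_seq(rng, intron, gc=0.40))
                elen = int(rng.integers(80, 300))
                exons.append((cursor, cursor + elen))
                chunks.append(_random_seq(rng, elen, gc=0.55))
                cursor += elen
        elif biotype == "rRNA":
            gene_id = f"rrna{i_r:02d}"
            i_r += 1
            elen = int(rng.integers(400, 900))
            exons = [(cursor, cursor + elen)]
            chunks.append(_random_seq(rng, elen, gc=0.55))
            cursor += elen
        else:
            gene_id = f"trna{i_t:02d}"
            i_t += 1
            elen = int(rng.integers(70, 95))
            exons = [(cursor, cursor + elen)]
            chunks.append(_random_seq(rng, elen, gc=0.55))
            cursor += elen
        genes.append(GeneModel(gene_id, strand, tuple(exons), biotype))
    _spacer()

    genome = "".join(chunks)
    transcripts = {g.gene_id: g.splice(genome) for g in genes}

    mrna_ids = [g.gene_id for g in genes if g.biotype == "mRNA"]
    array = rng.uniform(1.0, 20.0, size=(len(mrna_ids), n_tissues))
    marker_tissue = rng.integers(0, n_tissues, size=len(mrna_ids))
    is_marker = rng.random(len(mrna_ids)) < marker_fraction
    boost = rng.uniform(100.0, 500.0, size=len(mrna_ids))
    array[np.arange(len(mrna_ids))[is_marker], marker_tissue[is_marker]] = boost[
        is_marker
    ]
    array_matrix = pd.DataFrame(array, index=mrna_ids, columns=tissues)

    profiles = array_matrix / array_matrix.sum(axis=0)
    return ReferenceBundle(
        genome=genome,
        genes=genes,
        transcripts=transcripts,
        tissue_profiles=profiles,
        array_matrix=array_matrix,
    )


# ---------------------------------------------------------------------------
# On-disk formats.  GFF3 uses 1-based closed intervals; everything in memory
# is 0-based half-open.

def write_reference(ref: ReferenceBundle, outdir) -> None:
    """Write genome FASTA, transcript FASTA, GFF3 annotation and the
    expression-array TSV into ``outdir``."""
    import os

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    os.makedirs(outdir, exist_ok=True)
    SeqIO.write(
        [SeqRecord(Seq(ref.genome), id="chr1", description="")],
        os.path.join(outdir, "genome.fasta"),
        "fasta",
    )
    SeqIO.write(
        [
            SeqRecord(Seq(seq), id=gid, description="")
            for gid, seq in ref.transcripts.items()
        ],
        os.path.join(outdir, "transcripts.fasta"),
        "fasta",
    )
    with open(os.path.join(outdir, "annotation.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ref.genes:
            s, e = g.span
            fh.write(
                f"chr1\tpaleorna\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype={g.biotype}\n"
            )
            for j, (xs, xe) in enumerate(g.exons):
                fh.write(
                    f"chr1\tpaleorna\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{j};Parent={g.gene_id}\n"
                )
    ref.array_matrix.to_csv(
        os.path.join(outdir, "array_matrix.tsv"), sep="\t", index_label="gene"
    )
    ref.tissue_profiles.to_csv(
        os.path.join(outdir, "tissue_profiles.tsv"), sep="\t", index_label="gene"
    )


def read_annotation(path) -> list[GeneModel]:
    """Parse a GFF3 annotation written by :func:`write_reference` back into
    gene models (coordinates converted to 0-based half-open)."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            ftype, start, end, strand, attrs = (
                cols[2],
                int(cols[3]),
                int(cols[4]),
                cols[6],
                cols[8],
            )
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = fields["ID"]
                genes[gid] = {
                    "strand": strand,
                    "biotype": fields.get("biotype", "mRNA"),
                    "exons": [],
                }
                order.append(gid)
            elif ftype == "exon":
                gid = fields["Parent"]
                genes[gid]["exons"].append((start - 1, end))
    return [
        GeneModel(
            gid,
            genes[gid]["strand"],
            tuple(sorted(genes[gid]["exons"])),
            genes[gid]["biotype"],
        )
        for gid in order
    ]


def read_reference(indir) -> ReferenceBundle:
    """Load a reference bundle from a directory written by
    :func:`write_reference`."""
    import os

    from Bio import SeqIO

    genome = str(
        next(SeqIO.parse(os.path.join(indir, "genome.fasta"), "fasta")).seq
    )
    genes = read_annotation(os.path.join(indir, "annotation.gff3"))
    transcripts = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(os.path.join(indir, "transcripts.fasta"), "fasta")
    }
    array_matrix = pd.read_csv(
        os.path.join(indir, "array_matrix.tsv"), sep="\t", index_col="gene"
    )
    profiles = pd.read_csv(
        os.path.join(indir, "tissue_profiles.tsv"), sep="\t", index_col="gene"
    )
    return ReferenceBundle(genome, genes, transcripts, profiles, array_matrix)
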