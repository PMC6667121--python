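"""Authenticity statistics for putative ancient RNA libraries.

Three independent lines of evidence are computed:

* **Composition** — endogenous percentage (genome-mapped / total reads),
  rRNA proportion of all class-mapped reads, and the RNA enrichment
  factor: per-base read frequency on transcribed references divided by
  per-base read frequency on the genome.  Authentic RNA-seq shows strong
  enrichment (>> 1) and a high rRNA share; DNA does not.
* **Junction straddling** — reads crossing exon-exon junctions can only
  derive from spliced transcripts, whereas genomic DNA produces reads
  crossing intron-exon (splice) boundaries instead.
* **Damage profiles** — positional mismatch frequencies from each read
  end.  Hydrolytic deamination of cytosine yields C>T (C>U) signal; a
  single-stranded RNA library shows no complementary G>A excess.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentSet
from .reference import GeneModel

MISMATCH_CLASSES = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclasses.dataclass(frozen=True)
class MappingCounts:
    """The five per-sample read tallies of a mapping summary row."""

    sample_id: str
    platform: str
    total_reads: int       # T: total post-adapter-trimming reads
    genome: int            # G
    mrna: int              # M
    rrna: int              # R
    trna: int              # tR

    def __post_init__(self) -> None:
        for name in ("total_reads", "genome", "mrna", "rrna", "trna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.genome > self.total_reads:
            raise ValueError("genome-mapped reads cannot exceed total reads")

    @property
    def rna_mapped(self) -> int:
        return self.mrna + self.rrna + self.trna


def count_mappings(
    sample_id: str,
    total_reads: int,
    class_sets: Mapping[str, AlignmentSet],
    platform: str = "simulated",
) -> MappingCounts:
    """Tally mapped reads per reference class into a MappingCounts row."""
    for cls in ("genome", "mRNA", "rRNA", "tRNA"):
        if cls not in class_sets:
            raise KeyError(f"missing alignment set for reference class {cls!r}")
    return MappingCounts(
        sample_id=sample_id,
        platform=platform,
        total_reads=total_reads,
        genome=len(class_sets["genome"]),
        mrna=len(class_sets["mRNA"]),
        rrna=len(class_sets["rRNA"]),
        trna=len(class_sets["tRNA"]),
    )


def endogenous_percent(counts: MappingCounts) -> float:
    """Genome-mapped reads as a percentage of total reads (2-decimal)."""
    if counts.total_reads == 0:
        return float("nan")
    return round(100.0 * counts.genome / counts.total_reads, 2)


def rrna_proportion(counts: MappingCounts) -> float:
    """rRNA-mapped reads as a percentage of all class-mapped reads
    (denominator G + M + R + tR), 2-decimal.

    The denominator is a reconstruction: it is the only formula that
    reproduces every published summary row exactly.
    """
    denom = counts.genome + counts.mrna + counts.rrna + counts.trna
    if denom == 0:
        return float("nan")
    return round(100.0 * counts.rrna / denom, 2)


def enrichment_factor(counts: MappingCounts, L_g: float, L_t: float) -> float:
    """RNA enrichment factor: ((M+R+tR)/L_t) / (G/L_g).

    ``L_g`` and ``L_t`` are the genome and combined transcribed-reference
    lengths; only their ratio matters.  Values well above 1 indicate true
    transcript enrichment rather than DNA contamination.
    """
    if L_g <= 0 or L_t <= 0:
        raise ValueError("reference lengths must be positive")
    if counts.genome == 0:
        return float("nan")
    return (counts.rna_mapped / L_t) / (counts.genome / L_g)


def calibrate_length_ratio(counts: MappingCounts, printed_factor: float) -> float:
    """Solve the genome-to-transcribed-reference length ratio L_g / L_t
    from one row's counts and its published enrichment factor."""
    if counts.genome == 0 or counts.rna_mapped == 0:
        raise ValueError("calibration row must have genome- and RNA-mapped reads")
    return printed_factor / (counts.rna_mapped / counts.genome)


def duplication_rate(reads: Sequence) -> float:
    """1 - (distinct sequences / total reads) over full read sequences."""
    if len(reads) == 0:
        return float("nan")
    seqs = [getattr(r, "seq", r) for r in reads]
    return 1.0 - len(set(seqs)) / len(seqs)


@dataclasses.dataclass
class CompositionMetrics:
    sample_id: str
    endogenous_percent: float
    rrna_proportion: float
    enrichment_factor: float
    duplication_rate: float


# ---------------------------------------------------------------------------
# Junction analysis.

@dataclasses.dataclass
class JunctionIndex:
    """Exon-exon junctions in transcript coordinates and splice (intron
    boundary) junctions in genome coordinates."""

    exon_exon: dict[str, tuple[int, ...]]      # gene_id -> positions in transcript
    splice: dict[str, tuple[int, ...]]         # gene_id -> genome boundary coords

    @property
    def n_exon_exon(self) -> int:
        return sum(len(v) for v in self.exon_exon.values())

    @property
    def n_splice(self) -> int:
        return sum(len(v) for v in self.splice.values())


def build_junction_index(genes: Sequence[GeneModel]) -> JunctionIndex:
    """Index junctions from gene models.

    Exon-exon junctions sit at the cumulative exon lengths inside each
    multi-exon transcript (n_exons - 1 of them); splice junctions are both
    genome boundaries of every intron (2 per intron).
    """
    ee: dict[str, tuple[int, ...]] = {}
    sj: dict[str, tuple[int, ...]] = {}
    for g in genes:
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in gene {g.gene_id}")
        cum = np.cumsum(g.exon_lengths)[:-1]
        ee[g.gene_id] = tuple(int(c) for c in cum)
        bounds: list[int] = []
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            bounds.extend((e1, s2))  # intron start and end boundaries
        sj[g.gene_id] = tuple(bounds)
    return JunctionIndex(exon_exon=ee, splice=sj)


@dataclasses.dataclass
class JunctionCounts:
    sample_id: str
    exon_exon: int
    splice: int
    min_overhang: int

    @property
    def fold(self) -> float:
        """Exon-exon over splice-junction read count; inf when SJ = 0."""
        if self.splice == 0:
            return float("inf") if self.exon_exon > 0 else float("nan")
        return self.exon_exon / self.splice


def _straddles(start: int, end: int, junction: int, overhang: int) -> bool:
    return start <= junction - overhang and end >= junction + overhang


def count_junction_straddlers(
    transcript_alignments: AlignmentSet | None,
    genome_alignments: AlignmentSet | None,
    index: JunctionIndex,
    min_overhang: int = 1,
    sample_id: str | None = None,
) -> JunctionCounts:
    """Count reads crossing junctions (not merely proximal to them).

    A read straddles junction J iff it extends at least ``min_overhang``
    bases beyond J on both sides.  A read is counted at most once per
    category even if it crosses several junctions.  Exon-exon junctions are
    assessed on transcript-space alignments; splice junctions on
    genome-space alignments of the gene-spanning regions.
    """
    ee = 0
    if transcript_alignments is not None:
        for a in transcript_alignments.alignments:
            junctions = index.exon_exon.get(a.ref_id, ())
            if any(_straddles(a.start, a.end, j, min_overhang) for j in junctions):
                ee += 1
    sj = 0
    if genome_alignments is not None:
        all_bounds = np.sort(
            np.array(
                [b for bounds in index.splice.values() for b in bounds],
                dtype=np.int64,
            )
        )
        for a in genome_alignments.alignments:
            lo = np.searchsorted(all_bounds, a.start + min_overhang, side="left")
            hi = np.searchsorted(all_bounds, a.end - min_overhang, side="right")
            if hi > lo:
                sj += 1
    sid = sample_id or (
        transcript_alignments.sample_id
        if transcript_alignments is not None
        else genome_alignments.sample_id
    )
    return JunctionCounts(sid, ee, sj, min_overhang)


def junction_enrichment(
    rna: JunctionCounts,
    dna: JunctionCounts,
    index: JunctionIndex | None = None,
    per_junction: bool = False,
) -> pd.DataFrame:
    """Fold comparison (EE/SJ) between an RNA and a DNA library.

    By default the fold is the raw EE/SJ read-count ratio; with
    ``per_junction`` each count is first divided by the number of indexed
    junctions of its kind (requires ``index``).
    """
    if per_junction:
        if index is None:
            raise ValueError("per_junction normalisation requires the index")
        n_ee, n_sj = max(index.n_exon_exon, 1), max(index.n_splice, 1)
    else:
        n_ee = n_sj = 1
    rows = []
    for counts, molecule in ((rna, "RNA"), (dna, "DNA")):
        ee = counts.exon_exon / n_ee
        sj = counts.splice / n_sj
        if sj == 0:
            fold = float("inf") if ee > 0 else float("nan")
        else:
            fold = ee / sj
        rows.append((counts.sample_id, molecule, counts.exon_exon,
                     counts.splice, fold))
    return pd.DataFrame(
        rows, columns=["sample_id", "molecule", "exon_exon", "splice", "fold"]
    )


# ---------------------------------------------------------------------------
# Damage profiles.

@dataclasses.dataclass
class DamageProfile:
    """Positional mismatch frequencies from the 5' and 3' read ends.

    ``table`` columns: end ('5p'/'3p'), position (0-based distance from
    that end), mismatch_class (e.g. 'C>T'), opportunities (reference bases
    of the class's origin base seen at that position), count, frequency
    (NaN where there were no opportunities).
    """

    sample_id: str
    span: int
    table: pd.DataFrame

    def frequency(self, end: str, position: int, mismatch_class: str) -> float:
        t = self.table
        row = t[
            (t["end"] == end)
            & (t["position"] == position)
            & (t["mismatch_class"] == mismatch_class)
        ]
        return float(row["frequency"].iloc[0])

    def series(self, end: str, mismatch_class: str) -> np.ndarray:
        t = self.table
        sub = t[(t["end"] == end) & (t["mismatch_class"] == mismatch_class)]
        return sub.sort_values("position")["frequency"].to_numpy()


def damage_profile(
    aln_set: AlignmentSet,
    references: Mapping[str, str],
    span: int = 25,
    sample_id: str | None = None,
) -> DamageProfile:
    """Mismatch frequency by distance from each read end.

    Frequencies are mismatch counts divided by reference-base
    opportunities at that distance, computed in read orientation (bases
    complemented for minus-strand alignments), so the C>T column reads
    directly as the deamination signal.
    """
    # opportunities[end, pos, ref_base]; counts[end, pos, ref_base, read_base]
    opp = np.zeros((2, span, 4), dtype=np.int64)
    cnt = np.zeros((2, span, 4, 4), dtype=np.int64)
    enc = {b: i for i, b in enumerate("ACGT")}

    for a in aln_set.alignments:
        ref_seq = references.get(a.ref_id)
        if ref_seq is None:
            raise KeyError(f"no reference sequence for {a.ref_id!r}")
        seg = ref_seq[a.start:a.end]
        if a.strand == "-":
            seg = "".join(_COMP[c] for c in reversed(seg))
        L = len(seg)
        m5 = min(span, L)
        codes = np.fromiter((enc.get(c, 4) for c in seg), dtype=np.int64, count=L)
        valid5 = codes[:m5] < 4
        np.add.at(opp[0], (np.arange(m5)[valid5], codes[:m5][valid5]), 1)
        rev = codes[::-1]
        valid3 = rev[:m5] < 4
        np.add.at(opp[1], (np.arange(m5)[valid3], rev[:m5][valid3]), 1)
        for ref_pos, ref_b, read_b in a.mismatches:
            # convert to read orientation
            if a.strand == "+":
                i5 = ref_pos - a.start
                rb, qb = ref_b, read_b
            else:
                i5 = a.end - 1 - ref_pos
                rb, qb = _COMP[ref_b], _COMP[read_b]
            i3 = L - 1 - i5
            if rb not in enc or qb not in enc:
                continue
            if i5 < span:
                cnt[0, i5, enc[rb], enc[qb]] += 1
            if i3 < span:
                cnt[1, i3, enc[rb], enc[qb]] += 1

    rows = []
    for ei, end in enumerate(("5p", "3p")):
        for pos in range(span):
            for ai, a_b in enumerate("ACGT"):
                for bi, b_b in enumerate("ACGT"):
                    if ai == bi:
                        continue
                    o = int(opp[ei, pos, ai])
                    c = int(cnt[ei, pos, ai, bi])
                    freq = c / o if o > 0 else float("nan")
                    rows.append((end, pos, f"{a_b}>{b_b}", o, c, freq))
    table = pd.DataFrame(
        rows,
        columns=["end", "position", "mismatch_class", "opportunities",
                 "count", "frequency"],
    )
    return DamageProfile(
        sample_id=sample_id or aln_set.sample_id, span=span, table=table
    )


def end_composition(
    aln_set: AlignmentSet,
    genome: str,
    window: int = 4,
) -> pd.DataFrame:
    """Reference base frequencies at positions -window..+window around 5'
    read starts (genome-space; position 0 is the first read base).

    An excess of purines just upstream of fragment starts is the classic
    depurination fragmentation signature.
    """
    counts = np.zeros((2 * window + 1, 4), dtype=np.int64)
    enc = {b: i for i, b in enumerate("ACGT")}
    n = len(genome)
    for a in aln_set.alignments:
        if a.strand == "+":
            anchor = a.start
            for off in range(-window, window + 1):
                p = anchor + off
                if 0 <= p < n and genome[p] in enc:
                    counts[off + window, enc[genome[p]]] += 1
        else:
            anchor = a.end - 1
            for off in range(-window, window + 1):
                p = anchor - off
                if 0 <= p < n:
                    b = _COMP.get(genome[p])
                    if b in enc:
                        counts[off + window, enc[b]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / totals
    rows = []
    for i, off in enumerate(range(-window, window + 1)):
        for bi, b in enumerate("ACGT"):
            rows.append((off, b, int(counts[i, bi]), float(freqs[i, bi])))
    return pd.DataFrame(rows, columns=["offset", "base", "count", "frequency"])


# ---------------------------------------------------------------------------
# Mapping-summary table I/O (the published layout round-trips unchanged).

SUMMARY_COLUMNS = [
    "platform", "sample_id", "total_reads", "genome", "mrna", "rrna",
    "trna", "rrna_proportion", "enrichment_factor", "endogenous_percent",
]


def read_mapping_summary(path) -> list[MappingCounts]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MappingCounts(
            sample_id=str(r.sample_id),
            platform=str(r.platform),
            total_reads=int(r.total_reads),
            genome=int(r.genome),
            mrna=int(r.mrna),
            rrna=int(r.rrna),
            trna=int(r.trna),
        )
        for r in df.itertuples(index=False)
    ]


def composition_report(
    counts_list: Sequence[MappingCounts],
    length_ratio: float | None = None,
) -> pd.DataFrame:
    """Mapping-summary report in the published column layout.

    ``length_ratio`` is L_g / L_t for the enrichment factor; when omitted
    the factor column is left NaN.
    """
    rows = []
    for c in counts_list:
        ef = (
            round(enrichment_factor(c, length_ratio, 1.0), 2)
            if length_ratio is not None
            else float("nan")
        )
        rows.append(
            (c.platform, c.sample_id, c.total_reads, c.genome, c.mrna,
             c.rrna, c.trna, rrna_proportion(c), ef, endogenous_percent(c))
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
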