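"""Synthetic sequencing data with the statistical structure of degraded RNA.

Emulated features, each controlled by :class:`SimulationConfig`:

* ultrashort fragments (15-30 nt with geometric length decay) mixed with a
  longer 30-80 nt component;
* cytosine deamination: C->T substitutions whose per-position probability
  decays exponentially from each read end plus a flat interior component,
  with no complementary G->A signal (single-stranded library model);
* PCR duplication: a configurable fraction of emitted reads are exact
  copies of earlier reads;
* library composition: rRNA / tRNA / genomic-DNA-contaminant fractions on
  top of tissue-specific mRNA sampling;
* sequencing error as a uniform per-base substitution rate.

Every decision is recorded in a per-read truth table so parameter-recovery
tests can compare what the analysis estimates against what was simulated.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import BASES, ReferenceBundle, revcomp

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclasses.dataclass(frozen=True)
class ReadRecord:
    """A single-end read (FASTQ qualities are constant in this simulator)."""

    read_id: str
    seq: str


@dataclasses.dataclass(frozen=True)
class FragmentLengthModel:
    """Two-component fragment-length mixture.

    With probability ``weight_ultrashort`` the length is drawn from a
    truncated geometric decay on ``ultrashort_range``; otherwise uniformly
    from ``long_range``.  All lengths are >= 15 nt, the adapter-trimming
    retention floor.
    """

    weight_ultrashort: float = 0.7
    ultrashort_range: tuple[int, int] = (15, 30)
    geom_rate: float = 0.15
    long_range: tuple[int, int] = (30, 80)

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_ultrashort <= 1.0:
            raise ValueError("weight_ultrashort must be in [0, 1]")
        if self.ultrashort_range[0] < 15 or self.long_range[0] < 15:
            raise ValueError("fragment lengths must be >= 15 nt")
        if self.geom_rate < 0:
            raise ValueError("geom_rate must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo_u, hi_u = self.ultrashort_range
        lo_l, hi_l = self.long_range
        support = np.arange(lo_u, hi_u + 1)
        w = np.exp(-self.geom_rate * (support - lo_u))
        w /= w.sum()
        ultra = rng.choice(support, size=n, p=w)
        longs = rng.integers(lo_l, hi_l + 1, size=n)
        take_ultra = rng.random(n) < self.weight_ultrashort
        return np.where(take_ultra, ultra, longs)


@dataclasses.dataclass(frozen=True)
class DamageModel:
    """Positional C->T (C>U) deamination model.

    The probability that a reference C at distance ``i`` from a read end is
    read as T is ``delta_max * exp(-decay * i) + flat_rate``; the two ends
    act independently.  ``flat_rate`` carries the elevated interior
    deamination seen in ultrashort single-stranded data.
    """

    delta_max: float = 0.0
    decay: float = 0.5
    flat_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_max <= 1.0:
            raise ValueError("delta_max must be in [0, 1]")
        if not 0.0 <= self.flat_rate <= 1.0:
            raise ValueError("flat_rate must be in [0, 1]")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")

    def rate(self, i: np.ndarray | int) -> np.ndarray:
        """Single-end deamination rate at distance ``i`` from that end."""
        return np.minimum(
            1.0, self.delta_max * np.exp(-self.decay * np.asarray(i)) + self.flat_rate
        )

    def per_position(self, length: int) -> np.ndarray:
        """Combined two-end C->T probability for each position of a read."""
        i = np.arange(length)
        d5 = self.rate(i)
        d3 = self.rate(length - 1 - i)
        return 1.0 - (1.0 - d5) * (1.0 - d3)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated library."""

    seed: int = 0
    n_reads: int = 10_000
    tissue: str = "liver"
    frag: FragmentLengthModel = dataclasses.field(default_factory=FragmentLengthModel)
    damage: DamageModel = dataclasses.field(default_factory=DamageModel)
    dup_target: float = 0.0
    rrna_frac: float = 0.0
    trna_frac: float = 0.0
    dna_contam_frac: float = 0.0
    seq_error: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dup_target", "rrna_frac", "trna_frac", "dna_contam_frac",
                     "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dup_target >= 1.0:
            raise ValueError("dup_target must be < 1")
        if self.rrna_frac + self.trna_frac + self.dna_contam_frac > 1.0:
            raise ValueError("composition fractions must sum to <= 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


def ancient_config(tissue: str, *, seed: int = 0, n_reads: int = 10_000) -> SimulationConfig:
    """Study-condition preset for a degraded (ancient) library: ultrashort-
    heavy fragments, deamination, ~85% duplication, rRNA-dominated
    composition with some DNA carryover."""
    return SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        tissue=tissue,
        frag=FragmentLengthModel(weight_ultrashort=0.7),
        damage=DamageModel(delta_max=0.3, decay=0.5, flat_rate=0.01),
        dup_target=0.85,
        rrna_frac=0.30,
        trna_frac=0.05,
        dna_contam_frac=0.05,
        seq_error=0.001,
    )


def control_config(tissue: str, *, seed: int = 0, n_reads: int = 10_000) -> SimulationConfig:
    """Preset for a modern control library: long undamaged fragments,
    moderate duplication, little rRNA."""
    return SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        tissue=tissue,
        frag=FragmentLengthModel(weight_ultrashort=0.0, long_range=(60, 80)),
        damage=DamageModel(delta_max=0.0, flat_rate=0.0),
        dup_target=0.30,
        rrna_frac=0.05,
        trna_frac=0.01,
        dna_contam_frac=0.0,
        seq_error=0.001,
    )


@dataclasses.dataclass
class TruthSet:
    """Ground truth for a simulated read set, one row per read.

    Columns: read_id, source_class (mRNA/rRNA/tRNA/genomic-DNA/blank-noise),
    source_id, start, end (0-based half-open on the source), strand, tissue,
    duplicate_of (read id or ''), damage ('pos:C>T;...' in read coordinates).
    """

    table: pd.DataFrame

    COLUMNS = (
        "read_id", "source_class", "source_id", "start", "end",
        "strand", "tissue", "duplicate_of", "damage",
    )

    def __len__(self) -> int:
        return len(self.table)

    def duplicate_fraction(self) -> float:
        if len(self.table) == 0:
            return 0.0
        return float((self.table["duplicate_of"] != "").mean())

    def class_counts(self) -> pd.Series:
        return self.table["source_class"].value_counts()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthSet":
        table = pd.read_csv(
            path, sep="\t", dtype={"duplicate_of": str, "damage": str}
        )
        table["duplicate_of"] = table["duplicate_of"].fillna("")
        table["damage"] = table["damage"].fillna("")
        return cls(table)


def _apply_damage(
    seq: str, model: DamageModel, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    """Deaminate cytosines in read orientation; returns (sequence, events)."""
    if model.delta_max == 0.0 and model.flat_rate == 0.0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    c_pos = np.flatnonzero(arr == ord("C"))
    if c_pos.size == 0:
        return seq, []
    p = model.per_position(len(seq))[c_pos]
    hit = c_pos[rng.random(c_pos.size) < p]
    if hit.size == 0:
        return seq, []
    arr[hit] = ord("T")
    return arr.tobytes().decode(), [(int(i), "C", "T") for i in hit]


def _apply_seq_error(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0.0:
        return seq
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alts = [b for b in BASES if b != chars[i]]
        chars[i] = alts[rng.integers(0, 3)]
    return "".join(chars)


def simulate_sample(
    ref: ReferenceBundle, cfg: SimulationConfig
) -> tuple[list[ReadRecord], TruthSet]:
    """Simulate one single-end library from a reference bundle.

    RNA reads are sense-strand (small-RNA ligation libraries are stranded);
    genomic contaminant reads come from either strand with probability 1/2.
    Duplicates are exact copies of previously emitted reads, sampled
    uniformly, so the realised duplicate fraction matches ``dup_target`` in
    expectation.
    """
    if not ref.transcripts:
        raise ValueError("reference has no transcripts")
    rng = np.random.default_rng(cfg.seed)

    mrna_ids = list(ref.tissue_profiles.index)
    if cfg.tissue not in ref.tissue_profiles.columns:
        raise ValueError(f"unknown tissue {cfg.tissue!r}")
    mrna_p = ref.tissue_profiles[cfg.tissue].to_numpy()
    rrna_ids = [g.gene_id for g in ref.genes_by_biotype("rRNA")]
    trna_ids = [g.gene_id for g in ref.genes_by_biotype("tRNA")]

    reads: list[ReadRecord] = []
    rows: list[tuple] = []
    frag_lengths = cfg.frag.sample(rng, cfg.n_reads)

    for i in range(cfg.n_reads):
        rid = f"{cfg.tissue}_read{i:07d}"
        if i > 0 and rng.random() < cfg.dup_target:
            j = int(rng.integers(0, len(reads)))
            src = rows[j]
            reads.append(ReadRecord(rid, reads[j].seq))
            rows.append((rid, src[1], src[2], src[3], src[4], src[5],
                         src[6], reads[j].read_id, src[8]))
            continue

        u = rng.random()
        if u < cfg.rrna_frac:
            source_class, source_id = "rRNA", rrna_ids[int(rng.integers(len(rrna_ids)))]
            template, strand = ref.transcripts[source_id], "+"
        elif u < cfg.rrna_frac + cfg.trna_frac:
            source_class, source_id = "tRNA", trna_ids[int(rng.integers(len(trna_ids)))]
            template, strand = ref.transcripts[source_id], "+"
        elif u < cfg.rrna_frac + cfg.trna_frac + cfg.dna_contam_frac:
            source_class, source_id = "genomic-DNA", "chr1"
            template = ref.genome
            strand = "+" if rng.random() < 0.5 else "-"
        else:
            source_class = "mRNA"
            source_id = mrna_ids[int(rng.choice(len(mrna_ids), p=mrna_p))]
            template, strand = ref.transcripts[source_id], "+"

        length = int(min(frag_lengths[i], len(template)))
        start = int(rng.integers(0, len(template) - length + 1))
        end = start + length
        seq = template[start:end]
        if strand == "-":
            seq = revcomp(seq)
        seq, events = _apply_damage(seq, cfg.damage, rng)
        seq = _apply_seq_error(seq, cfg.seq_error, rng)
        damage_str = ";".join(f"{p}:{a}>{b}" for p, a, b in events)
        reads.append(ReadRecord(rid, seq))
        rows.append((rid, source_class, source_id, start, end, strand,
                     cfg.tissue, "", damage_str))

    truth = TruthSet(pd.DataFrame(rows, columns=list(TruthSet.COLUMNS)))
    return reads, truth


def simulate_blank(
    cfg: SimulationConfig,
    ref: ReferenceBundle | None = None,
    trace_frac: float = 0.0,
) -> tuple[list[ReadRecord], TruthSet]:
    """Simulate an extraction blank: random sequence plus an optional trace
    (< 0.1% by default convention) of reference-derived reads."""
    if trace_frac > 0.0 and ref is None:
        raise ValueError("trace_frac > 0 requires a reference bundle")
    rng = np.random.default_rng(cfg.seed)
    lengths = cfg.frag.sample(rng, cfg.n_reads)
    reads: list[ReadRecord] = []
    rows: list[tuple] = []
    transcript_ids = list(ref.transcripts) if ref is not None else []
    for i in range(cfg.n_reads):
        rid = f"blank_read{i:07d}"
        length = int(lengths[i])
        if transcript_ids and rng.random() < trace_frac:
            tid = transcript_ids[int(rng.integers(len(transcript_ids)))]
            template = ref.transcripts[tid]
            ln = min(length, len(template))
            start = int(rng.integers(0, len(template) - ln + 1))
            reads.append(ReadRecord(rid, template[start:start + ln]))
            rows.append((rid, "trace", tid, start, start + ln, "+", "blank", "", ""))
        else:
            idx = rng.integers(0, 4, size=length)
            reads.append(ReadRecord(rid, "".join(BASES[b] for b in idx)))
            rows.append((rid, "blank-noise", "", 0, length, "+", "blank", "", ""))
    return reads, TruthSet(pd.DataFrame(rows, columns=list(TruthSet.COLUMNS)))


def fragment_modern(
    reads: Sequence[ReadRecord],
    n_subsample: int,
    len_min: int = 15,
    n_subsets: int = 35,
    seed: int = 0,
) -> list[ReadRecord]:
    """In-silico fragmenter for modern control reads.

    For each subset ``k`` in ``[0, n_subsets)`` a fresh random subsample of
    ``n_subsample`` reads is truncated (from the 5' end) to length
    ``len_min + k`` and all subsets are merged, emulating degraded-length
    read sets built from long modern inserts.  With the defaults this is 35
    subsets of lengths 15..49.  Reads too short for the longest truncation
    are excluded from the sampling pool.
    """
    if n_subsample > len(reads):
        raise ValueError("n_subsample exceeds the number of input reads")
    max_len = len_min + n_subsets - 1
    pool = [r for r in reads if len(r.seq) >= max_len]
    n_rejected = len(reads) - len(pool)
    if n_rejected:
        import logging

        logging.getLogger(__name__).info(
            "fragment_modern: %d reads shorter than %d nt excluded from pool",
            n_rejected, max_len,
        )
    if n_subsample > len(pool):
        raise ValueError(
            f"n_subsample={n_subsample} exceeds usable pool of {len(pool)} reads"
        )
    rng = np.random.default_rng(seed)
    out: list[ReadRecord] = []
    for k in range(n_subsets):
        target = len_min + k
        idx = rng.choice(len(pool), size=n_subsample, replace=False)
        for j in idx:
            r = pool[int(j)]
            out.append(ReadRecord(f"{r.read_id}|sub{k}", r.seq[:target]))
    return out


# ---------------------------------------------------------------------------
# FASTQ I/O (fixed quality) and truth-backed alignments.

def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def read_fastq(path) -> list[ReadRecord]:
    from Bio import SeqIO

    return [
        ReadRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fastq")
    ]


def alignments_from_truth(
    reads: Sequence[ReadRecord],
    truth: TruthSet,
    ref: ReferenceBundle,
    source_classes: tuple[str, ...] = ("mRNA", "rRNA", "tRNA"),
    sample_id: str = "truth",
):
    """Build an alignment set by placing reads at their true intervals.

    Bypasses the mapper so estimator accuracy (e.g. damage-profile
    recovery) can be measured without mapper losses.  Mismatches are
    recomputed by comparing read to source sequence.
    """
    from .align import Alignment, AlignmentSet

    by_id = {r.read_id: r for r in reads}
    alignments = []
    for row in truth.table.itertuples(index=False):
        if row.source_class not in source_classes:
            continue
        read = by_id[row.read_id]
        if row.source_class == "genomic-DNA":
            template = ref.genome
        else:
            template = ref.transcripts[row.source_id]
        ref_seg = template[row.start:row.end]
        read_on_ref = read.seq if row.strand == "+" else revcomp(read.seq)
        mismatches = tuple(
            (row.start + k, a, b)
            for k, (a, b) in enumerate(zip(ref_seg, read_on_ref))
            if a != b
        )
        alignments.append(
            Alignment(
                read_id=row.read_id,
                ref_id=row.source_id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                seq=read.seq,
                mismatches=mismatches,
            )
        )
    ref_class = source_classes[0] if len(source_classes) == 1 else "mixed"
    return AlignmentSet(
        sample_id=sample_id,
        reference_class=ref_class,
        alignments=alignments,
        n_total_reads=len(reads),
    )
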