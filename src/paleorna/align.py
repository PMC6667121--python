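"""Lightweight alignment plumbing for desk-scale references.

The mapper is an ungapped k-mer-seeded aligner intended for toy references
(a few hundred kb): seeds of length k are taken at ``m + 1`` disjoint
offsets for a read allowed ``m`` mismatches, so by pigeonhole every
placement within the mismatch allowance is found; candidates are then
scored exactly and the best placement reported.  The mismatch allowance
follows read length: 0 below 20 nt, 1 for 20-31 nt, 2 from 32 nt.

Limitations (deliberate): no indels (fragments are <= 80 nt), no base
qualities, sense-strand-only search against transcript references
(stranded library), both strands against the genome.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import revcomp
from .simulate import ReadRecord

logger = logging.getLogger(__name__)

_SEED_K = 10
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def mismatch_allowance(length: int) -> int:
    """Allowed mismatches by read length: 0 (<20 nt), 1 (20-31 nt), 2 (>=32 nt)."""
    if length < 20:
        return 0
    if length <= 31:
        return 1
    return 2


@dataclasses.dataclass(frozen=True)
class Alignment:
    """An ungapped read placement on one reference sequence.

    ``mismatches`` are (reference coordinate, reference base, aligned base)
    with bases given on the reference strand.
    """

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    seq: str  # read sequence in read orientation
    mismatches: tuple[tuple[int, str, str], ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class AlignmentSet:
    """Alignments of one sample against one reference class."""

    sample_id: str
    reference_class: str
    alignments: list[Alignment]
    deduplicated: bool = False
    n_total_reads: int = 0
    n_unmapped: int = 0
    n_duplicates_removed: int = 0

    def __len__(self) -> int:
        return len(self.alignments)


class KmerIndex:
    """Exact k-mer index over a set of reference sequences."""

    def __init__(self, references: Mapping[str, str], k: int = _SEED_K):
        self.k = k
        self.ref_ids = list(references)
        seqs = [references[r] for r in self.ref_ids]
        self.ref_lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        # Concatenate with k 'N' separators so no window spans two references.
        sep = "N" * k
        concat = sep.join(seqs)
        self.concat = _ENC[np.frombuffer(concat.encode(), dtype=np.uint8)]
        starts = np.zeros(len(seqs), dtype=np.int64)
        off = 0
        for i, s in enumerate(seqs):
            starts[i] = off
            off += len(s) + k
        self.ref_starts = starts
        self.ref_ends = starts + self.ref_lengths

        if len(self.concat) >= k:
            win = np.lib.stride_tricks.sliding_window_view(self.concat, k)
            valid = (win < 4).all(axis=1)
            codes = win.astype(np.int64) @ (4 ** np.arange(k - 1, -1, -1))
            pos = np.flatnonzero(valid)
            codes = codes[pos]
            order = np.argsort(codes, kind="stable")
            self._sorted_codes = codes[order]
            self._sorted_pos = pos[order]
        else:
            self._sorted_codes = np.empty(0, dtype=np.int64)
            self._sorted_pos = np.empty(0, dtype=np.int64)

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted_codes, code, side="left")
        hi = np.searchsorted(self._sorted_codes, code, side="right")
        return self._sorted_pos[lo:hi]

    def ref_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.ref_ends, gpos, side="right"))


def _encode_read(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def map_reads(
    reads: Sequence[ReadRecord],
    references: Mapping[str, str],
    reference_class: str,
    *,
    sample_id: str = "sample",
    seed: int = 0,
    both_strands: bool | None = None,
    index: KmerIndex | None = None,
) -> AlignmentSet:
    """Map reads to references at their best (fewest-mismatch) placement.

    Multi-mapping ties are broken by a seeded uniform choice.  Reads with
    non-ACGT symbols are skipped with a log entry; unmapped reads are
    excluded but counted.
    """
    if not references:
        raise ValueError("references must be nonempty")
    if both_strands is None:
        both_strands = reference_class == "genome"
    idx = index if index is not None else KmerIndex(references)
    k = idx.k
    rng = np.random.default_rng(seed)
    powers = 4 ** np.arange(k - 1, -1, -1)

    alignments: list[Alignment] = []
    n_unmapped = 0
    n_skipped = 0
    for read in reads:
        ell = len(read.seq)
        if ell < k:
            n_unmapped += 1
            continue
        fwd = _encode_read(read.seq)
        if (fwd > 3).any():
            n_skipped += 1
            logger.debug("read %s contains non-ACGT symbols; skipped", read.read_id)
            continue
        m = mismatch_allowance(ell)
        n_seeds = min(m + 1, ell // k)
        offsets = [i * k for i in range(max(1, n_seeds))]

        strands = [("+", fwd)]
        if both_strands:
            strands.append(("-", fwd[::-1] ^ 3))

        best: list[tuple[int, str, int]] = []  # (mismatches, strand, gstart)
        best_mm = m + 1
        seen: set[tuple[str, int]] = set()
        for strand, arr in strands:
            for off in offsets:
                code = int(arr[off:off + k] @ powers)
                for hit in idx.lookup(code):
                    g = int(hit) - off
                    key = (strand, g)
                    if key in seen:
                        continue
                    seen.add(key)
                    r = idx.ref_of(g)
                    if g < idx.ref_starts[r] or g + ell > idx.ref_ends[r]:
                        continue
                    mm = int(np.count_nonzero(idx.concat[g:g + ell] != arr))
                    if mm < best_mm:
                        best_mm = mm
                        best = [(mm, strand, g)]
                    elif mm == best_mm and best_mm <= m:
                        best.append((mm, strand, g))
        if best_mm > m or not best:
            n_unmapped += 1
            continue
        mm, strand, g = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
        r = idx.ref_of(g)
        start = g - int(idx.ref_starts[r])
        ref_id = idx.ref_ids[r]
        arr = fwd if strand == "+" else fwd[::-1] ^ 3
        diff = np.flatnonzero(idx.concat[g:g + ell] != arr)
        mismatches = tuple(
            ("ACGT"[idx.concat[g + d]], "ACGT"[arr[d]], int(d)) for d in diff
        )
        mismatches = tuple(
            (start + d, a, b) for a, b, d in mismatches
        )
        alignments.append(
            Alignment(read.read_id, ref_id, start, start + ell, strand,
                      read.seq, mismatches)
        )
    if n_skipped:
        logger.info("%d reads with non-ACGT symbols skipped", n_skipped)
    return AlignmentSet(
        sample_id=sample_id,
        reference_class=reference_class,
        alignments=alignments,
        n_total_reads=len(reads),
        n_unmapped=n_unmapped + n_skipped,
    )


def deduplicate(obj):
    """Collapse identical full-length read sequences to one representative.

    Accepts either a sequence of :class:`ReadRecord` or an
    :class:`AlignmentSet`; returns the same kind.  The first occurrence is
    kept and the number removed is retained for duplication-rate reporting.
    Idempotent.
    """
    if isinstance(obj, AlignmentSet):
        seen: set[str] = set()
        kept = []
        for a in obj.alignments:
            if a.seq not in seen:
                seen.add(a.seq)
                kept.append(a)
        return AlignmentSet(
            sample_id=obj.sample_id,
            reference_class=obj.reference_class,
            alignments=kept,
            deduplicated=True,
            n_total_reads=obj.n_total_reads,
            n_unmapped=obj.n_unmapped,
            n_duplicates_removed=obj.n_duplicates_removed
            + (len(obj.alignments) - len(kept)),
        )
    seen = set()
    out = []
    for r in obj:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


def filter_min_length(aln_set: AlignmentSet, min_len: int = 30) -> AlignmentSet:
    """Retain alignments of reads at least ``min_len`` nt long (inclusive)."""
    kept = [a for a in aln_set.alignments if a.length >= min_len]
    return dataclasses.replace(aln_set, alignments=kept)


def per_base_depth(
    aln_set: AlignmentSet, transcript_id: str, ref_lengths: Mapping[str, int]
) -> np.ndarray:
    """Depth vector over one transcript: depth[p] = alignments covering p."""
    if transcript_id not in ref_lengths:
        raise KeyError(f"unknown transcript id {transcript_id!r}")
    L = ref_lengths[transcript_id]
    delta = np.zeros(L + 1, dtype=np.int64)
    for a in aln_set.alignments:
        if a.ref_id == transcript_id:
            delta[a.start] += 1
            delta[a.end] -= 1
    return np.cumsum(delta[:-1])


def mean_coverage(
    aln_set: AlignmentSet, ref_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-transcript coverage table.

    Columns: transcript_id, length, total_depth (summed per-position depth,
    equal to the total aligned bases on that transcript) and mean_coverage
    = total_depth / length.
    """
    depth: dict[str, int] = {t: 0 for t in ref_lengths}
    for a in aln_set.alignments:
        if a.ref_id in depth:
            depth[a.ref_id] += a.length
    rows = [
        (t, ref_lengths[t], depth[t], depth[t] / ref_lengths[t])
        for t in ref_lengths
    ]
    return pd.DataFrame(
        rows, columns=["transcript_id", "length", "total_depth", "mean_coverage"]
    )


def gc_content(seq_or_set) -> float:
    """G+C fraction of a sequence, an iterable of reads, or an AlignmentSet.

    Raises ValueError on empty input (an empty sequence has no defined GC).
    """
    if isinstance(seq_or_set, str):
        seqs: Iterable[str] = [seq_or_set]
    elif isinstance(seq_or_set, AlignmentSet):
        seqs = (a.seq for a in seq_or_set.alignments)
    else:
        seqs = (getattr(r, "seq", r) for r in seq_or_set)
    gc = total = 0
    for s in seqs:
        total += len(s)
        gc += s.count("G") + s.count("C")
    if total == 0:
        raise ValueError("GC content undefined for empty input")
    return gc / total


def gc_report(
    p95_transcripts: Mapping[str, str],
    aln_dedup: AlignmentSet,
    aln_dup: AlignmentSet,
) -> pd.DataFrame:
    """Per-sample GC summary: reference transcripts of the high-expression
    set vs mapped reads with and without duplicate collapsing."""

    def _safe(x):
        try:
            return gc_content(x)
        except ValueError:
            return float("nan")

    rows = [
        ("reference_p95_transcripts", _safe(list(p95_transcripts.values()))),
        ("reads_deduplicated", _safe(aln_dedup)),
        ("reads_duplicates_retained", _safe(aln_dup)),
    ]
    return pd.DataFrame(rows, columns=["set", "gc_fraction"])


# ---------------------------------------------------------------------------
# SAM I/O (text SAM; ungapped CIGAR, NM tag).

def write_sam(aln_set: AlignmentSet, ref_lengths: Mapping[str, int], path) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r, "LN": int(L)} for r, L in ref_lengths.items()],
    }
    ref_index = {r: i for i, r in enumerate(ref_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in aln_set.alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.reference_id = ref_index[a.ref_id]
            seg.reference_start = a.start
            seg.mapping_quality = 60
            seg.cigarstring = f"{a.length}M"
            seg.flag = 16 if a.strand == "-" else 0
            seg.query_sequence = a.seq if a.strand == "+" else revcomp(a.seq)
            seg.set_tag("NM", len(a.mismatches))
            fh.write(seg)


def read_sam(
    path,
    references: Mapping[str, str] | None = None,
    reference_class: str = "mRNA",
    sample_id: str = "sample",
) -> AlignmentSet:
    """Read a SAM file back into an AlignmentSet.

    If reference sequences are supplied, mismatch records are recomputed by
    comparison; otherwise alignments carry no mismatch detail.
    """
    import pysam

    alignments = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                n_unmapped += 1
                continue
            strand = "-" if seg.is_reverse else "+"
            seq_on_ref = seg.query_sequence
            seq = seq_on_ref if strand == "+" else revcomp(seq_on_ref)
            start = seg.reference_start
            end = start + len(seq)
            mismatches: tuple = ()
            if references is not None and seg.reference_name in references:
                ref_seg = references[seg.reference_name][start:end]
                mismatches = tuple(
                    (start + k, a, b)
                    for k, (a, b) in enumerate(zip(ref_seg, seq_on_ref))
                    if a != b
                )
            alignments.append(
                Alignment(seg.query_name, seg.reference_name, start, end,
                          strand, seq, mismatches)
            )
    return AlignmentSet(
        sample_id=sample_id,
        reference_class=reference_class,
        alignments=alignments,
        n_total_reads=len(alignments) + n_unmapped,
        n_unmapped=n_unmapped,
    )
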