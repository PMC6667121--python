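import numpy as np
import pytest

from paleorna import build_reference
from paleorna.align import mismatch_allowance

SEQUENCED_TISSUES = ["skin", "liver", "muscle", "cartilage"]


@pytest.fixture(scope="session")
def ref():
    """Shared 60-gene toy reference."""
    return build_reference(60, seed=1)


@pytest.fixture(scope="session")
def small_ref():
    """Minimal reference for brute-force oracle comparisons."""
    return build_reference(12, seed=7)


def brute_force_best_hits(read_seq, references, both_strands=False):
    """All-positions scan oracle: best mismatch count and the set of
    (ref_id, start, strand) placements achieving it (ungapped model)."""
    from paleorna.reference import revcomp

    ell = len(read_seq)
    best = ell + 1
    hits = []
    variants = [("+", read_seq)]
    if both_strands:
        variants.append(("-", revcomp(read_seq)))
    for ref_id, seq in references.items():
        for strand, query in variants:
            for start in range(0, len(seq) - ell + 1):
                mm = sum(
                    1 for a, b in zip(seq[start:start + ell], query) if a != b
                )
                if mm < best:
                    best = mm
                    hits = [(ref_id, start, strand)]
                elif mm == best:
                    hits.append((ref_id, start, strand))
    if best > mismatch_allowance(ell):
        return None, []
    return best, hits


def brute_force_depth(aln_set, transcript_id, length):
    """Position-loop depth oracle."""
    depth = np.zeros(length, dtype=int)
    for a in aln_set.alignments:
        if a.ref_id != transcript_id:
            continue
        for p in range(a.start, a.end):
            depth[p] += 1
    return depth


def brute_force_straddlers(aln_set, junctions_by_ref, overhang):
    """All (read, junction) pairs oracle; each read counted once."""
    n = 0
    for a in aln_set.alignments:
        for j in junctions_by_ref.get(a.ref_id, ()):
            if a.start <= j - overhang and a.end >= j + overhang:
                n += 1
                break
    return n
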