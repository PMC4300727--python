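import numpy as np
import pytest

from haplosv.refio import ReferenceSet, revcomp


def random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ref(rng):
    ref = ReferenceSet()
    ref.add_sequence("chr1", random_dna(3000, rng))
    return ref


def brute_force_repeats(seqs: dict[str, str], min_len: int,
                        include_rc: bool = True):
    """O(L^2) independent oracle: the set of (seq_id, start, end) intervals
    (1-based) taking part in any maximal exact match >= min_len, on either
    strand.  Matches are found by longest-common-extension over every pair
    of start positions on every diagonal."""
    intervals = set()
    items = sorted(seqs.items())
    for ai, (sa, A) in enumerate(items):
        for sb, B in items[ai:]:
            for i in range(len(A)):
                for j in range(len(B)):
                    if sa == sb and j <= i:
                        continue
                    # forward: maximal only if not extendable left
                    if A[i] == B[j] and "N" not in (A[i],):
                        if i > 0 and j > 0 and A[i - 1] == B[j - 1]:
                            pass
                        else:
                            k = 0
                            while (i + k < len(A) and j + k < len(B)
                                   and A[i + k] == B[j + k]
                                   and A[i + k] != "N"):
                                k += 1
                            if k >= min_len:
                                intervals.add((sa, i + 1, i + k))
                                intervals.add((sb, j + 1, j + k))
            if include_rc:
                Brc = revcomp(B)
                for i in range(len(A)):
                    for j in range(len(Brc)):
                        if A[i] == Brc[j] and A[i] != "N":
                            if i > 0 and j > 0 and A[i - 1] == Brc[j - 1]:
                                continue
                            k = 0
                            while (i + k < len(A) and j + k < len(Brc)
                                   and A[i + k] == Brc[j + k]
                                   and A[i + k] != "N"):
                                k += 1
                            if k >= min_len:
                                gA = (sa, i + 1, i + k)
                                gB = (sb, len(B) - (j + k) + 1, len(B) - j)
                                if sa == sb and gA == gB:
                                    continue  # a palindrome matching itself
                                intervals.add(gA)
                                intervals.add(gB)
    return intervals


def best_local_score_vs_reference(read: str, refseq: str) -> float:
    """Brute-force best ungapped local alignment score of a read against
    one reference sequence (both strands), +1 match / -3 mismatch.  An
    independent oracle for the mapper and the continuation-length logic."""
    best = 0.0
    for query in (read, revcomp(read)):
        n, m = len(query), len(refseq)
        for diag in range(-n + 1, m):
            cur = run_best = 0.0
            for k in range(n):
                g = diag + k
                if g < 0 or g >= m:
                    continue
                cur += 1.0 if query[k] == refseq[g] else -3.0
                if cur < 0:
                    cur = 0.0
                if cur > run_best:
                    run_best = cur
            if run_best > best:
                best = run_best
    return best
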