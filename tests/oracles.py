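"""Independent naive reference implementations used to check the package.

Everything here is deliberately written the simple, slow way (plain Python
loops, exhaustive enumeration) and shares no code with the package internals
beyond the public alphabet conventions.
"""

from __future__ import annotations

from collections import Counter

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def naive_window_counts(sequences: list[str], k: int) -> Counter:
    """Forward-strand k-mer counts by brute-force sliding window."""
    counts: Counter = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                counts[w] += 1
    return counts


def naive_unique_kmers(per_species: dict[str, list[str]], target: str,
                       k: int) -> set[str]:
    """Multiset difference: count==1 in target, absent from all others."""
    counts = {sp: naive_window_counts(seqs, k)
              for sp, seqs in per_species.items()}
    others: set[str] = set()
    for sp, c in counts.items():
        if sp != target:
            others |= set(c)
    return {w for w, n in counts[target].items() if n == 1 and w not in others}


# ---------------------------------------------------------------------------
# second, independent coding of the composition rules
# ---------------------------------------------------------------------------

def naive_filter_rules(seq: str,
                       tm_lo=67.0, tm_hi=82.0,
                       gc_full=(11, 17), gc_half=(4, 10),
                       end_win=5, end_gc=3, end_at=3,
                       run=4, dinuc=3) -> list[str]:
    """All failing rule labels of a 30-mer, evaluated independently."""
    failed = []
    n = len(seq)
    ngc = len([c for c in seq if c in "GC"])
    tm = 81.5 + 0.41 * (100.0 * ngc / n) - 675.0 / n
    if tm < tm_lo or tm > tm_hi:
        failed.append("TM")
    if ngc < gc_full[0] or ngc > gc_full[1]:
        failed.append("GC_FULL")
    h = n // 2
    for half in (seq[:h], seq[n - h:]):
        g = len([c for c in half if c in "GC"])
        if g < gc_half[0] or g > gc_half[1]:
            failed.append("GC_HALF")
            break
    if seq[0] in "AT" and seq[-1] in "AT":
        failed.append("END_BOTH_AT")
    head, tail = seq[:end_win], seq[-end_win:]
    if (len([c for c in head if c in "GC"]) >= end_gc
            and len([c for c in tail if c in "GC"]) >= end_gc):
        failed.append("END_GC_RUN")
    if (len([c for c in head if c in "AT"]) >= end_at
            and len([c for c in tail if c in "AT"]) >= end_at):
        failed.append("END_AT_RUN")
    longest = 1
    cur = 1
    for i in range(1, n):
        cur = cur + 1 if seq[i] == seq[i - 1] else 1
        longest = max(longest, cur)
    if longest >= run:
        failed.append("HOMOPOLYMER")
    best_rep = 0
    for i in range(n - 1):
        a, b = seq[i], seq[i + 1]
        if a == b:
            continue
        reps = 0
        j = i
        while j + 1 < n and seq[j] == a and seq[j + 1] == b:
            reps += 1
            j += 2
        best_rep = max(best_rep, reps)
    if best_rep >= dinuc:
        failed.append("DINUC_REPEAT")
    return failed


# ---------------------------------------------------------------------------
# exhaustive ungapped local alignment (all diagonals, both strands)
# ---------------------------------------------------------------------------

def _diagonal_best(q: str, t: str, match=1, mismatch=-3):
    """Best (score, length, qstart, tstart) segment over every diagonal."""
    out = []
    nq, nt = len(q), len(t)
    for d in range(-(nq - 1), nt):
        # diagonal: q[i] vs t[i + d]
        i0 = max(0, -d)
        i1 = min(nq, nt - d)
        best = (0, 0, 0, 0)
        cur = 0
        cur_start = i0
        for i in range(i0, i1):
            s = match if (q[i] == t[i + d] and q[i] != "N" and t[i + d] != "N") \
                else mismatch
            if cur <= 0:
                cur = s
                cur_start = i
            else:
                cur += s
            if cur > best[0]:
                best = (cur, i + 1 - cur_start, cur_start, cur_start + d)
        if best[0] > 0:
            out.append(best)
    return out


def naive_local_alignments(query: str, text: str, match=1, mismatch=-3
                           ) -> list[tuple[int, int, int, int, str]]:
    """All per-diagonal optimal ungapped segments of query vs text, both
    strands: (score, length, qstart, tstart_forward, strand). Coordinates of
    '-' strand hits are on the forward text."""
    hits = []
    for strand, q in (("+", query), ("-", rc(query))):
        for score, length, qs, ts in _diagonal_best(q, text, match, mismatch):
            hits.append((score, length, qs, ts, strand))
    return hits


def max_alignment_length(query: str, text: str, exclude_span=None) -> int:
    """Longest per-diagonal-optimal segment, optionally excluding the exact
    source span (tstart, tend) on the forward strand."""
    best = 0
    for score, length, qs, ts, strand in naive_local_alignments(query, text):
        if exclude_span and strand == "+" and ts == exclude_span[0] \
                and ts + length == exclude_span[1]:
            continue
        best = max(best, length)
    return best


def longest_common_exact(a: str, b: str) -> int:
    """Longest exact common substring (forward only), brute force."""
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            l = 0
            while (i + l < len(a) and j + l < len(b) and a[i + l] == b[j + l]
                   and a[i + l] != "N"):
                l += 1
            best = max(best, l)
    return best


def naive_identity_shorter(a: str, b: str) -> float:
    """Global identity of the shorter sequence against the longer, exhaustive
    over all ungapped placements (adequate oracle for substitution-only and
    containment test fixtures)."""
    s, l = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for off in range(len(l) - len(s) + 1):
        m = sum(1 for x, y in zip(s, l[off:]) if x == y and x != "N")
        best = max(best, m)
    return best / len(s)
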