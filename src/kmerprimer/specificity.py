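"""Two-stage cross-species specificity screen.

Stage 1 (exact): a candidate is discarded if its full-length sequence occurs
more than once in its own species (counting both strands), or if any
``exact_other_min`` (default 26) consecutive bases of it occur verbatim in
another species. This mirrors the fast short-read-mapper pre-filter used for
bulk removal.

Stage 2 (local alignment): survivors are aligned against every contig with a
seed-and-extend ungapped local alignment (exact seeds of ``seed_len`` bases,
+1 match / -3 mismatch). A candidate is discarded if, besides its own source
locus, it aligns to its own species over >= ``local_same_min`` columns
(a 24-29 bp partial hit or a second near-full-length hit), or to another
species over >= ``local_other_min`` (> 25 bp) columns. This is the
short-query BLASTN analogue and catches near matches the exact stage misses.

Implementation: per seeded diagonal the optimal ungapped segment is computed
(vectorised Kadane over the diagonal band), i.e. the alignment an X-drop
extension converges to; alignment length is the number of aligned columns,
the BLAST convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .kmer_core import PrimerCandidate
from .seqio import SpeciesSequenceSet, revcomp

REASON_SAME_MULTIMAP = "SAME_MULTIMAP"
REASON_OTHER_EXACT = "OTHER_EXACT"
REASON_SAME_EXTRA = "SAME_EXTRA"
REASON_OTHER_LOCAL = "OTHER_LOCAL"

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_PAD = 40  # sentinel run between/around contigs; > any query length


@dataclass(frozen=True)
class SpecificityConfig:
    exact_other_min: int = 26
    local_same_min: int = 24
    local_same_max: int = 29
    local_other_min: int = 26
    both_strands: bool = True
    align_match: int = 1
    align_mismatch: int = -3
    seed_len: int = 7
    xdrop: int = 12

    def __post_init__(self) -> None:
        if self.local_same_min > self.local_same_max:
            raise ValueError("local_same_min > local_same_max")

    @property
    def report_min(self) -> int:
        return min(self.local_same_min, self.local_other_min)


@dataclass
class Hit:
    species_id: str
    contig_id: str
    start: int          # 0-based half-open, contig forward strand
    end: int
    strand: str
    match_len: int      # aligned columns
    identity: float


@dataclass
class SpecificityReport:
    candidate_id: str
    stage: str                      # EXACT or LOCAL
    hits: list[Hit] = field(default_factory=list)
    removal_reason: str | None = None


class _SpeciesIndex:
    """Encoded text + sorted m-mer and seed tables for one species."""

    def __init__(self, sset: SpeciesSequenceSet, cfg: SpecificityConfig):
        self.species_id = sset.species_id
        sep = "N" * _PAD
        parts: list[str] = []
        self.contig_ids: list[str] = []
        starts: list[int] = []
        pos = _PAD
        parts.append(sep)
        for cid, seq in sset:
            self.contig_ids.append(cid)
            starts.append(pos)
            parts.append(seq)
            parts.append(sep)
            pos += len(seq) + _PAD
        self.text = "".join(parts)
        self.contig_starts = np.asarray(starts, dtype=np.int64)
        self.contig_lens = np.asarray([len(s) for _, s in sset], dtype=np.int64)
        self.arr = _CODE[np.frombuffer(self.text.encode("ascii"), dtype=np.uint8)]
        self.mmers, self.mmer_pos = _window_table(self.arr, cfg.exact_other_min)
        self.seeds, self.seed_pos = _window_table(self.arr, cfg.seed_len)
        self._tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def table(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        """Sorted window table of the given length, built on first use."""
        if length not in self._tables:
            self._tables[length] = _window_table(self.arr, length)
        return self._tables[length]

    def locate(self, text_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map text positions to (contig index, contig-local offset)."""
        ci = np.searchsorted(self.contig_starts, text_pos, side="right") - 1
        return ci, text_pos - self.contig_starts[ci]


def _window_table(arr: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted codes (base-4 packed) and positions of all valid windows."""
    n = arr.shape[0]
    if n < length:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    m = n - length + 1
    codes = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    a64 = arr.astype(np.uint64)
    for t in range(length):
        codes = codes * np.uint64(4) + a64[t : t + m]
        bad |= arr[t : t + m] == 4
    pos = np.nonzero(~bad)[0]
    codes = codes[pos]
    order = np.argsort(codes, kind="stable")
    return codes[order], pos[order].astype(np.int64)


def _encode_windows(seq: str, length: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, query offsets) of the valid length-``length`` windows of seq."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = arr.shape[0]
    if n < length:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    m = n - length + 1
    codes = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    a64 = arr.astype(np.uint64)
    for t in range(length):
        codes = codes * np.uint64(4) + a64[t : t + m]
        bad |= arr[t : t + m] == 4
    offs = np.nonzero(~bad)[0].astype(np.int64)
    return codes[~bad], offs


def _gather_ranges(values: np.ndarray, lefts: np.ndarray, rights: np.ndarray,
                   tags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate values[lefts[i]:rights[i]] for all i, with per-item tags."""
    counts = rights - lefts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=values.dtype), np.empty(0, dtype=tags.dtype)
    ends = np.cumsum(counts)
    starts = ends - counts
    idx = np.arange(total, dtype=np.int64) - np.repeat(starts, counts) \
        + np.repeat(lefts, counts)
    return values[idx], np.repeat(tags, counts)


class ScreenIndex:
    """Prebuilt per-species indexes over a universe of contig sets."""

    def __init__(self, universe: Sequence[SpeciesSequenceSet],
                 cfg: SpecificityConfig = SpecificityConfig()):
        self.cfg = cfg
        self.species: dict[str, _SpeciesIndex] = {
            s.species_id: _SpeciesIndex(s, cfg) for s in universe
        }


def _count_occurrences(text: str, pattern: str, limit: int) -> int:
    """Overlapping occurrence count, early exit at ``limit``."""
    n = 0
    i = text.find(pattern)
    while i != -1:
        n += 1
        if n >= limit:
            return n
        i = text.find(pattern, i + 1)
    return n


def _extend_exact(text: str, tpos: int, query: str, qpos: int, m: int) -> tuple[int, int]:
    """Maximal exact extension of an m-length match; returns (tstart, tend)."""
    s_t, s_q = tpos, qpos
    while s_t > 0 and s_q > 0 and text[s_t - 1] == query[s_q - 1] and text[s_t - 1] != "N":
        s_t -= 1
        s_q -= 1
    e_t, e_q = tpos + m, qpos + m
    while (e_t < len(text) and e_q < len(query)
           and text[e_t] == query[e_q] and text[e_t] != "N"):
        e_t += 1
        e_q += 1
    return s_t, e_t


def exact_match_screen(candidate: PrimerCandidate,
                       universe: Sequence[SpeciesSequenceSet] | ScreenIndex,
                       cfg: SpecificityConfig = SpecificityConfig()) -> SpecificityReport:
    """Stage-1 screen: full-length self multi-mapping and >= m-base exact
    matches to other species (both strands when configured)."""
    index = universe if isinstance(universe, ScreenIndex) else ScreenIndex(universe, cfg)
    cfg = index.cfg
    seq = candidate.sequence
    rc = revcomp(seq)
    report = SpecificityReport(candidate_id=candidate.id, stage="EXACT")

    own = index.species[candidate.species_id]
    n_own = _count_occurrences(own.text, seq, 2)
    if cfg.both_strands and n_own < 2 and rc != seq:
        n_own += _count_occurrences(own.text, rc, 2 - n_own)
    if n_own > 1:
        report.removal_reason = REASON_SAME_MULTIMAP
        return report

    m = cfg.exact_other_min
    queries = [(seq, "+")]
    if cfg.both_strands:
        queries.append((rc, "-"))
    for sp_id, sp in index.species.items():
        if sp_id == candidate.species_id:
            continue
        for q, strand in queries:
            codes, offs = _encode_windows(q, m)
            if codes.size == 0:
                continue
            lefts = np.searchsorted(sp.mmers, codes, side="left")
            rights = np.searchsorted(sp.mmers, codes, side="right")
            hit_mask = rights > lefts
            if not hit_mask.any():
                continue
            i = int(np.nonzero(hit_mask)[0][0])
            tpos = int(sp.mmer_pos[lefts[i]])
            ts, te = _extend_exact(sp.text, tpos, q, int(offs[i]), m)
            ci, local = sp.locate(np.asarray([ts]))
            report.hits.append(Hit(
                species_id=sp_id,
                contig_id=sp.contig_ids[int(ci[0])],
                start=int(local[0]), end=int(local[0]) + (te - ts),
                strand=strand, match_len=te - ts, identity=1.0,
            ))
            report.removal_reason = REASON_OTHER_EXACT
    return report


def _diagonal_hits(q: str, sp: _SpeciesIndex, cfg: SpecificityConfig
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best ungapped segment on every seeded diagonal.

    Returns (text_start, seg_len, score, diag) arrays for segments with
    positive score; coordinates are text positions of the segment start.
    """
    empty = np.empty(0, dtype=np.int64)
    codes, offs = _encode_windows(q, cfg.seed_len)
    if codes.size == 0:
        return empty, empty, empty, empty
    lefts = np.searchsorted(sp.seeds, codes, side="left")
    rights = np.searchsorted(sp.seeds, codes, side="right")
    pos, qoff = _gather_ranges(sp.seed_pos, lefts, rights, offs)
    if pos.size == 0:
        return empty, empty, empty, empty
    diags = np.unique(pos - qoff)  # text position aligned with q[0]
    lq = len(q)
    qarr = _CODE[np.frombuffer(q.encode("ascii"), dtype=np.uint8)]
    # gather the diagonal band; sentinels pad the text so indexes are safe
    band_idx = diags[:, None] + np.arange(lq)[None, :]
    np.clip(band_idx, 0, sp.arr.shape[0] - 1, out=band_idx)
    match = sp.arr[band_idx] == qarr[None, :]
    scores = np.where(match, cfg.align_match, cfg.align_mismatch).astype(np.int32)
    # vectorised Kadane: optimal segment per diagonal
    n = diags.shape[0]
    cur = np.zeros(n, dtype=np.int32)
    cur_start = np.zeros(n, dtype=np.int64)
    best = np.full(n, -1, dtype=np.int32)
    best_start = np.zeros(n, dtype=np.int64)
    best_end = np.zeros(n, dtype=np.int64)
    for j in range(lq):
        s = scores[:, j]
        restart = cur <= 0
        cur_start = np.where(restart, j, cur_start)
        cur = np.where(restart, s, cur + s)
        upd = cur > best
        best = np.where(upd, cur, best)
        best_start = np.where(upd, cur_start, best_start)
        best_end = np.where(upd, j + 1, best_end)
    keep = best > 0
    seg_len = best_end - best_start
    return (diags[keep] + best_start[keep], seg_len[keep],
            best[keep].astype(np.int64), diags[keep])


def local_align_screen(candidate: PrimerCandidate,
                       universe: Sequence[SpeciesSequenceSet] | ScreenIndex,
                       cfg: SpecificityConfig = SpecificityConfig(),
                       source_span: tuple[str, int, int] | None = None
                       ) -> SpecificityReport:
    """Stage-2 screen: seeded ungapped local alignments against all contigs.

    ``source_span`` (contig_id, start, end) identifies the candidate's own
    locus, excluded from the same-species rules; defaults to the candidate's
    recorded source location.
    """
    index = universe if isinstance(universe, ScreenIndex) else ScreenIndex(universe, cfg)
    cfg = index.cfg
    seq = candidate.sequence
    if source_span is None:
        source_span = (candidate.contig_id, candidate.offset,
                       candidate.offset + len(seq))
    report = SpecificityReport(candidate_id=candidate.id, stage="LOCAL")
    queries = [(seq, "+")]
    if cfg.both_strands:
        queries.append((revcomp(seq), "-"))
    same_extra = other_local = False
    for sp_id, sp in index.species.items():
        is_own = sp_id == candidate.species_id
        for q, strand in queries:
            starts, seg_lens, scores, _ = _diagonal_hits(q, sp, cfg)
            keep = seg_lens >= cfg.report_min
            if not keep.any():
                continue
            starts, seg_lens, scores = starts[keep], seg_lens[keep], scores[keep]
            ci, local = sp.locate(starts)
            for c, st, ln, sc in zip(ci, local, seg_lens, scores):
                cid = sp.contig_ids[int(c)]
                st, ln, sc = int(st), int(ln), int(sc)
                matches = (sc - ln * cfg.align_mismatch) // (cfg.align_match - cfg.align_mismatch)
                hit = Hit(sp_id, cid, st, st + ln, strand, ln, matches / ln)
                if (is_own and strand == "+" and cid == source_span[0]
                        and st == source_span[1] and st + ln == source_span[2]):
                    report.hits.append(hit)  # the source locus itself
                    continue
                report.hits.append(hit)
                if is_own and ln >= cfg.local_same_min:
                    same_extra = True
                elif not is_own and ln >= cfg.local_other_min:
                    other_local = True
    if same_extra:
        report.removal_reason = REASON_SAME_EXTRA
    elif other_local:
        report.removal_reason = REASON_OTHER_LOCAL
    report.hits.sort(key=lambda h: (h.species_id, h.contig_id, h.start))
    return report


def _screen_one_by_one(cands, index):
    survivors, reports = [], []
    for cand in cands:
        rep = exact_match_screen(cand, index)
        if rep.removal_reason:
            cand.removal_reason = rep.removal_reason
            reports.append(rep)
            continue
        rep2 = local_align_screen(cand, index)
        reports.append(rep2)
        if rep2.removal_reason:
            cand.removal_reason = rep2.removal_reason
        else:
            survivors.append(cand)
    return survivors, reports


def _horner_windows(mat: np.ndarray, length: int) -> np.ndarray:
    """Base-4 codes of every length-``length`` window of each row."""
    n, l = mat.shape
    w = l - length + 1
    codes = np.zeros((n, w), dtype=np.uint64)
    m64 = mat.astype(np.uint64)
    for t in range(length):
        codes = codes * np.uint64(4) + m64[:, t : t + w]
    return codes


def screen_candidates(candidates: Iterable[PrimerCandidate],
                      universe: Sequence[SpeciesSequenceSet] | ScreenIndex,
                      cfg: SpecificityConfig = SpecificityConfig()
                      ) -> tuple[list[PrimerCandidate], list[SpecificityReport]]:
    """Exact stage then local stage; survivors pass both.

    Every removal is annotated on the candidate; output order is
    (species, contig, offset). Equal-length candidates (the pipeline case)
    are screened in vectorised batches; results are identical to running
    exact_match_screen / local_align_screen candidate by candidate.
    """
    index = universe if isinstance(universe, ScreenIndex) else ScreenIndex(universe, cfg)
    cfg = index.cfg
    cands = sorted(candidates,
                   key=lambda c: (c.species_id, c.contig_id, c.offset))
    if not cands:
        return [], []
    lengths = {len(c.sequence) for c in cands}
    if len(lengths) != 1 or max(lengths) > 32:
        return _screen_one_by_one(cands, index)
    k = lengths.pop()
    n = len(cands)

    fwd = np.vstack([
        _CODE[np.frombuffer(c.sequence.encode("ascii"), dtype=np.uint8)]
        for c in cands
    ])
    rcm = fwd[:, ::-1]
    rcm = np.where(rcm < 4, 3 - rcm, rcm).astype(np.uint8)
    code_f = _horner_windows(fwd, k)[:, 0]
    code_r = _horner_windows(rcm, k)[:, 0]
    sp_of = np.array([list(index.species).index(c.species_id) for c in cands])
    removal: list[str | None] = [None] * n
    exact_hit: dict[int, Hit] = {}

    # ----- stage 1: full-length self multi-mapping -----
    for si, (sp_id, sp) in enumerate(index.species.items()):
        own = np.nonzero(sp_of == si)[0]
        if own.size == 0:
            continue
        tcodes, _tpos = sp.table(k)
        cnt = (np.searchsorted(tcodes, code_f[own], side="right")
               - np.searchsorted(tcodes, code_f[own], side="left"))
        if cfg.both_strands:
            rc_cnt = (np.searchsorted(tcodes, code_r[own], side="right")
                      - np.searchsorted(tcodes, code_r[own], side="left"))
            cnt = cnt + np.where(code_r[own] == code_f[own], 0, rc_cnt)
        for i in own[cnt > 1]:
            removal[int(i)] = REASON_SAME_MULTIMAP

    # ----- stage 1: exact >= m-base match to another species -----
    m = cfg.exact_other_min
    win_f = _horner_windows(fwd, m)
    win_r = _horner_windows(rcm, m) if cfg.both_strands else None
    for si, (sp_id, sp) in enumerate(index.species.items()):
        others = np.nonzero((sp_of != si)
                            & np.array([r is None for r in removal]))[0]
        if others.size == 0:
            continue
        for strand, wins in (("+", win_f), ("-", win_r)):
            if wins is None:
                continue
            sub = wins[others]
            lefts = np.searchsorted(sp.mmers, sub.ravel(), side="left")
            rights = np.searchsorted(sp.mmers, sub.ravel(), side="right")
            hit = (rights > lefts).reshape(sub.shape)
            rows = np.nonzero(hit.any(axis=1))[0]
            for r in rows:
                ci = int(others[r])
                if removal[ci] is not None:
                    continue
                removal[ci] = REASON_OTHER_EXACT
                wj = int(np.nonzero(hit[r])[0][0])
                flat = r * sub.shape[1] + wj
                tpos = int(sp.mmer_pos[lefts[flat]])
                q = cands[ci].sequence if strand == "+" else \
                    revcomp(cands[ci].sequence)
                ts, te = _extend_exact(sp.text, tpos, q, wj, m)
                cidx, local = sp.locate(np.asarray([ts]))
                exact_hit[ci] = Hit(sp_id, sp.contig_ids[int(cidx[0])],
                                    int(local[0]), int(local[0]) + te - ts,
                                    strand, te - ts, 1.0)

    # ----- stage 2: seeded ungapped local alignments -----
    alive = np.nonzero(np.array([r is None for r in removal]))[0]
    local_hits: dict[int, list[Hit]] = {int(i): [] for i in alive}
    seed_f = _horner_windows(fwd, cfg.seed_len)
    seed_r = _horner_windows(rcm, cfg.seed_len) if cfg.both_strands else None
    chunk = 256
    for si, (sp_id, sp) in enumerate(index.species.items()):
        for strand, seeds_all, mats in (("+", seed_f, fwd), ("-", seed_r, rcm)):
            if seeds_all is None:
                continue
            for c0 in range(0, alive.size, chunk):
                sel = alive[c0 : c0 + chunk]
                sub = seeds_all[sel]                     # (b, k-s+1)
                b, ns = sub.shape
                lefts = np.searchsorted(sp.seeds, sub.ravel(), side="left")
                rights = np.searchsorted(sp.seeds, sub.ravel(), side="right")
                qoffs = np.tile(np.arange(ns, dtype=np.int64), b)
                rowid = np.repeat(np.arange(b, dtype=np.int64), ns)
                pos, tag = _gather_ranges(
                    sp.seed_pos, lefts, rights,
                    rowid * np.int64(ns) + qoffs)
                if pos.size == 0:
                    continue
                rows = tag // ns
                diags = pos - (tag % ns)
                key = rows * np.int64(sp.arr.shape[0]) + diags
                ukey = np.unique(key)
                urows = (ukey // sp.arr.shape[0]).astype(np.int64)
                udiags = (ukey % sp.arr.shape[0]).astype(np.int64)
                band_idx = udiags[:, None] + np.arange(k)[None, :]
                np.clip(band_idx, 0, sp.arr.shape[0] - 1, out=band_idx)
                match = sp.arr[band_idx] == mats[sel][urows]
                scores = np.where(match, cfg.align_match,
                                  cfg.align_mismatch).astype(np.int32)
                nrow = urows.shape[0]
                cur = np.zeros(nrow, dtype=np.int32)
                cur_start = np.zeros(nrow, dtype=np.int64)
                best = np.full(nrow, -1, dtype=np.int32)
                best_start = np.zeros(nrow, dtype=np.int64)
                best_end = np.zeros(nrow, dtype=np.int64)
                for j in range(k):
                    s = scores[:, j]
                    restart = cur <= 0
                    cur_start = np.where(restart, j, cur_start)
                    cur = np.where(restart, s, cur + s)
                    upd = cur > best
                    best = np.where(upd, cur, best)
                    best_start = np.where(upd, cur_start, best_start)
                    best_end = np.where(upd, j + 1, best_end)
                seg_len = best_end - best_start
                keep = seg_len >= cfg.report_min
                if not keep.any():
                    continue
                starts = udiags[keep] + best_start[keep]
                lens = seg_len[keep]
                scs = best[keep]
                cidx, local = sp.locate(starts)
                for r, st, ln, sc, ci_ in zip(urows[keep], local, lens, scs,
                                              cidx):
                    cand_i = int(sel[int(r)])
                    ln, sc, st = int(ln), int(sc), int(st)
                    matches = (sc - ln * cfg.align_mismatch) // \
                        (cfg.align_match - cfg.align_mismatch)
                    local_hits[cand_i].append(Hit(
                        sp_id, sp.contig_ids[int(ci_)], st, st + ln,
                        strand, ln, matches / ln))

    survivors: list[PrimerCandidate] = []
    reports: list[SpecificityReport] = []
    for i, cand in enumerate(cands):
        if removal[i] is not None:
            cand.removal_reason = removal[i]
            rep = SpecificityReport(cand.id, "EXACT",
                                    removal_reason=removal[i])
            if i in exact_hit:
                rep.hits.append(exact_hit[i])
            reports.append(rep)
            continue
        rep = SpecificityReport(cand.id, "LOCAL")
        same_extra = other_local = False
        src = (cand.contig_id, cand.offset, cand.offset + k)
        for h in local_hits[i]:
            rep.hits.append(h)
            is_own = h.species_id == cand.species_id
            if (is_own and h.strand == "+" and h.contig_id == src[0]
                    and h.start == src[1] and h.end == src[2]):
                continue
            if is_own and h.match_len >= cfg.local_same_min:
                same_extra = True
            elif not is_own and h.match_len >= cfg.local_other_min:
                other_local = True
        if same_extra:
            rep.removal_reason = REASON_SAME_EXTRA
        elif other_local:
            rep.removal_reason = REASON_OTHER_LOCAL
        rep.hits.sort(key=lambda h: (h.species_id, h.contig_id, h.start))
        reports.append(rep)
        if rep.removal_reason:
            cand.removal_reason = rep.removal_reason
        else:
            survivors.append(cand)
    return survivors, reports


def write_report_tsv(reports: Iterable[SpecificityReport], path) -> None:
    """BLAST outfmt-6-like TSV of screen hits plus the triggered reason."""
    with open(path, "w") as fh:
        fh.write("query\tstage\tsubject_species\tsubject_contig\tidentity\t"
                 "length\tsstart\tsend\tstrand\treason\n")
        for rep in reports:
            if not rep.hits:
                fh.write(f"{rep.candidate_id}\t{rep.stage}\t-\t-\t-\t-\t-\t-\t-\t"
                         f"{rep.removal_reason or ''}\n")
            for h in rep.hits:
                fh.write(f"{rep.candidate_id}\t{rep.stage}\t{h.species_id}\t"
                         f"{h.contig_id}\t{h.identity:.3f}\t{h.match_len}\t"
                         f"{h.start}\t{h.end}\t{h.strand}\t"
                         f"{rep.removal_reason or ''}\n")
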