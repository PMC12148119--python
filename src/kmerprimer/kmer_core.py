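"""Exact k-mer counting and unique-k-mer extraction.

The discovery idea: a k-mer (default k=30, long enough to double as a PCR
primer) that occurs exactly once in its own species' contigs and never in any
other species is a candidate species-diagnostic oligo. Counting is exact and
forward-strand only; reverse-complement cross-matches are the specificity
screen's job (which, like the read mappers it emulates, looks at both
strands).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import SpeciesSequenceSet, revcomp

logger = logging.getLogger("kmerprimer")


@dataclass(frozen=True)
class KmerParams:
    k: int = 30
    canonical: bool = False  # count k-mer and reverse complement as one key

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError(f"k must be >= 8, got {self.k}")


@dataclass
class KmerTable:
    """Per-species map: k-mer -> list of (contig_id, 0-based offset, '+')."""

    species_id: str
    k: int
    entries: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)

    def count(self, kmer: str) -> int:
        return len(self.entries.get(kmer, ()))

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_windows(self) -> int:
        return sum(len(v) for v in self.entries.values())


@dataclass
class PrimerCandidate:
    """A candidate oligo with its source location and accumulated verdicts."""

    sequence: str
    species_id: str
    contig_id: str
    offset: int
    strand: str = "+"
    filter_passed: bool | None = None
    failed_rules: list[str] = field(default_factory=list)
    removal_reason: str | None = None

    @property
    def id(self) -> str:
        return f"{self.species_id}|{self.contig_id}|{self.offset}|{self.strand}"


def count_kmers(sset: SpeciesSequenceSet, params: KmerParams) -> KmerTable:
    """Tabulate every forward-strand window of length k; N windows skipped."""
    k = params.k
    table = KmerTable(species_id=sset.species_id, k=k)
    entries = table.entries
    for cid, seq in sset:
        n = len(seq)
        if n < k:
            logger.info("%s/%s: length %d < k=%d, skipped",
                        sset.species_id, cid, n, k)
            continue
        # positions of N, used to skip windows cheaply
        next_n = _next_n_positions(seq)
        i = 0
        while i <= n - k:
            nn = next_n[i]
            if nn < i + k:          # window contains an N: jump past it
                i = nn + 1
                continue
            kmer = seq[i : i + k]
            if params.canonical:
                rc = revcomp(kmer)
                if rc < kmer:
                    kmer = rc
            entries.setdefault(kmer, []).append((cid, i, "+"))
            i += 1
    return table


def _next_n_positions(seq: str) -> list[int]:
    """For each position, index of the next N at or after it (len(seq) if none)."""
    n = len(seq)
    out = [n] * n
    nxt = n
    for i in range(n - 1, -1, -1):
        if seq[i] == "N":
            nxt = i
        out[i] = nxt
    return out


def unique_kmers(tables: Sequence[KmerTable], target: str) -> list[PrimerCandidate]:
    """K-mers occurring exactly once in the target species and in no other.

    Both conditions are over forward-strand table keys; every survivor becomes
    an (unfiltered) PrimerCandidate carrying its single source location.
    Output is sorted by (contig_id, offset) for determinism.
    """
    by_id = {t.species_id: t for t in tables}
    if target not in by_id:
        raise KeyError(f"target species {target!r} not among tables")
    tgt = by_id[target]
    others = [t for t in tables if t.species_id != target]
    out: list[PrimerCandidate] = []
    for kmer, locs in tgt.entries.items():
        if len(locs) != 1:
            continue
        if any(kmer in o for o in others):
            continue
        cid, off, strand = locs[0]
        out.append(PrimerCandidate(kmer, target, cid, off, strand))
    out.sort(key=lambda c: (c.contig_id, c.offset))
    return out


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def write_kmer_table(table: KmerTable, path: str | Path, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"#kmerprimer\tstage=count\tk={table.k}\t"
                 f"species={table.species_id}{header_extra}\n")
        fh.write("kmer\tcount\tcontig_id\toffset\n")
        for kmer in sorted(table.entries):
            for cid, off, _ in table.entries[kmer]:
                fh.write(f"{kmer}\t{len(table.entries[kmer])}\t{cid}\t{off}\n")


def read_kmer_table(path: str | Path) -> KmerTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#kmerprimer"):
            raise ValueError(f"{path}: not a kmerprimer k-mer table")
        meta = dict(f.split("=", 1) for f in header.rstrip("\n").split("\t")[1:])
        table = KmerTable(species_id=meta["species"], k=int(meta["k"]))
        fh.readline()  # column header
        for line in fh:
            kmer, _count, cid, off = line.rstrip("\n").split("\t")
            table.entries.setdefault(kmer, []).append((cid, int(off), "+"))
    return table


def write_candidates_tsv(cands: Iterable[PrimerCandidate], path: str | Path,
                         k: int, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#kmerprimer\tstage={stage}\tk={k}\n")
        fh.write("kmer\tspecies\tcontig\toffset\tstrand\tfailed_rules\treason\n")
        for c in cands:
            fh.write(f"{c.sequence}\t{c.species_id}\t{c.contig_id}\t{c.offset}\t"
                     f"{c.strand}\t{';'.join(c.failed_rules)}\t"
                     f"{c.removal_reason or ''}\n")


def read_candidates_tsv(path: str | Path) -> tuple[list[PrimerCandidate], int]:
    cands: list[PrimerCandidate] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#kmerprimer"):
            raise ValueError(f"{path}: not a kmerprimer candidate table")
        meta = dict(f.split("=", 1) for f in header.rstrip("\n").split("\t")[1:])
        k = int(meta["k"])
        fh.readline()
        for line in fh:
            kmer, sp, cid, off, strand, rules, reason = line.rstrip("\n").split("\t")
            c = PrimerCandidate(kmer, sp, cid, int(off), strand)
            c.failed_rules = rules.split(";") if rules else []
            c.removal_reason = reason or None
            cands.append(c)
    return cands, k


def write_candidates_fasta(cands: Iterable[PrimerCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cands:
            fh.write(f">{c.id}\n{c.sequence}\n")
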