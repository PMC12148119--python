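"""Sequence I/O and redundancy removal.

Each species enters the pipeline as one FASTA file of assembled contigs.
Sequences are normalised to uppercase A/C/G/T/N on input; near-identical
contigs (assembly redundancy) are collapsed by greedy identity clustering
before any k-mer counting, mirroring the CD-HIT step used on transcriptome
assemblies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
from Bio import SeqIO

logger = logging.getLogger("kmerprimer")

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and replace any non-ACGTN character (IUPAC codes etc.) by N."""
    seq = seq.upper()
    if set(seq) <= DNA_ALPHABET:
        return seq
    return "".join(c if c in DNA_ALPHABET else "N" for c in seq)


@dataclass
class SpeciesSequenceSet:
    """A named species together with its (ordered) contig collection."""

    species_id: str
    contigs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            dup = next(c for c in ids if ids.count(c) > 1)
            raise ValueError(
                f"duplicate contig_id {dup!r} in species {self.species_id!r}"
            )
        for cid, seq in self.contigs:
            if not seq:
                raise ValueError(f"empty sequence for contig {cid!r}")
            if not set(seq) <= DNA_ALPHABET:
                raise ValueError(f"contig {cid!r} not normalised to ACGTN")

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def get(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]


@dataclass
class ClusterResult:
    representative: str
    members: list[str]
    identity_threshold: float


def read_fasta(path: str | Path, species_id: str) -> SpeciesSequenceSet:
    """Read one species' contigs from FASTA.

    Sequences are uppercased; characters outside A/C/G/T/N become N with a
    warning. Duplicate record ids are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    contigs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(
                f"duplicate contig_id {record.id!r} in {path} (species {species_id})"
            )
        seen.add(record.id)
        raw = str(record.seq)
        seq = normalize_sequence(raw)
        n_replaced = sum(
            1 for a, b in zip(raw.upper(), seq) if a != b
        )
        if n_replaced:
            logger.warning(
                "%s/%s: replaced %d non-ACGTN character(s) by N",
                species_id, record.id, n_replaced,
            )
        contigs.append((record.id, seq))
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return SpeciesSequenceSet(species_id=species_id, contigs=contigs)


def write_fasta(sset: SpeciesSequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in sset:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _pair_identity(shorter: str, longer: str) -> float:
    """Identity of the shorter sequence aligned within the longer one.

    Semi-global edit distance (free end gaps on the longer sequence), so a
    redundant fragment scores by how much of *itself* matches — the CD-HIT
    short-sequence-coverage convention. N counts as a mismatch.
    """
    res = edlib.align(shorter, longer, mode="HW", task="distance")
    dist = res["editDistance"]
    return max(0.0, 1.0 - dist / len(shorter))


def cluster_redundant(
    sset: SpeciesSequenceSet, identity: float = 0.95
) -> tuple[SpeciesSequenceSet, list[ClusterResult]]:
    """Collapse redundant contigs by greedy incremental clustering.

    Contigs are processed longest-first (ties broken by contig_id); each one
    joins the first existing cluster whose representative it matches at
    >= ``identity`` over the shorter sequence's length, otherwise it founds a
    new cluster. Only representatives are retained.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    order = sorted(sset.contigs, key=lambda c: (-len(c[1]), c[0]))
    clusters: list[ClusterResult] = []
    rep_seqs: list[str] = []
    for cid, seq in order:
        placed = False
        for cl, rep_seq in zip(clusters, rep_seqs):
            shorter, longer = (seq, rep_seq) if len(seq) <= len(rep_seq) else (rep_seq, seq)
            if _pair_identity(shorter, longer) >= identity:
                cl.members.append(cid)
                placed = True
                break
        if not placed:
            clusters.append(ClusterResult(cid, [cid], identity))
            rep_seqs.append(seq)
    reps = {cl.representative for cl in clusters}
    out = SpeciesSequenceSet(
        species_id=sset.species_id,
        contigs=[(cid, seq) for cid, seq in sset.contigs if cid in reps],
    )
    if len(out) < len(sset):
        logger.info(
            "%s: clustering removed %d redundant contig(s) of %d",
            sset.species_id, len(sset) - len(out), len(sset),
        )
    return out, clusters


def write_cluster_report(clusters: Iterable[ClusterResult], path: str | Path) -> None:
    """TSV: representative, member, identity_threshold."""
    with open(path, "w") as fh:
        fh.write("representative\tmember\tidentity_threshold\n")
        for cl in clusters:
            for m in cl.members:
                fh.write(f"{cl.representative}\t{m}\t{cl.identity_threshold:g}\n")


def check_unique_species(universe: Sequence[SpeciesSequenceSet]) -> None:
    ids = [s.species_id for s in universe]
    if len(ids) != len(set(ids)):
        raise ValueError(f"species_ids not unique: {ids}")
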