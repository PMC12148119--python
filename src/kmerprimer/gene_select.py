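"""Restricting the contig universe to a reference set of intronless genes.

Primers designed from transcripts are only safe on genomic DNA when the
underlying gene has no introns (otherwise the predicted product size, or the
product itself, is wrong). This module assigns each contig to its best
reference intronless gene by translated local alignment, flags putative
paralogs with a score-ratio heuristic (a species contributing two
near-equally-scoring contigs to one gene cannot be trusted to be single-copy
orthologous), and emits the per-gene, per-species contig universe for k-mer
counting.

The whole module is optional: the pipeline runs directly on user contig sets
when no reference genes are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .seqio import SpeciesSequenceSet, revcomp

logger = logging.getLogger("kmerprimer")

_PROTEIN_ONLY = set("DEFHIKLMPQRSVWY*X")  # letters impossible in clean DNA


@dataclass(frozen=True)
class ReferenceGene:
    gene_id: str
    sequence: str
    is_protein: bool


@dataclass(frozen=True)
class GeneAssignment:
    species_id: str
    contig_id: str
    gene_id: str
    score: float
    identity: float
    coverage: float        # fraction of reference length aligned
    frame: int             # +-1..3 for translated search, 0 for nucleotide
    paralog_flag: bool = False


def read_reference_genes(path: str | Path) -> list[ReferenceGene]:
    """Load reference genes from FASTA, autodetecting protein vs nucleotide
    by alphabet over all records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    letters = set("".join(str(r.seq).upper() for r in records))
    is_protein = bool(letters & _PROTEIN_ONLY)
    genes = [ReferenceGene(r.id, str(r.seq).upper(), is_protein) for r in records]
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate gene_id in {path}")
    return genes


def translate_six_frames(sequence: str) -> list[str]:
    """Peptides of frames +1,+2,+3,-1,-2,-3. Codons containing N give X;
    trailing partial codons are dropped."""
    out: list[str] = []
    for template in (sequence, revcomp(sequence)):
        for off in range(3):
            sub = template[off : off + 3 * ((len(template) - off) // 3)]
            out.append(str(Seq(sub).translate()))
    return out


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _nucleotide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _alignment_stats(alignment) -> tuple[float, int, int]:
    """(identity over aligned columns, aligned columns, aligned target cols)."""
    matches = columns = tcols = 0
    q, t = alignment[0], alignment[1]  # gapped strings
    for a, b in zip(q, t):
        if a == "-" and b == "-":
            continue
        columns += 1
        if b != "-":
            tcols += 1
        if a == b and a != "-":
            matches += 1
    if columns == 0:
        return 0.0, 0, 0
    return matches / columns, columns, tcols


def assign_to_reference(contigs: SpeciesSequenceSet,
                        refs: Sequence[ReferenceGene],
                        min_identity: float = 0.4,
                        min_coverage: float = 0.5) -> list[GeneAssignment]:
    """Best-scoring alignment of each contig against any reference gene.

    Protein references: the six frame translations of the contig are aligned
    with BLOSUM62 (gap open 11 / extend 1); nucleotide references: direct
    local nucleotide alignment of both strands. Assignments below the
    identity or reference-coverage thresholds are dropped; one best hit per
    contig is kept.
    """
    if not refs:
        raise ValueError("reference gene list is empty")
    is_protein = refs[0].is_protein
    aligner = _protein_aligner() if is_protein else _nucleotide_aligner()
    out: list[GeneAssignment] = []
    frame_labels = (1, 2, 3, -1, -2, -3)
    for cid, seq in contigs:
        queries: list[tuple[int, str]]
        if is_protein:
            queries = list(zip(frame_labels, translate_six_frames(seq)))
        else:
            queries = [(1, seq), (-1, revcomp(seq))]
        best: GeneAssignment | None = None
        for ref in refs:
            for frame, q in queries:
                if not q:
                    continue
                score = aligner.score(ref.sequence, q)
                if score <= 0:
                    continue
                if best is not None and score < best.score:
                    continue
                aln = aligner.align(ref.sequence, q)[0]
                ident, _cols, ref_cols = _alignment_stats(aln)
                cand = GeneAssignment(
                    species_id=contigs.species_id, contig_id=cid,
                    gene_id=ref.gene_id, score=float(score),
                    identity=ident, coverage=ref_cols / len(ref.sequence),
                    frame=frame,
                )
                if best is None or cand.score > best.score:
                    best = cand
        if best is None:
            continue
        if best.identity < min_identity or best.coverage < min_coverage:
            logger.debug("%s/%s below thresholds (id %.2f, cov %.2f)",
                         contigs.species_id, cid, best.identity, best.coverage)
            continue
        out.append(best)
    return out


def flag_paralogs(assignments: Sequence[GeneAssignment],
                  score_ratio: float = 0.8) -> list[GeneAssignment]:
    """Flag per (gene, species) groups with >= 2 near-equal-scoring contigs.

    If the second-best contig scores within ``score_ratio`` of the best, the
    species' relationship to that gene is ambiguous (likely paralogy): all
    its assignments for that gene are flagged. Otherwise only the best contig
    of the group is retained unflagged.
    """
    groups: dict[tuple[str, str], list[GeneAssignment]] = {}
    for a in assignments:
        groups.setdefault((a.gene_id, a.species_id), []).append(a)
    out: list[GeneAssignment] = []
    for group in groups.values():
        group = sorted(group, key=lambda a: -a.score)
        if len(group) >= 2 and group[1].score >= score_ratio * group[0].score:
            out.extend(replace(a, paralog_flag=True) for a in group)
        else:
            out.append(group[0])
    out.sort(key=lambda a: (a.gene_id, a.species_id, a.contig_id))
    return out


def select_ortholog_set(assignments: Sequence[GeneAssignment],
                        min_species: int = 2) -> list[GeneAssignment]:
    """One contig per gene per species; flagged entries excluded; genes kept
    only when represented in >= ``min_species`` species."""
    clean = [a for a in assignments if not a.paralog_flag]
    by_gene: dict[str, dict[str, GeneAssignment]] = {}
    for a in clean:
        slot = by_gene.setdefault(a.gene_id, {})
        prev = slot.get(a.species_id)
        if prev is None or a.score > prev.score:
            slot[a.species_id] = a
    out = [
        a
        for gene_id in sorted(by_gene)
        if len(by_gene[gene_id]) >= min_species
        for _, a in sorted(by_gene[gene_id].items())
    ]
    return out


def restrict_universe(universe: Sequence[SpeciesSequenceSet],
                      selected: Iterable[GeneAssignment]
                      ) -> list[SpeciesSequenceSet]:
    """Keep only contigs present in the selected ortholog set."""
    keep: dict[str, set[str]] = {}
    for a in selected:
        keep.setdefault(a.species_id, set()).add(a.contig_id)
    out = []
    for sset in universe:
        wanted = keep.get(sset.species_id, set())
        out.append(SpeciesSequenceSet(
            species_id=sset.species_id,
            contigs=[(cid, seq) for cid, seq in sset if cid in wanted],
        ))
    return out


def write_assignments_tsv(assignments: Iterable[GeneAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tspecies_id\tcontig_id\tscore\tidentity\tcoverage\t"
                 "frame\tparalog_flag\n")
        for a in assignments:
            fh.write(f"{a.gene_id}\t{a.species_id}\t{a.contig_id}\t{a.score:g}\t"
                     f"{a.identity:.4f}\t{a.coverage:.4f}\t{a.frame}\t"
                     f"{int(a.paralog_flag)}\n")
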