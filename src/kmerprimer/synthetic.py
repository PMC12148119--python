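"""Synthetic multi-species ortholog families with planted ground truth.

The generator emulates the input the pipeline is built for — one contig set
per species, where contigs are orthologous gene copies diverged by
substitutions from a common ancestor — plus three kinds of planted signal
with known expected outcomes:

* **markers**: composition-clean 30-mers overwritten into one species and
  verified (by rejection sampling against the whole dataset) to be unique to
  that species and to survive the specificity screen;
* **decoys**: a marker whose first L bases are additionally copied into a
  second species (or elsewhere in the same species), pinning the screen's
  removal boundaries (L = 24/25 survive, 26/30 are removed);
* **paralogs**: a within-species duplicate of a gene at 90% nucleotide
  identity, with substitutions redrawn when they would create an in-frame
  stop so the duplicate still aligns full-length to the gene's protein.

The mutation model is substitutions only (uniform over the three alternative
bases), so planted coordinates remain valid. ``divergence`` is the expected
per-site distance of each species from the ancestor; the realised pairwise
distance between two species is correspondingly larger. All randomness comes
from one seeded numpy default_rng (PCG64), so a given SimSpec reproduces
byte-identical FASTA on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .kmer_core import KmerParams, PrimerCandidate, count_kmers, unique_kmers
from .primer_filter import FilterConfig, apply_filters, filter_candidates
from .seqio import SpeciesSequenceSet, revcomp, write_fasta
from .specificity import (ScreenIndex, SpecificityConfig, exact_match_screen,
                          local_align_screen, screen_candidates)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimSpec:
    n_species: int = 3
    n_genes: int = 5
    gene_length: int = 1000
    divergence: float | tuple[float, ...] = 0.05  # per-species distance to ancestor
    planted_markers: tuple[tuple[str, int, int], ...] = ()
    # ((src_species, dst_species), block_length); src == dst plants a
    # same-species second occurrence
    planted_decoys: tuple[tuple[tuple[str, str], int], ...] = ()
    planted_paralogs: tuple[tuple[str, int], ...] = ()
    k: int = 30
    seed: int = 0
    max_attempts: int = 500

    def species_ids(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def contig_id(self, gene: int) -> str:
        return f"g{gene + 1:03d}"

    def rates(self) -> list[float]:
        if isinstance(self.divergence, (int, float)):
            rates = [float(self.divergence)] * self.n_species
        else:
            rates = [float(d) for d in self.divergence]
            if len(rates) != self.n_species:
                raise ValueError("one divergence per species required")
        if any(not 0.0 <= d < 0.75 for d in rates):
            raise ValueError("divergence must be in [0, 0.75)")
        return rates


@dataclass
class MarkerTruth:
    species_id: str
    contig_id: str
    offset: int
    sequence: str
    expect_survive: bool
    expected_reason: str | None = None
    decoy: tuple[str, int] | None = None  # (dst species, copied block length)


@dataclass
class TruthTable:
    markers: list[MarkerTruth] = field(default_factory=list)
    paralogs: list[tuple[str, str, str]] = field(default_factory=list)
    # (species_id, contig_id, duplicate_contig_id)

    def expected_surviving(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for m in self.markers:
            if m.expect_survive:
                out.setdefault(m.species_id, set()).add(m.sequence)
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tcontig\toffset\tsequence\texpect_survive\t"
                     "expected_reason\tdecoy_species\tdecoy_length\n")
            for m in self.markers:
                dsp, dln = m.decoy if m.decoy else ("", "")
                fh.write(f"{m.species_id}\t{m.contig_id}\t{m.offset}\t"
                         f"{m.sequence}\t{int(m.expect_survive)}\t"
                         f"{m.expected_reason or ''}\t{dsp}\t{dln}\n")


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniform over the other
    three bases (code arrays over 0..3)."""
    out = arr.copy()
    if rate <= 0:
        return out
    hit = rng.random(arr.shape[0]) < rate
    shifts = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + shifts) % 4
    return out


def _codes_to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _mutate_coding_preserving(seq: str, rate: float,
                              rng: np.random.Generator) -> str:
    """Substitution mutation that reverts codons turned into frame +1 stops."""
    arr = _mutate(_str_to_codes(seq), rate, rng)
    out = _codes_to_str(arr)
    chars = list(out)
    for i in range(0, len(seq) - 2, 3):
        if "".join(chars[i:i + 3]) in _STOPS and seq[i:i + 3] not in _STOPS:
            chars[i:i + 3] = seq[i:i + 3]
    return "".join(chars)


class _Dataset:
    """Mutable working state during generation."""

    def __init__(self, spec: SimSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        rates = spec.rates()
        self.seqs: dict[str, dict[str, str]] = {}
        ancestors = [rng.integers(0, 4, size=spec.gene_length, dtype=np.uint8)
                     for _ in range(spec.n_genes)]
        for s, sp_id in enumerate(spec.species_ids()):
            contigs = {}
            for g in range(spec.n_genes):
                contigs[spec.contig_id(g)] = _codes_to_str(
                    _mutate(ancestors[g], rates[s], rng))
            self.seqs[sp_id] = contigs
        self.reserved: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def reserve(self, sp: str, cid: str, start: int, end: int) -> None:
        self.reserved.setdefault((sp, cid), []).append((start, end))

    def is_free(self, sp: str, cid: str, start: int, end: int) -> bool:
        for a, b in self.reserved.get((sp, cid), ()):
            if start < b and a < end:
                return False
        return True

    def overwrite(self, sp: str, cid: str, start: int, block: str) -> None:
        seq = self.seqs[sp][cid]
        self.seqs[sp][cid] = seq[:start] + block + seq[start + len(block):]

    def to_universe(self) -> list[SpeciesSequenceSet]:
        return [
            SpeciesSequenceSet(sp, sorted(contigs.items()))
            for sp, contigs in self.seqs.items()
        ]

    def all_text(self) -> str:
        return "|".join(seq for contigs in self.seqs.values()
                        for seq in contigs.values())


def _occurrences(text: str, pattern: str, limit: int = 3) -> int:
    n, i = 0, text.find(pattern)
    while i != -1 and n < limit:
        n += 1
        i = text.find(pattern, i + 1)
    return n


def _screen_reason(ds: _Dataset, cand: PrimerCandidate,
                   scfg: SpecificityConfig) -> str | None:
    index = ScreenIndex(ds.to_universe(), scfg)
    reason = exact_match_screen(cand, index).removal_reason
    if reason is None:
        reason = local_align_screen(cand, index).removal_reason
    return reason


def _try_plant_marker(ds: _Dataset, sp: str, gene: int, offset: int,
                      fcfg: FilterConfig, scfg: SpecificityConfig
                      ) -> str | None:
    """One attempt: overwrite a k-window with a random filter-passing k-mer
    that is unique to ``sp`` and survives the screen; reverts on failure."""
    spec = ds.spec
    cid = spec.contig_id(gene)
    k = spec.k
    if offset + k > spec.gene_length:
        raise ValueError(f"marker at {sp}/{cid}:{offset} exceeds gene bounds")
    original = ds.seqs[sp][cid]
    cand_seq = _codes_to_str(ds.rng.integers(0, 4, size=k, dtype=np.uint8))
    if not apply_filters(cand_seq, fcfg).passed:
        return None
    ds.overwrite(sp, cid, offset, cand_seq)
    text = ds.all_text()
    if (_occurrences(text, cand_seq) != 1
            or _occurrences(text, revcomp(cand_seq), 1) != 0
            or _screen_reason(ds, PrimerCandidate(cand_seq, sp, cid, offset),
                              scfg) is not None):
        ds.seqs[sp][cid] = original
        return None
    return cand_seq


def _plant_marker(ds: _Dataset, sp: str, gene: int, offset: int,
                  fcfg: FilterConfig, scfg: SpecificityConfig) -> str:
    spec = ds.spec
    for _ in range(spec.max_attempts):
        seq = _try_plant_marker(ds, sp, gene, offset, fcfg, scfg)
        if seq is not None:
            ds.reserve(sp, spec.contig_id(gene), offset, offset + spec.k)
            return seq
    raise RuntimeError(
        f"could not plant a unique marker at {sp}/{spec.contig_id(gene)}:"
        f"{offset} after {spec.max_attempts} attempts; use longer genes or "
        f"fewer plants")


def _fix_flanks(ds: _Dataset, dst: str, dcid: str, dstart: int, length: int,
                src_seq: str, src_start: int, src_contig: str, src_sp: str
                ) -> None:
    """Force a mismatch immediately flanking a copied block so the shared
    region cannot extend by chance (the boundary truth depends on the exact
    block length)."""
    dseq = ds.seqs[dst][dcid]
    sseq = ds.seqs[src_sp][src_contig]
    # left flank
    if dstart > 0 and src_start > 0:
        if dseq[dstart - 1] == sseq[src_start - 1]:
            repl = "A" if sseq[src_start - 1] != "A" else "C"
            ds.overwrite(dst, dcid, dstart - 1, repl)
    # right flank
    dend, send = dstart + length, src_start + length
    if dend < len(dseq) and send < len(sseq):
        if dseq[dend] == sseq[send]:
            repl = "A" if sseq[send] != "A" else "C"
            ds.overwrite(dst, dcid, dend, repl)


def _random_free_site(ds: _Dataset, sp: str, length: int,
                      exclude_contig: str | None = None) -> tuple[str, int]:
    spec = ds.spec
    for _ in range(spec.max_attempts):
        g = int(ds.rng.integers(0, spec.n_genes))
        cid = spec.contig_id(g)
        if cid == exclude_contig:
            continue
        start = int(ds.rng.integers(0, spec.gene_length - length + 1))
        if ds.is_free(sp, cid, start, start + length):
            return cid, start
    raise RuntimeError("no free site found; use longer genes or fewer plants")


def generate_dataset(spec: SimSpec,
                     fcfg: FilterConfig = FilterConfig(),
                     scfg: SpecificityConfig = SpecificityConfig()
                     ) -> tuple[list[SpeciesSequenceSet], TruthTable]:
    """Generate the universe and its truth table.

    Paralogs are planted first (duplicating the pre-marker gene copy), then
    markers and decoys; decoy blocks are copied from their source marker
    immediately after it is planted, and the source marker's expected fate
    follows the screen thresholds (see module docstring).
    """
    rng = np.random.default_rng(spec.seed)
    ds = _Dataset(spec, rng)
    truth = TruthTable()
    known = {s for s in spec.species_ids()}
    for sp, g in spec.planted_paralogs:
        if sp not in known or not 0 <= g < spec.n_genes:
            raise ValueError(f"bad paralog spec ({sp}, {g})")
        cid = spec.contig_id(g)
        dup_id = f"{cid}_dup"
        ds.seqs[sp][dup_id] = _mutate_coding_preserving(
            ds.seqs[sp][cid], 0.10, rng)
        truth.paralogs.append((sp, cid, dup_id))

    for sp, g, offset in spec.planted_markers:
        seq = _plant_marker(ds, sp, g, offset, fcfg, scfg)
        truth.markers.append(MarkerTruth(sp, spec.contig_id(g), offset, seq,
                                         expect_survive=True))

    for (src, dst), length in spec.planted_decoys:
        if length > spec.k:
            raise ValueError(f"decoy block {length} longer than k={spec.k}")
        if src == dst:
            if length >= spec.k:
                expected = "SAME_MULTIMAP"
            elif length >= scfg.local_same_min:
                expected = "SAME_EXTRA"
            else:
                expected = None
        else:
            if length >= scfg.exact_other_min:
                expected = "OTHER_EXACT"
            elif length >= scfg.local_other_min:
                expected = "OTHER_LOCAL"
            else:
                expected = None
        planted = False
        for _ in range(spec.max_attempts):
            g = int(rng.integers(0, spec.n_genes))
            offset = int(rng.integers(0, spec.gene_length - spec.k + 1))
            cid = spec.contig_id(g)
            if not ds.is_free(src, cid, offset, offset + spec.k):
                continue
            src_original = ds.seqs[src][cid]
            seq = _try_plant_marker(ds, src, g, offset, fcfg, scfg)
            if seq is None:
                continue
            dcid, dstart = _random_free_site(
                ds, dst, length, exclude_contig=cid if src == dst else None)
            dst_original = ds.seqs[dst][dcid]
            ds.overwrite(dst, dcid, dstart, seq[:length])
            _fix_flanks(ds, dst, dcid, dstart, length, seq, offset, cid, src)
            got = _screen_reason(ds, PrimerCandidate(seq, src, cid, offset),
                                 scfg)
            if got != expected:
                ds.seqs[dst][dcid] = dst_original
                if not (src == dst and cid == dcid):
                    ds.seqs[src][cid] = src_original
                continue
            ds.reserve(src, cid, offset, offset + spec.k)
            ds.reserve(dst, dcid, dstart, dstart + length)
            truth.markers.append(MarkerTruth(
                src, cid, offset, seq,
                expect_survive=expected is None,
                expected_reason=expected, decoy=(dst, length)))
            planted = True
            break
        if not planted:
            raise RuntimeError(
                f"could not plant decoy ({src}->{dst}, {length} bp); "
                f"use longer genes or fewer plants")

    return ds.to_universe(), truth


def write_dataset(universe: Sequence[SpeciesSequenceSet], truth: TruthTable,
                  outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sset in universe:
        write_fasta(sset, outdir / f"{sset.species_id}.fasta")
    truth.write_tsv(outdir / "truth.tsv")


def divergence_sweep(base_spec: SimSpec, levels: Sequence[float],
                     fcfg: FilterConfig = FilterConfig(),
                     scfg: SpecificityConfig = SpecificityConfig()
                     ) -> list[tuple[float, int]]:
    """Total surviving-candidate count across species at each divergence
    level, holding the seed (hence the ancestral genes) fixed."""
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    out = []
    params = KmerParams(k=base_spec.k)
    for level in levels:
        spec = replace(base_spec, divergence=level)
        universe, _ = generate_dataset(spec, fcfg, scfg)
        tables = [count_kmers(s, params) for s in universe]
        index = ScreenIndex(universe, scfg)
        total = 0
        for s in universe:
            cands = unique_kmers(tables, s.species_id)
            passing, _ = filter_candidates(cands, fcfg)
            survivors, _ = screen_candidates(passing, index, scfg)
            total += len(survivors)
        out.append((float(level), total))
    return out
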