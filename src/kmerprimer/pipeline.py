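"""End-to-end pipeline orchestration and the plain-text configuration.

Stage order: cluster -> [gene selection] -> count -> unique -> filter ->
screen -> [pairing + in-silico PCR]. Every intermediate file carries a
one-line ``#kmerprimer`` header with the stage name and k so stages run
separately cannot be silently mixed; the run manifest records the config
hash and per-stage input/output counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from . import __version__
from .gene_select import (assign_to_reference, flag_paralogs,
                          read_reference_genes, restrict_universe,
                          select_ortholog_set, write_assignments_tsv)
from .kmer_core import (KmerParams, count_kmers, unique_kmers,
                        write_candidates_fasta, write_candidates_tsv,
                        write_kmer_table)
from .pairing import PairingConfig, propose_partners, validate_pair, \
    write_amplicons_tsv, write_pairs_tsv
from .primer_filter import FilterConfig, filter_candidates
from .seqio import (SpeciesSequenceSet, check_unique_species,
                    cluster_redundant, read_fasta, write_cluster_report,
                    write_fasta)
from .specificity import (ScreenIndex, SpecificityConfig, screen_candidates,
                          write_report_tsv)

logger = logging.getLogger("kmerprimer")


class ConfigError(Exception):
    """Configuration problem; reported before any computation (exit 2)."""


class StageError(Exception):
    """A pipeline stage failed (exit 3)."""


@dataclass
class PipelineConfig:
    species_fasta: dict[str, Path] = field(default_factory=dict)
    reference_genes: Path | None = None
    outdir: Path = Path("kmerprimer_out")
    seed: int = 0
    log_level: str = "INFO"
    cluster_identity: float = 0.95
    min_species_per_gene: int = 2
    min_identity: float = 0.4
    min_coverage: float = 0.5
    paralog_score_ratio: float = 0.8
    pair: bool = True
    pair_max_per_species: int = 2  # survivors sent to partner proposal
    allow_single_species: bool = False
    kmer: KmerParams = field(default_factory=KmerParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    specificity: SpecificityConfig = field(default_factory=SpecificityConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_flat_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def as_flat_dict(self) -> dict:
        d: dict = {
            "species": {sp: str(p) for sp, p in sorted(self.species_fasta.items())},
            "reference_genes": str(self.reference_genes) if self.reference_genes else None,
            "seed": self.seed,
            "cluster_identity": self.cluster_identity,
            "min_species_per_gene": self.min_species_per_gene,
            "min_identity": self.min_identity,
            "min_coverage": self.min_coverage,
            "paralog_score_ratio": self.paralog_score_ratio,
            "pair": self.pair,
            "pair_max_per_species": self.pair_max_per_species,
        }
        for section, obj in (("kmer", self.kmer), ("filter", self.filter),
                             ("specificity", self.specificity),
                             ("pairing", self.pairing)):
            for f in fields(obj):
                d[f"{section}.{f.name}"] = getattr(obj, f.name)
        return d


_BOOL = {"true": True, "false": False, "yes": True, "no": False,
         "1": True, "0": False}


def _coerce(value: str, typ):
    if typ is bool or typ == "bool":
        try:
            return _BOOL[value.lower()]
        except KeyError:
            raise ConfigError(f"not a boolean: {value!r}")
    if typ is int:
        return int(value)
    if typ is float:
        return float(value)
    return value


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse the plain-text ``key = value`` configuration file.

    Species FASTA paths use ``species.<id> = <path>``; threshold keys are the
    dataclass field names of the sub-configs (e.g. ``k``, ``tm_min``,
    ``exact_other_min``, ``product_max``). Unknown keys are a hard error.
    Relative paths resolve against the config file's directory.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    base = path.parent
    cfg = PipelineConfig()
    sub = {"kmer": {}, "filter": {}, "specificity": {}, "pairing": {}}
    sub_fields = {
        name: {f.name: f.type for f in fields(obj)}
        for name, obj in (("kmer", cfg.kmer), ("filter", cfg.filter),
                          ("specificity", cfg.specificity),
                          ("pairing", cfg.pairing))
    }
    top_types = {
        "seed": int, "log_level": str, "cluster_identity": float,
        "min_species_per_gene": int, "min_identity": float,
        "min_coverage": float, "paralog_score_ratio": float, "pair": bool,
        "pair_max_per_species": int, "allow_single_species": bool,
    }
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("species."):
            cfg.species_fasta[key[len("species."):]] = base / value
        elif key == "reference_genes":
            cfg.reference_genes = base / value
        elif key == "outdir":
            cfg.outdir = base / value
        elif key in top_types:
            setattr(cfg, key, _coerce(value, top_types[key]))
        else:
            for section, ftypes in sub_fields.items():
                if key in ftypes:
                    # field types are strings under postponed annotations
                    tname = str(ftypes[key])
                    if "bool" in tname:
                        pytype = bool
                    elif "int" in tname:
                        pytype = int
                    elif "float" in tname:
                        pytype = float
                    else:
                        pytype = str
                    sub[section][key] = _coerce(value, pytype)
                    break
            else:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
    cfg.kmer = replace(cfg.kmer, **sub["kmer"])
    cfg.filter = replace(cfg.filter, **sub["filter"])
    cfg.specificity = replace(cfg.specificity, **sub["specificity"])
    cfg.pairing = replace(cfg.pairing, **sub["pairing"])
    validate_config(cfg)
    return cfg


def validate_config(cfg: PipelineConfig) -> None:
    if not cfg.species_fasta:
        raise ConfigError("no species FASTA files configured")
    if len(cfg.species_fasta) < 2 and not cfg.allow_single_species:
        raise ConfigError("need >= 2 species (or allow_single_species)")
    for sp, p in cfg.species_fasta.items():
        if not Path(p).exists():
            raise ConfigError(f"species {sp}: file not found: {p}")
    if cfg.reference_genes and not Path(cfg.reference_genes).exists():
        raise ConfigError(f"reference_genes file not found: {cfg.reference_genes}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "kmerprimer",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    def stage(name):
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        universe = [read_fasta(p, sp)
                    for sp, p in sorted(cfg.species_fasta.items())]
        check_unique_species(universe)
        st = stage("read")
        st["contigs"] = {s.species_id: len(s) for s in universe}
    except Exception as e:
        raise StageError(f"read: {e}") from e

    try:
        clustered = []
        all_clusters = []
        for s in universe:
            reps, clusters = cluster_redundant(s, cfg.cluster_identity)
            clustered.append(reps)
            all_clusters.extend(clusters)
        write_cluster_report(all_clusters, out / "clusters.tsv")
        st = stage("cluster")
        st["representatives"] = {s.species_id: len(s) for s in clustered}
        universe = clustered
    except StageError:
        raise
    except Exception as e:
        raise StageError(f"cluster: {e}") from e

    if cfg.reference_genes:
        try:
            refs = read_reference_genes(cfg.reference_genes)
            assignments = []
            for s in universe:
                assignments.extend(assign_to_reference(
                    s, refs, cfg.min_identity, cfg.min_coverage))
            flagged = flag_paralogs(assignments, cfg.paralog_score_ratio)
            selected = select_ortholog_set(flagged, cfg.min_species_per_gene)
            write_assignments_tsv(flagged, out / "assignments.tsv")
            universe = restrict_universe(universe, selected)
            st = stage("gene_select")
            st["reference_genes"] = len(refs)
            st["assignments"] = len(assignments)
            st["paralog_flagged"] = sum(a.paralog_flag for a in flagged)
            st["selected"] = len(selected)
        except Exception as e:
            raise StageError(f"gene_select: {e}") from e

    try:
        tables = [count_kmers(s, cfg.kmer) for s in universe]
        tdir = out / "tables"
        tdir.mkdir(exist_ok=True)
        for t in tables:
            write_kmer_table(t, tdir / f"{t.species_id}.kmers.tsv")
        st = stage("count")
        st["distinct_kmers"] = {t.species_id: len(t) for t in tables}
    except Exception as e:
        raise StageError(f"count: {e}") from e

    try:
        unique = {s.species_id: unique_kmers(tables, s.species_id)
                  for s in universe}
        allu = [c for cands in unique.values() for c in cands]
        write_candidates_tsv(allu, out / "candidates.unique.tsv",
                             cfg.kmer.k, "unique")
        st = stage("unique")
        st["unique_kmers"] = {sp: len(c) for sp, c in unique.items()}
    except Exception as e:
        raise StageError(f"unique: {e}") from e

    try:
        passing, failing = filter_candidates(allu, cfg.filter)
        write_candidates_tsv(passing + failing, out / "candidates.filtered.tsv",
                             cfg.kmer.k, "filter")
        tally = Counter(r for c in failing for r in c.failed_rules)
        for rule, n in sorted(tally.items()):
            logger.info("filter rule %s removed %d candidate(s)", rule, n)
        st = stage("filter")
        st["passed"] = len(passing)
        st["failed"] = len(failing)
        st["rule_tally"] = dict(sorted(tally.items()))
    except Exception as e:
        raise StageError(f"filter: {e}") from e

    try:
        index = ScreenIndex(universe, cfg.specificity)
        survivors, reports = screen_candidates(passing, index, cfg.specificity)
        write_candidates_tsv(survivors, out / "survivors.tsv",
                             cfg.kmer.k, "screen")
        write_candidates_fasta(survivors, out / "survivors.fasta")
        write_report_tsv(reports, out / "screen_report.tsv")
        reason_tally = Counter(c.removal_reason for c in passing
                               if c.removal_reason)
        st = stage("screen")
        st["survivors"] = len(survivors)
        st["survivors_per_species"] = dict(Counter(
            c.species_id for c in survivors))
        st["removal_tally"] = dict(sorted(reason_tally.items()))
    except Exception as e:
        raise StageError(f"screen: {e}") from e

    if cfg.pair:
        try:
            by_species = {s.species_id: s for s in universe}
            pairs = []
            verdicts: dict[str, str] = {}
            amplicon_rows = []
            n_taken: Counter = Counter()
            for cand in survivors:
                if n_taken[cand.species_id] >= cfg.pair_max_per_species:
                    continue
                n_taken[cand.species_id] += 1
                context = by_species[cand.species_id].get(cand.contig_id)
                props = propose_partners(cand, context, index, cfg.pairing,
                                         cfg.filter, cfg.specificity)
                for p in props[:1]:  # report the top proposal per candidate
                    verdict, preds = validate_pair(
                        p, universe, cfg.pairing)
                    verdicts[p.forward.name] = verdict
                    pairs.append(p)
                    amplicon_rows.append((p, preds))
            write_pairs_tsv(pairs, out / "pairs.tsv", verdicts)
            with open(out / "amplicons.tsv", "w") as fh:
                fh.write("pair\tspecies\tcontig\tstart\tend\tsize\t"
                         "fwd_mismatches\trev_mismatches\n")
                for p, preds in amplicon_rows:
                    for pred in preds:
                        for cid, s0, e0, sz, fm, rm in pred.products:
                            fh.write(f"{p.forward.name}\t{pred.species_id}\t"
                                     f"{cid}\t{s0}\t{e0}\t{sz}\t{fm}\t{rm}\n")
            st = stage("pair")
            st["pairs"] = len(pairs)
            st["verdicts"] = dict(sorted(Counter(verdicts.values()).items()))
        except Exception as e:
            raise StageError(f"pair: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def discover_candidates(universe: list[SpeciesSequenceSet],
                        kparams: KmerParams = KmerParams(),
                        fcfg: FilterConfig = FilterConfig(),
                        scfg: SpecificityConfig = SpecificityConfig()):
    """Library-level shortcut: count -> unique -> filter -> screen for every
    species; returns {species_id: [surviving PrimerCandidate]}."""
    tables = [count_kmers(s, kparams) for s in universe]
    index = ScreenIndex(universe, scfg)
    out = {}
    for s in universe:
        cands = unique_kmers(tables, s.species_id)
        passing, _ = filter_candidates(cands, fcfg)
        survivors, _ = screen_candidates(passing, index, scfg)
        out[s.species_id] = survivors
    return out
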