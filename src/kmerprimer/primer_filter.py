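"""Composition and melting-temperature filters for candidate primers.

A 30-mer that is unique to a species is not automatically a usable primer:
it must melt in the right range, carry a balanced GC load along its whole
length, avoid weak (A/T) or over-strong (G/C-stacked) 3' and 5' ends, and be
free of homopolymer runs and dinucleotide repeats that cause slippage and
primer dimers. Every rule is evaluated (no short-circuit) so reports show the
complete failure profile of each candidate.

Default thresholds are tuned for 30-base oligos: GC counts 11-17 over the
full length (37-57%), 4-10 per 15-base half, Tm 67-82 deg C under the basic
GC formula. For other lengths the GC count bounds can be rescaled
proportionally (see ``scaled_for_length``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .kmer_core import PrimerCandidate

RULE_UNIQUENESS = "UNIQUENESS"
RULE_TM = "TM"
RULE_GC_FULL = "GC_FULL"
RULE_GC_HALF = "GC_HALF"
RULE_END_BOTH_AT = "END_BOTH_AT"
RULE_END_GC_RUN = "END_GC_RUN"
RULE_END_AT_RUN = "END_AT_RUN"
RULE_HOMOPOLYMER = "HOMOPOLYMER"
RULE_DINUC_REPEAT = "DINUC_REPEAT"

ALL_RULES = (
    RULE_TM, RULE_GC_FULL, RULE_GC_HALF, RULE_END_BOTH_AT,
    RULE_END_GC_RUN, RULE_END_AT_RUN, RULE_HOMOPOLYMER, RULE_DINUC_REPEAT,
)


@dataclass(frozen=True)
class FilterConfig:
    tm_min: float = 67.0
    tm_max: float = 82.0
    gc_min_full: int = 11
    gc_max_full: int = 17
    gc_min_half: int = 4
    gc_max_half: int = 10
    end_window: int = 5
    end_gc_limit: int = 3   # >= triggers, both ends
    end_at_limit: int = 3   # >= triggers, both ends
    max_run: int = 4        # >= triggers
    dinuc_repeat_limit: int = 3  # >= triggers (tandem units)
    tm_method: str = "gc_basic"

    def __post_init__(self) -> None:
        if self.gc_min_full > self.gc_max_full or self.gc_min_half > self.gc_max_half:
            raise ValueError("GC bounds inverted")
        for name in ("end_window", "end_gc_limit", "end_at_limit",
                     "max_run", "dinuc_repeat_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled_for_length(self, length: int, reference: int = 30) -> "FilterConfig":
        """Rescale the count-based GC bounds to an oligo of another length.

        Full-length bounds scale with length/reference, half bounds with the
        half lengths; thresholds that are already length-free (Tm band, end
        rules, runs, repeats) are kept.
        """
        if length == reference:
            return self
        f = length / reference
        h = (length // 2) / (reference // 2)
        return replace(
            self,
            gc_min_full=int(round(self.gc_min_full * f)),
            gc_max_full=int(round(self.gc_max_full * f)),
            gc_min_half=int(round(self.gc_min_half * h)),
            gc_max_half=int(round(self.gc_max_half * h)),
        )


@dataclass
class FilterVerdict:
    passed: bool
    failed_rules: list[str]


def gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def melting_temperature(seq: str, method: str = "gc_basic") -> float:
    """Estimate oligo Tm in deg C.

    ``gc_basic``: Tm = 81.5 + 0.41*(%GC) - 675/N, the classic GC-fraction
    formula for oligos >= ~14 bases; consistent in scale with the 67-82 band
    used for 30-mers.
    """
    if method != "gc_basic":
        raise ValueError(f"unknown Tm method {method!r}")
    n = len(seq)
    if n < 14:
        raise ValueError(f"gc_basic Tm needs length >= 14, got {n}")
    pct_gc = 100.0 * gc_count(seq) / n
    return 81.5 + 0.41 * pct_gc - 675.0 / n


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run."""
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best if seq else 0


def max_dinucleotide_repeat(seq: str) -> int:
    """Maximum tandem copy number of any dinucleotide XY with X != Y.

    "ATATAT" -> 3, "ATATA" -> 2 (the trailing lone A is not a full unit),
    "CGCGCGCG" -> 4. Homopolymeric units (XX) are excluded; those are the
    homopolymer rule's territory.
    """
    n = len(seq)
    best = 0
    for i in range(n - 1):
        if seq[i] == seq[i + 1]:
            continue
        # count tandem copies of seq[i:i+2] starting at i
        unit = seq[i : i + 2]
        j = i
        copies = 0
        while seq[j : j + 2] == unit:
            copies += 1
            j += 2
        if copies > best:
            best = copies
    return best


def end_composition(seq: str, window: int) -> tuple[str, str, int, int, int, int]:
    """(first_base, last_base, gc5, gc3, at5, at3) over the terminal windows."""
    if 2 * window > len(seq):
        raise ValueError(f"end window {window} exceeds half of length {len(seq)}")
    head, tail = seq[:window], seq[-window:]
    at = lambda s: s.count("A") + s.count("T")
    return seq[0], seq[-1], gc_count(head), gc_count(tail), at(head), at(tail)


def apply_filters(candidate: PrimerCandidate | str,
                  cfg: FilterConfig = FilterConfig()) -> FilterVerdict:
    """Evaluate every composition rule; record all failures.

    Accepts a PrimerCandidate (whose verdict fields are updated in place) or
    a bare sequence string.
    """
    seq = candidate if isinstance(candidate, str) else candidate.sequence
    k = len(seq)
    if 2 * cfg.end_window > k:
        raise ValueError(f"sequence length {k} too short for end window "
                         f"{cfg.end_window}")
    failed: list[str] = []

    tm = melting_temperature(seq, cfg.tm_method)
    if not cfg.tm_min <= tm <= cfg.tm_max:
        failed.append(RULE_TM)

    gc = gc_count(seq)
    if not cfg.gc_min_full <= gc <= cfg.gc_max_full:
        failed.append(RULE_GC_FULL)

    half = k // 2  # odd k: middle base belongs to neither half
    gc_a, gc_b = gc_count(seq[:half]), gc_count(seq[-half:])
    if not (cfg.gc_min_half <= gc_a <= cfg.gc_max_half
            and cfg.gc_min_half <= gc_b <= cfg.gc_max_half):
        failed.append(RULE_GC_HALF)

    first, last, gc5, gc3, at5, at3 = end_composition(seq, cfg.end_window)
    if first in "AT" and last in "AT":
        failed.append(RULE_END_BOTH_AT)
    if gc5 >= cfg.end_gc_limit and gc3 >= cfg.end_gc_limit:
        failed.append(RULE_END_GC_RUN)
    if at5 >= cfg.end_at_limit and at3 >= cfg.end_at_limit:
        failed.append(RULE_END_AT_RUN)

    if max_homopolymer_run(seq) >= cfg.max_run:
        failed.append(RULE_HOMOPOLYMER)
    if max_dinucleotide_repeat(seq) >= cfg.dinuc_repeat_limit:
        failed.append(RULE_DINUC_REPEAT)

    verdict = FilterVerdict(passed=not failed, failed_rules=failed)
    if isinstance(candidate, PrimerCandidate):
        candidate.filter_passed = verdict.passed
        candidate.failed_rules = list(failed)
    return verdict


def filter_candidates(candidates, cfg: FilterConfig = FilterConfig()):
    """Split candidates into (passing, failing); verdicts recorded on each."""
    passing, failing = [], []
    for c in candidates:
        if apply_filters(c, cfg).passed:
            passing.append(c)
        else:
            failing.append(c)
    return passing, failing
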