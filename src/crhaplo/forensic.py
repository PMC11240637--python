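"""Forensic comparison of an evidence sequence against references.

mtDNA is matrilineally inherited, so a sequence match never identifies an
individual; it places the evidence in a maternal lineage whose weight is the
haplotype's population frequency (the random match probability). Casework
convention requires two or more nucleotide discrepancies for a mismatch or
exclusion: zero discrepancies is a match, exactly one is inconclusive (a
single difference may be a private mutation or heteroplasmy), two or more
exclude a common source.

Discrepancies are counted only over jointly covered, unambiguous positions;
a comparison with no overlapping coverage is a distinct error outcome, never
a "match". Frequency weights are reported per region and overall, together
with a conservative add-one estimate ``(x+1)/(n+1)`` and an optional
one-sided 95% upper confidence bound — under-sampling then errs against the
prosecution, never for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from scipy.stats import beta

from ._util import UNAMBIGUOUS
from .diversity import PopulationTable
from .haplotyping import AlignmentWindow, PositionedSample


class NoOverlapError(ValueError):
    """Evidence and reference share no covered positions; not comparable."""


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a forensic sequence comparison."""

    discrepancies: int
    compared_positions: int
    verdict: str  # match | inconclusive | exclusion
    matched_haplotype: str | None = None
    rmp_regional: dict[str, float] = field(default_factory=dict)
    rmp_overall: float | None = None
    notes: tuple[str, ...] = ()


def _verdict(discrepancies: int) -> str:
    if discrepancies == 0:
        return "match"
    if discrepancies == 1:
        return "inconclusive"
    return "exclusion"


def compare_sequences(evidence: PositionedSample, reference: PositionedSample,
                      window: AlignmentWindow) -> MatchResult:
    """Compare two placed sequences under the 0/1/>=2 discrepancy rule.

    Symmetric in its arguments. Positions where either sequence is ambiguous
    or uncovered are skipped (with a note), so the reported
    ``compared_positions`` shows how much sequence actually supported the
    verdict.
    """
    lo = max(evidence.start, reference.start, window.start)
    hi = min(evidence.end, reference.end, window.end)
    if hi < lo:
        raise NoOverlapError("no overlapping coverage between evidence and "
                             "reference within the window")
    discrepancies = 0
    compared = 0
    skipped_ambiguous = 0
    for pos in range(lo, hi + 1):
        b1, b2 = evidence.base_at(pos), reference.base_at(pos)
        if b1 not in UNAMBIGUOUS or b2 not in UNAMBIGUOUS:
            skipped_ambiguous += 1
            continue
        compared += 1
        if b1 != b2:
            discrepancies += 1
    if compared == 0:
        raise NoOverlapError("overlap contains no jointly unambiguous positions")
    notes = []
    full = min(len(evidence.sequence), len(reference.sequence))
    if compared < full:
        notes.append(f"partial comparison: {compared} of {full} positions")
    if skipped_ambiguous:
        notes.append(f"{skipped_ambiguous} position(s) skipped as ambiguous "
                     "or missing")
    return MatchResult(discrepancies, compared, _verdict(discrepancies),
                       notes=tuple(notes))


def conservative_frequency(x: int, n: int) -> float:
    """Add-one frequency estimate (x+1)/(n+1); never below the sample value."""
    if n < 1:
        raise ValueError("database size must be >= 1")
    return (x + 1) / (n + 1)


def upper_confidence_frequency(x: int, n: int, level: float = 0.95) -> float:
    """One-sided Clopper–Pearson upper bound on the haplotype frequency."""
    if n < 1:
        raise ValueError("database size must be >= 1")
    if x >= n:
        return 1.0
    return float(beta.ppf(level, x + 1, n - x))


def match_weight(haplotype: str | tuple[str, ...] | list[str],
                 table: PopulationTable,
                 mode: str = "sample_frequency") -> dict:
    """Forensic weight of a haplotype match against a population database.

    For a single haplotype name, reports its sample frequency per region and
    overall; for a consistency set (a partial fragment), the summed member
    frequencies — an upper bound on the match probability. ``mode`` selects
    the headline figure: ``sample_frequency`` (default, matching the survey's
    RMP arithmetic), ``add_one``, or ``upper95``.
    """
    if table.counts.empty:
        raise ValueError("empty population table")
    names = [haplotype] if isinstance(haplotype, str) else list(haplotype)
    if not names:
        raise ValueError("empty haplotype (consistency) set")

    def freq(counts: Mapping[str, int]) -> tuple[int, int]:
        n = sum(counts.values())
        x = sum(counts.get(h, 0) for h in names)
        return x, n

    regional = {}
    for region in table.regions:
        x, n = freq(table.region_counts(region))
        regional[region] = {
            "sample_frequency": x / n,
            "add_one": conservative_frequency(x, n),
            "upper95": upper_confidence_frequency(x, n),
        }
    x, n = freq(table.pooled_counts())
    overall = {
        "sample_frequency": x / n,
        "add_one": conservative_frequency(x, n),
        "upper95": upper_confidence_frequency(x, n),
    }
    if mode not in overall:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        "haplotypes": names,
        "is_consistency_set": len(names) > 1,
        "mode": mode,
        "regional": regional,
        "overall": overall,
        "headline": overall[mode],
    }


def evaluate_match(evidence: PositionedSample, reference: PositionedSample,
                   window: AlignmentWindow,
                   assignments_by_sample: Mapping[str, object] | None = None,
                   table: PopulationTable | None = None,
                   mode: str = "sample_frequency") -> MatchResult:
    """Full casework evaluation: verdict plus frequency-based match weight.

    When the comparison is a match (or inconclusive) and the evidence maps
    onto registered haplotypes, the match weight of its haplotype (or
    consistency set) against the population database is attached.
    """
    result = compare_sequences(evidence, reference, window)
    if result.verdict == "exclusion" or table is None:
        return result
    matched = None
    weight = None
    if assignments_by_sample and evidence.sample_id in assignments_by_sample:
        a = assignments_by_sample[evidence.sample_id]
        names = (a.haplotype,) if a.assigned else a.consistency_set
        if names:
            weight = match_weight(list(names), table, mode=mode)
            matched = a.haplotype
    if weight is None:
        return result
    return MatchResult(result.discrepancies, result.compared_positions,
                       result.verdict, matched_haplotype=matched,
                       rmp_regional={r: v[mode]
                                     for r, v in weight["regional"].items()},
                       rmp_overall=weight["overall"][mode],
                       notes=result.notes)
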