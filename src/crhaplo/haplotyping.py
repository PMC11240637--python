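"""Mapping, segregating-site calling and haplotype collapsing.

Sample control-region sequences are placed on the reference window by a
gap-free sliding-offset search (no multiple-alignment heuristics: the
surveyed data are substitution-only, so a colinear placement exists whenever
the sample is genuine). Placed samples are collapsed onto named haplotypes; a
full-coverage sequence that matches no registered haplotype is registered
under the next sequential name, and a partial fragment receives a consistency
set — every registered haplotype that agrees with it at each covered variable
site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import UNAMBIGUOUS
from .registry import HaplotypeRegistry, ReferenceSequence
from .simulate import SampleRecord


class UnmappableError(ValueError):
    """Best gap-free placement still exceeds the mismatch threshold."""


class IndelUnsupportedError(ValueError):
    """An internal gap would be required; indels are a hard error by design."""


@dataclass(frozen=True)
class AlignmentWindow:
    """Inclusive 1-based window [start, end] on the mitogenome."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"window end {self.end} precedes start {self.start}")

    @property
    def L(self) -> int:
        """Evaluated length in bases (inclusive span)."""
        return self.end - self.start + 1


_PRIMER_RE = re.compile(r"^([FR])([\d,]+)$")


@dataclass(frozen=True)
class PrimerPair:
    """Primer pair named by the 1-based position of each 5' base.

    The convention encodes the position in the name, e.g. ``F15,386`` /
    ``R16,330``. The reverse primer's 5' base sits on the reverse strand, so
    the amplicon is the inclusive interval between the two 5' positions on
    the forward strand.
    """

    forward_name: str
    reverse_name: str
    forward_seq: str | None = None
    reverse_seq: str | None = None

    @staticmethod
    def _parse(name: str, expect: str) -> int:
        m = _PRIMER_RE.match(name.strip())
        if not m or m.group(1) != expect:
            raise ValueError(f"cannot parse primer name {name!r}")
        return int(m.group(2).replace(",", ""))

    @property
    def forward_pos(self) -> int:
        return self._parse(self.forward_name, "F")

    @property
    def reverse_pos(self) -> int:
        return self._parse(self.reverse_name, "R")


def amplicon_span(primers: PrimerPair) -> AlignmentWindow:
    """Amplicon window spanned by a primer pair, inclusive of both 5' bases."""
    fwd, rev = primers.forward_pos, primers.reverse_pos
    if rev <= fwd:
        raise ValueError(f"reverse 5' position {rev} must exceed forward {fwd}")
    return AlignmentWindow(fwd, rev)


@dataclass(frozen=True)
class PositionedSample:
    """A sample placed gap-free inside the reference window."""

    sample_id: str
    sequence: str
    start: int  # 1-based mitogenome coordinate of first base
    mismatches: int
    compared: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def base_at(self, position: int) -> str | None:
        """Base at a mitogenome position, or None outside coverage."""
        if self.start <= position <= self.end:
            return self.sequence[position - self.start]
        return None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_UNAMB = _encode("ACGT")


def map_to_reference(sample: SampleRecord | tuple[str, str],
                     reference: ReferenceSequence,
                     window: AlignmentWindow,
                     max_mismatch_fraction: float = 0.10) -> PositionedSample:
    """Place a sample in the window by exhaustive gap-free offset search.

    Every offset admitting the full sample inside the window is scored by
    matches over unambiguous positions; the best offset wins (smallest offset
    on ties). A best placement whose mismatch fraction exceeds
    ``max_mismatch_fraction`` raises :class:`UnmappableError`; a gap
    character in the input raises :class:`IndelUnsupportedError` naming the
    position, because internal gaps are unsupported by design.
    """
    if isinstance(sample, tuple):
        sample = SampleRecord(sample[0], sample[1], window.start)
    seq = sample.sequence.upper()
    gap = seq.find("-")
    if gap >= 0:
        raise IndelUnsupportedError(
            f"{sample.sample_id}: gap at sequence offset {gap + 1}; "
            "indels are not supported")
    m = len(seq)
    if m == 0:
        raise ValueError(f"{sample.sample_id}: empty sequence")
    if m > window.L:
        raise ValueError(f"{sample.sample_id}: sequence length {m} exceeds "
                         f"window length {window.L}")
    ref_arr = _encode(reference.subsequence(window.start, window.end))
    smp_arr = _encode(seq)
    unamb = np.isin(smp_arr, _UNAMB)
    best = (-1, -1, 0)  # (matches, -offset) maximised; compared carried along
    for off in range(window.L - m + 1):
        ref_slice = ref_arr[off:off + m]
        cmp_mask = unamb & np.isin(ref_slice, _UNAMB)
        matches = int(np.count_nonzero((ref_slice == smp_arr) & cmp_mask))
        compared = int(np.count_nonzero(cmp_mask))
        if (matches, -off) > (best[0], best[1]):
            best = (matches, -off, compared)
    matches, neg_off, compared = best
    off = -neg_off
    mismatches = compared - matches
    if compared > 0 and mismatches / compared > max_mismatch_fraction:
        raise UnmappableError(
            f"{sample.sample_id}: best placement has {mismatches}/{compared} "
            f"mismatches (> {max_mismatch_fraction:.0%})")
    return PositionedSample(sample.sample_id, seq, window.start + off,
                            mismatches, compared)


def call_segregating_sites(positioned: list[PositionedSample],
                           window: AlignmentWindow) -> list[int]:
    """Positions with >= 2 distinct unambiguous bases among covering samples.

    Ambiguity codes and N contribute no evidence at a site. Output is sorted
    ascending in mitogenome coordinates.
    """
    if not positioned:
        raise ValueError("no positioned samples")
    present = np.zeros((4, window.L), dtype=bool)
    for p in positioned:
        arr = _encode(p.sequence)
        off = p.start - window.start
        for i, b in enumerate(_UNAMB):
            hits = np.nonzero(arr == b)[0]
            present[i, hits + off] = True
    seg = np.nonzero(present.sum(axis=0) >= 2)[0]
    return [int(window.start + i) for i in seg]


@dataclass(frozen=True)
class HaplotypeAssignment:
    """Outcome of collapsing one sample onto the registry.

    ``haplotype`` is set only for samples with unambiguous coverage of every
    variable site; otherwise the sample carries its consistency set — the
    registered haplotypes it cannot be distinguished from.
    """

    sample_id: str
    haplotype: str | None
    consistency_set: tuple[str, ...]
    covered_start: int
    covered_end: int
    missing_sites: tuple[int, ...] = ()

    @property
    def assigned(self) -> bool:
        return self.haplotype is not None


def assign_haplotypes(positioned: list[PositionedSample],
                      registry: HaplotypeRegistry,
                      allow_new: bool = True,
                      ) -> tuple[list[HaplotypeAssignment], HaplotypeRegistry]:
    """Collapse placed samples onto named haplotypes.

    A sample matches a haplotype iff they agree at every covered unambiguous
    position of the window (not only at the variable sites — a difference at
    a private position makes the sample a new haplotype, never a silent
    match). Samples are processed in sorted sample-id order so that the
    naming of simultaneously discovered novelties is deterministic and the
    resulting partition is independent of input order. The registry grows
    monotonically; it is mutated in place and also returned.

    With ``allow_new=False`` an unmatched full-coverage sample raises
    ``ValueError`` instead of registering.
    """
    from .registry import HaplotypeDefinition

    assignments: dict[str, HaplotypeAssignment] = {}
    for p in sorted(positioned, key=lambda s: s.sample_id):
        sites = registry.variable_sites
        covered_sites = [s for s in sites
                         if (b := p.base_at(s)) is not None and b in UNAMBIGUOUS]
        missing = tuple(s for s in sites if s not in covered_sites)
        consistent = [d.name for d in registry
                      if _agrees(p, d.name, registry)]
        full_cover = not missing
        if full_cover and len(consistent) == 1:
            assignments[p.sample_id] = HaplotypeAssignment(
                p.sample_id, consistent[0], tuple(consistent),
                p.start, p.end, missing)
            continue
        if full_cover and not consistent:
            if not allow_new:
                raise ValueError(f"{p.sample_id}: unmatched haplotype vector "
                                 "and new-haplotype registration disabled")
            alleles = {}
            for pos in range(p.start, p.end + 1):
                b = p.base_at(pos)
                if b in UNAMBIGUOUS and b != registry.reference.base_at(pos):
                    alleles[pos] = b
            name = registry.next_name()
            registry.add(HaplotypeDefinition(name, alleles))
            assignments[p.sample_id] = HaplotypeAssignment(
                p.sample_id, name, (name,), p.start, p.end, missing)
            continue
        # partial coverage (or full coverage matching several — possible only
        # when coverage misses the sites separating them): consistency set
        assignments[p.sample_id] = HaplotypeAssignment(
            p.sample_id, None, tuple(consistent), p.start, p.end, missing)
    ordered = [assignments[p.sample_id] for p in positioned]
    return ordered, registry


def _agrees(p: PositionedSample, name: str, registry: HaplotypeRegistry) -> bool:
    hap_seq = registry.full_sequence(name, p.start, p.end)
    return all(b not in UNAMBIGUOUS or b == h
               for b, h in zip(p.sequence, hap_seq))


def haplotype_frequencies(assignments: list[HaplotypeAssignment],
                          metadata: pd.DataFrame) -> "PopulationTable":
    """Per-region haplotype counts from assigned samples.

    Samples that carry only a consistency set are excluded from the counts
    and reported on the returned table. A sample without a region label in
    the metadata is an error.
    """
    from .diversity import PopulationTable

    meta = metadata.set_index("sample_id")["region"]
    rows = []
    excluded = []
    for a in assignments:
        if a.sample_id not in meta.index:
            raise KeyError(f"sample {a.sample_id!r} has no region label")
        if a.assigned:
            rows.append((meta.loc[a.sample_id], a.haplotype))
        else:
            excluded.append(a.sample_id)
    if rows:
        df = pd.DataFrame(rows, columns=["region", "haplotype"])
        counts = (df.groupby(["region", "haplotype"]).size()
                    .unstack(fill_value=0))
    else:
        counts = pd.DataFrame()
    return PopulationTable(counts, excluded=tuple(excluded))


def read_fasta(path: str | Path, default_start: int | None = None,
               ) -> list[SampleRecord]:
    """Read a multi-FASTA written by this package (or any plain FASTA).

    Record descriptions may carry ``start=<pos>`` to anchor fragments; absent
    that, ``default_start`` (usually the window start) is used.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = re.search(r"start=(\d+)", rec.description)
        if m:
            start = int(m.group(1))
        elif default_start is not None:
            start = default_start
        else:
            raise ValueError(f"{rec.id}: no start coordinate in description and "
                             "no default_start given")
        records.append(SampleRecord(rec.id, str(rec.seq).upper(), start))
    return records


def read_reference(path: str | Path, origin: int | None = None,
                   ) -> ReferenceSequence:
    """Read the single-record reference FASTA (origin from description)."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise ValueError(f"expected exactly one reference record, got {len(recs)}")
    rec = recs[0]
    m = re.search(r"origin=(\d+)", rec.description)
    if m:
        origin = int(m.group(1))
    if origin is None:
        raise ValueError("reference origin not found; pass origin=")
    return ReferenceSequence(rec.id, str(rec.seq).upper(), origin)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "region"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return meta


def write_assignments(assignments: list[HaplotypeAssignment],
                      path: str | Path) -> None:
    rows = [{
        "sample_id": a.sample_id,
        "haplotype_or_set": a.haplotype or "{" + ",".join(a.consistency_set) + "}",
        "covered_start": a.covered_start,
        "covered_end": a.covered_end,
        "missing_sites": ",".join(map(str, a.missing_sites)),
    } for a in assignments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
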