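"""Synthetic survey fixtures for the fallow deer mtDNA control-region study.

The real survey's per-individual sequences are not public; only summary
numbers are (see :mod:`crhaplo.published`). This module reconstructs synthetic
datasets that realise those printed numbers exactly:

* a random A/C/G/T reference stand-in anchored at the amplicon coordinates
  (never downloaded from GenBank);
* six haplotypes ``Hun1``–``Hun6`` whose substitutions all fall inside the
  450-bp sub-window shared with earlier surveys, with an inter-haplotype
  difference matrix chosen to reproduce the per-region segregating-site
  counts (a documented constant of the fixture, not a claim about the real
  sequences);
* per-region sample sets drawn by exact counts — never multinomial draws —
  so every statistic computed downstream is non-stochastic. Randomness only
  affects the reference bases and fragment placement.

Per-region compositions are fixed to the unique solutions of the
count-inversion oracle (:func:`derive_counts_from_stats`) applied to the
printed RMP entries, except SW, whose printed Hd and RMP are mutually
inconsistent: SW uses {19,13,5}, which reproduces Hd 0.611. The pooled
192-sample inventory and the per-region compositions are jointly infeasible
at the table's printed precision, so ``global_192`` and ``regional`` exist as
separate fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .registry import HaplotypeDefinition, HaplotypeRegistry, ReferenceSequence

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Amplicon window: 5' positions of the forward and reverse primers, inclusive.
WINDOW = (15386, 16330)

#: 450-bp sub-window containing every variable site (combined-analysis window).
SUBWINDOW_450 = (15600, 16049)

#: Variable-site positions of the fixture (1-based mitogenome coordinates).
VARIABLE_SITES = (15650, 15711, 15784, 15871, 15942, 16015)

#: Which variable sites each haplotype substitutes at, as indices into
#: VARIABLE_SITES. Hun1 is the reference haplotype. The implied difference
#: matrix satisfies every per-region segregating-site count of the survey:
#: Hun1/Hun2 differ at exactly one site (forced by NW: S=1 with k=2), Hun3 and
#: Hun4 are each one substitution off Hun2, Hun5/Hun6 occupy the remaining
#: sites.
HAPLOTYPE_SITE_PATTERN: dict[str, tuple[int, ...]] = {
    "Hun1": (),
    "Hun2": (0,),
    "Hun3": (0, 1),
    "Hun4": (0, 2),
    "Hun5": (3,),
    "Hun6": (4, 5),
}

#: Transition partner used for every substituted base (purine<->purine etc.),
#: so variant bases are deterministic given the reference.
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Regional fixture: unique count-inversion solutions per region (SW chosen to
#: match Hd 0.611; see module docstring). Name assignment follows the survey's
#: presence constraints: Hun3 only NE, Hun4 only NM, Hun5/Hun6 southern only.
REGIONAL_COMPOSITION: dict[str, dict[str, int]] = {
    "NW": {"Hun1": 10, "Hun2": 24},
    "NM": {"Hun1": 18, "Hun2": 23, "Hun4": 1},
    "NE": {"Hun1": 17, "Hun2": 23, "Hun3": 1},
    "SW": {"Hun1": 19, "Hun2": 13, "Hun6": 5},
    "SM": {"Hun1": 25, "Hun2": 5, "Hun5": 1},
    "SE": {"Hun2": 2, "Hun5": 4, "Hun6": 1},
}

#: Global fixture: realises the printed pooled counts {66,108,1,1,9,7} exactly
#: while keeping the printed region sample sizes and presence constraints.
GLOBAL_192_COMPOSITION: dict[str, dict[str, int]] = {
    "NW": {"Hun1": 10, "Hun2": 24},
    "NM": {"Hun1": 18, "Hun2": 23, "Hun4": 1},
    "NE": {"Hun1": 17, "Hun2": 23, "Hun3": 1},
    "SW": {"Hun1": 14, "Hun2": 18, "Hun6": 5},
    "SM": {"Hun1": 7, "Hun2": 19, "Hun5": 5},
    "SE": {"Hun2": 1, "Hun5": 4, "Hun6": 2},
}

#: Newly collected samples only (previous-survey sequences removed): 138
#: animals from five regions carrying exactly four haplotypes.
NEW_COLLECTION_138_COMPOSITION: dict[str, dict[str, int]] = {
    "NW": {"Hun1": 10, "Hun2": 24},
    "NM": {"Hun1": 18, "Hun2": 23, "Hun4": 1},
    "SW": {"Hun1": 16, "Hun2": 11, "Hun5": 3},
    "SM": {"Hun1": 25, "Hun2": 5, "Hun5": 1},
    "SE": {"Hun2": 1},
}

FIXTURE_VARIANTS = ("global_192", "new_collection_138", "regional")


@dataclass(frozen=True)
class CompositionSolution:
    """An integer haplotype composition matching a target sum of squared
    frequencies, with the residual it achieves (reported, never hidden)."""

    counts: tuple[int, ...]
    achieved_sum_sq: float
    residual: float


@dataclass(frozen=True)
class FragmentModel:
    """Contiguous-fragment degradation: lengths uniform in [min_length,
    max_length], plus optional per-base missing probability (bases -> N)."""

    min_length: int
    max_length: int
    missing_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min fragment length exceeds max fragment length")
        if self.min_length < 1:
            raise ValueError("fragment length must be positive")
        if not 0.0 <= self.missing_probability <= 1.0:
            raise ValueError("missing probability must lie in [0, 1]")


@dataclass(frozen=True)
class SampleRecord:
    """One sample sequence anchored at a 1-based mitogenome coordinate."""

    sample_id: str
    sequence: str
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


@dataclass
class SimulationConfig:
    """Stated world of one simulated survey."""

    window: tuple[int, int] = WINDOW
    composition: dict[str, dict[str, int]] = field(default_factory=dict)
    fragment_model: FragmentModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for region, counts in self.composition.items():
            for name, c in counts.items():
                if c < 0:
                    raise ValueError(f"negative count for {name} in {region}")


@dataclass
class FixtureBundle:
    """A complete simulated dataset: reference, registry, samples, metadata."""

    reference: ReferenceSequence
    registry: HaplotypeRegistry
    records: list[SampleRecord]
    metadata: pd.DataFrame  # columns: sample_id, region, source
    composition: dict[str, dict[str, int]]


def generate_reference(length: int, origin: int = WINDOW[0],
                       seed: int = 0, id: str = "SYN_REF") -> ReferenceSequence:
    """Generate a deterministic random A/C/G/T reference stand-in.

    The result is byte-identical for a fixed seed; it stands in for a real
    mitogenome segment and is never downloaded.
    """
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=length).tobytes().decode("ascii")
    return ReferenceSequence(id=id, sequence=seq, coordinate_origin=origin)


def _compositions(n: int, k: int):
    """Yield all non-increasing compositions of n into k positive parts."""
    if k == 1:
        yield (n,)
        return
    for first in range((n + k - 1) // k, n - k + 2):
        for rest in _compositions(n - first, k - 1):
            if rest[0] <= first:
                yield (first,) + rest


def derive_counts_from_stats(n: int, k: int, target_rmp: float,
                             tolerance: float) -> list[CompositionSolution]:
    """Invert a printed sum-of-squared-frequencies against integer counts.

    Exhaustively enumerates the (order-insensitive) integer compositions of
    ``n`` into ``k`` positive parts and returns every composition whose
    sum(p_i^2) lies within ``tolerance`` of ``target_rmp``, sorted by residual
    (ties broken lexicographically for determinism). An empty list means no
    composition attains the target at that tolerance.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if not 0.0 < target_rmp <= 1.0:
        raise ValueError("target_rmp must lie in (0, 1]")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    solutions = []
    nsq = n * n
    for counts in _compositions(n, k):
        ssq = sum(c * c for c in counts) / nsq
        residual = abs(ssq - target_rmp)
        if residual <= tolerance:
            solutions.append(CompositionSolution(counts, ssq, residual))
    solutions.sort(key=lambda s: (s.residual, s.counts))
    return solutions


def build_registry(reference: ReferenceSequence) -> HaplotypeRegistry:
    """Instantiate Hun1–Hun6 on the reference via the fixed site pattern."""
    defs = []
    for name, site_idx in HAPLOTYPE_SITE_PATTERN.items():
        alleles = {}
        for i in site_idx:
            pos = VARIABLE_SITES[i]
            alleles[pos] = _TRANSITION[reference.base_at(pos)]
        defs.append(HaplotypeDefinition(name, alleles))
    return HaplotypeRegistry(reference, defs)


def simulate_survey(config: SimulationConfig) -> FixtureBundle:
    """Realise a composition as full-window sample sequences, by exact counts.

    Sample ids are ``{region}_{index:03d}`` in deterministic order; two runs
    with the same config produce byte-identical output.
    """
    start, end = config.window
    reference = generate_reference(end - start + 1, origin=start, seed=config.seed)
    registry = build_registry(reference)
    records: list[SampleRecord] = []
    meta_rows = []
    for region in sorted(config.composition):
        idx = 0
        for name in sorted(config.composition[region]):
            seq = registry.full_sequence(name, start, end)
            for _ in range(config.composition[region][name]):
                idx += 1
                sid = f"{region}_{idx:03d}"
                records.append(SampleRecord(sid, seq, start))
                meta_rows.append((sid, region, "survey"))
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "region", "source"])
    bundle = FixtureBundle(reference, registry, records, metadata,
                           {r: dict(c) for r, c in config.composition.items()})
    if config.fragment_model is not None:
        bundle.records = fragment_samples(bundle.records, config.fragment_model,
                                          seed=config.seed)
    return bundle


def build_fixture(variant: str, seed: int = 0) -> FixtureBundle:
    """Build one of the three named survey fixtures.

    ``global_192`` realises the printed pooled haplotype counts over 192
    samples in six regions; ``new_collection_138`` the 138 newly collected
    samples (five regions, four haplotypes); ``regional`` the per-region
    compositions recovered from the printed per-region statistics.
    """
    compositions = {
        "global_192": GLOBAL_192_COMPOSITION,
        "new_collection_138": NEW_COLLECTION_138_COMPOSITION,
        "regional": REGIONAL_COMPOSITION,
    }
    if variant not in compositions:
        raise ValueError(f"unknown fixture variant {variant!r}; "
                         f"expected one of {FIXTURE_VARIANTS}")
    return simulate_survey(SimulationConfig(composition=compositions[variant],
                                            seed=seed))


def fragment_samples(records: list[SampleRecord], model: FragmentModel,
                     seed: int = 0) -> list[SampleRecord]:
    """Degrade each record to one contiguous sub-sequence (seeded).

    Emulates the partial-coverage trace material forensic casework sees:
    each sample is replaced by a contiguous fragment with a recorded
    coverage interval, optionally with bases dropped to ``N``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        full_len = len(rec.sequence)
        if model.max_length > full_len:
            raise ValueError(f"fragment length {model.max_length} exceeds "
                             f"window length {full_len}")
        length = int(rng.integers(model.min_length, model.max_length + 1))
        offset = int(rng.integers(0, full_len - length + 1))
        seq = rec.sequence[offset:offset + length]
        if model.missing_probability > 0:
            mask = rng.random(length) < model.missing_probability
            seq = "".join("N" if m else b for b, m in zip(seq, mask))
        out.append(SampleRecord(rec.sample_id, seq, rec.start + offset))
    return out


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write samples.fasta / metadata.tsv / registry.json / reference.fasta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "samples.fasta",
        "metadata": outdir / "metadata.tsv",
        "registry": outdir / "registry.json",
        "reference": outdir / "reference.fasta",
    }
    write_fasta(bundle.records, paths["fasta"])
    bundle.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    bundle.registry.to_json(paths["registry"])
    ref = bundle.reference
    _write_seqrecords([SeqRecord(Seq(ref.sequence), id=ref.id,
                                 description=f"origin={ref.coordinate_origin}")],
                      paths["reference"])
    return paths


def write_fasta(records: list[SampleRecord], path: str | Path) -> None:
    _write_seqrecords(
        [SeqRecord(Seq(r.sequence), id=r.sample_id,
                   description=f"start={r.start} end={r.end}")
         for r in records], path)


def _write_seqrecords(seqrecords, path: str | Path) -> None:
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(seqrecords)
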