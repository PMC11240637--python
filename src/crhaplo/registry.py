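"""Reference sequences, haplotype definitions and the named-haplotype registry.

Coordinates are 1-based and inclusive throughout (GenBank convention). A
haplotype is defined relative to a reference as a sparse map from mitogenome
position to its substituted base; the reference haplotype has an empty map.
Indels are unsupported by design: the surveyed control-region data contained
substitutions only, and forensic traceability favours a hard error over a
silently placed gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from ._util import UNAMBIGUOUS


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference segment anchored at a 1-based mitogenome coordinate.

    Parameters
    ----------
    id : str
        Sequence identifier (e.g. a synthetic stand-in accession).
    sequence : str
        Uppercase A/C/G/T string.
    coordinate_origin : int
        Mitogenome coordinate of the first base, 1-based inclusive.
    """

    id: str
    sequence: str
    coordinate_origin: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence) - UNAMBIGUOUS
        if bad:
            raise ValueError(f"reference alphabet restricted to A/C/G/T, got {sorted(bad)}")
        if self.coordinate_origin < 1:
            raise ValueError("coordinate_origin must be >= 1")

    @property
    def end(self) -> int:
        """Mitogenome coordinate of the last base."""
        return self.coordinate_origin + len(self.sequence) - 1

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based mitogenome position."""
        if not self.coordinate_origin <= position <= self.end:
            raise IndexError(f"position {position} outside reference span "
                             f"[{self.coordinate_origin}, {self.end}]")
        return self.sequence[position - self.coordinate_origin]

    def subsequence(self, start: int, end: int) -> str:
        """Bases covering the inclusive mitogenome interval [start, end]."""
        if start > end:
            raise ValueError("start must be <= end")
        if start < self.coordinate_origin or end > self.end:
            raise IndexError(f"[{start}, {end}] outside reference span "
                             f"[{self.coordinate_origin}, {self.end}]")
        off = start - self.coordinate_origin
        return self.sequence[off:off + (end - start + 1)]


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A named haplotype as substitutions relative to the reference.

    ``alleles`` maps 1-based mitogenome positions to the substituted base;
    an empty map denotes the reference haplotype itself.
    """

    name: str
    alleles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, base in self.alleles.items():
            if base not in UNAMBIGUOUS:
                raise ValueError(f"{self.name}: substitutions only — allele at "
                                 f"{pos} must be A/C/G/T, got {base!r}")

    def base_at(self, position: int, reference: ReferenceSequence) -> str:
        return self.alleles.get(position, reference.base_at(position))


class HaplotypeRegistry:
    """Ordered collection of named haplotypes against a shared reference.

    Names follow a sequential prefix convention (``Hun1``, ``Hun2``, ...);
    newly discovered haplotypes are appended with the next free index.
    Registered entries are never renamed or removed (monotone growth).
    """

    def __init__(self, reference: ReferenceSequence,
                 definitions: list[HaplotypeDefinition] | None = None,
                 prefix: str = "Hun") -> None:
        self.reference = reference
        self.prefix = prefix
        self._definitions: list[HaplotypeDefinition] = []
        for d in definitions or []:
            self.add(d)

    def __len__(self) -> int:
        return len(self._definitions)

    def __iter__(self):
        return iter(self._definitions)

    def __contains__(self, name: str) -> bool:
        return any(d.name == name for d in self._definitions)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self._definitions]

    def get(self, name: str) -> HaplotypeDefinition:
        for d in self._definitions:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def variable_sites(self) -> list[int]:
        """Sorted union of all positions at which any haplotype substitutes."""
        sites: set[int] = set()
        for d in self._definitions:
            sites.update(d.alleles)
        return sorted(sites)

    def allele_vector(self, name: str) -> tuple[str, ...]:
        """Bases of `name` over the registry's union of variable sites."""
        d = self.get(name)
        return tuple(d.base_at(p, self.reference) for p in self.variable_sites)

    def add(self, definition: HaplotypeDefinition) -> None:
        if definition.name in self:
            raise ValueError(f"duplicate haplotype name {definition.name!r}")
        for pos in definition.alleles:
            ref = self.reference.base_at(pos)  # also range-checks
            if definition.alleles[pos] == ref:
                raise ValueError(f"{definition.name}: allele at {pos} equals the "
                                 f"reference base {ref!r}")
        self._definitions.append(definition)
        # allele vectors must stay pairwise distinct over the union of sites
        sites = self.variable_sites
        seen: dict[tuple[str, ...], str] = {}
        for d in self._definitions:
            vec = tuple(d.base_at(p, self.reference) for p in sites)
            if vec in seen:
                self._definitions.pop()
                raise ValueError(f"haplotypes {seen[vec]!r} and {d.name!r} share "
                                 "an allele vector")
            seen[vec] = d.name

    def next_name(self) -> str:
        """Next sequential haplotype name (prefix + max index + 1)."""
        indices = []
        for d in self._definitions:
            suffix = d.name[len(self.prefix):]
            if d.name.startswith(self.prefix) and suffix.isdigit():
                indices.append(int(suffix))
        return f"{self.prefix}{max(indices, default=0) + 1}"

    def full_sequence(self, name: str, start: int, end: int) -> str:
        """Haplotype bases over the inclusive window [start, end]."""
        seq = list(self.reference.subsequence(start, end))
        for pos, base in self.get(name).alleles.items():
            if start <= pos <= end:
                seq[pos - start] = base
        return "".join(seq)

    # JSON round trip: {name: {position: base}}, positions as string keys.

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reference": {"id": self.reference.id,
                          "sequence": self.reference.sequence,
                          "coordinate_origin": self.reference.coordinate_origin},
            "prefix": self.prefix,
            "haplotypes": {d.name: {str(p): b for p, b in sorted(d.alleles.items())}
                           for d in self._definitions},
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HaplotypeRegistry":
        payload = json.loads(Path(path).read_text())
        ref = ReferenceSequence(**payload["reference"])
        defs = [HaplotypeDefinition(name, {int(p): b for p, b in alleles.items()})
                for name, alleles in payload["haplotypes"].items()]
        return cls(ref, defs, prefix=payload.get("prefix", "Hun"))
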