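"""Model-style front end: a survey fitted to sequences yields results.

`HaplotypeSurvey` holds the data (sample sequences, region metadata, the
reference and optionally a pre-existing haplotype registry) together with
the analysis window; `fit()` runs mapping -> haplotype collapsing ->
diversity statistics -> pairwise differentiation and returns a
`SurveyResults` carrying the estimates, permutation p-values and a
`summary()` table mirroring the field's usual region-by-statistic layout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import published
from .differentiation import DifferentiationMatrix, differentiation_matrix
from .diversity import (DEFAULT_L, DifferenceMatrix, PopulationTable,
                        rounded_stats, stats_table, write_stats)
from .haplotyping import (AlignmentWindow, HaplotypeAssignment,
                          PositionedSample, assign_haplotypes,
                          call_segregating_sites, haplotype_frequencies,
                          map_to_reference, read_fasta, read_metadata,
                          read_reference, write_assignments)
from .registry import HaplotypeRegistry
from .simulate import (WINDOW, FixtureBundle, SampleRecord, build_fixture,
                       build_registry)


class HaplotypeSurvey:
    """An mtDNA control-region survey ready to be fitted.

    Parameters
    ----------
    records : list of SampleRecord
        Sample sequences anchored at 1-based mitogenome coordinates.
    metadata : DataFrame
        Columns ``sample_id`` and ``region`` (``source`` optional).
    reference : ReferenceSequence
    registry : HaplotypeRegistry, optional
        Known haplotypes; defaults to an empty registry (every distinct
        sequence then registers as a new haplotype).
    window : (start, end), optional
        Analysis window, default the full amplicon.
    L : int
        Evaluated alignment length for nucleotide diversity (default 450).
    """

    def __init__(self, records: list[SampleRecord], metadata: pd.DataFrame,
                 reference, registry: HaplotypeRegistry | None = None,
                 window: tuple[int, int] = WINDOW, L: int = DEFAULT_L,
                 allow_new: bool = True) -> None:
        self.records = records
        self.metadata = metadata
        self.reference = reference
        self.registry = registry if registry is not None \
            else HaplotypeRegistry(reference)
        self.window = AlignmentWindow(*window)
        self.L = L
        self.allow_new = allow_new

    @classmethod
    def from_files(cls, fasta: str | Path, metadata: str | Path,
                   reference: str | Path, registry: str | Path | None = None,
                   window: tuple[int, int] = WINDOW, L: int = DEFAULT_L,
                   allow_new: bool = True) -> "HaplotypeSurvey":
        ref = read_reference(reference)
        reg = HaplotypeRegistry.from_json(registry) if registry else None
        return cls(read_fasta(fasta, default_start=window[0]),
                   read_metadata(metadata), ref, reg, window=window, L=L,
                   allow_new=allow_new)

    @classmethod
    def from_fixture(cls, variant: str = "regional", seed: int = 0,
                     L: int = DEFAULT_L, use_registry: bool = True,
                     ) -> "HaplotypeSurvey":
        """Build a survey directly from a named synthetic fixture."""
        bundle: FixtureBundle = build_fixture(variant, seed=seed)
        registry = bundle.registry if use_registry else None
        return cls(bundle.records, bundle.metadata, bundle.reference,
                   registry, L=L)

    def fit(self, n_permutations: int = 0, seed: int = 0,
            corrected_gst: bool = True) -> "SurveyResults":
        """Run the full pipeline and return the fitted results.

        ``n_permutations=0`` (default) skips permutation significance; the
        survey's production setting is 10,000.
        """
        positioned = [map_to_reference(r, self.reference, self.window)
                      for r in self.records]
        assignments, registry = assign_haplotypes(positioned, self.registry,
                                                  allow_new=self.allow_new)
        seg_sites = call_segregating_sites(positioned, self.window)
        table = haplotype_frequencies(assignments, self.metadata)
        stats = stats_table(table, registry, L=self.L)
        diffs = DifferenceMatrix.from_registry(registry)
        differentiation = None
        if len(table.regions) >= 2:
            differentiation = differentiation_matrix(
                table, diffs, n_perm=n_permutations, seed=seed,
                corrected_gst=corrected_gst)
        return SurveyResults(self, positioned, assignments, registry,
                             seg_sites, table, stats, differentiation,
                             n_permutations, seed)


@dataclass
class SurveyResults:
    """Fitted survey: estimates, diagnostics and report writers."""

    model: HaplotypeSurvey
    positioned: list[PositionedSample]
    assignments: list[HaplotypeAssignment]
    registry: HaplotypeRegistry
    segregating_sites: list[int]
    population_table: PopulationTable
    diversity: pd.DataFrame
    differentiation: DifferentiationMatrix | None
    n_permutations: int
    seed: int

    @property
    def haplotype_names(self) -> list[str]:
        assigned = {a.haplotype for a in self.assignments if a.assigned}
        return sorted(assigned)

    def summary(self) -> str:
        """Human-readable report in the survey's region-by-statistic layout."""
        lines = [
            "mtDNA control-region survey summary",
            f"  samples: {len(self.assignments)}  "
            f"(unassigned fragments: {len(self.population_table.excluded)})",
            f"  window: {self.model.window.start}-{self.model.window.end} "
            f"(L = {self.model.L} evaluated)",
            f"  segregating sites: {len(self.segregating_sites)}  "
            f"haplotypes: {len(self.haplotype_names)}",
            "",
            rounded_stats(self.diversity).astype(object).T.to_string(),
        ]
        lines.append("")
        lines.append("  note: overall RMP is the unweighted mean of regional "
                     "RMPs; RMP_pooled is sum(p_i^2) over pooled counts. "
                     "Overall Hd and pi are pooled.")
        if self.differentiation is not None:
            sig = self.differentiation.significant_pairs()
            lines.append("")
            lines.append("pairwise Fst (lower) / Gst (upper):")
            for region in self.differentiation.regions:
                row = []
                for other in self.differentiation.regions:
                    if region == other:
                        row.append("  .  ")
                    else:
                        mat = (self.differentiation.fst
                               if self.differentiation.regions.index(region)
                               > self.differentiation.regions.index(other)
                               else self.differentiation.gst)
                        row.append(f"{mat.loc[region, other]:6.3f}")
                lines.append(f"  {region:>4} " + " ".join(row))
            lines.append(f"  Fst >= {published.FST_SIGNIFICANT}: significant "
                         f"genetic difference — pairs: "
                         f"{', '.join('-'.join(p) for p in sig) or 'none'}")
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the full report bundle (TSV + JSON + registry + run log)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "stats_tsv": outdir / "stats.tsv",
            "stats_json": outdir / "stats.json",
            "assignments": outdir / "assignments.tsv",
            "registry": outdir / "registry.json",
            "log": outdir / "run_log.json",
        }
        write_stats(self.diversity, paths["stats_tsv"], paths["stats_json"])
        write_assignments(self.assignments, paths["assignments"])
        self.registry.to_json(paths["registry"])
        if self.differentiation is not None:
            paths["diff_tsv"] = outdir / "differentiation.tsv"
            paths["diff_json"] = outdir / "differentiation.json"
            self.differentiation.to_tsv(paths["diff_tsv"])
            self.differentiation.to_json(paths["diff_json"])
        digest = hashlib.sha256(
            "".join(p.sequence for p in self.positioned).encode()).hexdigest()
        log = {
            "seed": self.seed,
            "n_permutations": self.n_permutations,
            "n_samples": len(self.assignments),
            "segregating_sites": self.segregating_sites,
            "haplotypes": self.haplotype_names,
            "input_digest_sha256": digest,
            "window": [self.model.window.start, self.model.window.end],
            "L": self.model.L,
        }
        paths["log"].write_text(json.dumps(log, indent=1) + "\n")
        return paths


__all__ = ["HaplotypeSurvey", "SurveyResults", "build_registry"]
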