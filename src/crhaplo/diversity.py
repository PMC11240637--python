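"""Haplotype diversity, nucleotide diversity and random match probability.

Estimators
----------
For haplotype counts ``c_i`` summing to ``n`` with frequencies ``p_i``:

* random match probability  ``RMP = sum p_i^2`` — the chance two unrelated
  individuals drawn at random share a haplotype;
* haplotype diversity ``Hd = n/(n-1) * (1 - sum p_i^2)`` (unbiased form; the
  plain form omits the n/(n-1) factor), so ``Hd = n/(n-1) * (1 - RMP)``
  holds exactly when both derive from the same counts;
* nucleotide diversity per site
  ``pi = [n/(n-1)] * sum_{i<j} 2 p_i p_j d_ij / L`` with ``d_ij`` the count
  of differing sites between haplotypes i and j and ``L`` the evaluated
  alignment length (default 450, the combined-analysis sub-window in which
  all variable sites of the surveyed population fall).

The overall RMP of a subdivided survey is reported two ways, because the
published table mixes them: the unweighted arithmetic mean of the regional
RMPs (the published headline) and the pooled ``sum p_i^2`` over summed
counts. Overall Hd and pi are pooled. That asymmetry is the published
record's, reproduced deliberately and flagged in reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up
from .registry import HaplotypeRegistry

DEFAULT_L = 450


@dataclass(frozen=True)
class PopulationTable:
    """Per-region haplotype counts; rows are regions, columns haplotypes."""

    counts: pd.DataFrame
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.counts.empty and (self.counts.to_numpy() < 0).any():
            raise ValueError("haplotype counts must be non-negative")

    @property
    def regions(self) -> list[str]:
        return list(self.counts.index)

    @property
    def haplotypes(self) -> list[str]:
        return list(self.counts.columns)

    def n(self, region: str) -> int:
        return int(self.counts.loc[region].sum())

    def region_counts(self, region: str) -> dict[str, int]:
        row = self.counts.loc[region]
        return {h: int(c) for h, c in row.items() if c > 0}

    def pooled_counts(self) -> dict[str, int]:
        tot = self.counts.sum(axis=0)
        return {h: int(c) for h, c in tot.items() if c > 0}

    def frequencies(self, region: str) -> dict[str, float]:
        n = self.n(region)
        return {h: c / n for h, c in self.region_counts(region).items()}

    @classmethod
    def from_counts(cls, composition: Mapping[str, Mapping[str, int]],
                    ) -> "PopulationTable":
        df = (pd.DataFrame(composition).T.fillna(0).astype(int)
              .sort_index(axis=0).sort_index(axis=1))
        return cls(df)


class DifferenceMatrix:
    """Pairwise counts of differing variable sites between named haplotypes."""

    def __init__(self, diffs: Mapping[tuple[str, str], int]) -> None:
        self._d: dict[tuple[str, str], int] = {}
        for (a, b), d in diffs.items():
            if d < 0:
                raise ValueError("difference counts must be non-negative")
            self._d[(a, b)] = d
            self._d[(b, a)] = d

    def d(self, a: str, b: str) -> int:
        if a == b:
            return 0
        try:
            return self._d[(a, b)]
        except KeyError:
            raise KeyError(f"no difference count for pair ({a!r}, {b!r})") from None

    @classmethod
    def from_registry(cls, registry: HaplotypeRegistry) -> "DifferenceMatrix":
        names = registry.names
        vecs = {n: registry.allele_vector(n) for n in names}
        diffs = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                diffs[(a, b)] = sum(x != y for x, y in zip(vecs[a], vecs[b]))
        return cls(diffs)


def _as_counts(counts: Mapping[str, int] | Iterable[int]) -> np.ndarray:
    if isinstance(counts, Mapping):
        arr = np.asarray(list(counts.values()), dtype=float)
    else:
        arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("empty haplotype counts")
    if (arr < 0).any():
        raise ValueError("haplotype counts must be non-negative")
    if arr.sum() < 1:
        raise ValueError("total count must be >= 1")
    return arr


def rmp(counts: Mapping[str, int] | Iterable[int]) -> float:
    """Random match probability ``sum (c_i/n)^2``."""
    arr = _as_counts(counts)
    p = arr / arr.sum()
    return float(np.dot(p, p))


def haplotype_diversity(counts: Mapping[str, int] | Iterable[int],
                        unbiased: bool = True) -> float:
    """Haplotype (gene) diversity; unbiased applies the n/(n-1) correction.

    A single-sample population is monomorphic by definition and returns 0
    even under the unbiased flag (the correction is undefined at n=1).
    """
    arr = _as_counts(counts)
    n = arr.sum()
    if n == 1:
        return 0.0
    return hd_from_sum_sq(n, rmp(arr), unbiased=unbiased)


def hd_from_sum_sq(n: float, sum_sq: float, unbiased: bool = True) -> float:
    """Haplotype diversity from a sample size and sum of squared frequencies.

    Useful when only the printed sum(p_i^2) of a survey is available rather
    than the underlying counts.
    """
    if unbiased:
        if n < 2:
            raise ValueError("unbiased Hd requires n >= 2")
        return float(n / (n - 1) * (1.0 - sum_sq))
    return float(1.0 - sum_sq)


def nucleotide_diversity(counts: Mapping[str, int],
                         diffs: DifferenceMatrix | int,
                         L: int = DEFAULT_L,
                         unbiased: bool = True) -> float:
    """Nucleotide diversity per site from haplotype counts and differences.

    ``diffs`` may be a scalar when every haplotype pair differs by the same
    number of sites (e.g. the forced d=1 of a two-haplotype, one-site
    region).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    names = list(counts)
    arr = _as_counts(counts)
    n = arr.sum()
    p = arr / n
    total = 0.0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = diffs if isinstance(diffs, (int, float)) else diffs.d(names[i], names[j])
            total += 2.0 * p[i] * p[j] * d
    if unbiased and n > 1:
        total *= n / (n - 1)
    return float(total / L)


def overall_rmp(regional_rmps: Iterable[float] | None = None,
                pooled_counts: Mapping[str, int] | None = None,
                mode: str = "mean_of_regions") -> float:
    """Survey-wide random match probability.

    ``mean_of_regions`` (the published headline) is the unweighted arithmetic
    mean of the regional RMPs; ``pooled`` is sum(p_i^2) over the summed
    counts. Both are legitimate; reports carry both side by side.
    """
    if mode == "mean_of_regions":
        vals = list(regional_rmps or [])
        if not vals:
            raise ValueError("mean_of_regions requires regional RMP values")
        return float(np.mean(vals))
    if mode == "pooled":
        if not pooled_counts:
            raise ValueError("pooled mode requires pooled counts")
        return rmp(pooled_counts)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class DiversityStats:
    """One region's (or the pooled survey's) summary statistics."""

    n: int
    S: int
    k: int
    Hd: float
    pi_nt: float
    RMP: float


def _segregating_among(names: list[str], registry: HaplotypeRegistry) -> int:
    """Number of variable sites among a set of registered haplotypes."""
    vecs = [registry.allele_vector(nm) for nm in names]
    if not vecs:
        return 0
    return sum(len({v[i] for v in vecs}) >= 2 for i in range(len(vecs[0])))


def stats_table(table: PopulationTable, registry: HaplotypeRegistry,
                L: int = DEFAULT_L, unbiased: bool = True) -> pd.DataFrame:
    """Per-region diversity statistics plus an overall row.

    S and k are computed from the data (which haplotypes actually occur and
    at how many sites they differ), never taken from configuration. The
    ``Overall`` row pools counts for n/S/k/Hd/pi; its ``RMP`` column is the
    unweighted mean of the regional RMPs and ``RMP_pooled`` the pooled
    sum(p_i^2) (for regions the two columns coincide).
    """
    diffs = DifferenceMatrix.from_registry(registry)
    rows = {}
    regional_rmps = []
    for region in table.regions:
        counts = table.region_counts(region)
        n = sum(counts.values())
        if n == 0:
            raise ValueError(f"region {region!r} has no samples")
        r = rmp(counts)
        regional_rmps.append(r)
        rows[region] = DiversityStats(
            n=n, S=_segregating_among(list(counts), registry), k=len(counts),
            Hd=haplotype_diversity(counts, unbiased=unbiased),
            pi_nt=nucleotide_diversity(counts, diffs, L=L, unbiased=unbiased),
            RMP=r)
    pooled = table.pooled_counts()
    n_all = sum(pooled.values())
    overall = DiversityStats(
        n=n_all, S=_segregating_among(list(pooled), registry), k=len(pooled),
        Hd=haplotype_diversity(pooled, unbiased=unbiased),
        pi_nt=nucleotide_diversity(pooled, diffs, L=L, unbiased=unbiased),
        RMP=overall_rmp(regional_rmps, mode="mean_of_regions"))
    df = pd.DataFrame({reg: vars(st) for reg, st in rows.items()}).T
    df.loc["Overall"] = vars(overall)
    df["RMP_pooled"] = [rows[r].RMP for r in table.regions] + [rmp(pooled)]
    df = df.astype({"n": int, "S": int, "k": int})
    return df


def rounded_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Display-rounded copy (3 decimals; 5 for pi). Never fed downstream."""
    out = df.copy()
    for col, nd in (("Hd", 3), ("RMP", 3), ("RMP_pooled", 3), ("pi_nt", 5)):
        out[col] = [round_half_up(v, nd) for v in out[col]]
    return out


def write_stats(df: pd.DataFrame, tsv_path: str | Path,
                json_path: str | Path | None = None) -> None:
    """Write the stats table as TSV (regions as columns, statistics as rows)
    and optionally as JSON with full-precision values."""
    rounded = rounded_stats(df)
    rounded.astype(object).T.to_csv(tsv_path, sep="\t")
    if json_path is not None:
        payload = {region: {k: (int(v) if k in ("n", "S", "k") else float(v))
                            for k, v in row.items()}
                   for region, row in df.T.to_dict().items()}
        Path(json_path).write_text(json.dumps(payload, indent=1) + "\n")
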