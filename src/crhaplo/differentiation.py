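"""Pairwise population differentiation: Hudson-style Fst and Nei Gst.

Fst follows the Hudson–Slatkin–Maddison sequence formulation
``Fst = 1 - Hw/Hb`` where ``Hw`` is the unweighted mean of the two
within-population mean pairwise difference counts and ``Hb`` the mean
difference count over all between-population pairs; ``Hb = 0`` is defined as
Fst 0 (no divergence anywhere). Negative estimates on near-identical
populations are reported as computed, never clamped — a small negative value
is the estimator's way of saying "no subdivision".

Gst is Nei's coefficient of gene differentiation ``(Ht - Hs)/Ht`` on
haplotype frequencies; the corrected variant applies the Nei–Chesser
small-sample estimators with the harmonic mean of sample sizes,

    Hs_hat = n~/(n~ - 1) * (1 - mean_k sum_i x_ik^2)
    Ht_hat = 1 - sum_i xbar_i^2 + Hs_hat/(n~ s)

with ``s`` populations and ``x_ik`` sample frequencies.

Significance per pair comes from a label permutation test with the add-one
p-value estimator ``p = (1 + #{perm >= obs})/(1 + n_perm)``. An Fst at or
above 0.15 is annotated as indicating significant genetic difference between
subpopulations (the survey's working threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .diversity import DifferenceMatrix, PopulationTable
from .published import FST_SIGNIFICANT


def _mean_within(counts: Mapping[str, int], diffs: DifferenceMatrix) -> float:
    """Mean pairwise difference count over unordered within-population pairs."""
    names = list(counts)
    n = sum(counts.values())
    if n < 1:
        raise ValueError("population of size 0")
    if n == 1:
        return 0.0  # no within pairs; contributes no diversity
    total = 0.0
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            total += counts[a] * counts[b] * diffs.d(a, b)
    return total / (n * (n - 1) / 2)


def _mean_between(ca: Mapping[str, int], cb: Mapping[str, int],
                  diffs: DifferenceMatrix) -> float:
    na, nb = sum(ca.values()), sum(cb.values())
    total = 0.0
    for a, x in ca.items():
        for b, y in cb.items():
            total += x * y * diffs.d(a, b)
    return total / (na * nb)


def hudson_fst(counts_a: Mapping[str, int], counts_b: Mapping[str, int],
               diffs: DifferenceMatrix) -> float:
    """Hudson–Slatkin–Maddison Fst = 1 - Hw/Hb between two populations."""
    if not counts_a or not counts_b:
        raise ValueError("both populations must be non-empty")
    hw = 0.5 * (_mean_within(counts_a, diffs) + _mean_within(counts_b, diffs))
    hb = _mean_between(counts_a, counts_b, diffs)
    if hb == 0.0:
        return 0.0
    return 1.0 - hw / hb


def nei_gst(table: PopulationTable, corrected: bool = False) -> float:
    """Nei's Gst over all populations of the table.

    ``corrected=True`` applies the Nei–Chesser small-sample estimators
    (harmonic-mean sample size), honouring the survey's "corrected Gst which
    also considers the population sizes". All-monomorphic-identical input
    yields 0 with a warning rather than 0/0.
    """
    import warnings

    regions = table.regions
    if len(regions) < 2:
        raise ValueError("Gst needs >= 2 populations")
    haps = table.haplotypes
    freqs = np.array([[table.counts.loc[r, h] / table.n(r) for h in haps]
                      for r in regions], dtype=float)
    sizes = np.array([table.n(r) for r in regions], dtype=float)
    s = len(regions)
    hs_obs = float(np.mean(1.0 - (freqs ** 2).sum(axis=1)))
    xbar = freqs.mean(axis=0)
    ht_obs = float(1.0 - (xbar ** 2).sum())
    if corrected:
        n_harm = s / float((1.0 / sizes).sum())
        hs = n_harm / (n_harm - 1.0) * hs_obs
        ht = ht_obs + hs / (n_harm * s)
    else:
        hs, ht = hs_obs, ht_obs
    if ht == 0.0:
        warnings.warn("all populations monomorphic for the same haplotype; "
                      "Gst defined as 0")
        return 0.0
    return (ht - hs) / ht


def pair_gst(counts_a: Mapping[str, int], counts_b: Mapping[str, int],
             corrected: bool = True) -> float:
    """Gst restricted to one population pair."""
    return nei_gst(PopulationTable.from_counts({"a": counts_a, "b": counts_b}),
                   corrected=corrected)


def permutation_test(counts_a: Mapping[str, int], counts_b: Mapping[str, int],
                     statistic: Callable[[Mapping[str, int], Mapping[str, int]], float],
                     n_perm: int = 10_000, seed: int = 0) -> float:
    """Label-permutation p-value for a pairwise differentiation statistic.

    Population labels are shuffled across the pooled pair (equivalently, a
    multivariate-hypergeometric draw of one group from the pooled counts) and
    the statistic recomputed; ``p = (1 + #{perm >= obs})/(1 + n_perm)`` so p
    can never be exactly 0. Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    names = sorted(set(counts_a) | set(counts_b))
    pooled = np.array([counts_a.get(h, 0) + counts_b.get(h, 0) for h in names])
    if (pooled > 0).sum() < 2:
        raise ValueError("degenerate pair: pooled samples carry one haplotype")
    na = sum(counts_a.values())
    observed = statistic(counts_a, counts_b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        draw = rng.multivariate_hypergeometric(pooled, na)
        ca = {h: int(c) for h, c in zip(names, draw) if c > 0}
        cb = {h: int(c) for h, c in zip(names, pooled - draw) if c > 0}
        if statistic(ca, cb) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


@dataclass
class DifferentiationMatrix:
    """All pairwise Fst/Gst values with permutation p-values."""

    regions: list[str]
    fst: pd.DataFrame
    gst: pd.DataFrame
    fst_p: pd.DataFrame
    n_permutations: int
    seed: int

    def significant_pairs(self, threshold: float = FST_SIGNIFICANT,
                          ) -> list[tuple[str, str]]:
        """Pairs whose Fst meets the working significance threshold."""
        out = []
        for a, b in combinations(self.regions, 2):
            if self.fst.loc[a, b] >= threshold:
                out.append((a, b))
        return out

    def to_tsv(self, path: str | Path) -> None:
        """Combined triangle layout: Fst below the diagonal, Gst above."""
        combined = pd.DataFrame("", index=self.regions, columns=self.regions)
        for a, b in combinations(self.regions, 2):
            combined.loc[b, a] = f"{self.fst.loc[a, b]:.3f}"
            combined.loc[a, b] = f"{self.gst.loc[a, b]:.3f}"
        combined.to_csv(path, sep="\t")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": self.regions,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "fst_significance_threshold": FST_SIGNIFICANT,
            "pairs": [{
                "pair": [a, b],
                "fst": float(self.fst.loc[a, b]),
                "gst": float(self.gst.loc[a, b]),
                "fst_p": (None if self.fst_p.empty
                          else float(self.fst_p.loc[a, b])),
                "fst_significant": bool(self.fst.loc[a, b] >= FST_SIGNIFICANT),
            } for a, b in combinations(self.regions, 2)],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def differentiation_matrix(table: PopulationTable, diffs: DifferenceMatrix,
                           n_perm: int = 10_000, seed: int = 0,
                           corrected_gst: bool = True,
                           bonferroni: bool = False) -> DifferentiationMatrix:
    """Compute every pairwise Fst and Gst, with optional permutation tests.

    ``n_perm=0`` skips significance testing. ``bonferroni=True`` multiplies
    each p-value by the number of pairs (capped at 1); the default applies no
    multiple-testing adjustment, matching the survey's reporting.
    """
    regions = table.regions
    if len(regions) < 2:
        raise ValueError("need >= 2 populations")
    fst = pd.DataFrame(np.nan, index=regions, columns=regions)
    gst = pd.DataFrame(np.nan, index=regions, columns=regions)
    pvals = pd.DataFrame(np.nan, index=regions, columns=regions)
    pairs = list(combinations(regions, 2))
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        ca, cb = table.region_counts(a), table.region_counts(b)
        f = hudson_fst(ca, cb, diffs)
        g = pair_gst(ca, cb, corrected=corrected_gst)
        fst.loc[a, b] = fst.loc[b, a] = f
        gst.loc[a, b] = gst.loc[b, a] = g
        if n_perm > 0:
            pair_seed = int(rng.integers(0, 2**31 - 1))
            p = permutation_test(ca, cb,
                                 lambda x, y: hudson_fst(x, y, diffs),
                                 n_perm=n_perm, seed=pair_seed)
            if bonferroni:
                p = min(1.0, p * len(pairs))
            pvals.loc[a, b] = pvals.loc[b, a] = p
    if n_perm == 0:
        pvals = pd.DataFrame()
    return DifferentiationMatrix(regions, fst, gst, pvals, n_perm, seed)
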