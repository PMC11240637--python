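"""Published summary statistics of the Hungarian fallow deer mtDNA CR survey.

The six-region survey of the Hungarian fallow deer (*Dama dama*) mitochondrial
control region is the dataset this package's synthetic fixtures emulate. Only
its printed summary numbers are public (per-region sample sizes, segregating
sites, haplotype counts, Hd, pi, RMP, and the pooled haplotype inventory); the
underlying per-individual sequences are not. The constants below are those
printed values, kept verbatim so that estimator checks and the composition
inversion oracle can use them as inputs.

Two internal inconsistencies of the printed table are preserved deliberately
(they are the published record, not ours to repair):

* the SW column's Hd (0.611) and RMP (0.617) cannot both arise from one
  haplotype composition of n = 37 — Hd 0.611 implies sum(p_i^2) ~ 0.405;
* the overall RMP (0.547) is the unweighted mean of the six regional RMP
  entries, while the overall Hd (0.565) is the pooled estimate.
"""

from __future__ import annotations

#: Region codes in the survey's column order.
REGIONS = ("NW", "NM", "NE", "SW", "SM", "SE")

#: Per-region sample sizes (n row); 192 in total.
SAMPLE_SIZES = {"NW": 34, "NM": 42, "NE": 41, "SW": 37, "SM": 31, "SE": 7}

#: Per-region segregating-site counts (S row); 6 overall.
SEGREGATING_SITES = {"NW": 1, "NM": 2, "NE": 2, "SW": 3, "SM": 2, "SE": 4}

#: Per-region haplotype counts (k row); 6 overall.
HAPLOTYPE_COUNTS_K = {"NW": 2, "NM": 3, "NE": 3, "SW": 3, "SM": 3, "SE": 3}

#: Haplotype diversity row (unbiased estimator); overall is pooled.
HD = {"NW": 0.428, "NM": 0.529, "NE": 0.526, "SW": 0.611, "SM": 0.333,
      "SE": 0.667, "Overall": 0.565}

#: Nucleotide diversity row (per site, L = 450 evaluated window).
PI = {"NW": 0.00095, "NM": 0.00123, "NE": 0.00123, "SW": 0.00221,
      "SM": 0.00076, "SE": 0.00423, "Overall": 0.00162}

#: Random match probability row; overall is the unweighted regional mean.
RMP = {"NW": 0.585, "NM": 0.484, "NE": 0.487, "SW": 0.617, "SM": 0.677,
       "SE": 0.429, "Overall": 0.547}

#: Pooled haplotype inventory over all 192 individuals.
GLOBAL_HAPLOTYPE_COUNTS = {
    "Hun1": 66, "Hun2": 108, "Hun3": 1, "Hun4": 1, "Hun5": 9, "Hun6": 7,
}

#: Printed pooled percentages and the precision at which each is printed.
GLOBAL_PERCENTAGES = {
    "Hun1": (34.0, 0), "Hun2": (56.0, 0), "Hun3": (0.5, 1),
    "Hun4": (0.5, 1), "Hun5": (4.7, 1), "Hun6": (3.6, 1),
}

#: Amplicon primers: names encode the 1-based mitogenome position of the 5' base.
FORWARD_PRIMER = "F15,386"
REVERSE_PRIMER = "R16,330"

#: Evaluated alignment length for nucleotide diversity: all variable sites fall
#: inside the 450-bp sub-window shared with earlier surveys.
COMBINED_WINDOW_LENGTH = 450

#: Fst at or above this marks a significant difference between subpopulations.
FST_SIGNIFICANT = 0.15
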