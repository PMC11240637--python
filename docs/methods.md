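# Methods

## Scope and model

`crhaplo` analyses mitochondrial control-region (CR) sequence surveys for
forensic use. The pipeline is: gap-free placement of each sample on a
reference window → segregating-site calling → collapsing onto named
haplotypes → per-population diversity statistics → pairwise differentiation
→ match evaluation. There is no fitted stochastic model; the "fit" of a
`HaplotypeSurvey` is the deterministic computation of these estimators, with
uncertainty entering only through permutation p-values for differentiation.

## Coordinates, windows and primers

All coordinates are 1-based inclusive (GenBank convention). Primer names
encode the 5'-base position (`F15,386`, `R16,330`); the amplicon is the
inclusive interval between the two 5' positions on the forward strand, so
F15,386/R16,330 spans 945 bp. Nucleotide diversity is evaluated over
`L = 450` by default: in the population this package emulates, every
variable site falls inside the 450-bp sub-window shared with earlier
surveys, and the printed π values are only reproduced with that denominator
(0.42781/450 = 0.00095 for the two-haplotype region). `L` is configurable
for other datasets. End-trimming of the amplicon is supported but defaults
to none, since the survey's trimmed boundaries ("approx. 900 bp evaluated")
were not published.

## Estimators

* `RMP = Σ p_i²`; haplotype diversity `Hd = n/(n−1)·(1 − Σ p_i²)` (unbiased
  by default — the published regional values are only reproduced with the
  correction); `π = [n/(n−1)]·Σ_{i<j} 2 p_i p_j d_ij / L`.
* A single-sample population returns Hd = π = 0 (the n/(n−1) factor is
  undefined at n = 1, and one sequence is monomorphic by definition).
* The overall RMP of a subdivided survey is reported both as the unweighted
  mean of regional RMPs (the published headline convention) and as the
  pooled `Σ p_i²`; overall Hd and π are pooled. The asymmetry is the
  published record's and is flagged in the report rather than repaired.
* Display rounding is half-up to 3 decimals (5 for π); full precision is
  kept internally and rounding never feeds downstream computation.

## Differentiation

Fst is the Hudson–Slatkin–Maddison sequence estimator `1 − Hw/Hb`, with
`Hw` the unweighted mean of the two within-population mean pairwise
difference counts (over the C(n,2) unordered pairs) and `Hb` the mean count
over all between-population pairs. The software the emulated survey used is
named but its estimator variant is not; this choice is the conventional
sequence-data Fst of that software and is documented as an assumption. Two
consequences are deliberate: duplicating a population yields exactly
`−1/(n−1)` (the finite-sample floor, tending to zero and conventionally
read as zero), and near-identical populations may print small negative
values, which are reported unclamped.

Gst is Nei's `(Ht − Hs)/Ht` on haplotype frequencies; the corrected variant
uses the Nei–Chesser small-sample estimators with the harmonic mean sample
size `ñ`: `Ĥs = ñ/(ñ−1)·(1 − mean_k Σ_i x²_ik)`, `Ĥt = 1 − Σ_i x̄_i² +
Ĥs/(ñ s)`. Both corrected and uncorrected are available.

Significance per pair is a label permutation test (a multivariate
hypergeometric re-draw of one group from the pooled counts), with the
add-one estimator `p = (1 + #{perm ≥ obs})/(1 + n_perm)` so p is never 0.
Default `n_perm = 10,000`; the test suite uses 99–999 to stay fast. No
multiple-testing adjustment is applied by default (matching the emulated
survey); a Bonferroni flag exists. Fst ≥ 0.15 is annotated as indicating a
significant genetic difference between subpopulations — a working threshold
from the wildlife-forensics literature, not a hypothesis test.

## Haplotype collapsing

A sample matches a registered haplotype iff they agree at every covered
unambiguous position — not only at the variable sites, so a private
substitution creates a new haplotype rather than a silent match. IUPAC
codes and N are missing data: they contribute no segregating-site evidence,
are skipped in match-discrepancy counts, and block assignment (a fragment
missing any variable site gets a consistency set instead — all registered
haplotypes agreeing with it where covered). New haplotypes take the next
sequential name; samples are processed in sorted-id order so discovery
naming is deterministic and the partition is input-order invariant. Indels
are a hard, named error: the emulated data contained none, and forensic
traceability favours refusal over a silently placed gap.

## Forensic match evaluation

Verdicts follow the casework convention: 0 discrepancies = match, 1 =
inconclusive (possible private mutation or heteroplasmy), ≥2 = exclusion.
Comparisons with no jointly covered unambiguous position are a distinct
error, never a match. Match weights report the haplotype's sample frequency
per region and overall; a conservative add-one estimate `(x+1)/(n+1)` and a
one-sided 95% Clopper–Pearson upper bound are attached (under-sampling then
errs against the prosecution). The sample frequency stays the headline to
match the emulated survey's arithmetic. For a consistency set the summed
member frequencies are reported — an upper bound on the match probability.

## Synthetic data: what it emulates and what it does not

The generator reconstructs a published six-region fallow deer survey from
its printed summary numbers; the real per-individual sequences are not
public. The stated world: 192 samples (NW 34, NM 42, NE 41, SW 37, SM 31,
SE 7), six haplotypes Hun1–Hun6 with global counts 66/108/1/1/9/7, six
substitution-only variable sites inside the 450-bp sub-window, and rare
haplotypes restricted by region (Hun3 NE-only, Hun4 NM-only, Hun5/Hun6
southern). Per-region compositions are the solutions of exhaustive
composition inversion against the printed per-region RMPs: NW {24,10},
NM {23,18,1} (four compositions tie on sum-of-squares; the deterministic
lexicographic tie-break selects this one), NE {23,17,1}, SM {25,5,1},
SE {4,2,1}. SW's printed Hd (0.611) and RMP (0.617) are mutually
inconsistent; SW uses {19,13,5}, which matches the Hd. Because the printed
per-region table and the printed pooled inventory are jointly infeasible at
printed precision, `regional` and `global_192` are separate fixtures; a
`new_collection_138` fixture realises the 138 newly collected samples
(five regions, four haplotypes).

The inter-haplotype difference matrix is a fixture constant chosen to
reproduce every per-region segregating-site count (Hun1↔Hun2 differ at one
site, forced by NW's S=1 with k=2; Hun3/Hun4 one step off Hun2; Hun5/Hun6
on the remaining sites) — it is not a claim about the real sequences, which
is why the printed Fst/Gst and per-region π values are not acceptance
quantities. Sampling is by exact counts, never multinomial draws, so every
downstream statistic is non-stochastic; the seed affects only the random
reference bases and fragment placement. Consequently a green statistics
test establishes estimator correctness on the stated composition, not
robustness to sampling noise, sequencing error or alignment ambiguity —
none of which the generator emulates.

Known fixture limitation: no integer composition of n = 42 into 3 parts can
reproduce both the NM region's printed Hd (0.529) and RMP (0.484) — parity
forces the sum of squares to be even, and matching both would need 853.
The fixture reproduces the RMP; its NM Hd is 0.528.

## Numerical and degenerate-input choices

Composition inversion enumerates non-increasing positive integer partitions
exhaustively (feasible throughout the survey's range) and reports every
solution within tolerance with its exact residual, sorted (residual, then
lexicographic) — ties are visible, never hidden. `Hb = 0` defines Fst = 0;
identical monomorphic populations define Gst = 0 with a warning. Placement
uses the smallest offset on tied scores; the mappability threshold is a 10%
mismatch fraction over unambiguous compared positions. Byte-identical
outputs for a fixed seed and config are a tested contract.
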