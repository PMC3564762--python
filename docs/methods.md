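# Methods

## Scope and data model

`aqpmeta` analyses per-experiment probe-set × sample matrices of log2-scale
signals that were background-corrected and normalized upstream (GcRMA-style
output is assumed; normalization itself is out of scope).  All comparisons
are made strictly within an experiment — the meta-analysis draws strength
from compiling many within-experiment contrasts, never from cross-experiment
signal comparison, so no batch correction is attempted.

## Probe-set reannotation and EST assignment

Alignment execution is external; the contract starts at the standard
12-column tabular hit format.  Coordinates are 1-based inclusive and a
minus-strand hit is encoded by subject start > subject end.

* EST evidence filter: percent identity **strictly above 96** and alignment
  length **at least 100 bp**.  The mixed phrasing ("above" vs "at least") is
  resolved as strict/inclusive respectively and applied uniformly.
* Best-hit cascade (ESTs and probe sets alike): highest bit score → higher
  identity → longer alignment → lexicographically smaller subject id.  The
  final lexicographic step makes assignment a pure function of the hit set,
  invariant to input order.
* Ambiguity: a probe set is ambiguous when its best bit score is attained by
  more than one distinct gene.  This is the only parameter-free reading of
  "ambiguous assignment" and is therefore the implemented rule.
* Region class: a best hit overlapping any exon is exonic; a hit inside the
  gene span touching no exon is intronic (rejected); no overlapping gene
  model means an invalid target.
* Rejection reasons are logged in the fixed priority minus-strand →
  ambiguous → intronic → invalid-target; filtering is idempotent.

Genes with zero assigned ESTs are reported as explicit zero rows: absence
of expression evidence is a result, not missing data.

## Gene-level consolidation

Within an experiment, replicate samples are averaged per condition on the
log2 scale.  A gene's signal is the **maximum** over its valid probe sets.
The median alternative is retained as a diagnostic only: on a
multispecies-designed chip the median depends on how many of a gene's probe
sets match the hybridized species, so `median_max_divergence` flags
gene × condition cells where the max is present but at most half of the
probe sets are — the situation in which an automatic median consolidation
silently reports background.

Presence: a consolidated signal ≥ 3.2 log2 units is present; strictly below
is absent.  A gene with no valid probe set is "no data", which is reported
distinctly from absent throughout (an unsuitable array is not evidence of
non-expression).

Expression domains use control arrays only; the cell value is the maximal
consolidated signal over the control conditions of a tissue.  Because the
consolidation operator is the maximum, maximizing over conditions before or
after collapsing probe sets provably gives the same result; the median
diagnostic is order-sensitive, and is always computed per condition first.

Clustering uses Euclidean distance with complete linkage (the default of
the classical `hclust`-style agglomeration when only the distance is
specified).  Rows are sorted by label before linkage so the merge tree and
leaf order are invariant to input permutation; absent cells are imputed at
the cutoff (3.2) for the distance computation only.  A brute-force O(n³)
agglomeration oracle in the test suite verifies merge heights and nested
cluster composition.

## Regulation scoring

* Comparison inventory: treatment (or transgenic line) vs its control
  within the same experiment; in temporal series each later time point vs
  the initial one (t0/predawn).  The inventory is data-driven — the module
  reports its own comparison count rather than assuming any fixed number.
* Constrained log2 ratio: 0 when **both** condition means are below 3.2,
  otherwise the plain difference.  One-sided below-cutoff cases are genuine
  on/off switches and are computed.  The constrained value is numeric 0
  with direction "none" and still counts as a compared case.  The operation
  is antisymmetric by construction (property-tested).
* Gene-level ratio: the probe-set ratio of maximal absolute value, sign
  preserved; an exact |ratio| tie with opposite signs resolves toward the
  probe set with higher mean signal over the two conditions, then by id.
* Classes (FC = 2^|ratio|): none < 1.5 ≤ weak < 2 ≤ moderate < 4 ≤ strong;
  boundaries are left-closed, so FC exactly 1.5/2/4 falls in the higher
  class.  No p-values are involved anywhere: the procedure is a pure
  fold-change classification, stated explicitly so users do not read
  statistical control into the counts.
* Responsiveness codes per gene × (cue category, tissue): "-" when nothing
  is regulated, "x" when both directions occur, "C" when every comparison
  in the group is regulated in one direction, else the number of regulated
  comparisons.  "C" is allowed at group size 1 (a single regulated
  comparison is 100 % of cases); the column's comparison count is reported
  alongside so such cells are interpretable.

## Duplicate-pair profiling

Per pair and comparison: none / divergent-single / divergent-opposite /
convergent, the convergent case sub-classed weak vs strong by the **pair's
minimum FC** against 2 — a convergent event is only as strong as its weaker
member (the alternative, mean FC, was considered and rejected as it can
grade a weak+strong pair "strong").  Comparisons where either member has no
data are excluded from the denominator and counted separately, so
array-design gaps cannot masquerade as regulatory divergence.  Percentages
over the retained comparisons sum to 100.  The package reports percentages
only; what level of convergence constitutes "functional redundancy" is left
to interpretation.

## Sequence divergence (dN/dS and 4DTV)

Nei–Gojobori (1986) counting with Jukes–Cantor correction, the classical
method behind pairwise codon-level interfaces; the estimator is a named
choice behind one entry point so a transition/transversion-weighted variant
can be added without changing the data model.

* Sites: per codon position, the fraction of the three possible changes
  that are synonymous; a change to a stop codon counts as nonsynonymous.
  This convention keeps N + S = 3 × (codon count) exact.
* Differences: single-hit pairs classified directly; 2–3-hit pairs averaged
  with equal weights over all mutational pathways avoiding stop-codon
  intermediates (pathways through stops excluded, standard practice).
* Correction: d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 raises an explicit error.
  dS = 0 makes dN/dS undefined and it is reported as NA — never 0 or ∞.
* Gaps: any codon column containing a gap in either sequence is dropped.
* 4DTV: a site qualifies only when both codons are four-fold degenerate at
  the third position **and** the first two positions are identical across
  the sequences (the strict reading of a *shared* four-fold site); the
  statistic is the transversion fraction among qualifying sites, undefined
  when none qualify.
* The packaged divergence table's ratio column is recomputed as
  dN/dS from the printed dN and dS (3-decimal rounding).  19 of 24 rows
  agree with the printed ratio within 0.002; the remainder were evidently
  printed from unrounded estimates, so the summary range (min over all
  pairs, max over non-pseudogene pairs, 2 decimals) is the quantity checked
  rather than row-wise equality.

## Synthetic data

The generator emulates the structural features of the real collection that
the pipeline must be robust to, with these defaults:

| parameter | default | rationale |
|---|---|---|
| probe multiplicity | {1: 0.59, 2: 0.06, 3: 0.35} | reproduces a collection where ~94 probe sets cover ~53 genes with most genes one-to-one |
| n_species | 12 | probe sets designed across 12 source species |
| affinity offsets | −\|N(0, 1)\| log2 units, 0 for the design species | cross-species hybridization never gains efficiency |
| background | N(2.5, 0.2) per (probe set, experiment) | below the 3.2 cutoff |
| expressed baseline | uniform 8 ± 1.5 | above the cutoff |
| replicate noise | N(0, 0.1) additive on log2 | small but non-zero measurement noise |
| effect grid | {0, ±0.7, ±1.5, ±2.5} | one planted level inside each FC class |
| pair effect ρ | 1.0 | pair members copy effects (dial down to plant divergence) |

Matrix entries decompose **exactly** as baseline + planted effect +
affinity offset + noise; with noise 0 the decomposition is bit-exact and is
asserted in tests.  Pair members share their expressed-tissue set (recent
duplicates inherit the ancestral domain); their regulation diverges only
through the effect-correlation dial.  A single integer seed drives one root
RNG plus per-experiment sub-streams, making every output bit-reproducible.

What the generator does **not** emulate: probe-level (25-mer) intensities
and the normalization model itself, correlated noise across genes, batch
effects, and real cross-hybridization between homologous genes.  Passing
the recovery tests therefore shows the *rules* are implemented correctly
and are robust to the modelled biases — not that the thresholds are optimal
for any real chip.  The additive Gaussian-on-log2 noise is a stand-in: no
distributional form is claimed for real normalized arrays.

Codon fixtures draw base codons from four-fold degenerate families only and
place each planted substitution on its own codon: synonymous changes are
third-position transitions, 4DTV changes are third-position transversions
(which are also synonymous — total planted Sd = n_syn + n_4dtv), and
nonsynonymous changes are stop-avoiding first-position changes.  This keeps
every planted count unambiguous under the counting rules above, verified in
tests by an independent per-codon re-count.

EST reads are contiguous subsequences (≥ 100 nt) of their source gene with
a planted uniform mismatch rate; 2 % divergence survives the >96 % identity
filter, 5 % does not.

## Problem sizes

The test suite and the reproduction script run on synthetic collections of
200 genes × 4 experiments (≈ 360 probe sets, 12 comparisons) and on
exhaustive enumerations over all 3 721 sense-codon pairs; both complete in
seconds.  These sizes were chosen as the smallest at which every class of
the effect grid is populated densely enough for modal-recovery statements
to be stable across seeds.

## Known limitations

* The constrained-ratio rule zeroes only the both-below case; a gene
  hovering at the cutoff can flip between 0 and a small ratio with noise.
* "C" cells with a single comparison are weak evidence of consistency; the
  per-column counts must be consulted.
* The NG86 estimator assumes equal mutation rates across pathways and no
  transition/transversion bias; dN/dS from highly diverged pairs
  (p approaching 3/4) is not computable by design.
* Clustering determinism is achieved by label-sorted input, which resolves
  distance ties arbitrarily but reproducibly.
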