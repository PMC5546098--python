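# Methods

## Similarity and network construction

Fingerprints are sets of substructure-bit indices; which dictionary
produced them (PubChem-style 2D substructure keys, RDKit pattern bits, …)
is a loader concern, not an assumption of the analysis. Tanimoto similarity
is `|A∩B| / |A∪B|`, 1 for identical non-empty fingerprints, 0 for disjoint
ones; the degenerate case of two empty fingerprints is defined as 0 with a
warning. Similarity-graph edges use an **inclusive** threshold
(`T(i,j) ≥ t`, default `t = 0.65`); all `n(n−1)/2` pairs are compared with
vectorized bit-matrix algebra, which is comfortable at desk scale (a few
thousand chemicals).

K-core filtration (`networkx.k_core`) keeps the maximal subgraph of minimum
degree `k`. `k = 30` is the documented full-scale reproduction value; small
`k` (2–5) is appropriate for the few-hundred-chemical universes in the test
suite. Chemicals removed by the filtration are carried in an explicit
"Undefined" module so prevalence and information tables account for every
chemical.

Module detection is Louvain greedy modularity optimization
(`networkx.community.louvain_communities`) with edge similarities as
weights and resolution 1.0 (both exposed). The seed shuffles the node visit
order, making the algorithm's stochasticity explicit; module numbering is
by decreasing size with lexicographic tie-break, so label-switching across
runs is tamed but comparisons between partitions should still be
label-invariant (Rand index).

The force layout is a plain 2-D force simulation — 1/d repulsion between
charged nodes, linear spring attraction along edges scaled by similarity,
weak central gravity, per-step displacement capping, inertial blending and
an auto-stabilizing speed damper — honoring the conventional force-atlas
parameter names (inertia 0.1, repulsion 200, attraction 10, max
displacement 10, gravity 9000 ×10⁻⁴, speed 10, etc.). Coordinates exist for
GEXF export and visual QC only; no downstream statistic depends on them,
and only qualitative contracts (determinism given seed; springs pull
connected pairs closer) are tested.

## Structural alerts

The five mechanism alerts are implemented as a small SMARTS rulebase
(see `alerts.ALERT_SMARTS`): Michael acceptors as α,β-unsaturated
aldehyde/ketone/ester (and propiolate-type alkynes); Schiff-base formers as
aldehydes and 1,2-diketones; acylating agents as acyl halides, anhydrides,
sulfonyl halides and isocyanates; SNAr as aryl halides activated by an
ortho/para nitro group; SN2 as primary/secondary aliphatic halides,
sulfonate esters and epoxides. RD is recomputed as the OR of the five after
any load or generation. This rulebase is deliberately minimal: it is *not*
a reimplementation of any expert system's rules, and analyses accept
precomputed flags in the chemical CSV precisely so authoritative external
alert calls can be substituted. α,β-unsaturated alcohols (pro-Michael
acceptors after metabolic oxidation) are not flagged by default; an
optional `include_pro_ma` pattern covers them.

In the heuristic classifier, "alerts > 0" counts the five mechanism flags
only — RD is their OR and would always double-count.

## Entropy and information gain

Entropy uses log base 2, so `H ∈ [0, 1]` with 1 at an even
sensitizer/non-sensitizer split and 0 for a pure module (`0·log 0 := 0`).
Information gain of a boolean attribute is the parent entropy minus the
size-weighted child entropies; empty children contribute 0, and float dust
is clipped so `0 ≤ gain ≤ H` holds to 1e-9. Normalized gain is
`100·gain/H`, undefined (n/a) when `H = 0`. Unknown-label chemicals are
excluded from every entropy computation, so a module's labeled count can be
smaller than its size; tables report both.

The molecular-weight threshold search evaluates the gain of `MW < t` at
every midpoint between consecutive distinct sorted MWs and returns the
maximizer (ties toward the smallest threshold). An exhaustive scan is used
rather than a bisection-style search because the gain curve over thresholds
is generally not unimodal; the scan is `O(n²)` in the worst case but exact,
and instances here are small.

## Classifiers and evaluation

Heuristic: sensitizer iff `alerts > 0` and `MW < 500 Da`; the cutoff is
strict (`MW == 500` predicts non-sensitizer) and configurable. Threshold
KNN: neighbors are all *other* labeled chemicals with similarity at or
above T (inclusive by default; a strict rule is available in `KNNConfig`),
majority vote with ties to sensitizer, abstention when no neighbor exists.
Evaluation is leave-one-out — a chemical never votes for itself, since
self-inclusion would trivially inflate accuracy — and abstaining chemicals
are excluded from the confusion counts but reported. Unknown-label
chemicals may receive predictions but never enter counts. Sensitivity,
specificity, BAC and accuracy are n/a whenever their denominator is empty.

## Assay agreement

Per-chemical, per-type calls are the majority of conclusive outcomes; even
splits are ties. Off-diagonal cells compare the calls of two study types
over chemicals tested in both, *excluding* ties — forcing ties positive
would leak the KNN tie rule into an unrelated statistic. Diagonal cells
cover chemicals with ≥ 2 conclusive studies of the type and require **all**
repeats concordant (a majority-vs-majority rule is vacuous within one
type). Inconclusive outcomes never contribute. The animal-use estimate is a
straight per-year sum of user-supplied average animals per study type; no
default averages are shipped.

## Synthetic universe generator

The generator emulates the statistical features the analysis relies on,
not chemistry: fingerprints have no corresponding SMILES, and bits are
independent (an optional `nested_bits` mode adds implication chains
mimicking the counted, mutually redundant substructure keys of real
dictionaries).

* **Clusters.** Each of `n_clusters` (default 10) clusters has a prototype
  with each of `n_bits = 256` bits set at density 0.30. Members flip each
  bit independently at a rate calibrated (closed form
  `expected_within_similarity`, verified by simulation) so within-cluster
  Tanimoto averages 0.90. A `background_fraction` (default 0.10) of
  chemicals gets fresh random fingerprints. Note the expected similarity is
  *not* monotone in the flip rate all the way to 0.5 for sparse prototypes
  — flipping pushes effective density toward 0.5 and chance overlap grows
  again — so the calibration bisects only the decreasing branch.
* **Labels.** Cluster sensitizer prevalences are an even spread (span 0.20)
  centered on the global rate 0.21, the prevalence reported for industrial
  chemical universes; an explicit per-cluster list overrides (e.g.
  alternating 0.95/0.05 for "purity" regimes).
* **Fingerprint–label association.** `label_bits` (default 12) bits per
  cluster are set in sensitizers and cleared in non-sensitizers before
  noise. This encodes the premise of read-across — sensitizers carry
  reactive substructures, so close structural neighbors share labels — and
  gives the generator the scale structure real data show: same-label
  within-cluster similarity ≈ 0.90 versus ≈ 0.78 across labels. With
  `label_bits = 0` labels are independent of structure given the cluster.
* **Alerts.** Flags are drawn per label with class-conditional
  probabilities (defaults: MA 0.30/0.09, AA 0.18/0.066, SB 0.15/0.055,
  SN2 0.09/0.04, SNAr 0.012/0.005 for sensitizer/non-sensitizer), chosen so
  overall prevalences at 21% sensitizers land near the rates typical of an
  industrial universe (MA ≈ 13%, RD ≈ 30%). RD is recomputed as the OR.
* **Molecular weight.** Lognormal, median 250 Da, σ = 0.7 — a realistic
  span for registered industrial chemicals (roughly 60–1100 Da within ±2σ);
  an optional multiplicative factor shifts the sensitizer median.
* **Studies.** Each chemical gets `1 + Poisson(0.8)` studies (LLNA 40%,
  GPMT 30%, Buehler 20%, patch test 10%), Klimisch scores mostly ≤ 2, years
  1975–2014. Outcomes flip away from the true label with probability 0.05
  per study and are inconclusive with probability 0.02.

What passing tests on this generator do **not** show: robustness to
correlated fingerprint bits, to activity cliffs (the generator has none —
labels vary smoothly with structure at the label-bit scale), to size bias
(larger molecules having more bits and hence more neighbors), or to the
heterogeneous reliability of real study records. Results on generated
universes validate the machinery and its qualitative behavior, not
real-data performance figures.

## Problem sizes and numerical choices

The test suite runs universes of 300–2000 chemicals (500 for cluster
recovery, 2000 for agreement closed-form checks, 800–1000 for threshold
sweeps), sizes at which every statistic under test is already
well-concentrated; the full suite completes in well under a minute.
Stochastic tests fix seeds and use three-sigma binomial bands or the
explicit tolerances stated in their assertions. The closed-form agreement
check restricts to chemicals with exactly two studies of a type because
`(1−f)² + f²` is the two-draw formula; chemicals with k repeats concord
with probability `(1−f)^k + f^k`.

Known limitations: no potency (EC3) modeling; no metabolic or 3-D
similarity; the SMARTS rulebase is intentionally small and will disagree
with full expert systems on edge cases (precomputed flags are first-class
input for exactly this reason); Louvain results depend on the seed on
degenerate near-tie graphs; the exact module numbering of any particular
full-scale map is not reproducible — only label-invariant structure is.
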