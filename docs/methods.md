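# Methods

`coevnet` detects coevolving amino-acid site pairs in deep protein families,
attaches phylogenetic bootstrap support to them, organizes the survivors into
networks, tests whether clade-specific groups of coevolving sites are
statistically independent, and scores the spatial clustering and
secondary-structure composition of site groups on a reference structure.  The
design target is the bacterial chaperonin system (GroES/GroEL, cpn10/cpn60),
but nothing in the machinery is specific to it.

## The covariation statistic

For one alignment column *i* and every unordered sequence pair (*s*, *t*)
with both residues ungapped, the transition score is the BLOSUM62 value
B(a<sub>s</sub>, a<sub>t</sub>) of the residue exchange.  Scores are centered
at the column mean and divided by the divergence time of the two sequences:

    v_i(s,t) = ( B(a_s, a_t) − mean_B(i) ) / t(s,t)

Two columns coevolve when their score vectors are strongly positively
correlated (Pearson, over jointly ungapped pairs; one-tailed — compensatory
covariation predicts positive correlation).  Negative correlations are
reported but never flagged.

Divergence times t(s,t) come in three modes:

- `li_ks` — Li-type (LWL85) synonymous distances from a matched in-frame CDS
  alignment (codons gapped or ambiguous in either sequence dropped pairwise;
  saturated estimates flagged and replaced by the matrix maximum);
- `patristic` — path length on a supplied or neighbor-joining tree;
- `poisson_protein` — −ln(1 − p) on pairwise amino-acid p-distances.

Times below a floor ε (default 1e-4) are raised to ε before division, since
deduplicated alignments can still contain pairs of zero measured divergence.
Multiplying all times by a positive constant rescales every score vector
uniformly and leaves all correlations unchanged.

## The empirical null and its tie structure

Significance is judged against correlations of the same statistic computed on
neutrally evolving alignments simulated on the same tree (stationary residue
frequencies estimated from the data, Laplace-smoothed), with the same
divergence times.  Column pairs are drawn from the simulated alignments until
the configured null sample size (default 100,000) is pooled; a pair is
significant when its upper-tail exceedance probability is below α (default
0.001).

Two empirical facts about this statistic at realistic tree depths drive the
implementation:

1. **Compression.**  The shared 1/t weighting gives every pair of columns a
   common dominant component (close sequence pairs are almost always
   identical at both columns, contributing large positive entries to both
   vectors), so the null correlations concentrate extremely close to 1.
   Rank-based inference is unaffected — data and null share the compression —
   but point values of r near 1 carry no intrinsic meaning.
2. **An atom of exact ties at r = 1.**  Any two columns whose substitution
   pattern is a single binary partition of the sequences (one substitution
   event each, on the same branch) have centered score vectors that are
   exactly proportional, hence r = 1.0 exactly.  The probability mass of this
   atom depends on the tree and can exceed α.

Because of the atom, the textbook add-one estimator p = (k+1)/(n+1) (k =
null values ≥ r) can be incapable of rejecting at small α: every tied pair
inherits the whole atom's mass.  Detection therefore uses the exact
randomized tie-breaking form

    p = ( #{null > r} + U · (#{null = r} + 1) ) / (n + 1),   U ~ Uniform(0,1)

which is uniformly distributed under exchangeability even in the presence of
atoms.  The U draws are seeded (the detection functions take a `seed`), so
runs are reproducible; the conservative add-one form remains available.
Correlations for data pairs, null pairs and bootstrap replicates all go
through the same numerical routine so that exact ties compare exactly.

The number of simulated alignments matters beyond the pooled sample size:
tie-atom mass is estimated much better from many alignments than from few
(the atom's realizations are bursty within one alignment).  The pipeline
default is 40 simulated alignments.

## Phylogenetic pair bootstrap

Each replicate samples ⌈0.8·n⌉ sequences uniformly **without** replacement
(with replacement would create zero-divergence duplicates the statistic
cannot use), prunes the tree to the sample (leaf-to-leaf path lengths are
preserved, so the divergence-time submatrix is reused), rebuilds the null at
reduced effort, and re-tests each originally detected column pair at the same
α.  Support is the fraction of replicates in which the pair is re-detected;
pairs with support strictly above 0.70 are retained.  Replicate seeds derive
from the master seed plus the replicate index, so replicates are independent
and aggregation is order-insensitive.  A replicate whose detection fails
outright counts as a non-detection for every pair.

On synthetic data this filter behaves as intended: perfectly coupled planted
pairs reach support ≈ 0.8–1.0 while chance detections on neutral data sit
near 0.4–0.7 and are dropped.

## Networks

Nodes are sites, edges are retained pairs (bootstrap support kept as edge
metadata; shortest paths are hop-based).  Degree is a raw edge count;
closeness is component-normalized inverse farness, (n_c − 1)/Σd; betweenness
is the unnormalized shortest-path pass-through sum over unordered pairs.  A
globally normalized closeness column is emitted alongside, since published
figures rarely state their normalization.  All three measures are verified
against exhaustive shortest-path enumeration on every connected graph with at
most six nodes.

## Sector entropies and the independence test

Site conservation is a two-outcome relative entropy: with f the frequency of
the column's modal residue (among ungapped rows) and q the background
frequency of that amino acid across the whole alignment,

    D_i = f ln(f/q) + (1−f) ln((1−f)/(1−q)),   0·ln 0 ≡ 0.

For a site group S the joint form uses f_S = the fraction of sequences
carrying the modal residue at **every** site of S simultaneously, against the
product background q_S = Π q_i — the independence expectation of the joint
modal pattern.  (The printed form of the group entropy leaves the multi-site
background ambiguous; the product reading makes the group form reduce
*exactly* to the per-site form for singletons, which the implementation
asserts.)  Sequences gapped at any site of S are dropped from f_S's
denominator.  The correlation entropy is I_S = D_S − Σ D_i; covariation
raises it, and singleton groups have I_S = 0 identically.

Two groups g1, g2 from the same protein domain are compared through
θ = I<sub>g1∪g2</sub> − (I<sub>g1</sub> + I<sub>g2</sub>).  The null draws
`n_random` (default 1000) pairs of disjoint random site sets of the same
sizes from the domain's site pool; the verdict is a two-sided z test of
θ_obs against the null mean and standard deviation ("independent" when
p ≥ 0.05).  Null sizes are drawn in sorted order so the test is symmetric
under swapping g1 and g2.  Backgrounds are computed once from the combined
alignment of the clades under comparison, putting both groups on a common
reference.  GroEL domain ranges (apical/intermediate/equatorial) are user
configuration, not code.

## Structure statistics

The distance between two residues is the minimum over all carbon–carbon atom
pairs ("proximal carbons"; a Cα-only flag exists for sensitivity analysis).
"Proximal" means strictly below 4 Å.  Group compactness is the mean pairwise
minimum-carbon distance; its significance is the add-one fraction of random
equal-size residue sets from a candidate pool at least as compact.
Secondary-structure enrichment is a plain χ² of observed versus
composition-expected counts over {helix, strand, coil} (PDB HELIX/SHEET
records assign the first two classes; everything else is coil); classes with
zero expectation are dropped with the degrees of freedom reduced, and a
single-class chain is an error rather than a χ² with df 0.

## Synthetic data

The generator supplies the null model and the test substrate:

- **Trees** — pure-birth with the requested number of leaves, rescaled to a
  mean root-to-tip depth (default 0.3 substitutions/site; 0.5 in the power
  analyses, where deeper trees give columns enough states to resolve
  coupling).
- **Alignments** — sites evolve independently down the tree; substitution
  events arrive as a Poisson process at rate 1 per unit branch length and
  draw the new state from configurable stationary frequencies (uniform by
  default).  The default profile (30 taxa, depth 0.3, 200 columns) yields
  mean pairwise amino-acid divergence around 0.26–0.33, the regime of deep
  bacterial protein families.
- **Planted pairs** — an event at one site of a planted pair is mirrored at
  the partner with probability ρ, forcing the partner into the state paired
  with the new state under a fixed bijection.  The default pairing is the
  identity, so ρ = 1 produces literally duplicated columns with identical
  transition-score vectors (r = 1 exactly); a seeded random permutation
  pairing is available, but note that a non-identity pairing does not
  preserve BLOSUM scores, so even ρ = 1 pairs are then not guaranteed
  detectable.  ρ = 0 reduces to independent evolution.
- **CDS** — reverse translation with per-column reference codons and a
  configurable synonymous switch probability; translate(emit_cds(a)) == a.
- **Structures** — toy single-chain models: background residues uniform in a
  ball sized so the mean pairwise distance matches a target spread (default
  40 Å); designated groups packed so all pairwise carbon distances stay below
  a cluster radius (default 4 Å); HELIX/SHEET ranges configurable.  These
  emulate the distance scales of a chaperonin subunit, not real geometry.

What the synthetic substrate does **not** emulate: indels (gaps enter only
through user data), across-site rate heterogeneity, biochemically realistic
exchange matrices, and real protein geometry.  Green tests therefore
demonstrate statistical correctness of the machinery under the declared
model, not biological performance on real alignments.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script run the detector at 30 taxa
× 200 columns with 100,000-sample nulls pooled from 40 simulated alignments,
20 replicates per condition, 100–1000 bootstrap replicates, and 200-replicate
independence nulls — sizes chosen so the full suite completes in a few
minutes on one core while keeping Monte-Carlo error well inside the asserted
bands.  Other conventions: alignment columns and structure residues are
1-based; intervals are closed; NJ ties break on the smallest index pair
(dendropy's deterministic order) and negative NJ branch lengths clamp to 0;
PDB altLoc handling follows Bio.PDB (highest occupancy, first on ties);
tables are written sorted so identical runs are byte-identical.

## Known limitations

- With the add-one (non-randomized) estimator the detector can be strictly
  conservative at small α on shallow trees; randomized tie-breaking is the
  default for exactly this reason.
- The compressed correlation scale means r values are only meaningful
  relative to the null sample, never as absolute effect sizes.
- Li-type synonymous distances saturate quickly for deep divergences; the
  patristic and Poisson modes are the practical defaults at chaperonin-scale
  depths.
- The independence test assumes an approximately normal null for θ; with
  very small domain pools the normal approximation (and the disjointness
  requirement) can fail, which surfaces as explicit errors rather than
  silent results.
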