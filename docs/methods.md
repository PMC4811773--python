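# Methods

This note documents the models implemented in `arbortwig`, the choices
made where a design was genuinely open, and what the synthetic test bed
does and does not establish about real reconstructions.

## Data model and units

A skeleton is a single rooted tree: every node has at most one parent,
exactly one node has none, and parent links are validated to be acyclic
and connected at construction.  All coordinates and raw edge lengths are
kept in nanometres; every reported length is in micrometres.  The SWC
`type` column is preserved on read and ignored by all analyses —
biological compartment identity comes exclusively from node tags
(`'soma'`, `'microtubules end'`, `'mitochondrion'`, review tags), which
is how proofreading annotations are actually expressed.  Before any
analysis a skeleton is re-rooted at its `'soma'`-tagged node when one
exists, so "proximal" and "distal" have their anatomical meaning.
Connector positions are metadata only; every distance in the package is
measured node-to-node along the cable, never through space, because
points close in 3-D can be arbitrarily far apart along the arbor.

Virtual (interpolated) nodes of the annotation front-end are not
modeled; skeletons are taken as materialized.  Timestamps are seconds
since epoch, and activity bins are half-open `[k·bin, (k+1)·bin)`:
reconstruction time uses 20 s bins over node and connector creation
events, review time 60 s bins per contributor, summed.

## Backbone/twig decomposition

A `'microtubules end'` tag marks the last microtubule-containing node of
a branch.  Each tag that is not itself inside another tag's distal
subtree spawns exactly one twig: the strictly distal subtree, even when
internally branched.  The tagged base node remains backbone; the edge
from the base to the first member counts as twig cable because that
cable is already microtubule-free.  Tags nested inside a twig are
ignored; a tag at a leaf produces no twig; a tag at the root is an
error, since the whole arbor would become twig.

Twig *depth* is cable distance from the base, not Euclidean distance.
A twig is spine-like when its maximal depth is under 3 µm **and** it
carries no presynaptic site; "carries no presynaptic site" is the
operationalization chosen for "not a presynaptic varicosity", since no
numeric rule exists for varicosity.  Both the 3 µm spine threshold and
the 3 µm landmark-proximity threshold are overridable defaults.

Twig cropping retains backbone synapses always and twig synapses up to a
given cable depth from their base; depth 0 therefore reproduces a
backbone-only reconstruction, the natural lower envelope of an
iterative mapping strategy.

## Synapse flow centrality and the split

For inputs (postsynaptic relations) and outputs (presynaptic relations)
on one arbor, with `I(v)`, `O(v)` the counts inside the subtree of `v`:

    centrifugal(v) = (I − I(v)) · O(v)
    centripetal(v) = I(v) · (O − O(v))

Pairs whose connecting path merely turns at `v` (both endpoints inside,
in different child subtrees) count in neither flavor.  A synapse sitting
exactly at `v` counts as inside `subtree(v)`; the brute-force oracle in
the tests uses the same convention, so the equivalence check is over the
convention, not an accident of it.  Input multiplicity: each
postsynaptic relation counts once, and each presynaptic connector counts
once (not once per target) for flow; the density estimator, by
contrast, weights presynaptic sites by their number of postsynaptic
partners.  Both conventions are arguments, not constants.

The split node is the node with maximal centrifugal flow, choosing the
maximizer closest to the root by cable (then smallest id).  The axon is
its subtree; the linker cable is the cable over all maximizers.  The
segregation index of the resulting two compartments is attached as a
post-hoc success check, and `H < 0.05` raises an "unsegregated arbor"
warning — such arbors are anatomically dendrite-like throughout, and a
two-way split of them is not meaningful.

Entropies use natural logarithms with `0·log 0 ≡ 0`; `H` is invariant to
the log base.  `H` is undefined (an error, not a NaN) when the whole
arbor carries only inputs or only outputs.

## Synapse clustering

Density at node `i` is `d(i) = Σ_j exp(−δ²_ij / 2λ²)` over the synapse
multiset (geodesic δ, per-target presynaptic multiplicity).  Basins are
found by discrete gradient ascent to the neighbor with the largest
positive density difference; ties break toward the root, then the
smaller node id.  On an exact plateau (density difference below 1e-12
relative) the walk continues root-ward, so a flat maximum — which arises
in perfectly symmetric synthetic arbors — drains to one deterministic
terminus instead of fragmenting into cosmetic duplicate clusters.  Real
densities essentially never tie exactly; the rule only pins down the
degenerate case.

The default bandwidth is λ = 10 µm: for first-instar-larva-scale arbors
(hundreds to ~2000 µm of cable) bandwidths of roughly 8–30 µm separate
"dendritic arbor" from "axon", with smaller values giving more granular
subtrees.  The condensed cluster graph joins two clusters when the
skeleton path between their density peaks crosses no third peak.

## Wiring diagrams

Edge weight counts postsynaptic relations, not connectors: a polyadic
connector contacting the same target twice contributes two synapses,
because the two contacts are anatomically independent.  (The
alternative—counting connectors—is a documented flag at the call sites
that consume relations.)  Autapses are kept but flagged; they virtually
always indicate reconstruction errors and are surfaced by the linter.
Ranked-input curves fit ρ in `1 − exp(−r/ρ)` by unweighted least squares
over all ranks; nothing more elaborate is warranted for a two-parameter
summary of a monotone curve.  The "main branch" used by the morphology
summary is the longest root-to-leaf cable path.  Path search enumerates
simple directed paths of bounded hop count over edges at or above a
synapse threshold.

## Error models

**Edge omission.**  With twig recall `q` and the empirical twig-span
distribution `p(n_b; m)` of edges with `m` synapses,
`P_loss(m) = Σ_{n_b≥1} p(n_b; m)(1−q)^{n_b}`.  Edges touching backbone
(`n_b = 0`) are immune: backbone reconstruction is not subject to twig
omission.  A vectorized Monte-Carlo twin (`simulate_edge_omission`)
deletes twigs independently per trial and is checked against the
analytic sum within binomial error.

**False edges.**  `m = r·L_t·k̄` spurious synapses per neuron (rate of
false branches per µm of twig cable × twig cable × synapses per false
branch), rounded to the nearest integer, are thrown uniformly over `N`
candidate axons for each of two homologous neurons; the model reports
the probability that some truly unconnected axon (of `N_0`) reaches
`k ≥ k_θ` synapses on both.  The threshold is inclusive (`≥`); a strict
variant is a flag.  An exhaustive enumerator over all `N^m` assignment
pairs (feasible for `N ≤ 6`, `m ≤ 4`) serves as the independent check of
the Monte-Carlo estimator.

**Matching and consensus.**  Independent reconstructions of one neuron
are resampled so adjacent nodes are ≤ 80 nm apart and matched with a
600 nm radius — tight enough to separate branches, loose enough that
low-order branch points in correct reconstructions remain consistent.
Consensus chunks need support from at least half the reconstructions
(rounded up); the full vote-posterior machinery of consensus-skeleton
methods is out of scope, and majority support is the minimal sensible
stand-in.  Synapses are identified across reconstructions by equal
polarity and connector positions within the match radius (first-come
grouping in deterministic position order); a consensus synapse weighs
`(annotating reconstructions) / (reconstructions supporting the chunk)`,
so unanimous annotation weighs 1.

**Gold-standard comparison.**  Gold-only connected components are missed
branches, test-only components are false continuations; each is reported
with cable, postsynaptic count and branch points, and attributed to twig
or backbone by the gold compartment at its attachment point.  A gold
twig counts as recovered when its deepest member is matched: missing the
tip means the twig is absent or incomplete.  Note a resolution limit
inherited from the match radius: structure closer than 600 nm to
retained cable cannot register as missing, so sub-micrometre twigs are
invisible to this accounting; validation fixtures therefore use twigs
that extend beyond the radius.

**Error spatial clustering.**  Observed nearest-error geodesic distances
are compared (two-sample Kolmogorov–Smirnov) against repeated same-size
draws from twig nodes, at most one node per twig; the count of
significant draws calibrates whether errors cluster more than uniform
placement explains.

## Synthetic generators

`generate_neuron` emulates the empirical regularities of first-instar
larval arbors: a branching backbone (default 150 µm), twigs at a
configurable rate with exponentially distributed depth (median 1 µm,
truncated at 16 µm — the largest typical twig), ~80% of postsynaptic
sites on twigs, ~90% of presynaptic sites on or near backbone, and
mitochondrion tags at ~97% of presynaptic sites.  Twig bases are short
tagged stubs whose distal subtree is exactly the planted twig, so the
decomposition is recoverable to numerical precision.  Synaptic partners
are single-node placeholder skeletons, one per connector, as in
placeholder-seeded reconstruction.  `generate_textbook_neuron` plants a
fully polarized arbor with a known split node and exactly 10 µm of
maximal-centrifugal linker cable.  `generate_circuit` realizes planted
`(m, n_b)` edges exactly (each spanned twig gets at least one synapse;
`n_b = 0` edges land on backbone).  `corrupt_reconstruction` deletes
each twig with probability `1 − q`, truncates surviving twigs with a
configurable probability, and grafts false branches at a per-µm rate
with Poisson-distributed spurious inputs — node ids and positions of
retained structure are unchanged, so scoring the corruption against its
gold recovers the planted error regime.  All generators are pure
functions of `(params, seed)`.

What the generators do **not** emulate: real EM image noise, section
loss, annotator-specific biases, correlated errors along a neurite,
tortuous neurite paths (synthetic segments are straight between jitter
steps), or realistic spatial packing of neuropil.  Passing
parameter-recovery tests on this test bed shows the *accounting and
estimators* are correct, not that real reconstructions meet any
particular error rate.

Homolog pairs are mirrored across the midline and deformed by a smooth
random displacement field (three low-frequency sinusoids of amplitude
equal to the jitter), so nearby nodes move together and cable length is
nearly preserved — per-node independent noise would inflate cable at
this node spacing.

## Problem sizes and numerical notes

The test suite and the reproduction script run on synthetic arbors of
roughly 150–300 µm of cable (≈1000–3000 nodes), circuits of up to 16
neurons, Monte-Carlo runs of 10⁴–10⁵ trials, and 100-tree oracle sweeps;
these sizes were chosen so every statistical check has adequate power
while the whole suite completes in a couple of minutes.  Resampling
preserves total cable to better than 1e-6 relative error by
construction (equal collinear subdivision).  Review sequences break
path-length ties by smallest leaf id; all stochastic functions take
explicit seeds and are reproducible bit-for-bit.

## Known limitations

- The omission and false-edge models treat twigs as independent; real
  errors can be correlated (e.g. a section artifact hitting many
  neighboring twigs at once).
- Consensus chunk support uses simple majority; with two
  reconstructions every self-supported node qualifies, so two-way
  comparison derives its signal entirely from the match radius.
- `compare_to_gold` attributes an error to twig or backbone via the
  nearest gold node at the attachment point, which can misattribute
  errors exactly at a twig base.
- The segregation index treats clusters as given; it does not correct
  for cluster count or size imbalance beyond the synapse-count
  weighting.
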