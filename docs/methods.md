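# Methods

## Surface areas and buried interfaces

Solvent-accessible surface area uses the Shrake–Rupley construction: each
heavy atom is expanded by the probe radius (default 1.4 Å) and sampled
with a deterministic golden-section lattice (default 960 points/atom); a
point is accessible when it lies outside every neighbouring expanded
sphere. The lattice is fixed, so results are bit-reproducible for a given
point count. Van der Waals radii come from a fixed element table
(C 1.70, N 1.55, O 1.52, S 1.80 Å); hydrogens are ignored, matching
heavy-atom SASA practice. Exactly coincident equal-radius atoms are
tolerated: the first occludes the second rather than double-counting.
Convergence on bead fixtures is < 0.5% between 960 and 3840 points, and
per-residue values agree with biotite's independent implementation within
2%. Discretisation does mean that the two sides of an exactly symmetric
dimer can differ by a few percent at 960 points (≈0.8% at 3840); tests
account for this.

A pairwise interface between chains *a* and *b* is the per-residue ASA
difference of each chain between isolation and the presence of the
*partner chain only*. This pure-pairwise context (rather than burial
against the full complex) is the default because the assembly-order
predictor assumes pairwise additivity of interfaces; the full-complex
context is available via a flag. Per-residue differences below 10⁻⁶ Å²
are treated as numerical noise. An interface's size is the mean of its
two buried sides; per-side totals are exposed wherever the analysis is
per-subunit (first/last comparisons use the subunit's own side).
Interfaces at or below 400 Å² are excluded as not biologically
significant; the 800 Å² threshold is used only for the multi-interface
inclusion rule (a chain must bury > 800 Å² with ≥ 2 distinct partners).
Both are configuration keys.

Relative accessibility normalises residue ASA by a published theoretical
maximum per amino acid (Tien et al. 2013); a residue is "surface" when
rASA strictly exceeds 0.25. The non-interacting-surface composition
(NIS apolar/charged percentages) is computed over surface residues of the
chain in its complexed context, with the threshold configurable because
the convention is not fixed in the field. Residue chemistry: apolar
{A,F,G,I,L,V,M,P,Y}, charged {D,E,K,R} (His polar), polar the remainder;
whole residues are classified, boundary residues are not split by atom.

## Midpoints, first/last interfaces, and derived metrics

The interface midpoint is the smallest position whose N→C cumulative
per-residue BSA reaches half the side total (so a single-residue
interface is its own midpoint), and is invariant to uniform scaling of
the per-residue areas. Relative interface location is (i−1)/(L−1); the
N-terminal half is relative location ≤ 0.5, assigning the boundary to the
earlier-synthesised half. L is taken from a full-length sequence table
when supplied, else from the maximum observed residue number; the source
is recorded per chain, since structures may be incomplete.

For a subunit with ≥ 2 retained interfaces, the first translated
interface minimises the most-N-terminal interface residue and the last
maximises the most-C-terminal one, treating the termini symmetrically.
Ties on the extreme residue go to the larger interface; subunits whose
interfaces fully nest (first = last) are excluded from first/last
analyses, as no ordering is defined. Derived metrics follow the stated
formulas: translational distance (f_last − f_first)/L over the
interfaces' first residues, and the size difference normalised by the
area sum, an antisymmetric quantity in [−1, 1].

## Assembly order

Assembly pathways are predicted by greedy agglomeration under interface
additivity: starting from monomers, each step merges the two components
whose union gains the largest summed pairwise BSA. Ties break by the
lexicographically smallest chain-id pair, making the pathway
deterministic; on random ≤ 5-subunit complexes the greedy result matches
exhaustive enumeration of maximal-gain merge sequences. An interface
forms at the step where its chains first co-occur in a component, so one
step can gain several interfaces, which then share that step's
normalised order (s−1)/(S−1); a single-step pathway has order 0 by
convention. Steps with order ≤ 0.5 are "early". Sub-threshold interfaces
contribute gained area but are not emitted as ordered interfaces (flag).
Disconnected interface graphs are agglomerated per connected component;
merging stops when no pair gains area.

## Onset mapping

Raw assembly-onset positions are shifted N-terminally by 30 residues for
the ribosome exit tunnel and clamped at position 1 (the convention for
onsets ≤ 30, where the nascent chain has barely left the tunnel). The
adjusted onset maps to the nearest interface midpoint in the linear
sequence - compressing each interface to one residue avoids biasing the
mapping towards large interfaces with many residues. Nearest-homomeric
mappings are discarded (homomeric interfaces are assumed hierarchically
dominant and cis-assembling); equidistant midpoints resolve to the more
N-terminal, earlier-translated interface. Onsets beyond the protein's
length (annotation mismatches) are logged and skipped. Mapping recovery
is reported conditional on the designated interface passing the area
cutoff, so the number measures the mapping itself rather than cutoff
censoring.

## Inference layer

Interface areas are right-skewed and left-bounded by the area cutoff, so
comparisons are nonparametric. Rank-sum tests use exact enumeration for
n ≤ 12 without ties, otherwise the tie-corrected continuity-corrected
normal approximation; signed-rank tests are one-tailed by default, drop
zero differences before ranking (recorded in the result), and are exact
for n ≤ 20 without ties. Effect sizes are r = |Z|/√n with Z the normal
quantile of the p value; |Z| is used because only magnitudes are
reported, and n is an explicit parameter because the appropriate sample
size depends on the comparison design. Dunn's test uses pooled-rank z
statistics with tie correction and Holm–Bonferroni step-down adjustment.
Fisher's exact test reports the sample odds ratio (a·d)/(b·c) alongside
the relative risk; the tail is selectable, with a two-sided default.

The stratified bootstrap resamples subunits with replacement within
strata (age class or operon membership), B = 10⁴ by default; the point
estimate is the pooled mean first-minus-last difference, and the
probability of a non-positive difference carries the add-one
finite-sampling correction p = (1 + #{estimates ≤ 0})/(B + 1), flooring p
at 1/(B+1). Under a null cohort the bootstrap p is approximately uniform
(KS distance ≈ 0.04 over 500 replications at B = 500). Binomial
proportions carry Jeffreys intervals, the Beta(x+½, n−x+½) central
quantiles at 68% by default, with lower = 0 at x = 0 and upper = 1 at
x = n. Isoelectric points interpolate pH~charge curves linearly at
charge 0; fragmented proteins average fragment pIs. The contact-based
affinity model is linear in contact-class counts and NIS terms with
user-supplied coefficients only - no trained weights ship with the
package.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated.

**Bead complexes.** One 3.0 Å sphere per residue; each planned interface
is realised as two parallel bead rows 6 Å apart (within occlusion reach
for a 1.4 Å probe), blocks of different interfaces 150 Å apart, and all
non-interface residues on a distant sparse grid. Buried area scales with
window length, so planned size ranks are realised geometrically. This
makes analytic oracles tractable and ground truth exact; it deliberately
omits realistic protein geometry, secondary structure, side-chain
packing and crystallographic artefacts - passing tests demonstrate the
correctness of the computations, not robustness to real-structure noise.

**Cohorts.** Per-subunit first/last areas follow a paired log-normal
model: a shared subunit-level size factor (log-mean log 1000 ≈ 6.9,
log-sd 0.7, matching the right-skewed ~10²–10⁴ Å² range of real
interfaces) plus an interface-level residual (log-sd 0.25, reflecting
that interfaces of one subunit share a size scale), with the first
interface inflated by δ (default 1.15, the observed ~15% first/last
excess). Under these defaults the first interface is larger in ~65% of
subunits and a 150-subunit cohort is detected by the one-tailed
signed-rank test in ≥ 90% of seeds, while δ = 1 cohorts reject at the
nominal 5%. Cotranslational flags follow a logistic link on log first
area; onsets sit at the designated interface midpoint plus the tunnel
offset plus Gaussian noise (default σ = 5 residues); age and operon
labels are drawn at fixed fractions, with optional per-stratum δ for the
stratified analyses. Interfaces occupy disjoint sequence windows spread
evenly over chains of 300–600 residues, so midpoints are ≥ 100 residues
apart. Every generator takes an explicit seed and no global random state
is used.

## Problem sizes and numerical choices

Default point count 960 balances < 1% analytic error against cost;
oracle comparisons in tests use 240 points where only self-consistency is
measured. Validation simulations use 100 seeds for power, 2000 for
type-I calibration, and 500 replications at B = 500 for bootstrap
uniformity - sizes at which binomial/KS noise is well below the margins
being asserted. Degenerate inputs fail loudly: empty atom lists,
all-zero paired differences, constant correlation input, curves without a
zero crossing and missing affinity coefficients raise errors rather than
returning placeholders.

## Known limitations

Bead fixtures cannot detect errors specific to all-atom chemistry (e.g.
element-dependent radii interacting with packing). The greedy assembly
predictor commits to stepwise-maximal gain; non-greedy optima of other
pathway tools are out of scope, as are geometric interaction typing
(hydrogen bonds, pi-stacking, salt bridges), symmetry detection,
continuum-electrostatics titration, and ribosome-profiling raw-data
processing - symmetry labels, onsets and charge curves are inputs.
mmCIF parsing is not feature-complete; structures are read as Brookhaven
PDB (model 1, first altloc, heteroatoms excluded, common nonstandard
residues mapped to canonical equivalents).
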