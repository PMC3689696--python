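# Methods

## The analysis problem

A yeast genome carries its rRNA operon in a tandem chromosomal array whose
repeats are normally kept sequence-identical by concerted evolution (gene
conversion, unequal crossover). When homogenisation is inefficient, a single
strain yields many distinct D1/D2 sequences, database "consensus" entries
accumulate IUPAC ambiguity codes, and barcoding-style species assignment
breaks down. This package quantifies that heterogeneity from cloned repeat
sequences and asks three questions: where is the variation (variable-site
profile, variable regions), why is it tolerated (hairpin stem context,
wobble and compensatory pairing), and how did it arise (distance trees,
bootstrap, and the Phi recombination test).

## Coordinates

All positions are 1-based amplicon coordinates: position 1 is the first base
behind the 3' end of the forward amplification primer (NL1 for the D1/D2
amplicon). An `Alignment` carries an `offset` so trimmed alignments keep
reporting original positions. T and U denote the same state everywhere;
input spelling is preserved, comparisons canonicalise U→T. `.` gaps are
normalised to `-`.

## Variable-site profiling and the substitution spectrum

A column is a variable site when at least one strain group shows ≥2 states
(gap included) in it; columns that differ only *between* groups (fixed
differences) are not sites of intragenomic heterogeneity and are omitted.
Pooled state sets classify a site as dimorphic (two bases, no gap) or
multistate (≥3 bases), with indel involvement an orthogonal flag.

Spectrum percentages are **per site, not per inferred event**: a site enters
the transition/transversion denominator when its gap-stripped state set for
the group has exactly two bases ({A,G}/{C,T} → transition, otherwise
transversion); sites with ≥3 bases are excluded as multistate. The T-C share
is computed among transition sites. Reported percentages are rounded to the
nearest integer (half away from zero); exact rationals are kept alongside.
On the bundled catalog this rule gives 19/24 = 79% and 23/28 = 82%
transitions and 14/19 = 74% and 15/23 = 65% T-C shares for the two strains —
the gap-stripped rule (under which an A/T/− site counts as a transversion
and a T/− site drops out) is the one that reproduces all four published
values simultaneously, which is why it is the package's counting convention.

Variable regions are maximal runs of variable positions with inter-site
spacing ≤ `max_gap` (default 5) and at least `min_sites` (default 3)
members. The canonical reporting windows VR1 = 154–172 and VR2 = 432–452
(9 and 16 sites on the catalog) are fixed; detected runs are supplementary
output. Site 103 is deliberately outside VR1: it sits apart on the 5' stem
strand, paired with 159.

Ambiguity reconciliation: an IUPAC symbol in a database consensus is
`consistent` when the states observed in that strain's clones are a subset
of the symbol's expansion and at least two states alternate;
`uninformative` when the clones do not vary there; `inconsistent`
otherwise. Single-clone outlier states (e.g. at 159 and 432, possibly
sequencing errors) are not filtered by default.

## Secondary structure

The analyses depend only on stem/loop topology, so folding is weighted
base-pair maximization (Nussinov-style dynamic programming) with pair
scores GC=3, AU=2, GU=1, minimum hairpin loop 3, and a fixed traceback
preference (pair the interval ends, else leave the right end unpaired, else
the smallest optimal bifurcation) that makes results deterministic. External
thermodynamic predictions can be imported as dot-bracket strings and used
interchangeably; folding is applied to extracted hairpin windows, not whole
domains. Allowed pairs everywhere are {A:U, G:C, G:U}; no other
non-canonical pair is recognised.

Classification of a variable stem site: if every observed state pairs with
the (invariant) partner state, the variation is **wobble-neutral** — the
G:U wobble is what makes C↔T changes opposite a stem G structurally silent;
if the partner site is itself variable and at least one observed joint
state combination restores pairing, the pair is **compensatory**; otherwise
**disruptive**. Loop sites are reported as loop variants, unpaired flanking
sites as unpaired variants, and any gap state at a stem position yields
`indeterminate` (a deleted position has no defined pairing to preserve).

Compensatory types at the diagnostic positions are exact catalog lookups:
VR1 types I–IV for (103,159) ∈ {AT, GT, AC, GC}, with the
ambiguity-consensus pattern (R/N, T) as type V matched only for consensus
records; VR2 types I–VI for the (389,390,391)/(443,442,441) triplet pairs
AAA/TTT, AAA/CTT, AAA/TTC, AAA/CTC, GAG/CTC, GAG/CTT. Unknown combinations
are labelled `novel`. `pairing_integrity` counts diagnostic pairs still
forming A:U/G:C/G:U; every cataloged clone keeps ≥2 of its 4 diagnostic
pairs intact.

## Distances, neighbor joining, bootstrap

Distances use pairwise deletion (gaps and ambiguity codes are missing
data). `p` is the raw mismatch proportion. `K3ST` is Kimura's
three-substitution-types distance. `F84` uses the closed form with
empirical base frequencies and observed transition/transversion proportions
(the parameterization used by classic distance programs); it needs no
preset ts/tv ratio and reduces exactly to the Kimura two-parameter distance
at equal frequencies (unit-tested). A non-positive logarithm argument
(saturation) raises an error naming the pair instead of returning infinity.

Neighbor joining is the standard Q-criterion agglomeration; ties are broken
by the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf), making the tree independent of input order.
Negative branch-length estimates are clamped to zero with a warning.
NJ exactly recovers additive matrices (property-tested against 100 random
trees of 4–12 taxa) and matches scikit-bio's implementation on random
matrices. Bootstrap resampling draws one column-index vector per replicate
against the canonical column order, so supports are record-order invariant
under a fixed seed; replicates whose distances saturate are skipped and
excluded from the denominator. Reproducing the study tree's exact topology
is explicitly not a goal — the published supports are very low, which is
part of the reticulation argument.

## The Phi recombination test

Informative sites have ≥2 states each carried by ≥2 records (gaps are
missing data). Two sites are compatible iff their partition-intersection
graph (states as vertices, observed joint states as edges, after pairwise
deletion) is acyclic; for two biallelic sites this is the four-gamete test.
The implementation is verified against an exhaustive perfect-phylogeny
search over all unrooted trees on ≤6 taxa. Incompatibility is normalised to
{0,1}; Φ is the mean over unordered informative-site pairs within `w`
positions of each other (default 100). The null distribution permutes site
positions; `p = (1 + #{Φ_perm ≤ Φ_obs})/(1 + n_permutations)` (add-one, so
p is never 0; small p means nearby sites are *more* compatible than
position-random, the distance signature of recombination).

**Calibration.** The permutation test controls type-I error: on clonal
simulations the rejection rate at α = 0.05 never exceeds the nominal level.
It is, however, conservative rather than exact, for two structural reasons:
(i) at study-like divergence most clonal arrays contain no incompatible
site pairs at all, so Φ is degenerate at 0 and p = 1; (ii) the
hairpin-biased mutation model concentrates homoplasy inside the two stems,
so under the clonal null *nearby* pairs are more incompatible than distant
ones — the known conservative direction of Phi under mutation-rate
heterogeneity. Power is characterised at a documented setting of
0.5 crossovers/generation with mu = 2×10⁻³ (the upper end of study-like
divergence), 18 sampled clones, w = 100, 999 permutations, where the
rejection rate over 50 replicates clears 80%.

## The repeat-array simulator

`synth` emulates the Discussion-level event model: a fixed-size array of
~0.5 kb repeats evolving by per-generation duplication (one repeat
overwritten by a copy of another — the homogenising Moran move),
substitution of the new copy, and optional reticulate events. Defaults,
chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| `repeat_length` | 499 nt | amplicon length |
| `n_repeats` | 20 | array size (desk-scale stand-in for a real array) |
| `hairpin_spec` | stems 90–113/149–172 and 380–413/419–452 | two hairpins mimicking the VR1/VR2 geometry, with the 103–159-style pair and a 3-bp diagnostic block |
| `mu` | 1×10⁻³ /site/duplication | with n_repeats=20 this yields clone pools whose most-divergent pairs differ at ~3–5% of sites, the observed range |
| `ts_bias` | 0.8 | transition share among substitutions |
| `tc_opposite_g_bias` | 5 | rate multiplier for pyrimidines opposite a master-stem G (wobble-tolerated changes accumulate) |
| `comp_comutation_p` | 0.5 | chance a pairing-breaking stem change is immediately compensated at the partner |
| `rec_rate`, `conv_rate` | 0 | reticulate events off by default (clonal null) |
| `conv_tract_mean` | 50 nt | geometric conversion tract |
| `n_generations` | 400 | ≳ the n²/2 Moran coalescence timescale |

One seeded RNG stream is consumed in a fixed order (master; then per
generation duplication, substitutions + compensation, homogenization,
recombination, conversion), so paired-seed comparisons across parameter
values are meaningful. Every event is logged and replay of the log from the
master reproduces the array byte-for-byte — the invariant that anchors all
ground-truth evaluation. The consensus emitter produces the minimal IUPAC
code per column (gap-containing columns emit a gap and are flagged),
matching what a Sanger read of a mixed PCR pool would show.

What the simulator does *not* emulate: length variation beyond whole-tract
copying (no indel drift, so alignments stay trivial), selection on rRNA
function, chromatin-level silencing of repeats, and PCR/sequencing error.
Passing tests on simulated data therefore validate the statistical
machinery, not the wet-lab error model.

## The bundled study fixture

`fixture.reconstruct_alignment()` realises the published variable-site
catalog (35 positions; per-strain state sets; consensus rows for AJ745110,
AJ745108, AF360542; compensatory type assignments for all 18 clones) as a
synthetic 499-nt alignment. Group-level state sets — the inputs to every
reproduced quantity — are exact. Per-clone states are pinned at the six
diagnostic positions by the compensatory catalog; at the remaining
within-group variable positions the r-th such position (ascending) hands
its j-th alternative state to clone (r+j−1) mod n — a fixed, documented
convention, not data, so per-clone quantities away from the diagnostic
positions (e.g. pairwise difference maxima) are not comparable with the
published ones. The invariant background realises the two hairpins exactly
(stems complementary, wobble-site partners set to G, diagnostic pairs
paired), with hairpin loops filled with A and other positions from a fixed
cycle.

## Numerical and degenerate-input conventions

Rounding of reported percentages: nearest integer, half away from zero;
zero denominators yield `None` (undefined), never 0. Folding traceback,
NJ tie-breaks and the permutation stream are all deterministic under a
seed. Saturated distances, all-gap trimming results, sites outside folded
windows, and gaps at diagnostic positions raise errors rather than being
silently patched.

## Problem sizes

Defaults used by the test suite and the acceptance script: 200 clonal and
50 recombinant simulations for Phi calibration (199 and 999 permutations),
100 replicates for spectrum recovery, 200 random sequences (length ≤ 14)
for the folding oracle, 100 random additive trees (4–12 taxa) for NJ, and
100 random column pairs (≤6 taxa) for the compatibility oracle.
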