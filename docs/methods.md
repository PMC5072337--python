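# Methods

## Scope and design stance

`famforge` re-creates an iterative profile-search workflow for delineating a
family of polytopic membrane proteins, at desk scale and against synthetic
proteomes with known truth. The external tools of the original workflow
(profile search engines, profile–profile comparers, ML/Bayesian tree
programs, TM predictors) are replaced by self-contained, oracle-testable
components: a fixed-cost local-alignment profile, an explicitly calibrated
logistic probability, a hydropathy sliding window, and distance-based
neighbor joining. The goal is not to reproduce any database-dependent count
but to make the *method* — shallow search plus zipper-masked validation —
measurable against planted truth.

## The synthetic superfamily

The generator emulates the statistical situation of the real search.

**Architecture.** An ancestor of `n_tm_helices = 4` hydrophobic helices
(`tm_len = 20`) alternating with hydrophilic loops (`loop_len = 20`,
including both termini). Helix residues are drawn from
{L, I, V, F, A, M, G} with weights 25/15/15/10/15/5/15; loop residues
uniformly from the remaining 13 amino acids. Each helix carries one exact
GxxxGxxxG zipper (three glycines, spacer residues hydrophobic non-G); the
loop between helices 2 and 3 carries one fixed R and one fixed D, mirroring
the family's conserved charged pair.

**Evolution.** Substitutions follow a Poisson process: per branch of length
`t` each site draws `Poisson(t * r)` replacement events, each uniform over
the 19 alternatives. Zipper glycines and the charged pair evolve at
`r = 0.1` (conserved); everything else at `r = 1`. Loops additionally
accept single-residue indels at 0.1× the substitution rate; helices never
do. Indels are tracked in a shared column registry, so the generator emits
a true multiple alignment, the true tree, and the alignment columns of the
ancestral zipper glycines. Members of a subfamily sit at depth
`intra/2 = 0.15` below their subfamily ancestor (pairwise intra divergence
0.3); subfamily ancestors sit at `inter/2 = 0.5` from the centre (pairwise
inter divergence 1.0 — for three subfamilies the backbone is the unrooted
binary star). These defaults put cross-subfamily identity at ~33%, just
below the 40% clustering cutoff, which is the interesting regime: each
subfamily clusters separately, and cross-subfamily detection must come from
profile sensitivity, not near-identity.

**Confounds.** Decoys are i.i.d. uniform-composition proteins (length 200)
with 2–4 exact zippers implanted at non-overlapping random positions — they
share the motif and nothing else. Background proteins are i.i.d. uniform,
lengths 100–400. Tandems concatenate two distinct family members with a
random hydrophilic linker of 10–30 residues. The default benchmark is
3 proteomes × (3 subfamilies × 20 members + 20 decoys + 200 background +
2 tandems), 846 records, one global integer seed.

**What the generator does not emulate:** site-heterogeneous rates beyond
the binary conserved/neutral split, realistic amino-acid exchangeabilities
(replacement is uniform), domain shuffling, paralog birth/death, fragments,
and real database composition. Passing tests therefore demonstrate that the
pipeline's logic discriminates motif-only similarity from descent under a
clean model; they do not certify performance on real proteomes.

## Profiles and scoring

A profile stores per-column residue frequencies built from an alignment:
match columns are those with < 50% gaps (or a pinned list — the pipeline
pins the seed's match columns for the whole run so masks and envelopes stay
in one coordinate frame), sequence weights follow the Henikoff
position-based scheme (gap treated as a 21st symbol), and frequencies get
background-proportional pseudocounts of total weight 1. The background is
the alignment's overall composition, floored at 1e-4 and renormalized.
'X' is a legal residue and always scores 0 (background).

Sequence-vs-profile scoring is a local Gotoh DP over match/insert/delete
states: emission `log2(f_i(a)/q(a))`, gap open 4 bits, extend 0.25 bits,
insertions and deletions may not abut, alignments start and end in match
states, and a non-positive optimum reports score 0. The same DP core
drives profile–profile comparison with the co-emission score
`log2(sum_a f_i(a) g_j(a) / q_m(a))` against the master's background.
These fixed costs trade modeling power for exact testability: every score
is checked against brute-force path enumeration on small instances.

**Masking.** Zipper columns are detected on the alignment: a match column
is G-rich when ≥ 70% of its non-gap residues are G, and an anchor triplet
is (c, c+4±1, c+8±2) in match-column coordinates (the tolerance absorbs
loop-indel jitter). The masked set is the anchors plus intervening match
columns. A masked column's contribution is clipped to `min(0, s)` rather
than forced to exactly 0: zero-clamping would let masked columns act as
free bridges for chance local paths and could *raise* a decoy's score,
whereas the clip guarantees masked ≤ unmasked for every sequence while
keeping "a fully masked profile scores 0" (the local floor).

**E-values.** A profile is calibrated by scoring 200 i.i.d. sequences of
its own background composition (length = median database length) and
fitting a Gumbel by maximum likelihood; `E = N * sf(s)` with `N` the number
of sequences in the current search. The fit is slightly conservative in
the extreme tail — measured chance-hit counts at E ≤ 1 run ~0.5–0.7 per
500-sequence null database rather than 1.0 — because the true score
distribution decays a little faster than the Gumbel extrapolation beyond
the fitted range. Conservative e-values cost nothing here (family scores
sit hundreds of bits above the cutoff) and help precision.

**Probability calibration.** The external probability scale of the original
workflow is not exportable, so the master profile carries its own: raw
profile–profile scores are mapped to P(homolog) by a two-parameter logistic
fitted by maximum likelihood. The pipeline self-calibrates without truth
labels — positives are master rows mutated along a divergence ladder
(0.25–1.5 subs/site, uniform replacement), negatives are random
zipper-implanted sequences, 30 per class. A ridge of 1e-4 on the scaled
slope keeps the optimum finite when the classes separate perfectly (the
usual case); it shifts recovered parameters by far less than sampling
error. The 0.9 acceptance threshold applies to the probability of the
*masked* score.

## The iteration loop

Each round: greedy-cluster the homolog set at 40% identity (descending
length, ties by id; identity maximizes identities among score-optimal
global alignments, denominated by the shorter sequence so fragments still
cluster) → build one profile per cluster from the members' master rows
(singletons become single-sequence profiles) → calibrate and search all
proteomes at E ≤ 1 → validate each new hit as a single-sequence profile
against the masked, probability-calibrated master → attach accepted hits to
the master by the DP traceback (insert-state residues are recorded
per-row, lowercase, and get no new columns). The loop caps at 10 rounds
and declares a fixed point when an iteration adds nothing; on the default
benchmark it converges in 2. Validation uses the evolving master by
default; a `pin_seed_master` flag reverts to the original seed for users
who prefer the stricter variant.

## Architecture analysis

PRAT (`[GA]-x-x-[FY]-x(10)-R-x(3)-D-x(6)-[GAS]-G-x(3)-G`, 31 positions) and
zipper scanning return all, possibly overlapping, window matches; `x`
matches any residue including X, fixed positions do not. TM segments come
from Kyte–Doolittle hydropathy: every residue inside at least one
full 19-residue window of mean > 1.6 is membrane-flagged; flagged runs
separated by ≤ 3 residues merge, runs shorter than 15 are dropped. The
window-coverage rule (rather than thresholding each residue's centred
window value) is what makes a 20-residue helix of realistic composition
recoverable at these defaults: centred-value runs are systematically
shorter than the helix and would fall under the minimum length.
Sequences shorter than the window return an empty prediction with a
warning.

Tandem detection scores a record against the calibrated family profile,
hard-masks the best envelope with X, and rescores; a second envelope at
E ≤ 1 (scaled by the search database size — at database size 1 the check
would be vacuous since a survival probability never exceeds 1) overlapping
the first by < 10 residues makes the record two-domain, reported in N→C
order. Two-domain records enter the tree as two leaves, `id#N` and `id#C`,
each half re-attached to the master independently.

## Classification

The leaf alignment is trimmed to columns with ≤ 50% gaps; distances are
p-distances over mutually ungapped columns with Poisson correction
`d = -ln(1-p)`, capped at 5, with an error below 10 shared columns.
Neighbor joining uses the standard Q-criterion, ties broken by the smallest
node-index pair, negative branch lengths floored at 0 with the deficit
moved to the sister. Subfamily assignment takes, for each leaf, the
smallest split side (over all edges of the tree) containing the leaf and at
least one reference leaf, and assigns the majority reference label when the
majority reaches 75%, else "unclassified"; split sides rather than
midpoint-rooted clades make the rule independent of degenerate midpoint
placement (midpoint rooting is still applied for traversal). The
presence/absence matrix marks a proteome × subfamily cell when ≥ 1 record
of that proteome is assigned there; tandem halves credit their source
record's proteome; all-absent proteomes still appear as rows.

## Problem sizes and determinism

The package's own evaluation uses the 846-record benchmark above (full
pipeline ≈ 15 s on one core), 50 × 500-sequence null databases for the
e-value check, 100 random 6-leaf additive matrices for neighbor joining,
and exhaustive-enumeration oracles on instances up to 5 profile columns ×
7 residues, 4 × 4 profile columns, and length-8 sequence pairs. All
randomness flows from one integer seed through named generators;
`generate`, `iterate` and `classify` reruns are byte-identical, and run
logs carry no wall-clock times for exactly that reason (timestamps appear
on the console only).

## Known limitations

- The decoys' similarity to the family is concentrated in the motif by
  construction, but in *absolute* bits a genuine homolog always loses more
  to masking than a decoy does (it aligns all ~12 conserved zipper
  glycines; a decoy's chance alignment rarely engages more than one zipper
  above the local-alignment chance floor). Masking specificity should
  therefore be read from the rejection/acceptance rates and from the
  *relative* motif concentration (contribution / raw score), not from
  absolute contribution differences.
- Profile transitions are fixed costs, not learned; no forward-algorithm
  summed scores; no position-specific gap penalties.
- The identity definition (max identities among score-optimal global
  alignments) is exact but O(nm); fine at desk scale, not for real
  databases.
- Subfamily boundaries follow the reference-anchored majority rule; with
  no references in a region, leaves go "unclassified" rather than founding
  new subfamilies.
- E-values are conservative in the deep tail (see above); absolute
  e-values should not be compared across profiles of very different
  lengths.
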