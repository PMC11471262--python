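# Methods

## The model

`motifcfg` learns RNA sequence-structure motifs from unaligned positive
and negative sequence sets.  A motif is described by a *search pattern*
μ — a modified dot-bracket string over `.` `(` `)` `*` — in which each
dot is a single-stranded motif position with its own base profile
θ<sub>i</sub>, each matched bracket pair a base-paired motif position
with a profile θ<sub>i,j</sub> over the six canonical pair types
(AU, CG, GC, GU, UA, UG), and `*` a structure-unspecified *insertion
region* emitted by one shared background profile θ<sub>0</sub>.
Patterns begin and end with `*` so the motif can occur anywhere in a
sequence.  Every motif state may repeat its emission through
self-transitions with a constant log-weight ω, so stem and loop lengths
vary without deletion states; each motif symbol emits at least once, and
a parse places the motif exactly once or not at all.

The profile grammar alone matches short motifs everywhere.  To suppress
spurious matches, each joint parse τ couples a profile parse φ with a
secondary structure σ drawn from a nearest-neighbor ensemble, and is
weighted

&nbsp;&nbsp;w(τ) = exp(−λ·ΔG(σ)/kT) · exp(Σ θ·N(φ) + ω·N<sub>self</sub>(φ)),

subject to consistency: positions emitted by a dot are unpaired in σ,
the two blocks of a bracket pair form a helix whose pairs are pairs of
σ (outermost-left with outermost-right, stacked contiguously), and
insertion-region positions are unconstrained.  λ ≥ 0 is a trainable
scale balancing motif match against thermodynamic stability.  Summing
w(τ) over all parses gives the partition function Z; restricting to
motif-containing or motif-free parses gives Z⁺ and Z⁻, and the motif
probability is P(y=1|x) = Z⁺/Z.

## Energy model

The structure ensemble uses the standard loop decomposition with a
simplified, swappable parameter table
(`src/motifcfg/data/energy_params.tsv`): 16 Watson-Crick×Watson-Crick
stack terms plus one default for GU-containing stacks, a logarithmic
hairpin penalty `hairpin_base + hairpin_log·ln(n/3)`, affine bulge and
internal-loop penalties sharing one per-nucleotide slope, and an affine
multiloop cost (closing + per-branch + per-unpaired).  Bulge/internal
penalties are affine rather than logarithmic because a separable
per-base cost lets the joint dynamic programming grow interior-loop
runs one base at a time instead of enumerating all (left, right) size
splits — the package's own design choice; at the loop sizes admitted by
the span constraint the difference is well under the uncertainty of any
simplified parameter set.  Defaults: kT = 0.6163 kcal/mol (T = 310.15
K), maximal pair span W = 50, minimum hairpin loop 3 nt.  Only the six
canonical pair types pair; `T` is read as `U`; other letters are
rejected.  Dangling ends, coaxial stacking and pseudoknots are not
modeled.

## The joint dynamic programming

Z⁻ is the background-profile score of the whole sequence times the
plain (λ-scaled) McCaskill partition function.  Z⁺ is computed by one
engine that threads a small automaton derived from the pattern through
the Zuker-style structure grammar: boundary states track linear
progress through the pattern (one state per inter-symbol gap plus one
"run" state per dot), base pairs are emitted either by a pattern
bracket pair or as background pairs with both ends in insertion
regions, and hairpin/stack/bulge/internal/multiloop cases are assembled
exactly as in the single-grammar decomposition.  Because the automaton
must traverse every motif symbol, the engine computes Z⁺ directly, and
Z = Z⁺ + Z⁻ is assembled in log space — the motif probability is never
obtained by subtraction, so there is no cancellation to guard.

All charts live in linear space with one scale factor per sequence
position (every position is emitted exactly once in every parse, so
the scales cancel exactly in all reported ratios).  The initial scale
is the largest single-base emission weight per position; if the run
under- or overflows the scale is shifted uniformly and the pass is
retried (weights far below the dominant parse may flush to zero, which
is harmless for the reported log-partition values and posteriors).
The outside pass is the literal adjoint of the inside pass and yields
expected emission counts (the CRF gradient), the expected −ΔG/kT (the
λ gradient), per-position motif-membership posteriors and base-pair
posterior matrices.  The engine is validated against brute-force
enumeration over all (structure, parse) pairs on sequences up to
length 9 to a relative error of 1e−9, and its counts against central
finite differences.

Complexity is O(L·W) pair items with O(states) work per interior
transition; the profile-state dimension of interior charts is
restricted to the states at which they can be entered.  Memory grows
as O(L·W·states²); at L = 300, W = 50 and a typical pattern this is a
few hundred MB during gradient computation.

## Training

The objective is the conditional-random-field criterion: the summed
log-probability of motif presence over positives plus motif absence
over negatives, minus an L2 regularizer ½c<sub>θ</sub>‖θ‖² +
½c<sub>λ</sub>λ² (defaults c<sub>θ</sub> = 0.01, c<sub>λ</sub> =
0.001).  The gradient per positive is the expected-count difference
E⁺[N] − E[N], per negative E⁻[N] − E[N], with the expected −ΔG/kT
differences driving λ.  Optimization is Adam (learning rate 0.02 by
default, minibatch 16, up to 50 epochs with patience-5 early stopping
on a validation objective), with λ projected to stay non-negative.
ω is a fixed constant (−1.0 natural-log units): it is described by the
model as a constant minor weight and only θ and λ are treated as
trainable.  Self-transitions are counted for motif (dot and bracket)
states; insertion emissions carry no ω, so insertion length is
penalized only through the background profile.

*Simulated negatives*: each epoch, dinucleotide-shuffled copies of the
positives (Euler-path shuffle preserving exact dinucleotide counts) are
mixed into the negative stream at a 1:1 ratio by default.  This is an
interpretation of a briefly-named device: it prevents the model from
exploiting background composition, forcing structure- and
position-specific signal.

The full workflow trains every candidate pattern (by default the
shipped 135-pattern set) under K-fold cross-validation (K = 5), ranks
patterns by mean held-out enrichment score (the AUROC of P(y=1|x)
between positives and negatives; ties credited 0.5), breaks ties by
fewer motif symbols then pattern text, and retrains the best pattern on
the complete data.

### Recovered profiles

Discriminative training stops sharpening parameters once the classes
separate, so the softmax of θ understates the conservation of the
motif a model has found.  The *recovered profile* readout therefore
aggregates posterior-expected emission counts under Z⁺ over a sequence
set and normalizes per state, after one expectation-maximization
realignment step (re-estimating emissions from expected counts and
recomputing the alignment, as alignment-based motif finders do).  The
same counts provide the mean insertion length annotated on logos.

## Default pattern set

The default search space is enumerated by topology: dot segments of
length 1, at most two segments, at most three bracket pairs nested to
depth two, at most one insertion star besides the mandatory flanks, no
empty brackets, and internal stars only in patterns containing a pair
(an insertion without pairing would split the motif into unrelated
pieces).  These bounds were calibrated once and frozen; they emit
exactly 135 patterns covering loop, hairpin, bulge, internal-loop and
multi-stem topologies.

## Synthetic benchmarks

The generator plants one structural motif per positive sequence:
all secondary structures of 10 positions with at least one pair are
enumerated (64 skeletons), each given an internal gap of 1–10 nt
(cycling deterministically) placed inside its first hairpin loop, a
per-position sequence profile with conservation 0.9 (dominant base or
pair type at probability 0.9; stem positions favor CG/GC), fixed per
motif index.  A positive draws the motif instance from the profiles,
a uniform-random gap filling, and uniform flanks at a random offset
within L = 100 nt, and is accepted only if the energy model assigns
every planted pair a posterior ≥ 0.5 *and* every planted loop position
a pairing probability ≤ 0.5 (the instance must fold into the expected
structure, loops included — otherwise the ensemble routinely extends
planted helices into adjacent loop positions and corrupts the planted
loop profiles).  This rejection sampling plays the role of an external
structure-aware designer plus folding check.
Motifs whose structures are too unstable to realize (for instance
isolated single pairs or bulge-broken two-stacks under this parameter
set) exhaust the retry cap and raise an error, mirroring the fact that
such motifs cannot be designed at all.  Negatives are uniform i.i.d.
sequences; decoys remove each positive's motif bases and re-insert
them at random positions, preserving base composition exactly while
destroying both structure and contiguity, so decoy discrimination
specifically probes structure/position signal rather than composition.

What the generator does *not* emulate: transcript-like background
composition, shared flanking context, multiple motif occurrences,
expression-driven noise, or peak-calling artifacts of cross-linking
data.  Passing these benchmarks demonstrates correct inference and
learning under the model's own assumptions, not performance on
biological data.

## Evaluation protocol and problem sizes

The shipped experiments run at desk scale, chosen as the package's own
evaluation design:

- Oracle agreement: 200 random instances, |x| ≤ 9, θ ∈ [−2, 2],
  λ ∈ {0, 0.5, 1}, W = 9, relative error ≤ 1e−9.
- Gradient agreement: 20 instances, every parameter component, central
  differences (h = 1e−5), relative error ≤ 1e−4.
- Parameter recovery: the planted stem-loop `(((····)))` with a 2 nt
  gap, 200 positives / 200 negatives per seed (train 100/100, evaluate
  on the held-out 100/100), L = 100, W = 14 (the largest planted span
  is 11), 5 epochs at learning rate 0.05, seeds 1–5.  Checks: held-out
  AUROC ≥ 0.95 and recovered-loop-profile KL ≤ 0.15 bits/column
  (medians over seeds).
- Discrimination across motifs: five planted stem-loops with
  insertion gaps of 1, 2, 4, 6 and 8 nt, 100/100 sequences each (train
  60/60), analysis span W = span + 2 per motif; mean held-out AUROC
  ≥ 0.95 versus negatives and > 0.90 versus composition-matched
  decoys.  Under the shipped energy parameters only contiguous
  three-stack stem-loop skeletons are stable enough to design (isolated
  or bulge-broken helices never reach the acceptance posterior — a
  property of the physics, not of the learner), so the five motifs are
  gap-length variants of those skeletons, each with its own planted
  profiles; the selection rule is "designable within the retry cap,
  ascending skeleton index, varied gap".
- Energy model: partition values equal exhaustive enumeration on 100
  random sequences (≤ 9 nt); with zeroed energies the partition counts
  structures (65 at n = 10, W = 10, minimum hairpin 3), checked against
  an independent counting recurrence.

## Numerical choices and edge cases

- All DP in natural-log-equivalent scaled linear space; logo heights in
  bits.
- If a motif cannot occur in a sequence (for example no canonical pair
  exists for a bracket pattern), Z⁺ = 0: the motif probability is 0 and
  expected counts under Z⁺ are defined as zeros with a warning.
- Patterns like `*()*` (a bracket with no interior symbols) are valid
  strings whose motif can never satisfy the minimum hairpin size; they
  simply score Z⁺ = 0.
- Ties in pattern ranking are broken deterministically (fewer motif
  symbols, then lexicographic text).
- The interior of a motif helix may contain any consistent structure;
  insertion-region pairs, pairs spanning different insertion regions,
  and background pairs enclosing the whole motif are all admitted — the
  ensemble is global and the only coupling constraints are those stated
  for dots and brackets.

## Known limitations

- The energy parameters are deliberately simplified; absolute folding
  probabilities should not be read as thermodynamic predictions.
- Exactly one motif occurrence is modeled per parse; tandem motifs are
  matched only once.
- The span constraint W bounds all pairs, including motif pairs, so
  motifs wider than W are invisible.
- Training cost is dominated by the joint inside-outside pass; a full
  135-pattern selection on hundreds of sequences is an overnight run on
  one core, which is why the shipped experiments use one or a few
  matched patterns.
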