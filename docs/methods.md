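# Methods

## Problem and approach

Given a drug-like substrate, the package predicts which metabolite a human
metabolic system is most likely to produce. It follows a mine–enumerate–rank
design:

1. **Mine** reaction-SMARTS templates from atom-mapped substrate→metabolite
   records. A template captures the reaction center (the atoms whose bonding
   changes) plus one shell of context, so it can be re-applied to new
   molecules.
2. **Enumerate** candidate metabolites by applying every library template at
   every matching site of the query substrate. Candidates matching a recorded
   metabolite are positives; all other enumerated products are chemically
   plausible negatives — the enumeration step is also a negative-sampling
   machine.
3. **Rank** candidates with a shared-weight neural scorer: every candidate row
   (substrate fingerprint ‖ candidate fingerprint) passes through the same
   fully-connected network to a scalar score, and a masked softmax over the
   candidate set yields a probability distribution that sums to 1. Training
   minimizes cross-entropy against the recorded product(s); evaluation is
   Top-k accuracy.

## Record model and filtering

A record is one mapped reaction `substrate >> product(s)`. Atom maps tie each
surviving substrate atom to its product image; leaving-group atoms are
unmapped (or mapped only on the substrate side); atoms gained from the medium
(the oxygen of an oxidation) are unmapped on the product side.

Filtering assigns the first matching reject reason in a fixed order
(unparsable → R-group → radical → metal → map-inconsistent → no-change →
chirality-only), which makes it deterministic and idempotent. Map consistency
requires: no duplicate maps per molecule, no product map absent from the
substrate, no wholly unmapped product molecule, and every unmapped product
heavy atom adjacent to at least one mapped atom. The last rule is the
operative definition of "attributable": a gained atom anchored to a mapped
atom can be placed by the template extractor, whereas an unanchored fragment
cannot. Records differing from their substrate only in stereo descriptors are
flagged chirality-only and excluded from template extraction and training —
the 2-D fingerprints used downstream cannot distinguish them — but they stay
countable for corpus statistics.

The metal filter treats every element outside {H, B, C, N, O, F, Si, P, S,
Cl, Se, Br, I} as a metal; the set is configurable.

## Template extraction

The reaction center is the set of mapped atoms whose signature changes
between substrate and product, where the signature is (element, aromaticity,
formal charge, total hydrogen count, heavy-atom degree, multiset of
(bond order, neighbor map) incident bonds). Bond cleavage and formation are
caught by the bond multiset.

The substrate pattern contains:

- **center atoms** in full detail — element, aromaticity, H-count, formal
  charge, map index (`[NH;+0:1]`, `[O;H0;+0:1]`);
- **first-shell neighbors** (mapped, retained, non-hydrogen) in low detail —
  element + aromaticity + map only (`[C:2]`, `[c:3]`). One shell is the
  default radius: high coverage at the cost of specificity; the radius is a
  config knob;
- **context atoms** — leaving-group atoms and, on the product side, gained
  atoms — unmapped, element-only (`O=C-`, `[O-]`);
- **double/triple-bond completion**: any atom attached to an included atom by
  a multiple bond is pulled in (recursively). This keeps carbonyl context
  intact, so an ester template reads `O=C-[O;H0;+0:1]-[C:2]` rather than an
  ambiguous `C-[O;H0;+0:1]-[C:2]`. A side effect is that genuinely different
  chemical environments (e.g. a CH2 adjacent to a carbonyl vs. a plain CH2)
  mine to distinct templates; a mined library can therefore be somewhat
  larger than the set of planted rule classes, which is chemically faithful.

The product pattern holds the images of all retained pattern atoms plus
gained atoms adjacent to the center.

**Canonicalization.** Patterns are canonicalized by Weisfeiler–Lehman
refinement over atom descriptors (ties broken by singling out one member of
the lowest tied class and re-refining — adequate for the small tree-like
patterns templates produce), after which map indices are renumbered in
substrate rank order and both sides are rendered by a deterministic writer
(fixed primitive order, explicit bond tokens, branches in rank order).
Templates that differ only in map numbering, token order, or typographic
whitespace collapse to the same string; the frequency library groups by that
string, orders by descending count with lexicographic tie-break, and drops
classes below `min_count` (default 1 — no support threshold).

**Known notation quirk.** The published form of the tertiary-amine oxidation
rule omits the oxide oxygen, producing an aminium species that RDKit
perceives as a radical cation — which the radical filter would itself
reject. The library shipped with the generator therefore writes this rule as
a proper N-oxidation (`[O-]` on the aminium nitrogen, in the same notation as
the pyridine N-oxidation rule); the golden-rule tests keep the published
variant to pin extraction behavior.

## Candidate enumeration

`apply_template` runs the template at every substructure match (symmetric
sites dedupe via canonical SMILES), sanitizes, and discards unsanitizable
products. `generate_candidates` unions all templates, removes candidates
identical to the substrate, labels positives by stereo-stripped canonical
SMILES equality with the recorded products, and — above `max_candidates`
(default 128) — keeps all positives and subsamples negatives with a seeded
PRNG. Single-step, single-site transformations only: a recorded multi-step
product simply yields a candidate set with no positive, which counts as a
miss during evaluation.

## Features

Each candidate row is `[fp(substrate) ‖ fp(candidate)]` of hashed binary
Morgan (circular) fingerprints — radius 2, 1024 bits per molecule by default,
giving 2048 input dimensions. Counts are not used; bits only. The radius-3
(ECFP6-equivalent) path is intended for use with the autoencoder: a
symmetric MLP (2048→512→256 encoder by default, sigmoid reconstruction,
binary cross-entropy, Adam, 50 epochs), trained on the concatenated rows.
Whether to encode each molecule separately or the concatenated pair was an
open choice; the concatenated row is encoded, as it preserves cross-molecule
structure for the decoder.

## Ranker

The scorer is a fully-connected network (default hidden layers 512–256, ReLU,
dropout 0.2) with a scalar head; the same parameters score every candidate,
so the model is permutation-equivariant over the set by construction.
Probabilities come from a masked softmax; padding rows get probability
exactly 0 and contribute nothing to the loss. Variable-size sets are handled
by concatenating rows and computing segmented softmaxes (padding + mask is
used at the scoring interface).

Training: cross-entropy with the target distribution uniform over all
positives of a set (a record can have several recorded metabolites); Adam at
1e-3; batches of 32 candidate sets; 200 epochs by default with 5-fold
cross-validation and a 7:1:2 train/validation/test split. When a validation
set is supplied, the returned parameters are from the epoch with the best
validation Top-1, which guards against overfitting small corpora over long
runs. Records with no generated positive are skipped with a warning during
training but count as misses during evaluation. All randomness (splits, fold
assignment, init, shuffling, dropout, negative subsampling) flows from one
seed.

Top-k accuracy counts a record as a hit when **any** positive candidate ranks
within the top k; ties in probability break lexicographically by SMILES so
rankings are deterministic.

## Synthetic corpus generator

The generator emulates a curated single-step human metabolic-reaction corpus
at desk scale. Scaffolds are assembled from a fragment grammar — alkyl/aryl
terminals joined by one or two bivalent linkers (amide, reversed amide,
ester, reversed ester, thioether, tertiary amine, alkylene) — which
guarantees valence-valid molecules that contain the functional groups the
rule library recognizes. Defaults: 14–36 heavy atoms (drug-like), 50%
aromatic terminals, hydrolyzable linkers drawn most often to mirror the
amide/ester-rich composition of real corpora. Scaffolds are unique within a
dataset, so record-level splits cannot leak substrates.

Each record plants one biotransformation: among the templates that match the
scaffold, one is drawn with probability proportional to its propensity
(default: geometric decay with ratio 0.7 down the class ordering, hydrolyses
first), then a site is drawn uniformly within the chosen template. The
mapped product, the planted rule and the planted site are all recorded, so
empirical class frequencies are checkable against the generator's own
availability-restricted prediction (chi-square in the test suite).

What the generator does **not** emulate: real chemical-space statistics
(molecular-weight and logP distributions, ring-system diversity), enzyme or
isoform attribution, multi-step pathways, stereochemistry, and the long tail
of rare reaction classes. Passing tests on this corpus demonstrate that the
pipeline's machinery is correct and that the ranker can learn planted
structure; they say nothing quantitative about accuracy on real metabolic
data.

## Propensity recovery

`recover_propensities` averages, per template, the model probability mass of
the candidates that template generates on held-out records, and reports the
Spearman rank correlation with the planted propensities. Because templates
match different scaffold subsets (availability restriction) and split mass
across sites, even an oracle scorer scores below ρ = 1; the statistic is
read against a permutation null (95% bound ≈ 0.64 for 10 templates).

## Numerical and benchmark choices

- Problem sizes in the shipped benchmark: 2,400 generated records (2,000
  train / 400 test), 30 training epochs, radius-2 1024-bit fingerprints —
  large enough for stable accuracy estimates while keeping the full pipeline
  runnable in minutes on one CPU.
- The neural components are plain NumPy with explicit backprop (deterministic
  given seed and BLAS); He initialization; a zero-initialized variant exists
  as the exact uniform baseline.
- Softmax is computed with max-subtraction; masked entries are excluded
  before normalization, so their probability is exactly 0, not merely small.
- Degenerate inputs: identity reactions raise `NoChangeDetected`; an
  all-masked candidate set raises; an empty candidate set is a valid result
  that callers must handle (it counts as a miss in evaluation).

## Limitations

- Single-step, single-site predictions; no metabolite-tree expansion.
- No stereochemistry (chirality-only records are excluded by design).
- No probability calibration of site occurrence: the softmax is over the
  enumerated set, not over reaction events.
- The mined template language covers one shell of context; reactions whose
  selectivity depends on distant substituents mine to over-general rules.
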