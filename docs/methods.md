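# Methods

## Scope and pipeline

`contactfuse` post-processes residue–residue contact predictions for
contact-assisted *ab initio* modelling and molecular replacement (MR).
It does not predict contacts and does not run a folding or MR engine;
it sits between the predictors (a general metapredictor plus an
optional β-sheet-specific predictor) and the downstream programs,
performing:

1. **Canonicalization and top-L selection.** Predicted pairs are
   stored with `res1 < res2` over the modelled FASTA sequence
   (1-based), duplicates collapse to the maximum confidence, and the
   list is ranked by descending confidence. Only the top *L* contacts
   (*L* = chain length) are converted to restraints; each carries a
   squared-well bonus wd = −15.00.
2. **β-contact fusion.** Strand-pairing predictions arrive grouped
   into ladders with a parallel/antiparallel direction. Pairings of
   only one or two contacts are removed (high false-positive rate).
   For each remaining β contact (i, j), any top-L pair within the
   neighbour tolerance — the pair itself or (i, j±1), (i, j±2),
   (i±1, j), (i±2, j) — has its bonus doubled to −30.00; β contacts
   matching nothing in the top-L list are appended at −15.00. No
   further length cutoff is applied, so the fused list may exceed *L*.
3. **Restraint generation.** Each pair becomes an atom-pair FADE
   restraint between Cβ atoms (Cα for glycine).
4. **Evaluation.** Precision (PPV) of a contact list against
   structure-derived reference contacts; alignment diversity (Neff,
   η); and the MR success gate.

## The FADE well

FADE(d) with parameters (lb, ub, z, wd, offset) is:

- `wd + offset` for `d ∈ [lb + z, ub − z]` (the full-depth well);
- `0` for `d ≤ lb` or `d ≥ ub`;
- a cubic Hermite smoothstep between those plateaus, with zero slope
  at both edges of each fade zone, so the function is continuous and
  once-differentiable everywhere. At the fade-zone midpoint the value
  is exactly `wd/2` by symmetry.

Defaults are `(lb, ub, z, offset) = (−10, 19, 10, 0)`: the full-depth
region is exactly [0, 9] Å, i.e. a restraint is "satisfied" when the
two representative atoms are within 9 Å, and the bonus vanishes beyond
19 Å — a false-positive contact never pulls distant residues together.
Only the 9 Å satisfaction radius and the depths (−15.00/−30.00) are
protocol constants; the outer bounds are a parameterization choice
that realizes them, and every restraint line carries its parameters
explicitly so any divergence is visible in the file.

The upweight factor (default 2.0, giving −30.00) and the minimum
strand-group size (default 3) are exposed as parameters.

## Fusion semantics in corner cases

- A β contact that matches ≥1 top-L pair is *consumed*: it upweights
  all matched pairs and is not appended. Equality counts as a match,
  so an identical β/top-L pair can never appear twice.
- A top-L pair matched by several β contacts is upweighted once;
  weights never stack beyond −30.00 (the upweighted value is fixed,
  so stacking is excluded by construction).
- When indices differ within the tolerance, the *top-L* pair is the
  one kept and upweighted (it is already in the restraint list); the
  β indices are discarded.
- Appended β contacts are de-duplicated on (res1, res2), first
  occurrence wins. Contact lists are duplicate-free everywhere else,
  and the fused list follows suit.
- Output order is deterministic: top-L rank order first, then added β
  contacts in input order. Score ties in ranking break on ascending
  (res1, res2).

## Reference contacts and PPV

Reference contacts are all residue pairs whose representative atoms —
Cβ, or Cα for glycine — lie within 9 Å (inclusive) in the crystal
structure. Non-glycine residues missing Cβ (incomplete side chains)
also fall back to Cα, mirroring the glycine rule. Because the modelled
sequence is the full FASTA entry rather than the residues visible in
the crystal, the structure is first mapped onto model numbering by a
global alignment with free end gaps; an identity below 90% over the
aligned columns raises an error (chain mix-up guard). Predictions are
scored by exact pair membership — no neighbour tolerance — with
PPV = TP/(TP + FP). Pairs involving residues that are unresolved in
the crystal cannot be verified and are excluded from both counts; this
avoids penalizing predictions that cannot be checked (the alternative,
counting them false, is a stricter convention some benchmarks use).
No minimum sequence separation is applied by default; a configurable
filter is provided because |i − j| ≥ 5 is common in comparison sets.

## Alignment diversity

Neff clusters alignment members at 62% pairwise identity and sums the
fractional weights 1/(cluster size), which equals the number of
clusters. Identity follows the CD-HIT convention: identical non-gap
columns divided by the shorter ungapped length. Clustering is a direct
greedy pass — members sorted by descending ungapped length (ties keep
input order), each joining the first cluster whose *founder* it
matches at ≥ threshold — rather than CD-HIT's word-filter heuristics;
results can differ from CD-HIT on edge cases, acceptable because Neff
is a diagnostic, not a result. η = sqrt(N/L) uses the raw sequence
count of the provided alignment; any redundancy filtering is upstream.

## MR success gate

A trial succeeds iff SHELXE CC ≥ 25.00 **and** mean traced chain
length ACL ≥ 10.00 **and** the best (minimum) rebuild R_free over the
available rebuilding programs is ≤ 0.45. All comparisons are
inclusive, matching the printed ≥/≤ thresholds.

## Synthetic fixtures

Generators produce every input class with known ground truth so that
the full pipeline, including the command-line round trip, runs without
external data:

- **Structures**: idealized geometry — an α-helix (radius 2.3 Å, rise
  1.5 Å, twist 100°), a β-hairpin (straight antiparallel strands,
  3.4 Å per-residue rise, 4.8 Å inter-strand spacing, pleated Cβ
  ±1.5 Å), and a two-sheet "sandwich" of two hairpins 10 Å apart.
  Cross-strand partners (i, L+1−i) and helical (i, i+4) pairs fall
  well inside 9 Å by construction. A seeded jitter ≤ 0.05 Å keeps
  seeds distinguishable without moving any pair across the cutoff.
- **Contact maps**: `n_true` pairs drawn from the reference set with
  high scores, `n_false` from its complement over resolved residues,
  so PPV = n_true/(n_true+n_false) exactly.
- **Strand groups**: antiparallel ladders ((i, j), (i+1, j−1), …)
  mined from the reference; optional jitter of one index by ≤ 2
  exercises the neighbour tolerance.
- **MSAs**: a query plus mutated copies with a per-column substitution
  rate (expected pairwise identity ≈ 1 − rate).

All generators are pure functions of a spec that includes the seed
(one `numpy` generator per operation, no global state). What the
fixtures do **not** emulate: real contact-score distributions, MSA
phylogenetic structure, alignment gaps from real homolog searches,
crystallographic disorder beyond "residue absent", or physically
relaxed geometry. Passing tests therefore demonstrate algorithmic
correctness of the selection/fusion/scoring rules, not predictive
performance on real proteins.

## Numerical and scale choices

- Restraint files print well depths to two decimals and integral
  bounds as integers, making outputs byte-identical across platforms;
  write→read is the identity on all fields.
- Score-matrix input must be symmetric within 1e−6; RR confidences are
  accepted unnormalized by default (strict [0, 1] behind a flag).
- Randomized cross-checks run at deliberately small problem sizes —
  fusion instances with L ≤ 40 and ≤ 30 top-L pairs (1000 instances),
  structures ≤ 50 residues, alignments with n ≤ 20 — where brute-force
  oracles are exact and fast; the algorithms themselves are
  size-independent.
- The top-L cardinality checks use chain lengths 87, 62 and 203 with
  ≥ 2L ranked predictions, the three worked-example targets for which
  the baseline restraint count must equal the chain length.

## Known limitations

- PDB input only (no mmCIF), single chain / first model; targets with
  one molecule per asymmetric unit are the intended case.
- No A3M parsing beyond gap-preserving aligned FASTA.
- Neff here is the cluster-count interpretation of fractional-weight
  summing; alternative weightings (e.g. per-sequence 80% identity
  weights) are not implemented.
- The toolkit emits restraints for, but does not drive, folding or MR
  software.
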