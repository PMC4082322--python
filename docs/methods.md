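# Methods

## Conservation scoring and domain delimitation

The per-column conservation score is the property-based count of
Livingstone & Barton's AMAS method: a column scores one point for each of
the ten Taylor/Zvelebil physicochemical classes whose membership status is
uniform down the column (all residues inside the class, or all outside).
The table is shipped as versioned package data
(`domainscout/data/properties.json`) and printable via
`domainscout conserve --print-properties`. Gaps and `X` are treated as
residues belonging to no class, so a gapped column loses every "uniformly
present" property but can still score "uniformly absent" ones; this
penalizes gaps without making scores undefined. Scores live on the 0–10
scale with 10 for identical columns. One documented degeneracy of the
classification: Ile and Leu carry identical fingerprints (hydrophobic +
aliphatic only), so a pure I/L column also scores 10.

Smoothing is a centered moving average (window 10, step 1 by default) with
edge truncation; for even windows the window at column *i* covers
`[i-(w-1)//2, i+w//2]`. Delimitation thresholds the smoothed curve
(threshold 4 by default, exposed because the plotted scale of the original
analysis is not fully specified): maximal runs of columns strictly above
threshold are merged when separated by ≤ `merge_gap` columns (default 10,
one smoothing window), runs shorter than `min_len` (default 25) are
dropped, and segments are minimally extended to include anchor residues
falling within `merge_gap` of a boundary. Reference coordinates count only
non-gap reference characters. Pairwise identity divides by positions where
both rows are non-gap (the common convention; alignment-length denominators
are available via a flag since conventions differ between tools).

## Profile HMM

The model is a Plan7-like chain of M match states with per-node
insert/delete states, uniform local entry `B→M_k = 1/M`, and per-node local
exit `M_k→E` (certain at the last node). It is HMMER-like but deliberately
not bit-compatible: no Dirichlet mixture priors, no filter pipeline, and
its own E-value semantics.

* Match columns: alignment columns with ≤ 50% gaps.
* Sequence weighting: Henikoff position-based (scaled to sum to n);
  `none` for unit tests.
* Emissions: mixture `p = (1−α)f + αg` with `α = 20/(20+n)`, observed
  frequencies `f`, and matrix pseudocounts `g_a = Σ_b f_b P(a|b)` where
  the conditionals are reconstructed from BLOSUM62 or BLOSUM90 log-odds in
  half-bit units (`P(a|b) ∝ q_a·2^{s_ab/2}`). A Laplace add-one fallback
  exists for didactic tests.
* Transitions: per-node counts over the seed's match/insert/delete paths
  plus fixed prior counts (M→{M,I,D,E} = 1.0, 0.1, 0.1, 0.1;
  I→{M,I} = 1.0, 0.3; D→{M,D} = 1.0, 0.3).
* Background: uniform 1/20 by default (a BLOSUM62-marginal preset exists),
  matching the synthetic generator's null.

Scoring is in log₂-odds bits against the i.i.d. background. Flanking
residues outside the aligned window are emitted by the null and contribute
zero bits, so a path's score is entry × transitions × emission odds; exits
are taken from match states only. Viterbi and forward share this exact
semantics (the test suite checks forward against exhaustive path
enumeration on small models) with ties broken toward the smaller start
coordinate. E-values come from Viterbi scores of `n_decoys` (default 200)
background sequences of length 2M, fitted by maximum likelihood to a
Gumbel law; `E(s) = N(1−exp(−exp(−λ(s−µ))))` for a database of N
sequences. Iterative search rebuilds the model each round from the seed
projected onto its match columns plus the Viterbi match-aligned rows of all
hits so far; reported hit lists are cumulative (best E-value retained), so
they are monotone non-shrinking, and iteration stops when the hit set is
stable or after `max_iter` (default 3) rounds at cutoff 10⁻¹⁰.

## Architecture census

Hits on one protein are resolved greedily by descending score; a candidate
is dropped when it overlaps a kept hit by more than max(10 residues, 20% of
the shorter hit). For fully conflicting hit sets this equals the max-weight
subset (tested against exhaustive enumeration). Census fractions use
target-containing proteins as the denominator; because annotation tables
do not always state their denominator convention, the same fractions over
all proteins are also reported. Display values round to one decimal; exact
values are kept internally.

## Trees

Sequence side: coverage filtering keeps sequences whose ungapped length is
≥ 70% of the model length; redundancy removal is a greedy, fully
deterministic analogue of CD-HIT computed exactly on shared alignment
columns (descending ungapped length, join the first representative at
≥ 95% identity); column trimming keeps columns with gap fraction ≤ 0.2 — a
single-rule simplification of TrimAl's automated heuristic, with kept/total
counts reported for comparison. Distances are p or Kimura-corrected
(`d = −ln(1−p−0.2p²)`, error at p ≥ 0.85). Neighbor joining is standard
Saitou–Nei with ties broken by the lexicographically smallest label pair
and negative branch lengths clamped to zero (logged). Bootstrap resamples
columns with replacement; saturated replicates are skipped and counted, and
supports are bipartition frequencies in [0, 1]. Maximum-likelihood
inference (model selection, ML optimization, aLRT supports) is out of
scope by design; externally computed newick trees can be ingested at any
downstream step.

Structure side: residue correspondence comes from a sequence MSA (columns
where both rows are non-gap) rather than a multiple structure alignment —
for families modeled on one template the two are nearly identical.
Superposition is Kabsch/SVD with the proper-rotation determinant
correction; collinear point sets are rejected. The distance is
`100·RMSD/n_aligned`, and the tree minimizes `E = Σ_{i<j}(d−p)²/d^P`
(`P = 2.0`) by stepwise taxon addition in input order, non-negative least
squares (NNLS) for branch lengths at every step, and
nearest-neighbor-interchange hill climbing until no move lowers E. Zero
off-diagonal distances are replaced by 10⁻⁸ (the 1/d² weight is undefined
at zero), with a log entry. The heuristic matches the brute-force global
optimum over all 15 topologies at five taxa in the tests; classic
Phylip-output equality is not a goal.

## Synthetic study conditions

The generators are pure functions of (parameters, seed) and write the
exact dialects the pipeline consumes.

* **Domain family** — n = 14 sequences, one 193-residue consensus domain
  drawn from a uniform background, per-site substitution probability
  p_sub = 0.16 (chosen so the expected pairwise domain identity,
  `(1−p)² + 2p(1−p)q + p²q ≈ 0.71`, matches the ~70% regime of the
  motivating seed family), background flanks of 30–120 residues (or fixed
  at 256 to emulate the reference's 257–449 domain placement). Substitution
  replacements are drawn from the background and may restore the consensus.
* **Search database** — 20 planted-domain targets plus 80 pure-background
  decoys of matched lengths, shuffled.
* **Architecture catalogue** — six architectures whose analytic fractions
  equal the published census shape exactly: single-copy 85.8%, target-only
  21.9%, GRAM co-occurrence 70.3% (VASt 0.219, GRAM-VASt 0.561,
  C2-VASt 0.048, Pex24p-VASt 0.030, GRAM-VASt-VASt 0.100,
  C2-VASt-C2-GRAM-VASt 0.042).
* **Tree-correlated alignments** — Jukes–Cantor-like on 20 letters: along
  a branch of length t each site substitutes with probability 1−e^(−rate·t)
  to a background letter.
* **Structures** — per group, a smooth random-walk Cα trace (3.8 Å steps,
  turning angle ≤ 40°); members add iid Gaussian noise (σ = 0.5 Å default)
  and a random rigid motion. All structures in a run share one sequence so
  MSA pairing is total.

What these do **not** emulate: indels, compositional bias, tree-correlated
domain families in the search database, database taxonomy, or realistic
protein geometry. Passing tests therefore demonstrate the correctness and
statistical calibration of the algorithms under their stated models, not
performance on real proteomes — in particular E-values are calibrated
against i.i.d. decoys, which is optimistic for low-complexity real
sequences.

## Numerical and scale choices

Problem sizes in the stochastic suites are desk-scale by design: search
benchmarks use 100-sequence databases (10–20 replicate seeds), iterative
search demonstrations use 40-residue domains and three-tier families, and
structure suites use 2 × 4 models of 100 residues. The full 193-residue /
14-sequence defaults are retained everywhere they are cheap (delimitation,
identity statistics, the recall benchmark). Other numerics: emission and
transition rows are validated to 10⁻⁹ at construction; degenerate decoy
score variance raises an error advising more decoys; the forward recursion
uses base-2 log-sum-exp prefix scans; NNLS guarantees non-negative branch
lengths so only NJ needs clamping; FM stepwise ties keep the first edge in
deterministic enumeration order.

## Known limitations

* Not bit-compatible with HMMER; absolute E-values are calibration-specific
  and should be compared only within a run.
* The single-best-path envelope reports one domain per target; additional
  copies on the same protein require masked re-search.
* Fitch–Margoliash uses a heuristic search; global optimality is verified
  only at small taxon counts.
* The iterative-search gain over single-pass search is modest under the
  generator's iid substitution model, which lacks the stepping-stone
  correlation structure that drives large jackhmmer gains on real families;
  the tests assert monotone recall and observed gains rather than a fixed
  gain rate.
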