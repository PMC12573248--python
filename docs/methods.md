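# Methods

## The model

`ghostshift` treats HGT order inference as a purely temporal problem on a
dated species tree. All times are **ages before present** in the units of
the input branch lengths (Ga for the eukaryogenesis trees); larger is
older, extant tips sit at age 0, and every branch is the interval
`[death_age, birth_age]` between the ages of its child and parent nodes.
This sign-free convention is why the acceptor window is written
`(feca_age, leca_age)` with the older bound first.

The acceptor is the stem lineage of a recipient clade. Its window is
located from two tip sets: the younger bound is the age of the MRCA of the
recipient tips, the older bound the age of the MRCA of recipient ∪ sister
tips. Both are point ages read off the tree (trees are assumed already
dated; no rate or date inference is performed, and posterior uncertainty
on node ages is out of scope).

**Donor branch space.** A branch is an eligible ghost-sister iff (i) all
its descendant tips belong to the donor domain tip set, and (ii) it
strictly overlaps the open window: `birth_age > leca_age` and
`death_age < feca_age`. Strictness matters: a branch merely touching a
bound would have an empty ghost-birth or transfer sampling interval. On
real trees the excluded set has measure zero. The acceptor branch and its
ancestors are excluded automatically because they are not in the donor
domain; no extra masking is applied. Zero- or near-zero-length branches
that pass the overlap test are kept.

**Ghost sampling.** One simulated donor = one sister branch drawn
uniformly over the space (the *branch* is the sampling unit, not its
duration), a ghost birth `g ~ U(max(death, leca), birth]` and a transfer
`τ ~ U(leca, min(g, feca)]`. All "random" choices are uniform — the
maximum-entropy reading of an otherwise unconstrained choice. This single
interval rule reproduces every per-branch case one can enumerate:

| branch vs window                  | ghost birth           | transfer                         |
|-----------------------------------|-----------------------|----------------------------------|
| spans the whole window            | `U(leca, birth]`      | `U(leca, min(g, feca)]`          |
| born before FECA, dies inside     | `U(death, birth]`     | same; whole window when `g > feca` |
| born inside, dies after LECA      | `U(leca, birth]`      | `U(leca, g]`                     |
| born and dies inside the window   | `U(death, birth]`     | `U(leca, g]`                     |

The fourth row is not usually enumerated; the unified rule is the unique
consistent extension. The ghost's death time is a formalism (any time
after the transfer) and plays no role in shift assessment, so it is never
sampled. Endpoint convention for all uniforms is half-open `(low, high]`
(`high − U[0,1)·(high−low)`); the choice is measure-zero but fixed so runs
are bit-reproducible.

**Pairs and shifts.** Each iteration draws two donors independently *with
replacement* (same-branch pairs are legitimate and populate the diagonal
of the clade-pair matrix). The *observed* age of a transfer is `g` for a
ghost donor and `τ` for a sampled donor. A pair is a **shift** when the
ordering by observed age strictly reverses the ordering by `τ`; ties
(probability zero under continuous draws) conservatively count as no
shift. Among shifted pairs, `outside_window` flags any member with
observed age `> feca_age` — such an inference predates the recipient's
origin, would be discarded as artifactual, and we flag the whole pair
because the comparison it supports would be discarded with it. The
confounding proportion is `shift × (1 − outside|shift)` per round by
construction.

**Ghost-proportion sweep.** Each pair member is independently a ghost with
probability p (Bernoulli); at p = 0 observed and true orders coincide and
the shift proportion is identically 0. The whole p-grid shares one set of
draws (common random numbers): each member keeps an auxiliary
`u ~ U[0,1)` and is a ghost iff `u < p`, so the curve's shape carries no
between-p Monte Carlo noise. This makes grid values seed-dependent in a
correlated way, which is intended and documented.

## Aggregation and uncertainty

An experiment is `n_rounds` independent rounds of `n_pairs` pairs
(defaults mirror the reference workflow: 1,000 × 1,000). Per-round
proportions give the Monte Carlo distribution; pooled statistics are
unweighted means across rounds, identical to pooling pairs because n is
equal per round, with empirical 2.5/25/50/75/97.5% quantiles. Rounds with
zero shifts have an *undefined* outside-given-shift and are excluded from
its pooling (not counted as zero); their confounding proportion is 0. The
clade-pair matrix pools pairs over all rounds by unordered label pair;
cells never sampled are reported as empty (NaN), not 0.

## Reproducibility

Round *r* of a run with master seed *s* uses the numpy substream
`SeedSequence(entropy=s, spawn_key=(r,))`, so per-round results are
order-independent and a fixed seed gives byte-identical output files.
Seeds are mandatory in the CLI and in `fit()`; every output TSV embeds the
version, seed and a hash of the resolved configuration (output paths are
excluded from the hash, since where results land does not affect what
they are).

## Synthetic data and what it does (not) show

The birth–death generator emulates a dated, fully sampled tree of extant
lineages: crown start (two lineages), constant per-lineage rates, extinct
subtrees pruned, stop at a tip count (with one extra exponential waiting
time appended so no terminal edge is zero-length) or at a fixed age. Ghost
lineages are *added analytically* by the simulator, never represented as
tips. It does **not** emulate: fossilized sampling, lineage-specific
rates, calibration/dating uncertainty, topological error, or the highly
uneven taxon sampling of real trees of life. Passing tests on synthetic
trees therefore validate the *simulation machinery and its probabilities*,
not any empirical claim about a particular tree; empirical conclusions
require the deposited dated reference trees (see README).

Hand-declared fixture spaces bypass tree construction but pass through the
same eligibility validation. The canonical **symmetric fixture** — one
donor branch born exactly at the older window bound and alive today —
has closed-form shift probability 1/4: scale the window to (0,1]; given
`g1 > g2`, a reversal needs `τ1 < τ2`, which has probability
`g2/(2·g1)`; and `E[min(g1,g2)/max(g1,g2)] = 1/2` for iid uniforms. The
constant was re-derived with the brute-force oracle before being frozen
into tests.

The oracle itself (`shift_probability_oracle`) is a deliberately naive
re-implementation — stdlib RNG, per-draw Python loop, intervals written
out from their definitions — sharing no code with the vectorized
simulator. Agreement within Monte Carlo error on randomized two-branch
configurations is the principal correctness gate. Its branch pair is
canonicalized by sorting before sampling so the estimate is symmetric in
its arguments under a fixed seed. When several oracle estimates are
combined (e.g. mixing the three unordered branch pairs of a two-branch
space), each cell must use its own seed: identical seeds would correlate
the cell errors and invalidate the independence-based standard error.

## Numerical choices

- Ultrametricity is checked as max deviation of root-to-tip path lengths,
  relative to the root age (default tolerance 1e-6); the worst-offending
  tip is named in the error. Tip ages are then snapped to exactly 0 so
  strict inequalities hold downstream.
- Newick is re-serialized at 17 significant digits so
  parse → write → parse preserves node ages; branch durations derived as
  age differences carry epsilon-level absolute error at root-age scale,
  which is the tolerance used when comparing them to literal branch
  lengths.
- Branch ids are `(alphabetically first descendant tip, clade size)` —
  unique within a tree (clades sharing their minimum tip are nested and so
  differ in size) and stable under pruning of other tips.
- Ancestral clade labels are mechanical joins of the distinct descendant
  labels (`"X+Y"`, sorted); tips without a label map to `"unassigned"`.
  Named ancestor tables are user data, not method.
- Pruning by explicit tip list only; partially organellar clades are the
  user's responsibility to enumerate.
- The vectorized experiment path draws, per round: all branch indices,
  then all ghost births, then all transfer ages, then all Bernoulli
  auxiliaries. The scalar `sample_ghost`/`sample_pair` API draws per ghost
  in order. Both are deterministic under a given generator, but the two
  paths do not produce bitwise-identical streams and are not asserted to.

## Problem sizes

Unit and property tests run at 10³–10⁵ pairs; oracle comparisons use
3×10⁴–10⁵ draws per configuration, sized so that 3 standard errors
resolve the differences being tested. The acceptance script uses
100 × 1,000 pairs for the symmetric fixture, ten random two-branch
configurations at 10⁵ pairs, and a 150-tip synthetic tree at
200 × 1,000 pairs — the full suite and script each complete in well under
a minute. The reference workflow on a deposited tree (1,000 × 1,000
pairs) takes seconds per experiment thanks to the vectorized sampler.

## Known limitations

- Point estimates only for FECA/LECA ages; no propagation of dating
  posteriors.
- Uniform ghost-birth and transfer densities are an assumption, not an
  inference; donor-lineage diversification is not modeled.
- No sequences, gene trees, or branch-length ratio machinery are
  simulated: the framework works directly in the time domain, so it
  quantifies the *temporal* component of ghost-induced error only.
- The clade-pair matrix conditions on the sampled sister's clade, which
  for deep donor branches is a composite ("X+Y") ancestor label.
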