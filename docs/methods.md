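# Methods

This note records the models, conventions and numerical choices behind
disparitree, and what the synthetic-data tests do and do not demonstrate.

## Data model and conventions

All ages are Ma before present. A dated tree stores absolute node ages;
branch durations are `parent_age − child_age`, and Newick input (durations
as lengths) is anchored either by placing the youngest tip at a given age
(default 0 Ma) or by an explicit tip-age table, which must agree with path
lengths to 1e-6 Ma. A stem edge above the root is parsed but ignored for
durations (no sampled ancestor above the root). Time bins are half-open
`[older, younger)` 1-Ma intervals from 37 to 0 Ma by default.

Character matrices keep missing (`?`) and inapplicable (`-`) cells distinct
in storage and in the audit, but every computation treats both as missing:
inapplicability is not modelled. Polymorphic cells are state sets; they are
never overwritten, count as observed in audits, and make a character
variant when the union of observed sets has two or more states (partial
information, as in common Bayesian treatments of polymorphism). The audit
reports the missing fraction under both conventions (with and without
inapplicable cells) because published figures rarely state which was used.

## Parsimony MPR engine

Ancestral states use most-parsimonious-reconstruction (MPR) sets: all
states a node takes in at least one minimum-cost assignment. Costs are
1{a≠b} for unordered and |a−b| for ordered characters. Rather than separate
Fitch/Hartigan and Farris interval passes, one generalized Sankoff dynamic
program covers both cost regimes plus hard polytomies, missing tips (zero
cost everywhere) and polymorphic tips (zero cost on the set): a postorder
pass accumulates per-state subtree costs, a preorder pass accumulates
rest-of-tree costs, and the MPR set at any node is the argmin of their sum
(ties at 1e-9). State universes are 0..max observed state per character
(declared symbols when a character is entirely missing — such characters
get the full set everywhere and length 0). The engine is verified against
exhaustive enumeration over all internal assignments on random instances
(≤8 tips, ≤4 states, both cost regimes, missing and polymorphic cells,
polytomies); agreement is exact.

The phylogenetically adjusted sample applies the singleton rule — "only
unambiguous reconstructions": a hypothetical ancestor (one per internal
branch, identified with the branch's child node) takes a state only where
its MPR set is a singleton; a missing tip cell is filled with the tip's own
MPR set (an unknown tip never constrains the passes, so no re-optimization
is needed) only when that set is a singleton. Observed cells, including
polymorphisms, are never modified. Alternatives (ACCTRAN/DELTRAN
resolutions) would fill more cells at the cost of arbitrary tie-breaking;
they are deliberately not implemented.

## Distances and ordination

The pairwise distance rescales the per-pair summed squared differences by
`C_total / |shared characters|` before the square root, so incompletely
scored rows are not pulled towards the origin; with no missing data it is
exactly the Euclidean distance on state vectors. A raw pairwise-deletion
variant (`rescale=False`) is available; at the ~7–14% missingness of
adjusted samples the two differ little. Polymorphic cells contribute the
minimum difference over cross-set pairs. Pairs sharing no characters are
dropped row-wise (greedily, most-incomparable row first) with a warning,
and are a hard error above 5% of pairs.

PCoA double-centers −½d² and takes a symmetric eigendecomposition.
Negative eigenvalues (possible because the rescaled distance is not
guaranteed Euclidean) are discarded; percent variance is over positive
eigenvalues only, and no Cailliez/Lingoes correction is applied — matching
the default behaviour of common ordination software. Axis scores satisfy
Σ scores² = λ, so the sum of per-axis sample variances over all positive
axes equals Σλ/(n−1) (checked to 1e-9), and reconstructed distances from
complete coordinates match inputs to 1e-9.

## Binned curves

Disparity per bin is the sum over the first k axes of the n−1 sample
variance of member scores. Defaults, stated because published work is often
silent on them: k is the smallest axis count reaching 95% cumulative
variance (an explicit k override exists); bin membership is any
positive-length overlap of a row's duration with the bin (a midpoint mode
exists); variance uses n−1. Bins with fewer than two members are flagged
undefined, never zero-filled. Bands are percentile bootstrap (default 1000
replicates, 95%), resampling members within bins independently, clipped to
bracket the point estimate (raw percentile intervals can exclude it by a
hair for tiny bins). Rarefaction draws n=8 members without replacement per
bin and reports the mean and percentile band; under-filled bins are
undefined. All resampling flows from a mandatory seed.

LTT diversity counts lineages alive at each 1-Ma boundary. Terminal
durations are closed at the younger end (a taxon still counts at its last
appearance; extant tips count at 0 Ma) while ghost-lineage durations are
half-open there (an internal branch hands over to its descendants exactly
at the split) — this makes the count at the root age equal the root degree
and the count at 0 equal the number of extant tips, with no double
counting at split boundaries. Boundary ages above the root count zero.
Taxon durations may be extended down to younger referred material for
diversity and disparity; rate curves never use those extensions, because a
branch's change is in place by the tip's oldest occurrence.

Rate curves average absolute rates (`relative × clock × 100`, %/Ma)
unweighted over branches overlapping each bin — "average across lineages"
— with a duration-weighted option; the band is ±SEM (sd/√n), zero for
single-branch bins.

## Synthetic data generator

The generator emulates the shape of a total-evidence dataset for a clade
radiating over the last ~38 Ma: defaults are birth 0.3, death 0.22 and
fossil-recovery ψ 0.7 per lineage per Ma from a single origin lineage at
38 Ma, rejection-conditioned on 60–130 sampled tips (mean ≈ 90); 272
characters of which 25/272 are ordered (4-state ±1 birth–death chains;
unordered characters binary); across-character Γ(shape 1, mean 1) factors;
i.i.d. mean-1 gamma branch multipliers with variance ν = 0.1 (a
duration-independent simplification of the independent-gamma-rates clock);
a whole-tree clock drawn from N(0.01, 0.1) truncated positive, emulating a
common clock-rate prior; uniform random deletion of 43% of cells (a
taxon-biased beta-weighted mode emulates fragmentary fossils); and a 5×
epoch multiplier over 38–30 Ma giving an early-burst regime. Fossil
occurrences fall as a Poisson process on extinct terminal branches; a
sampled fossil tip is dated at its oldest occurrence, its stratigraphic
record gets a 2-Ma uniform uncertainty window, and occurrences below the
window become younger referred material. Every draw comes from one seeded
generator, so identical configs give byte-identical fixtures (the truth
JSON includes tip ages for exact re-anchoring, per-branch multipliers, and
full per-character change histories whose replay reproduces the tips).

What the generator does **not** emulate: character correlation,
state-frequency asymmetries, selective (trait-dependent) extinction,
sampled ancestors, and stratigraphic age error in the tree itself (tips are
dated at their true oldest occurrence). Passing recovery tests therefore
show that the pipeline detects rate regimes and is robust to uniform
missingness at realistic scale — not that it corrects biases these absent
features would introduce.

## Recovery experiments and their limits

The two-epoch experiment (50-tip trees, 100 characters, clock fixed at
0.01 changes/character/Ma, 5× multiplier before 28 Ma, 20 seeded
replicates; trees redrawn until the crown spans the fast epoch) checks two
qualitative signatures: the binned rate curve built from the true
time-averaged branch rates separates the epochs (early/late mean ratio > 2
in ≥16/20 replicates; observed median ≈ 4), and the disparity peak
predates the diversity peak (≥16/20). The second signature is the weaker
one by design of the generative model: with neutral (trait-independent)
extinction, between-lineage variance accumulated in the burst persists, so
simulated disparity plateaus rather than declining the way empirical curves
do when disparate early clades die out; the peak ordering, not an early
absolute peak, is the honest expectation here.

## Pipeline

`run_pipeline` executes audit → ancestral states → disparity (full and
rarefied) → diversity → rates from one config (input paths or a simulation
block, exactly one of the two), writing TSV/JSON per stage plus a manifest
with a config hash (output directory excluded, so runs into different
directories compare equal), the seed and per-stage row counts — no
timestamps, so identical config+seed runs are byte-identical. For
simulated inputs the rate stage defaults to the truth clock; real inputs
must supply `clock_rate`. Stage failures abort with the stage name and
leave a manifest marked incomplete. The CLI exposes the stages as
subcommands and exits 2 on validation errors, 3 on computation failures.

## Known limitations

- Inapplicable states are treated as missing; no secondary-character logic.
- No likelihood or Bayesian ancestral states; no step matrices beyond unit
  and linear costs.
- Negative-eigenvalue corrections are off by default; strongly non-Euclidean
  distance matrices shift variance percentages.
- The LTT makes no attempt at sampling-standardized diversity.
- Analysis scripts 02–04 read the fixture written by script 01
  (`results/fixture/`), which is regenerated, not shipped.
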