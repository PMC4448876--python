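# disparitree

Macroevolutionary dynamics from dated phylogenies with fossil tips:
phylogenetically corrected **disparity through time**, **lineage-through-time
(LTT) diversity**, and **absolute evolutionary-rate curves**, for clades —
such as baleen whales — whose history is written in both extant species and
dated fossils.

Who it is for: palaeobiologists and systematists who have (i) a dated tree
whose tips include fossils at non-zero ages, optionally annotated with
per-branch relative clock rates from a relaxed-clock analysis, (ii) a
discrete morphological character matrix (NEXUS, states 0–9, `?` missing,
`-` inapplicable, `{..}` polymorphisms, ordered characters declared in an
ASSUMPTIONS block), and (iii) a stratigraphic range table (CSV). A seeded
synthetic-data generator (fossilized birth–death trees, independent-gamma
relaxed clock, Mk+Γ characters) provides study-shaped data with known truth,
so the entire pipeline is testable without any downloads.

## The methods in brief

**Disparity.** Rows of the sample (taxa plus hypothetical ancestors, see
below) are compared with a Euclidean-style distance on discrete characters:
per-character difference δ = |a−b| for ordered, 1{a≠b} for unordered
characters, rescaled for missing data,

d(i,j) = sqrt( (C / |S_ij|) · Σ_{k∈S_ij} δ_k² ),

where S_ij is the set of characters scored in both rows and C the total
character count. Principal coordinates analysis (PCoA; Gower double-centering
of −½d², eigendecomposition, negative eigenvalues discarded) embeds the
matrix; disparity in each 1-Ma bin is the **sum of sample variances** of the
member scores over the first k axes (default: smallest k reaching 95% of the
positive-eigenvalue variance), with 95% percentile bootstrap bands (1000
replicates) and an optional fixed-n rarefaction (n = 8 per bin).

**Phylogenetic corrections.** Three corrections counter the patchiness of
the fossil record: missing cells are filled with unambiguously reconstructed
parsimony ancestral states; each taxon ranges over its full duration in the
dated tree (ghost range, optionally extended to younger referred material);
and every internal branch joins the sample as a hypothetical ancestor
(ghost lineage) carrying its reconstructed morphology. MPR state sets —
states appearing in at least one most-parsimonious reconstruction, under
unit (unordered) or linear |a−b| (ordered) costs, with hard polytomies and
missing/polymorphic tips — are computed exactly by a Sankoff-style up/down
dynamic program; only singleton sets are used as fills.

**Diversity.** An LTT curve on the dated tree in 1-Ma steps: a lineage
counts at a boundary age while its duration spans it. Because fossil tips
drop out at their last appearance, the curve can decline — unlike
extant-only LTT plots.

**Rates.** Per-branch relative clock rates are converted to absolute rates
as `relative × clock × 100` (% change/Ma); e.g. a relative rate of 1.0 at a
median clock of 0.0018 changes/character/Ma is 0.18 %/Ma. The rate curve is
the unweighted mean over branches whose duration overlaps each 1-Ma bin,
banded by the standard error of the mean.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
dataset shaped like a ~90-taxon, 272-character total-evidence matrix:

```bash
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_ancestral_states.py
python analysis/03_disparity_through_time.py --seed 1
python analysis/04_diversity_and_rates.py
python analysis/05_recovery_experiment.py --seed 1
```

With `--seed 1` this prints (abridged):

```
tree: 86 tips (85 fossil, 1 extant), root age 37.9 Ma
matrix: 86 x 272 (25 ordered), missing fraction 0.431
observed matrix: 86 rows, missing 43.1%
adjusted sample: 170 rows (84 hypothetical ancestors), missing 14.2%
PCoA: 105 positive axes; first 45 cover 95.2% of variance
disparity peak in bin [2, 1) Ma: 60.88 (95% band 55.19-61.67)
rarefied (n=8) curve inside the full band in 100% of 24 doubly-defined bins
diversity: 10 lineages at present, peak of 22 at 6 Ma
rate ratio > 2 in 20/20 replicates (median 4.28)
disparity peak precedes diversity peak in 16/20
```

Reading this: ancestral-state filling plus hypothetical ancestors roughly
triple the usable cells (43% → 14% missing while doubling the rows); the
rarefied disparity curve tracks the full one, so bin sample sizes are not
driving the signal; and in the two-epoch recovery experiment the binned rate
curve clearly separates a 5× early-burst epoch from the later background
(median ratio 4.3). Curves land in `results/` as TSV
(`bin_older  bin_younger  n  value  lo  hi`).

The same stages are available as a CLI (`disparitree audit|asr|disparity|
diversity|rates|simulate|all`) and as plain library calls; `disparitree all`
runs everything from one YAML config and writes a manifest whose outputs are
byte-identical for identical config and seed.

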