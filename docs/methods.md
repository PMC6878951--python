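# Methods

`lucatrace` implements a decision framework for a classic question in
molecular evolution: did a gene family descend vertically from the last
universal common ancestor (LUCA), or did it arise inside one prokaryotic
domain after the archaea/bacteria split and spread by horizontal gene
transfer (HGT)? The motivating case is reverse gyrase (RG), the
helicase–topoisomerase fusion protein of hyperthermophiles, but every
component is generic to any two-domain presence/absence question.

## The decision rule

A gene family present in the LUCA should look like the universal marker
proteins (RNA polymerase subunits, elongation factors, rRNA):

1. **Domain monophyly.** Archaeal and bacterial sequences each form a
   clade; on an unrooted tree this is an edge whose bipartition separates
   the two domains exactly.
2. **A long interdomain stem.** The tempo of sequence evolution between
   the LUCA and the domain ancestors was high, so the edge separating the
   two domain crowns is long relative to the crown depths.
3. **Statistical robustness.** When monophyly fails in the inferred tree,
   forcing it back and comparing the constrained topology against the
   inferred one with likelihood-based tree-selection tests should *not*
   rescue it — for a genuinely post-LUCA gene the constrained topology is
   soundly rejected.

`GeneOriginModel.fit()` measures all three against a marker alignment
over the same species and reports one of:

- `CONSISTENT_WITH_LUCA`: both domains monophyletic, gene stem/crown
  ratio at least `stem_ratio_factor` (default 0.25) times the marker's,
  and the constrained topology not rejected by any test at `alpha`.
- `POST_LUCA_ORIGIN`: monophyly fails *and* the monophyly-constrained
  topology is rejected by every test in the battery.
- `INDETERMINATE`: anything in between — reported with the full evidence
  table so the user can see which sub-criterion failed.

The 0.25 stem-ratio factor is calibrated on the simulator (vertical
histories concentrate near ratio parity with the marker; post-divergence
histories that happen to end up monophyletic have ratios far below it);
it is exposed in the configuration and echoed in every verdict.

### Clade counts versus monophyly

`minimal_clade_count` computes the minimum number of label changes *s*
over all internal labelings of the two-state (domain) tip colouring — the
two-state parsimony score — by dynamic programming, and reports the
monochromatic components left after deleting the *s* change edges:
`sum(clade counts) = s + 1` always. Tied optima (different per-domain
splits of the *s* + 1 components) are all reported rather than resolved,
because drawn trees can be read either way. Note that a clade count of 1
does **not** imply monophyly: a connected "backbone" component of one
domain with the other domain's clades attached at two or more points has
count 1 but no separating edge. The monophyly flag therefore always comes
from the bipartition test.

### Stem statistics

When both domains are monophyletic, the stem is the unique separating
edge; crown depth is the mean tip-to-stem path per domain, and
`stem_ratio = stem / mean(crown depths)` (scale-invariant). For
paraphyletic trees these fields are explicitly undefined and a fallback
separation score is reported instead: mean between-domain minus mean
within-domain patristic distance, which tracks the "short interdomain
branches" observation even without monophyly.

### Constrained topologies

The rearrangement that restores domain monophyly is deliberately minimal:
each domain keeps its largest minimal clade; tips outside it are pruned
and regrafted next to the patristically nearest kept tip of their domain,
after which all branch lengths are re-estimated by maximum likelihood.
This gives the constrained hypothesis its best possible likelihood before
testing it. When the inferred tree is already monophyletic the constraint
is a fixed point and the battery is skipped (the verdict treats monophyly
as unrejected).

### Topology tests

All tests are RELL-based: per-site log-likelihoods are computed once per
topology (Felsenstein pruning) and only resampled afterwards, 10,000
resamplings by default. One joint resampling drives KH, SH and ELW, so
the conservativeness ordering p_SH >= p_KH holds replicate by replicate:

- **KH / weighted KH** — pairwise against the maximum-likelihood tree
  with the centered bootstrap null, one-sided by default (a two-sided
  flag exists). The weighted variant standardises by the per-pair
  standard deviation of site differences and picks the reference tree by
  the standardised statistic; for two trees it coincides with KH.
- **SH / weighted SH** — simultaneous comparison against the
  per-replicate maximum after centering every tree at its own expectation.
- **ELW** — per-replicate normalised likelihood weights, averaged.
- **AU** — multiscale bootstrap over ten scales 0.5–1.4; bootstrap
  proportions are fitted by weighted least squares to
  `Phi^-1(1 - BP) = d*sqrt(r) + c/sqrt(r)` with binomial weights and
  `p_AU = 1 - Phi(d - c)`. Proportions of 0 or 1 receive a 0.5/B
  continuity correction; exact ties in a replicate are split evenly; a
  degenerate fit (all proportions identical) falls back to the raw
  proportion with a warning.

Under an exchangeable two-tree null the measured type-I error of KH and
AU at alpha = 0.05 sits in the low 0.03–0.05 range (slightly
conservative), which the acceptance script re-measures on every run.

A classic Felsenstein bootstrap (resample columns, rebuild by neighbor
joining, count bipartitions) provides branch support; the ultrafast
bootstrap of large-scale ML programs is out of scope.

## The phylogenetic engine

The engine is intentionally minimal — enough to exercise every statistic
on simulated data, not a general ML tree searcher:

- **Models.** POISSON (equal rates/frequencies; every closed form used in
  testing follows from its 20-state symmetry) and WAG, both normalised to
  one expected substitution per site per unit length, with optional
  discrete-gamma rate categories (k equal-probability bins, default off).
  Transition matrices come from the eigendecomposition of the
  pi-symmetrised generator, so P(t) is exact for any t.
- **Distances.** Poisson-corrected distances
  d = -(19/20) ln(1 - 20p/19) over gap-free column pairs; saturated pairs
  (p >= 19/20) are capped at 10 substitutions/site with a warning. The cap
  only affects the neighbor-joining starting tree; branch lengths used in
  statistics are re-estimated by ML.
- **Neighbor joining** with deterministic tie-breaking; negative branch
  lengths are clamped to zero with the deficit moved to the sister edge.
- **Likelihoods** by pruning with per-node, per-site scaling; gaps are
  missing data; impossible configurations (conflicting states across a
  zero-length path) hit a -700 per-site floor rather than -inf.
- **Branch lengths** by coordinate-wise ML: each sweep computes inside
  and outside partial likelihoods once, then optimises every edge against
  them through the model eigenbasis (the per-edge likelihood curve is
  `sum_s log(C_s . exp(lambda t))`, so a Brent search costs microseconds).
  Simultaneous updates are accepted only if the total log-likelihood
  improves; otherwise the sweep retreats along the update direction and,
  as a last resort, walks edges sequentially — so the log-likelihood is
  non-decreasing across sweeps. Convergence tolerance 0.01 log units,
  default cap of 8 sweeps in the fitting pipeline.

## The synthetic-data generator

The generator produces the two competing histories the framework must
tell apart, plus the raw material of the curation stage. Its defaults are
the study conditions used throughout testing: 12 + 12 taxa, crown height
1.0 substitutions/site, stem 3.0, 2,000 alignment columns, POISSON model.

- **Species trees** are ultrametric in time: two Yule crowns rescaled to
  the crown height, joined by a stem edge of exactly the requested length
  with the root at its midpoint. Per-edge rate multipliers are exposed
  (default 1, i.e. time equals expected substitutions); nothing in the
  validation depends on a particular multiplier calibration.
- **Gene histories** are simulated by an event-driven walk down the
  species tree. `VERTICAL_LUCA` places the origin at the root; with all
  rates zero the gene tree equals the species tree exactly (the
  foundational invariant). `DOMAIN_ORIGIN_HGT` places the origin on the
  bacterial side and, by default, schedules three forced
  bacteria-to-archaea transfers at evenly spread times in the crown era
  on top of a background Poisson transfer rate of 0.1 events per carrier
  lineage per unit time. Restricting forced-transfer donors to bacterial
  carriers makes the archaeal copies enter the gene tree at distinct
  points — the interleaving pattern that breaks domain monophyly. A
  transfer replaces the recipient lineage's copy by default; an
  `additive` switch keeps both (emulating dual-copy lineages).
  Duplications copy in place. Every event is logged (type, donor edge,
  recipient edge, time), and the test-suite replays the log with an
  independent reconstruction to validate the scenario machinery.
- **Sequences** evolve without indels (alignment inference is out of
  scope); the trimming stage is exercised through gap masking instead.
  The observed mismatch fraction on a two-tip tree matches the 20-state
  closed form within binomial error — the generator's calibration check.
- **Hit tables** plant true two-domain fusion records (strong E-values,
  helicase plus topoisomerase envelopes on one target) among
  helicase-only, topoisomerase-only and weak-E-value decoys, emulating
  what a fusion-protein profile search returns. Coverage is expressed
  against nominal profile lengths (helicase 400, topoisomerase 550
  residues).
- **Split genes** are emitted as prefix/suffix fragment pairs with a
  configurable overlap and a pairing manifest; concatenation is its exact
  inverse for all overlaps tested (0–10).

What the generator does *not* emulate: indels and alignment error,
among-lineage rate variation beyond fixed multipliers, compositional
heterogeneity, long-branch-attraction artefacts from model violation, and
gene loss. Passing the scenario-recovery check therefore shows the
*inference logic* is sound under clean signal at these problem sizes; it
does not certify performance on real, saturated, compositionally biased
alignments.

## Curation stage

The screen module mirrors the dataset-construction decisions for a
fusion protein: an **inclusive** E-value cutoff at 1e-100 (inclusivity
is a committed choice and is logged), a two-domain architecture call with
a default minimum envelope coverage of 0.5 per domain (the source
procedure was a visual alignment check, so no published number exists;
overlapping envelopes of different labels resolve by bitscore),
split-gene concatenation with exact overlap verification (heuristic
same-organism pairing is available and always logged; curated manifests
are preferred), a scanner for the second zinc-finger motif
CxxC-x(9–11)-CxxC (non-overlapping, left-to-right, shortest spacer at
ties), mean pairwise identity over gap-free column pairs, and optimum
growth temperature summaries with 65 °C and 75 °C thresholds.

## Numerical and reproducibility choices

- Distance cap 10 substitutions/site; branch-length search bounded in
  [1e-8, 25]; per-site log-likelihood floor -700; ELW/AU tie tolerance
  1e-9.
- Every stochastic stage derives its generator from the master seed by
  SHA-256 stream splitting (`subseed(master, stage_label)`), so a run is
  reproducible from its config file alone and stages can be re-run in
  isolation. Two pipeline runs with the same config produce byte-identical
  verdict JSON.
- Newick round-trips preserve branch lengths to six significant digits;
  internal labels are read as support values; `.` gap characters
  normalise to `-`.

## Validation summary

The test-suite and `scripts/acceptance.py` recompute, from scratch:
pruning likelihoods against explicit enumeration over all interior-state
assignments (agreement < 1e-8); monophyly and clade counts against
exhaustive bipartition/labeling enumeration on random trees up to 12
tips; the analytic two-tip branch-length MLE; type-I error calibration of
KH and AU under an exchangeable null; origin-scenario recovery at the
study conditions above (both scenarios recovered in >= 90% of replicates,
typically 97–100%); exact curation round trips; and pipeline determinism.
Problem sizes in the default suite (e.g. 100 replicates per scenario,
2,000 sites, B = 2,000 resamplings; 30 replicates in the acceptance
script) are the package's chosen desk-scale study conditions.

## Known limitations

- The engine does no topology search beyond neighbor joining; with very
  short internal edges or heavy saturation the NJ topology itself can be
  wrong in ways branch-length re-estimation cannot repair.
- The verdict rule is two-domain (archaea/bacteria); eukaryotes or
  three-way questions are out of scope.
- Root placement classification assumes a reasonably clean outgroup; a
  deeply polyphyletic outgroup degrades to a largest-component heuristic
  with a warning.
- The replay oracle (and hence the strongest scenario-machinery check)
  covers replacing, duplication-free histories; additive transfers and
  duplications are validated by their own invariants instead.
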