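# Methods

This note documents the statistical machinery in `quillnet`, the data
conventions behind the bundled survey fixtures, the choices made where the
underlying methods admit more than one reasonable implementation, and what
the synthetic-data generators do and do not emulate.

## Data model and web assembly

The survey data live in six hand-transcribed TSV fixtures under
`quillnet/data/` (taxonomies, interaction records with zoogeographic
regions, per-host examination counts, the curated co-infestation table,
and the never-infested hosts).  The interaction fixture follows the host
spectra of the survey's specificity tables, which define the published
network: three host records that appear in the distribution table but not
in any spectrum or count row (*Streptopelia decipiens*, *Geophaps
plumifera*, *Ptilinopus jambu*) are outside the web; *P. jambu* keeps its
examination row in the prevalence table.

The weighted web is 25 parasites x 65 columbiform hosts (68 with the three
parrot hosts of *Peristerophila mucuya*; parrots are excluded from the
default network scope but drive the polyxenous specificity class).  Three
weighting conventions are supported:

* `prevalence` (default): the interaction strength is the prevalence score
  recorded in the survey table (percent of examined individuals infested,
  as printed there), with score 1 for associations known only from records
  without prevalence information.  This is the convention under which the
  published network indices are reproducible; the printed scores are used
  verbatim even where they disagree with the row's own counts, because the
  table as printed is the dataset the network analysis consumed.
* `counts`: the number of infested individuals (1 for literature records).
* `binary`: presence/absence.

The occurrence fixture keeps the printed prevalence/interval strings next
to the raw counts.  A `note` column flags rows whose printed values
contradict their own counts (a 2/7 row printed as 42%, four n = 1 rows
printed with the n = 2 interval 22.4-100, two display-rounding slips);
flagged fields are excluded from reproduction checks but never silently
corrected.

## Prevalence: Sterne exact intervals

Point prevalence is IP = 100·x/n.  The two-sided interval inverts Sterne's
exact binomial test: at each candidate proportion p the acceptance set
collects outcomes in decreasing order of probability mass until the
cumulative mass reaches the confidence level, ties broken toward the
smaller outcome so the construction is deterministic at symmetric p.  The
interval is the closure of the set of p whose acceptance set contains the
observation; endpoints are found by bisection to 1e-8 on p, reporting the
outer edge of the final bracket so that boundary ties (e.g. the p = 1/2
tie pair at x and n-x) remain covered.  Clopper-Pearson intervals are
implemented as an internal reference: Sterne's interval is never wider,
though its endpoints are not always nested inside Clopper-Pearson's — the
width comparison, not endpoint containment, is the tested property.
Simulated coverage at the 95% level stays above 94% across the tested
(p, n) grid.

Reported tables round half-up to one decimal.  Unknown counts propagate as
missing values and are never imputed.

## Network indices

**H2'** standardizes the two-dimensional Shannon entropy H2 of the
interaction distribution between the extremal entropies attainable under
the observed marginal totals: H2' = (H2max − H2)/(H2max − H2min).  For
integer webs the extrema honour discreteness: H2max by proportional fill
with largest-remainder adjustment under the marginal constraints, H2min by
greedy diagonal packing (largest remaining row total joined to largest
remaining column total).  For non-integer webs (the default
prevalence-score web) the continuous joint-entropy bounds apply:
max(Hr, Hc) ≤ H2 ≤ Hr + Hc.  This mirrors the behaviour of the standard
implementation in the field, which switches to the continuous bounds
whenever the web is not made of integers — and it is the convention under
which the published network-level value is recovered.

**d'** is the Kullback-Leibler divergence of a parasite's partner
distribution from partner availability (column marginals), standardized
between its attainable minimum and maximum given the row total: the
maximum fills the rarest partners first, each up to its observed column
total; the minimum distributes the row total as close to proportionally as
integer scores allow (largest-remainder allocation).  Because the
standardization is defined through integer allocations, non-integer webs
are rounded to whole score units (keeping observed links at ≥ 1) before
computing d'.

**Connectance** is definitional: realized links over rows x columns
(0.056 for the survey web).  The published headline connectance (0.90) is
not reproducible from the stated definition on a 25 x 65 web with 91
links; the pipeline logs this discrepancy and reports the definitional
value.  No acceptance target is tied to connectance.

**Nestedness temperature.**  The binary web is packed (rows and columns by
decreasing totals, ties by name) and each cell centre is placed in the
unit square.  The perfect-nestedness isocline is the curve
x^q + y^q = 1 whose enclosed area equals the observed fill (q solved by
bisection on the closed-form area Γ(1+1/q)²/Γ(1+2/q)).  A presence beyond
the isocline or an absence within it contributes (d/D)², the distance to
the isocline along the cell's diagonal normalized by that diagonal's
length; T rescales the mean contribution by the conventional factor
100/0.04145, and N = (100 − T)/100.  Because temperature is defined at the
maximally packed state, the marginal sort is refined by a deterministic
greedy relocation search minimizing total unexpectedness (fill, and hence
the isocline, is order-invariant, so each candidate order is scored as a
sum of fixed per-cell penalties).  Different published packing optimizers
stop at slightly different packings; this is the main source of small
deviations from published temperatures (here: N = 0.915 on the survey web
against a published 0.908).

**Null models.**  Two families are implemented.  The Patefield sampler
draws integer tables uniformly with both marginals fixed
(`scipy.stats.random_table`; non-integer webs are rounded first, keeping
observed links at ≥ 1) — marginal preservation is exact in every draw.
The cell-shuffle null permutes the positions of all cell values (keeping
the value multiset and connectance, not the marginals); rows or columns
emptied by a shuffle are dropped before computing indices.  The null
comparison for H2' follows the reference tool's null t-test, which is
built on the shuffle null; the survey's published null mean (≈ 0.56) is
recovered by that construction on the count web, whereas the
fixed-marginal null is far less specialized (mean H2' ≈ 0.05 on the
weighted web).  Both families reject the observed specialization at
p << 0.05; the analysis reports both.  Significance uses the two-sided
one-sample t-test of the null sample against the observed value.

## Modularity

Barber's bipartite modularity Q = (1/m) Σ (W_ij − k_i d_j / m) δ(g_i, g_j)
is maximized by simulated annealing over joint row/column labels with four
proposal kinds: single-node relabel (to an existing or fresh module),
module merge, random module split, and extraction of a linked
(parasite, host) pair into a fresh module.  The extraction move matters on
star-like webs, where a profitable two-node move is invisible to
single-node proposals.  Cooling is geometric (T0 = 1, ratio 0.99), with a
sparse sampling of the undirected hot phase above T = 0.05, a floor at
T = 1e-5, and a patience rule below T = 0.01; steps per temperature scale
with node count (max(200, 20·n)) so the 90-node survey web converges
within the schedule.  The best partition over restarts is polished by a
deterministic hill climb (single-node relabels plus pair extraction), and
module ids are ordered by descending module weight.  Determinism is per
(seed, restart).  On webs of ≤ 8 nodes the annealer reaches the enumerated
optimum (all set partitions) in ≥ 95% of seeded runs; the small-web tests
run a shortened schedule (T0 = 0.2, 120 steps/temperature), with the
default schedule exercised on the survey web.

On the survey web the optimizer reaches Q ≈ 0.847 with 16-17 modules.
The published partition (Q = 0.83, 20 modules) scores lower under the same
objective: the annealer merges a handful of host-sharing species groups
(e.g. *G. masalaje* + *P. lature*, which share two *Ducula* hosts) that
the original stochastic optimizer left separate.  The quoted exemplar
modules (the *G. metriopelia* single-host pair, the *G. zumpti* +
*M. lengai* multi-parasite module, the four-host *P. geopelis* module) are
reproduced.  Modules are classified single-host / multi-host /
multi-parasite, multi-parasite taking precedence.

## Specificity, co-infestation, zoogeography

Specificity applies the standard ladder (monoxenous → polyxenous) to the
host spectrum's taxonomy, resolved from the host fixture (subfamilies
Columbinae / Claravinae / Raphinae; parrot hosts carry their own order).
Co-infestation emits one pattern per unordered mite pair on every host
with ≥ 2 mite species, labelled Syr-Pic / Syr-Syr / Pic-Pic from the
mites' subfamilies, with a same-niche flag when the pair shares a
normalized quill-niche label on that host ("unknown" never counts as
shared).  Quill-niche labels pass through a documented synonym map onto a
controlled vocabulary; the bare "tail cov." is mapped to under-tail
covert.  Zoogeographic incidence is a boolean parasite x 9-region matrix
derived from the region codes of the interaction records (the distribution
table is the source; its own prose summary disagrees with it in a few
places, and the fixture follows the table).

## Parsimony

Characters are unordered, unweighted, multistate; missing "?" and
inapplicable "-" entries are fully ambiguous in Fitch scoring (no
reductive recoding).  Searches are unrooted; with ≤ 10 OTUs all
(2n−5)!! topologies are enumerated and scored (Fitch sets as bitmasks),
guaranteeing all most-parsimonious trees.  Tree statistics: CI = M/L,
RI = (G−L)/(G−M), RC = CI·RI, HI = 1−CI, with per-character minima
(observed states − 1) and maxima (determinate taxa − most frequent state);
a Goloboff fit sum (k = 3) is reported alongside without any published
expectation.  Bremer decay per ingroup clade is the extra length of the
best topology lacking that clade, found by scanning the full enumeration.
The ratchet (iterated 25%-reweighting perturbation + leaf-SPR hill climbs
over random-addition starts) serves larger matrices and cross-checks the
exact search; it recovers the exhaustive optimum on every seeded 6-taxon
trial in the test battery.

The study's own character supplement is not published, so no published
tree statistic is asserted anywhere; the pipeline demonstrates the
machinery on a synthetic 7-OTU matrix clearly labelled as such, and the
test battery validates the algorithms against brute-force oracles
(exhaustive internal-state enumeration for Fitch, full topology scans for
Bremer) and the homoplasy-free recovery property (unique MPT = generating
tree, CI = 1).

## Synthetic data

`synth` provides: Poisson block webs with planted modules (within/
background rates 3 / 0.05 by default — a strong, sparse contrast matching
the highly modular survey web; Poisson counts rather than Bernoulli so the
weighted indices are exercised), uniform fixed-marginal webs (the
Patefield sampler reused as a generator), binomial infestation counts at
stated true prevalences, and characters evolved one change per branch with
optional parallel origins.  Generators are deterministic under a fixed
seed and the writers emit byte-identical files.  They emulate statistical
structure only — no transmission or colonization biology, no taxonomic
correlation between hosts, no observation effort bias — so passing tests
demonstrate correctness of the estimators on well-specified structure, not
robustness to the messiness of real survey data.

## Problem sizes and determinism

The simulation studies use these sizes: Sterne coverage at
p ∈ {0.05, 0.2, 0.5} x n ∈ {4, 24, 50} with 10,000 draws per cell; index
ranges on 1,000 random small webs; null comparisons with 100 permutations;
modularity best-of-ten restarts on the survey web and best-of-two on
small-web batteries; ratchet-vs-exhaustive on 100 seeded 6-taxon matrices.
Every stochastic routine takes an explicit seed, and the pipeline manifest
records all seeds, versions and configuration needed to reproduce a run
byte-for-byte.

## Known limitations

* The nestedness temperature depends on the packing optimizer; values are
  comparable only between implementations that pack identically.
* The annealed modularity is a lower bound on the true optimum on large
  webs (on ≤ 8-node webs it is verified against enumeration).
* The prevalence-score weighting inherits the printed table's internal
  inconsistencies by design; the `counts` weighting provides the cleaned
  alternative.
* Sterne endpoints are reported to a 1e-8 bracket; published tables
  computed with coarser search grids can differ by one display unit in the
  first decimal.
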