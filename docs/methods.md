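# Methods

## Model and procedure

The package asks whether the target sets of miRNAs are arranged with respect
to protein complexes more coherently than chance predicts, in four stages
that share one statistical vocabulary.

### Association of target sets with complexes

Each unit — a single miRNA, or a cluster represented by the union of its
members' target sets — is tested against every complex with the
hypergeometric upper tail P(X ≥ N_c) for X ~ Hypergeom(N, K, N_t).  The
universe N is the union of all miRNA targets (N_T) and all complex members
(N_C); both the complex size K and the unit's target count N_t are restricted
to this universe before testing, so the contingency is internally consistent
(a protein outside the universe can occur on neither margin).  The tail is
summed in log space (logsumexp over log-pmf terms) so deep tails do not
underflow.

Records are materialised for every (unit, complex) pair with N_c ≥ 1 —
pairs with a single hit are needed downstream by the fold-change validation —
but significance additionally requires N_c ≥ `min_targets` (default 2): a
"co-targeted" complex means at least two distinct subunits hit.

Family-wise correction is Holm step-down by default (plain Bonferroni by
flag; both orderings of the raw p-values are always written out so either
reading can be reconstructed).  The correction family is a genuine design
choice, because "corrected for multiple testing of the miRNAs" does not pin
down whether the family is units, complexes or pairs.  Default scope
`pairs`: correct once over all materialised (unit, complex) pairs — the most
conservative well-defined reading.  Scope `units`: correct within each
unit's complexes, then Bonferroni-scale by the family of units (`family_m`,
defaulting to the number of miRNAs in the network or the number of
clusters), which mirrors a per-miRNA screen corrected across miRNAs.

`adjust_pvalues` takes the family size m as an explicit parameter with
m ≥ len(p): tests that were never materialised (miRNAs with no overlap
anywhere) still count toward the family.

### Co-expression of co-targeting miRNAs

Pairwise Pearson correlations of expression profiles (≥ 3 conditions
required; zero-variance profiles skipped and logged) are pooled over miRNA
pairs significant for a common complex and compared to all other defined
pairwise correlations with a one-sided two-sample KS test, alternative
"foreground stochastically greater", p = exp(−2mnD²/(m+n)) (the asymptotic
form; small-sample correctness is covered by brute-force ECDF oracles in the
tests rather than by printed constants).  Choices made where the design was
open:

* a pair targeting several complexes contributes its correlation **once**
  (deduplicated) to avoid pseudo-replication; `weight_by_complex` restores
  multiplicity counting;
* the background excludes the (unfiltered) foreground pairs, so foreground
  and background partition the defined pairs and nothing is double-counted;
* pairs removed from the foreground by the same-transcription-unit filter do
  not migrate into the background; their fraction is reported ("correlated
  miRNAs contained in one transcription unit" is read as a pair property —
  only pairs have a joint TU status);
* zero-variance and absent profiles are dropped with logged counts.

### Interconnectivity of clustered targets

Within a cluster, only the first member of each seed family in genomic order
is counted (family members share predicted targets by construction, which
would otherwise inflate the statistic).  The statistic is the number of PPI
edges with one endpoint in each of two target sets, summed over all
representative pairs; an edge inside the intersection of both sets counts
once (edge-set semantics), and the count is symmetric.  The null redraws the
same number of miRNAs uniformly without replacement from all non-cluster
miRNAs — matching sets of miRNAs, not degree-matched target sets, so null
target-set sizes vary exactly as the real ones do.  A `match_degree` option
bins candidates by target-set-size decile for users worried about degree
confounding, and `exclude_same_family` additionally removes the cluster's
family members from the candidate pool.

The permutation p-value uses the add-one rule (1 + #{null ≥ obs})/(1 + R),
so p ∈ [1/(R+1), 1] and a reported "p = 0" is impossible by construction.

Global summaries: a Wilcoxon signed-rank test of observed counts vs
per-cluster null medians (exact null distribution for ≤ 25 tie-free
differences, normal approximation with tie correction otherwise; ≥ 6
clusters required), and a Fisher 2×2 with rows {cluster, pooled null} and
columns {bridging, non-bridging candidate protein pairs}, aggregated over
all clusters and replicates.  The Fisher construction is under-determined by
its verbal description; the chosen table is recorded in the result's method
string so it can be swapped.

### Fold-change validation and duplex-site statistics

For a perturbed miRNA, the component pool is the union of members of every
complex containing ≥ 1 of its targets (significant or not — restricting to
significant complexes would leave too few measured proteins).  Measured
components are split into targets and non-targets and compared with a
one-sided KS test, alternative "targets stochastically smaller" (more
negative log2 fold change).  Each measured protein is used at most once per
miRNA and the two sides are disjoint by protein.

Site filtering keeps rows with p < 0.02 **and** energy strictly below the
empirical 25% quantile of the energy column — the lowest quarter, because
lower hybridisation energy means a more stable duplex.  The quantile is the
type-7 (linear-interpolation) estimate and is always computed on the
original table: the filter is deliberately not idempotent, and both the
quantile method and the direction are configurable and logged.  The
membership-overlap test (are site-level targets enriched among complex
members?) requires the universe size as an explicit argument; no default
proteome size is invented.  The "moderately down-regulated" fraction is
reported both matched (protein is a site target of the perturbed miRNA) and
pooled (site target of any miRNA), side by side.

## Synthetic scenarios

`SyntheticConfig` fixes the dimensions and planted effect sizes; defaults
are n_proteins = 400, n_complexes = 60 (sizes 4–10, membership capped at 3
complexes per protein, overlaps allowed as real catalogs have), n_mirnas =
80 with 8 clusters of 2–4 members and 64 seed families, π₀ = 0.02 background
targeting, π₁ = 0.8 within planted complexes, 26 expression conditions,
ρ = 0.6, δ = −0.3, σ = 0.2, and 5 fold-change perturbations.  These mirror
the regimes the analyses are designed for at roughly 1/25 of the scale of
the real catalogs, keeping every test and the acceptance script fast on one
CPU.

Construction details that matter:

* **Planted targeting.**  A planted single miRNA hits each member of its
  complex independently with π₁.  A planted *cluster* assigns each targeted
  subunit to exactly one member (chosen uniformly), so the cluster-level
  union carries signal that no single member shows — the situation the
  cluster-level test exists for.
* **Expression.**  Correlated groups (miRNAs planted on a common complex,
  and every polycistronic cluster) share a latent condition profile:
  x = √ρ·z + √(1−ρ)·ε, giving correlation exactly ρ in expectation without
  building a covariance matrix.  Profiles are shifted to a non-negative
  scale (10 + x), which leaves correlations untouched.
* **PPI.**  Edge probability `ppi_within` (0.4) inside each complex,
  `ppi_background` (0.01) elsewhere.
* **Sites.**  True sites echo the target network with p ~ U(0, 0.02) and
  energies ~ N(−25, 3); an equal number of decoy non-target pairs get
  p ~ U(0, 1) and energies ~ N(−12, 3).
* Every miRNA is guaranteed ≥ 1 target (a target-less miRNA would vanish in
  a two-column file round trip).
* All randomness flows from the single config seed through one generator;
  stage-local reseeding is forbidden, so a bundle is reproducible as a
  whole and two bundles differ only through their seeds.

`null_scenario` sets π₁ = π₀, ρ = 0, δ = 0 and flags the (retained) planted
assignment list inert, so calibration runs can still ask "would the planted
pairs have been called?".

**What the generator does not emulate** — and hence what passing tests do
not show about real data: seed-match sequence biology, 3'UTR architecture,
genomic coordinates, realistic tissue expression shapes (profiles are
Gaussian around a common level, real atlases are heavy-tailed and
tissue-specific), the size and degree distributions of real PPI networks,
and identifier harmonisation between gene symbols and protein accessions
(identifiers are opaque strings throughout; mapping is the caller's job).

## Calibration and validation regimes

The statistical acceptance tests run: a full sweep of the hypergeometric
tail against exhaustive subset enumeration for every contingency with
N ≤ 12; Wilcoxon and permutation p-values against 2ⁿ sign enumeration and
direct counting; 200 null scenarios (400 proteins, 60 complexes, 80 miRNAs,
π₀ = 0.02) for the family-wise error rate and the uniformity of per-cluster
permutation p-values at R = 200; 50 planted scenarios (π₁ = 0.8, 8-subunit
complexes, 10 planted pairs) for sensitivity and false complexes; 50
replicates each for co-expression and fold-change detection and their null
calibrations; 1,000 random instances for the PPI counting oracle; and a
40-row fixture for the site filter.  `scripts/acceptance.py` recomputes the
same quantities at reduced replicate counts (100/25/25/10) so a full run
takes under a minute.

Two regime choices deserve note.  The **calibration scenarios use
ppi_background = 0.2** (much denser than the default): the uniformity
diagnostic on permutation p-values is only meaningful when the count
statistic has near-continuous support, because with heavily tied discrete
counts the add-one p-value is conservative by construction — correct
behaviour, but indistinguishable from a bug in a KS-vs-uniform test.  The
**detection scenarios instantiate their stated preconditions**: the
co-expression check plants 40 assignments at 5 units per 8-subunit complex
(so ≥ 50 co-targeting pairs actually survive the association stage), and the
fold-change check raises π₀ to 0.12 so perturbed miRNAs carry ≥ 30 measured
in-complex targets, the regime its claim is conditional on.

## Numerical choices and degenerate inputs

* Hypergeometric tail: log-space summation; k = 0 returns exactly 1.
* Holm: stable argsort, running maximum, clipped at 1; ties in p keep input
  order.
* KS: ECDFs evaluated at all pooled sample points via searchsorted; D⁺ ≥ 0
  always holds at the pooled maximum, and D = 0 maps to p = 1.
* Wilcoxon: zero differences dropped; < 6 non-zero differences, or all-zero
  differences, raise rather than return a meaningless p.
* Pearson: zero-variance profiles raise a dedicated error; callers skip and
  log the pair.  Values are clipped to [−1, 1] against rounding.
* Catalog loading: complexes with < 2 distinct members are dropped with a
  warning (they can never be reported); identical member sets are merged
  keeping the lexicographically smallest id, making the catalog
  deterministic regardless of input order.
* Readers tolerate `#` comments and one header row; every parse error names
  its line number; no structurally invalid object is ever constructed
  silently.

## Known limitations

* The one-sided KS p-value is asymptotic; at very small sample sizes it is
  conservative relative to the exact distribution.
* The exact Wilcoxon path requires tie-free |differences|; with ties the
  normal approximation (tie-corrected variance) is used at any n.
* Permutation p-values are discrete; with R = 200 the finest resolvable
  level is 1/201.
* The global Fisher test treats pooled candidate pairs as exchangeable
  units, ignoring within-cluster dependence; it is a coarse global summary,
  not a per-cluster inference.
* Cluster definitions arrive pre-grouped; no genomic-coordinate parsing is
  attempted, and no identifier mapping between transcript, gene and protein
  namespaces is performed.
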