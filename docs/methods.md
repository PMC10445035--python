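# Methods

This document defines the models implemented by `ndgpmap`, the conventions
and parameter choices baked into the package, and their known limitations.

## 1. Deterministic and non-deterministic GP maps

A genotype space is the set of all strings of fixed length `L` over an
ordered alphabet of size `K` (`K**L` genotypes); two genotypes are
point-mutation neighbours when they differ at exactly one position, so every
genotype has `(K-1)·L` neighbours (`3L` for RNA).

A **deterministic (D) GP map** assigns one phenotype label per genotype
(many-to-one). A **non-deterministic (ND) GP map** assigns each genotype a
probability distribution `P(p|g)` over phenotype labels (many-to-many). For
RNA, `P(p|g)` is the Boltzmann distribution over a sequence's suboptimal
secondary structures; for other systems it can be any per-genotype
distribution. Phenotype labels are opaque strings throughout.

The **deterministic projection** of an ND map maps each genotype to its most
probable phenotype. Ties are broken by the lexicographically smallest label
so the projection is reproducible. For RNA the projection recovers the
conventional MFE-structure map (the MFE structure is the most probable
member of the ensemble).

An equivalent reading of an ND map is as a distribution over deterministic
maps: a **realization** draws one phenotype per genotype, independently,
with probability `P(p|g)`.

## 2. Quantities

With `N` the number of phenotypes in a deterministic map and `Ñ` the size of
the ND phenotype universe (every label appearing in any ensemble):

| deterministic | definition |
|---|---|
| `f_p` | neutral-set size over `K**L` |
| `rho_g` | fraction of neighbours with the same phenotype |
| `rho_p` | mean `rho_g` over the neutral set |
| `e_g` | number of distinct other phenotypes among the neighbours |
| `e_p` | number of distinct other phenotypes adjacent to the neutral set |

The ND quantities replace 0/1 indicators by probabilities:

* `f̃_p = (1/K**L) Σ_g P(p|g)` — equals `E[f_p]` over realizations exactly.
* `ρ̃_g = (1/(K-1)L) Σ_p P(p|g) Σ_{g'∈N(g)} P(p|g')` — equals `E[rho_g]`
  exactly.
* `ρ̃_p = [Σ_g P(p|g) Σ_{g'∈N(g)} P(p|g')] / [K**L · f̃_p · (K-1)L]` — a
  **ratio of exact expectations** (expected number of neutral neighbour
  pairs over expected neutral-set size times `(K-1)L`). It is *not* the
  expectation of the per-realization `rho_p`; see §7.
* `ẽ_g = Σ_p P(p|g) Σ_{p'≠p} (1 − Π_{g'∈N(g)} (1 − P(p'|g')))` — equals
  `E[e_g]` exactly (the inner product is the probability that no neighbour
  realizes `p'`).
* `ẽ_p = Σ_{p'≠p} (1 − Π_{g∈G̃_p} Π_{g'∈N(g)} (1 − P(p'|g')·P(p|g)))` —
  an approximation of `E[e_p]` that treats the per-(g,g') events as
  independent; see §7.

Normalized phenotypic evolvabilities divide by each map's own phenotype
count: `e_p / N` and `ẽ_p / Ñ`.

The **null model** for phenotypic robustness assigns phenotypes to genotypes
at random with the observed frequencies, giving `ρ̃_p = f̃_p`. Robustness
above this line indicates genuine neutral correlations (like phenotypes
clustering in sequence space).

Long products of `(1 − x)` are accumulated in log space with `log1p` and
short-circuit to probability 1 when any factor is exactly 0; sums that must
reduce bit-exactly in the point-mass limit use exactly-rounded `math.fsum`.

## 3. Validation: realizations and the exact oracle

Two independent routes validate the closed-form ND quantities:

* **Monte-Carlo**: `average_deterministic_quantities` draws 500 seeded
  realizations by default, computes the deterministic quantities of each,
  and reports streaming means and standard errors next to the ND values.
  Per-phenotype robustness/evolvability averages are conditional on the
  phenotype being present in a realization (`n_present` is reported);
  frequency averages are unconditional. Each genotype uses an independent
  RNG substream keyed by its rank, so sampling is iteration-order
  independent.
* **Exact oracle**: `exact_expectation_oracle` enumerates the full product
  of per-genotype supports (guarded at 10^6 joint states), yielding exact
  `E[rho_g]`, `E[e_g]`, `E[f_p]`, presence probabilities, conditional
  `E[rho_p | present]`, and the numerator/denominator decomposition whose
  ratio reproduces `ρ̃_p`.

The test suite pins `f̃`, `ρ̃_g`, `ẽ_g` and `ρ̃_p` against the oracle to
1e−12 on the toy map and 50 seeded random maps, and the array engine
(`fast.py`, a compiled CSR kernel over genotype ranks) against the
independent dict-based reference implementation.

## 4. Sample-based estimation

For spaces too large to enumerate (e.g. `4**30`), quantities are estimated
from a uniform i.i.d. sample of `n` sequences:

* `f̂_p = (1/n) Σ_{g∈sample} P(p|g)` (unbiased).
* `ρ̂_p`: the exact formula with both genotype sums over the sample and the
  ND neutral-set size replaced by `n·f̂_p`. By default `f̂_p` comes from
  the same sample (the estimator is then exactly the sample-restricted
  formula); external frequency estimates can be supplied.
* Genotypic quantities are computed exactly per sampled sequence — they
  depend only on the sequence's own neighbourhood, so they need no
  correction. Neighbour folds are memoized (`CachedFold`).
* **Phenotypic evolvability is refused for samples**: it depends on the
  whole neutral set, and a uniform sample of a huge space essentially never
  contains two neighbouring sequences, so no reliable estimator exists.
  The exhaustive-sample limit of the other estimators reduces exactly to
  the full-map values (tested).

A half-sample convergence diagnostic (`half_sample_diagnostic`) flags
phenotypes whose estimates have not stabilized at the given sample size.

## 5. RNA backend

* Engine: the ViennaRNA Python bindings (version recorded in every
  provenance header via `engine_version()`); default temperature 37 °C;
  `kT = GASCONST/1000 · (K0 + T)` is taken from the engine's constants
  (≈ 0.6163 kcal/mol at 37 °C).
* Ensembles: all suboptimal structures within an energy window of
  **15 kT ≈ 9.24 kcal/mol** above the MFE, enumerated with the engine's
  `subopt` routine (`uniq_ML=1`; the window is passed as
  `int(round(window_kbt·kT·100))` in the engine's 0.01 kcal/mol units).
  Reported energies are rounded to the engine's 0.01 kcal/mol grid.
* The **unfolded state** (open chain) is always part of the ensemble with
  characteristic free energy `G = 0.0 kcal/mol`, even when it falls outside
  the window. Probabilities are Boltzmann weights `exp(−G/kT)` renormalized
  over the retained set; `ensemble_record` reports the retained Boltzmann
  mass relative to the full partition function.
* Exhaustive maps: `build_rna_map(L)` folds all `4**L` sequences. Lengths
  ≤ 10 are desk-scale (length 9: ~1 minute; length 10: ~4 minutes); length
  12 takes hours and is supported through a streamed, checkpointed,
  resumable build (`tsv_path=...`, `.progress` sidecar).
* Shape-level maps (the length-30 protocol): per-structure Boltzmann
  probabilities are aggregated by level-2 abstract shape, with **isolated
  base pairs disabled** (`noLP`). Sampled shape maps are declared
  `complete=False` and flow through the estimator semantics.

## 6. Abstract shapes

`ndgpmap.shapes` implements shape abstraction natively (levels 1–5) and is
pinned against the engine's `RNA.abstract_shapes` by exact string comparison
on ensembles of random sequences (tests) — 10^4+ structures at level 2, all
five levels on a diverse subset. Conventions:

* hairpin-loop unpaired regions are never represented, at any level;
* level 1 marks unpaired stretches in exterior loops, multiloops, bulges
  and internal loops; level 2 only where a helix is interrupted (bulges and
  internal loops); level 3 drops all `_`; level 4 merges helices separated
  by one-sided bulges; level 5 merges across any interruption;
* the open chain maps to the shape `"_"` at every level. (The engine's
  routine errors on unpaired-only structures at levels ≥ 2; the package
  defines the unfolded shape uniformly instead.)

## 7. Approximations and limitations

* **`ρ̃_p` is a ratio of expectations**, not `E[rho_p]`. On small maps the
  two differ visibly (toy map, phenotype B: `ρ̃_B = 0.300` vs
  `E[rho_B] ≈ 0.213`); the difference vanishes as neutral sets
  grow. The oracle exposes both so the approximation is measurable.
* **`ẽ_p` assumes independence** across (genotype, neighbour) pairs when
  aggregating "phenotype `p'` is reachable" events. Events sharing a
  neighbour are in fact mutually exclusive within one realization, so
  `ẽ_p` can deviate from `E[e_p]`; `ẽ_g` does not suffer from this
  (within one neighbourhood the per-neighbour events are independent).
* **Regime classification is descriptive.** `neutral_correlation_report`
  labels each phenotype by whichever of the null line (`ρ̃ = f̃`, absolute
  residual) or the global log-linear fit (`ρ̃ = a + b·log10 f̃`) it sits
  closer to, and exposes both residuals plus the relative null residual.
  With few phenotypes (small `L`) the absolute comparison is dominated by
  the smallness of low-frequency robustnesses: maps with only dozens of
  phenotypes can classify *every* phenotype as null-regime even though
  mid-frequency phenotypes exceed the null robustness by 1–2 orders of
  magnitude in relative terms. The clean two-regime separation emerges only
  at scales with hundreds of phenotypes; use `resid_null_rel` when a
  relative criterion is wanted.
* **Engine-version contingency.** Ensemble contents, phenotype counts and
  correlation values for RNA maps depend on the folding engine's parameter
  set and version. All outputs carry the engine version in their
  provenance; comparisons across engine versions should expect small
  quantitative shifts (correlations within a few hundredths, counts within
  a few percent).
* **Scale choices.** The packaged acceptance run (`scripts/acceptance.py`)
  enumerates length 9 exhaustively and samples 1000 sequences at length 30;
  the test suite enumerates length 8. These keep the full pipeline —
  enumeration, projection, quantities, reports — identical to a full
  length-12 study while fitting in minutes; the length-12 build itself is
  provided (`build_rna12_map`, `ndgpmap build-rna --length 12`) but takes
  hours on one CPU.
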