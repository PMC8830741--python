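# Methods

## The mixture model

An observed genotype matrix `D` has one row per cell and one column per SNV
locus; entries are 0 (absent), 1 (present) or missing. Cells are assumed to
come from `K` latent subclones; subclone `k` carries a binary genotype
`C_k` and prior weight `π_k`. Conditional on the subclone, observed entries
are independent draws through an error channel:

    p(1|0) = α (false positive)      p(0|0) = 1 − α
    p(0|1) = β (false negative)      p(1|1) = 1 − β

Missing entries contribute a factor of one to the cell likelihood and are
excluded from every error-rate sum. This treats missingness as
non-informative (missing-at-random); it keeps all M-step updates in closed
form. The model ignores doublets, copy-number loss and site-specific error
rates; see Limitations.

### EM estimation

- **E-step**: responsibilities `γ_ik ∝ π_k p(D_i | C_k)`, computed in the
  log domain with log-sum-exp stabilisation (two `N×M×K` matrix products
  per iteration).
- **M-step**, in the order `C → β → α → π`, each sub-update a closed-form
  maximiser of the expected complete-data log-likelihood given the others,
  so the observed likelihood is non-decreasing:
  - `C_kj = argmax_{s∈{0,1}} Σ_i γ_ik log p(D_ij | s)` over observed
    entries; exact ties resolve to 0 (no mutation — conservative under
    infinite-sites-like priors).
  - `β = Σ_ik γ_ik #(D=0, C=1) / Σ_ik γ_ik #(D∈{0,1}, C=1)`, and the
    mirror-image update for `α`; both clamped to `[1e−6, 1−1e−6]` to avoid
    `log 0`. A zero denominator keeps the previous value and warns.
  - `π_k = Σ_i γ_ik / N`.
- **Convergence**: absolute log-likelihood change below `tol = 1e−6`, cap
  `max_iter = 300`.

`α` defaults to 0.01 and is **not** estimated unless requested
(`estimate_alpha=True`) or pinned to another value (`fixed_alpha`): the
platform FPR is usually known, and holding it fixed also removes a degree
of freedom that under-split models otherwise use to disguise themselves in
the model-selection score (see below). `β` is always estimated unless
pinned, because dropout varies strongly between experiments.

### Initialisation and search

The final solution depends on the start, so each fit runs
`n_restarts = 10` random initialisations for every initial `β⁰` in the grid
`{0.1, 0.2, 0.3, 0.4, 0.5}`: `π⁰` uniform, `α⁰ = 0.01`, `C⁰` = `K` distinct
observed cell rows with missing entries zeroed. The run with the best final
likelihood wins; ties keep the earliest run. All randomness flows from one
seed.

Two refinements address failure modes of plain EM on this model:

- **Dead-component rescue.** A component that no cell's posterior argmax
  points at can never re-separate (exact duplicates split responsibility
  forever; starved components decay). Such components are re-seeded with
  the genotype of the cell the current mixture explains worst and given
  weight `1/K` (renormalised), at most 12 events per run. The likelihood
  may transiently drop at a re-seed; these iterations are recorded on the
  fit and exempted from the monotonicity guarantee.
- **Genotype polish.** EM's `C`-update maximises the expected objective
  under the *previous* responsibilities, so a converged `C` need not be
  entry-wise optimal for the observed likelihood. After the winning run, a
  greedy pass flips the single best `(k, j)` entry while any flip increases
  the observed likelihood (each gain is exact and closed-form given the
  responsibilities), alternating with further EM sweeps until neither
  moves. On exhaustively enumerable instances this reaches the global
  optimum over all `2^(K·M)` genotype matrices at the fitted rates.

## Choosing the number of subclones

For a fitted model, every unordered cluster pair `(i, k)` is scored by
comparing the *expected* distance between their cells with the *observed*
one. Per locus, the probability that two cells from clusters with true
states `(s, t)` show different observed states (counting exactly one
missing as a difference) is

    p00 = 2α*(1−α*)(1−η)² + 2η(1−η)
    p01 = p10 = [(1−α*)(1−β*) + α*β*](1−η)² + 2η(1−η)
    p11 = 2β*(1−β*)(1−η)² + 2η(1−η)

with `η` the matrix-wide missing fraction. The expected distance `d(i,k)`
sums these over the loci categorised by `(C_i, C_k)`; the observed
`d̂(i,k)` is the mean ternary mismatch count over all cross-pairs of cells
(missing ≠ 0, missing ≠ 1, missing = missing, mirroring the `2η(1−η)`
term). The pair score is `exp(−(d−d̂)²)`, the model score `s_K` the mean
over pairs, with `s_1 := 0` so any separable structure beats homogeneity.
Clusters left empty by the hard assignment are dropped before scoring.

The search fits `K = 1, 2, 3, …` (each `K` seeded deterministically from
the global seed and `K`, with the full restart protocol) and stops once the
best `s_K` has not strictly improved (tolerance `1e−12`) for `κ = 10`
consecutive values, or `K` reaches `min(N, 50)`. The best-scoring fit is
returned; ties favour the smallest `K`.

### Statistical fragility of the score

Two properties of this score matter in practice, and both are documented
here because they bound what the package can promise:

1. **At `β* ≈ 0.5` the score loses its contrast**: `p01 = p11` exactly, so
   mutated loci contribute the same expected distance whether or not the
   cluster genotypes differ there. Only the both-absent category separates
   models, and an under-split fit can absorb that by inflating its fitted
   genotypes and `β̂`.
2. **A `K = 2` model has one pair and the fitted rates track the merged
   clusters' marginal statistics**, so its single gap `d − d̂` lands near
   zero more often than chance would suggest, while the score of a correct
   `K`-cluster fit is dragged below 1 by irreducible sampling noise and by
   doublets, which inflate observed distances by one to three loci at the
   benchmark scales. The result is an occasional catastrophic collapse to
   `K = 2–3` (roughly a quarter of runs at the 500×200, `β = 0.5` design;
   rarer elsewhere), which lowers the mean V-measure well below what the
   genotype-accuracy metrics suffer.

Holding `α` fixed removes one interpolation degree of freedom and measurably
improves `K` recovery at high `β`; nothing in the score's form removes the
single-pair lottery. Likelihood-based criteria would discriminate these
cases strongly (the true-`K` fit typically leads by thousands of nats) but
are outside this package's selection scheme.

## The simulator

`simulate_dataset` generates ground-truthed data by the process the model
family assumes, plus the two corruptions it does not model:

1. a subclonal tree grows from a root: node 1 attaches to the root, each
   later node to a uniformly chosen existing non-root node;
2. each of `M` mutations lands on exactly one uniformly chosen edge
   (infinite sites: acquired once, never lost);
3. cells pick subclones with probability proportional to current subclone
   size (pseudo-size one each), yielding right-skewed clone sizes; empty
   subclones are topped up with one reassigned cell so truth labels stay
   usable;
4. a cell's true genotype is the union of mutations on its root path;
5. `round(ρN)` cells become doublets: their row is OR-merged with the row
   of a uniformly chosen other cell (a doublet shows a mutation if either
   constituent cell carries it); noise is applied after merging;
6. per entry, independently: missing with probability `η`, else `0→1` with
   probability `α` and `1→0` with probability `β`.

Defaults `(α, β, η, ρ) = (0.01, 0.2, 0.2, 0.1)` reflect reported scDNA-seq
error regimes. Preset factories `D1`–`D7` reproduce the benchmark designs
used in the tests (D1: 500×200, `K=10`, `β` up to 0.5; D2: the same at
`η` up to 0.5; D3: 1000×500 at `β=0.8`; D6: 200×50, `K=5`; D7: 100×100,
`K=5`, `α ~ U(0.01, 0.1)`, `β ~ U(0.05, 0.4)`; presets that sweep a factor
default to the hardest listed value).

What the simulator does **not** emulate: read-count-level noise (coverage,
allele fractions), copy-number events, site- or cell-specific error rates,
and spatially or temporally structured sampling. Passing the simulation
benchmarks therefore demonstrates correctness of the inference machinery
under the model's own assumptions plus doublets and missingness — not
robustness to every artifact of real data.

## Evaluation metrics

Clustering is scored by the V-measure (harmonic mean of homogeneity and
completeness, computed from contingency-table entropies; an independent
scikit-learn implementation cross-checks it in the tests). Genotype
recovery compares the predicted matrix `Z` (row `i` = inferred genotype of
cell `i`'s cluster) with the simulated truth `Z*`: accuracy (all entries),
sensitivity (true 1s called 1) and specificity (true 0s called 0).
Doublets have no single true label or genotype, so all metrics drop them.

## Lineage sketch

Inferred subclone genotypes (plus an all-zero root) are joined by a minimum
spanning tree under Hamming distance, with lexicographic edge insertion so
Kruskal tie-breaks deterministically. Under infinite-sites evolution the
MST of the true clone genotypes recovers the ancestry chain; it is a
display-quality sketch, not a substitute for phylogeny inference.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on instances up to a few hundred cells; the
end-to-end checks use 10 replicates of the 200×50 design, 5 replicates of
500×200 at `β = 0.5`, 3 at `η = 0.5`, 2 of 1000×500 at `β = 0.8` (with a
2-point `β⁰` grid and 4 restarts), 50 fits of the 100×100 design, and
200 exhaustively enumerated tiny instances. The acceptance script runs the
same designs minus the 1000×500 one. These sizes were chosen so a full run
completes in minutes on a single CPU while keeping the Monte-Carlo error of
each reported mean well inside the tolerances quoted for it.

## Known limitations

- No explicit doublet component: doublets bias `α̂` upward and the
  selection score downward; they are excluded from evaluation but not from
  fitting.
- The `K`-selection score is fragile at `β ≈ 0.5` and vulnerable to
  single-pair flukes at small `K` (see above); on such regimes the
  clustering V-measure has a heavy lower tail across seeds even though
  genotype accuracy stays high.
- Missingness is assumed non-informative; systematically missing loci
  (e.g. coverage dropout correlated with copy number) violate this.
- Error rates are global; per-site or per-cell rates are not modelled.
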