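# Methods

This note records what the package computes, the default parameters and why
they were chosen, what the synthetic generator does and does not capture, and
the numerical conventions a user may need when comparing against other
implementations.

## 1. Alignment handling

**Alphabet.** The modelling alphabet is the 20 amino acids in alphabetical
order followed by the gap: `ACDEFGHIKLMNPQRSTVWY-` (gap index 20). Ambiguous
or non-standard residue codes (`B J O U X Z *`) carry no usable state and are
mapped to the gap on input. Synthetic models may use reduced, gap-free
alphabets (the first q amino-acid letters); all downstream code is generic in
q.

**A2M convention.** In FASTA/A2M input, lowercase letters and `.` mark insert
states; a column is a focus (match) column only if no row marks it as an
insert. Only focus columns are modelled; their original 1-based indices are
kept in the model's `index_map` so mutation tables report positions in the
input numbering.

**Distance.** All identity/distance computations use normalized Hamming
distance over focus columns: gap↔residue counts as a mismatch, gap↔gap as a
match. This single convention is used for filtering, reweighting, and every
design penalty.

**Filtering.** Fragment sequences covering less than 50% of the target's
non-gap positions are removed first, then columns with more than 30% gaps.
The target row is never dropped. Order matters (fragments inflate column gap
fractions) and the filter is idempotent.

**Reweighting.** Each sequence gets weight `w_s = 1 / |{t : D(s,t) < θ}|`
with θ = 0.2 (the set includes s itself, so weights lie in (0, 1]). The
effective sample size is `Neff = Σ w_s`. The reweighted consensus takes the
weight-maximal non-gap symbol per column, breaking ties toward the lower
alphabet index.

## 2. Pseudolikelihood inference

The estimator minimizes the weighted negative log pseudolikelihood — for each
sequence and each site, the conditional log-likelihood of the observed symbol
given the rest — plus L2 penalties `λ_h‖h‖² + λ_J‖J‖²`.

- `λ_h = 0.01` by default; `λ_J = λ_h · (L−1) · (q−1)` scales the coupling
  penalty with the number of interaction partners per site, the standard
  plmDCA heuristic that keeps the per-parameter shrinkage comparable between
  fields and couplings across problem sizes.
- `J` is estimated asymmetrically (each site's conditionals own their rows)
  and the returned couplings are the symmetrized average
  `J_ij(a,b) ← (J_ij(a,b) + J_ji(b,a)) / 2`; self-couplings are zero.
- Optimization: scipy L-BFGS-B with an analytic gradient (verified against
  finite differences to relative error < 1e−6). Defaults `maxiter = 500`,
  `gtol = 1e−5`, `ftol = 1e−9`. The objective is strictly convex (L2
  penalties), so non-convergence only means the iteration cap was reached; it
  emits a `RuntimeWarning` and is flagged in the results and in the model
  metadata — never silently ignored.

The interface follows the statsmodels convention: `PottsPseudolikelihood`
(data + hyperparameters) → `.fit()` → `PlmResults` with the estimated
`PottsModel` in `.params` and a `summary()` table of fit diagnostics.

## 3. Statistical energy and scans

`evh` sums fields and strict upper-triangle couplings. `delta_evh` computes
multi-site mutation effects incrementally (fields, cross-terms to unmutated
positions, and within-mutation pairs) and agrees with full recomputation to
1e−9 relative — this is a tested contract, since the samplers rely on it.
`mutation_matrix` enumerates all `L × (q_design − 1)` single substitutions
(gap is never proposed as a design state). `epistasis` returns the closed
form `ΔΔ = J(a',b') − J(a',b) − J(a,b') + J(a,b)`; note only such double
differences of `J` are gauge-invariant, so individual matrix entries should
not be interpreted in isolation.

## 4. Design

**Batch Gibbs sampler.** A batch of M sequences is annealed jointly under
the penalized energy U (statistical energy plus target-band, batch-diversity
and MSA-novelty penalties). One sweep performs `M × L` single-site updates at
uniformly random (member, position) slots; the inverse temperature rises
linearly from 0.5 to 10 over the sweeps. Defaults: `M = 6`,
`n_sweeps = 1000`, `λ_T = 1000` (a hard wall: one band violation outweighs
any achievable EVH gain), `λ_D = λ_A = 10` (soft: a few units of EVH can
buy a marginal proximity violation), `d_max = d_min + 0.05`, and
`d_div = d_aln = d_min`. These defaults are the study conditions used by the
acceptance benchmarks.

Because the diversity penalty is symmetric in (a, b), flipping a site of
member *a* changes both `U_a` and every `U_b`; the Gibbs conditional
therefore counts each batch-pair indicator twice. The implementation keeps
incremental mismatch counters (to the target, within the batch, and to every
MSA row) so one update costs O(M + n_msa + q) instead of a full energy
recomputation.

**Determinism.** All randomness comes from `numpy.random.default_rng(seed)`;
the (member, position, uniform) streams are pre-generated, so the compiled
numba kernel and the pure-Python reference implementation replay *identical*
trajectories — this is tested, and is the package's main defence against
kernel bugs. Numba caching is disabled; kernels JIT-compile on first use
(a few seconds).

**Greedy hill climb.** Steepest ascent over all single substitutions,
accepting only strictly positive gains, breaking ties toward the first
(position, alphabet-index) maximum. Verified to agree exactly with an
exhaustive-recomputation oracle on enumerable models.

**Parallel tempering.** Default 19 replicas with base inverse temperatures
evenly spaced in [0.1, 1.0], each annealed geometrically by factor 1.002 per
sweep (×~7.4 over 1000 sweeps). After each sweep, adjacent replicas attempt a
Metropolis configuration swap with acceptance `min(1, exp(Δβ·ΔU))`,
`U = −EVH`. The best-EVH sequence ever visited by any replica is returned,
with its score. At least two replicas are required — a single chain is plain
annealing and the swap machinery would silently degenerate, so it is rejected
with an error.

## 5. Evaluation

**Coupling maps.** Pair scores are Frobenius norms of `J_ij` over the
*non-gap* states (gap statistics reflect alignment structure, not contacts).
The average-product correction (APC) subtracts `row_mean × col_mean /
grand_mean`; means are taken over the full matrix including the diagonal so
that exact rank-one score matrices are annihilated to machine precision
(≤ 1e−9, a tested contract). Implementations that exclude the diagonal
rescale the correction by O(1/L) without changing top-pair ranking in our
tests. The diagonal is zeroed after correction. Contact precision is the
fraction of the top-n APC pairs (minimum sequence separation 5 by default)
that are true contacts.

**Mutational-scan comparison.** `dms_compare` merges a ΔEVH scan with an
experimental table on (position, mutant) and reports Spearman's ρ per
replicate (scipy), requiring ≥ 3 matched mutations. `fitness_defect_flags`
marks mutations with score < −1 (strict) in *any* replicate.

**Design forensics.** `quadrant_analysis` classifies each design mutation by
the sign of its effect in the wild-type background vs. the design background
(reversion effect negated), exposing entrenchment and sign epistasis;
zero effects count as non-positive. `random_mutation_baseline` draws k-point
mutants for calibration. `reverse_translate` builds DNA for a designed
protein from the wild-type gene: unchanged residues keep their codon, changed
residues take the codon whose usage frequency is closest to the replaced
codon's (alphabetical tie-break), using a standard codon table (bacterial,
id 11, by default).

## 6. Synthetic ground truth: realism and limits

The synthetic module is the package's test bed: `planted_model` draws sparse
interaction graphs (random with minimum sequence separation, or chains) with
Gaussian couplings and fields; `enumerate_boltzmann` gives exact state
probabilities for small (L, q); `sample_msa` draws i.i.d. sequences either
exactly (inverse CDF on the enumerated distribution) or by a burned-in,
thinned Gibbs chain; `synthetic_dms` adds i.i.d. Gaussian noise to true ΔEVH
values; `two_basin_model` is a ferromagnetic ring with two competing ground
states for testing global optimization.

Deliberate limits: samples are equilibrium-independent draws — there is **no
phylogeny**, so the redundancy-reweighting machinery is exercised but not
stressed the way real family trees stress it; no alignment errors, no
fragment/gap structure unless injected; Gaussian couplings lack the sparse,
contact-driven topology statistics of real proteins; synthetic scan noise is
homoscedastic. Conclusions about statistical efficiency on real MSAs should
not be read off synthetic recovery numbers.

**Benchmark problem sizes** (chosen to give unambiguous oracles at interactive
runtimes, and frozen before the acceptance thresholds were tested): sampler
TV distance on L = 6, q = 3 (729 states, 1e5 sweeps); constraint satisfaction
on L = 40, q = 20 with a 50-sequence MSA, 20 seeded runs at the default
design parameters; greedy agreement on 100 random L = 5, q = 3 models;
tempering on the enumerable two-basin model, 20 seeded runs; interaction
recovery on L = 30, q = 8, 30 edges, 2000 sequences, precision of the top 30
APC pairs.

## 7. Numerical conventions and edge cases

- Model files (`.evhm`) are a one-line JSON header plus little-endian float64
  `h`, `J` and int64 `index_map` / `target_seq` payloads; round trips are
  bit-exact. Truncated files and unknown versions fail with explicit
  messages.
- Ties are always broken deterministically toward the lowest index
  (consensus symbol, greedy move, codon choice alphabetically); seeds fully
  determine every stochastic path, and derived seeds stay below 2³¹.
- Degenerate inputs fail loudly with the offender named: ragged alignments,
  empty files, all-gap consensus columns, filters that would remove every
  sequence, weights that don't align 1:1 with records, mutation indices out
  of range, single-replica tempering.
- Pairwise weight computation is chunked to bound memory at ~20 M boolean
  comparisons per block, so large alignments never materialize an n × n × L
  array.
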