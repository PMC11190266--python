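"""Sequence design: penalized batch Gibbs sampling, greedy ascent, tempering.

A batch of M candidate sequences is sampled from the joint Boltzmann
distribution of the penalized batch energy

    U(s_1..s_M) = sum_a U(s_a)
    U(s_a) = -EVH(s_a)
             + lam_target  * 1[D(s_a, target) not in [d_min, d_max]]
                           * |D(s_a, target) - d_min|
             + lam_diversity * sum_{b != a} 1[D(s_a, s_b) < d_diversity]
             + lam_alignment * sum_b 1[D(s_a, msa_b) < d_alignment]

with D the normalized Hamming distance. The inverse temperature is
annealed linearly (default 0.5 -> 10 over 1000 sweeps; one sweep is
M*L random single-site updates). Gap states are never proposed: designs
are full-length proteins.

Two single-sequence optimizers complement the batch sampler: a greedy
hill-climb that repeatedly applies the single most favorable point
mutation, and annealed parallel tempering (19 replicas by default) for
global optimization on rugged landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .alphabet import GAP
from .msa import Alignment
from .potts import PottsModel, evh


@dataclass
class DesignConfig:
    """Hyperparameters of the penalized batch design sampler.

    Defaults reproduce the published setting: lam_target = 1000,
    lam_diversity = lam_alignment = 10, d_max = d_min + 0.05,
    d_diversity = d_alignment = d_min, beta annealed 0.5 -> 10 over
    1000 sweeps, batch size 6. A "70% identity" design goal maps to
    d_min = 0.30.
    """

    d_min: float = 0.30
    d_max: float | None = None
    d_diversity: float | None = None
    d_alignment: float | None = None
    M: int = 6
    lambda_target: float = 1000.0
    lambda_diversity: float = 10.0
    lambda_alignment: float = 10.0
    beta_start: float = 0.5
    beta_end: float = 10.0
    n_sweeps: int = 1000
    seed: int = 0
    mode: str = "gibbs"
    # tempering-specific knobs
    n_replicas: int = 19
    tempering_beta_low: float = 0.1
    tempering_beta_high: float = 1.0
    tempering_growth: float = 1.002

    def __post_init__(self) -> None:
        if self.d_max is None:
            self.d_max = self.d_min + 0.05
        if self.d_diversity is None:
            self.d_diversity = self.d_min
        if self.d_alignment is None:
            self.d_alignment = self.d_min
        if not (0.0 <= self.d_min < self.d_max <= 1.0):
            raise ValueError("require 0 <= d_min < d_max <= 1")
        for lam in (self.lambda_target, self.lambda_diversity, self.lambda_alignment):
            if lam < 0:
                raise ValueError("penalty strengths must be non-negative")
        if self.M < 1:
            raise ValueError("batch size M must be >= 1")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.mode not in ("gibbs", "greedy", "tempering"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_replicas < 1:
            raise ValueError("need at least one tempering replica")


@dataclass
class DesignResult:
    """Batch design output: sequences, energies, traces, constraint flags."""

    sequences: list[str]
    evh: np.ndarray
    U: np.ndarray
    target_penalty: np.ndarray
    diversity_penalty: np.ndarray
    alignment_penalty: np.ndarray
    trace_total_U: np.ndarray
    trace_beta: np.ndarray
    target_band_ok: np.ndarray
    min_batch_distance: np.ndarray
    min_msa_distance: np.ndarray
    seed: int
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# energies and penalties (reference implementations)


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a != b))


def penalty_terms(seq, batch_others, target_seq, msa, cfg: DesignConfig,
                  model: PottsModel | None = None):
    """Per-member penalty triple (target, diversity, alignment).

    ``seq``/``batch_others``/``target_seq`` are encoded index arrays (or
    strings if ``model`` is given); ``msa`` is an Alignment, an encoded
    matrix, or None.
    """
    enc = (lambda s: model._as_indices(s)) if model is not None else np.asarray
    s = enc(seq)
    t = enc(target_seq)
    L = s.shape[0]
    if t.shape[0] != L:
        raise ValueError("target length mismatch")

    d = _dist(s, t)
    tpen = cfg.lambda_target * abs(d - cfg.d_min) \
        if (d < cfg.d_min or d > cfg.d_max) else 0.0

    dpen = 0.0
    for b in batch_others:
        if _dist(s, enc(b)) < cfg.d_diversity:
            dpen += cfg.lambda_diversity

    apen = 0.0
    X = _msa_matrix(msa, L)
    for n in range(X.shape[0]):
        if _dist(s, X[n]) < cfg.d_alignment:
            apen += cfg.lambda_alignment
    return tpen, dpen, apen


def _msa_matrix(msa, L: int) -> np.ndarray:
    if msa is None:
        return np.empty((0, L), dtype=np.int64)
    if isinstance(msa, Alignment):
        X = msa.encoded()
    else:
        X = np.asarray(msa, dtype=np.int64)
    if X.ndim != 2 or X.shape[1] != L:
        raise ValueError("alignment rows must match sequence length")
    return X


def batch_energy(batch, model: PottsModel, target_seq, msa, cfg: DesignConfig):
    """Per-member penalized energies U(s_a) and their total."""
    members = [model._as_indices(s) for s in batch]
    U = np.empty(len(members))
    for a, s in enumerate(members):
        others = [m for b, m in enumerate(members) if b != a]
        tpen, dpen, apen = penalty_terms(s, others, target_seq, msa, cfg, model=model)
        U[a] = -evh(model, s) + tpen + dpen + apen
    return U, float(U.sum())


# ---------------------------------------------------------------------------
# Gibbs machinery


def _design_states(model: PottsModel) -> int:
    """Proposable states 0..n-1; requires the gap, if any, to be the last symbol."""
    if GAP in model.alphabet:
        if model.alphabet.index(GAP) != model.q - 1:
            raise ValueError("design sampling requires the gap as the last alphabet symbol")
        return model.q - 1
    return model.q


def conditional_probs(model: PottsModel, S: np.ndarray, a: int, i: int, beta: float,
                      target: np.ndarray, msa, cfg: DesignConfig) -> np.ndarray:
    """Gibbs conditional over proposable symbols at batch slot (a, i).

    Uses the full batch energy; the diversity indicator between members
    a and b appears in both U(a) and U(b) and therefore counts twice.
    """
    n_states = _design_states(model)
    L = model.L
    X = _msa_matrix(msa, L)
    U = np.empty(n_states)
    s = S[a].copy()
    for x in range(n_states):
        s[i] = x
        e = model.h[i, x]
        other = np.concatenate([np.arange(i), np.arange(i + 1, L)])
        e += float(model.J[i, other, x, s[other]].sum())
        u = -e
        d = _dist(s, target)
        if d < cfg.d_min or d > cfg.d_max:
            u += cfg.lambda_target * abs(d - cfg.d_min)
        for b in range(S.shape[0]):
            if b != a and _dist(s, S[b]) < cfg.d_diversity:
                u += 2.0 * cfg.lambda_diversity
        for n in range(X.shape[0]):
            if _dist(s, X[n]) < cfg.d_alignment:
                u += cfg.lambda_alignment
        U[x] = u
    w = np.exp(-beta * (U - U.min()))
    return w / w.sum()


def gibbs_update(model: PottsModel, S: np.ndarray, a: int, i: int, beta: float,
                 rng: np.random.Generator, target: np.ndarray, msa,
                 cfg: DesignConfig) -> np.ndarray:
    """Resample the symbol at batch slot (a, i) from its conditional, in place."""
    p = conditional_probs(model, S, a, i, beta, target, msa, cfg)
    u = rng.random()
    S[a, i] = int(np.searchsorted(np.cumsum(p), u * p.sum(), side="right").clip(0, p.size - 1))
    return S


def _beta_schedule(cfg: DesignConfig) -> np.ndarray:
    if cfg.n_sweeps == 1:
        return np.array([cfg.beta_end])
    return np.linspace(cfg.beta_start, cfg.beta_end, cfg.n_sweeps)


def _prepare_run(model: PottsModel, cfg: DesignConfig, target_seq, msa):
    if cfg.d_min >= 1.0:
        raise ValueError("infeasible constraints: d_min >= 1")
    n_states = _design_states(model)
    if target_seq is None:
        target_seq = model.target_seq
    if target_seq is None:
        raise ValueError("no target sequence given and the model stores none")
    t = model._as_indices(target_seq)
    X = _msa_matrix(msa, model.L)
    return n_states, t, X


def design_batch(model: PottsModel, cfg: DesignConfig | None = None,
                 target_seq=None, msa=None, _reference: bool = False) -> DesignResult:
    """Run the annealed penalized batch Gibbs sampler.

    Each batch member starts from an independent uniformly random
    sequence over the proposable alphabet. One sweep performs M*L
    single-site updates at uniformly random (member, position) slots.
    Fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or DesignConfig()
    n_states, t, X = _prepare_run(model, cfg, target_seq, msa)
    L, M = model.L, cfg.M
    rng = np.random.default_rng(cfg.seed)
    S = rng.integers(0, n_states, size=(M, L)).astype(np.int64)

    n_upd = cfg.n_sweeps * M * L
    members = rng.integers(0, M, size=n_upd).astype(np.int64)
    positions = rng.integers(0, L, size=n_upd).astype(np.int64)
    unifs = rng.random(n_upd)
    betas = _beta_schedule(cfg)

    runner = _run_batch_gibbs_py if _reference else _kernels.run_batch_gibbs
    trace = runner(
        S, model.h, model.J, n_states, t, X,
        cfg.lambda_target, cfg.d_min, cfg.d_max,
        cfg.lambda_diversity, cfg.d_diversity,
        cfg.lambda_alignment, cfg.d_alignment,
        betas, members, positions, unifs, np.empty(0, dtype=np.int64),
    )
    return _finalize(model, cfg, S, t, X, np.asarray(trace), betas)


def _finalize(model, cfg, S, t, X, trace, betas) -> DesignResult:
    M = S.shape[0]
    evhs = np.array([evh(model, S[a]) for a in range(M)])
    tp = np.empty(M)
    dp = np.empty(M)
    ap = np.empty(M)
    for a in range(M):
        others = [S[b] for b in range(M) if b != a]
        tp[a], dp[a], ap[a] = penalty_terms(S[a], others, t, X, cfg)
    U = -evhs + tp + dp + ap
    d_t = np.array([_dist(S[a], t) for a in range(M)])
    d_batch = np.array([
        min((_dist(S[a], S[b]) for b in range(M) if b != a), default=1.0)
        for a in range(M)
    ])
    d_msa = np.array([
        min((_dist(S[a], X[n]) for n in range(X.shape[0])), default=1.0)
        for a in range(M)
    ])
    return DesignResult(
        sequences=[model.decode(S[a]) for a in range(M)],
        evh=evhs, U=U,
        target_penalty=tp, diversity_penalty=dp, alignment_penalty=ap,
        trace_total_U=trace, trace_beta=betas,
        target_band_ok=(d_t >= cfg.d_min - 1e-12) & (d_t <= cfg.d_max + 1e-12),
        min_batch_distance=d_batch, min_msa_distance=d_msa,
        seed=cfg.seed, config=asdict(cfg),
    )


def _run_batch_gibbs_py(S, h, J, n_states, target, msa,
                        lam_t, d_min, d_max, lam_d, d_div, lam_a, d_aln,
                        betas, members, positions, unifs, counts):
    """Pure-Python mirror of the numba kernel (same RNG stream consumption)."""
    M, L = S.shape
    N = msa.shape[0]
    trace = np.empty(len(betas))
    do_count = counts.shape[0] > 0
    t = 0
    for sweep, beta in enumerate(betas):
        for _ in range(M * L):
            a, i = members[t], positions[t]
            U = np.empty(n_states)
            s = S[a].copy()
            for x in range(n_states):
                s[i] = x
                other = np.concatenate([np.arange(i), np.arange(i + 1, L)])
                u = -(h[i, x] + float(J[i, other, x, s[other]].sum()))
                if lam_t > 0:
                    d = _dist(s, target)
                    if d < d_min or d > d_max:
                        u += lam_t * abs(d - d_min)
                if lam_d > 0:
                    for b in range(M):
                        if b != a and _dist(s, S[b]) < d_div:
                            u += 2.0 * lam_d
                if lam_a > 0:
                    for n in range(N):
                        if _dist(s, msa[n]) < d_aln:
                            u += lam_a
                U[x] = u
            w = np.exp(-beta * (U - U.min()))
            cum = np.cumsum(w)
            r = unifs[t] * cum[-1]
            new = n_states - 1
            for x in range(n_states):
                if r < cum[x]:
                    new = x
                    break
            S[a, i] = new
            if do_count:
                idx = 0
                for k in range(L):
                    idx = idx * n_states + S[0, k]
                counts[idx] += 1
            t += 1
        trace[sweep] = _trace_energy_py(S, h, J, target, msa,
                                        lam_t, d_min, d_max, lam_d, d_div, lam_a, d_aln)
    return trace


def _trace_energy_py(S, h, J, target, msa, lam_t, d_min, d_max, lam_d, d_div, lam_a, d_aln):
    M, L = S.shape
    total = 0.0
    iu, ju = np.triu_indices(L, k=1)
    for a in range(M):
        e = float(h[np.arange(L), S[a]].sum() + J[iu, ju, S[a][iu], S[a][ju]].sum())
        u = -e
        d = _dist(S[a], target)
        if d < d_min or d > d_max:
            u += lam_t * abs(d - d_min)
        for b in range(M):
            if b != a and _dist(S[a], S[b]) < d_div:
                u += lam_d
        for n in range(msa.shape[0]):
            if _dist(S[a], msa[n]) < d_aln:
                u += lam_a
        total += u
    return total


# ---------------------------------------------------------------------------
# single-sequence optimizers


def greedy_design(model: PottsModel, start_seq) -> str:
    """Steepest-ascent hill climb in the one-mutant neighborhood.

    Repeatedly applies the single point mutation with the largest
    strictly positive EVH gain; stops at a local optimum. Ties broken
    by (position, alphabet) order. Gap states are never proposed.
    """
    s = model._as_indices(start_seq).copy()
    n_states = _design_states(model)
    L = model.L
    while True:
        # candidate energies e[i, x] relative to current symbol at i
        gains = np.empty((L, n_states))
        for i in range(L):
            other = np.concatenate([np.arange(i), np.arange(i + 1, L)])
            cand = model.h[i] + model.J[i, other, :, s[other]].sum(axis=0)  # (q,)
            gains[i] = cand[:n_states] - cand[s[i]]
            if s[i] < n_states:
                gains[i, s[i]] = -np.inf
        best = np.unravel_index(np.argmax(gains), gains.shape)
        if gains[best] <= 0.0:
            break
        s[best[0]] = best[1]
    return model.decode(s)


def tempering_design(model: PottsModel, cfg: DesignConfig | None = None,
                     start_seq=None) -> tuple[str, float]:
    """Annealed parallel tempering maximization of EVH.

    Default: 19 replicas with initial inverse temperatures linearly
    spaced on [0.1, 1.0], multiplied by 1.002 per sweep; adjacent
    Metropolis replica exchanges each sweep. Returns the best-EVH
    sequence ever visited and its EVH.
    """
    cfg = cfg or DesignConfig(mode="tempering")
    if cfg.n_replicas < 2:
        raise ValueError("parallel tempering needs at least 2 replicas")
    n_states = _design_states(model)
    L, R = model.L, cfg.n_replicas
    rng = np.random.default_rng(cfg.seed)
    if start_seq is None:
        S = rng.integers(0, n_states, size=(R, L)).astype(np.int64)
    else:
        s0 = model._as_indices(start_seq)
        S = np.tile(s0, (R, 1)).astype(np.int64)
    beta0 = np.linspace(cfg.tempering_beta_low, cfg.tempering_beta_high, R)
    positions = rng.integers(0, L, size=(cfg.n_sweeps, R, L)).astype(np.int64)
    unifs = rng.random((cfg.n_sweeps, R, L))
    swap_unifs = rng.random((cfg.n_sweeps, R - 1 if R > 1 else 1))
    best_seq, best_evh = _kernels.run_tempering(
        S, model.h, model.J, n_states, beta0, cfg.tempering_growth,
        positions, unifs, swap_unifs,
    )
    return model.decode(np.asarray(best_seq)), float(best_evh)


def sample_state_counts(model: PottsModel, beta: float, n_sweeps: int, seed: int,
                        _reference: bool = False) -> np.ndarray:
    """Visited-state histogram of a single-sequence Gibbs chain at fixed beta.

    Runs the batch sampler with M = 1 and all penalties off, counting the
    encoded state after every single-site update (row-major encoding,
    last position fastest). Used to compare the sampler's empirical
    distribution against exact Boltzmann enumeration.
    """
    n_states = _design_states(model)
    L = model.L
    if n_states ** L > 10 ** 6:
        raise ValueError("state space too large to count")
    rng = np.random.default_rng(seed)
    S = rng.integers(0, n_states, size=(1, L)).astype(np.int64)
    n_upd = n_sweeps * L
    members = rng.integers(0, 1, size=n_upd).astype(np.int64)
    positions = rng.integers(0, L, size=n_upd).astype(np.int64)
    unifs = rng.random(n_upd)
    betas = np.full(n_sweeps, float(beta))
    counts = np.zeros(n_states ** L, dtype=np.int64)
    runner = _run_batch_gibbs_py if _reference else _kernels.run_batch_gibbs
    runner(S, model.h, model.J, n_states, S[0].copy(),
           np.empty((0, L), dtype=np.int64),
           0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0,
           betas, members, positions, unifs, counts)
    return counts
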