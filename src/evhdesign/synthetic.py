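"""Planted Potts landscapes, exact Boltzmann enumeration, sampled MSAs,
and synthetic mutational-scan tables.

These generators make every part of the package testable without any
external data: a planted model provides ground-truth couplings for
inference-recovery checks, exact enumeration provides the oracle for
sampler-correctness checks, and synthetic scan tables emulate the
replicate structure of experimental deep mutational scans. Sequences
are drawn i.i.d. from the model's Boltzmann distribution; phylogenetic
correlation among natural homologs is deliberately not simulated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import DEFAULT_ALPHABET, GAP
from .msa import Alignment
from .potts import PottsModel, delta_evh

_ENUM_GUARD = 10 ** 6


def _synthetic_alphabet(q: int) -> str:
    """Gap-free alphabet of the first q amino-acid letters (q <= 20), or AA+gap at 21."""
    if q == 21:
        return DEFAULT_ALPHABET
    if not 2 <= q <= 20:
        raise ValueError("synthetic alphabets support 2 <= q <= 20 (or 21 with gap)")
    return DEFAULT_ALPHABET[:q]


@dataclass
class PlantedModel:
    """A PottsModel with known interaction topology."""

    model: PottsModel
    edges: list[tuple[int, int]]
    params: dict

    def edge_set(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j in self.edges}


def planted_model(
    L: int,
    q: int = 8,
    n_edges: int = 0,
    coupling_strength: float = 1.0,
    field_scale: float = 0.5,
    seed: int = 0,
    topology: str = "random-graph",
    min_sep: int = 5,
) -> PlantedModel:
    """Random Potts model with couplings planted on a known edge set.

    Fields are i.i.d. normal(0, field_scale^2); each planted edge gets a
    dense q x q coupling block with i.i.d. normal(0, strength^2) entries
    (symmetrized into J). The default random-graph topology only uses
    pairs at least ``min_sep`` apart in the chain so that contact-style
    evaluations with a sequence-separation filter are exercised; the
    chain topology links consecutive positions.
    """
    if L < 2:
        raise ValueError("need L >= 2")
    rng = np.random.default_rng(seed)
    alphabet = _synthetic_alphabet(q)

    if topology == "chain":
        candidates = [(i, i + 1) for i in range(L - 1)]
    elif topology == "random-graph":
        candidates = [(i, j) for i in range(L) for j in range(i + 1, L) if j - i >= min_sep]
    else:
        raise ValueError(f"unknown topology {topology!r}")
    if n_edges > len(candidates):
        raise ValueError(
            f"cannot place {n_edges} edges: only {len(candidates)} candidate pairs "
            f"(L={L}, topology={topology}, min_sep={min_sep})"
        )
    if n_edges < 0:
        raise ValueError("n_edges must be >= 0")
    pick = rng.choice(len(candidates), size=n_edges, replace=False) if n_edges else []
    edges = [candidates[k] for k in sorted(pick)]

    h = rng.normal(0.0, field_scale, size=(L, q))
    J = np.zeros((L, L, q, q))
    for i, j in edges:
        block = rng.normal(0.0, coupling_strength, size=(q, q))
        J[i, j] = block
        J[j, i] = block.T
    model = PottsModel(h=h, J=J, alphabet=alphabet, metadata={
        "generator": "planted_model", "seed": seed, "topology": topology,
        "coupling_strength": coupling_strength, "field_scale": field_scale,
        "n_edges": n_edges, "min_sep": min_sep,
    })
    return PlantedModel(model=model, edges=edges, params=dict(model.metadata))


def enumerate_states(L: int, q: int) -> np.ndarray:
    """All q**L sequences in row-major order (last position fastest)."""
    if q ** L > _ENUM_GUARD:
        raise ValueError(f"state space q^L = {q ** L} exceeds enumeration guard {_ENUM_GUARD}")
    return np.array(list(itertools.product(range(q), repeat=L)), dtype=np.int64)


def enumerate_boltzmann(model: PottsModel, beta: float = 1.0):
    """Exact Boltzmann distribution p(s) = exp(beta*EVH(s)) / Z over all states.

    Returns (states, probabilities); probabilities sum to 1 within 1e-12.
    Guarded at q^L <= 1e6.
    """
    L, q = model.L, model.q
    states = enumerate_states(L, q)
    E = model.h[np.arange(L), states].sum(axis=1)
    for i in range(L):
        for j in range(i + 1, L):
            E = E + model.J[i, j][states[:, i], states[:, j]]
    logp = beta * E
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return states, p


def sample_msa(
    model: PottsModel,
    n: int,
    beta: float = 1.0,
    method: str = "exact",
    burn_in: int = 100,
    thin: int = 10,
    seed: int = 0,
    id_prefix: str = "synth",
) -> Alignment:
    """Sample an i.i.d. (exact) or Gibbs-chain MSA from the model.

    exact: inverse-CDF draws from :func:`enumerate_boltzmann` (guarded).
    gibbs: one chain, ``burn_in`` sweeps discarded, one record kept every
    ``thin`` sweeps (a sweep is L sequential site updates).
    """
    rng = np.random.default_rng(seed)
    L, q = model.L, model.q
    if method == "exact":
        states, p = enumerate_boltzmann(model, beta)
        idx = rng.choice(states.shape[0], size=n, p=p)
        X = states[idx]
    elif method == "gibbs":
        X = np.empty((n, L), dtype=np.int64)
        s = rng.integers(0, q, size=L)
        kept = 0
        sweep = 0
        while kept < n:
            for i in range(L):
                other = np.concatenate([np.arange(i), np.arange(i + 1, L)])
                logits = beta * (model.h[i] + model.J[i, other, :, s[other]].sum(axis=0))
                logits -= logits.max()
                w = np.exp(logits)
                s[i] = rng.choice(q, p=w / w.sum())
            sweep += 1
            if sweep > burn_in and (sweep - burn_in) % thin == 0:
                X[kept] = s
                kept += 1
    else:
        raise ValueError(f"unknown sampling method {method!r}")

    rows = ["".join(model.alphabet[a] for a in row) for row in X]
    ids = [f"{id_prefix}_{k}" for k in range(n)]
    return Alignment(ids, rows, alphabet=model.alphabet)


def synthetic_dms(
    model: PottsModel,
    wt,
    noise_sd: float = 0.5,
    n_replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy replicate scan table: score = dEVH(wt -> mut) + N(0, noise_sd^2).

    Columns: position (model numbering), wt, mut, score_1..score_R.
    Emulates the replicate structure of an experimental deep mutational
    scan whose scores track the model's energies up to measurement noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    s = model._as_indices(wt)
    aa_states = [i for i, c in enumerate(model.alphabet) if c != GAP]
    rows = []
    for i in range(model.L):
        for a in aa_states:
            if a == s[i]:
                continue
            d = delta_evh(model, s, [(i, a)])
            rows.append([int(model.index_map[i]), model.alphabet[s[i]],
                         model.alphabet[a], d])
    df = pd.DataFrame(rows, columns=["position", "wt", "mut", "true_delta"])
    for r in range(1, n_replicates + 1):
        df[f"score_{r}"] = df["true_delta"] + rng.normal(0.0, noise_sd, size=len(df))
    return df.drop(columns="true_delta")


def two_basin_model(L: int = 8, coupling: float = 2.0, tilt: float = 0.25,
                    seed: int = 0) -> PottsModel:
    """Binary-state landscape with two deep basins and one global optimum.

    Ferromagnetic chain-plus-ring couplings make the two uniform
    sequences local optima; a small uniform field tilt makes one of them
    the global optimum. Useful for testing global-optimization samplers
    that must cross an energy barrier.
    """
    alphabet = _synthetic_alphabet(2)
    q = 2
    h = np.zeros((L, q))
    h[:, 1] = tilt  # uniform state 1 wins globally
    J = np.zeros((L, L, q, q))
    edges = [(i, (i + 1) % L) for i in range(L)]
    block = coupling * (np.eye(q) - 0.5)  # + for equal symbols, - for unequal
    for i, j in edges:
        a, b = min(i, j), max(i, j)
        J[a, b] += block
        J[b, a] += block.T
    return PottsModel(h=h, J=J, alphabet=alphabet,
                      metadata={"generator": "two_basin_model", "seed": seed,
                                "coupling": coupling, "tilt": tilt})
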