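"""Self-contained correctness benchmarks on synthetic ground truth.

Each routine generates its own planted inputs, runs the corresponding
package machinery, and returns a scalar quality measure:

* sampler correctness — total-variation distance between the Gibbs
  chain's visited-state histogram and exact Boltzmann enumeration;
* constraint satisfaction — fraction of seeded design runs whose final
  batch meets the target-band, batch-diversity and homolog-distance
  constraints simultaneously;
* greedy oracle agreement — identity of the greedy optimizer with an
  exhaustive hill-climb on small enumerable models;
* tempering success — how often parallel tempering reaches the
  enumerated global optimum of a two-basin landscape;
* inference recovery — precision of the top APC coupling pairs against
  the planted interaction graph after a pseudolikelihood fit.

Problem sizes are chosen to run on a single CPU in minutes while still
exercising every code path at meaningful scale.
"""

from __future__ import annotations

import numpy as np

from .design import DesignConfig, design_batch, greedy_design, sample_state_counts, \
    tempering_design
from .evaluate import contact_precision, coupling_scores
from .msa import Alignment, sequence_weights
from .plm import PottsPseudolikelihood
from .potts import PottsModel, evh
from .synthetic import enumerate_boltzmann, planted_model, sample_msa, two_basin_model


def gibbs_tv_distance(seed: int = 0, n_sweeps: int = 100_000) -> dict:
    """TV distance between Gibbs visits and exact Boltzmann, L=6 / q=3.

    Single-sequence chain at fixed beta = 1 with all penalties off,
    counting the visited state after every single-site update.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    pm = planted_model(6, 3, n_edges=3, coupling_strength=0.7, field_scale=0.5,
                       seed=_sub(ss[0]), topology="chain")
    counts = sample_state_counts(pm.model, beta=1.0, n_sweeps=n_sweeps, seed=_sub(ss[1]))
    _, p = enumerate_boltzmann(pm.model, 1.0)
    emp = counts / counts.sum()
    tv = 0.5 * float(np.abs(emp - p).sum())
    return {"value": tv, "n": int(counts.sum())}


def constraint_satisfaction_rate(seed: int = 0, n_runs: int = 20) -> dict:
    """Fraction of seeded design runs meeting every distance constraint.

    Synthetic L=40 / q=20 model, 50-record sampled alignment, published
    defaults (lambda 1000/10/10, d_min=0.30, d_max=0.35, M=6, 1000
    sweeps). A run counts only if all six designs end inside the target
    band, pairwise >= d_min apart, and >= d_min from every record.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    pm = planted_model(40, 20, n_edges=60, coupling_strength=0.8, field_scale=1.0,
                       seed=_sub(ss[0]))
    aln = sample_msa(pm.model, 51, beta=1.0, method="gibbs", burn_in=200, thin=10,
                     seed=_sub(ss[1]))
    target = aln.rows[0]
    msa = Alignment(aln.ids[1:], aln.rows[1:], alphabet=aln.alphabet)
    base = _sub(ss[2])
    ok = 0
    for k in range(n_runs):
        cfg = DesignConfig(d_min=0.30, seed=(base + k) % (2 ** 31))
        res = design_batch(pm.model, cfg, target_seq=target, msa=msa)
        eps = 1e-12
        if (res.target_band_ok.all()
                and (res.min_batch_distance >= cfg.d_diversity - eps).all()
                and (res.min_msa_distance >= cfg.d_alignment - eps).all()):
            ok += 1
    return {"value": ok / n_runs, "n": n_runs}


def greedy_oracle_agreement(seed: int = 0, n_models: int = 100) -> dict:
    """Fraction of small random models where greedy equals the exhaustive
    hill-climb oracle (L=5, q=3, same strict-improvement tie rule)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for k in range(n_models):
        pm = planted_model(5, 3, n_edges=4, coupling_strength=1.0, field_scale=0.7,
                           seed=int(rng.integers(2 ** 31)), topology="chain")
        start = pm.model.decode(rng.integers(0, 3, size=5))
        agree += greedy_design(pm.model, start) == exhaustive_hillclimb(pm.model, start)
    return {"value": agree / n_models, "n": n_models}


def exhaustive_hillclimb(model: PottsModel, start) -> str:
    """Brute-force steepest ascent: full EVH recomputation per candidate.

    Independent oracle for :func:`evhdesign.greedy_design` — shares only
    :func:`evh` with it, and applies the same first-maximum tie rule.
    """
    s = model._as_indices(start).copy()
    n_states = model.n_design_states
    while True:
        base = evh(model, s)
        best_gain, best_move = 0.0, None
        for i in range(model.L):
            for x in range(n_states):
                if x == s[i]:
                    continue
                s2 = s.copy()
                s2[i] = x
                gain = evh(model, s2) - base
                if gain > best_gain:
                    best_gain, best_move = gain, (i, x)
        if best_move is None:
            return model.decode(s)
        s[best_move[0]] = best_move[1]


def tempering_success_rate(seed: int = 0, n_runs: int = 20) -> dict:
    """Fraction of seeded tempering runs reaching the enumerated global
    optimum of an L=8 binary two-basin landscape."""
    model = two_basin_model(L=8, coupling=2.0, tilt=0.25)
    states, _ = enumerate_boltzmann(model, 1.0)
    energies = np.array([evh(model, s) for s in states])
    optimum = model.decode(states[int(energies.argmax())])
    base = _sub(np.random.SeedSequence(seed))
    ok = 0
    for k in range(n_runs):
        cfg = DesignConfig(mode="tempering", seed=(base + k) % (2 ** 31))
        seq, _ = tempering_design(model, cfg)
        ok += seq == optimum
    return {"value": ok / n_runs, "n": n_runs}


def planted_recovery_precision(seed: int = 0, n_seqs: int = 2000) -> dict:
    """Top-30 APC pair precision against a planted graph (L=30, q=8).

    Samples ``n_seqs`` Gibbs sequences from a 30-edge planted model,
    reweights at theta = 0.2, fits by regularized pseudolikelihood, and
    scores pairs by APC-corrected Frobenius norm with the 5-position
    sequence-separation filter.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    pm = planted_model(30, 8, n_edges=30, coupling_strength=1.0, field_scale=0.5,
                       seed=_sub(ss[0]))
    aln = sample_msa(pm.model, n_seqs, beta=1.0, method="gibbs", burn_in=100, thin=5,
                     seed=_sub(ss[1]))
    weights = sequence_weights(aln, 0.2)
    fitted = PottsPseudolikelihood(aln, weights=weights).fit(maxiter=300).params
    scores = coupling_scores(fitted, "apc")
    prec = contact_precision(scores, pm.edge_set(), len(pm.edges), min_sep=5)
    return {"value": prec, "n": n_seqs}


def _sub(ss: np.random.SeedSequence) -> int:
    """A 31-bit integer seed derived from a SeedSequence."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
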