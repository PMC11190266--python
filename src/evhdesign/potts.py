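"""Site-and-pairwise (Potts) sequence models and statistical-energy scores.

A :class:`PottsModel` carries site terms ``h[i, a]`` and coupling terms
``J[i, j, a, b]`` over ``L`` focus positions and a ``q``-letter alphabet.
The statistical energy (evolutionary Hamiltonian, EVH) of a sequence
``s`` is

    EVH(s) = sum_i h[i, s_i] + sum_{i<j} J[i, j, s_i, s_j]

and is the fitness proxy used for mutation-effect prediction and design.
Only EVH *differences* are used downstream, which are invariant to the
gauge freedom of the parameterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import DEFAULT_ALPHABET, GAP, decode, encode

_MODEL_FORMAT_VERSION = 1


@dataclass
class PottsModel:
    """Pairwise maximum-entropy model over aligned sequences.

    Attributes
    ----------
    h : (L, q) float array
        Site terms.
    J : (L, L, q, q) float array
        Coupling terms, with ``J[i, j, a, b] == J[j, i, b, a]`` and zero
        diagonal blocks.
    alphabet : str
        Ordered symbols, default 20 amino acids + gap.
    index_map : (L,) int array
        Focus position -> residue number in the target sequence's own
        numbering (strictly increasing).
    target_seq : (L,) int array or None
        Encoded target sequence, if the model has one.
    metadata : dict
        Provenance: theta, n_eff, regularization, optimizer record, seed.
    """

    h: np.ndarray
    J: np.ndarray
    alphabet: str = DEFAULT_ALPHABET
    index_map: np.ndarray | None = None
    target_seq: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.ascontiguousarray(self.h, dtype=np.float64)
        self.J = np.ascontiguousarray(self.J, dtype=np.float64)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError(f"J shape {self.J.shape} incompatible with h shape {self.h.shape}")
        if q != len(self.alphabet):
            raise ValueError("alphabet length does not match q")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("model parameters must be finite")
        if self.index_map is None:
            self.index_map = np.arange(1, L + 1, dtype=np.int64)
        else:
            self.index_map = np.asarray(self.index_map, dtype=np.int64)
            if self.index_map.shape != (L,) or np.any(np.diff(self.index_map) <= 0):
                raise ValueError("index_map must be strictly increasing of length L")
        if self.target_seq is not None:
            self.target_seq = np.asarray(self.target_seq, dtype=np.int64)
            if self.target_seq.shape != (L,):
                raise ValueError("target_seq must have length L")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def n_design_states(self) -> int:
        """Number of proposable states: the alphabet minus the gap, if present."""
        return self.q - 1 if GAP in self.alphabet else self.q

    def validate_symmetry(self, atol: float = 0.0) -> None:
        """Check J[i,j,a,b] == J[j,i,b,a] and zero diagonal blocks."""
        JT = np.transpose(self.J, (1, 0, 3, 2))
        if not np.allclose(self.J, JT, atol=atol, rtol=0):
            raise ValueError("J is not symmetric under (i,j,a,b) -> (j,i,b,a)")
        diag = self.J[np.arange(self.L), np.arange(self.L)]
        if not np.allclose(diag, 0.0, atol=atol, rtol=0):
            raise ValueError("diagonal coupling blocks must be zero")

    # -- encoding helpers ------------------------------------------------

    def encode(self, seq: str) -> np.ndarray:
        s = encode(seq, self.alphabet)
        if s.shape[0] != self.L:
            raise ValueError(f"sequence length {s.shape[0]} != model length {self.L}")
        return s

    def decode(self, s: np.ndarray) -> str:
        return decode(s, self.alphabet)

    def _as_indices(self, seq) -> np.ndarray:
        if isinstance(seq, str):
            return self.encode(seq)
        s = np.asarray(seq, dtype=np.int64)
        if s.shape != (self.L,):
            raise ValueError(f"sequence length {s.shape} != model length {self.L}")
        if s.size and (s.min() < 0 or s.max() >= self.q):
            raise ValueError("sequence contains symbols outside the alphabet")
        return s


# ---------------------------------------------------------------------------
# statistical energy


def evh(model: PottsModel, seq) -> float:
    """Statistical energy of a sequence: site terms plus all pair couplings."""
    s = model._as_indices(seq)
    L = model.L
    e = float(model.h[np.arange(L), s].sum())
    iu, ju = np.triu_indices(L, k=1)
    e += float(model.J[iu, ju, s[iu], s[ju]].sum())
    return e


def delta_evh(model: PottsModel, background, mutations) -> float:
    """EVH change of applying ``mutations`` (pairs of (position, symbol)) to a background.

    Computed incrementally from the terms touching mutated positions;
    identical to ``evh(mutant) - evh(background)`` up to 1e-9 relative.
    Positions are 0-based focus indices; symbols may be characters or
    alphabet indices.
    """
    s = model._as_indices(background)
    muts: dict[int, int] = {}
    for pos, sym in mutations:
        pos = int(pos)
        if not 0 <= pos < model.L:
            raise ValueError(f"position {pos} out of range for L={model.L}")
        a = model.alphabet.index(sym) if isinstance(sym, str) else int(sym)
        if not 0 <= a < model.q:
            raise ValueError(f"symbol index {a} outside alphabet")
        if pos in muts:
            raise ValueError(f"duplicate mutated position {pos}")
        muts[pos] = a
    if not muts:
        return 0.0

    positions = np.array(sorted(muts), dtype=np.int64)
    new = np.array([muts[p] for p in positions], dtype=np.int64)
    mask = np.zeros(model.L, dtype=bool)
    mask[positions] = True
    other = np.flatnonzero(~mask)

    d = float((model.h[positions, new] - model.h[positions, s[positions]]).sum())
    for p, a in zip(positions, new):
        d += float(model.J[p, other, a, s[other]].sum()
                   - model.J[p, other, s[p], s[other]].sum())
    for u in range(len(positions)):
        for v in range(u + 1, len(positions)):
            i, j = positions[u], positions[v]
            d += float(model.J[i, j, new[u], new[v]] - model.J[i, j, s[i], s[j]])
    return d


def mutation_matrix(model: PottsModel, background, background_id: str = "background") -> pd.DataFrame:
    """Full single-substitution EVH scan: L x (n_aa - 1) rows.

    The gap state is never proposed as a mutation. Positions are reported
    in the model's ``index_map`` numbering. Columns: position, wt, mut,
    delta_evh, background_id.
    """
    s = model._as_indices(background)
    aa_states = [i for i, c in enumerate(model.alphabet) if c != GAP]
    rows = []
    # vectorized per-position candidate energies: e[x] - e[wt]
    for i in range(model.L):
        other = np.concatenate([np.arange(i), np.arange(i + 1, model.L)])
        # advanced indexing gives (L-1, q): couplings of each candidate at i
        # with the fixed background symbols elsewhere
        cand = model.h[i] + model.J[i, other, :, s[other]].sum(axis=0)
        base = cand[s[i]]
        wt_sym = model.alphabet[s[i]]
        for a in aa_states:
            if a == s[i]:
                continue
            rows.append((int(model.index_map[i]), wt_sym, model.alphabet[a],
                         float(cand[a] - base), background_id))
    return pd.DataFrame(rows, columns=["position", "wt", "mut", "delta_evh", "background_id"])


def epistasis(model: PottsModel, background, mut_a, mut_b) -> float:
    """Pairwise epistasis: ddEVH = d({A,B}) - d({A}) - d({B}).

    For a pairwise model this reduces to the coupling-term combination
    J[i,j,a',b'] - J[i,j,a',b] - J[i,j,a,b'] + J[i,j,a,b].
    """
    (pi, sa), (pj, sb) = mut_a, mut_b
    if int(pi) == int(pj):
        raise ValueError("epistasis is undefined for two mutations at the same position")
    return (delta_evh(model, background, [mut_a, mut_b])
            - delta_evh(model, background, [mut_a])
            - delta_evh(model, background, [mut_b]))


# ---------------------------------------------------------------------------
# model container I/O (.evhm): one JSON header line + little-endian float64
# payload, arrays in documented order (h, J, index_map, target_seq).


def save_model(model: PottsModel, path) -> None:
    """Write the model to the versioned ``.evhm`` single-file container."""
    header = {
        "format": "evhm",
        "version": _MODEL_FORMAT_VERSION,
        "L": model.L,
        "q": model.q,
        "alphabet": model.alphabet,
        "has_target": model.target_seq is not None,
        "metadata": _jsonable(model.metadata),
    }
    with open(str(path), "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode("utf-8"))
        fh.write(model.h.astype("<f8").tobytes())
        fh.write(model.J.astype("<f8").tobytes())
        fh.write(model.index_map.astype("<i8").tobytes())
        if model.target_seq is not None:
            fh.write(model.target_seq.astype("<i8").tobytes())


def load_model(path) -> PottsModel:
    """Read a ``.evhm`` container; bit-exact inverse of :func:`save_model`."""
    with open(str(path), "rb") as fh:
        header_line = fh.readline()
        payload = fh.read()
    try:
        header = json.loads(header_line.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ValueError(f"not an evhm model file: bad header ({exc})") from exc
    if header.get("format") != "evhm":
        raise ValueError("not an evhm model file")
    version = header.get("version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model file version {version} unsupported; this reader handles "
            f"version {_MODEL_FORMAT_VERSION}"
        )
    L, q = int(header["L"]), int(header["q"])
    n_f8 = L * q + L * L * q * q
    n_i8 = L + (L if header.get("has_target") else 0)
    expected = 8 * (n_f8 + n_i8)
    if len(payload) != expected:
        raise ValueError(
            f"truncated or corrupt model file: expected {expected} payload bytes, "
            f"found {len(payload)}"
        )
    buf = np.frombuffer(payload[: 8 * n_f8], dtype="<f8")
    h = buf[: L * q].reshape(L, q).copy()
    J = buf[L * q :].reshape(L, L, q, q).copy()
    ints = np.frombuffer(payload[8 * n_f8 :], dtype="<i8")
    index_map = ints[:L].copy()
    target = ints[L:].copy() if header.get("has_target") else None
    return PottsModel(h=h, J=J, alphabet=header["alphabet"], index_map=index_map,
                      target_seq=target, metadata=header.get("metadata", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
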