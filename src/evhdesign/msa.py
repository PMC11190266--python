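"""Multiple sequence alignments: I/O, filtering, reweighting, consensus.

An :class:`Alignment` holds aligned homologs of a designated target
sequence over the retained ("focus") columns. Redundancy reweighting
follows the standard direct-coupling-analysis recipe: each sequence is
down-weighted by the number of alignment members within a normalized
Hamming distance ``theta`` of it, giving an effective sequence number
``n_eff``.

Distance convention (documented, applied everywhere): gap-vs-residue is a
mismatch, gap-vs-gap is a match. This makes the normalized Hamming
distance a metric on aligned rows and makes ``1 - D`` agree with the
intuitive "% identity" over focus columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMBIGUOUS, DEFAULT_ALPHABET, GAP, encode_matrix


@dataclass
class Alignment:
    """Aligned sequence rows over focus columns.

    Parameters
    ----------
    ids : list of str
        One identifier per row.
    rows : list of str
        Equal-length uppercase rows over ``alphabet``; gaps as ``-``.
    focus_columns : list of int
        Original column indices retained, strictly increasing.
    target_index : int
        Row index of the target (design reference) sequence.
    alphabet : str
        Ordered symbol set; default 20 amino acids + gap.
    """

    ids: list[str]
    rows: list[str]
    focus_columns: list[int] = field(default_factory=list)
    target_index: int = 0
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no records")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        L = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"ragged alignment: record {rid!r} has length {len(row)}, expected {L}"
                )
        if not self.focus_columns:
            self.focus_columns = list(range(L))
        if len(self.focus_columns) != L:
            raise ValueError("focus_columns length does not match row length")
        if any(b <= a for a, b in zip(self.focus_columns, self.focus_columns[1:])):
            raise ValueError("focus_columns must be strictly increasing")
        if not 0 <= self.target_index < len(self.rows):
            raise ValueError(f"target_index {self.target_index} out of range")

    # -- basic views -----------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def target(self) -> str:
        return self.rows[self.target_index]

    def encoded(self) -> np.ndarray:
        """(n_records, L) int64 matrix of alphabet indices."""
        return encode_matrix(self.rows, self.alphabet)


# ---------------------------------------------------------------------------
# reading / writing


def _a2m_to_alignment(records: list[tuple[str, str]], target_id: str | None) -> Alignment:
    """Build an Alignment from A2M records (lowercase/'.' = insert states)."""
    length = len(records[0][1])
    for rid, row in records:
        if len(row) != length:
            raise ValueError(f"ragged alignment: record {rid!r} has length {len(row)}")
    # a column is a match (focus) column iff no row marks it as an insert
    is_insert = [False] * length
    for _, row in records:
        for k, c in enumerate(row):
            if c == "." or c.islower():
                is_insert[k] = True
    focus = [k for k in range(length) if not is_insert[k]]
    ids = [rid for rid, _ in records]
    rows = ["".join(row[k] for k in focus).upper() for _, row in records]
    return Alignment(ids, rows, focus_columns=focus, target_index=_target_idx(ids, target_id))


def _target_idx(ids: list[str], target_id: str | None) -> int:
    if target_id is None:
        return 0
    try:
        return ids.index(target_id)
    except ValueError:
        raise ValueError(f"target id {target_id!r} not found in alignment") from None


def read_alignment(
    path,
    format_hint: str = "auto",
    target_id: str | None = None,
    alphabet: str = DEFAULT_ALPHABET,
) -> Alignment:
    """Read an alignment from FASTA, A2M or Stockholm.

    ``format_hint='auto'`` picks Stockholm if the file starts with
    ``# STOCKHOLM``, otherwise FASTA/A2M (which share a syntax; lowercase
    or ``.`` characters are treated as A2M insert states either way).
    The target defaults to the first record.
    """
    path = str(path)
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"empty alignment file: {path}")

    fmt = format_hint
    if fmt == "auto":
        fmt = "stockholm" if text.lstrip().startswith("# STOCKHOLM") else "fasta"
    if fmt == "a2m":
        fmt = "fasta"
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unknown alignment format {format_hint!r}")

    if fmt == "stockholm":
        aln = AlignIO.read(io.StringIO(text), "stockholm")
        records = [(r.id, str(r.seq)) for r in aln]
    else:
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(io.StringIO(text), "fasta")]
    if not records:
        raise ValueError(f"no records parsed from {path}")

    out = _a2m_to_alignment(records, target_id)
    # ambiguous/non-standard residue codes carry no usable state: map to gap
    trans = str.maketrans({c: GAP for c in AMBIGUOUS if c not in alphabet})
    return replace(out, rows=[r.translate(trans) for r in out.rows], alphabet=alphabet)


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    """Write focus columns as FASTA or Stockholm."""
    recs = [SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(aln.ids, aln.rows)]
    with open(str(path), "w") as fh:
        if fmt == "fasta":
            SeqIO.write(recs, fh, "fasta")
        elif fmt == "stockholm":
            from Bio.Align import MultipleSeqAlignment

            AlignIO.write(MultipleSeqAlignment(recs), fh, "stockholm")
        else:
            raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# filtering


def filter_alignment(
    aln: Alignment, max_col_gap: float = 0.30, min_coverage: float = 0.50
) -> Alignment:
    """Drop fragment records, then over-gapped columns.

    A record is a fragment if it covers fewer than ``min_coverage`` of the
    target's non-gap positions (coverage = positions where both record and
    target are non-gap, over the target's non-gap count). A column is then
    dropped when its gap fraction over the remaining records exceeds
    ``max_col_gap``. The target row is never dropped.
    """
    if not (0 < max_col_gap < 1 and 0 < min_coverage < 1):
        raise ValueError("thresholds must lie strictly between 0 and 1")
    X = aln.encoded()
    gap_idx = aln.alphabet.index(GAP)
    tgt = X[aln.target_index]
    tgt_nongap = tgt != gap_idx
    n_tgt = int(tgt_nongap.sum())
    if n_tgt == 0:
        raise ValueError("target sequence is all gaps")

    coverage = ((X != gap_idx) & tgt_nongap).sum(axis=1) / n_tgt
    keep_rec = coverage >= min_coverage
    keep_rec[aln.target_index] = True
    if keep_rec.sum() <= 1 and aln.n_records > 1:
        raise ValueError(
            "fragment filter removed every non-target record; lower min_coverage"
        )

    Xk = X[keep_rec]
    gap_frac = (Xk == gap_idx).mean(axis=0)
    keep_col = gap_frac <= max_col_gap

    ids = [rid for rid, k in zip(aln.ids, keep_rec) if k]
    col_idx = np.flatnonzero(keep_col)
    rows = ["".join(row[j] for j in col_idx) for row, k in zip(aln.rows, keep_rec) if k]
    focus = [aln.focus_columns[j] for j in col_idx]
    new_target = int(np.flatnonzero(keep_rec).tolist().index(aln.target_index))
    return Alignment(ids, rows, focus_columns=focus, target_index=new_target,
                     alphabet=aln.alphabet)


# ---------------------------------------------------------------------------
# distances, weights, consensus


def normalized_hamming(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Fraction of focus positions at which two aligned rows differ.

    Accepts strings or encoded index arrays. Gap-vs-residue counts as a
    mismatch; gap-vs-gap as a match.
    """
    if isinstance(a, str):
        a = np.frombuffer(a.encode(), dtype=np.uint8)
    if isinstance(b, str):
        b = np.frombuffer(b.encode(), dtype=np.uint8)
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.size == 0:
        raise ValueError("empty sequences")
    return float(np.mean(a != b))


@dataclass(frozen=True)
class WeightSet:
    """Per-record redundancy weights at distance cutoff ``theta``."""

    weights: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or np.any(w <= 0) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must be in (0, 1]")
        object.__setattr__(self, "weights", w)

    @property
    def n_eff(self) -> float:
        return float(self.weights.sum())


def sequence_weights(aln: Alignment, theta: float = 0.2) -> WeightSet:
    """Down-weight redundant records: w_s = 1 / #{t : D(s,t) < theta}.

    The neighbour set includes the record itself, so weights lie in
    (0, 1] and ``n_eff = sum(w)`` is the effective sequence count.
    """
    X = aln.encoded()
    n, L = X.shape
    counts = np.zeros(n, dtype=np.int64)
    # chunked pairwise distances to bound memory at large n
    step = max(1, int(2e7) // max(n * L, 1))
    for s in range(0, n, step):
        block = X[s : s + step]
        d = (block[:, None, :] != X[None, :, :]).mean(axis=2)
        counts[s : s + step] = (d < theta).sum(axis=1)
    return WeightSet(weights=1.0 / counts, theta=theta)


def reweighted_consensus(aln: Alignment, weights: WeightSet) -> str:
    """Most-frequent non-gap residue per focus column under the weights.

    Ties are broken by alphabet order. A column containing only gaps
    raises an error (cannot occur after default filtering).
    """
    X = aln.encoded()
    w = weights.weights
    if w.shape[0] != X.shape[0]:
        raise ValueError("weights do not align 1:1 with records")
    q = len(aln.alphabet)
    gap_idx = aln.alphabet.index(GAP) if GAP in aln.alphabet else -1
    out = []
    for j in range(X.shape[1]):
        freq = np.bincount(X[:, j], weights=w, minlength=q)
        if gap_idx >= 0:
            freq[gap_idx] = -np.inf
        if not np.isfinite(freq.max()) or freq.max() <= 0:
            raise ValueError(f"focus column {j} contains only gaps")
        out.append(aln.alphabet[int(np.argmax(freq))])  # argmax ties -> lowest index
    return "".join(out)


def identity(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Percent-style identity over focus columns, 1 - normalized_hamming."""
    return 1.0 - normalized_hamming(a, b)
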