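"""Model- and design-evaluation analyses.

Covers coupling-strength contact comparison (Frobenius norm with
average-product correction), rank correlation against mutational-scan
tables, fitness-defect flagging, per-design summary statistics,
background-dependence (quadrant) and reversion analyses, a random-
mutant energy baseline, and codon-usage-aware reverse translation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .alphabet import GAP
from .msa import Alignment, normalized_hamming
from .potts import PottsModel, delta_evh, evh


# ---------------------------------------------------------------------------
# coupling scores and contacts


def coupling_scores(model: PottsModel, correction: str = "apc") -> np.ndarray:
    """L x L coupling-strength matrix: Frobenius norm of each J block.

    The norm is taken over the non-gap states. With ``correction='apc'``
    the average-product correction S_ij - (mean_i * mean_j) / mean_all is
    subtracted (means over the full matrix, which annihilates exact
    rank-one score matrices); the diagonal is zero either way.
    """
    aa = np.array([i for i, c in enumerate(model.alphabet) if c != GAP])
    blocks = model.J[np.ix_(np.arange(model.L), np.arange(model.L), aa, aa)]
    S = np.sqrt((blocks ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(S, 0.0)
    if correction == "none":
        return S
    if correction == "apc":
        return apc(S)
    raise ValueError(f"unknown correction {correction!r}")


def apc(S: np.ndarray) -> np.ndarray:
    """Average-product correction of a symmetric score matrix."""
    S = np.asarray(S, dtype=float)
    grand = S.mean()
    if grand == 0:
        out = S.copy()
    else:
        row = S.mean(axis=1)
        out = S - np.outer(row, row) / grand
    np.fill_diagonal(out, 0.0)
    return out


def top_pairs(S: np.ndarray, top_n: int, min_sep: int = 5) -> list[tuple[int, int]]:
    """Highest-scoring position pairs with |i - j| >= min_sep, descending."""
    L = S.shape[0]
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L) if j - i >= min_sep]
    if top_n > len(pairs):
        raise ValueError(f"top_n={top_n} exceeds the {len(pairs)} available pairs")
    pairs.sort(key=lambda ij: (-S[ij], ij))
    return pairs[:top_n]


def contact_precision(S: np.ndarray, contacts, top_n: int, min_sep: int = 5) -> float:
    """Fraction of the top-n well-separated predicted pairs that are contacts."""
    cset = {(min(i, j), max(i, j)) for i, j in contacts}
    top = top_pairs(S, top_n, min_sep=min_sep)
    return sum(1 for p in top if p in cset) / top_n


# ---------------------------------------------------------------------------
# mutational-scan comparison


def dms_compare(scan: pd.DataFrame, dms: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation between predicted and measured effects.

    ``scan`` is a mutation-effect table (columns position, wt, mut,
    delta_evh); ``dms`` has columns position, wt, mut plus one or more
    replicate score columns. Rows are matched on (position, mut); ties
    get average ranks (scipy default). Returns one row per replicate
    with columns (replicate, spearman, n).
    """
    score_cols = [c for c in dms.columns if c not in ("position", "wt", "mut")]
    if not score_cols:
        raise ValueError("dms table has no replicate score columns")
    merged = scan.merge(dms, on=["position", "mut"], suffixes=("", "_dms"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} matched mutations; need at least 3")
    out = []
    for c in score_cols:
        sub = merged[["delta_evh", c]].dropna()
        rho = spearmanr(sub["delta_evh"], sub[c]).statistic
        out.append((c, float(rho), len(sub)))
    return pd.DataFrame(out, columns=["replicate", "spearman", "n"])


def fitness_defect_flags(dms: pd.DataFrame, cutoff: float = -1.0) -> pd.DataFrame:
    """Mutations whose score falls strictly below ``cutoff`` in any replicate."""
    score_cols = [c for c in dms.columns if c not in ("position", "wt", "mut")]
    flagged = (dms[score_cols] < cutoff).any(axis=1)
    return dms.loc[flagged, ["position", "wt", "mut"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# design summaries


def design_summary(designs: dict[str, str] | list[str], wt: str,
                   msa: Alignment | None, model: PottsModel | None = None) -> pd.DataFrame:
    """Per-design table: mutation count, % identity to wt, max % identity
    over the alignment, EVH and dEVH versus wt (when a model is given)."""
    if not isinstance(designs, dict):
        designs = {f"design_{k}": d for k, d in enumerate(designs)}
    wt_evh = evh(model, wt) if model is not None else np.nan
    rows = []
    for name, seq in designs.items():
        d = normalized_hamming(seq, wt)
        L = len(seq)
        max_id = np.nan
        if msa is not None:
            max_id = 100.0 * max(1.0 - normalized_hamming(seq, r) for r in msa.rows)
        e = evh(model, seq) if model is not None else np.nan
        rows.append((name, int(round(d * L)), 100.0 * (1.0 - d), max_id,
                     e, e - wt_evh if model is not None else np.nan))
    return pd.DataFrame(rows, columns=[
        "design", "n_mutations", "identity_to_wt_pct", "max_identity_msa_pct",
        "evh", "delta_evh_vs_wt",
    ])


# ---------------------------------------------------------------------------
# background-dependence analyses


def quadrant_analysis(model: PottsModel, wt, design) -> pd.DataFrame:
    """Score each design mutation in both the wt and the design background.

    For each position where design != wt, the substitution wt_i ->
    design_i is evaluated once in the wt background and once in the
    design background (the design with position i reverted to wt).
    Quadrants: Q1 = positive in design / negative in wt, Q2 = positive in
    both, Q3 = negative in design / positive in wt, Q4 = negative in
    both (zero counts as negative). Returns per-mutation rows; use
    :func:`quadrant_percentages` for the 4-way summary.
    """
    s_wt = model._as_indices(wt)
    s_de = model._as_indices(design)
    rows = []
    for i in np.flatnonzero(s_wt != s_de):
        d_wt = delta_evh(model, s_wt, [(i, s_de[i])])
        d_design = -delta_evh(model, s_de, [(i, s_wt[i])])
        pos_wt, pos_de = d_wt > 0, d_design > 0
        quadrant = ("Q2" if pos_wt else "Q1") if pos_de else ("Q3" if pos_wt else "Q4")
        rows.append((int(model.index_map[i]), model.alphabet[s_wt[i]],
                     model.alphabet[s_de[i]], d_wt, d_design, quadrant))
    return pd.DataFrame(rows, columns=[
        "position", "wt", "mut", "delta_evh_wt_background",
        "delta_evh_design_background", "quadrant",
    ])


def quadrant_percentages(table: pd.DataFrame) -> pd.Series:
    """Percent of mutations per quadrant; empty input gives an empty series."""
    if len(table) == 0:
        return pd.Series(dtype=float)
    pct = table["quadrant"].value_counts(normalize=True) * 100.0
    return pct.reindex(["Q1", "Q2", "Q3", "Q4"], fill_value=0.0)


def reversion_scan(model: PottsModel, wt, design) -> pd.DataFrame:
    """dEVH of individually reverting each design mutation back to wt,
    evaluated in the design background."""
    s_wt = model._as_indices(wt)
    s_de = model._as_indices(design)
    rows = []
    for i in np.flatnonzero(s_wt != s_de):
        d = delta_evh(model, s_de, [(i, s_wt[i])])
        rows.append((int(model.index_map[i]), model.alphabet[s_de[i]],
                     model.alphabet[s_wt[i]], d, "design"))
    return pd.DataFrame(rows, columns=["position", "wt", "mut", "delta_evh",
                                       "background_id"])


def random_mutation_baseline(model: PottsModel, wt, k: int, n: int,
                             seed: int = 0) -> np.ndarray:
    """EVH of n random k-mutants of wt (distinct positions, non-wt amino acids)."""
    s = model._as_indices(wt)
    if not 0 <= k <= model.L:
        raise ValueError("mutation count k must lie in [0, L]")
    aa_states = np.array([i for i, c in enumerate(model.alphabet) if c != GAP])
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    for t in range(n):
        mut = s.copy()
        pos = rng.choice(model.L, size=k, replace=False)
        for i in pos:
            choices = aa_states[aa_states != s[i]]
            mut[i] = rng.choice(choices)
        out[t] = evh(model, mut)
    return out


# ---------------------------------------------------------------------------
# codon-aware reverse translation


def reverse_translate(protein: str, wt_dna: str, usage: dict[str, float],
                      table_id: int = 11) -> str:
    """Reverse-translate a designed protein reusing wild-type codons.

    Unchanged residues keep the wild-type codon. A changed residue gets
    the synonymous codon (standard/bacterial table ``table_id``) whose
    usage frequency is closest to the wild-type codon's; ties break
    alphabetically. ``usage`` maps codon -> frequency.
    """
    wt_dna = wt_dna.upper().replace("U", "T")
    if len(wt_dna) % 3 != 0:
        raise ValueError("wt_dna length is not a multiple of 3")
    wt_prot = str(Seq(wt_dna).translate(table=table_id))
    if wt_prot.endswith("*"):
        wt_prot = wt_prot[:-1]
    codons = [wt_dna[3 * k : 3 * k + 3] for k in range(len(wt_dna) // 3)]
    has_stop = len(codons) == len(wt_prot) + 1
    if len(wt_prot) != len(protein):
        raise ValueError(
            f"wt_dna translates to {len(wt_prot)} residues but protein has {len(protein)}"
        )
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in tab.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)

    out = []
    for k, (aa_new, aa_wt) in enumerate(zip(protein.upper(), wt_prot)):
        if aa_new == aa_wt:
            out.append(codons[k])
            continue
        candidates = sorted(by_aa.get(aa_new, []))
        if not candidates:
            raise ValueError(f"no codon encodes residue {aa_new!r}")
        wt_freq = usage.get(codons[k], 0.0)
        out.append(min(candidates, key=lambda c: (abs(usage.get(c, 0.0) - wt_freq), c)))
    if has_stop:
        out.append(codons[-1])
    return "".join(out)
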