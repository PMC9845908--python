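"""Consensus miRNA-target calling and reciprocal-best-hit orthology.

Targets are called only when both predictors agree: predictor A pairs must
pass its score/energy thresholds (score >= 140, energy <= -20 kcal/mol) and
predictor B must report the same pair with p below the cutoff (default
0.01).  Orthologs between two gene sets are reciprocal best hits in
directional similarity tables, best = lowest e-value with deterministic tie
breaking (higher bitscore, then lexicographic subject), both e-values at or
below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .correspondence import hypergeometric_overlap


@dataclass(frozen=True)
class RBHPair:
    gene_a: str
    gene_b: str
    evalue_ab: float
    evalue_ba: float


def consensus_targets(
    preds_a: pd.DataFrame,
    preds_b: pd.DataFrame,
    p_max: float = 0.01,
    min_score_a: float = 140.0,
    max_energy: float = -20.0,
) -> set[tuple[str, str]]:
    """(miRNA, gene) pairs predicted by both programs with B's p < p_max.

    ``preds_a`` must carry score/energy columns, ``preds_b`` energy/p; the
    argument order is enforced, not guessed.
    """
    for col in ("mirna", "gene", "score", "energy"):
        if col not in preds_a.columns:
            raise ValueError(f"predictor A table missing column {col!r}")
    if "p" in preds_a.columns:
        raise ValueError("predictor A table carries a p column; arguments swapped?")
    for col in ("mirna", "gene", "energy", "p"):
        if col not in preds_b.columns:
            raise ValueError(f"predictor B table missing column {col!r}")

    a_ok = preds_a[(preds_a["score"] >= min_score_a) & (preds_a["energy"] <= max_energy)]
    b_ok = preds_b[(preds_b["energy"] <= max_energy) & (preds_b["p"] < p_max)]
    pairs_a = set(zip(a_ok["mirna"], a_ok["gene"]))
    pairs_b = set(zip(b_ok["mirna"], b_ok["gene"]))
    return pairs_a & pairs_b


def _best_hits(hits: pd.DataFrame) -> dict[str, tuple[str, float]]:
    """Best subject per query: lowest e-value, ties by bitscore then subject."""
    best: dict[str, tuple[str, float, float]] = {}
    for row in hits.itertuples(index=False):
        q, s, ev, bits = row.query, row.subject, float(row.evalue), float(row.bitscore)
        cur = best.get(q)
        if (
            cur is None
            or ev < cur[1]
            or (ev == cur[1] and (bits > cur[2] or (bits == cur[2] and s < cur[0])))
        ):
            best[q] = (s, ev, bits)
    return {q: (s, ev) for q, (s, ev, _) in best.items()}


def rbh_orthologs(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    evalue_max: float = 1e-5,
) -> list[RBHPair]:
    """Reciprocal best hits between gene sets A and B.

    A pair (a, b) is emitted iff b is a's best hit, a is b's best hit, and
    both e-values are at or below ``evalue_max``.  One-to-one by
    construction; output sorted by gene A identifier.
    """
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a, (b, ev_ab) in best_ab.items():
        back = best_ba.get(b)
        if back is None:
            continue
        a_back, ev_ba = back
        if a_back == a and ev_ab <= evalue_max and ev_ba <= evalue_max:
            pairs.append(RBHPair(a, b, ev_ab, ev_ba))
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def set_overlap_test(set_a, set_b, universe) -> dict:
    """Hypergeometric overlap of two gene sets plus coverage of set A.

    Reports k, hypergeometric p, representation factor, and the fraction of
    set A found in set B.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not universe:
        raise ValueError("empty universe")
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    p, rf = hypergeometric_overlap(k, len(a), len(b), len(universe))
    return {
        "k": k,
        "n_a": len(a),
        "n_b": len(b),
        "universe": len(universe),
        "p_hypergeom": p,
        "representation_factor": rf,
        "coverage_of_a": (k / len(a)) if a else 0.0,
    }
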