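"""Seed-based fragment retrieval, precision-recall evaluation and NN search.

The retrieval protocol mirrors a motif-search scenario: one family member
(the seed) is scored against a bank mixing family members and decoys, hits
are ranked by increasing dissimilarity, and the ranking is summarized by a
precision-recall curve and its area (average precision).  ``rank_asdasym``
adds the mirror-discrimination step: hits whose chirality determinant
against the seed is positive are ranked first, mirror-image hits after.

Because the padded spectral score is a pseudometric, nearest-neighbor
search can be pruned exactly with the triangle inequality against a set of
pivot fragments (:func:`nn_search_ti`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import partial
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .fragment import CAlphaFragment, LengthMismatchError
from .reference import chirality_sign, rmsd, rmsd_d
from .spectral import asd, asd_truncated, asd_unpadded, nasd

__all__ = [
    "SCORERS",
    "RankedRetrieval",
    "PRCurve",
    "rank_against",
    "rank_asdasym",
    "precision_recall",
    "precision_at_recall",
    "jackknife",
    "nn_search_ti",
    "score_quantiles",
]

#: Named scorers usable in rankings and matrices; all ascending (lower = more similar).
SCORERS: Dict[str, Callable[[CAlphaFragment, CAlphaFragment], float]] = {
    "asd": asd,
    "asd_unpadded": asd_unpadded,
    "nasd": nasd,
    "asd_truncated": partial(asd_truncated, k=5),
    "rmsd": lambda p, q: rmsd(p, q).rmsd,
    "rmsd_d": rmsd_d,
}


@dataclass(frozen=True)
class Hit:
    fragment_id: str
    score: float
    relevant: Optional[bool] = None
    chirality: Optional[int] = None


@dataclass(frozen=True)
class RankedRetrieval:
    """Hits sorted by score (ascending), ties broken by fragment id."""

    seed_id: str
    hits: List[Hit]
    direction: str = "lower-is-better"
    unscorable: List[str] = field(default_factory=list)


@dataclass(frozen=True)
class PRCurve:
    """One precision-recall point per rank position; auc is average precision."""

    recall: np.ndarray
    precision: np.ndarray
    auc: float


def _resolve_scorer(scorer) -> Callable[[CAlphaFragment, CAlphaFragment], float]:
    if callable(scorer):
        return scorer
    try:
        return SCORERS[scorer]
    except KeyError:
        raise ValueError(f"unknown scorer {scorer!r}; options: {sorted(SCORERS)}")


def _labels_for(bank: Sequence[CAlphaFragment],
                labels: Optional[Dict[str, bool]]) -> Dict[str, Optional[bool]]:
    if labels is None:
        return {f.id: None for f in bank}
    return {f.id: labels.get(f.id) for f in bank}


def rank_against(
    seed: CAlphaFragment,
    bank: Sequence[CAlphaFragment],
    scorer="asd",
    labels: Optional[Dict[str, bool]] = None,
) -> RankedRetrieval:
    """Score every bank member against the seed and sort ascending.

    Pairs a scorer cannot handle (length mismatch for superposition-style
    scores) are excluded from the ranking and reported in ``unscorable``.
    """
    if not bank:
        raise ValueError("bank is empty")
    fn = _resolve_scorer(scorer)
    lab = _labels_for(bank, labels)
    scored, unscorable = [], []
    for frag in bank:
        try:
            s = fn(seed, frag)
        except LengthMismatchError:
            unscorable.append(frag.id)
            continue
        scored.append(Hit(frag.id, float(s), lab[frag.id]))
    scored.sort(key=lambda h: (h.score, h.fragment_id))
    return RankedRetrieval(seed.id, scored, unscorable=unscorable)


def rank_asdasym(
    seed: CAlphaFragment,
    bank: Sequence[CAlphaFragment],
    labels: Optional[Dict[str, bool]] = None,
) -> RankedRetrieval:
    """Two-block ranking: positive-chirality hits by asd, then mirror hits.

    Requires an equal-length bank (the determinant test needs one-to-one
    coordinates).  Indeterminate chirality goes in the positive block,
    flagged through the hit's ``chirality`` field (0).
    """
    if not bank:
        raise ValueError("bank is empty")
    lab = _labels_for(bank, labels)
    pos_block, neg_block = [], []
    for frag in bank:
        sign = chirality_sign(seed, frag)
        hit = Hit(frag.id, float(asd(seed, frag)), lab[frag.id], chirality=sign)
        (neg_block if sign < 0 else pos_block).append(hit)
    key = lambda h: (h.score, h.fragment_id)
    pos_block.sort(key=key)
    neg_block.sort(key=key)
    return RankedRetrieval(seed.id, pos_block + neg_block)


def precision_recall(ranking: RankedRetrieval) -> PRCurve:
    """PR curve over rank positions; auc is the average precision.

    AP-style integration (sum of precision at each relevant hit over the
    number of relevant items) avoids the linear-interpolation bias of
    trapezoids in PR space.
    """
    rel = np.array([bool(h.relevant) for h in ranking.hits])
    n_rel = int(rel.sum())
    if n_rel == 0:
        raise ValueError("ranking has no relevant item; recall is undefined")
    positions = np.arange(1, rel.size + 1)
    tp = np.cumsum(rel)
    recall = tp / n_rel
    precision = tp / positions
    auc = float(np.sum(precision[rel]) / n_rel)
    return PRCurve(recall=recall, precision=precision, auc=auc)


def precision_at_recall(curve: PRCurve, recall_level: float) -> float:
    """Precision at the first rank position whose recall reaches the level."""
    if not 0 < recall_level <= 1:
        raise ValueError("recall_level must be in (0, 1]")
    idx = np.nonzero(curve.recall >= recall_level - 1e-12)[0]
    if idx.size == 0:
        raise ValueError(f"recall never reaches {recall_level}")
    return float(curve.precision[idx[0]])


def jackknife(
    bank: Sequence[CAlphaFragment],
    labels: Dict[str, bool],
    scorer="asd",
    include_seed: bool = True,
    asdasym: bool = False,
) -> List[tuple[str, PRCurve]]:
    """Use every positive fragment in turn as the seed; one PR curve each.

    ``include_seed=False`` removes the seed from its own bank before
    ranking (leave-one-out); the default keeps it as a trivial first hit.
    """
    curves = []
    for seed in bank:
        if not labels.get(seed.id):
            continue
        members = list(bank) if include_seed else [f for f in bank if f.id != seed.id]
        if asdasym:
            ranking = rank_asdasym(seed, members, labels=labels)
        else:
            ranking = rank_against(seed, members, scorer=scorer, labels=labels)
        curves.append((seed.id, precision_recall(ranking)))
    return curves


def nn_search_ti(
    query: CAlphaFragment,
    bank: Sequence[CAlphaFragment],
    pivots: Sequence[CAlphaFragment],
    scorer="asd",
    pivot_bank_scores: Optional[np.ndarray] = None,
) -> tuple[CAlphaFragment, float, int]:
    """Exact nearest neighbor under a pseudometric, with triangle pruning.

    For each candidate x the lower bound ``max_p |d(query,p) - d(p,x)|``
    (valid by the triangle inequality) is compared to the current best;
    candidates whose bound is not smaller are skipped without scoring.
    Returns (nearest fragment, its score, number of full evaluations) — the
    result is identical to a linear scan for any pivot choice.

    ``pivot_bank_scores`` may carry precomputed ``(len(pivots), len(bank))``
    distances.
    """
    if not bank:
        raise ValueError("bank is empty")
    fn = _resolve_scorer(scorer)
    if pivot_bank_scores is None:
        pivot_bank_scores = np.array(
            [[fn(p, x) for x in bank] for p in pivots], dtype=float
        ).reshape(len(pivots), len(bank))
    d_query_pivot = np.array([fn(query, p) for p in pivots], dtype=float)
    if len(pivots):
        bounds = np.max(np.abs(d_query_pivot[:, None] - pivot_bank_scores), axis=0)
    else:
        bounds = np.zeros(len(bank))
    order = np.argsort(bounds, kind="stable")
    best_idx, best_score, n_eval = -1, np.inf, 0
    for i in order:
        if bounds[i] > best_score:
            continue
        s = float(fn(query, bank[i]))
        n_eval += 1
        if s < best_score or (s == best_score and best_idx >= 0
                              and bank[i].id < bank[best_idx].id):
            best_idx, best_score = int(i), s
    return bank[best_idx], best_score, n_eval


def score_quantiles(
    bank: Sequence[CAlphaFragment],
    scorer="asd",
    quantiles: Sequence[float] = (0.05,),
) -> Dict[float, float]:
    """Empirical quantiles of the all-against-all score distribution.

    Scores are collected over the upper triangle (each unordered pair once);
    a low quantile (e.g. 5%) serves as a significance threshold below which
    a score indicates good similarity.
    """
    if len(bank) < 2:
        raise ValueError("bank must contain at least 2 fragments")
    if len(quantiles) == 0:
        raise ValueError("quantile list is empty")
    fn = _resolve_scorer(scorer)
    scores = [
        fn(bank[i], bank[j])
        for i in range(len(bank))
        for j in range(i + 1, len(bank))
    ]
    values = np.quantile(np.asarray(scores, dtype=float), list(quantiles))
    return {float(q): float(v) for q, v in zip(quantiles, values)}
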