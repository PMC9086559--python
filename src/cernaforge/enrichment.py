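"""GSEA-style weighted Kolmogorov-Smirnov enrichment statistic.

Given a gene list ranked by a signed metric (log2 fold-change by
default), the running sum increments by |metric|^weight (normalized by
the in-set total) at set members and decrements by 1/(N - N_hit)
elsewhere; the enrichment score ES is the signed maximum deviation.  The
null distribution comes from random gene-label sets of matching size
(the ranking is a precomputed statistic here, so gene-label permutation
replaces the sample-permutation scheme used when expression replicates
are available).  NES divides ES by the mean magnitude of same-sign null
scores, and the permutation p uses the add-one estimator so it is never
zero.  A set is flagged significant when |NES| > 2 and p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, NumericError


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p: float
    n_perm: int
    significant: bool


def _check_ranking(ranking: pd.Series) -> pd.Series:
    if ranking.index.has_duplicates:
        dup = ranking.index[ranking.index.duplicated()][0]
        raise InvalidArgumentError(f"duplicate gene id in ranking: {dup!r}")
    vals = ranking.to_numpy(dtype=float)
    if np.any(np.diff(vals) > 0):
        ranking = ranking.sort_values(ascending=False, kind="stable")
    return ranking


def _es_from_mask(metric: np.ndarray, mask: np.ndarray, weight: float
                  ) -> tuple[float, np.ndarray]:
    n = len(metric)
    n_hit = int(mask.sum())
    w = np.abs(metric) ** weight
    hit_total = w[mask].sum()
    if hit_total == 0:
        # all in-set metrics are zero: hits carry equal weight
        w = np.ones(n)
        hit_total = float(n_hit)
    steps = np.where(mask, w / hit_total, -1.0 / (n - n_hit))
    running = np.clip(np.cumsum(steps), -1.0, 1.0)  # guard float accumulation
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def enrichment_score(ranking: pd.Series, gene_set: set[str], weight: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running sum.

    ``ranking`` maps gene id -> signed metric, ordered descending.  The
    gene set must intersect the ranking but not contain all of it.
    ``weight=0`` reduces to the classic (unweighted) KS statistic.
    """
    if weight < 0:
        raise InvalidArgumentError("weight must be >= 0")
    ranking = _check_ranking(ranking)
    mask = ranking.index.isin(gene_set)
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise InvalidArgumentError("gene set does not intersect the ranking")
    if n_hit == len(ranking):
        raise InvalidArgumentError("gene set covers the entire ranking")
    return _es_from_mask(ranking.to_numpy(dtype=float), mask, weight)


def gsea(ranking: pd.Series, gene_sets: dict[str, set[str]], n_perm: int = 1000,
         seed: int = 0, weight: float = 1.0,
         min_abs_nes: float = 2.0, max_p: float = 0.05) -> list[EnrichmentResult]:
    """Permutation GSEA over a collection of gene sets.

    For each set the null is built from ``n_perm`` random same-size
    gene-label sets; NES = ES / mean(|null ES| of matching sign);
    p = (1 + #{|null ES| >= |ES|}) / (1 + n_perm), which is uniform
    under a sign-symmetric null.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100")
    ranking = _check_ranking(ranking)
    metric = ranking.to_numpy(dtype=float)
    n = len(metric)
    rng = np.random.default_rng(seed)

    results = []
    for set_id in sorted(gene_sets):
        es, _ = enrichment_score(ranking, gene_sets[set_id], weight)
        n_hit = int(ranking.index.isin(gene_sets[set_id]).sum())
        null = np.empty(n_perm)
        for b in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n_hit, replace=False)] = True
            null[b], _ = _es_from_mask(metric, mask, weight)
        same_sign = null[null >= 0] if es >= 0 else null[null <= 0]
        denom = np.abs(same_sign).mean() if same_sign.size else 0.0
        if denom == 0:
            raise NumericError(f"degenerate permutation null for set {set_id!r}")
        nes = es / denom
        extreme = int(np.sum(np.abs(null) >= abs(es)))
        p = (1 + extreme) / (1 + n_perm)
        results.append(EnrichmentResult(set_id, es, float(nes), float(p), n_perm,
                                        bool(abs(nes) > min_abs_nes and p < max_p)))
    return results
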