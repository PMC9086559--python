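"""Expression quantification and two-group differential testing.

Covers the count-based abundance units used for the two RNA classes —
FPKM (fragments per kilobase of exon per million mapped reads) for linear
mRNAs and SRPBM (spliced reads per billion mapped reads) for back-splice
junction counts of circRNAs — together with TMM between-sample
normalization, an exact conditional two-group count test, and
Benjamini-Hochberg multiple-testing correction.

The differential test is the Poisson-limit analogue of the edgeR-style
exact test: counts are summed within each group and the test-group sum is
compared to a binomial null whose success probability is the ratio of
TMM-adjusted effective library sizes.  Under negative-binomial
overdispersion the raw p-values are anti-conservative; calibration holds
in the Poisson limit (dispersion -> 0), which is the regime the null
simulations use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError

Kind = Literal["count", "FPKM", "SRPBM"]


@dataclass
class ExprMatrix:
    """A features x samples abundance matrix with per-sample depth metadata.

    Parameters
    ----------
    values:
        DataFrame indexed by unique feature ids, columns are unique sample
        ids.  Non-negative.
    kind:
        ``"count"`` for raw (junction) read counts, ``"FPKM"`` or
        ``"SRPBM"`` for normalized abundances.
    lib_sizes:
        Total mapped reads per sample.  Required for counts; carried along
        otherwise.
    feature_lengths_kb:
        Exonic length in kilobases per feature; required for FPKM only.
    """

    values: pd.DataFrame
    kind: Kind = "count"
    lib_sizes: pd.Series | None = None
    feature_lengths_kb: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InvalidArgumentError(f"duplicate feature id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise InvalidArgumentError(f"duplicate sample id: {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise InvalidArgumentError("expression values must be non-negative")
        if self.lib_sizes is not None:
            self.lib_sizes = self.lib_sizes.reindex(self.values.columns)
            if self.lib_sizes.isna().any() or (self.lib_sizes <= 0).any():
                raise InvalidArgumentError("lib_sizes must be positive for every sample")
        if self.feature_lengths_kb is not None:
            self.feature_lengths_kb = self.feature_lengths_kb.reindex(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DEResult:
    """Differential-expression summary for a single feature."""

    feature_id: str
    logFC: float
    p: float
    adj_p: float
    direction: Literal["up", "down", "ns"] = "ns"


def fpkm(counts: ExprMatrix) -> ExprMatrix:
    """Fragments per kilobase of exon per million mapped reads.

    FPKM[i, j] = counts[i, j] / ((lib_sizes[j] / 1e6) * length_kb[i]).
    """
    if counts.kind != "count":
        raise InvalidArgumentError("fpkm expects a count matrix")
    if counts.lib_sizes is None:
        raise InvalidArgumentError("fpkm requires lib_sizes")
    if counts.feature_lengths_kb is None or counts.feature_lengths_kb.isna().any():
        raise InvalidArgumentError("fpkm requires feature_lengths_kb for every feature")
    if (counts.feature_lengths_kb <= 0).any():
        raise InvalidArgumentError("feature lengths must be > 0")
    denom = np.outer(counts.feature_lengths_kb.to_numpy(), counts.lib_sizes.to_numpy() / 1e6)
    vals = counts.values / denom
    return ExprMatrix(vals, kind="FPKM", lib_sizes=counts.lib_sizes,
                      feature_lengths_kb=counts.feature_lengths_kb)


def srpbm(junction_counts: ExprMatrix) -> ExprMatrix:
    """Spliced reads per billion mapped reads for back-splice junction counts.

    SRPBM[i, j] = junction_counts[i, j] / (lib_sizes[j] / 1e9).
    """
    if junction_counts.lib_sizes is None:
        raise InvalidArgumentError("srpbm requires lib_sizes")
    vals = junction_counts.values / (junction_counts.lib_sizes / 1e9)
    return ExprMatrix(vals, kind="SRPBM", lib_sizes=junction_counts.lib_sizes,
                      feature_lengths_kb=junction_counts.feature_lengths_kb)


def tmm_factors(counts: ExprMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, one per sample.

    The reference sample is the one whose 75th count-fraction percentile is
    closest to the mean of those percentiles.  For every other sample the
    factor is 2**(precision-weighted mean of per-feature log2 ratios M),
    after two-sided trimming of the most extreme ``trim_m`` fraction of M
    values and ``trim_a`` fraction of A values (features with a zero in
    either sample excluded).  Factors are rescaled so their geometric mean
    is one.
    """
    mat = counts.values.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise InvalidArgumentError("TMM requires at least two samples")
    if (mat.sum(axis=0) == 0).any():
        raise InvalidArgumentError("TMM: sample with all-zero counts")
    lib = (counts.lib_sizes.to_numpy(dtype=float) if counts.lib_sizes is not None
           else mat.sum(axis=0))

    f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(mat.shape[1])
    cr, lr = mat[:, ref], lib[ref]
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        c, l = mat[:, j], lib[j]
        keep = (c > 0) & (cr > 0)
        if keep.sum() == 0:
            continue
        p, pr = c[keep] / l, cr[keep] / lr
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        # precision weights: inverse of the delta-method variance of M
        w = 1.0 / ((l - c[keep]) / (l * c[keep]) + (lr - cr[keep]) / (lr * cr[keep]))

        n = m.size
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if sel.sum() == 0 or w[sel].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.values.columns, name="tmm_factor")


def _two_level(groups: Sequence[str], samples: Sequence[str], reference: str | None):
    g = pd.Series(list(groups), index=list(samples))
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise InvalidArgumentError(f"exactly two group levels required, got {levels}")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise InvalidArgumentError(f"reference level {ref!r} not among {levels}")
    test = levels[0] if levels[1] == ref else levels[1]
    if (g == ref).sum() < 2 or (g == test).sum() < 2:
        raise InvalidArgumentError("each group needs at least two samples")
    return g, ref, test


def de_test(counts: ExprMatrix, groups: Sequence[str], reference: str | None = None,
            paired: bool = False, pairs: Sequence[str] | None = None,
            pseudo_count: float = 0.5) -> list[DEResult]:
    """Two-group differential test on summed, depth-adjusted counts.

    Per feature the test-group count sum is compared to a binomial null
    conditional on the total, with success probability equal to the
    test-group share of the TMM-adjusted effective library size (an exact
    conditional test in the Poisson limit).  log2 fold-changes come from
    depth-normalized group means with a pseudo-count.  ``paired=True``
    conditions within sample pairs instead (normal approximation to the sum
    of per-pair binomials, continuity-corrected); ``pairs`` then gives the
    pair label of every sample.
    """
    if counts.lib_sizes is None:
        raise InvalidArgumentError("de_test requires lib_sizes on the count matrix")
    g, ref, test = _two_level(groups, counts.sample_ids, reference)
    tmm = tmm_factors(counts)
    eff = counts.lib_sizes * tmm
    mat = counts.values
    is_test = (g == test).to_numpy()
    is_ref = (g == ref).to_numpy()

    # normalized counts on the mean-effective-depth scale, for logFC only
    scale = eff.mean() / eff
    norm = mat * scale.to_numpy()[None, :]
    m_test = norm.to_numpy()[:, is_test].mean(axis=1)
    m_ref = norm.to_numpy()[:, is_ref].mean(axis=1)
    logfc = np.log2((m_test + pseudo_count) / (m_ref + pseudo_count))

    if paired:
        if pairs is None:
            raise InvalidArgumentError("paired=True requires pairs labels")
        pvals = _paired_pvalues(mat, g, ref, test, eff, pd.Series(list(pairs), index=counts.sample_ids))
    else:
        d_test = float(eff[is_test].sum())
        d_ref = float(eff[is_ref].sum())
        p0 = d_test / (d_test + d_ref)
        s_test = mat.to_numpy()[:, is_test].sum(axis=1).astype(int)
        total = s_test + mat.to_numpy()[:, is_ref].sum(axis=1).astype(int)
        pvals = np.ones(len(mat))
        for i in range(len(mat)):
            if total[i] > 0:
                pvals[i] = stats.binomtest(int(s_test[i]), int(total[i]), p0).pvalue

    adj = multipletests(pvals, method="fdr_bh")[1]
    return [DEResult(fid, float(lf), float(p), float(ap))
            for fid, lf, p, ap in zip(counts.feature_ids, logfc, pvals, adj)]


def _paired_pvalues(mat: pd.DataFrame, g: pd.Series, ref: str, test: str,
                    eff: pd.Series, pairs: pd.Series) -> np.ndarray:
    """Stratified (within-pair) conditional test, normal approximation."""
    strata = []
    for pid in pairs.unique():
        members = pairs.index[pairs == pid]
        t = [s for s in members if g[s] == test]
        r = [s for s in members if g[s] == ref]
        if len(t) != 1 or len(r) != 1:
            raise InvalidArgumentError(f"pair {pid!r} must contain one sample per group")
        p_i = float(eff[t[0]] / (eff[t[0]] + eff[r[0]]))
        strata.append((t[0], r[0], p_i))

    n_feat = len(mat)
    pvals = np.ones(n_feat)
    obs = np.zeros(n_feat)
    mean = np.zeros(n_feat)
    var = np.zeros(n_feat)
    for t_s, r_s, p_i in strata:
        tot = mat[t_s].to_numpy() + mat[r_s].to_numpy()
        obs += mat[t_s].to_numpy()
        mean += tot * p_i
        var += tot * p_i * (1 - p_i)
    ok = var > 0
    z = np.zeros(n_feat)
    # 0.5 continuity correction toward the mean
    z[ok] = (np.abs(obs[ok] - mean[ok]) - 0.5).clip(min=0) / np.sqrt(var[ok])
    pvals[ok] = 2 * stats.norm.sf(z[ok])
    return pvals.clip(max=1.0)


def call_de(results: list[DEResult], min_abs_logfc: float = 2.0, max_p: float = 0.05,
            use_adjusted: bool = True) -> list[DEResult]:
    """Apply the screening thresholds and set directions.

    A feature is kept iff |logFC| > min_abs_logfc (strict) and the chosen
    p-value (adjusted or raw) is < max_p (strict).  Directions are set in
    place on every result (``ns`` when not kept); the kept sublist is
    returned.
    """
    if min_abs_logfc <= 0 or max_p <= 0:
        raise InvalidArgumentError("thresholds must be positive")
    kept = []
    for r in results:
        p = r.adj_p if use_adjusted else r.p
        if abs(r.logFC) > min_abs_logfc and p < max_p:
            r.direction = "up" if r.logFC > 0 else "down"
            kept.append(r)
        else:
            r.direction = "ns"
    return kept


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """Tabulate DE results (feature, logFC, p, adj_p, direction)."""
    return pd.DataFrame(
        [(r.feature_id, r.logFC, r.p, r.adj_p, r.direction) for r in results],
        columns=["feature_id", "logFC", "p", "adj_p", "direction"],
    ).set_index("feature_id")
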