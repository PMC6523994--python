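"""Count normalization, differential expression, and gene-set enrichment.

Normalization uses the median-of-ratios method: each sample's size factor is
the median, over features whose counts are nonzero in every sample, of that
sample's count divided by the feature's geometric mean across samples.

Differential testing models counts as negative binomial with
``var = mu + dispersion * mu^2``. Per-feature dispersions are estimated by
the method of moments within groups and shrunk 50/50 toward the global
median dispersion, then a Wald test is applied to the log2 fold change of
the normalized group means. Multiple testing is controlled by
Benjamini-Hochberg. Features below a mean-count floor are excluded from
testing (independent filtering) and flagged.

One-versus-one comparisons (no replicates) cannot support a dispersion
estimate and fall back to a two-sided exact binomial test on the pooled
proportion per feature — documented lower power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2_SQ = np.log(2.0) ** 2


class SizeFactorError(ValueError):
    pass


def estimate_size_factors(matrix: pd.DataFrame, pseudocount_fallback: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Features with a zero count in any sample are excluded from the medians
    (their log-ratios are undefined). If no feature survives, either raise
    or — with ``pseudocount_fallback`` — re-estimate on counts + 1.
    """
    counts = matrix.to_numpy(dtype=float)
    if counts.size == 0:
        raise SizeFactorError("empty count matrix")
    if (counts < 0).any():
        raise ValueError("count matrix contains negative entries")
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        if not pseudocount_fallback:
            raise SizeFactorError(
                "no feature has nonzero counts in all samples; "
                "enable pseudocount_fallback to estimate on counts + 1"
            )
        counts = counts + 1.0
        usable = np.ones(len(counts), dtype=bool)
    sub = counts[usable]
    log_geomean = np.mean(np.log(sub), axis=1)
    log_ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


@dataclass
class DEOptions:
    alpha: float = 0.05          # padj threshold for the significance flag
    min_mean: float = 1.0        # independent-filtering floor on mean normalized count
    lfc_pseudocount: float = 0.5
    min_dispersion: float = 1e-8
    pseudocount_fallback: bool = False


def de_test(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    options: Optional[DEOptions] = None,
) -> pd.DataFrame:
    """Two-group differential expression on a feature x sample count matrix.

    Returns one row per feature: base_mean_a, base_mean_b (normalized group
    means), log2fc (B over A), p_value, padj, significant, tested. Features
    failing the mean-count floor carry NaN p/padj and tested=False.
    """
    opts = options or DEOptions()
    opts.alpha = alpha
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both comparison groups need at least one sample")
    missing = [s for s in group_a + group_b if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples absent from count matrix: {missing}")

    sub = matrix[group_a + group_b]
    sf = estimate_size_factors(sub, pseudocount_fallback=opts.pseudocount_fallback)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()
    na, nb = len(group_a), len(group_b)
    xa, xb = norm[:, :na], norm[:, na:]
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    mean_all = norm.mean(axis=1)
    tested = mean_all >= opts.min_mean

    lfc = np.log2(mu_b + opts.lfc_pseudocount) - np.log2(mu_a + opts.lfc_pseudocount)
    p = np.full(len(sub), np.nan)

    if na >= 2 and nb >= 2:
        disp = _moment_dispersion(xa, xb, mu_a, mu_b, opts.min_dispersion)
        # The median of the moment estimator underestimates the common
        # dispersion (the pooled variance is ~ chi^2_df scaled); correct by
        # the median of chi^2_df/df before using it as the shrinkage target.
        df = na + nb - 2
        bias = stats.chi2.median(df) / df
        if tested.any():
            target = np.median(disp[tested]) / bias
        else:
            target = opts.min_dispersion
        # 50/50 shrink toward the global target, floored at the target so a
        # feature with an under-estimated dispersion cannot inflate its Wald
        # statistic (the main small-sample failure mode of the plain moment
        # estimator).
        disp = np.maximum(0.5 * disp + 0.5 * target, target)
        # delta-method variance of log2 of an NB mean of n samples
        var_lfc = (
            (1.0 / np.maximum(mu_a, opts.lfc_pseudocount) + disp) / (na * LN2_SQ)
            + (1.0 / np.maximum(mu_b, opts.lfc_pseudocount) + disp) / (nb * LN2_SQ)
        )
        z = lfc / np.sqrt(var_lfc)
        p[tested] = 2.0 * stats.norm.sf(np.abs(z[tested]))
    else:
        # no replicates: exact binomial on pooled raw counts per feature
        raw = sub.to_numpy(dtype=float)
        ka = raw[:, :na].sum(axis=1)
        kb = raw[:, na:].sum(axis=1)
        prob_a = sf[group_a].sum() / sf.sum()
        for i in np.flatnonzero(tested):
            n_tot = int(round(ka[i] + kb[i]))
            if n_tot == 0:
                p[i] = 1.0
                continue
            p[i] = stats.binomtest(int(round(ka[i])), n_tot, prob_a).pvalue
    p = np.clip(p, 0.0, 1.0)

    padj = np.full(len(sub), np.nan)
    if tested.any():
        padj[tested] = bh_adjust(p[tested])
    result = pd.DataFrame({
        "feature": matrix.index,
        "base_mean_a": mu_a,
        "base_mean_b": mu_b,
        "log2fc": lfc,
        "p_value": p,
        "padj": padj,
        "tested": tested,
    })
    result["significant"] = result["padj"] < opts.alpha
    return result.set_index("feature")


def _moment_dispersion(xa, xb, mu_a, mu_b, floor) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per feature."""
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)
    pooled_var = (var_a * (xa.shape[1] - 1) + var_b * (xb.shape[1] - 1)) / (
        xa.shape[1] + xb.shape[1] - 2
    )
    pooled_mu = (mu_a * xa.shape[1] + mu_b * xb.shape[1]) / (xa.shape[1] + xb.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - pooled_mu) / np.where(pooled_mu > 0, pooled_mu**2, 1.0)
    return np.clip(np.nan_to_num(disp, nan=floor), floor, None)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    return multipletests(p, method="fdr_bh")[1]


def enrichment_test(
    hits: Sequence[str],
    universe: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    ``hits`` must be a subset of ``universe``; each set is intersected with
    the universe first. Returns per set: set size (in universe), overlap,
    p_value, padj (BH across sets), significant (padj < fdr).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    hit_set = set(hits)
    stray = hit_set - universe_set
    if stray:
        raise ValueError(f"{len(stray)} hit(s) not present in the universe")
    m_total = len(universe_set)
    n_hits = len(hit_set)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe_set
        overlap = len(in_universe & hit_set)
        # P(X >= overlap), X ~ Hypergeom(M=m_total, K=|set|, N=n_hits)
        pval = stats.hypergeom.sf(overlap - 1, m_total, len(in_universe), n_hits)
        rows.append((name, len(in_universe), overlap, float(pval)))
    result = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    result["padj"] = bh_adjust(result["p_value"].to_numpy()) if len(result) else []
    result["significant"] = result["padj"] < fdr
    return result.set_index("set")
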