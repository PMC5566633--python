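"""Negative-binomial exact testing for over-expressed silk transcripts.

The test conditions on the total count after equalizing library sizes to
their geometric mean (simple proportional scaling with rounding).  Group
sums of n i.i.d. NB(mu, phi) libraries are treated as NB with mean n*mu and
dispersion phi/n; two-sided p-values sum conditional probabilities of all
outcomes no more likely than the observed one.  Dispersion 0 degenerates to
the conditional binomial (Poisson) test.

Dispersion estimation maximizes the conditional (on per-group totals) NB
log-likelihood, pooled over transcripts for the common value and shrunk
toward it by a weighted likelihood for transcript-wise values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .normalize import (
    CountMatrix,
    compute_cpm,
    low_expression_filter,
    tmm_factors,
)

__all__ = [
    "estimate_common_dispersion",
    "estimate_tagwise_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "call_oests",
    "per_gland_contrast",
    "twofold_silk_flag",
]

_PHI_FLOOR = 1e-8


def equalize_library_sizes(counts: pd.DataFrame, effective_sizes: pd.Series) -> pd.DataFrame:
    """Scale counts to the geometric-mean effective library size, rounded.

    A simplification of quantile-adjusted pseudo-counts: each library's
    counts are multiplied by (geomean size / its size) and rounded to the
    nearest integer, preserving the conditional-test logic.
    """
    sizes = effective_sizes.reindex(counts.columns).astype(float)
    if (sizes <= 0).any():
        raise ValueError("effective library sizes must be > 0")
    common = float(np.exp(np.log(sizes).mean()))
    return counts.mul(common / sizes, axis=1).round().astype(np.int64)


def _group_cond_loglik(Y: np.ndarray, phi: float) -> np.ndarray:
    """Conditional NB log-likelihood per transcript for one group.

    ``Y`` is transcripts x replicate libraries (equal effective sizes).
    Terms independent of phi are dropped.  Groups of size 1 contribute 0.
    """
    n = Y.shape[1]
    if n < 2:
        return np.zeros(Y.shape[0])
    r = 1.0 / max(phi, _PHI_FLOOR)
    z = Y.sum(axis=1)
    return (
        gammaln(Y + r).sum(axis=1)
        + gammaln(n * r)
        - gammaln(z + n * r)
        - n * gammaln(r)
    )


def _total_cond_loglik(groups: list[np.ndarray], phi: float) -> np.ndarray:
    out = None
    for Y in groups:
        ll = _group_cond_loglik(Y, phi)
        out = ll if out is None else out + ll
    return out


def _split_groups(counts: pd.DataFrame, group_labels: pd.Series) -> list[np.ndarray]:
    labels = group_labels.reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("every library needs a group label")
    return [
        counts.loc[:, labels.index[labels == g]].to_numpy()
        for g in labels.unique()
    ]


def estimate_common_dispersion(
    counts: pd.DataFrame,
    group_labels: pd.Series,
    effective_sizes: pd.Series,
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Requires at least one group with >= 2 libraries.  Returns phi >= 0 (the
    squared biological coefficient of variation).
    """
    groups = _split_groups(equalize_library_sizes(counts, effective_sizes), group_labels)
    if all(Y.shape[1] < 2 for Y in groups):
        raise ValueError("no replicated group: common dispersion is not estimable")

    def neg_ll(log_phi: float) -> float:
        return -float(_total_cond_loglik(groups, np.exp(log_phi)).sum())

    res = minimize_scalar(neg_ll, bounds=(np.log(1e-6), np.log(50.0)), method="bounded")
    phi = float(np.exp(res.x))
    return 0.0 if phi <= 2e-6 else phi


def estimate_tagwise_dispersion(
    counts: pd.DataFrame,
    group_labels: pd.Series,
    effective_sizes: pd.Series,
    common_dispersion: float | None = None,
    prior_weight: float = 10.0,
    grid_size: int = 121,
) -> pd.Series:
    """Transcript-wise dispersions shrunk toward the common value.

    Maximizes ``l_t(phi) + prior_weight * lbar(phi)`` per transcript, where
    ``lbar`` is the mean conditional log-likelihood over all transcripts and
    ``prior_weight`` is the prior strength in equivalent observations.  An
    infinite prior weight returns the common dispersion for every
    transcript; weight 0 gives the stand-alone conditional ML.
    """
    if common_dispersion is None:
        common_dispersion = estimate_common_dispersion(counts, group_labels, effective_sizes)
    if np.isinf(prior_weight):
        return pd.Series(common_dispersion, index=counts.index)

    groups = _split_groups(equalize_library_sizes(counts, effective_sizes), group_labels)
    grid = np.exp(np.linspace(np.log(1e-6), np.log(50.0), grid_size))
    L = np.column_stack([_total_cond_loglik(groups, phi) for phi in grid])
    objective = L + prior_weight * L.mean(axis=0)[None, :]
    best = objective.argmax(axis=1)

    # parabolic refinement on log-phi around the grid argmax
    log_grid = np.log(grid)
    phi_hat = grid[best].astype(float)
    interior = (best > 0) & (best < grid_size - 1)
    idx = np.where(interior)[0]
    if idx.size:
        b = best[idx]
        y0, y1, y2 = (objective[idx, b - 1], objective[idx, b], objective[idx, b + 1])
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        step = log_grid[1] - log_grid[0]
        phi_hat[idx] = np.exp(log_grid[b] + np.clip(shift, -1, 1) * step)
    phi_hat[phi_hat <= 2e-6] = 0.0
    return pd.Series(phi_hat, index=counts.index)


def _group_sum_logpmf(k: np.ndarray, n_libs: int, mu_per_lib: float, phi: float) -> np.ndarray:
    """log pmf of the sum of ``n_libs`` NB(mu, phi) counts at values ``k``."""
    mean = n_libs * mu_per_lib
    if phi <= 0:
        return k * np.log(mean) - mean - gammaln(k + 1)
    r = n_libs / phi
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def nb_exact_test(
    counts_a,
    counts_b,
    dispersion: float,
    effective_sizes_a=None,
    effective_sizes_b=None,
) -> float:
    """Two-sided exact NB test of a single transcript between two groups.

    ``counts_a``/``counts_b`` are per-library counts.  If effective sizes
    are given, counts are first equalized to the pooled geometric-mean size.
    The p-value sums the conditional probabilities of all splits of the
    total whose probability does not exceed the observed split's
    (minimum-likelihood two-sided convention, ties included).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.atleast_1d(np.asarray(counts_a, dtype=float))
    b = np.atleast_1d(np.asarray(counts_b, dtype=float))
    if effective_sizes_a is not None or effective_sizes_b is not None:
        sizes = np.concatenate(
            [np.asarray(effective_sizes_a, float), np.asarray(effective_sizes_b, float)]
        )
        common = np.exp(np.log(sizes).mean())
        a = np.round(a * common / np.asarray(effective_sizes_a, float))
        b = np.round(b * common / np.asarray(effective_sizes_b, float))
    na, nb = len(a), len(b)
    sa, sb = int(round(a.sum())), int(round(b.sum()))
    total = sa + sb
    if total == 0:
        return 1.0
    mu = total / (na + nb)
    k = np.arange(total + 1)
    logp = _group_sum_logpmf(k, na, mu, dispersion) + _group_sum_logpmf(
        total - k, nb, mu, dispersion
    )
    logp -= logsumexp(logp)
    obs = logp[sa]
    # relative tie tolerance keeps exact symmetric ties (k, total-k) together
    return float(min(1.0, np.exp(logsumexp(logp[logp <= obs + 1e-10]))))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _de_table(
    counts: pd.DataFrame,
    libs_a: list[str],
    libs_b: list[str],
    effective_sizes: pd.Series,
    dispersions: pd.Series,
    alpha: float,
) -> pd.DataFrame:
    """Exact tests of group A (silk) vs group B (non-silk) per transcript."""
    eq = equalize_library_sizes(counts[libs_a + libs_b], effective_sizes[libs_a + libs_b])
    A, B = eq[libs_a].to_numpy(), eq[libs_b].to_numpy()
    pvals = np.empty(len(eq))
    for i in range(len(eq)):
        pvals[i] = nb_exact_test(A[i], B[i], float(dispersions.iloc[i]))
    # log2FC on CPM + 0.25 pseudo-count; sizes are equalized so CPM ~ counts
    cpm_a = A.mean(axis=1) + 0.25
    cpm_b = B.mean(axis=1) + 0.25
    logfc = np.log2(cpm_a / cpm_b)
    fdr = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "p": pvals,
            "fdr": fdr,
            "dispersion": dispersions.to_numpy(),
            "oest_flag": (fdr < alpha) & (logfc > 0),
        },
        index=eq.index,
    )


def call_oests(
    cm: CountMatrix,
    silk_tissues,
    alpha: float = 0.05,
    dispersion_mode: str = "tagwise",
    prior_weight: float = 10.0,
) -> pd.DataFrame:
    """Call over-expressed silk transcripts: pooled silk vs pooled non-silk.

    Pipeline: TMM -> CPM filter (>= 1 CPM in >= 1 library) -> common and
    transcript-wise dispersion -> exact test -> BH.  ``oest_flag`` is true
    for silk-overrepresented transcripts with FDR < ``alpha``.
    """
    silk_tissues = set(silk_tissues)
    sheet = cm.sample_sheet.loc[list(cm.libraries)]
    silk_libs = list(sheet.index[sheet["tissue"].isin(silk_tissues)])
    nonsilk_libs = list(sheet.index[~sheet["tissue"].isin(silk_tissues)])
    if not silk_libs or not nonsilk_libs:
        raise ValueError("need both silk and non-silk libraries")

    factors = tmm_factors(cm)
    cpm = compute_cpm(cm, factors)
    keep = low_expression_filter(cpm)
    counts = cm.counts.loc[keep]
    eff_sizes = cm.library_size.reindex(cm.libraries) * factors

    groups = pd.Series(
        ["silk" if lib in silk_libs else "nonsilk" for lib in cm.libraries],
        index=cm.libraries,
    )
    common = estimate_common_dispersion(counts, groups, eff_sizes)
    if dispersion_mode == "tagwise":
        disp = estimate_tagwise_dispersion(
            counts, groups, eff_sizes, common, prior_weight=prior_weight
        )
    elif dispersion_mode == "common":
        disp = pd.Series(common, index=counts.index)
    else:
        raise ValueError("dispersion_mode must be 'tagwise' or 'common'")
    out = _de_table(counts, silk_libs, nonsilk_libs, eff_sizes, disp, alpha)
    out.attrs["common_dispersion"] = common
    return out


def per_gland_contrast(
    cm: CountMatrix,
    gland: str,
    silk_tissues,
    alpha: float = 0.05,
    fixed_dispersion: float = 0.4,
    prior_weight: float = 10.0,
) -> pd.DataFrame:
    """One gland type vs pooled non-silk tissues.

    Transcript-wise dispersions are used when the gland has replicates; with
    a single gland library the dispersion is fixed (default 0.4) to
    approximate the biological coefficient of variation.
    """
    sheet = cm.sample_sheet.loc[list(cm.libraries)]
    if gland not in set(sheet["tissue"]):
        raise KeyError(f"unknown gland {gland!r}")
    silk_tissues = set(silk_tissues)
    gland_libs = list(sheet.index[sheet["tissue"] == gland])
    nonsilk_libs = list(sheet.index[~sheet["tissue"].isin(silk_tissues)])
    if not nonsilk_libs:
        raise ValueError("no non-silk libraries")

    factors = tmm_factors(cm)
    cpm = compute_cpm(cm, factors)
    keep = low_expression_filter(cpm)
    sub_libs = gland_libs + nonsilk_libs
    counts = cm.counts.loc[keep, sub_libs]
    eff_sizes = (cm.library_size.reindex(cm.libraries) * factors)[sub_libs]

    replicated = len(gland_libs) >= 2
    if replicated:
        groups = pd.Series(
            ["gland" if lib in gland_libs else "nonsilk" for lib in sub_libs],
            index=sub_libs,
        )
        disp = estimate_tagwise_dispersion(counts, groups, eff_sizes, prior_weight=prior_weight)
    else:
        disp = pd.Series(fixed_dispersion, index=counts.index)
    out = _de_table(counts, gland_libs, nonsilk_libs, eff_sizes, disp, alpha)
    out.attrs["gland_replicated"] = replicated
    return out


def twofold_silk_flag(
    tissue_profile: pd.DataFrame,
    silk_tissues,
    fold: float = 2.0,
    fpkm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-transcript 2-fold-silk and mean-FPKM>1 flags for one species.

    ``twofold``: mean over silk-gland tissue means strictly greater than
    ``fold`` x mean over non-silk tissue means; a zero non-silk mean with a
    positive silk mean counts as above threshold, 0/0 does not.
    ``fpkm_gt1``: mean FPKM above ``fpkm_threshold`` in at least one tissue.
    """
    silk_tissues = [t for t in tissue_profile.columns if t in set(silk_tissues)]
    non_silk = [t for t in tissue_profile.columns if t not in set(silk_tissues)]
    if not silk_tissues or not non_silk:
        raise ValueError("profile needs both silk and non-silk tissues")
    silk_mean = tissue_profile[silk_tissues].mean(axis=1)
    non_mean = tissue_profile[non_silk].mean(axis=1)
    twofold = (silk_mean > fold * non_mean) & (silk_mean > 0)
    return pd.DataFrame(
        {
            "twofold": twofold,
            "fpkm_gt1": (tissue_profile > fpkm_threshold).any(axis=1),
        },
        index=tissue_profile.index,
    )
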