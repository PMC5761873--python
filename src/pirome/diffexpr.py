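"""Differential expression calls for piRNA counts and gene expression.

Two routes match the two data types:

* **Counts, no replicates** — median-of-ratios size factors, then a
  "blind" dispersion estimate: the two conditions are pooled as if they
  were replicates, a gamma-family mean-dispersion trend
  ``alpha(q) = a0 + a1/q`` is fitted, and each feature uses only its
  fitted (trend) dispersion.  Case and control totals are then compared
  with a two-sided negative-binomial exact-style test (probability
  ordering).  This is the only defensible path with one library per
  condition and is conservative by construction.
* **Expression matrix** — log2 intensities, 20th-percentile intensity
  floor, Welch unpaired t-test per feature, Benjamini-Hochberg FDR.

Calls use fold-change >= 1.5 with raw p <= 0.05 for counts, and
fold-change >= 2.0 with BH q <= 0.05 for the expression matrix;
"anomalous" marks features silent in exactly one condition, whose
fold-change is undefined.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

_MIN_DISP = 1e-8


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    Only features with nonzero counts in every sample enter the
    geometric means; if there are none the data cannot be normalized
    this way and a pseudocount is advised.
    """
    counts = counts.astype(float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; "
            "add a pseudocount or filter samples"
        )
    log_counts = np.log(counts.loc[all_pos])
    log_geomean = log_counts.mean(axis=1)
    factors = np.exp((log_counts.sub(log_geomean, axis=0)).median(axis=0))
    return factors


def _fit_dispersion_trend(q: np.ndarray, alpha_raw: np.ndarray) -> tuple[float, float]:
    """Fit alpha(q) = a0 + a1/q by a gamma GLM with identity link.

    The fit is iterated with outlier trimming (features whose raw
    dispersion exceeds 4x the current trend are dropped and the trend
    refitted) so that a minority of genuinely differential features
    cannot inflate the shared dispersion of the majority.  Falls back to
    a flat median dispersion when the fit degenerates.
    """
    ok = (q > 0) & np.isfinite(alpha_raw) & (alpha_raw > 0)
    fallback = (float(np.median(alpha_raw[ok])) if ok.any() else 0.1, 0.0)
    if ok.sum() < 10:
        return fallback

    def glm_fit(mask: np.ndarray) -> tuple[float, float] | None:
        X = np.column_stack([np.ones(mask.sum()), 1.0 / q[mask]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(alpha_raw[mask], X,
                               family=sm.families.Gamma(sm.families.links.Identity()))
                res = model.fit(start_params=[max(fallback[0], 1e-4), 1.0],
                                maxiter=100)
            a0, a1 = float(res.params[0]), float(res.params[1])
        except Exception:
            return None
        if not np.isfinite(a0) or not np.isfinite(a1) or a0 < 0:
            return None
        return a0, max(a1, 0.0)

    # start from the robust flat median so a minority of large raw
    # dispersions cannot set the trimming threshold
    params = fallback
    for _ in range(3):
        trend = params[0] + params[1] / np.where(q > 0, q, np.inf)
        keep = ok & (alpha_raw <= 4.0 * np.maximum(trend, 1e-8))
        if keep.sum() < 10:
            break
        refit = glm_fit(keep)
        if refit is None:
            break
        params = refit
    return params


def _nb_size(mu: float, var: float) -> float:
    """NB size (r) matching a mean/variance pair; huge r when var <= mu
    (Poisson limit)."""
    if var <= mu:
        return 1e8
    return mu * mu / (var - mu)


def _exact_nb_pvalue(ka: int, kb: int, mu_a: float, var_a: float,
                     mu_b: float, var_b: float) -> float:
    """Two-sided exact-style test: sum the probabilities of all splits of
    the observed total that are no more likely than the observed one."""
    total = ka + kb
    if total == 0 or mu_a <= 0 or mu_b <= 0:
        return 1.0
    a = np.arange(total + 1)
    ra, rb = _nb_size(mu_a, var_a), _nb_size(mu_b, var_b)
    logp = (stats.nbinom.logpmf(a, ra, ra / (ra + mu_a))
            + stats.nbinom.logpmf(total - a, rb, rb / (rb + mu_b)))
    logp -= logp.max()
    p = np.exp(logp)
    denom = p.sum()
    if denom <= 0:
        return 1.0
    return float(min(1.0, p[p <= p[ka] * (1 + 1e-12)].sum() / denom))


def nb_test_noreplicates(
    counts: pd.DataFrame,
    factors: pd.Series,
    conditions: dict[str, str],
) -> pd.DataFrame:
    """Per-feature NB test of case vs control totals without replicates.

    ``conditions`` maps sample name to ``case``/``control``.  Dispersion
    is estimated blind (conditions pooled as replicates) and shared
    through the fitted trend only.  Returns a frame with base means,
    fold_change (case/control on normalized counts), log2fc and p_value.
    """
    case = [s for s, c in conditions.items() if c == "case"]
    control = [s for s, c in conditions.items() if c == "control"]
    if not case or not control:
        raise ValueError("need at least one case and one control sample")
    counts = counts[case + control].astype(float)
    f = factors[case + control].astype(float)

    norm = counts / f
    q = norm.mean(axis=1).to_numpy()
    # blind single-treatment dispersion: pooled sample variance
    w = norm.var(axis=1, ddof=1).to_numpy()
    z = q * float((1.0 / f).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(q > 0, (w - z) / np.square(q), np.nan)
    a0, a1 = _fit_dispersion_trend(q, alpha_raw)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_fit = np.where(q > 0, np.maximum(a0 + a1 / np.maximum(q, 1e-300), _MIN_DISP), _MIN_DISP)

    s_case, s_control = float(f[case].sum()), float(f[control].sum())
    s2_case = float(np.square(f[case]).sum())
    s2_control = float(np.square(f[control]).sum())
    k_case = counts[case].sum(axis=1).to_numpy()
    k_control = counts[control].sum(axis=1).to_numpy()

    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        if k_case[i] + k_control[i] == 0:
            pvals[i] = 1.0
            continue
        mu_a = q[i] * s_control
        mu_b = q[i] * s_case
        var_a = mu_a + alpha_fit[i] * q[i] ** 2 * s2_control
        var_b = mu_b + alpha_fit[i] * q[i] ** 2 * s2_case
        pvals[i] = _exact_nb_pvalue(
            int(k_control[i]), int(k_case[i]), mu_a, var_a, mu_b, var_b)

    mean_case = norm[case].mean(axis=1)
    mean_control = norm[control].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_case / mean_control
        log2fc = np.log2(fc)
    return pd.DataFrame({
        "base_mean": q,
        "base_mean_control": mean_control,
        "base_mean_case": mean_case,
        "fold_change": fc,
        "log2fc": log2fc,
        "p_value": pvals,
    }, index=counts.index)


def call_de(
    results: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach regulation status: up iff FC >= threshold and p <= alpha
    (both bounds inclusive), down iff FC <= 1/threshold and p <= alpha,
    anomalous iff exactly one condition has zero total count."""
    res = results.copy()
    zero_control = res["base_mean_control"] == 0
    zero_case = res["base_mean_case"] == 0
    anomalous = zero_control ^ zero_case
    status = np.full(len(res), "unchanged", dtype=object)
    sig = res["p_value"] <= alpha
    status[(res["fold_change"] >= fc_threshold) & sig] = "up"
    status[(res["fold_change"] <= 1.0 / fc_threshold) & sig] = "down"
    status[anomalous.to_numpy()] = "anomalous"
    res["status"] = status
    return res


def de_genes_expression_matrix(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    intensity_percentile: float = 20.0,
) -> pd.DataFrame:
    """DE genes from a normalized log2 expression matrix.

    Features whose overall mean intensity falls below the given
    percentile are excluded, then a Welch unpaired t-test per feature
    with BH correction; DE requires q <= alpha and |FC| >= fc_threshold.
    """
    case = [s for s, g in groups.items() if g == "case"]
    control = [s for s, g in groups.items() if g == "control"]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    matrix = matrix[case + control].astype(float)

    overall = matrix.mean(axis=1)
    floor = np.percentile(overall, intensity_percentile)
    kept = matrix.loc[overall >= floor]

    tstat, pvals = stats.ttest_ind(
        kept[case], kept[control], axis=1, equal_var=False)
    _rej, qvals, _a, _b = multipletests(pvals, method="fdr_bh")
    log2fc = kept[case].mean(axis=1) - kept[control].mean(axis=1)
    fc = np.power(2.0, log2fc.abs()) * np.sign(log2fc).replace(0, 1)

    status = np.full(len(kept), "unchanged", dtype=object)
    de = (qvals <= alpha) & (log2fc.abs() >= np.log2(fc_threshold))
    status[de & (log2fc > 0).to_numpy()] = "up"
    status[de & (log2fc < 0).to_numpy()] = "down"
    return pd.DataFrame({
        "mean_control": kept[control].mean(axis=1),
        "mean_case": kept[case].mean(axis=1),
        "log2fc": log2fc,
        "fold_change": fc,
        "t": tstat,
        "p_value": pvals,
        "q_value": qvals,
        "status": status,
    }, index=kept.index)
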