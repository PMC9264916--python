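"""Two-group association tests between mutation status and knockout essentiality.

For every (knockout, biomarker) pair the null hypothesis is that expected
essentiality is identical in mutant and wild-type cell lines.  Two tests are
provided:

* a moderated t-test: per-knockout pooled variances are shrunk toward a
  common prior by empirical Bayes, assuming sample variances follow a scaled-F
  law around a prior variance ``s0^2`` with prior degrees of freedom ``d0``.
  The shrunk (posterior) variance is
  ``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)`` and the t statistic gains ``d0``
  degrees of freedom — the standard gain in power for small-n screens;
* a one-way ANOVA (two-level), the baseline used by conventional screen
  pipelines; with two groups its F statistic is the square of the ordinary
  equal-variance t.

Hyper-parameters (d0, s0^2) are estimated by moment-matching the log sample
variances: under the scaled-F model  E[log s^2] and Var[log s^2] have closed
forms in digamma/trigamma functions, which are inverted numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_data import EssentialityMatrix, MutationMatrix

__all__ = [
    "ShrinkageModel",
    "fit_variance_prior",
    "moderated_t_test",
    "anova_test",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "knockout_id",
    "biomarker_id",
    "n_mut",
    "n_wt",
    "delta",
    "t_stat",
    "df_total",
    "p_value",
    "group_id",
    "skipped",
]


@dataclass
class ShrinkageModel:
    """Fitted empirical-Bayes variance prior and per-knockout posterior variances."""

    prior_df: float  # d0 >= 0, possibly +inf
    prior_var: float  # s0^2 > 0
    posterior_var: np.ndarray
    fallback_ordinary: bool = False  # True when too few variances to moderate

    def shrink(self, sample_vars: np.ndarray, resid_dfs: np.ndarray) -> np.ndarray:
        d0, s0 = self.prior_df, self.prior_var
        if np.isinf(d0):
            return np.full_like(np.asarray(sample_vars, dtype=float), s0)
        return (d0 * s0 + resid_dfs * sample_vars) / (d0 + resid_dfs)


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-8:
            break
    return float(x)


def fit_variance_prior(
    sample_vars: np.ndarray, resid_dfs: np.ndarray
) -> ShrinkageModel:
    """Estimate (prior_df, prior_var) from per-knockout sample variances.

    Moment-matches ``log s^2`` against the scaled-F model.  Degenerate cases:
    fewer than 2 positive-df variances falls back to no moderation
    (``prior_df = 0``); zero spread in the log variances yields
    ``prior_df = +inf`` with ``prior_var`` the geometric mean of the sample
    variances (their common value when all are equal).
    """
    sample_vars = np.asarray(sample_vars, dtype=float)
    resid_dfs = np.asarray(resid_dfs, dtype=float)
    ok = np.isfinite(sample_vars) & (sample_vars > 0) & (resid_dfs >= 1)
    if ok.sum() < 2:
        warnings.warn("fewer than 2 usable variances; no moderation applied")
        post = np.where(ok, sample_vars, np.nan)
        pv = float(sample_vars[ok][0]) if ok.any() else 1.0
        return ShrinkageModel(
            prior_df=0.0, prior_var=pv, posterior_var=post, fallback_ordinary=True
        )

    v, d = sample_vars[ok], resid_dfs[ok]
    z = np.log(v)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    n = len(e)
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(special.polygamma(1, d / 2.0))
    if evar > 0:
        prior_df = 2.0 * _trigamma_inverse(evar)
        prior_var = float(
            np.exp(emean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0))
        )
    else:
        prior_df = np.inf
        prior_var = float(np.exp(z.mean()))

    model = ShrinkageModel(prior_df=prior_df, prior_var=prior_var, posterior_var=np.empty(0))
    post = np.full(sample_vars.shape, np.nan)
    post[ok] = model.shrink(v, d)
    model.posterior_var = post
    return model


def _group_stats(scores: np.ndarray, mut: np.ndarray):
    """Per-knockout group means, pooled variance and residual df for one biomarker.

    ``scores``: (knockouts x samples), may contain NaN; ``mut``: boolean mask.
    """
    def _masked(cols: np.ndarray):
        sub = scores[:, cols]
        n = np.sum(~np.isnan(sub), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sub, axis=1)
            ss = np.nansum((sub - mean[:, None]) ** 2, axis=1)
        return n, mean, ss

    n1, mean1, ss1 = _masked(mut)
    n0, mean0, ss0 = _masked(~mut)
    resid_df = n1 + n0 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled_var = np.where(resid_df > 0, (ss1 + ss0) / np.maximum(resid_df, 1), np.nan)
    return n1, n0, mean1, mean0, pooled_var, resid_df.astype(float)


def _run_tests(
    essentiality: EssentialityMatrix,
    mutations: MutationMatrix,
    min_group_size: int,
    moderated: bool,
) -> pd.DataFrame:
    if min_group_size < 2:
        raise ValueError("min_group_size must be >= 2")
    if essentiality.sample_ids != mutations.sample_ids:
        raise ValueError("matrices are not sample-aligned; run align_samples first")

    scores = essentiality.values
    frames = []
    for b, biomarker in enumerate(mutations.biomarker_ids):
        mut = mutations.indicator[b].astype(bool)
        n1, n0, mean1, mean0, pooled_var, resid_df = _group_stats(scores, mut)
        delta = mean1 - mean0
        tested = (n1 >= min_group_size) & (n0 >= min_group_size)

        if moderated:
            if tested.any() and not np.any(pooled_var[tested] > 0):
                raise ValueError(
                    f"biomarker {biomarker!r}: zero residual variance for every "
                    "testable knockout"
                )
            model = fit_variance_prior(
                np.where(tested, pooled_var, np.nan), np.where(tested, resid_df, 0)
            )
            var = model.posterior_var
            df_total = resid_df + (model.prior_df if np.isfinite(model.prior_df) else np.inf)
        else:
            var = pooled_var
            df_total = resid_df

        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(var * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n0, 1)))
            t_stat = delta / se
        p = np.full(len(t_stat), np.nan)
        sel = tested & np.isfinite(t_stat)
        if np.isinf(np.atleast_1d(df_total)).any():
            p[sel] = 2.0 * stats.norm.sf(np.abs(t_stat[sel]))
        else:
            p[sel] = 2.0 * stats.t.sf(np.abs(t_stat[sel]), np.asarray(df_total)[sel])

        frames.append(
            pd.DataFrame(
                {
                    "knockout_id": essentiality.knockout_ids,
                    "biomarker_id": biomarker,
                    "n_mut": n1,
                    "n_wt": n0,
                    "delta": delta,
                    "t_stat": np.where(sel, t_stat, np.nan),
                    "df_total": np.broadcast_to(df_total, (len(t_stat),)),
                    "p_value": p,
                    "group_id": biomarker,
                    "skipped": ~tested,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["knockout_id", "biomarker_id"], kind="stable").reset_index(drop=True)
    return out


def moderated_t_test(
    essentiality: EssentialityMatrix,
    mutations: MutationMatrix,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Moderated two-sample t-test for every (knockout, biomarker) pair.

    Variances are moderated across knockouts within each biomarker's test
    family.  Pairs with fewer than ``min_group_size`` mutant or wild-type
    lines are emitted with ``skipped=True`` and NaN statistics, never
    silently dropped.  ``delta = mean(mutant) - mean(wild-type)``; negative
    delta means mutants are more sensitive to the knockout.
    """
    return _run_tests(essentiality, mutations, min_group_size, moderated=True)


def anova_test(
    essentiality: EssentialityMatrix,
    mutations: MutationMatrix,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """One-way two-level ANOVA baseline; adds an ``f_stat`` column.

    With two groups F = t^2 of the ordinary pooled-variance t-test and the
    p-values coincide.
    """
    out = _run_tests(essentiality, mutations, min_group_size, moderated=False)
    out["f_stat"] = out["t_stat"] ** 2
    return out


def write_results(table: pd.DataFrame, path) -> None:
    """Serialize a test-result table as TSV with stable column order."""
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, na_rep="NA")
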