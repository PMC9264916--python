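"""Multiple-testing machinery: pi0, local FDR, q-values and grouped corrections.

The central idea is covariate-grouped correction: the p-values of all
(knockout, biomarker) tests are split into groups, one per biomarker.  "Hub"
biomarkers — alterations associated with essentiality shifts of many
knockouts — produce p-value histograms with a tall peak near zero, while
inert biomarkers produce flat histograms.  Estimating the proportion of true
nulls (pi0) and the local false discovery rate

    lfdr(p) = pi0 * f0(p) / f(p),     f0 = U(0,1) density

within each group concentrates the multiple-testing budget on the groups
that carry signal, which is where the power gain over pooled corrections
comes from.  A group-weighted Benjamini-Hochberg variant (weights
proportional to each group's estimated alternative fraction) provides the
same idea on the FDR scale.

The mixture density f is estimated by a quantile-binned histogram under a
monotone non-increasing constraint (Grenander-style, fitted by weighted
isotonic regression), which keeps lfdr in (0, 1] and non-decreasing in p
without ad-hoc clipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LocalFDRModel",
    "CorrectionResult",
    "estimate_pi0",
    "local_fdr",
    "grouped_local_fdr",
    "storey_qvalues",
    "classical_corrections",
    "covariate_bh",
    "group_diagnostics",
]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)

#: groups smaller than this fall back to the pooled estimate
MIN_GROUP_TESTS = 50


def _check_pvalues(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    return p


# ---------------------------------------------------------------------------
# pi0


def estimate_pi0(
    pvalues,
    method: str = "bootstrap",
    lambda_grid: np.ndarray | None = None,
) -> float:
    """Estimate the proportion of true null hypotheses from the lambda-tail excess.

    ``pi0(lambda) = #{p > lambda} / (m * (1 - lambda))`` is stabilized either
    by the plug-in bootstrap MSE rule (``bootstrap``, default; deterministic),
    a cubic smoother evaluated at the largest lambda (``smoother``), or a
    single ``fixed_lambda`` (grid midpoint 0.5 unless a one-element grid is
    given).  The estimate is clamped to [1/m, 1].
    """
    p = _check_pvalues(pvalues)
    m = p.size
    grid = np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float)
    if m < 20 and method in ("smoother", "bootstrap"):
        warnings.warn(
            f"only {m} p-values; falling back to fixed_lambda=0.5 pi0 estimation"
        )
        method, grid = "fixed_lambda", np.array([0.5])

    tail = np.array([np.mean(p > lam) for lam in grid])
    pi0_lam = tail / (1.0 - grid)

    if method == "fixed_lambda":
        lam = grid[0] if grid.size == 1 else 0.5
        pi0 = np.mean(p > lam) / (1.0 - lam)
    elif method == "smoother":
        if grid.size >= 4:
            coef = np.polyfit(grid, pi0_lam, deg=3)
            pi0 = float(np.polyval(coef, grid.max()))
        else:
            pi0 = float(pi0_lam[-1])
    elif method == "bootstrap":
        # plug-in bootstrap MSE rule: pick lambda minimising the estimated
        # MSE of pi0(lambda) around the 10th-percentile pilot value
        min_pi0 = np.quantile(pi0_lam, 0.1)
        W = tail * m
        mse = (W / (m**2 * (1.0 - grid) ** 2)) * (1.0 - W / m) + (pi0_lam - min_pi0) ** 2
        pi0 = float(np.min(pi0_lam[mse == mse.min()]))
    else:
        raise ValueError(f"unknown pi0 method {method!r}")

    lower = 1.0 / m
    if pi0 < lower:
        warnings.warn(f"pi0 estimate {pi0:.3g} below 1/m; clamping to {lower:.3g}")
    return float(np.clip(pi0, lower, 1.0))


# ---------------------------------------------------------------------------
# local FDR


@dataclass
class LocalFDRModel:
    """Monotone mixture-density estimate and per-test local FDR for one group."""

    group_id: str
    pi0: float
    density_x: np.ndarray  # bin edges on [0, 1]
    density_f: np.ndarray  # non-increasing density value per bin
    lfdr: np.ndarray  # per input test, aligned with the input order
    n_tests: int
    pooled_fallback: bool = False

    def density_at(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        idx = np.clip(np.searchsorted(self.density_x, p, side="right") - 1, 0,
                      len(self.density_f) - 1)
        return self.density_f[idx]


def _n_knots(n: int) -> int:
    # ~sqrt(n)/12 quantile bins: quantile spacing concentrates resolution in
    # the zero-peak where the mixture density moves, while keeping enough
    # points per bin that a flat (null) histogram stays near density 1
    return int(np.clip(np.sqrt(n) / 12.0, 4, 100))


def local_fdr(pvalues, pi0: float, group_id: str = "all") -> LocalFDRModel:
    """Estimate lfdr(p) = min(1, pi0 / f(p)) with a monotone histogram density.

    The mixture density f is a quantile-binned histogram fitted under a
    non-increasing constraint by width-weighted isotonic regression (the
    discrete Grenander estimator).  It integrates to 1 by construction, so
    lfdr is in (0, 1] and non-decreasing in p.
    """
    p = _check_pvalues(pvalues)
    n = p.size
    if np.ptp(p) == 0.0:
        warnings.warn("degenerate p-value vector (all identical); lfdr = pi0 everywhere")
        return LocalFDRModel(
            group_id=group_id,
            pi0=pi0,
            density_x=np.array([0.0, 1.0]),
            density_f=np.array([1.0]),
            lfdr=np.full(n, pi0),
            n_tests=n,
        )

    k = _n_knots(n)
    edges = np.unique(np.concatenate([[0.0], np.quantile(p, np.arange(1, k) / k), [1.0]]))
    counts, _ = np.histogram(p, bins=edges)
    widths = np.diff(edges)
    dens = counts / (n * widths)
    mids = 0.5 * (edges[:-1] + edges[1:])
    iso = IsotonicRegression(increasing=False)
    f = iso.fit_transform(mids, dens, sample_weight=widths)

    model = LocalFDRModel(
        group_id=group_id,
        pi0=pi0,
        density_x=edges,
        density_f=f,
        lfdr=np.empty(0),
        n_tests=n,
    )
    with np.errstate(divide="ignore"):
        lfdr = pi0 / model.density_at(p)
    model.lfdr = np.clip(lfdr, 0.0, 1.0)
    return model


@dataclass
class GroupedLfdrResult:
    """Per-test lfdr plus the per-group models and diagnostics."""

    table: pd.DataFrame
    models: dict = field(default_factory=dict)


def grouped_local_fdr(
    results: pd.DataFrame,
    pi0_method: str = "bootstrap",
    min_group_tests: int = MIN_GROUP_TESTS,
) -> pd.DataFrame:
    """Attach a per-biomarker-group local FDR column to a test-result table.

    pi0 and the mixture density are estimated independently within each
    ``group_id`` (biomarker).  Groups with fewer than ``min_group_tests``
    non-skipped tests fall back to the pooled all-tests model and are flagged
    in ``lfdr_pooled_fallback``.  Skipped tests keep NaN lfdr.
    """
    out = results.copy()
    tested = ~out["skipped"] if "skipped" in out else out["p_value"].notna()
    tested &= out["p_value"].notna()
    out["lfdr"] = np.nan
    out["pi0_group"] = np.nan
    out["lfdr_pooled_fallback"] = False

    pooled_p = out.loc[tested, "p_value"].to_numpy()
    if pooled_p.size == 0:
        return out
    pooled_pi0 = estimate_pi0(pooled_p, method=pi0_method)
    pooled_model = local_fdr(pooled_p, pooled_pi0, group_id="__pooled__")
    pooled_lfdr = pd.Series(pooled_model.lfdr, index=out.index[tested])

    for gid, idx in out.index[tested].groupby(out.loc[tested, "group_id"]).items():
        p = out.loc[idx, "p_value"].to_numpy()
        if p.size < min_group_tests:
            out.loc[idx, "lfdr"] = pooled_lfdr.loc[idx].to_numpy()
            out.loc[idx, "pi0_group"] = pooled_pi0
            out.loc[idx, "lfdr_pooled_fallback"] = True
            continue
        pi0 = estimate_pi0(p, method=pi0_method)
        model = local_fdr(p, pi0, group_id=str(gid))
        out.loc[idx, "lfdr"] = model.lfdr
        out.loc[idx, "pi0_group"] = pi0
    return out


# ---------------------------------------------------------------------------
# q-values and classical corrections


def storey_qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """pi0-adaptive q-values: ``q_i = pi0 * min_{p_j >= p_i} m * p_j / rank(p_j)``.

    With ``pi0 = 1`` this is exactly Benjamini-Hochberg adjustment.
    """
    p = _check_pvalues(pvalues)
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CorrectionResult:
    """Adjusted p-values (or q-values) from one correction method."""

    method: str
    adjusted: np.ndarray
    n_significant_at: dict[float, int] = field(default_factory=dict)

    def n_significant(self, alpha: float) -> int:
        return int(np.sum(self.adjusted <= alpha))


_SM_METHOD = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}


def classical_corrections(pvalues, method: str = "bh",
                          thresholds: tuple[float, ...] = (0.05, 0.20)) -> CorrectionResult:
    """Benjamini-Hochberg, Bonferroni or Holm adjustment (textbook definitions)."""
    p = _check_pvalues(pvalues)
    if method not in _SM_METHOD:
        raise ValueError(f"unknown correction method {method!r}")
    adjusted = multipletests(p, method=_SM_METHOD[method])[1]
    result = CorrectionResult(method=method, adjusted=adjusted)
    result.n_significant_at = {a: result.n_significant(a) for a in thresholds}
    return result


# ---------------------------------------------------------------------------
# covariate-weighted BH


def group_signal_fraction(
    pvalues: np.ndarray,
    weight_lambda: float = 0.001,
    guard_p: float | None = None,
) -> float:
    """Conservative estimate of a group's alternative fraction, ``1 - pi0_g``.

    Uses the Storey complement at a *small* lambda — the excess fraction of
    p-values at or below ``weight_lambda`` over the uniform expectation — so
    only clearly active tests register.  If ``guard_p`` is given, the
    estimate is zeroed unless the sub-lambda count is significantly larger
    than its uniform-null binomial expectation at that level; this keeps
    groups with chance excess (or weak, borderline shifts) from capturing
    weight they cannot repay in discoveries.
    """
    gp = np.asarray(pvalues, dtype=float)
    m = gp.size
    if m == 0:
        return np.nan
    x = int(np.sum(gp <= weight_lambda))
    if guard_p is not None and scipy_stats.binom.sf(x - 1, m, weight_lambda) > guard_p:
        return 0.0
    return max(0.0, (x / m - weight_lambda) / (1.0 - weight_lambda))


def covariate_bh(
    results: pd.DataFrame,
    alpha: float = 0.20,
    weight_lambda: float = 0.001,
    guard_level: float | None = 0.05,
) -> CorrectionResult:
    """Group-weighted Benjamini-Hochberg correction over biomarker groups.

    Each group's weight is proportional to its estimated alternative fraction
    ``1 - pi0_g``, normalized so the test-weighted mean weight is 1, and BH
    is applied to ``p_i / w_i``.  The alternative fraction uses the
    conservative small-lambda estimator of :func:`group_signal_fraction`
    with a binomial significance guard (familywise level ``guard_level``
    across groups), so that noise in the per-group estimates — which would
    otherwise up-weight lucky null groups and inflate the realized FDR —
    cannot capture weight.  When no group shows significant signal, or all
    groups show the same signal, every weight is 1 and the procedure reduces
    to plain BH.  This is a deliberately simple single-fit weighting scheme
    over a fixed grouping — no cross-fitted hypothesis weighting.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    tested = (~results["skipped"]) if "skipped" in results else results["p_value"].notna()
    tested &= results["p_value"].notna()
    p = results.loc[tested, "p_value"].to_numpy()
    if p.size == 0:
        raise ValueError("no testable rows")

    all_groups = results["group_id"].unique()
    uniq = np.sort(all_groups.astype(str))
    groups = results.loc[tested, "group_id"].astype(str).to_numpy()
    inverse = np.searchsorted(uniq, groups)
    counts = np.bincount(inverse, minlength=len(uniq))
    guard_p = None if guard_level is None else guard_level / len(uniq)

    signal = np.zeros(len(uniq))
    for g in range(len(uniq)):
        gp = p[inverse == g]
        if gp.size == 0:
            warnings.warn(f"empty group {uniq[g]!r}; assigned weight 1")
            signal[g] = np.nan
            continue
        signal[g] = group_signal_fraction(gp, weight_lambda, guard_p)

    mean_signal = np.nansum(signal * counts) / counts.sum()
    if mean_signal <= 0:
        weights = np.ones(len(uniq))
    else:
        weights = np.where(np.isnan(signal), 1.0, signal / mean_signal)

    w = weights[inverse]
    with np.errstate(divide="ignore", invalid="ignore"):
        weighted_p = np.where(w > 0, np.clip(p / np.where(w > 0, w, 1.0), 0.0, 1.0), 1.0)
    adjusted_tested = multipletests(weighted_p, method="fdr_bh")[1]

    adjusted = np.full(len(results), np.nan)
    adjusted[np.flatnonzero(tested.to_numpy())] = adjusted_tested
    result = CorrectionResult(method="covariate_bh", adjusted=adjusted)
    result.n_significant_at = {alpha: int(np.nansum(adjusted <= alpha))}
    return result


# ---------------------------------------------------------------------------
# diagnostics


def group_diagnostics(results: pd.DataFrame, pi0_method: str = "bootstrap") -> pd.DataFrame:
    """Per-group summary: size, pi0 and the fraction of p-values below 0.05.

    The ``frac_p_below_05`` column is the one-number summary of each group's
    p-value histogram: hub biomarkers show a large excess over 0.05.
    """
    tested = (~results["skipped"]) if "skipped" in results else results["p_value"].notna()
    tested &= results["p_value"].notna()
    rows = []
    for gid, sub in results.loc[tested].groupby("group_id"):
        p = sub["p_value"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pi0 = estimate_pi0(p, method=pi0_method) if p.size else np.nan
        rows.append(
            {
                "group_id": gid,
                "n_tests": p.size,
                "pi0": pi0,
                "frac_p_below_05": float(np.mean(p < 0.05)) if p.size else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("group_id").reset_index(drop=True)


def plot_group_histograms(results: pd.DataFrame, group_ids, path) -> None:
    """Export per-group p-value histograms (PNG/SVG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    group_ids = list(group_ids)
    fig, axes = plt.subplots(1, len(group_ids), figsize=(3 * len(group_ids), 2.5),
                             squeeze=False)
    for ax, gid in zip(axes[0], group_ids):
        p = results.loc[results["group_id"] == gid, "p_value"].dropna()
        ax.hist(p, bins=20, range=(0, 1), color="steelblue")
        ax.set_title(str(gid))
        ax.set_xlabel("p-value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
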