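"""Moment-to-moment forecasting of per-video outcomes from windowed neural
series, plus the behavioral composites.

The forecasting unit is the video: at every rolling window the group-level
neural statistic (FAA or ISC) across videos is correlated with a per-video
outcome — population investment interest (Pearson), binary deal outcome
(point-biserial, i.e. Pearson on 0/1 coding), or funding amount. Rank-order
(Spearman) correlation is available as a robustness method. Uncertainty is
quantified by nonparametric bootstrap over videos (5,000 resamples by
default) and window-wise p-values are reported unadjusted, with an optional
FDR variant.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# behavioral composites
# ---------------------------------------------------------------------------

def _composite(items: Sequence[float], k: int, name: str,
               missing: str = "error") -> float:
    vals = np.asarray(items, dtype=float)
    if vals.shape != (k,):
        raise ValueError(f"{name} composite expects {k} items, got {vals.shape}")
    nan = np.isnan(vals)
    if nan.any():
        if missing == "error":
            raise ValueError(f"{name} composite has missing items at {np.flatnonzero(nan)}")
        if missing == "impute":
            vals = np.where(nan, np.nanmean(vals), vals)
        elif missing == "drop":
            vals = vals[~nan]
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    if np.any((vals < 1) | (vals > 7)):
        raise ValueError(f"{name} items must lie in [1, 7]")
    return float(vals.mean())


def composite_interest(items: Sequence[float], missing: str = "error") -> float:
    """Unweighted mean of the five 7-point investment-interest items."""
    return _composite(items, 5, "interest", missing)


def composite_dc(items: Sequence[float], missing: str = "error") -> float:
    """Unweighted mean of the fourteen dynamic-capability items."""
    return _composite(items, 14, "dc", missing)


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an (n_observations, k_items) score matrix."""
    items = np.asarray(items, dtype=float)
    k = items.shape[1]
    item_var = items.var(axis=0, ddof=1).sum()
    total_var = items.sum(axis=1).var(ddof=1)
    return k / (k - 1) * (1.0 - item_var / total_var)


# ---------------------------------------------------------------------------
# window-wise correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForecastResult:
    """Correlation of one window's group metric with the outcome."""

    window: tuple[float, float] | int
    metric: str
    method: str
    r: float
    p: float
    ci: tuple[float, float] | None
    n_videos: int
    flagged: bool = False  # undefined correlation or < 4 distinct outcomes


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:  # pearson / point-biserial coincide on 0/1 coding
        r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _resolve_method(outcome: np.ndarray, method: str) -> str:
    if method == "rank":
        return "spearman"
    if method in ("pearson", "spearman", "point-biserial"):
        if method == "pearson" and set(np.unique(outcome)) <= {0.0, 1.0}:
            return "point-biserial"
        return method
    raise ValueError(f"unknown method {method!r}")


def momentwise_forecast(metric: np.ndarray, outcome: np.ndarray,
                        windows: Sequence[tuple[float, float]] | None = None,
                        method: str = "pearson",
                        metric_name: str = "metric") -> list[ForecastResult]:
    """One correlation per window across videos.

    ``metric`` is (n_windows, n_videos); ``outcome`` is per video. Binary
    outcomes automatically use the point-biserial coefficient; ``method
    = 'rank'`` switches to Spearman. Windows where the metric or outcome is
    constant are reported with NaN and flagged.
    """
    metric = np.asarray(metric, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if metric.ndim != 2 or metric.shape[1] != len(outcome):
        raise ValueError("metric must be (n_windows, n_videos) matching outcome")
    if len(outcome) < 4:
        raise ValueError("forecasting needs at least 4 videos")
    meth = _resolve_method(outcome, method)
    results = []
    few_outcomes = len(np.unique(outcome)) < 4 and meth != "point-biserial"
    for w in range(metric.shape[0]):
        r, p = _corr(metric[w], outcome, "spearman" if meth == "spearman" else "pearson")
        win = windows[w] if windows is not None else w
        results.append(ForecastResult(
            window=win, metric=metric_name, method=meth, r=r, p=p, ci=None,
            n_videos=len(outcome), flagged=bool(np.isnan(r)) or few_outcomes,
        ))
    return results


def bootstrap_ci(metric: np.ndarray, outcome: np.ndarray, n_boot: int = 5000,
                 seed: int | np.random.Generator | None = None,
                 method: str = "pearson",
                 ci: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for one window's correlation.

    Videos are resampled with replacement; degenerate resamples (zero
    variance in either variable) are redrawn. Deterministic given the seed.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be at least 100, got {n_boot}")
    metric = np.asarray(metric, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    n = len(outcome)
    if n < 4:
        raise ValueError("bootstrap needs at least 4 videos")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meth = _resolve_method(outcome, method)
    rank = meth == "spearman"
    draws = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            x, y = metric[idx], outcome[idx]
            if np.std(x) > 0 and np.std(y) > 0:
                break
            redraws += 1
            if redraws > 100 * n_boot:
                raise RuntimeError("bootstrap cannot find non-degenerate resamples")
        if rank:
            x = stats.rankdata(x)
            y = stats.rankdata(y)
        xc, yc = x - x.mean(), y - y.mean()
        draws[b] = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
    lo_q = (1.0 - ci) / 2.0
    return float(np.quantile(draws, lo_q)), float(np.quantile(draws, 1.0 - lo_q))


def significance_mask(results: Sequence[ForecastResult], alpha: float = 0.05,
                      fdr: bool = False) -> list[ForecastResult]:
    """Windows with p below ``alpha`` (unadjusted by default, FDR optional)."""
    ps = np.array([r.p for r in results], dtype=float)
    ok = ~np.isnan(ps)
    sig = np.zeros(len(ps), dtype=bool)
    if fdr and ok.any():
        sig[ok] = multipletests(ps[ok], alpha=alpha, method="fdr_bh")[0]
    else:
        sig[ok] = ps[ok] < alpha
    return [r for r, s in zip(results, sig) if s]


# ---------------------------------------------------------------------------
# model-style wrapper
# ---------------------------------------------------------------------------

class MomentwiseForecast:
    """Window-wise forecasting model for one neural metric and one outcome.

    Parameters
    ----------
    metric : ndarray, shape (n_windows, n_videos)
        Group-level windowed neural statistic, column order matching
        ``video_ids``.
    outcome : ndarray, shape (n_videos,)
        Per-video outcome (continuous or 0/1).
    windows : sequence of (start, stop), optional
        Window intervals in seconds; defaults to window indices.
    """

    def __init__(self, metric: np.ndarray, outcome: np.ndarray,
                 windows: Sequence[tuple[float, float]] | None = None,
                 metric_name: str = "metric", outcome_name: str = "outcome",
                 video_ids: Sequence[str] | None = None):
        self.metric = np.asarray(metric, dtype=float)
        self.outcome = np.asarray(outcome, dtype=float)
        self.windows = list(windows) if windows is not None else None
        self.metric_name = metric_name
        self.outcome_name = outcome_name
        self.video_ids = list(video_ids) if video_ids is not None else None

    def fit(self, method: str = "pearson", n_boot: int = 0,
            seed: int | None = None) -> "MomentwiseForecastResults":
        """Correlate every window; optionally attach bootstrap CIs."""
        results = momentwise_forecast(self.metric, self.outcome, self.windows,
                                      method=method, metric_name=self.metric_name)
        if n_boot:
            rng = np.random.default_rng(seed)
            with_ci = []
            for w, res in enumerate(results):
                ci = (bootstrap_ci(self.metric[w], self.outcome, n_boot=n_boot,
                                   seed=rng, method=method)
                      if not np.isnan(res.r) else None)
                with_ci.append(ForecastResult(res.window, res.metric, res.method,
                                              res.r, res.p, ci, res.n_videos,
                                              res.flagged))
            results = with_ci
        return MomentwiseForecastResults(self, results)


class MomentwiseForecastResults:
    """Fitted window-wise correlations with significance and plotting."""

    def __init__(self, model: MomentwiseForecast, results: list[ForecastResult]):
        self.model = model
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for res in self.results:
            start, stop = (res.window if isinstance(res.window, tuple)
                           else (res.window, res.window))
            rows.append({"window_start": start, "window_stop": stop,
                         "r": res.r, "p": res.p,
                         "ci_lo": res.ci[0] if res.ci else np.nan,
                         "ci_hi": res.ci[1] if res.ci else np.nan,
                         "flagged": res.flagged})
        return pd.DataFrame(rows)

    def significant_windows(self, alpha: float = 0.05, fdr: bool = False
                            ) -> list[ForecastResult]:
        return significance_mask(self.results, alpha=alpha, fdr=fdr)

    def summary(self) -> str:
        df = self.frame
        sig = self.significant_windows()
        lines = [
            f"Moment-to-moment forecast: {self.model.metric_name} -> "
            f"{self.model.outcome_name}",
            f"  method: {self.results[0].method}, videos: {self.results[0].n_videos}, "
            f"windows: {len(self.results)}",
            f"  peak r = {df['r'].abs().max():.3f} at window start "
            f"{df.loc[df['r'].abs().idxmax(), 'window_start']} s",
        ]
        if sig:
            starts = [r.window[0] if isinstance(r.window, tuple) else r.window
                      for r in sig]
            lines.append(
                f"  significant windows (p < 0.05, unadjusted): "
                f"{len(sig)}/{len(self.results)}, starts spanning "
                f"{min(starts):g}-{max(starts):g} s")
        else:
            lines.append("  significant windows (p < 0.05, unadjusted): none")
        return "\n".join(lines)

    def plot(self, ax=None, alpha: float = 0.05):
        """r over window start time with the significant region shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.frame
        ax.plot(df["window_start"], df["r"], marker="o", ms=3,
                label=self.model.metric_name)
        if df["ci_lo"].notna().any():
            ax.fill_between(df["window_start"], df["ci_lo"], df["ci_hi"], alpha=0.2)
        sig = df["p"] < alpha
        if sig.any():
            ax.scatter(df.loc[sig, "window_start"], df.loc[sig, "r"],
                       color="crimson", zorder=3, s=18, label=f"p < {alpha}")
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_xlabel("window start (s)")
        ax.set_ylabel(f"r ({self.model.outcome_name})")
        ax.legend(frameon=False)
        return ax
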