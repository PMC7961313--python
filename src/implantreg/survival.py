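"""Implant survivorship: Kaplan-Meier estimation and model stratification.

The product-limit estimator is implemented here directly (it is the quantity
under audit, compared against an independent library in the test suite):

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

with Greenwood's variance  Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
and, by default, the exponential-Greenwood (log(-log)) 95% confidence
interval, which stays inside [0, 1] without clipping artifacts. Ties between
removals and censorings on the same day follow the standard convention:
removals happen first, so same-day censored components are still at risk.

Stratification compares one model's CI band against the pooled band of all
other models of the same class: a model is *worse* when its upper CI bound
drops below the comparator's lower bound and stays below at every later
evaluation time (and symmetrically *better*). Evaluation times are the union
of both curves' event times, truncated where either arm's at-risk count
falls below ``min_at_risk``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import PipelineConfig

DAYS_PER_YEAR = 365.25


@dataclass
class SurvivalCurve:
    times: np.ndarray        # event times, days, ascending
    at_risk: np.ndarray      # n_i
    events: np.ndarray       # d_i
    survival: np.ndarray     # S(t_i)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    variance: np.ndarray     # Greenwood Var[S(t_i)]
    n_total: int
    implant_years: float
    # raw inputs, kept for at-risk evaluation at arbitrary times
    durations: np.ndarray = field(default=None, repr=False)
    observed: np.ndarray = field(default=None, repr=False)

    def survival_at(self, t) -> np.ndarray:
        """Step-function S(t) (right-continuous)."""
        t_arr = np.atleast_1d(t)
        if len(self.times) == 0:
            s = np.ones_like(t_arr, dtype=float)
            return s if np.ndim(t) else 1.0
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        s = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return s if np.ndim(t) else float(s[0])

    def ci_at(self, t) -> tuple[np.ndarray, np.ndarray]:
        t_arr = np.atleast_1d(t)
        if len(self.times) == 0:
            ones = np.ones_like(t_arr, dtype=float)
            return (ones, ones) if np.ndim(t) else (1.0, 1.0)
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        lo = np.where(idx >= 0, self.ci_lower[np.maximum(idx, 0)], 1.0)
        hi = np.where(idx >= 0, self.ci_upper[np.maximum(idx, 0)], 1.0)
        if np.ndim(t):
            return lo, hi
        return float(lo[0]), float(hi[0])

    def at_risk_at(self, t) -> np.ndarray:
        """Number still under observation at time t (durations >= t)."""
        d = np.sort(self.durations)
        cnt = len(d) - np.searchsorted(d, np.atleast_1d(t), side="left")
        return cnt if np.ndim(t) else int(cnt[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_days": self.times, "at_risk": self.at_risk, "events": self.events,
            "survival": self.survival, "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper, "variance": self.variance,
        })


@dataclass
class StratificationResult:
    model_key: str
    component_class: str
    verdict: str                       # better | similar | worse
    divergence_time: Optional[float]   # days, absent when similar
    n_uses: int
    implant_years: float


def km_estimate(durations, observed, alpha: float = 0.05,
                ci_method: str = "exp_greenwood") -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood confidence intervals.

    ``durations`` are days from implantation to removal or censoring;
    ``observed`` is True where the component was removed. All-censored input
    yields a flat curve at 1 with a degenerate CI.
    """
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if len(durations) == 0:
        raise ValueError("km_estimate requires at least one episode")
    if (durations < 0).any():
        raise ValueError("negative durations are invalid")

    implant_years = float(durations.sum() / DAYS_PER_YEAR)
    event_times = np.unique(durations[observed])
    if len(event_times) == 0:
        return SurvivalCurve(
            times=np.array([]), at_risk=np.array([], dtype=int),
            events=np.array([], dtype=int), survival=np.array([]),
            ci_lower=np.array([]), ci_upper=np.array([]), variance=np.array([]),
            n_total=len(durations), implant_years=implant_years,
            durations=durations, observed=observed)

    srt = np.sort(durations)
    n_at_risk = len(srt) - np.searchsorted(srt, event_times, side="left")
    d = np.array([np.count_nonzero(observed & (durations == t)) for t in event_times])

    frac = 1.0 - d / n_at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf)
    gw = np.cumsum(gw_terms)
    with np.errstate(invalid="ignore"):
        var = np.where(surv > 0, surv ** 2 * gw, 0.0)  # S=0 tail: variance degenerate

    z = norm.ppf(1.0 - alpha / 2.0)
    if ci_method == "greenwood":
        half = z * np.sqrt(var)
        lo = np.clip(surv - half, 0.0, 1.0)
        hi = np.clip(surv + half, 0.0, 1.0)
    elif ci_method == "exp_greenwood":
        lo = np.empty_like(surv)
        hi = np.empty_like(surv)
        interior = (surv > 0) & (surv < 1) & np.isfinite(gw)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(surv[interior])
            se_theta = np.sqrt(gw[interior]) / np.abs(logs)
            theta = np.log(-logs)
            lo[interior] = np.exp(-np.exp(theta + z * se_theta))
            hi[interior] = np.exp(-np.exp(theta - z * se_theta))
        lo[~interior] = np.where(surv[~interior] <= 0, 0.0, surv[~interior])
        hi[~interior] = surv[~interior]
        lo = np.clip(lo, 0.0, 1.0)
        hi = np.clip(hi, 0.0, 1.0)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return SurvivalCurve(
        times=event_times, at_risk=n_at_risk, events=d, survival=surv,
        ci_lower=lo, ci_upper=hi, variance=var,
        n_total=len(durations), implant_years=implant_years,
        durations=durations, observed=observed)


def km_from_episodes(episodes: pd.DataFrame, **kw) -> SurvivalCurve:
    return km_estimate(episodes.duration_days.to_numpy(),
                       (episodes.end_reason == "removed").to_numpy(), **kw)


def stratify_model(model_curve: SurvivalCurve, comparator_curve: SurvivalCurve,
                   min_at_risk: int = 10) -> tuple[str, Optional[float]]:
    """Compare one model's CI band against the pooled comparator band.

    Returns ``(verdict, divergence_time)``. Verdict is *worse* when there is a
    time t0 with ``model.ci_upper(t) < comparator.ci_lower(t)`` at every
    evaluation time t >= t0 (*better* symmetric, else *similar*); the
    divergence time is the earliest such t0. Evaluation times are the union
    of event times where both arms retain at least ``min_at_risk`` at risk.
    """
    eval_times = np.union1d(model_curve.times, comparator_curve.times)
    if len(eval_times) == 0:
        return "similar", None
    ok = ((model_curve.at_risk_at(eval_times) >= min_at_risk)
          & (comparator_curve.at_risk_at(eval_times) >= min_at_risk))
    eval_times = eval_times[ok]
    if len(eval_times) == 0:
        return "similar", None
    m_lo, m_hi = model_curve.ci_at(eval_times)
    c_lo, c_hi = comparator_curve.ci_at(eval_times)

    def earliest_persistent(sep: np.ndarray) -> Optional[float]:
        # earliest index from which sep holds through the last evaluation time
        if not sep[-1]:
            return None
        rev = np.flip(sep)
        k = int(np.argmin(rev)) if not rev.all() else len(rev)
        return float(eval_times[len(sep) - k])

    t_worse = earliest_persistent(m_hi < c_lo)
    t_better = earliest_persistent(m_lo > c_hi)
    if t_worse is not None and (t_better is None or t_worse <= t_better):
        return "worse", t_worse
    if t_better is not None:
        return "better", t_better
    return "similar", None


def stratify_all(episodes: pd.DataFrame, component_class: str,
                 config: PipelineConfig | None = None) -> list[StratificationResult]:
    """Stratify every sufficiently used model of one class against its peers.

    Models with fewer than ``min_uses`` episodes are skipped (their curves are
    too unstable to compare). The comparator for each model pools every other
    model of the class, including the rarely used ones.
    """
    cfg = config or PipelineConfig()
    eps = episodes[episodes.component_class == component_class]
    results = []
    for mk, grp in eps.groupby("model_key"):
        if len(grp) < cfg.min_uses:
            continue
        others = eps[eps.model_key != mk]
        if len(others) == 0:
            continue
        mc = km_from_episodes(grp, ci_method=cfg.ci_method)
        cc = km_from_episodes(others, ci_method=cfg.ci_method)
        verdict, tdiv = stratify_model(mc, cc, cfg.min_at_risk)
        results.append(StratificationResult(
            model_key=mk, component_class=component_class, verdict=verdict,
            divergence_time=tdiv, n_uses=len(grp),
            implant_years=mc.implant_years))
    return results


def head_material_trend(typed: pd.DataFrame, mapping: pd.DataFrame
                        ) -> tuple[pd.DataFrame, Optional[int]]:
    """Per-year metal vs ceramic share of identified femoral heads.

    Percentages are of all identified heads that year; years with zero
    identified heads are omitted. The crossover year is the first year in
    which the ceramic share strictly exceeds the metal share (absent if
    never).
    """
    heads = mapping[(mapping.component_class == "head") & (mapping.status == "mapped")]
    if len(heads) == 0:
        return pd.DataFrame(columns=["year", "n_heads", "metal_pct", "ceramic_pct"]), None
    years = pd.to_datetime(heads.surgery_date).dt.year
    tab = (heads.assign(year=years)
           .groupby("year").material
           .agg(n_heads="size",
                metal=lambda s: (s == "metal").sum(),
                ceramic=lambda s: (s == "ceramic").sum())
           .reset_index())
    tab["metal_pct"] = 100.0 * tab.metal / tab.n_heads
    tab["ceramic_pct"] = 100.0 * tab.ceramic / tab.n_heads
    cross = tab.loc[tab.ceramic_pct > tab.metal_pct, "year"]
    crossover_year = int(cross.iloc[0]) if len(cross) else None
    return tab[["year", "n_heads", "metal_pct", "ceramic_pct"]], crossover_year


def plot_model_vs_comparator(model_curve: SurvivalCurve, comparator_curve: SurvivalCurve,
                             model_label: str, path: str,
                             at_risk_years=(0, 2, 4, 6, 8, 10, 12)) -> None:
    """Write a survivorship figure: model + pooled-comparator curves with CI
    bands and an at-risk table underneath."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for curve, label, color in ((comparator_curve, "all other models", "0.4"),
                                (model_curve, model_label, "C3")):
        t = np.concatenate([[0.0], curve.times]) / DAYS_PER_YEAR
        s = np.concatenate([[1.0], curve.survival])
        lo = np.concatenate([[1.0], curve.ci_lower])
        hi = np.concatenate([[1.0], curve.ci_upper])
        ax.step(t, s, where="post", label=label, color=color)
        ax.fill_between(t, lo, hi, step="post", alpha=0.2, color=color)
    ax.set_xlabel("years since implantation")
    ax.set_ylabel("survivorship (in situ)")
    ax.set_ylim(0.5, 1.02)
    ax.legend(loc="lower left")
    rows = [[str(int(curve.at_risk_at(y * DAYS_PER_YEAR)))
             for y in at_risk_years]
            for curve in (model_curve, comparator_curve)]
    tbl = ax.table(cellText=rows,
                   rowLabels=[model_label, "others"],
                   colLabels=[f"{y}y" for y in at_risk_years],
                   loc="bottom", bbox=(0.0, -0.45, 1.0, 0.25))
    tbl.auto_set_font_size(False)
    tbl.set_fontsize(8)
    fig.subplots_adjust(bottom=0.35)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def capture_report(mapping: pd.DataFrame, gt_parts: pd.DataFrame) -> pd.DataFrame:
    """Per-year, per-class fraction of implanted major components fully identified.

    ``expected`` comes from ground truth (one row per implanted component);
    ``identified`` counts ground-truth components whose part entry was mapped
    and classified with the correct component class in the correct surgery.
    """
    gt = gt_parts[gt_parts.component_class.isin(["shell", "liner", "stem", "head"])]
    mapped = mapping[mapping.status == "mapped"][
        ["surgery_id", "entry_index", "component_class"]].rename(
            columns={"component_class": "pipeline_class"})
    merged = gt.merge(mapped, left_on=["entry_surgery_id", "entry_index"],
                      right_on=["surgery_id", "entry_index"], how="left",
                      suffixes=("", "_map"))
    own_record = merged.entry_surgery_id == merged.surgery_id
    merged["identified"] = (own_record
                            & (merged.pipeline_class == merged.component_class))
    out = (merged.groupby(["year", "component_class"])
           .agg(expected=("identified", "size"), identified=("identified", "sum"))
           .reset_index())
    out["capture_pct"] = 100.0 * out.identified / out.expected
    return out
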