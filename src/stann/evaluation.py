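"""Statistical harness: stratified bootstrap splits, rank AUC with
Hanley-McNeil confidence intervals, quartile-dichotomized Cox hazard
ratios at multiple horizons, net reclassification, Kaplan-Meier curves
and paired model comparisons.

Summary AUCs/HRs are means over retained bootstrap rounds, and summary
CIs are means of the per-round CIs (not CIs of the means).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from . import models as _models
from .models import MinMaxScaler, fit_ann, fit_lr

DEFAULT_HORIZONS = (365, 60, 30, 14)


@dataclass(frozen=True)
class BootstrapPlan:
    n_rounds: int = 1000
    test_fraction: float = 0.2
    stratify_on_event: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class ReclassificationCounts:
    events_n: int
    events_up: int
    events_down: int
    nonevents_n: int
    nonevents_up: int
    nonevents_down: int

    def __post_init__(self) -> None:
        if self.events_n < 1 or self.nonevents_n < 1:
            raise ValueError("both classes must be non-empty")
        if self.events_up + self.events_down > self.events_n:
            raise ValueError("reclassified events exceed event count")
        if self.nonevents_up + self.nonevents_down > self.nonevents_n:
            raise ValueError("reclassified nonevents exceed nonevent count")


class RoundEliminated(RuntimeError):
    """Signal that a bootstrap round cannot support the requested statistic."""


def stratified_splits(
    events: np.ndarray, plan: BootstrapPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """80/20-style splits with the test event count fixed across rounds.

    Test size = round(f*n); test events = round(f*n_events) (at least 1);
    events and non-events are sampled without replacement each round.
    """
    y = np.asarray(events, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) < 1 or len(neg) < 1:
        raise ValueError("cohort must contain at least one event and one non-event")
    n = len(y)
    n_test = int(round(plan.test_fraction * n))
    n_test_pos = int(round(plan.test_fraction * len(pos))) if plan.stratify_on_event else None
    if plan.stratify_on_event:
        n_test_pos = min(max(n_test_pos, 1), len(pos))
        if n_test_pos >= n_test:
            raise ValueError("cohort too small to stratify the requested test fraction")
        if len(pos) - n_test_pos < 1:
            raise ValueError(
                f"cohort has only {len(pos)} event(s); stratified splitting would "
                "leave no events for training"
            )
    rng = np.random.default_rng(plan.seed)
    splits = []
    for _ in range(plan.n_rounds):
        if plan.stratify_on_event:
            p = rng.permutation(pos)
            q = rng.permutation(neg)
            test = np.concatenate([p[:n_test_pos], q[: n_test - n_test_pos]])
            train = np.concatenate([p[n_test_pos:], q[n_test - n_test_pos :]])
        else:
            order = rng.permutation(n)
            test, train = order[:n_test], order[n_test:]
        splits.append((np.sort(train), np.sort(test)))
    return splits


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based concordance probability; ties contribute 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def hanley_mcneil_ci(
    auc_value: float, n_pos: int, n_neg: int
) -> tuple[float, float, float]:
    """(SE, lower, upper): closed-form AUC standard error and 95% CI.

    Q1 = A/(2-A), Q2 = 2A^2/(1+A); CI = A +/- 1.96*SE clipped to [0,1].
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one observation in each class")
    a = float(auc_value)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    return se, max(a - 1.96 * se, 0.0), min(a + 1.96 * se, 1.0)


def truncate_sig(x: float, digits: int = 1) -> float:
    """Truncate toward zero at the given number of significant digits."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    e = math.floor(math.log10(abs(x))) - (digits - 1)
    return math.trunc(x / 10**e) * 10**e


def dichotomize_upper_quartile(
    scores: np.ndarray, external_cutoff: float | None = None
) -> tuple[np.ndarray, float]:
    """High-risk indicator: score strictly above the 75th percentile.

    An external cutoff (e.g. transferred from another cohort) is truncated
    to one significant digit before use.
    """
    s = np.asarray(scores, dtype=float)
    if external_cutoff is not None:
        cut = truncate_sig(float(external_cutoff), 1)
    else:
        if len(s) < 4:
            raise ValueError("need at least 4 scores to derive a quartile cutoff")
        cut = float(np.percentile(s, 75))  # linear interpolation
    return (s > cut).astype(int), cut


def cox_hr(
    high_risk: np.ndarray,
    time_days: np.ndarray,
    event: np.ndarray,
    horizon_days: float = 365.0,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float, float]:
    """Cox PH hazard ratio of high-risk vs rest, censored at the horizon.

    Events after the horizon are administratively censored at the horizon.
    Returns (HR, CI_low, CI_high); degenerate rounds raise RoundEliminated.
    """
    hr_flag = np.asarray(high_risk, dtype=int)
    t = np.asarray(time_days, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(np.unique(hr_flag)) < 2:
        raise RoundEliminated("one risk group is empty")
    e_h = np.where(t > horizon_days, 0, e)
    t_h = np.minimum(t, horizon_days)
    if e_h.sum() < 1:
        raise RoundEliminated("no events before the horizon")
    if e_h[hr_flag == 1].sum() < 1 or e_h[hr_flag == 0].sum() < 1:
        raise RoundEliminated("no events in one risk group before the horizon")
    df = pd.DataFrame({"T": t_h, "E": e_h, "high_risk": hr_flag})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        df = pd.concat([df, cov], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except Exception as exc:  # lifelines convergence errors
        raise RoundEliminated(f"Cox fit failed: {exc}") from exc
    beta = float(cph.params_["high_risk"])
    se = float(cph.standard_errors_["high_risk"])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 50:
        raise RoundEliminated("non-finite/degenerate Cox estimate")
    return math.exp(beta), math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)


def nri(counts: ReclassificationCounts) -> float:
    """Net reclassification index:
    P(up|event) - P(up|nonevent) + P(down|nonevent) - P(down|event)."""
    return (
        counts.events_up / counts.events_n
        - counts.nonevents_up / counts.nonevents_n
        + counts.nonevents_down / counts.nonevents_n
        - counts.events_down / counts.events_n
    )


def counts_from_classes(
    old_class: np.ndarray, new_class: np.ndarray, labels: np.ndarray
) -> ReclassificationCounts:
    """Two-category reclassification counts from old/new high-risk indicators."""
    old = np.asarray(old_class, dtype=int)
    new = np.asarray(new_class, dtype=int)
    y = np.asarray(labels, dtype=int)
    up = (new > old).astype(int)
    down = (new < old).astype(int)
    ev, nv = y == 1, y == 0
    return ReclassificationCounts(
        events_n=int(ev.sum()),
        events_up=int(up[ev].sum()),
        events_down=int(down[ev].sum()),
        nonevents_n=int(nv.sum()),
        nonevents_up=int(up[nv].sum()),
        nonevents_down=int(down[nv].sum()),
    )


def counts_from_scores(
    old_scores: np.ndarray, new_scores: np.ndarray, labels: np.ndarray
) -> ReclassificationCounts:
    """Category-free counts: up/down = raw model output increased/decreased."""
    old = np.asarray(old_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    up = (new > old).astype(int)
    down = (new < old).astype(int)
    ev, nv = y == 1, y == 0
    return ReclassificationCounts(
        events_n=int(ev.sum()),
        events_up=int(up[ev].sum()),
        events_down=int(down[ev].sum()),
        nonevents_n=int(nv.sum()),
        nonevents_up=int(up[nv].sum()),
        nonevents_down=int(down[nv].sum()),
    )


def km_curve(
    time_days: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    horizon_days: float = 60.0,
    tick_times: tuple = (0, 10, 20, 30, 40, 50, 60),
) -> pd.DataFrame:
    """Product-limit survival per group truncated at the horizon, with at-risk counts."""
    t = np.asarray(time_days, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    e_h = np.where(t > horizon_days, 0, e)
    t_h = np.minimum(t, horizon_days)
    frames = []
    for label in np.unique(g):
        mask = g == label
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t_h[mask], e_h[mask])
        sf = kmf.survival_function_
        times = sf.index.to_numpy(dtype=float)
        surv = sf.iloc[:, 0].to_numpy(dtype=float)
        at_risk = np.array([(t_h[mask] >= tt).sum() for tt in times])
        frames.append(
            pd.DataFrame(
                {"group": label, "time": times, "survival": surv, "at_risk": at_risk}
            )
        )
        tick_risk = {tt: int((t_h[mask] >= tt).sum()) for tt in tick_times}
        frames[-1].attrs["tick_at_risk"] = tick_risk
    out = pd.concat(frames, ignore_index=True)
    out.attrs["tick_at_risk"] = {
        str(f["group"].iloc[0]): f.attrs["tick_at_risk"] for f in frames
    }
    return out


def paired_compare(metric_a: np.ndarray, metric_b: np.ndarray) -> float:
    """Two-sided paired t-test p-value over per-round metric differences."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    if np.allclose(np.std(d, ddof=1), 0.0):
        if np.isclose(np.mean(d), 0.0):
            return 1.0
        warnings.warn("zero-variance nonzero paired differences", stacklevel=2)
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class BootstrapResult:
    per_round: pd.DataFrame  # one row per (round, model) with AUC/SE/CI + flags
    summary: dict
    n_rounds: int
    n_eliminated: int


MODEL_CHOICES = ("lr_hx", "lr_st", "lr_hx_st", "rnn", "ann", "trs")


def _score_round(
    model_names: tuple,
    tr: np.ndarray,
    te: np.ndarray,
    history: np.ndarray,
    st_feats: np.ndarray | None,
    windows: np.ndarray | None,
    trs: np.ndarray | None,
    y: np.ndarray,
    seed: int,
    rnn_kwargs: dict | None,
) -> dict[str, np.ndarray]:
    """Test-set scores for every requested model on one train/test split.

    When the ensemble is requested its sub-models (history LR, RNN) are
    read off the fitted bundle rather than refit, so a round costs one
    RNN fit regardless of how many of the three appear in model_names.
    """
    out: dict[str, np.ndarray] = {}
    want = set(model_names)
    bundle = None
    if "ann" in want:
        with warnings.catch_warnings():
            # the per-fit parameter-budget warning would fire on every round
            warnings.filterwarnings("ignore", message=".*trainable parameters exceed.*")
            bundle = fit_ann(
                history[tr], windows[tr], y[tr], seed=seed, rnn_kwargs=rnn_kwargs
            )
        scores = bundle.predict(history[te], windows[te])
        out["ann"] = scores["ann"]
        if "rnn" in want:
            out["rnn"] = scores["rnn"]
        if "lr_hx" in want:
            out["lr_hx"] = scores["lr_hx"]
    if "rnn" in want and "rnn" not in out:
        m = _models.fit_rnn(windows[tr], y[tr], seed=seed, **(rnn_kwargs or {}))
        out["rnn"] = m.predict_proba(windows[te])
    for model in ("lr_hx", "lr_st", "lr_hx_st"):
        if model not in want or model in out:
            continue
        if model == "lr_hx":
            X = history
        elif model == "lr_st":
            X = st_feats
        else:
            X = np.column_stack([history, st_feats])
        if X is None:
            raise ValueError(f"model {model} requires ST summary features")
        scaler = MinMaxScaler().fit(X[tr])
        m = fit_lr(scaler.transform(X[tr]), y[tr], seed=seed)
        out[model] = m.predict_proba(scaler.transform(X[te]))
    if "trs" in want:
        if trs is None:
            raise ValueError("TRS scores requested but no TRS column supplied")
        out["trs"] = np.array([_models.trs_ordinal(v) for v in trs[te]], dtype=float)
    return out


def run_benchmark(
    history: np.ndarray,
    y: np.ndarray,
    time_days: np.ndarray,
    plan: BootstrapPlan,
    st_feats: np.ndarray | None = None,
    windows: np.ndarray | None = None,
    trs: np.ndarray | None = None,
    model_names: tuple = ("lr_hx", "lr_hx_st", "ann"),
    horizons: tuple = DEFAULT_HORIZONS,
    compute_hr: bool = True,
    rnn_kwargs: dict | None = None,
) -> BootstrapResult:
    """Fit/score every requested model on each stratified bootstrap round.

    Per round and model: test AUC with Hanley-McNeil CI and, optionally,
    upper-quartile Cox HRs per horizon. Rounds with fewer than 2 test
    events at a horizon, or failed Cox fits, are flagged eliminated for
    that statistic; summaries average the retained rounds.
    """
    y = np.asarray(y, dtype=int)
    history = np.atleast_2d(np.asarray(history, dtype=float))
    splits = stratified_splits(y, plan)
    rows = []
    for rnd, (tr, te) in enumerate(splits):
        round_seed = plan.seed * 100003 + rnd
        n_pos = int(y[te].sum())
        n_neg = len(te) - n_pos
        round_scores = _score_round(
            model_names, tr, te, history, st_feats, windows, trs, y, round_seed, rnn_kwargs
        )
        for model in model_names:
            scores = round_scores[model]
            a = auc(scores, y[te])
            se, lo, hi = hanley_mcneil_ci(a, n_pos, n_neg)
            rec = {
                "round": rnd,
                "model": model,
                "auc": a,
                "auc_se": se,
                "auc_ci_low": lo,
                "auc_ci_high": hi,
            }
            if compute_hr:
                for h in horizons:
                    eliminated = False
                    hr = ci_lo = ci_hi = np.nan
                    if (np.asarray(time_days)[te] <= h)[y[te] == 1].sum() < 2:
                        eliminated = True
                    else:
                        try:
                            flag, _ = dichotomize_upper_quartile(scores)
                            hr, ci_lo, ci_hi = cox_hr(
                                flag, np.asarray(time_days)[te], y[te], horizon_days=h
                            )
                        except RoundEliminated:
                            eliminated = True
                    rec[f"hr_{h}"] = hr
                    rec[f"hr_{h}_ci_low"] = ci_lo
                    rec[f"hr_{h}_ci_high"] = ci_hi
                    rec[f"hr_{h}_eliminated"] = eliminated
            rows.append(rec)

    per_round = pd.DataFrame(rows)
    summary: dict = {}
    n_elim_total = 0
    if len(per_round):
        for model in model_names:
            sub = per_round[per_round["model"] == model]
            entry = {
                "auc": float(sub["auc"].mean()),
                "auc_ci_low": float(sub["auc_ci_low"].mean()),
                "auc_ci_high": float(sub["auc_ci_high"].mean()),
            }
            if compute_hr:
                for h in horizons:
                    keep = ~sub[f"hr_{h}_eliminated"]
                    n_elim = int((~keep).sum())
                    n_elim_total = max(n_elim_total, n_elim)
                    if n_elim > 0.05 * max(len(sub), 1):
                        warnings.warn(
                            f"{model}: {n_elim}/{len(sub)} rounds eliminated at "
                            f"{h}-day horizon",
                            stacklevel=2,
                        )
                    entry[f"hr_{h}"] = float(sub.loc[keep, f"hr_{h}"].mean()) if keep.any() else np.nan
                    entry[f"hr_{h}_ci_low"] = (
                        float(sub.loc[keep, f"hr_{h}_ci_low"].mean()) if keep.any() else np.nan
                    )
                    entry[f"hr_{h}_ci_high"] = (
                        float(sub.loc[keep, f"hr_{h}_ci_high"].mean()) if keep.any() else np.nan
                    )
                    entry[f"hr_{h}_n_eliminated"] = n_elim
            summary[model] = entry
    return BootstrapResult(
        per_round=per_round,
        summary=summary,
        n_rounds=plan.n_rounds,
        n_eliminated=n_elim_total,
    )
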