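"""Survival statistics on pooled, per-dataset-dichotomized samples.

The estimators here are deliberately specialised to the two-group
setting the dichotomization produces: the Kaplan-Meier product-limit
curve per group, the two-group log-rank test, and a Cox proportional
hazards fit with a single binary covariate (high vs low) using Efron's
tie correction.  The one-parameter Cox partial likelihood is strictly
concave, so a scalar Newton iteration converges in a handful of steps —
fast enough to run once per gene in a transcriptome-wide screen.

All three share one sufficient-statistics tabulation: for every distinct
event time, the number of deaths overall and in the high group, and the
numbers at risk overall and in the high group.

Hazard ratios are reported high-versus-low: HR > 1 means high expression
carries worse outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from survpool.cohorts import Compendium, ValidationError
from survpool.stratify import (
    HIGH,
    InsufficientDataError,
    QuerySpec,
    assign_groups,
    combine_all_high,
    filter_samples,
)

logger = logging.getLogger("survpool")

#: Newton convergence tolerance on the Cox coefficient.
COX_TOL = 1e-9
COX_MAX_ITER = 50
#: |beta| beyond this is treated as monotone likelihood (separation).
COX_BETA_BOUND = 20.0


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``event_times`` are the distinct times with >=1 event; ``survival_prob``
    the estimate just after each; ``at_risk`` the risk-set size just
    before each.  With no events the arrays are empty and S(t) == 1.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def evaluate(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_prob[idx - 1])


@dataclass
class CoxResult:
    """Single-binary-covariate Cox fit (high vs low)."""

    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    beta: float
    se: float
    converged: bool
    n_iter: int

    @property
    def flagged(self) -> bool:
        """True on monotone likelihood / non-convergence (infinite CI)."""
        return not self.converged


@dataclass
class SurvivalResult:
    """Pooled two-group survival analysis of one query."""

    hr: float
    hr_ci_low: float
    hr_ci_high: float
    wald_p: float
    logrank_chi2: float
    logrank_p: float
    n: int
    n_high: int
    n_low: int
    n_events: int
    km_high: KMCurve
    km_low: KMCurve
    endpoint: str
    genes: tuple[str, ...]
    cutoff: str
    contributing_datasets: dict[str, int] = field(default_factory=dict)
    per_dataset_cutoffs: dict[str, float] = field(default_factory=dict)
    cox_flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "endpoint": self.endpoint,
            "cutoff": self.cutoff,
            "hr": self.hr,
            "hr_ci_low": self.hr_ci_low,
            "hr_ci_high": self.hr_ci_high,
            "wald_p": self.wald_p,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "n": self.n,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "n_events": self.n_events,
            "contributing_datasets": self.contributing_datasets,
            "per_dataset_cutoffs": self.per_dataset_cutoffs,
            "cox_flagged": self.cox_flagged,
        }


# ---------------------------------------------------------------------------
# Core estimators
# ---------------------------------------------------------------------------

def _as_arrays(times, events, group=None):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValidationError("times and events differ in length")
    if times.size == 0:
        raise ValidationError("empty survival input")
    if not np.all(np.isfinite(times)) or np.any(times < 0):
        raise ValidationError("times must be finite and non-negative")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("events must be 0/1")
    if group is None:
        return times, events
    group = np.asarray(group, dtype=bool)
    if group.shape != times.shape:
        raise ValidationError("group indicator differs in length")
    return times, events, group


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``events``: 1 = event observed, 0 = censored.  Censoring ties at an
    event time are handled with the usual convention that censored
    samples at t remain at risk for the event at t.
    """
    times, events = _as_arrays(times, events)
    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    uniq = np.unique(t[e == 1])
    if uniq.size == 0:
        return KMCurve(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    # risk set just before u: #\{t_i >= u\}
    n_at_risk = t.size - np.searchsorted(t, uniq, side="left")
    deaths = np.array([np.sum((t == u) & (e == 1)) for u in uniq])
    surv = np.cumprod(1.0 - deaths / n_at_risk)
    return KMCurve(uniq, surv, n_at_risk.astype(int))


def _event_table(times, events, group):
    """Per distinct event time: deaths (total, high), at-risk (total, high)."""
    order = np.argsort(times, kind="mergesort")
    t, e, g = times[order], events[order], group[order]
    uniq = np.unique(t[e == 1])
    start = np.searchsorted(t, uniq, side="left")
    n = t.size - start
    g_rev_cum = np.concatenate([np.cumsum(g[::-1])[::-1], [0]])
    n1 = g_rev_cum[start]
    d = np.zeros(uniq.size)
    d1 = np.zeros(uniq.size)
    ev_idx = np.searchsorted(uniq, t[e == 1])
    np.add.at(d, ev_idx, 1.0)
    np.add.at(d1, ev_idx, g[e == 1].astype(float))
    return uniq, d, d1, n.astype(float), n1.astype(float)


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test.

    ``group`` is the boolean high-group indicator.  Returns the
    chi-square statistic and its two-sided p-value on 1 df, from the
    standard observed-minus-expected sums over distinct event times with
    the hypergeometric variance.
    """
    times, events, group = _as_arrays(times, events, group)
    if not group.any():
        raise ValidationError("log-rank: high group is empty")
    if group.all():
        raise ValidationError("log-rank: low group is empty")
    if events.sum() == 0:
        raise ValidationError("log-rank: no events")
    _, d, d1, n, n1 = _event_table(times, events, group)
    expected = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1.0)
    var = np.where(n > 1, var, 0.0)
    o_minus_e = float(np.sum(d1 - expected))
    v = float(np.sum(var))
    if v <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _efron_terms(times, events, group, strata=None):
    """Flattened Efron per-(event-time, within-tie-index) constants.

    Returns arrays (n0, n1, d0frac, d1frac, s_total, d_total) where each
    flattened entry carries the at-risk counts and the Efron down-weight
    a = l/d for l = 0..d-1; contributions are concatenated across strata.
    """
    if strata is None:
        strata = np.zeros(times.size, dtype=int)
    parts = []
    s_total = 0.0
    for s in np.unique(strata):
        m = strata == s
        if not (events[m] == 1).any():
            continue
        _, d, d1, n, n1 = _event_table(times[m], events[m], group[m])
        s_total += d1.sum()
        reps = d.astype(int)
        n0_e = np.repeat(n - n1, reps)
        n1_e = np.repeat(n1, reps)
        # within-tie index l = 0..d_j-1, giving the Efron weight a = l/d_j
        total = int(reps.sum())
        l = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
        a = l / np.repeat(reps, reps)
        parts.append((n0_e, n1_e, a * np.repeat(d - d1, reps), a * np.repeat(d1, reps)))
    n0, n1, a0, a1 = (np.concatenate(cols) for cols in zip(*parts))
    return n0, n1, a0, a1, s_total


def cox_binary(times, events, group, strata=None) -> CoxResult:
    """Cox proportional-hazards fit of a single binary covariate.

    Maximizes the Efron-tie-corrected partial likelihood for the
    coefficient of the high-group indicator by scalar Newton iteration
    (tolerance 1e-9, max 50 iterations); HR = exp(beta) with a 95% Wald
    CI.  Monotone partial likelihood (the groups perfectly separate the
    event ordering) cannot be maximized at a finite beta; the result is
    then flagged with an infinite CI rather than raising.

    ``strata``, if given, fits one shared beta with stratum-specific
    baseline hazards (dataset-stratified sensitivity mode).
    """
    times, events, group = _as_arrays(times, events, group)
    if not group.any() or group.all():
        empty = "high" if not group.any() else "low"
        raise ValidationError(f"cox: {empty} group is empty")
    if events.sum() < 2:
        raise ValidationError("cox: need at least 2 events")
    n0, n1, a0, a1, s_total = _efron_terms(
        times, events, group, None if strata is None else np.asarray(strata)
    )

    def score_info(beta: float) -> tuple[float, float]:
        eb = np.exp(beta)
        A = (n0 - a0) + (n1 - a1) * eb
        B = (n1 - a1) * eb
        r = B / A
        return s_total - r.sum(), float(np.sum(r * (1.0 - r)))

    beta = 0.0
    converged = False
    it = 0
    for it in range(1, COX_MAX_ITER + 1):
        u, info = score_info(beta)
        if info <= 1e-12:
            break
        step = u / info
        # damp huge steps; keeps iterates inside the representable range
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < COX_TOL:
            converged = True
            break
        if abs(beta) > COX_BETA_BOUND:
            break
    _, info = score_info(beta)
    if not converged or info <= 1e-12 or abs(beta) > COX_BETA_BOUND:
        logger.warning("cox: monotone likelihood or non-convergence (beta=%.3g)", beta)
        return CoxResult(
            hr=float(np.exp(beta)),
            ci_low=0.0,
            ci_high=np.inf,
            wald_p=1.0,
            beta=beta,
            se=np.inf,
            converged=False,
            n_iter=it,
        )
    se = 1.0 / np.sqrt(info)
    z = beta / se
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        wald_p=float(2.0 * stats.norm.sf(abs(z))),
        beta=float(beta),
        se=float(se),
        converged=True,
        n_iter=it,
    )


def efron_partial_loglik(beta: float, times, events, group) -> float:
    """Efron partial log-likelihood at ``beta`` (used for diagnostics and
    as a target for independent maximization in tests)."""
    times, events, group = _as_arrays(times, events, group)
    n0, n1, a0, a1, s_total = _efron_terms(times, events, group)
    eb = np.exp(beta)
    A = (n0 - a0) + (n1 - a1) * eb
    return float(s_total * beta - np.sum(np.log(A)))


# ---------------------------------------------------------------------------
# Pooled queries
# ---------------------------------------------------------------------------

def gather_pooled_samples(
    comp: Compendium, spec: QuerySpec
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assemble the pooled labelled sample table for a query.

    Per cohort: apply the clinical filter, drop samples missing the
    endpoint, dichotomize each query gene at that cohort's cutoff,
    combine multi-gene assignments as all-high-vs-rest.  Cohorts missing
    a query gene, the endpoint, or enough usable values contribute
    nothing (logged).

    Returns a DataFrame (time, event, group, dataset_id) — ``group`` the
    boolean high indicator — and the per-dataset cutoffs used.
    """
    tcol, ecol = ("os_time", "os_event") if spec.endpoint == "OS" else ("dfs_time", "dfs_event")
    frames = []
    cutoffs: dict[str, float] = {}
    for cohort in comp:
        missing = [g for g in spec.genes if g not in cohort.expression.index]
        if missing:
            logger.info(
                "cohort %s: gene(s) %s absent, skipped", cohort.dataset_id, ",".join(missing)
            )
            continue
        sub = filter_samples(cohort, spec.filters)
        usable = sub.clinical[tcol].notna() & sub.clinical[ecol].notna()
        usable &= sub.clinical[tcol] > 0
        if usable.sum() < 2:
            logger.info("cohort %s: no usable %s samples", cohort.dataset_id, spec.endpoint)
            continue
        from survpool.cohorts import subset_cohort

        sub = subset_cohort(sub, sub.clinical.index[usable])
        try:
            assignments = [
                assign_groups(sub, g, spec.cutoff, extremes_only=spec.extremes_only)
                for g in spec.genes
            ]
        except InsufficientDataError as exc:
            logger.info("cohort %s: %s; skipped", cohort.dataset_id, exc)
            continue
        assignment = assignments[0] if len(assignments) == 1 else combine_all_high(assignments)
        labelled = assignment.labels[assignment.labels != "excluded"]
        if labelled.empty:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "time": sub.clinical.loc[labelled.index, tcol].to_numpy(),
                    "event": sub.clinical.loc[labelled.index, ecol].to_numpy(dtype=int),
                    "group": (labelled == HIGH).to_numpy(),
                    "dataset_id": cohort.dataset_id,
                },
                index=labelled.index,
            )
        )
        cutoffs.update(assignment.per_dataset_cutoffs)
    if not frames:
        raise ValidationError(
            f"no cohort contributes to the query (genes={list(spec.genes)}, "
            f"endpoint={spec.endpoint})"
        )
    return pd.concat(frames), cutoffs


def pooled_query(comp: Compendium, spec: QuerySpec) -> SurvivalResult:
    """Run a pooled two-group survival analysis of one query.

    Every contributing cohort is dichotomized at its own cutoff; the
    labelled samples are pooled and analysed together (a single global
    Kaplan-Meier pair, log-rank test and Cox fit).  With
    ``spec.stratified`` the Cox fit keeps per-dataset baseline hazards.
    """
    samples, cutoffs = gather_pooled_samples(comp, spec)
    grp = samples["group"].to_numpy()
    if grp.all() or not grp.any():
        raise ValidationError("pooled samples form a single group; nothing to compare")
    times = samples["time"].to_numpy()
    events = samples["event"].to_numpy()
    chi2, p = logrank_test(times, events, grp)
    strata = samples["dataset_id"].to_numpy() if spec.stratified else None
    cox = cox_binary(times, events, grp, strata=strata)
    contributing = samples.groupby("dataset_id").size().to_dict()
    return SurvivalResult(
        hr=cox.hr,
        hr_ci_low=cox.ci_low,
        hr_ci_high=cox.ci_high,
        wald_p=cox.wald_p,
        logrank_chi2=chi2,
        logrank_p=p,
        n=int(samples.shape[0]),
        n_high=int(grp.sum()),
        n_low=int((~grp).sum()),
        n_events=int(events.sum()),
        km_high=km_estimate(times[grp], events[grp]),
        km_low=km_estimate(times[~grp], events[~grp]),
        endpoint=spec.endpoint,
        genes=spec.genes,
        cutoff=spec.cutoff,
        contributing_datasets={k: int(v) for k, v in contributing.items()},
        per_dataset_cutoffs=cutoffs,
        cox_flagged=cox.flagged,
    )


def plot_km(result: SurvivalResult, path=None, ax=None):
    """Plot the pooled high/low Kaplan-Meier curves (months vs survival
    probability).  Requires matplotlib; headless-safe."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for curve, label, color in (
        (result.km_high, f"high (n={result.n_high})", "black"),
        (result.km_low, f"low (n={result.n_low})", "grey"),
    ):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival_prob])
        ax.step(t, s, where="post", label=label, color=color)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(
        f"{'+'.join(result.genes)} ({result.endpoint}): HR={result.hr:.2f}, "
        f"p={result.logrank_p:.2e}, n={result.n}"
    )
    ax.legend(loc="lower left", frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
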