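"""Transcriptome-wide prognostic screen.

Every gene in the compendium's universe is put through the pooled
dichotomized survival analysis; log-rank p-values are adjusted across
all tested genes by Benjamini-Hochberg, significant genes are ranked by
the extremity of their hazard ratio (|log HR|, so protective and
deleterious effects compete on equal footing), and the ranked hits are
scored with Harrell's concordance index whose significance is calibrated
by shuffling the survival information.

The concordance index uses the *continuous* expression of the gene as
the risk score.  Raw intensities are not comparable across platforms, so
C is computed within each dataset and combined as the usable-pair-
weighted average of the per-dataset indices (a pooled-rank mode exists
for sensitivity checks).  For protective genes (HR < 1) discrimination
is measured on the negated risk, so the reported C is always the
discriminative ability in the direction of the fitted effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from survpool.cohorts import Compendium, ValidationError
from survpool.survival import cox_binary, logrank_test

logger = logging.getLogger("survpool")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j>=i} (p_(j) * m / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------

def _usable_pairs(times, events) -> np.ndarray:
    """Boolean matrix U with U[i, j] = True iff pair (i, j) is usable and
    sample i is the one that must fail first: t_i < t_j with an event at
    t_i, or t_i == t_j with i an event and j censored.  Pairs tied on
    time with both events are not usable (Harrell's original rule)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    earlier = t[:, None] < t[None, :]
    tied = t[:, None] == t[None, :]
    return (earlier & e[:, None]) | (tied & e[:, None] & ~e[None, :])


def concordance_index(risk, times, events) -> float:
    """Harrell's C: fraction of usable pairs where the higher-risk sample
    fails first; risk ties count 1/2.  C = 0.5 is random ordering, 1.0
    perfect discrimination."""
    r = np.asarray(risk, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if r.size != t.size or t.size != e.size:
        raise ValidationError("risk, times and events differ in length")
    if r.size < 2 or e.sum() < 1:
        raise ValidationError("concordance needs >=2 samples and >=1 event")
    usable = _usable_pairs(t, e)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValidationError("no usable pairs (all censored or fully tied)")
    conc = np.sum(usable & (r[:, None] > r[None, :]))
    ties = np.sum(usable & (r[:, None] == r[None, :]))
    return float((conc + 0.5 * ties) / n_usable)


def _concordance_counts(risks_2d: np.ndarray, usable: np.ndarray) -> np.ndarray:
    """Concordant + half-tie counts for each row of ``risks_2d`` against a
    fixed usable-pair mask; vectorized over many risk vectors."""
    out = np.empty(risks_2d.shape[0])
    for k, r in enumerate(risks_2d):
        conc = np.sum(usable & (r[:, None] > r[None, :]))
        ties = np.sum(usable & (r[:, None] == r[None, :]))
        out[k] = conc + 0.5 * ties
    return out


def combined_concordance(blocks) -> tuple[float, int]:
    """Usable-pair-weighted combination of per-dataset concordance indices.

    ``blocks`` iterates (risk, times, events) per dataset.  Returns the
    weighted C and the total usable-pair count.  Equivalent to counting
    concordant pairs only within datasets — cross-platform intensity
    comparisons are meaningless.
    """
    num = 0.0
    den = 0
    for risk, times, events in blocks:
        r = np.asarray(risk, dtype=float)
        usable = _usable_pairs(times, events)
        w = int(usable.sum())
        if w == 0:
            continue
        num += _concordance_counts(r[None, :], usable)[0]
        den += w
    if den == 0:
        raise ValidationError("no usable pairs in any dataset")
    return num / den, den


def empirical_p(
    c_true: float,
    risk,
    times,
    events,
    n_perm: int = 10000,
    seed: int = 0,
    datasets=None,
    add_one: bool = False,
) -> float:
    """Permutation p-value of a concordance index.

    Shuffles the survival information against the risk scores ``n_perm``
    times (within datasets when ``datasets`` labels are given, matching
    how the observed C was combined) and reports the fraction of
    shuffles with C >= ``c_true``.  With ``add_one`` the positively
    biased estimator (r + 1) / (n_perm + 1) is returned instead, which
    never reports exactly zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    r = np.asarray(risk, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if datasets is None:
        datasets = np.zeros(r.size, dtype=int)
    datasets = np.asarray(datasets)
    rng = np.random.default_rng(seed)
    blocks = []
    for ds in np.unique(datasets):
        m = datasets == ds
        usable = _usable_pairs(t[m], e[m])
        blocks.append((r[m], usable, int(usable.sum())))
    den = sum(w for _, _, w in blocks)
    if den == 0:
        raise ValidationError("no usable pairs")
    count = 0
    for _ in range(n_perm):
        num = 0.0
        for rb, usable, w in blocks:
            if w == 0:
                continue
            perm = rng.permutation(rb.size)
            num += _concordance_counts(rb[perm][None, :], usable)[0]
        if num / den >= c_true - 1e-12:
            count += 1
    if add_one:
        return (count + 1) / (n_perm + 1)
    return count / n_perm


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenRow:
    """One gene's row in the transcriptome-wide screen."""

    gene: str
    hr: float
    logrank_p_raw: float
    p_adjusted: float
    n: int
    c_index: float = np.nan
    c_index_direction: int = 0  # +1 risk = expression, -1 risk = -expression
    c_index_p_empirical: float = np.nan
    c_index_p_addone: float = np.nan


SCREEN_COLUMNS = [
    "gene",
    "hr",
    "logrank_p_raw",
    "wald_p",
    "p_adjusted",
    "n",
    "n_events",
    "c_index",
    "c_index_direction",
    "c_index_p_empirical",
    "c_index_p_addone",
]


def _gene_seed(master_seed: int, gene_index: int) -> np.random.SeedSequence:
    # per-gene stream independent of screen order
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(gene_index),))


def screen_all_genes(
    comp: Compendium,
    endpoint: str = "OS",
    method: str = "median",
    *,
    alpha: float = 0.05,
    seed: int = 0,
    n_perm: int = 1000,
    cindex: str = "top",
    top_k: int = 10,
    p_source: str = "logrank",
    cindex_mode: str = "within",
    min_group: int = 10,
) -> pd.DataFrame:
    """Screen every gene in the compendium for prognostic association.

    For each gene in the gene universe the pooled dichotomized analysis
    is run (per-dataset cutoffs, pooled log-rank and Cox HR); genes for
    which the analysis fails (absent everywhere, degenerate groups,
    fewer than ``min_group`` samples per pooled group) are logged and
    omitted.  BH adjustment is applied across all tested genes to the
    ``p_source`` p-value (log-rank by default, ``"wald"`` optional).

    Concordance indices (continuous expression as risk, oriented along
    the fitted effect, combined across datasets per ``cindex_mode``) and
    their permutation p-values are computed for ``cindex="all"`` genes or
    only for the ranked ``top_k`` hits in each HR direction
    (``cindex="top"``, the default) or not at all (``"none"``).  The
    permutation stream is derived from ``seed`` and the gene's index in
    the sorted universe, so per-gene results do not depend on screen
    order.

    Returns a DataFrame with one row per tested gene (columns
    :data:`SCREEN_COLUMNS`), in gene-universe order.
    """
    if cindex not in ("top", "all", "none"):
        raise ValueError(f"unknown cindex option {cindex!r}")
    if p_source not in ("logrank", "wald"):
        raise ValueError(f"unknown p_source {p_source!r}")
    if cindex_mode not in ("within", "pooled"):
        raise ValueError(f"unknown cindex_mode {cindex_mode!r}")
    tcol, ecol = ("os_time", "os_event") if endpoint == "OS" else ("dfs_time", "dfs_event")

    # Precompute, per cohort: usable samples' survival arrays and the
    # full per-gene high/valid matrices (vectorized dichotomization).
    prepared = []
    for cohort in comp:
        usable = (
            cohort.clinical[tcol].notna()
            & cohort.clinical[ecol].notna()
            & (cohort.clinical[tcol] > 0)
        )
        if usable.sum() < 2:
            continue
        X = cohort.expression.loc[:, usable.to_numpy()].to_numpy(dtype=float)
        valid = ~np.isnan(X)
        enough = valid.sum(axis=1) >= 2
        with np.errstate(invalid="ignore", all="ignore"):
            if method == "median":
                cut = np.nanpercentile(X, 50.0, axis=1)
                high = X > cut[:, None]
            elif method == "upper_quartile":
                cut = np.nanpercentile(X, 75.0, axis=1)
                high = X > cut[:, None]
            elif method == "lower_quartile":
                cut = np.nanpercentile(X, 25.0, axis=1)
                high = X >= cut[:, None]
            else:
                raise ValueError(f"unknown cutoff method {method!r}")
        prepared.append(
            {
                "dataset": cohort.dataset_id,
                "genes": pd.Index(cohort.expression.index),
                "row_of": {g: i for i, g in enumerate(cohort.expression.index)},
                "times": cohort.clinical.loc[usable, tcol].to_numpy(dtype=float),
                "events": cohort.clinical.loc[usable, ecol].to_numpy(dtype=int),
                "X": X,
                "high": high,
                "valid": valid,
                "enough": enough,
            }
        )
    if not prepared:
        raise ValidationError(f"no cohort has usable {endpoint} samples")

    universe = sorted(comp.gene_universe)
    rows = []
    n_skipped = 0
    for gi, gene in enumerate(universe):
        times_parts, events_parts, group_parts, risk_parts, ds_parts = [], [], [], [], []
        for prep in prepared:
            i = prep["row_of"].get(gene)
            if i is None or not prep["enough"][i]:
                continue
            v = prep["valid"][i]
            times_parts.append(prep["times"][v])
            events_parts.append(prep["events"][v])
            group_parts.append(prep["high"][i, v])
            risk_parts.append(prep["X"][i, v])
            ds_parts.append(np.full(int(v.sum()), prep["dataset"], dtype=object))
        if not times_parts:
            n_skipped += 1
            continue
        times = np.concatenate(times_parts)
        events = np.concatenate(events_parts)
        group = np.concatenate(group_parts)
        if (
            group.sum() < min_group
            or (~group).sum() < min_group
            or events.sum() < 2
            or events[group].sum() + events[~group].sum() < 1
        ):
            n_skipped += 1
            continue
        try:
            chi2, lr_p = logrank_test(times, events, group)
            cox = cox_binary(times, events, group)
        except ValidationError as exc:
            logger.info("screen: gene %s skipped (%s)", gene, exc)
            n_skipped += 1
            continue
        rows.append(
            {
                "gene": gene,
                "gene_index": gi,
                "hr": cox.hr,
                "logrank_p_raw": lr_p,
                "wald_p": cox.wald_p,
                "n": int(times.size),
                "n_events": int(events.sum()),
                "_blocks": (times_parts, events_parts, risk_parts, ds_parts),
                "cox_flagged": cox.flagged,
            }
        )
    if n_skipped:
        logger.info("screen: %d of %d genes skipped", n_skipped, len(universe))
    if not rows:
        return pd.DataFrame(columns=SCREEN_COLUMNS)

    df = pd.DataFrame(rows)
    raw = df["logrank_p_raw"] if p_source == "logrank" else df["wald_p"]
    df["p_adjusted"] = bh_adjust(raw.to_numpy())
    for col in ("c_index", "c_index_p_empirical", "c_index_p_addone"):
        df[col] = np.nan
    df["c_index_direction"] = 0

    if cindex != "none":
        if cindex == "all":
            targets = df.index
        else:
            ranked = rank_by_hr(df, alpha=alpha)
            high_df, low_df = top_by_direction(ranked, k=top_k)
            targets = high_df.index.union(low_df.index)
        for idx in targets:
            row = df.loc[idx]
            direction = -1 if row["hr"] < 1.0 else 1
            times_parts, events_parts, risk_parts, ds_parts = row["_blocks"]
            if cindex_mode == "within":
                blocks = [
                    (direction * r, t, e)
                    for r, t, e in zip(risk_parts, times_parts, events_parts)
                ]
                datasets = np.concatenate(ds_parts)
            else:  # pooled ranks across datasets
                pooled_risk = direction * np.concatenate(
                    [pd.Series(r).rank().to_numpy() for r in risk_parts]
                )
                blocks = [
                    (pooled_risk, np.concatenate(times_parts), np.concatenate(events_parts))
                ]
                datasets = None
            try:
                c, _ = combined_concordance(blocks)
            except ValidationError:
                continue
            df.loc[idx, "c_index"] = c
            df.loc[idx, "c_index_direction"] = direction
            if n_perm >= 1:
                rng_seed = _gene_seed(seed, int(row["gene_index"]))
                risk_all = direction * np.concatenate(risk_parts)
                p_emp = empirical_p(
                    c,
                    risk_all,
                    np.concatenate(times_parts),
                    np.concatenate(events_parts),
                    n_perm=n_perm,
                    seed=rng_seed,
                    datasets=datasets,
                )
                df.loc[idx, "c_index_p_empirical"] = p_emp
                df.loc[idx, "c_index_p_addone"] = (p_emp * n_perm + 1) / (n_perm + 1)

    return df[SCREEN_COLUMNS + ["cox_flagged"]].reset_index(drop=True)


def rank_by_hr(rows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep BH-significant rows (p_adjusted < alpha) and order them by
    effect extremity, descending |log HR| — a protective HR of h and a
    deleterious HR of 1/h tie."""
    if "p_adjusted" not in rows.columns:
        raise ValidationError("rows lack a p_adjusted column; run the screen first")
    sig = rows[rows["p_adjusted"] < alpha].copy()
    if sig.empty:
        return sig
    sig["_extremity"] = np.abs(np.log(sig["hr"].to_numpy()))
    sig = sig.sort_values(["_extremity", "gene"], ascending=[False, True], kind="mergesort")
    return sig.drop(columns="_extremity")


def top_by_direction(ranked: pd.DataFrame, k: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a ranked table into the top-k deleterious (HR > 1) and top-k
    protective (HR < 1) genes, each ordered by extremity."""
    if ranked.empty:
        return ranked, ranked
    high = ranked[ranked["hr"] > 1.0].head(k)
    low = ranked[ranked["hr"] < 1.0].head(k)
    return high, low


def write_screen_table(df: pd.DataFrame, path) -> None:
    """Write a screen result as the canonical tab-separated table."""
    df.loc[:, [c for c in SCREEN_COLUMNS if c in df.columns]].to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )
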