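"""Ranking of cell-state-specific promoter candidates.

Specificity is the log2 fold-difference between a promoter's predicted
activities in two states. Candidates are drawn either from the model
predictions (top fold-differences per state, plus range classes spanning
each state's activity spectrum) or, for low-coverage screens where the model
cannot be trusted, from a count-level heuristic over the most informative
features: total counts over all bins, counts in the negative bin, and which
bin holds the maximal counts. Enrichment of a validated subset against the
library background uses a two-sided Wilcoxon rank-sum test, enumerated
exactly for small samples.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ngs_preprocess import CountMatrix
from .screen_simulator import BIN_NAMES

FOLD_10 = float(np.log2(10))
FOLD_100 = float(np.log2(100))

CLASS_SPECIFIC_A = "specific-to-A"
CLASS_SPECIFIC_B = "specific-to-B"
CLASS_RANGE_A = "range-in-A"
CLASS_RANGE_B = "range-in-B"


# ---------------------------------------------------------------------------
# Fold difference
# ---------------------------------------------------------------------------

def fold_difference(pred: pd.DataFrame, state_a: str, state_b: str) -> pd.DataFrame:
    """Per-construct log2 fold-difference (state A minus state B).

    Input is a construct x state table of predicted log2 median
    fluorescence. Constructs missing either state are flagged
    (``missing=True``) and excluded from ranking; ranks are dense over the
    remaining constructs, largest fold first, ties broken by construct_id.
    """
    for s in (state_a, state_b):
        if s not in pred.columns:
            raise KeyError(f"state {s!r} absent from prediction table")
    out = pd.DataFrame(index=pred.index)
    out["pred_" + state_a] = pred[state_a]
    out["pred_" + state_b] = pred[state_b]
    out["log2_fold"] = pred[state_a] - pred[state_b]
    out["missing"] = out["log2_fold"].isna()
    out["ge_10fold"] = out["log2_fold"] >= FOLD_10
    out["ge_100fold"] = out["log2_fold"] >= FOLD_100
    # deterministic ranking: largest fold first, ties by construct_id
    ranked = out.loc[~out["missing"]]
    ranked = ranked.iloc[np.lexsort(
        (ranked.index.to_numpy(), -ranked["log2_fold"].to_numpy()))]
    out["rank"] = pd.Series(np.arange(1, len(ranked) + 1), index=ranked.index)
    out.index.name = "construct_id"
    return out


def _quantile_spread(series: pd.Series, n: int) -> list[str]:
    """n constructs at evenly spaced quantiles of a predicted-activity series."""
    clean = series.dropna().sort_values(kind="mergesort")
    clean = clean.iloc[np.lexsort((clean.index.to_numpy(), clean.to_numpy()))]
    if clean.empty or n <= 0:
        return []
    idx = np.round(np.linspace(0, len(clean) - 1, min(n, len(clean)))).astype(int)
    return list(dict.fromkeys(clean.index[idx]))


def select_candidates(pred: pd.DataFrame, state_a: str, state_b: str,
                      n_per_class: int) -> pd.DataFrame:
    """Pick validation candidates in the four promoter classes.

    Top ``n_per_class`` largest fold-differences (specific to A), smallest
    (specific to B), and ``n_per_class`` spanning the predicted-activity
    range of each state (evenly spaced quantiles). Deterministic: ties
    resolve by construct_id; a construct keeps its first assigned class.
    """
    folds = fold_difference(pred, state_a, state_b)
    usable = folds.loc[~folds["missing"]]
    if n_per_class > len(usable):
        import warnings
        warnings.warn("n_per_class exceeds available constructs; truncating")
    ordered = usable.iloc[np.lexsort(
        (usable.index.to_numpy(), -usable["log2_fold"].to_numpy()))]
    picks: dict[str, str] = {}
    for cid in ordered.index[:n_per_class]:
        picks.setdefault(cid, CLASS_SPECIFIC_A)
    for cid in ordered.index[::-1][:n_per_class]:
        picks.setdefault(cid, CLASS_SPECIFIC_B)
    for cid in _quantile_spread(pred.loc[usable.index, state_a], n_per_class):
        picks.setdefault(cid, CLASS_RANGE_A)
    for cid in _quantile_spread(pred.loc[usable.index, state_b], n_per_class):
        picks.setdefault(cid, CLASS_RANGE_B)
    table = folds.loc[sorted(picks)].copy()
    table["class"] = pd.Series(picks)
    return table.sort_values(["class", "rank"])


# ---------------------------------------------------------------------------
# Enrichment (two-sided Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

def _rank_sum_exact(subset: np.ndarray, background: np.ndarray) -> float:
    """Exact two-sided permutation p-value of the Mann-Whitney U statistic.

    Enumerates all C(n, m) assignments of the pooled values to the subset;
    two-sided p doubles the smaller tail (capped at 1), matching the exact
    rank-sum convention. Handles ties naturally through enumeration.
    """
    pooled = np.concatenate([subset, background])
    m = len(subset)
    ranks = stats.rankdata(pooled)  # midranks under ties
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = np.array([ranks[list(c)].sum() - m * (m + 1) / 2
                   for c in combinations(range(len(pooled)), m)])
    n_total = len(us)
    eps = 1e-9
    p_le = np.sum(us <= u_obs + eps) / n_total
    p_ge = np.sum(us >= u_obs - eps) / n_total
    return float(min(1.0, 2 * min(p_le, p_ge)))


def enrichment_test(subset: Sequence[float], background: Sequence[float],
                    exact_limit: int = 12) -> dict:
    """Two-sided Wilcoxon rank-sum test of subset folds vs. library background.

    The background should already exclude the subset. For combined
    n <= ``exact_limit`` the null distribution of U is enumerated exactly;
    larger samples use the tie-corrected normal approximation. All-tied
    inputs give p = 1.
    """
    subset = np.asarray(list(subset), dtype=float)
    background = np.asarray(list(background), dtype=float)
    if subset.size == 0 or background.size == 0:
        raise ValueError("subset and background must be non-empty")
    pooled = np.concatenate([subset, background])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:subset.size].sum() - subset.size * (subset.size + 1) / 2)
    if np.all(pooled == pooled[0]):
        return {"p_value": 1.0, "u_statistic": u, "method": "degenerate"}
    if subset.size + background.size <= exact_limit:
        p = _rank_sum_exact(subset, background)
        method = "exact"
    else:
        res = stats.mannwhitneyu(subset, background, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        p, method = float(res.pvalue), "normal-approximation"
    return {"p_value": p, "u_statistic": u, "method": method}


# ---------------------------------------------------------------------------
# Low-coverage heuristic (no model required)
# ---------------------------------------------------------------------------

def _state_triples(counts: CountMatrix, state: str) -> pd.DataFrame:
    """Per-construct (total, negative-bin count, argmax bin) raw-count triple."""
    sheet = counts.samples[counts.samples["state"] == state]
    per_bin = {}
    for bin_name, bin_sheet in sheet.groupby("bin", sort=False):
        per_bin[bin_name] = counts.raw[bin_sheet.index].sum(axis=1)
    table = pd.DataFrame(per_bin)[list(BIN_NAMES)]
    out = pd.DataFrame(index=table.index)
    out["total"] = table.sum(axis=1)
    out["negative"] = table["negative"]
    arr = table.to_numpy()
    out["argmax_bin"] = [BIN_NAMES[i] for i in np.argmax(arr, axis=1)]
    with np.errstate(invalid="ignore"):
        out["neg_fraction"] = np.where(out["total"] > 0,
                                       out["negative"] / out["total"], 1.0)
    return out


def low_coverage_rank(counts: CountMatrix, state_a: str, state_b: str,
                      neg_fraction_threshold: float = 0.25,
                      n_shortlist: int | None = None) -> pd.DataFrame:
    """Model-free candidate ranking for sparse screens.

    A construct is a candidate specific to state A when its maximal-count bin
    in A is a positive bin and its negative-bin count fraction in A is below
    ``neg_fraction_threshold``, while in state B the maximal-count bin is the
    negative bin (and symmetrically for B). Candidates are ranked by the
    negative-fraction contrast between states, ties by total counts then
    construct_id; constructs with zero counts in either state are excluded.
    """
    ta = _state_triples(counts, state_a)
    tb = _state_triples(counts, state_b)
    present = (ta["total"] > 0) & (tb["total"] > 0)
    ta, tb = ta.loc[present], tb.loc[present]

    active_a = (ta["argmax_bin"] != "negative") & \
               (ta["neg_fraction"] < neg_fraction_threshold)
    active_b = (tb["argmax_bin"] != "negative") & \
               (tb["neg_fraction"] < neg_fraction_threshold)
    silent_a = ta["argmax_bin"] == "negative"
    silent_b = tb["argmax_bin"] == "negative"

    out = pd.DataFrame(index=ta.index)
    out["candidate"] = np.select(
        [active_a & silent_b, active_b & silent_a],
        [f"specific-to-{state_a}", f"specific-to-{state_b}"], default="none")
    for state, t in ((state_a, ta), (state_b, tb)):
        out[f"total_{state}"] = t["total"]
        out[f"negative_{state}"] = t["negative"]
        out[f"argmax_{state}"] = t["argmax_bin"]
        out[f"neg_fraction_{state}"] = t["neg_fraction"]
    out["score"] = np.abs(tb["neg_fraction"] - ta["neg_fraction"])
    out.loc[out["candidate"] == "none", "score"] = -np.inf

    candidates = out[out["candidate"] != "none"].copy()
    order = np.lexsort((
        candidates.index.to_numpy(),
        -(candidates[f"total_{state_a}"] + candidates[f"total_{state_b}"]).to_numpy(),
        -candidates["score"].to_numpy(),
    ))
    candidates = candidates.iloc[order]
    if n_shortlist is not None:
        candidates = candidates.head(n_shortlist)
    candidates.index.name = "construct_id"
    return candidates
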