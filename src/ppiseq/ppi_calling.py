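"""Replicate fitness estimates -> per-environment PPI calls.

For every protein pair in every environment we compute a mean fitness
``f`` over replicate lineages and a one-sided Welch t-test p-value ``p``
against the pooled negative-control fitness distribution (ORF x Null and
RRS strains by default).  Calling thresholds ``(f_min, p_max)`` are chosen
per environment by grid search against positive/negative reference sets,
either balancing precision and recall (F1, the default) or bounding the
false-positive rate on the negative reference.  Proteins that "interact"
with untethered DHFR-fragment controls are promiscuous and blacklisted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ControlSets",
    "Thresholds",
    "pair_statistics",
    "aggregate_pairs",
    "choose_dynamic_threshold",
    "call_ppis",
    "flag_promiscuous",
    "evaluate_against_reference",
]

MIN_REPLICATES = 2


@dataclass(frozen=True)
class ControlSets:
    """Identifier lists for the five control roles (disjoint)."""

    dhfr_plus: tuple[str, ...] = ()
    dhfr_minus: tuple[str, ...] = ()
    orf_x_null: tuple[str, ...] = ()
    prs: tuple[str, ...] = ()
    rrs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sets = [set(getattr(self, f.name)) for f in self.__dataclass_fields__.values()]
        n_union = len(set().union(*sets))
        if n_union != sum(len(s) for s in sets):
            raise ValueError("control roles must be disjoint")


@dataclass(frozen=True)
class Thresholds:
    f_min: float
    p_max: float
    objective: str = "f1"
    score: float = float("nan")


def pair_statistics(replicates, negative_control_fitnesses) -> tuple[float, float]:
    """Mean fitness ``f`` and one-sided Welch p-value ``p`` of the
    replicates exceeding the negative-control distribution."""
    reps = np.asarray(replicates, dtype=float)
    neg = np.asarray(negative_control_fitnesses, dtype=float)
    if len(reps) < MIN_REPLICATES:
        raise ValueError("need >= 2 replicate fitness values")
    if len(neg) < 30:
        raise ValueError("need >= 30 negative-control fitness values")
    f = float(reps.mean())
    p = float(stats.ttest_ind(reps, neg, equal_var=False, alternative="greater").pvalue)
    return f, p


def aggregate_pairs(
    fitness: pd.DataFrame,
    negative_control_fitnesses,
    min_replicates: int = MIN_REPLICATES,
) -> pd.DataFrame:
    """Per-pair records for one environment from a per-lineage fitness table.

    ``fitness`` has columns ``lineage_id, pair_id, s`` (already filtered to
    kept lineages).  Pairs with fewer than ``min_replicates`` lineages are
    dropped (not callable).  Returns ``pair_id, f, p, n_replicates``.
    """
    neg = np.asarray(negative_control_fitnesses, dtype=float)
    rows = []
    for pair_id, grp in fitness.groupby("pair_id"):
        s = grp["s"].to_numpy(dtype=float)
        if len(s) < min_replicates:
            continue
        f, p = pair_statistics(s, neg)
        rows.append((pair_id, f, p, len(s)))
    return pd.DataFrame(rows, columns=["pair_id", "f", "p", "n_replicates"])


def _confusion(records: pd.DataFrame, called: np.ndarray, positive_ref, negative_ref):
    is_pos = records["pair_id"].isin(positive_ref).to_numpy()
    is_neg = records["pair_id"].isin(negative_ref).to_numpy()
    tp = int((called & is_pos).sum())
    fn = int((~called & is_pos).sum())
    fp = int((called & is_neg).sum())
    tn = int((~called & is_neg).sum())
    return tp, fn, fp, tn


def choose_dynamic_threshold(
    records: pd.DataFrame,
    positive_ref,
    negative_ref,
    objective: str = "f1",
    n_f_grid: int = 50,
    p_grid=None,
) -> Thresholds:
    """Grid-search the (f_min, p_max) pair optimising ``objective``.

    ``objective`` is ``"f1"`` (best precision/recall balance on the
    reference sets) or ``"fpr<=X"`` (max recall subject to a false-positive
    rate of at most X on the negative reference).  f_min candidates are
    quantiles of the observed f; p_max candidates a log grid.  Ties break
    toward larger f_min, then smaller p_max.
    """
    positive_ref, negative_ref = set(positive_ref), set(negative_ref)
    pres = set(records["pair_id"])
    if not (pres & positive_ref) or not (pres & negative_ref):
        raise ValueError("reference sets must overlap the records")
    f_grid = np.unique(np.quantile(records["f"], np.linspace(0.0, 1.0, n_f_grid)))
    if p_grid is None:
        p_grid = np.logspace(-12, 0, 25)
    fpr_bound = None
    if objective.startswith("fpr<="):
        fpr_bound = float(objective[5:])
    elif objective != "f1":
        raise ValueError(f"unknown objective: {objective}")

    fvals = records["f"].to_numpy()
    pvals = records["p"].to_numpy()
    best = None  # (score, f_min, p_max)
    for f_min in f_grid:
        for p_max in p_grid:
            called = (fvals >= f_min) & (pvals <= p_max)
            tp, fn, fp, tn = _confusion(records, called, positive_ref, negative_ref)
            if fpr_bound is not None:
                fpr = fp / max(fp + tn, 1)
                if fpr > fpr_bound:
                    continue
                score = tp / max(tp + fn, 1)  # recall
            else:
                prec = tp / max(tp + fp, 1)
                rec = tp / max(tp + fn, 1)
                score = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            key = (score, f_min, -p_max)
            if best is None or key > best[0]:
                best = (key, f_min, p_max)
    if best is None:
        raise ValueError("no threshold satisfies the objective")
    return Thresholds(f_min=float(best[1]), p_max=float(best[2]), objective=objective, score=float(best[0][0]))


def call_ppis(
    records: pd.DataFrame,
    thresholds: Thresholds | dict[str, Thresholds],
    blacklist=(),
) -> pd.DataFrame:
    """Apply per-environment thresholds to pair records.

    ``records`` must carry ``pair_id, f, p, n_replicates`` and, when
    ``thresholds`` is a per-environment mapping, an ``environment`` column.
    A pair is called iff f >= f_min, p <= p_max, it has >= 2 replicates and
    neither protein is blacklisted.  Pair ids of the form ``"A:B"`` expose
    their proteins to the blacklist check.
    """
    out = records.copy()
    if isinstance(thresholds, Thresholds):
        th_f = np.full(len(out), thresholds.f_min)
        th_p = np.full(len(out), thresholds.p_max)
    else:
        th_f = out["environment"].map(lambda e: thresholds[e].f_min).to_numpy()
        th_p = out["environment"].map(lambda e: thresholds[e].p_max).to_numpy()
    blacklist = set(blacklist)
    banned = out["pair_id"].map(
        lambda pid: any(prot in blacklist for prot in str(pid).split(":"))
    )
    out["called"] = (
        (out["f"].to_numpy() >= th_f)
        & (out["p"].to_numpy() <= th_p)
        & (out["n_replicates"] >= MIN_REPLICATES)
        & ~banned.to_numpy()
    )
    return out


def flag_promiscuous(
    orf_null_records: pd.DataFrame,
    thresholds: Thresholds | dict[str, Thresholds],
    global_blacklist: bool = True,
) -> set[str] | dict[str, set[str]]:
    """Blacklist proteins whose pairing with an untethered DHFR-fragment
    control is itself called positive.

    ``orf_null_records`` are pair records restricted to ORF x Null pairs
    (pair ids ``"PROT:NULL"``).  With ``global_blacklist`` a protein
    flagged in any environment is blacklisted everywhere; otherwise a
    per-environment mapping is returned.
    """
    called = call_ppis(orf_null_records, thresholds)
    hits = called.loc[called["called"]]
    if global_blacklist:
        return {str(pid).split(":")[0] for pid in hits["pair_id"]}
    out: dict[str, set[str]] = {}
    for env, grp in hits.groupby("environment"):
        out[str(env)] = {str(pid).split(":")[0] for pid in grp["pair_id"]}
    return out


def evaluate_against_reference(calls: pd.DataFrame, positive_ref, negative_ref) -> dict[str, float]:
    """PPV and TPR of the calls over reference pairs present in the assay."""
    positive_ref, negative_ref = set(positive_ref), set(negative_ref)
    pres = set(calls["pair_id"])
    if not (pres & (positive_ref | negative_ref)):
        raise ValueError("reference sets must overlap the assayed pairs")
    called = calls["called"].to_numpy(dtype=bool)
    tp, fn, fp, tn = _confusion(calls, called, positive_ref, negative_ref)
    return {
        "PPV": tp / max(tp + fp, 1),
        "TPR": tp / max(tp + fn, 1),
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "TN": tn,
    }
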