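"""Clonal growth-curve validation and the validation-rate (confidence) model.

Called PPIs are re-tested as clones in multi-well plates: optical density
is read every 15 minutes for 48 h with and without methotrexate.  The area
under the curve (AUC) is the sum of OD readings after saturation (40 h
with methotrexate, 25 h without); a pair validates when its replicate
AUC differences beat the negative-control wells in a one-sided Welch test
at Benjamini-Hochberg Q <= 0.05.

The binary validation outcomes then train a linear model of the
validation rate ``v`` as a function of the mean fitness ``f`` and the
number of environments ``n`` in which the PPI was detected.  Outcomes are
binned (once on f, once on n) into (f_bin, n_bin, v_bin) rows; the model
``v = a + b*f + c*n`` is fit by OLS on one binned dataset and scored by
rank correlation on the other.  Predictions are clamped to [0, 1] so they
can act as retention probabilities downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ValidationModelFit",
    "auc_statistics",
    "auc_change",
    "validate_clones",
    "fit_validation_model",
    "predict_confidence",
]

T_SAT_MTX_PLUS_H = 40.0
T_SAT_MTX_MINUS_H = 25.0


@dataclass(frozen=True)
class ValidationModelFit:
    intercept: float
    coef_f: float
    coef_n: float
    train_bins: pd.DataFrame
    test_bins: pd.DataFrame
    heldout_spearman: float


def auc_statistics(
    curves: pd.DataFrame,
    t_sat_plus_h: float = T_SAT_MTX_PLUS_H,
    t_sat_minus_h: float = T_SAT_MTX_MINUS_H,
) -> pd.DataFrame:
    """Per-well AUC: the sum of OD readings after the saturation time.

    ``curves`` is long format with columns ``well, pair_id, condition,
    mtx, minutes, od`` (``mtx`` boolean: with methotrexate).  Saturation is
    40 h for MTX+ wells and 25 h for MTX- wells.
    """
    if (curves["od"] < 0).any():
        raise ValueError("OD readings must be non-negative")
    t_sat_min = np.where(curves["mtx"].to_numpy(dtype=bool), t_sat_plus_h, t_sat_minus_h) * 60.0
    post = curves.loc[curves["minutes"].to_numpy() >= t_sat_min]
    auc = (
        post.groupby(["well", "pair_id", "condition", "mtx"], as_index=False)["od"]
        .sum()
        .rename(columns={"od": "auc"})
    )
    return auc


def auc_change(
    auc_target_condition: float,
    auc_control_condition: float,
    auc_target_sd: float,
    auc_control_sd: float,
) -> float:
    """Relative AUC change of a pair in a condition versus standard media,
    MTX+ only: the control-normalised excess AUC in the condition minus
    the same quantity in SD."""
    return (auc_target_condition - auc_control_condition) / auc_control_condition - (
        auc_target_sd - auc_control_sd
    ) / auc_control_sd


def validate_clones(
    auc_diffs_target: dict[str, np.ndarray] | pd.Series,
    auc_diffs_control,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pair validation against negative-control wells.

    ``auc_diffs_target`` maps pair_id -> replicate values of
    (AUC_MTX+ - AUC_MTX-); ``auc_diffs_control`` holds the same quantity
    for negative-control wells.  One-sided Welch t-test per pair, BH across
    pairs; validated iff Q <= ``alpha``.
    """
    control = np.asarray(auc_diffs_control, dtype=float)
    if len(control) < 3:
        raise ValueError("need >= 3 negative-control wells")
    items = (
        auc_diffs_target.items()
        if hasattr(auc_diffs_target, "items")
        else auc_diffs_target
    )
    rows = []
    for pair_id, reps in items:
        reps = np.asarray(reps, dtype=float)
        if len(reps) < 2:
            raise ValueError(f"pair {pair_id}: need >= 2 replicate wells")
        p = float(stats.ttest_ind(reps, control, equal_var=False, alternative="greater").pvalue)
        rows.append((pair_id, p))
    out = pd.DataFrame(rows, columns=["pair_id", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["validated"] = out["q"] <= alpha
    return out


def _bin_table(df: pd.DataFrame, key: np.ndarray) -> pd.DataFrame:
    g = df.groupby(key)
    return pd.DataFrame(
        {
            "f_bin": g["f"].mean(),
            "n_bin": g["n"].mean(),
            "v_bin": g["validated"].mean(),
        }
    ).reset_index(drop=True)


def fit_validation_model(
    validated: np.ndarray,
    f_values: np.ndarray,
    n_values: np.ndarray,
    f_bin_width: float = 0.01,
    train_on: str = "f",
) -> ValidationModelFit:
    """Fit ``v = a + b*f + c*n`` on binned validation outcomes.

    Two binned datasets are built — one binned on f (width
    ``f_bin_width``), one on integer n — each row holding the bin means
    (f_bin, n_bin) and the validated fraction v_bin.  The model is fit by
    OLS on the ``train_on`` dataset ("f" or "n") and scored by Spearman
    rank correlation of predictions on the other.
    """
    df = pd.DataFrame(
        {
            "validated": np.asarray(validated, dtype=float),
            "f": np.asarray(f_values, dtype=float),
            "n": np.asarray(n_values, dtype=float),
        }
    )
    fbins = _bin_table(df, np.floor(df["f"] / f_bin_width).astype(int).to_numpy())
    nbins = _bin_table(df, np.round(df["n"]).astype(int).to_numpy())
    train, test = (fbins, nbins) if train_on == "f" else (nbins, fbins)
    X = sm.add_constant(train[["f_bin", "n_bin"]].to_numpy())
    fit = sm.OLS(train["v_bin"].to_numpy(), X).fit()
    a, b, c = fit.params
    pred_test = np.clip(a + b * test["f_bin"] + c * test["n_bin"], 0.0, 1.0)
    if len(test) > 1 and np.std(test["v_bin"]) > 0 and np.std(pred_test) > 0:
        rho = float(stats.spearmanr(pred_test, test["v_bin"]).statistic)
    else:
        rho = float("nan")
    return ValidationModelFit(
        intercept=float(a),
        coef_f=float(b),
        coef_n=float(c),
        train_bins=train,
        test_bins=test,
        heldout_spearman=rho,
    )


def predict_confidence(f, n, model: ValidationModelFit):
    """Predicted validation rate v = clamp(a + b*f + c*n, 0, 1)."""
    v = model.intercept + model.coef_f * np.asarray(f, dtype=float) + model.coef_n * np.asarray(n, dtype=float)
    return np.clip(v, 0.0, 1.0)
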