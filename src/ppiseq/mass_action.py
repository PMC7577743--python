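"""Mass-action explanation of heterodimer fitness changes.

Under simple mass-action kinetics the abundance of a heterodimer AB scales
with the product of the free concentrations of A and B, so — using each
homodimer's fitness as a proxy for its constituent's abundance — the
heterodimer fitness should track the geometric mean of the two homodimer
fitnesses up to a scale factor embodying the relative functional
affinities:

    S_AB ~ beta * sqrt(S_AA * S_BB) + alpha

Each heterodimer with both homodimers measured is fit by OLS across
environments.  A heterodimer is "explained" by abundance when its slope
survives FDR control (BH across heterodimers, q < 0.05) while its
intercept stays insignificant (single-test p > 0.05).  A logistic model of
the explained flag on protein features (two observations per heterodimer,
one per constituent) then asks which features predict explainability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = [
    "DimerRecord",
    "MassActionFit",
    "build_dimer_dataset",
    "fit_mass_action",
    "classify_explained",
    "explainability_logistic",
]

MIN_ENVIRONMENTS = 4
SLOPE_FDR = 0.05
INTERCEPT_ALPHA = 0.05


@dataclass(frozen=True)
class DimerRecord:
    pair_id: str
    protein_a: str
    protein_b: str
    s_ab: np.ndarray
    s_aa: np.ndarray
    s_bb: np.ndarray
    environments: tuple[str, ...]


@dataclass(frozen=True)
class MassActionFit:
    pair_id: str
    slope: float
    intercept: float
    slope_p: float
    intercept_p: float


def build_dimer_dataset(
    fitness_matrix: pd.DataFrame,
    calls_matrix: pd.DataFrame,
) -> list[DimerRecord]:
    """Select heterodimers among homodimer-participating proteins.

    ``fitness_matrix`` is pair_id x environment normalised fitness (NaN
    when unquantified) with pair ids ``"A:B"``; ``calls_matrix`` the
    aligned boolean call matrix.  A heterodimer is retained when both
    constituent homodimers are present and at least ``MIN_ENVIRONMENTS``
    environments carry all three fitnesses, and the pair is called
    positive in at least one environment.  Measurements from both tag
    orientations (A:B and B:A) are pooled as extra environment
    observations.
    """
    envs = list(fitness_matrix.columns)
    homodimers = {}
    for pid in fitness_matrix.index:
        parts = str(pid).split(":")
        if len(parts) != 2:  # control strains and other non-pair rows
            continue
        a, b = parts
        if a == b:
            homodimers[a] = fitness_matrix.loc[pid].to_numpy(dtype=float)
    records = []
    seen = set()
    for pid in fitness_matrix.index:
        parts = str(pid).split(":")
        if len(parts) != 2:
            continue
        a, b = parts
        if a == b or a not in homodimers or b not in homodimers:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        orientations = [p for p in (f"{a}:{b}", f"{b}:{a}") if p in fitness_matrix.index]
        s_ab, s_aa, s_bb, env_used, called_any = [], [], [], [], False
        for orient in orientations:
            row = fitness_matrix.loc[orient].to_numpy(dtype=float)
            for j, e in enumerate(envs):
                if np.isnan(row[j]) or np.isnan(homodimers[a][j]) or np.isnan(homodimers[b][j]):
                    continue
                s_ab.append(row[j])
                s_aa.append(homodimers[a][j])
                s_bb.append(homodimers[b][j])
                env_used.append(e)
            if orient in calls_matrix.index:
                called_any = called_any or bool(calls_matrix.loc[orient].any())
        if len(s_ab) < MIN_ENVIRONMENTS or not called_any:
            continue
        records.append(
            DimerRecord(
                pair_id=f"{a}:{b}",
                protein_a=a,
                protein_b=b,
                s_ab=np.asarray(s_ab),
                s_aa=np.asarray(s_aa),
                s_bb=np.asarray(s_bb),
                environments=tuple(env_used),
            )
        )
    return records


def fit_mass_action(s_ab, s_aa, s_bb, pair_id: str = "") -> MassActionFit:
    """OLS of S_AB on the geometric mean of the homodimer fitnesses.

    Negative fitnesses are clamped to 0 before the geometric mean (the
    square root of a negative product is undefined).
    """
    s_ab = np.asarray(s_ab, dtype=float)
    g = np.sqrt(np.clip(np.asarray(s_aa, dtype=float), 0, None) * np.clip(np.asarray(s_bb, dtype=float), 0, None))
    if len(s_ab) < MIN_ENVIRONMENTS or len(g) != len(s_ab):
        raise ValueError("need >= 4 aligned environments")
    X = sm.add_constant(g)
    fit = sm.OLS(s_ab, X).fit()
    return MassActionFit(
        pair_id=pair_id,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_p=float(fit.pvalues[1]),
        intercept_p=float(fit.pvalues[0]),
    )


def classify_explained(fits: list[MassActionFit]) -> pd.DataFrame:
    """BH-adjust slope p-values across heterodimers and flag the explained
    ones: slope_q < 0.05 and intercept_p > 0.05."""
    df = pd.DataFrame([f.__dict__ for f in fits]).set_index("pair_id")
    df["slope_q"] = multipletests(df["slope_p"].fillna(1.0), method="fdr_bh")[1]
    df["explained"] = (df["slope_q"] < SLOPE_FDR) & (df["intercept_p"] > INTERCEPT_ALPHA)
    return df


def explainability_logistic(
    explained: pd.Series,
    feature_table: pd.DataFrame,
    dimers: list[DimerRecord],
) -> pd.DataFrame:
    """Logistic regression of the explained flag on protein features.

    Each heterodimer contributes one observation per constituent protein
    (its features paired with the dimer's explained status).  Constant
    features are dropped as non-identifiable; perfect separation falls
    back to an L2-regularised fit with p-values reported as NaN.  Features
    are fit on their raw scales; standardised coefficients are reported
    alongside.  p-values are BH-adjusted across features.
    """
    rows, ys = [], []
    for rec in dimers:
        if rec.pair_id not in explained.index:
            continue
        for prot in (rec.protein_a, rec.protein_b):
            if prot in feature_table.index:
                rows.append(feature_table.loc[prot])
                ys.append(bool(explained.loc[rec.pair_id]))
    X = pd.DataFrame(rows).reset_index(drop=True).astype(float)
    y = np.asarray(ys, dtype=float)
    if X.empty:
        raise ValueError("no overlapping observations between dimers and features")
    keep, dropped = [], []
    for col in X.columns:
        if np.nanstd(X[col].to_numpy()) == 0:
            dropped.append(col)
        else:
            keep.append(col)
    if dropped:
        logger.info("dropped constant (non-identifiable) features: %s", dropped)
    Xk = X[keep].fillna(X[keep].mean())
    sds = Xk.std(ddof=0)
    design = sm.add_constant(Xk.to_numpy())
    pvals, coefs = None, None
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)):
            raise PerfectSeparationError("non-finite standard errors")
        coefs = fit.params[1:]
        pvals = fit.pvalues[1:]
    except Exception:  # PerfectSeparationError, singular design, non-convergence
        reg = sm.Logit(y, design).fit_regularized(alpha=1.0, disp=0)
        coefs = np.asarray(reg.params)[1:]
        pvals = np.full(len(keep), np.nan)
        logger.warning("logistic fit degenerate (separation?); regularised coefficients, p=NaN")
    out = pd.DataFrame(
        {
            "coef": coefs,
            "coef_standardized": coefs * sds.to_numpy(),
            "p": pvals,
        },
        index=pd.Index(keep, name="feature"),
    )
    finite = out["p"].notna()
    q = np.full(len(out), np.nan)
    if finite.any():
        q[finite.to_numpy()] = multipletests(out.loc[finite, "p"], method="fdr_bh")[1]
    out["q"] = q
    for col in dropped:
        out.loc[col] = [np.nan, np.nan, np.nan, np.nan]
    return out
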