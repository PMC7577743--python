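"""End-to-end orchestration of the pooled-competition analysis.

Chains the stages on in-memory tables: count tables (simulated or
counted from reads) -> chimera correction -> per-environment fitness
estimation -> pair aggregation and dynamic-threshold PPI calling with
promiscuity filtering -> cross-environment normalisation and mutability ->
confidence-weighted richness estimation.  The file-based command line
interface wraps these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import richness as richness_mod
from .barcode_processing import correct_chimeras
from .fitness_inference import estimate_fitness
from .mutability import mutability_table, normalize_fitness, ppi_cv
from .ppi_calling import (
    Thresholds,
    aggregate_pairs,
    call_ppis,
    choose_dynamic_threshold,
    flag_promiscuous,
)
from .synthetic_data import SimConfig, SimTruth, simulate_experiment

__all__ = [
    "PipelineResult",
    "counts_to_matrix",
    "environment_fitness",
    "call_environment",
    "normalized_pair_matrix",
    "run_end_to_end",
]

NEGATIVE_CONTROL_CLASSES = ("orf_x_null", "rrs")
ASSAY_CLASSES = ("immutable", "mutable", "negative")


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces, keyed for inspection."""

    truth: SimTruth
    fitness: pd.DataFrame          # lineage_id, environment, pair_id, pair_class, s, d, status
    records: pd.DataFrame          # pair_id, environment, f, p, n_replicates, called
    thresholds: dict[str, Thresholds]
    blacklist: set[str]
    calls_matrix: pd.DataFrame     # assayed pairs x environments (bool)
    f_matrix: pd.DataFrame         # normalised pair fitness, pairs x environments
    ppi_cvs: dict[tuple, float]
    mutability: pd.DataFrame
    richness: richness_mod.RichnessResult
    metrics: dict[str, float] = field(default_factory=dict)


def counts_to_matrix(
    counts: pd.DataFrame, lineages: pd.DataFrame, environment: str, count_col: str = "count"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pivot one environment's long count table to lineage x timepoint.

    Double barcodes absent from the lineage map (e.g. novel chimeras) are
    dropped.  Returns the matrix (indexed by lineage_id) and the
    generation per timepoint column.
    """
    env = counts.loc[counts["environment"] == environment]
    keyed = env.merge(
        lineages[["barcode1_id", "barcode2_id", "lineage_id"]],
        on=["barcode1_id", "barcode2_id"],
        how="inner",
    )
    mat = keyed.pivot_table(
        index="lineage_id", columns="generation", values=count_col, aggfunc="sum", fill_value=0
    )
    gens = np.asarray(sorted(env["generation"].unique()), dtype=float)
    mat = mat.reindex(index=lineages["lineage_id"], columns=gens).fillna(0.0)
    return mat, gens


def environment_fitness(
    counts: pd.DataFrame,
    lineages: pd.DataFrame,
    environment: str,
    kappa: float = 2.5,
    chimera_correct: bool = False,
    d_max: float = 19.0,
) -> pd.DataFrame:
    """Per-lineage fitness for one environment (optionally after chimera
    correction of each timepoint's sample)."""
    count_col = "count"
    env_counts = counts.loc[counts["environment"] == environment]
    if chimera_correct:
        designed = set(zip(lineages["barcode1_id"], lineages["barcode2_id"]))
        corrected = []
        for _, sample in env_counts.groupby("timepoint"):
            corrected.append(correct_chimeras(sample, designed, count_col="count"))
        env_counts = pd.concat(corrected, ignore_index=True)
        count_col = "corrected_count"
    mat, gens = counts_to_matrix(env_counts, lineages, environment, count_col=count_col)
    neutral = lineages.loc[lineages["pair_class"] == "dhfr_minus", "lineage_id"]
    est = estimate_fitness(mat, gens, kappa=kappa, neutral_lineages=list(neutral), d_max=d_max)
    est = est.join(lineages.set_index("lineage_id")[["pair_id", "pair_class"]])
    est["environment"] = environment
    return est.reset_index()


def call_environment(
    fitness: pd.DataFrame,
    objective: str = "f1",
) -> tuple[pd.DataFrame, Thresholds]:
    """Aggregate one environment's kept lineages to pair records and pick
    the calling threshold from the PRS/RRS reference sets."""
    kept = fitness.loc[fitness["status"] == "kept"]
    neg = kept.loc[kept["pair_class"].isin(NEGATIVE_CONTROL_CLASSES), "s"]
    records = aggregate_pairs(kept, neg)
    records = records.merge(
        kept[["pair_id", "pair_class"]].drop_duplicates(), on="pair_id", how="left"
    )
    prs = records.loc[records["pair_class"] == "prs", "pair_id"]
    rrs = records.loc[records["pair_class"] == "rrs", "pair_id"]
    th = choose_dynamic_threshold(records, prs, rrs, objective=objective)
    return records, th


def normalized_pair_matrix(fitness_all: pd.DataFrame) -> pd.DataFrame:
    """Pair x environment matrix of normalised mean fitness.

    Lineage fitnesses are rescaled to the DHFR(-)/DHFR(+) control span per
    environment, averaged per pair, and negative means clamped to 0.
    """
    mats = {}
    for env, fit in fitness_all.groupby("environment"):
        kept = fit.loc[fit["status"] == "kept"]
        lo = kept.loc[kept["pair_class"] == "dhfr_minus", "s"].mean()
        hi = kept.loc[kept["pair_class"] == "dhfr_plus", "s"].mean()
        norm = normalize_fitness(kept["s"].to_numpy(), lo, hi)
        col = (
            pd.DataFrame({"pair_id": kept["pair_id"].to_numpy(), "norm": norm})
            .groupby("pair_id")["norm"]
            .mean()
            .clip(lower=0.0)
        )
        mats[env] = col
    return pd.DataFrame(mats)


def run_end_to_end(
    config: SimConfig,
    objective: str = "f1",
    chimera_correct: bool | None = None,
    richness_trials: int = 8,
    richness_permutations: int = 200,
    richness_seed: int = 0,
) -> PipelineResult:
    """Simulate and analyse one full multi-environment experiment.

    ``chimera_correct`` defaults to on exactly when the simulation injects
    chimeras.  Richness runs on the assayed (non-control) call matrix with
    unit confidence.  ``metrics`` reports per-cell recall and false
    positive rates against the simulation truth, plus the richness
    estimate against the true pan-environment PPI count.
    """
    counts, truth = simulate_experiment(config)
    if chimera_correct is None:
        chimera_correct = config.chimera_rate > 0

    fitness_all = pd.concat(
        [
            environment_fitness(
                counts, truth.lineages, env, kappa=config.kappa, chimera_correct=chimera_correct
            )
            for env in config.environments
        ],
        ignore_index=True,
    )

    record_blocks, thresholds = [], {}
    for env, fit in fitness_all.groupby("environment"):
        recs, th = call_environment(fit, objective=objective)
        recs["environment"] = env
        record_blocks.append(recs)
        thresholds[env] = th
    records = pd.concat(record_blocks, ignore_index=True)

    orf_null = records.loc[records["pair_class"] == "orf_x_null"]
    blacklist = flag_promiscuous(orf_null, thresholds) if len(orf_null) else set()
    records = call_ppis(records, thresholds, blacklist)

    assayed = records.loc[records["pair_class"].isin(ASSAY_CLASSES)]
    calls_matrix = (
        assayed.pivot_table(index="pair_id", columns="environment", values="called", aggfunc="any", fill_value=False)
        .astype(bool)
    )

    f_matrix = normalized_pair_matrix(fitness_all)

    # mutability over pairs called somewhere, zeros for measured negatives
    called_pairs = calls_matrix.index[calls_matrix.any(axis=1)]
    cvs: dict[tuple, float] = {}
    for pid in called_pairs:
        vec = f_matrix.loc[pid].dropna()
        if len(vec) < 2 or vec.mean() <= 0:
            continue
        a, b = str(pid).split(":")
        cvs[(a, b)] = ppi_cv(vec.to_numpy())
    mut = mutability_table(cvs) if cvs else pd.DataFrame()

    confidence = pd.DataFrame(1.0, index=calls_matrix.index, columns=calls_matrix.columns)
    rich = richness_mod.estimate_pan_interactome(
        calls_matrix,
        confidence,
        n_trials=richness_trials,
        n_permutations=richness_permutations,
        seed=richness_seed,
    )

    metrics = _truth_metrics(truth, calls_matrix, rich)
    return PipelineResult(
        truth=truth,
        fitness=fitness_all,
        records=records,
        thresholds=thresholds,
        blacklist=blacklist,
        calls_matrix=calls_matrix,
        f_matrix=f_matrix,
        ppi_cvs=cvs,
        mutability=mut,
        richness=rich,
        metrics=metrics,
    )


def _truth_metrics(truth: SimTruth, calls_matrix: pd.DataFrame, rich) -> dict[str, float]:
    assay_pairs = truth.pair_class.index[truth.pair_class.isin(ASSAY_CLASSES)]
    tm = truth.truth_matrix.loc[assay_pairs]
    cm = calls_matrix.reindex(index=tm.index, columns=tm.columns).fillna(False).astype(bool)
    t = tm.to_numpy()
    c = cm.to_numpy()
    tp = int((t & c).sum())
    fn = int((t & ~c).sum())
    fp = int((~t & c).sum())
    tn = int((~t & ~c).sum())
    true_pan = int(tm.any(axis=1).sum())
    return {
        "recall": tp / max(tp + fn, 1),
        "fpr": fp / max(fp + tn, 1),
        "fdr": fp / max(fp + tp, 1),
        "n_true_pan": true_pan,
        "s_obs_mean": float(rich.s_obs.mean()),
        "s_boot_mean": rich.s_boot_mean,
        "s_boot_median": rich.s_boot_median,
        "s_boot_rel_err": abs(rich.s_boot_mean - true_pan) / max(true_pan, 1),
    }
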