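import numpy as np
import pandas as pd
import pytest

from ppiseq import SimConfig, simulate_experiment
from ppiseq.synthetic_data import ControlCounts


@pytest.fixture(scope="session")
def small_sim():
    """A small single-environment simulation shared across tests."""
    cfg = SimConfig(
        n_proteins=20,
        n_pairs=60,
        n_environments=1,
        depth_per_timepoint=2e5,
        control_counts=ControlCounts(dhfr_plus=5, dhfr_minus=40, orf_x_null=20, prs=10, rrs=10),
        seed=42,
    )
    counts, truth = simulate_experiment(cfg)
    return cfg, counts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def pair_grid_bruteforce(records: pd.DataFrame, pos, neg, f_grid, p_grid, objective="f1"):
    """Independent exhaustive enumeration oracle for threshold choice."""
    pos, neg = set(pos), set(neg)
    best = None
    for f_min in f_grid:
        for p_max in p_grid:
            called = (records["f"] >= f_min) & (records["p"] <= p_max)
            tp = int((called & records["pair_id"].isin(pos)).sum())
            fn = int((~called & records["pair_id"].isin(pos)).sum())
            fp = int((called & records["pair_id"].isin(neg)).sum())
            tn = int((~called & records["pair_id"].isin(neg)).sum())
            if objective == "f1":
                prec = tp / max(tp + fp, 1)
                rec = tp / max(tp + fn, 1)
                score = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            else:
                fpr = fp / max(fp + tn, 1)
                if fpr > float(objective[5:]):
                    continue
                score = tp / max(tp + fn, 1)
            key = (score, f_min, -p_max)
            if best is None or key > best[0]:
                best = (key, f_min, p_max)
    return best[1], best[2]
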