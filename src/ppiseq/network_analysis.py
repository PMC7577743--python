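"""Network-level analyses of the multi-environment PPI map.

* GO-term interaction density: called PPIs over assayed pairs for every
  unordered pair of GO terms, with significance from degree-preserving
  network randomisation (a Monte-Carlo permutation test whose statistic is
  the density itself) and variability (CV) across environments.
* Community detection (fast-greedy, walktrap, infomap via igraph).
* Binned bootstrap associations between protein mutability scores and
  external gene features, binned by PPI degree (hubs: degree > 15).
"""

from __future__ import annotations

import random as _random

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HUB_DEGREE",
    "interaction_density",
    "randomize_degree_preserving",
    "density_significance",
    "density_variability",
    "detect_communities",
    "binned_bootstrap_association",
]

HUB_DEGREE = 15  # degree above which a protein counts as a hub

COMMUNITY_METHODS = ("fast_greedy", "walktrap", "infomap")


def _term_pairs_for(pair: tuple[str, str], terms: dict[str, set[str]]):
    """Unordered GO term pairs spanned by one protein pair."""
    a, b = pair
    ta, tb = terms.get(a, set()), terms.get(b, set())
    out = set()
    for x in ta:
        for y in tb:
            out.add((x, y) if x <= y else (y, x))
    return out


def interaction_density(
    calls: set[tuple[str, str]] | list,
    go_annotations: pd.DataFrame,
    assayed_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Interaction density per unordered GO-term pair.

    ``go_annotations`` has columns ``gene, term`` (extra columns such as a
    domain column are ignored).  A protein pair spanning several term
    pairs contributes once to each.  Term pairs with no assayed pair are
    omitted.  Returns ``term_a, term_b, n_assayed, n_ppi, density``.
    """
    terms: dict[str, set[str]] = {}
    for gene, term in zip(go_annotations["gene"], go_annotations["term"]):
        terms.setdefault(gene, set()).add(term)
    call_set = {frozenset(p) for p in calls}
    n_assayed: dict[tuple[str, str], int] = {}
    n_ppi: dict[tuple[str, str], int] = {}
    for pair in assayed_pairs:
        tps = _term_pairs_for(tuple(pair), terms)
        hit = frozenset(pair) in call_set
        for tp in tps:
            n_assayed[tp] = n_assayed.get(tp, 0) + 1
            if hit:
                n_ppi[tp] = n_ppi.get(tp, 0) + 1
    rows = [
        (ta, tb, na, n_ppi.get((ta, tb), 0), n_ppi.get((ta, tb), 0) / na)
        for (ta, tb), na in sorted(n_assayed.items())
    ]
    return pd.DataFrame(rows, columns=["term_a", "term_b", "n_assayed", "n_ppi", "density"])


def randomize_degree_preserving(edges, protein_universe, rng) -> list[tuple[str, str]]:
    """Degree-preserving randomisation by injective node relabeling.

    Every protein appearing in the network is mapped to a distinct protein
    drawn without replacement from the screen's universe; edges follow the
    relabeling.  The degree multiset and edge count are exactly preserved
    and no duplicate edges can arise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nodes = sorted({p for e in edges for p in e})
    universe = sorted(set(protein_universe))
    if not set(nodes) <= set(universe):
        raise ValueError("universe must contain all network proteins")
    new_labels = rng.choice(len(universe), size=len(nodes), replace=False)
    mapping = {n: universe[i] for n, i in zip(nodes, new_labels)}
    return [(mapping[a], mapping[b]) for a, b in edges]


def density_significance(observed_density: float, randomized_densities) -> float:
    """One-sided Monte-Carlo permutation p-value:
    (1 + #{random >= observed}) / (n + 1)."""
    rand = np.asarray(randomized_densities, dtype=float)
    if len(rand) < 100:
        raise ValueError("need >= 100 randomizations")
    return float((1 + (rand >= observed_density).sum()) / (len(rand) + 1))


def density_variability(per_env_density: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """CV of interaction density across environments.

    ``per_env_density`` is indexed by (term_a, term_b) with one column per
    environment.  Returns the per-term-pair CV and, per term, the mean CV
    over the term pairs it participates in.
    """
    if per_env_density.shape[1] < 2:
        raise ValueError("need >= 2 environments")
    x = per_env_density.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, x.std(axis=1, ddof=1) / mean, np.nan)
    cv = pd.Series(cv, index=per_env_density.index, name="cv")
    per_term: dict[str, list[float]] = {}
    for (ta, tb), v in cv.items():
        if np.isnan(v):
            continue
        per_term.setdefault(ta, []).append(v)
        if tb != ta:
            per_term.setdefault(tb, []).append(v)
    mean_cv = pd.Series({t: float(np.mean(v)) for t, v in per_term.items()}, name="mean_cv")
    return cv, mean_cv


def detect_communities(edges, method: str = "infomap", seed: int = 0) -> tuple[pd.Series, pd.DataFrame]:
    """Partition the PPI network into communities.

    ``method`` is one of fast_greedy, walktrap, infomap.  Deterministic
    given method and seed.  Returns (labels: protein -> community id,
    summary: per-community size and within/between PPI counts).
    """
    edges = [tuple(e) for e in edges]
    if not edges:
        raise ValueError("empty network")
    nodes = sorted({p for e in edges for p in e})
    idx = {n: i for i, n in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes), edges=[(idx[a], idx[b]) for a, b in edges], directed=False
    )
    g.simplify()
    state = _random.getstate()
    try:
        _random.seed(seed)
        if method == "fast_greedy":
            part = g.community_fastgreedy().as_clustering()
        elif method == "walktrap":
            part = g.community_walktrap().as_clustering()
        elif method == "infomap":
            part = g.community_infomap()
        else:
            raise ValueError(f"unknown method: {method}")
    finally:
        _random.setstate(state)
    labels = pd.Series({n: part.membership[idx[n]] for n in nodes}, name="community")
    within = {c: 0 for c in set(part.membership)}
    between = dict(within)
    for a, b in edges:
        ca, cb = labels[a], labels[b]
        if ca == cb:
            within[ca] += 1
        else:
            between[ca] += 1
            between[cb] += 1
    summary = pd.DataFrame(
        {
            "n_proteins": labels.value_counts().sort_index(),
            "ppis_within": pd.Series(within),
            "ppis_between": pd.Series(between),
        }
    )
    return labels, summary


def binned_bootstrap_association(
    protein_scores: pd.Series,
    feature: pd.Series,
    degrees: pd.Series,
    degree_bins=((1, HUB_DEGREE), (HUB_DEGREE + 1, np.inf)),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation between mutability scores and a gene feature,
    within PPI-degree bins, with a bootstrap standard deviation.

    Proteins are resampled with replacement ``n_boot`` times before
    binning.  ``feature`` may be numeric or binary (e.g. the
    share-a-compartment colocalization indicator).
    """
    rng = np.random.default_rng(seed)
    common = protein_scores.index.intersection(feature.dropna().index).intersection(degrees.index)
    s = protein_scores.loc[common].to_numpy(dtype=float)
    f = feature.loc[common].to_numpy(dtype=float)
    d = degrees.loc[common].to_numpy(dtype=float)
    rows = []
    for lo, hi in degree_bins:
        mask = (d >= lo) & (d <= hi)
        n = int(mask.sum())
        if n < 3:
            rows.append((lo, hi, n, np.nan, np.nan))
            continue
        rho = float(stats.spearmanr(s[mask], f[mask]).statistic)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            take = rng.integers(0, len(s), size=len(s))
            m = (d[take] >= lo) & (d[take] <= hi)
            if m.sum() < 3 or np.std(s[take][m]) == 0 or np.std(f[take][m]) == 0:
                boots[b] = np.nan
                continue
            boots[b] = stats.spearmanr(s[take][m], f[take][m]).statistic
        rows.append((lo, hi, n, rho, float(np.nanstd(boots))))
    return pd.DataFrame(
        rows, columns=["degree_lo", "degree_hi", "n_proteins", "spearman", "bootstrap_sd"]
    )
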