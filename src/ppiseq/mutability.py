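"""Cross-environment fitness normalisation and mutability scores.

Because the strength of methotrexate selection differs between
environments, raw fitnesses are first rescaled per environment to the span
between the DHFR(-) (no reporter; 0) and DHFR(+) (full-length reporter; 1)
control means.  Replicate barcodes are averaged per tag orientation, the
two orientations averaged when both exist, and negative pair means clamped
to zero.  A PPI's mutability is the coefficient of variation (sample sd /
mean) of its normalised fitness across all environments; a protein's
mutability score is the mean CV of the PPIs it participates in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutabilityScore",
    "normalize_fitness",
    "pair_environment_fitness",
    "ppi_cv",
    "protein_mutability",
    "mutability_table",
]


@dataclass(frozen=True)
class MutabilityScore:
    protein_id: str
    score: float
    degree: int
    neighbor_score: float = float("nan")


def normalize_fitness(f_barcode, f_dhfr_minus_mean: float, f_dhfr_plus_mean: float):
    """Rescale fitness to the DHFR control span:
    (f - mean_DHFR(-)) / (mean_DHFR(+) - mean_DHFR(-)).  Not clamped."""
    if f_dhfr_plus_mean <= f_dhfr_minus_mean:
        raise ValueError("DHFR(+) mean must exceed DHFR(-) mean")
    return (np.asarray(f_barcode, dtype=float) - f_dhfr_minus_mean) / (
        f_dhfr_plus_mean - f_dhfr_minus_mean
    )


def pair_environment_fitness(replicates_by_orientation: dict[str, np.ndarray]) -> float:
    """Mean normalised fitness of one pair in one environment.

    Replicates are averaged within each tag orientation, the orientation
    means averaged, and a negative result clamped to 0 (measurement error
    of a non-interacting pair).
    """
    means = [float(np.mean(np.asarray(v, dtype=float))) for v in replicates_by_orientation.values() if len(v)]
    if not means:
        raise ValueError("no replicate fitness values supplied")
    return max(float(np.mean(means)), 0.0)


def ppi_cv(fitness_vector) -> float:
    """Coefficient of variation of a pair's fitness across environments:
    sample (n-1) standard deviation over the mean, zeros included."""
    x = np.asarray(fitness_vector, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError("CV undefined for a non-positive mean fitness vector")
    return float(x.std(ddof=1) / m)


def protein_mutability(
    protein: str,
    ppi_cvs: dict[frozenset, float] | dict[tuple, float],
    exclude_edge: tuple[str, str] | None = None,
) -> float:
    """Mean CV over the PPIs the protein participates in.

    ``ppi_cvs`` maps protein pairs (frozenset or tuple) to their CV.  With
    ``exclude_edge`` the shared edge is removed first (used for neighbour
    scores); NaN when no PPI remains.
    """
    excl = frozenset(exclude_edge) if exclude_edge is not None else None
    vals = [
        cv
        for pair, cv in ppi_cvs.items()
        if protein in frozenset(pair) and frozenset(pair) != excl
    ]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def mutability_table(ppi_cvs: dict) -> pd.DataFrame:
    """Per-protein mutability scores, degrees, and neighbour scores.

    The neighbour score of a protein is the mean, over its network
    neighbours, of the neighbour's mutability computed with the shared
    edge removed; neighbours whose only PPI is the shared edge are
    excluded (logged).
    """
    edges = {frozenset(p): cv for p, cv in ppi_cvs.items()}
    proteins = sorted({q for pair in edges for q in pair})
    neighbors: dict[str, set[str]] = {p: set() for p in proteins}
    for pair in edges:
        ps = tuple(pair)
        if len(ps) == 1:  # homodimer: self-loop, contributes to score only
            continue
        a, b = ps
        neighbors[a].add(b)
        neighbors[b].add(a)
    rows = []
    n_degenerate = 0
    for p in proteins:
        score = protein_mutability(p, edges)
        nb_scores = []
        for q in neighbors[p]:
            nb = protein_mutability(q, edges, exclude_edge=(p, q))
            if np.isnan(nb):
                n_degenerate += 1
                continue
            nb_scores.append(nb)
        rows.append(
            MutabilityScore(
                protein_id=p,
                score=score,
                degree=len([e for e in edges if p in e]),
                neighbor_score=float(np.mean(nb_scores)) if nb_scores else float("nan"),
            )
        )
    if n_degenerate:
        logger.info("excluded %d neighbour scores with only the shared edge", n_degenerate)
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("protein_id")
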