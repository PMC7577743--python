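"""Synthetic pooled double-barcode competition experiments.

Generates serial-batch competition data with the statistical structure the
downstream pipeline assumes: replicate double-barcode lineages per protein
pair, spiked control strains (DHFR(+), DHFR(-), ORF x Null, PRS, RRS),
overdispersed count noise, and PCR chimeras.  Ground truth (per-lineage
fitness, the PPI-by-environment truth matrix, and pair class labels) is
returned alongside the counts so every downstream stage can be tested
without external data.

The growth model is deterministic exponential selection: a lineage with
per-generation log-fitness ``s`` changes frequency as
``x * exp(s*t)`` renormalised over the pool.  Bottlenecks are not simulated
explicitly; their stochastic contribution is folded into the count
dispersion ``kappa`` (variance = kappa * mean).
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ControlCounts",
    "SimConfig",
    "SimTruth",
    "propagate_frequencies",
    "sample_counts",
    "inject_chimeras",
    "simulate_experiment",
    "random_barcode",
    "generate_barcode_set",
    "write_count_table",
    "write_truth",
    "write_config",
    "write_fastq",
]

#: classes a simulated protein pair may belong to
PAIR_CLASSES = (
    "immutable",
    "mutable",
    "negative",
    "dhfr_plus",
    "dhfr_minus",
    "orf_x_null",
    "prs",
    "rrs",
)


@dataclass(frozen=True)
class ControlCounts:
    """Numbers of spiked control strains of each role."""

    dhfr_plus: int = 10
    dhfr_minus: int = 100
    orf_x_null: int = 100
    prs: int = 30
    rrs: int = 30


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated multi-environment competition.

    Defaults describe a desk-scale pool: tens of proteins, a few hundred
    assayed pairs, five timepoints spanning twelve generations with a
    sequencing depth of one million reads per timepoint.  ``kappa`` is the
    variance/mean ratio of the count noise (>=1; 1 reduces to Poisson) and
    stands in for the combined noise of growth bottlenecks, PCR, and
    sequencing.  ``chimera_rate`` is the expected number of chimeric reads
    per unit of the product of the two constituent single-barcode totals.
    """

    n_proteins: int = 40
    n_pairs: int = 200
    n_environments: int = 9
    replicates_per_pair: int = 4
    control_replicates: int = 2
    timepoint_generations: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0)
    depth_per_timepoint: float = 1e6
    kappa: float = 2.5
    chimera_rate: float = 0.0
    fraction_immutable: float = 0.05
    fraction_mutable: float = 0.15
    homodimer_fraction: float = 0.1
    fitness_positive_range: tuple[float, float] = (0.2, 0.8)
    fitness_env_jitter_sd: float = 0.02
    negative_fitness_sd: float = 0.01
    dhfr_plus_fitness: float = 0.8
    negative_baseline: float = 0.0
    initial_freq_lognormal_sd: float = 0.3
    control_counts: ControlCounts = field(default_factory=ControlCounts)
    seed: int = 0

    def __post_init__(self) -> None:
        gens = tuple(float(g) for g in self.timepoint_generations)
        if len(gens) < 2 or gens[0] != 0.0:
            raise ValueError("timepoint_generations must start at 0 with >=2 points")
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("timepoint_generations must be strictly increasing")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        for name in ("fraction_immutable", "fraction_mutable", "homodimer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fraction_immutable + self.fraction_mutable > 1.0:
            raise ValueError("class fractions must sum to <= 1")
        if self.depth_per_timepoint <= 0:
            raise ValueError("depth_per_timepoint must be positive")

    @property
    def environments(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_environments)]


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    Attributes
    ----------
    lineages
        One row per double-barcode lineage: ``lineage_id, barcode1_id,
        barcode2_id, pair_id, protein1, protein2, pair_class``.
    fitness
        Per-lineage true per-generation fitness, lineages x environments.
    truth_matrix
        Boolean pair x environment matrix of true PPIs (control and
        negative pairs are all-False rows).
    pair_class
        Series mapping pair_id -> class label.
    """

    lineages: pd.DataFrame
    fitness: pd.DataFrame
    truth_matrix: pd.DataFrame
    pair_class: pd.Series


# ---------------------------------------------------------------------------
# core stochastic primitives
# ---------------------------------------------------------------------------

def propagate_frequencies(freqs, fitnesses, t: float):
    """Deterministic selection of lineage frequencies over ``t`` generations.

    Returns ``x_i * exp(s_i * t) / sum_j x_j * exp(s_j * t)``.
    """
    x = np.asarray(freqs, dtype=float)
    s = np.asarray(fitnesses, dtype=float)
    if x.shape != s.shape:
        raise ValueError("freqs and fitnesses must have the same shape")
    if t < 0:
        raise ValueError("t must be >= 0")
    if np.any(x < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1 within 1e-9")
    # subtract max(s)*t before exponentiating for numerical stability
    w = x * np.exp((s - s.max()) * t)
    return w / w.sum()


def sample_counts(freqs, depth: float, kappa: float, rng) -> np.ndarray:
    """Draw overdispersed counts with E[c_i] = depth*x_i, Var ~= kappa*E.

    Negative binomial with variance ``kappa * mean``; ``kappa == 1``
    degenerates to Poisson sampling.  ``rng`` is a seeded
    :class:`numpy.random.Generator` or an integer seed.
    """
    x = np.asarray(freqs, dtype=float)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = depth * x
    out = np.zeros_like(m, dtype=np.int64)
    pos = m > 0
    if kappa == 1.0:
        out[pos] = rng.poisson(m[pos])
    else:
        # NB(n, p): mean = n(1-p)/p, var = mean/p  =>  p = 1/kappa
        p = 1.0 / kappa
        n = m[pos] * p / (1.0 - p)
        out[pos] = rng.negative_binomial(n, p)
    return out


def inject_chimeras(count_table: pd.DataFrame, chimera_rate: float, rng) -> pd.DataFrame:
    """Add PCR-chimera reads to a one-sample double-barcode count table.

    The expected number of chimeric reads for a pair (b1, b2) is
    ``chimera_rate * T1 * T2`` where T1/T2 are the pool-wide totals of each
    constituent single barcode.  Chimeras are drawn as a Poisson total,
    partitioned by sampling each constituent independently in proportion to
    its total — which realises exactly that per-pair expectation and can
    create novel double barcodes.  Original counts are never reduced.
    """
    if chimera_rate < 0:
        raise ValueError("chimera_rate must be >= 0")
    if (count_table["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if chimera_rate == 0:
        return count_table.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    t1 = count_table.groupby("barcode1_id")["count"].sum()
    t2 = count_table.groupby("barcode2_id")["count"].sum()
    total = chimera_rate * float(t1.sum()) * float(t2.sum())
    n_chim = rng.poisson(total)
    out = count_table.copy()
    if n_chim == 0:
        return out
    b1 = rng.choice(t1.index.to_numpy(), size=n_chim, p=t1.to_numpy() / t1.sum())
    b2 = rng.choice(t2.index.to_numpy(), size=n_chim, p=t2.to_numpy() / t2.sum())
    chim = (
        pd.DataFrame({"barcode1_id": b1, "barcode2_id": b2})
        .value_counts()
        .rename("count")
        .reset_index()
    )
    meta_cols = [c for c in out.columns if c not in ("barcode1_id", "barcode2_id", "count")]
    for c in meta_cols:
        chim[c] = out[c].iloc[0]
    merged = (
        pd.concat([out, chim[out.columns]], ignore_index=True)
        .groupby(["barcode1_id", "barcode2_id"] + meta_cols, as_index=False)["count"]
        .sum()
    )
    return merged[out.columns.tolist()]


# ---------------------------------------------------------------------------
# truth-network construction
# ---------------------------------------------------------------------------

def _draw_pairs(cfg: SimConfig, rng) -> list[tuple[str, str]]:
    proteins = [f"P{i + 1:03d}" for i in range(cfg.n_proteins)]
    n_homo = int(round(cfg.homodimer_fraction * cfg.n_pairs))
    n_homo = min(n_homo, cfg.n_proteins)
    homo_prots = rng.choice(cfg.n_proteins, size=n_homo, replace=False)
    pairs = [(proteins[i], proteins[i]) for i in sorted(homo_prots)]
    n_hetero = cfg.n_pairs - len(pairs)
    max_hetero = cfg.n_proteins * (cfg.n_proteins - 1) // 2
    if n_hetero > max_hetero:
        raise ValueError("n_pairs too large for n_proteins")
    seen: set[tuple[int, int]] = set()
    while len(seen) < n_hetero:
        i, j = rng.integers(0, cfg.n_proteins, size=2)
        if i == j:
            continue
        seen.add((min(i, j), max(i, j)))
    pairs.extend((proteins[i], proteins[j]) for i, j in sorted(seen))
    return pairs


def _assign_truth(cfg: SimConfig, pairs: list[tuple[str, str]], rng):
    """Assign each assayed pair a class and a per-environment true fitness."""
    envs = cfg.environments
    n = len(pairs)
    n_imm = int(round(cfg.fraction_immutable * n))
    n_mut = int(round(cfg.fraction_mutable * n))
    order = rng.permutation(n)
    classes = np.array(["negative"] * n, dtype=object)
    classes[order[:n_imm]] = "immutable"
    classes[order[n_imm : n_imm + n_mut]] = "mutable"

    lo, hi = cfg.fitness_positive_range
    strength = rng.uniform(lo, hi, size=n)
    active = np.zeros((n, len(envs)), dtype=bool)
    for k in range(n):
        if classes[k] == "immutable":
            n_active = int(rng.integers(max(1, len(envs) - 1), len(envs) + 1))
        elif classes[k] == "mutable":
            n_active = int(rng.integers(1, min(3, len(envs)) + 1))
        else:
            continue
        idx = rng.choice(len(envs), size=min(n_active, len(envs)), replace=False)
        active[k, idx] = True

    s_true = rng.normal(cfg.negative_baseline, cfg.negative_fitness_sd, size=(n, len(envs)))
    jitter = rng.normal(0.0, cfg.fitness_env_jitter_sd, size=(n, len(envs)))
    s_true[active] = (strength[:, None] + jitter)[active]
    return classes, active, s_true


def simulate_experiment(config: SimConfig):
    """Simulate pooled competitions in every environment.

    Returns
    -------
    counts : pandas.DataFrame
        Long table ``barcode1_id, barcode2_id, environment, timepoint,
        generation, count`` covering every timepoint of every environment.
    truth : SimTruth
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cc = cfg.control_counts
    n_controls = cc.dhfr_plus + cc.dhfr_minus + cc.orf_x_null + cc.prs + cc.rrs
    envs = cfg.environments

    pairs = _draw_pairs(cfg, rng)
    classes, active, s_assay = _assign_truth(cfg, pairs, rng)
    if not active.any() and n_controls == 0:
        raise ValueError("simulation needs at least one positive pair or control strain")

    # --- assemble the pair table: assayed pairs then controls -------------
    rows = []  # (pair_id, protein1, protein2, class, n_replicates)
    for (a, b), cls in zip(pairs, classes):
        rows.append((f"{a}:{b}", a, b, cls, cfg.replicates_per_pair))
    proteins = sorted({p for ab in pairs for p in ab})
    # control strains carry their own barcodes (distinct per strain)
    for i in range(cc.dhfr_plus):
        rows.append((f"DHFRplus_{i + 1}", f"DHFRplus_{i + 1}", f"DHFRplus_{i + 1}", "dhfr_plus", cfg.control_replicates))
    for i in range(cc.dhfr_minus):
        rows.append((f"DHFRminus_{i + 1}", f"DHFRminus_{i + 1}", f"DHFRminus_{i + 1}", "dhfr_minus", cfg.control_replicates))
    null_prots = [proteins[i] for i in rng.choice(len(proteins), size=min(cc.orf_x_null, len(proteins)), replace=False)]
    for p in sorted(null_prots):
        # "NULLFRAG" marks the untethered DHFR-fragment partner (avoids
        # pandas' NA token list, which includes the bare string NULL)
        rows.append((f"{p}:NULLFRAG", p, "NULLFRAG", "orf_x_null", cfg.control_replicates))
    for i in range(cc.prs):
        rows.append((f"PRS_{i + 1}", f"PRSa{i + 1}", f"PRSb{i + 1}", "prs", cfg.replicates_per_pair))
    for i in range(cc.rrs):
        rows.append((f"RRS_{i + 1}", f"RRSa{i + 1}", f"RRSb{i + 1}", "rrs", cfg.replicates_per_pair))

    pair_df = pd.DataFrame(rows, columns=["pair_id", "protein1", "protein2", "pair_class", "n_rep"])

    # --- per-pair per-environment true fitness ----------------------------
    lo, hi = cfg.fitness_positive_range
    n_total = len(pair_df)
    s_pair = np.zeros((n_total, len(envs)))
    act_pair = np.zeros((n_total, len(envs)), dtype=bool)
    n_assay = len(pairs)
    s_pair[:n_assay] = s_assay
    act_pair[:n_assay] = active
    for k in range(n_assay, n_total):
        cls = pair_df["pair_class"].iloc[k]
        if cls == "dhfr_plus":
            s_pair[k] = cfg.dhfr_plus_fitness + rng.normal(0, cfg.fitness_env_jitter_sd, len(envs))
        elif cls == "prs":
            st = rng.uniform(lo, hi)
            s_pair[k] = st + rng.normal(0, cfg.fitness_env_jitter_sd, len(envs))
            act_pair[k] = True
        elif cls == "dhfr_minus":
            s_pair[k] = cfg.negative_baseline
        else:  # orf_x_null, rrs
            s_pair[k] = rng.normal(cfg.negative_baseline, cfg.negative_fitness_sd, len(envs))

    # --- expand to lineages (replicate double barcodes) -------------------
    lin_rows = []
    for k, row in enumerate(pair_df.itertuples(index=False)):
        for r in range(row.n_rep):
            lin_rows.append(
                (
                    f"{row.pair_id}~r{r + 1}",
                    f"{row.protein1}_b{r + 1}",
                    f"{row.protein2}_b{r + 1}",
                    row.pair_id,
                    row.protein1,
                    row.protein2,
                    row.pair_class,
                    k,
                )
            )
    lineages = pd.DataFrame(
        lin_rows,
        columns=[
            "lineage_id",
            "barcode1_id",
            "barcode2_id",
            "pair_id",
            "protein1",
            "protein2",
            "pair_class",
            "_pair_index",
        ],
    )
    s_lin = s_pair[lineages["_pair_index"].to_numpy()]
    fitness = pd.DataFrame(s_lin, index=lineages["lineage_id"], columns=envs)

    truth_matrix = pd.DataFrame(act_pair, index=pair_df["pair_id"], columns=envs)

    # --- simulate counts ---------------------------------------------------
    gens = np.asarray(cfg.timepoint_generations, dtype=float)
    blocks = []
    for e_idx, env in enumerate(envs):
        s = s_lin[:, e_idx]
        x0 = rng.lognormal(0.0, cfg.initial_freq_lognormal_sd, size=len(s))
        x0 /= x0.sum()
        for tp, g in enumerate(gens):
            x = propagate_frequencies(x0, s, g)
            counts = sample_counts(x, cfg.depth_per_timepoint, cfg.kappa, rng)
            block = pd.DataFrame(
                {
                    "barcode1_id": lineages["barcode1_id"].to_numpy(),
                    "barcode2_id": lineages["barcode2_id"].to_numpy(),
                    "environment": env,
                    "timepoint": tp,
                    "generation": g,
                    "count": counts,
                }
            )
            if cfg.chimera_rate > 0:
                block = inject_chimeras(block, cfg.chimera_rate, rng)
            blocks.append(block)
    counts = pd.concat(blocks, ignore_index=True)

    truth = SimTruth(
        lineages=lineages.drop(columns="_pair_index"),
        fitness=fitness,
        truth_matrix=truth_matrix,
        pair_class=pair_df.set_index("pair_id")["pair_class"],
    )
    return counts, truth


# ---------------------------------------------------------------------------
# synthetic sequences / FASTQ emission
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def random_barcode(rng, which: int = 1) -> str:
    """One 30-nt synthetic barcode matching the structural pattern for
    barcode ``which`` (1 or 2): fixed anchors separated by 4-nt random gaps.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mid = "AA" if which == 2 else "TT"
    tail = "TTAC" if which == 2 else "ATAA"
    return (
        "TACC" + _rand_seq(rng, 4) + "AA" + _rand_seq(rng, 4) + mid
        + _rand_seq(rng, 4) + "TT" + _rand_seq(rng, 4) + tail
    )


def generate_barcode_set(n: int, rng, which: int = 1, min_distance: int = 3) -> list[str]:
    """``n`` structurally valid barcodes with pairwise edit distance >=
    ``min_distance`` (rejection sampling; intended for small test pools)."""
    import edlib

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out: list[str] = []
    while len(out) < n:
        cand = random_barcode(rng, which)
        ok = all(
            edlib.align(cand, b, k=min_distance - 1)["editDistance"] == -1 for b in out
        )
        if ok:
            out.append(cand)
    return out


def write_fastq(
    count_table: pd.DataFrame,
    barcode_seqs: dict[str, str],
    path1,
    path2,
    rng,
    multiplex_tag: str = "ACGTC",
    umi_len: int = 8,
):
    """Emit synthetic paired FASTQ reads for one sample.

    Read layout (both mates): ``UMI(umi_len) + multiplex_tag + barcode``.
    One read pair per count, each with fresh random UMIs; quality is Q40
    throughout.  Exercises the barcode-processing stage end to end.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    buf1, buf2 = _io.StringIO(), _io.StringIO()
    i = 0
    for row in count_table.itertuples(index=False):
        seq_b1 = barcode_seqs[row.barcode1_id]
        seq_b2 = barcode_seqs[row.barcode2_id]
        for _ in range(int(row.count)):
            umi1, umi2 = _rand_seq(rng, umi_len), _rand_seq(rng, umi_len)
            r1 = umi1 + multiplex_tag + seq_b1
            r2 = umi2 + multiplex_tag + seq_b2
            q1, q2 = "I" * len(r1), "I" * len(r2)
            buf1.write(f"@read{i}/1\n{r1}\n+\n{q1}\n")
            buf2.write(f"@read{i}/2\n{r2}\n+\n{q2}\n")
            i += 1
    with open(path1, "w") as fh:
        fh.write(buf1.getvalue())
    with open(path2, "w") as fh:
        fh.write(buf2.getvalue())


# ---------------------------------------------------------------------------
# table output
# ---------------------------------------------------------------------------

def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_truth(truth: SimTruth, lineage_path, matrix_path) -> None:
    truth.lineages.merge(
        truth.fitness.reset_index().melt(
            id_vars="lineage_id", var_name="environment", value_name="s_true"
        ),
        on="lineage_id",
    ).to_csv(lineage_path, sep="\t", index=False)
    truth.truth_matrix.reset_index().to_csv(matrix_path, sep="\t", index=False)


def write_config(cfg: SimConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["timepoint_generations"] = list(d["timepoint_generations"])
    d["fitness_positive_range"] = list(d["fitness_positive_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
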