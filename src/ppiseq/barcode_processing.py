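"""Paired barcode reads -> chimera-corrected double-barcode UMI counts.

Three stages, each exposed as one function:

* :func:`assign_read` — quality and structural filters, then Levenshtein
  matching of each barcode region against the known barcode list.
* :func:`count_umis` — collapse assigned reads to molecule counts by the
  number of distinct (UMI1, UMI2) combinations per double barcode.
* :func:`correct_chimeras` — per-sample linear fit of counts against the
  product of constituent single-barcode totals; the fitted chimeric
  expectation is subtracted and counts are clamped at zero.

Known barcodes are supplied by design (the pool layout is known), so
matching is direct: a read barcode is assigned to a known barcode at edit
distance <= 1, and left unassigned when the match is ambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "BARCODE1_PATTERN",
    "BARCODE2_PATTERN",
    "BarcodeRead",
    "ReadAssignment",
    "assign_read",
    "count_umis",
    "correct_chimeras",
    "parse_paired_fastq",
    "process_fastq",
]

# default structural patterns for the two barcode regions
BARCODE1_PATTERN = r"\D*?(.ACC|T.CC|TA.C|TAC.)\D{4,7}?AA\D{4,7}?TT\D{4,7}?TT\D{4,7}?(.TAA|A.AA|AT.A|ATA.)\D*"
BARCODE2_PATTERN = r"\D*?(.ACC|T.CC|TA.C|TAC.)\D{4,7}?AA\D{4,7}?AA\D{4,7}?TT\D{4,7}?(.TAC|T.AC|TT.C|TTA.)\D*"


@dataclass(frozen=True)
class BarcodeRead:
    """One paired read after layout parsing: barcode regions, their
    qualities (Phred scores), UMIs, and the multiplex tag."""

    seq1: str
    seq2: str
    qual1: tuple[int, ...]
    qual2: tuple[int, ...]
    umi1: str
    umi2: str
    multiplex_tag: str = ""


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of :func:`assign_read`; ``reason`` is ``"assigned"`` or the
    first filter that rejected the read."""

    barcode1_id: str | None
    barcode2_id: str | None
    reason: str

    @property
    def assigned(self) -> bool:
        return self.reason == "assigned"


def _match_known(seq: str, known: dict[str, str], max_dist: int = 1) -> str | None:
    """Unique known barcode within ``max_dist`` edits of ``seq``, else None.

    Ambiguous reads (two known barcodes at the same minimal distance) are
    never guessed.
    """
    best_id, best_d, tie = None, max_dist + 1, False
    for bc_id, bc_seq in known.items():
        d = edlib.align(seq, bc_seq, k=max_dist)["editDistance"]
        if d == -1:
            continue
        if d < best_d:
            best_id, best_d, tie = bc_id, d, False
        elif d == best_d:
            tie = True
    if best_id is None or tie:
        return None
    return best_id


def assign_read(
    read: BarcodeRead,
    known_barcodes1: dict[str, str],
    known_barcodes2: dict[str, str],
    min_quality: float = 30.0,
    structure_patterns: tuple[str, str] = (BARCODE1_PATTERN, BARCODE2_PATTERN),
) -> ReadAssignment:
    """Filter and resolve one read to a (barcode1_id, barcode2_id) pair.

    Filters, applied in order: mean Phred quality of each barcode region
    must exceed ``min_quality``; each region must match its structural
    regex; each barcode must match a unique known barcode at Levenshtein
    distance < 2.
    """
    if not known_barcodes1 or not known_barcodes2:
        raise ValueError("known barcode maps must be non-empty")
    if np.mean(read.qual1) <= min_quality or np.mean(read.qual2) <= min_quality:
        return ReadAssignment(None, None, "low_quality")
    pat1, pat2 = structure_patterns
    if not re.fullmatch(pat1, read.seq1):
        return ReadAssignment(None, None, "structure_barcode1")
    if not re.fullmatch(pat2, read.seq2):
        return ReadAssignment(None, None, "structure_barcode2")
    b1 = _match_known(read.seq1, known_barcodes1)
    if b1 is None:
        return ReadAssignment(None, None, "no_match_barcode1")
    b2 = _match_known(read.seq2, known_barcodes2)
    if b2 is None:
        return ReadAssignment(None, None, "no_match_barcode2")
    return ReadAssignment(b1, b2, "assigned")


def count_umis(assignments: Iterable[tuple[str, str, str, str]]) -> pd.DataFrame:
    """Collapse assigned reads of one sample into UMI counts.

    ``assignments`` yields ``(barcode1_id, barcode2_id, umi1, umi2)``.
    Returns one row per observed double barcode with ``umi_count`` (distinct
    UMI combinations) and ``raw_read_count``.
    """
    df = pd.DataFrame(
        list(assignments), columns=["barcode1_id", "barcode2_id", "umi1", "umi2"]
    )
    if df.empty:
        return pd.DataFrame(
            columns=["barcode1_id", "barcode2_id", "umi_count", "raw_read_count"]
        )
    keys = ["barcode1_id", "barcode2_id"]
    raw = df.groupby(keys).size().rename("raw_read_count")
    umi = df.drop_duplicates().groupby(keys).size().rename("umi_count")
    return (
        pd.concat([umi, raw], axis=1)
        .reset_index()[keys + ["umi_count", "raw_read_count"]]
    )


def correct_chimeras(
    count_table: pd.DataFrame,
    designed_pairs: set[tuple[str, str]],
    count_col: str = "umi_count",
) -> pd.DataFrame:
    """Subtract the expected PCR-chimera contribution from one sample.

    Chimeric reads arise in proportion to the product ``T1*T2`` of the
    pool-wide totals of the two constituent barcodes.  The proportionality
    is re-fit for every sample by ordinary least squares over the barcode
    pairs known to exist in the designed pool (whose true counts are
    uncorrelated with ``T1*T2``); the fitted ``slope * T1 * T2`` is then
    subtracted from every pair and the result clamped at zero.  A negative
    fitted slope is treated as zero (no correction), so counts never
    increase.
    """
    df = count_table.copy()
    t1 = df.groupby("barcode1_id")[count_col].sum()
    t2 = df.groupby("barcode2_id")[count_col].sum()
    df["_t1t2"] = t1.reindex(df["barcode1_id"]).to_numpy() * t2.reindex(
        df["barcode2_id"]
    ).to_numpy()
    designed = df.apply(
        lambda r: (r["barcode1_id"], r["barcode2_id"]) in designed_pairs, axis=1
    )
    if int(designed.sum()) < 10:
        raise ValueError("need >= 10 designed pairs for a reliable chimera fit")
    x = df.loc[designed, "_t1t2"].to_numpy(dtype=float)
    y = df.loc[designed, count_col].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    slope = max(float(slope), 0.0)
    corrected = np.maximum(df[count_col].to_numpy(dtype=float) - slope * df["_t1t2"], 0.0)
    df["corrected_count"] = corrected
    df.attrs["chimera_slope"] = slope
    df.attrs["chimera_intercept"] = float(intercept)
    return df.drop(columns="_t1t2")


# ---------------------------------------------------------------------------
# FASTQ plumbing
# ---------------------------------------------------------------------------

def parse_paired_fastq(
    path1, path2, umi_len: int = 8, tag_len: int = 5
) -> Iterator[BarcodeRead]:
    """Stream paired 4-line FASTQ records (Phred+33) into BarcodeReads.

    Read layout: ``UMI + multiplex_tag + barcode_region`` on both mates.
    """
    with open(path1) as f1, open(path2) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip()
            f1.readline()
            q1 = f1.readline().strip()
            f2.readline()
            s2 = f2.readline().strip()
            f2.readline()
            q2 = f2.readline().strip()
            off = umi_len + tag_len
            yield BarcodeRead(
                seq1=s1[off:],
                seq2=s2[off:],
                qual1=tuple(ord(c) - 33 for c in q1[off:]),
                qual2=tuple(ord(c) - 33 for c in q2[off:]),
                umi1=s1[:umi_len],
                umi2=s2[:umi_len],
                multiplex_tag=s1[umi_len:off],
            )


def process_fastq(
    path1,
    path2,
    known_barcodes1: dict[str, str],
    known_barcodes2: dict[str, str],
    min_quality: float = 30.0,
    umi_len: int = 8,
    tag_len: int = 5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full stage: parse, filter/assign, and UMI-count one sample.

    Returns the count table and a tally of assignment outcomes by reason.
    """
    tallies: dict[str, int] = {}
    assigned = []
    for read in parse_paired_fastq(path1, path2, umi_len=umi_len, tag_len=tag_len):
        res = assign_read(read, known_barcodes1, known_barcodes2, min_quality=min_quality)
        tallies[res.reason] = tallies.get(res.reason, 0) + 1
        if res.assigned:
            assigned.append((res.barcode1_id, res.barcode2_id, read.umi1, read.umi2))
    return count_umis(assigned), tallies
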