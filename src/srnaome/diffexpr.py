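"""Tags-per-million normalisation and threshold-based regulation calls.

Normalised expression is ``count / total clean reads x 10^6`` with the
library's total *clean* reads as denominator (not total miRNA reads —
both conventions exist in the field; this one is the study convention
this pipeline follows).  The contrast statistic is
``log2(tpm_D / tpm_G)`` with cutoffs +1/-1 for up/down calls.  Zero
counts are never pseudo-counted: a sequence detected in a single library
is called exclusively expressed there when it has at least
``exclusive_min`` (default 3) reads, and ``below_detection`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LibraryStats",
    "RegulationThresholds",
    "tpm",
    "log2_ratio",
    "call_regulation",
    "expression_table",
]

#: The regulation call vocabulary.
CALLS = (
    "dormant_up",
    "germinated_up",
    "unchanged",
    "dormant_only",
    "germinated_only",
    "below_detection",
)


@dataclass(frozen=True)
class LibraryStats:
    library: str
    total_clean_reads: int

    def __post_init__(self) -> None:
        if self.total_clean_reads <= 0:
            raise ValueError("total_clean_reads must be positive")


@dataclass(frozen=True)
class RegulationThresholds:
    up: float = 1.0
    down: float = -1.0
    exclusive_min: int = 3


def tpm(count: int | float, total: int | float) -> float:
    """Tags per million: ``count / total * 1e6``; *total* must be positive."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total * 1_000_000.0


def log2_ratio(tpm_d: float, tpm_g: float) -> float:
    """``log2(tpm_D / tpm_G)``; undefined (ValueError) unless both positive.

    Callers route zero-expression cases to the exclusive-detection logic
    instead of imputing pseudo-counts.
    """
    if tpm_d <= 0 or tpm_g <= 0:
        raise ValueError("log2 ratio requires both tpm values > 0")
    return math.log2(tpm_d / tpm_g)


def call_regulation(
    count_d: int,
    count_g: int,
    total_d: int,
    total_g: int,
    thresholds: RegulationThresholds | None = None,
) -> str:
    """Regulation call for one sequence across the two libraries."""
    th = thresholds or RegulationThresholds()
    if count_d > 0 and count_g > 0:
        ratio = log2_ratio(tpm(count_d, total_d), tpm(count_g, total_g))
        if ratio > th.up:
            return "dormant_up"
        if ratio < th.down:
            return "germinated_up"
        return "unchanged"
    if count_d > 0:
        return "dormant_only" if count_d >= th.exclusive_min else "below_detection"
    if count_g > 0:
        return "germinated_only" if count_g >= th.exclusive_min else "below_detection"
    return "below_detection"


def expression_table(
    records: pd.DataFrame | Iterable[Mapping],
    stats_d: LibraryStats,
    stats_g: LibraryStats,
    thresholds: RegulationThresholds | None = None,
    include_star: bool = False,
) -> pd.DataFrame:
    """Build the differential-expression table for mature sequences.

    *records* needs columns ``name`` (optional), ``sequence`` (optional;
    at least one of the two), ``count_D`` and ``count_G``.  Star rows
    (name ending in ``*``) are excluded unless *include_star* is set —
    regulation analysis concerns mature sequences.  Rows with defined
    ratios come first, sorted by descending ``log2_ratio`` (ties by
    name); exclusive/below-detection rows follow, sorted by name.
    """
    th = thresholds or RegulationThresholds()
    df = pd.DataFrame(records).copy()
    if df.empty:
        return pd.DataFrame(
            columns=[
                "name",
                "sequence",
                "count_D",
                "count_G",
                "tpm_D",
                "tpm_G",
                "log2_ratio",
                "call",
            ]
        )
    if "name" not in df.columns:
        df["name"] = df["sequence"]
    if "sequence" not in df.columns:
        df["sequence"] = ""
    if not include_star:
        df = df[~df["name"].astype(str).str.endswith("*")].copy()
    df["tpm_D"] = df["count_D"].map(lambda c: tpm(c, stats_d.total_clean_reads))
    df["tpm_G"] = df["count_G"].map(lambda c: tpm(c, stats_g.total_clean_reads))
    both = (df["count_D"] > 0) & (df["count_G"] > 0)
    df["log2_ratio"] = np.where(
        both, np.log2(df["tpm_D"].where(both, 1.0) / df["tpm_G"].where(both, 1.0)), np.nan
    )
    df["call"] = [
        call_regulation(cd, cg, stats_d.total_clean_reads, stats_g.total_clean_reads, th)
        for cd, cg in zip(df["count_D"], df["count_G"])
    ]
    defined = df[both].sort_values(
        ["log2_ratio", "name"], ascending=[False, True], kind="mergesort"
    )
    rest = df[~both].sort_values("name", kind="mergesort")
    out = pd.concat([defined, rest], ignore_index=True)
    return out[
        ["name", "sequence", "count_D", "count_G", "tpm_D", "tpm_G", "log2_ratio", "call"]
    ]
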