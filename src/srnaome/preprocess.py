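"""Read cleaning and library length/redundancy profiling.

"Clean reads" are produced by an explicit, configurable filter chain:
3' adapter trimming (exact prefix match), ambiguous-base and mean-quality
filters, and an 18-30 nt length window.  The library profile reports, per
length class, redundant (read occurrences) and nonredundant (distinct
sequences) counts together with the redundancy frequency
redundant/nonredundant — the statistics used to contrast a 24-nt-dominant
(heterochromatic siRNA rich) library with a 21-nt-dominant (miRNA rich)
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from srnaome.io import CollapsedRead, RawRead, to_dna

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "LibraryProfile",
    "clean_reads",
    "profile_library",
    "dominant_length",
]

#: Discard reasons tallied by :func:`clean_reads`, in application order.
DISCARD_REASONS = ("adapter_only", "n_bases", "low_quality", "too_short", "too_long")


@dataclass
class CleaningConfig:
    """Filter chain parameters for raw-read cleaning.

    adapter3
        3' adapter sequence; the first exact occurrence of its prefix
        (``adapter_prefix_len`` bases) marks the trim point.
    min_len, max_len
        The clean-read length window (default 18-30 nt).
    max_N
        Maximum number of ambiguous bases tolerated (default 0).
    min_mean_quality
        Mean phred threshold, applied only when qualities exist.
    """

    adapter3: str | None = None
    min_len: int = 18
    max_len: int = 30
    max_N: int = 0
    min_mean_quality: float | None = 20.0
    adapter_prefix_len: int = 8

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("require 1 <= min_len <= max_len")
        if self.adapter3 is not None:
            self.adapter3 = to_dna(self.adapter3)


@dataclass
class CleaningReport:
    """Per-reason discard tallies and totals for one cleaning run."""

    raw_reads: int = 0
    clean_reads: int = 0
    discarded: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in DISCARD_REASONS}
    )

    @property
    def clean_fraction(self) -> float:
        return self.clean_reads / self.raw_reads if self.raw_reads else 0.0


def clean_reads(
    raw: Iterable[RawRead], cfg: CleaningConfig | None = None
) -> tuple[list[str], CleaningReport]:
    """Apply the cleaning filter chain; every failure is a tallied discard.

    Order: adapter trim, N filter, mean-quality filter (on the trimmed
    bases, only when the read has qualities), then the length window.
    Returned sequences are in the internal DNA alphabet.
    """
    cfg = cfg or CleaningConfig()
    report = CleaningReport()
    kept: list[str] = []
    adapter_key = (
        cfg.adapter3[: cfg.adapter_prefix_len] if cfg.adapter3 is not None else None
    )
    for read in raw:
        report.raw_reads += 1
        seq = to_dna(read.sequence)
        qual = read.quality
        if adapter_key:
            pos = seq.find(adapter_key)
            if pos == 0:
                report.discarded["adapter_only"] += 1
                continue
            if pos > 0:
                seq = seq[:pos]
                if qual is not None:
                    qual = qual[:pos]
        if seq.count("N") > cfg.max_N:
            report.discarded["n_bases"] += 1
            continue
        if (
            cfg.min_mean_quality is not None
            and qual is not None
            and sum(qual) / len(qual) < cfg.min_mean_quality
        ):
            report.discarded["low_quality"] += 1
            continue
        if len(seq) < cfg.min_len:
            report.discarded["too_short"] += 1
            continue
        if len(seq) > cfg.max_len:
            report.discarded["too_long"] += 1
            continue
        report.clean_reads += 1
        kept.append(seq)
    return kept, report


@dataclass
class LibraryProfile:
    """Per-length-class redundant/nonredundant profile of one library.

    ``per_length`` is a DataFrame indexed by length with columns
    ``redundant``, ``nonredundant``, ``redundancy_frequency``,
    ``redundant_share`` and ``nonredundant_share``; both share columns
    each sum to 1.
    """

    library: str
    per_length: pd.DataFrame
    clean_reads: int
    nonredundant_reads: int
    raw_reads: int | None = None

    def share(self, basis: str) -> pd.Series:
        if basis not in ("redundant", "nonredundant"):
            raise ValueError("basis must be 'redundant' or 'nonredundant'")
        return self.per_length[f"{basis}_share"]

    def to_tsv(self, path) -> None:
        df = self.per_length.reset_index()
        df.insert(0, "library", self.library)
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def profile_library(
    collapsed: dict[str, CollapsedRead], library: str
) -> LibraryProfile:
    """Compute the length-class profile of *library* from collapsed reads."""
    rows: dict[int, list[int]] = {}
    for seq, cr in collapsed.items():
        n = cr.count(library)
        if n == 0:
            continue
        red_nonred = rows.setdefault(len(seq), [0, 0])
        red_nonred[0] += n
        red_nonred[1] += 1
    if not rows:
        raise ValueError(f"empty library {library!r}")
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["redundant", "nonredundant"]
    ).sort_index()
    df.index.name = "length"
    df["redundancy_frequency"] = df["redundant"] / df["nonredundant"]
    clean = int(df["redundant"].sum())
    nonred = int(df["nonredundant"].sum())
    df["redundant_share"] = df["redundant"] / clean
    df["nonredundant_share"] = df["nonredundant"] / nonred
    return LibraryProfile(
        library=library, per_length=df, clean_reads=clean, nonredundant_reads=nonred
    )


def dominant_length(profile: LibraryProfile, basis: str = "redundant") -> int:
    """Argmax length of the chosen share vector; ties go to the smaller length."""
    shares = profile.share(basis)
    best = shares.max()
    # idxmax alone would hide the tie rule; make it explicit.
    return int(min(l for l, s in shares.items() if s == best))
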