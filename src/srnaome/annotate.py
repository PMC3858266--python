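"""Hierarchical sRNA annotation against reference catalogs.

Each collapsed read is assigned to exactly one category by trying the
categories in a configurable precedence order (default
rRNA > tRNA > snRNA > snoRNA > miRNA > repeat > mRNA); the first category
with a hit wins and a read hitting nothing is ``unknown``.  Matching is
ungapped full-length substring alignment (no indels): the 18-30 nt read
must occur inside a catalog sequence, optionally with mismatches (by
default 2 for the homology-based miRNA search, 0 elsewhere).  A k-mer/
``str.find`` fast path is used internally but never changes results
relative to the brute-force all-offsets scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from srnaome.io import (
    CATEGORIES,
    CatalogEntry,
    CollapsedRead,
    ReferenceCatalog,
    revcomp,
    to_dna,
)

__all__ = [
    "Hit",
    "AnnotationConfig",
    "CategoryAssignment",
    "match_to_catalog",
    "annotate_read",
    "annotate_collapsed",
    "category_composition",
    "group_conserved_families",
]

#: The 8 reporting categories (the closed catalog set plus ``unknown``).
REPORT_CATEGORIES = CATEGORIES + ("unknown",)


@dataclass(frozen=True)
class Hit:
    """Best ungapped occurrence of a read inside a reference sequence."""

    ref_id: str
    mismatches: int
    offset: int
    strand: str  # '+' read matches reference as-is; '-' its reverse complement does


@dataclass
class AnnotationConfig:
    precedence: tuple[str, ...] = CATEGORIES
    mirna_max_mismatch: int = 2
    other_max_mismatch: int = 0
    #: categories searched on both strands (repeats and mRNA fragments can
    #: derive from either strand; structural RNAs and matures are sense-only)
    both_strand_categories: frozenset[str] = frozenset({"repeat", "mRNA"})

    def __post_init__(self) -> None:
        if sorted(self.precedence) != sorted(CATEGORIES):
            raise ValueError("precedence must be a permutation of the category set")

    def max_mismatch(self, category: str) -> int:
        return self.mirna_max_mismatch if category == "miRNA" else self.other_max_mismatch

    def strands(self, category: str) -> tuple[str, ...]:
        return ("+", "-") if category in self.both_strand_categories else ("+",)


@dataclass
class CategoryAssignment:
    sequence: str
    category: str
    best_hit: Hit | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if (self.category == "unknown") != (self.best_hit is None):
            raise ValueError("category is 'unknown' iff best_hit is absent")


def _best_in_entry(query: str, ref: str, max_mismatch: int, cap: int) -> tuple[int, int] | None:
    """Best ``(mismatches, offset)`` of *query* inside *ref*, or None.

    *cap* bounds the useful mismatch count (exclusive upper bound from the
    running best); early-exits keep the scan cheap without changing the
    result of the exhaustive all-offsets scan.
    """
    n, m = len(ref), len(query)
    if m > n:
        return None
    limit = min(max_mismatch, cap)
    exact = ref.find(query)
    if exact >= 0:
        return (0, exact)
    if limit == 0:
        return None
    best: tuple[int, int] | None = None
    for off in range(n - m + 1):
        mm = 0
        window = ref[off : off + m]
        for a, b in zip(query, window):
            if a != b:
                mm += 1
                if mm > limit:
                    break
        else:
            best = (mm, off)
            limit = mm - 1  # only strictly better later offsets matter
            if limit < 0:
                break
    return best


def match_to_catalog(
    seq: str,
    catalog: ReferenceCatalog | Sequence[CatalogEntry],
    max_mismatch: int = 0,
    strands: tuple[str, ...] = ("+", "-"),
) -> Hit | None:
    """Minimum-mismatch ungapped full-length occurrence of *seq* in the catalog.

    Ties are broken by (fewer mismatches, earlier catalog entry, smaller
    offset, sense before antisense).  Returns ``None`` when no occurrence
    has at most *max_mismatch* mismatches.
    """
    seq = to_dna(seq)
    entries = catalog.entries if isinstance(catalog, ReferenceCatalog) else list(catalog)
    queries = [(0, "+", seq)]
    if "-" in strands:
        queries.append((1, "-", revcomp(seq)))
    if "+" not in strands:
        queries = queries[1:]
    best_key: tuple[int, int, int, int] | None = None
    best_hit: Hit | None = None
    for idx, entry in enumerate(entries):
        cap = best_key[0] if best_key is not None else max_mismatch
        candidates: list[tuple[tuple[int, int, int, int], Hit]] = []
        for srank, strand, query in queries:
            found = _best_in_entry(query, entry.sequence, max_mismatch, cap)
            if found is not None:
                mm, off = found
                candidates.append(
                    ((mm, idx, off, srank), Hit(entry.id, mm, off, strand))
                )
        for key, hit in candidates:
            if best_key is None or key < best_key:
                best_key, best_hit = key, hit
        if best_key is not None and best_key[0] == 0:
            break  # nothing later can beat 0 mismatches at an earlier id
    return best_hit


def _as_entry_map(
    catalogs: ReferenceCatalog | Iterable[ReferenceCatalog],
) -> dict[str, list[CatalogEntry]]:
    if isinstance(catalogs, ReferenceCatalog):
        catalogs = [catalogs]
    by_cat: dict[str, list[CatalogEntry]] = {}
    for cat in catalogs:
        for e in cat:
            by_cat.setdefault(e.category, []).append(e)
    return by_cat


def annotate_read(
    seq: str,
    catalogs: ReferenceCatalog | Iterable[ReferenceCatalog],
    cfg: AnnotationConfig | None = None,
    _entry_map: Mapping[str, list[CatalogEntry]] | None = None,
) -> CategoryAssignment:
    """Assign one read to the first category (in precedence order) with a hit."""
    cfg = cfg or AnnotationConfig()
    seq = to_dna(seq)
    by_cat = _entry_map if _entry_map is not None else _as_entry_map(catalogs)
    for category in cfg.precedence:
        entries = by_cat.get(category)
        if not entries:
            continue
        hit = match_to_catalog(
            seq, entries, cfg.max_mismatch(category), cfg.strands(category)
        )
        if hit is not None:
            family = None
            if category == "miRNA":
                family = next(e.family for e in entries if e.id == hit.ref_id)
            return CategoryAssignment(seq, category, hit, family)
    return CategoryAssignment(seq, "unknown")


def annotate_collapsed(
    collapsed: dict[str, CollapsedRead],
    catalogs: ReferenceCatalog | Iterable[ReferenceCatalog],
    cfg: AnnotationConfig | None = None,
) -> dict[str, CategoryAssignment]:
    """Annotate every collapsed read (unique sequences only, by construction)."""
    cfg = cfg or AnnotationConfig()
    entry_map = _as_entry_map(catalogs)
    return {
        seq: annotate_read(seq, (), cfg, _entry_map=entry_map) for seq in collapsed
    }


def category_composition(
    assignments: Mapping[str, CategoryAssignment],
    collapsed: dict[str, CollapsedRead],
    library: str,
) -> pd.DataFrame:
    """Redundant and nonredundant category fractions for one library.

    Returns a DataFrame indexed by the 8 reporting categories with columns
    ``redundant``, ``nonredundant``, ``redundant_fraction`` and
    ``nonredundant_fraction``; both fraction columns sum to 1.
    """
    red = {c: 0 for c in REPORT_CATEGORIES}
    nonred = {c: 0 for c in REPORT_CATEGORIES}
    for seq, cr in collapsed.items():
        n = cr.count(library)
        if n == 0:
            continue
        cat = assignments[seq].category
        red[cat] += n
        nonred[cat] += 1
    total_red = sum(red.values())
    total_nonred = sum(nonred.values())
    if total_red == 0:
        raise ValueError(f"no reads for library {library!r}")
    df = pd.DataFrame(
        {
            "redundant": pd.Series(red),
            "nonredundant": pd.Series(nonred),
        }
    ).loc[list(REPORT_CATEGORIES)]
    df.index.name = "category"
    df["redundant_fraction"] = df["redundant"] / total_red
    df["nonredundant_fraction"] = df["nonredundant"] / total_nonred
    return df


def group_conserved_families(
    assignments: Mapping[str, CategoryAssignment],
    collapsed: dict[str, CollapsedRead],
    libraries: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group miRNA-assigned sequences by reference family.

    One row per family with the number of distinct member sequences and
    per-library read counts; empty when nothing annotated as miRNA.
    """
    if libraries is None:
        libs: list[str] = sorted(
            {lib for cr in collapsed.values() for lib in cr.counts}
        )
    else:
        libs = list(libraries)
    rows: dict[str, dict[str, int]] = {}
    for seq, asn in assignments.items():
        if asn.category != "miRNA":
            continue
        fam = asn.family or "?"
        row = rows.setdefault(fam, {"members": 0, **{f"reads_{l}": 0 for l in libs}})
        row["members"] += 1
        cr = collapsed.get(seq)
        if cr is not None:
            for l in libs:
                row[f"reads_{l}"] += cr.count(l)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "family"
    if df.empty:
        df = pd.DataFrame(
            columns=["members", *(f"reads_{l}" for l in libs)], dtype=int
        )
        df.index.name = "family"
    return df
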