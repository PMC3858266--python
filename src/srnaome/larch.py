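"""Published larch (*Larix leptolepis*) embryo sRNA reference data.

Deep-sequencing read counts for the 19 novel/candidate mature miRNAs
(llemiR-1..19) and the 3 sequenced miRNA* strands reported for dormant
versus germinated somatic-embryo libraries, together with the printed
per-library clean-read totals.  These numbers serve as a fixture for the
star-evidence classification and regulation-call layers; sequences are
stored in RNA flavour as published.
"""

from __future__ import annotations

import pandas as pd

from srnaome.diffexpr import LibraryStats

__all__ = [
    "LIBRARY_TOTALS",
    "RAW_READ_TOTALS",
    "NONREDUNDANT_TOTALS",
    "novel_mirna_table",
    "library_stats",
    "classify_novel_candidates",
]

#: Total clean reads (18-30 nt) per library — the TPM denominators.
LIBRARY_TOTALS = {"dormant": 16_342_531, "germinated": 16_123_435}
#: Raw read totals, for reference.
RAW_READ_TOTALS = {"dormant": 16_514_593, "germinated": 16_415_719}
#: Nonredundant (distinct clean sequence) totals, for reference.
NONREDUNDANT_TOTALS = {"dormant": 5_644_091, "germinated": 2_880_823}

# name, sequence (RNA, 5'-3'), length, reads dormant, reads germinated, EST
_ROWS = [
    ("llemiR-1", "UGCCGUGGUUCGGAGCGAUCGA", 22, 11005, 15905, "JR179967"),
    ("llemiR-1*", "AUCCUCCCAACCAAGGCAACC", 21, 2, 7, "JR179967"),
    ("llemiR-2", "UGACCAGUCCUUCUGCGAUCCA", 22, 148, 162, "JR164575"),
    ("llemiR-2*", "AAUUGCAGAAGGGCUGGUUAGC", 22, 789, 1007, "JR164575"),
    ("llemiR-3", "UCAAGUGUUUCUGGACUCACC", 21, 5, 0, "JR164003"),
    ("llemiR-3*", "UGAGUCCAGACACACUUCGGC", 21, 1, 1, "JR164003"),
    ("llemiR-4", "UUUGAUAGAUCCGAGGUUAAG", 21, 70, 64, "PEMSG842X"),
    ("llemiR-5", "UGCAAAUGGUGUUUGCGUCGU", 21, 16, 26, "JR170741"),
    ("llemiR-6", "UCCAUGACUUUCCAGAGGGGU", 21, 336, 298, "JR184550"),
    ("llemiR-7", "UCAUUCCAGUUAUCGUUCUCC", 22, 50, 74, "JR185282"),
    ("llemiR-8", "UCUGCCUGGUACCUUGACGUA", 21, 98, 124, "JR174289"),
    ("llemiR-9", "UCGCAGGUGAGAUGACGCCGGC", 22, 52, 88, "JR160786"),
    ("llemiR-10", "UGAGCUCUUGGAAGUGUUGGA", 21, 205, 290, "PEMSJJR7E"),
    ("llemiR-11", "GCCGUGACCGUGGCGAUCGUGG", 22, 9, 7, "JR167874"),
    ("llemiR-12", "UACACCUCAAGAAAUUGGAUCCCU", 24, 4, 1, "JR176014"),
    ("llemiR-13", "UGAUUCAGGCAUGGAGGAGGACUA", 24, 10, 1, "JR179449"),
    ("llemiR-14", "UCUUUCUGAGGCAUGUAUGGGCAU", 24, 6, 1, "JR181565"),
    ("llemiR-15", "UCAGUGAGCUUAGGGUACGUUGG", 23, 0, 4, "JR184842"),
    ("llemiR-16", "UCGGAAUGCUGGAGGAGGCAA", 21, 1, 6, "JR190670"),
    ("llemiR-17", "UGAGUCCAGACACACUUCGGCU", 22, 4, 3, "JR164003"),
    ("llemiR-18", "CAACGAUCAACAGGACCACUG", 21, 24, 16, "JR195099"),
    ("llemiR-19", "UGUGACGGGGAUGGGAUGCU", 20, 0, 11, "JR155419"),
]


def novel_mirna_table() -> pd.DataFrame:
    """The packaged 22-row table: 19 mature entries plus 3 star strands.

    Columns: ``name``, ``sequence`` (RNA), ``length``, ``count_D``,
    ``count_G``, ``est_id``, ``is_star``.
    """
    df = pd.DataFrame(
        _ROWS, columns=["name", "sequence", "length", "count_D", "count_G", "est_id"]
    )
    df["is_star"] = df["name"].str.endswith("*")
    return df


def library_stats() -> tuple[LibraryStats, LibraryStats]:
    """Clean-read totals as :class:`~srnaome.diffexpr.LibraryStats` pair."""
    return (
        LibraryStats("dormant", LIBRARY_TOTALS["dormant"]),
        LibraryStats("germinated", LIBRARY_TOTALS["germinated"]),
    )


def classify_novel_candidates(table: pd.DataFrame | None = None) -> pd.Series:
    """Novel-vs-candidate verdict for each mature entry, from star evidence.

    A mature miRNA is ``novel`` when its miRNA* strand was sequenced with
    at least one read in either library, otherwise ``candidate`` — the
    same rule :func:`srnaome.discover.classify_novel` applies to hairpin
    candidates, driven here by the packaged star rows.
    """
    df = novel_mirna_table() if table is None else table
    star_support = {
        row["name"].rstrip("*"): (row["count_D"] + row["count_G"]) >= 1
        for _, row in df[df["is_star"]].iterrows()
    }
    mature = df[~df["is_star"]]
    verdicts = [
        "novel" if star_support.get(name, False) else "candidate"
        for name in mature["name"]
    ]
    return pd.Series(verdicts, index=mature["name"].tolist(), name="verdict")
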