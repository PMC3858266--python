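import numpy as np
import pytest

from oracles import brute_force_match

from srnaome.annotate import (
    AnnotationConfig,
    annotate_collapsed,
    annotate_read,
    category_composition,
    group_conserved_families,
    match_to_catalog,
)
from srnaome.io import CatalogEntry, ReferenceCatalog, collapse, revcomp


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def catalog():
    return ReferenceCatalog(
        [
            CatalogEntry("rrna1", "GGGGACGTACGTACGTACGTACGTGGGG", "rRNA"),
            CatalogEntry("mir156a", "TGACAGAAGAGAGTGAGCAC", "miRNA", family="miR156"),
            CatalogEntry("mir156b", "TGACAGAAGAGAGAGAGCAC", "miRNA", family="miR156"),
            CatalogEntry("rep1", "ATCGGATTCAACGGATCCAAGGATTCAGGTAC", "repeat"),
        ]
    )


class TestMatchToCatalog:
    def test_exact_hit_offset(self, catalog):
        hit = match_to_catalog("ACGTACGTACGTACGTACGT", catalog, 0, ("+",))
        assert (hit.ref_id, hit.mismatches, hit.offset, hit.strand) == ("rrna1", 0, 4, "+")

    def test_mismatch_threshold(self):
        ref = ReferenceCatalog([CatalogEntry("x", "AAAAAAAAAAAAAAAAAAAA", "rRNA")])
        assert match_to_catalog("AAAAAAAACCCAAAAAAAAA", ref, 2, ("+",)) is None
        hit = match_to_catalog("AAAAAAAACCAAAAAAAAAA", ref, 2, ("+",))
        assert hit.mismatches == 2

    def test_antisense_strand(self, catalog):
        query = revcomp("ATCGGATTCAACGGATCCAA")
        hit = match_to_catalog(query, catalog, 0, ("-",))
        assert hit is not None and hit.strand == "-"
        assert match_to_catalog(query, catalog, 0, ("+",)) is None

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_matches_brute_force_scan(self, max_mismatch):
        rng = np.random.default_rng(1234 + max_mismatch)
        entries = [
            CatalogEntry(f"e{i}", _rand_seq(rng, int(rng.integers(50, 400))), "rRNA")
            for i in range(4)
        ]
        cat = ReferenceCatalog(entries)
        for _ in range(40):
            read = _rand_seq(rng, int(rng.integers(18, 31)))
            if rng.random() < 0.5:  # plant a near-match so hits actually occur
                donor = entries[int(rng.integers(len(entries)))].sequence
                off = int(rng.integers(0, len(donor) - len(read) + 1))
                read = list(donor[off : off + len(read)])
                for pos in rng.choice(len(read), size=int(rng.integers(0, 3)), replace=False):
                    read[pos] = "ACGT"[int(rng.integers(4))]
                read = "".join(read)
            expected = brute_force_match(read, entries, max_mismatch)
            got = match_to_catalog(read, cat, max_mismatch)
            got_tuple = (
                None if got is None else (got.ref_id, got.mismatches, got.offset, got.strand)
            )
            assert got_tuple == expected


class TestAnnotateRead:
    def test_precedence_rrna_over_mirna(self):
        cat = ReferenceCatalog(
            [
                CatalogEntry("r", "TGACAGAAGAGAGTGAGCAC", "rRNA"),
                CatalogEntry("m", "TGACAGAAGAGAGTGAGCAC", "miRNA", family="miR156"),
            ]
        )
        asn = annotate_read("TGACAGAAGAGAGTGAGCAC", cat)
        assert asn.category == "rRNA"

    def test_mirna_with_one_mismatch_resolves_family(self, catalog):
        asn = annotate_read("TGACAGAAGAGAGTGAGCAA", catalog)
        assert asn.category == "miRNA"
        assert asn.family == "miR156"
        assert asn.best_hit.mismatches == 1

    def test_no_hit_is_unknown(self, catalog):
        asn = annotate_read("T" * 25, catalog)
        assert asn.category == "unknown" and asn.best_hit is None

    def test_mismatch_tolerance_monotonicity(self, catalog):
        rng = np.random.default_rng(77)
        reads = [_rand_seq(rng, 20) for _ in range(60)] + [
            "TGACAGAAGAGAGTGAGCTT",  # 2 mm from mir156a
            "TGACAGAAGAGAGTGAGCAC",
        ]
        counts = []
        for mm in (0, 1, 2, 3):
            cfg = AnnotationConfig(mirna_max_mismatch=mm, other_max_mismatch=0)
            n = sum(annotate_read(r, catalog, cfg).category != "unknown" for r in reads)
            counts.append(n)
        assert counts == sorted(counts)


class TestComposition:
    def test_all_unknown(self, catalog):
        collapsed = collapse(["T" * 25] * 10, "lib")
        asn = annotate_collapsed(collapsed, catalog)
        comp = category_composition(asn, collapsed, "lib")
        assert comp.loc["unknown", "redundant_fraction"] == 1.0
        assert comp.loc["unknown", "nonredundant_fraction"] == 1.0

    def test_share_arithmetic(self, catalog):
        collapsed = collapse(
            ["TGACAGAAGAGAGTGAGCAC"] * 37 + ["T" * 25] * 63, "lib"
        )
        asn = annotate_collapsed(collapsed, catalog)
        comp = category_composition(asn, collapsed, "lib")
        assert comp.loc["miRNA", "redundant_fraction"] == pytest.approx(0.37)
        assert comp["redundant_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert comp["nonredundant_fraction"].sum() == pytest.approx(1.0, abs=1e-9)


class TestFamilies:
    def test_two_members_one_family(self, catalog):
        collapsed = collapse(
            ["TGACAGAAGAGAGTGAGCAC"] * 3 + ["TGACAGAAGAGAGAGAGCAC"] * 2, "lib"
        )
        asn = annotate_collapsed(collapsed, catalog)
        fam = group_conserved_families(asn, collapsed)
        assert list(fam.index) == ["miR156"]
        assert fam.loc["miR156", "members"] == 2
        assert fam.loc["miR156", "reads_lib"] == 5

    def test_empty_when_no_mirna(self, catalog):
        collapsed = collapse(["T" * 25], "lib")
        asn = annotate_collapsed(collapsed, catalog)
        assert group_conserved_families(asn, collapsed).empty
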