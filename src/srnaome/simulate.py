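"""Paired synthetic sRNA libraries with known ground truth.

The generator emulates the statistical structure of a dormant-vs-
germinated conifer embryo contrast: a 24-nt-dominant "dormant-like"
library against a 21-nt-shifted "germinated-like" one, an annotation-
category mixture (rRNA/tRNA/snRNA/snoRNA/repeat/mRNA/unknown), conserved
miRNA family spike-ins with fixed tags-per-million abundances and log2
fold changes, and hairpin loci on short EST-like scaffolds that emit
mature reads and, optionally, miRNA* reads at the 2-nt-overhang
position.  The generator writes its own reference catalogs, so the
pipeline is tested against the catalogs its reads were generated from
and needs no external databases.

Design notes
------------
* Spike and hairpin mature sequences are fixed module constants; all
  other sequence content is drawn uniformly over {A,C,G,T} from the
  seed, which keeps annotation in the closed loop unambiguous.
* The miRNA category mass of each library is the sum of the spike
  proportions (``tpm/1e6`` with ``tpm = base x 2^(+-lfc/2)``), so the
  realized expected fold change of every spike equals its nominal one;
  ``category_mix`` therefore spans the non-miRNA categories and is
  scaled to the remaining read mass.
* Background redundancy is controlled per length class by drawing reads
  from finite sequence pools shared between the two libraries (pool size
  = expected reads / target redundancy frequency), which reproduces the
  low redundancy of 24-nt sRNAs against high-copy 21/22-nt classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from srnaome.io import (
    CatalogEntry,
    RawRead,
    ReferenceCatalog,
    revcomp,
    to_dna,
)

__all__ = [
    "Spike",
    "HairpinLocus",
    "SimConfig",
    "SimResult",
    "TruthManifest",
    "simulate_pair",
    "paired_embryo_config",
]

LIBRARIES = ("dormant", "germinated")

#: Background annotation categories (miRNA mass comes from the spikes).
BACKGROUND_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA", "unknown")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Spike:
    """A conserved-family mature miRNA spike-in with a set fold change."""

    family: str
    sequence: str  # mature sequence, fixed input
    base_tpm: float  # geometric mean of the two per-library tpms
    log2fc: float  # log2(tpm_dormant / tpm_germinated)

    def tpm(self, library: str) -> float:
        sign = +0.5 if library == "dormant" else -0.5
        return self.base_tpm * 2.0 ** (sign * self.log2fc)


@dataclass(frozen=True)
class HairpinLocus:
    """A precursor locus emitting mature (and optionally star) reads."""

    scaffold_id: str
    mature: str  # fixed input, 5' arm of the designed stem
    with_star: bool
    mature_depth: tuple[int, int]  # expected reads (dormant, germinated)
    star_depth: tuple[int, int] = (0, 0)

    def expected_verdict(self) -> str:
        return "novel" if self.with_star else "candidate"


# Fixed spike matures: well-known conserved plant families plus a
# miR950-like conifer-dominant family (synthetic 21-mer standing in for
# the family's mature sequence).
DEFAULT_SPIKES = (
    Spike("miR950", "UUGGCAUUGGAGGAAUGACGC", 180_000.0, -0.7),
    Spike("miR166", "UCGGACCAGGCUUCAUUCCCC", 44_000.0, -1.17),
    Spike("miR156", "UGACAGAAGAGAGUGAGCAC", 20_784.0, -1.28),
    Spike("miR159", "UUUGGAUUGAAGGGAGCUCUA", 8_000.0, 1.2),
    Spike("miR168", "UCGCUUGGUGCAGGUCGGGAA", 6_000.0, -1.0),
    Spike("miR396", "UUCCACAGCUUUCUUGAACUG", 6_000.0, 0.0),
    Spike("miR397", "UCAUUGAGUGCAGCGUUGAUG", 5_000.0, 1.6),
    Spike("miR167", "UGAAGCUGCCAGCAUGAUCUA", 4_000.0, -0.4),
    Spike("miR160", "UGCCUGGCUCCCUGUAUGCCA", 400.0, -1.5),
)

# Fixed hairpin matures (synthetic 21-mers, all > 2 mismatches from every
# spike so they stay unannotated and reach the discovery stage).
DEFAULT_HAIRPINS = (
    HairpinLocus("EST_hp1", "UACGAUCGUUAGGCACUUCGA", True, (120, 180), (25, 35)),
    HairpinLocus("EST_hp2", "UGGUUCAACGGAUCAGUUACC", True, (60, 40), (12, 8)),
    HairpinLocus("EST_hp3", "UCCUAGCUAAGGUUCACCGGU", True, (30, 90), (6, 18)),
    HairpinLocus("EST_hp4", "UAGCCAGUUAGCGAUCCAUGC", False, (80, 50)),
    HairpinLocus("EST_hp5", "UCGAUUAGGCUUCAAGUCGGA", False, (45, 110)),
    HairpinLocus("EST_hp6", "UGGCAUCCAGUUAACGGCUUA", False, (25, 20)),
)

# Designed stem geometry: mature + _STEM_EXT + _LOOP + rc(_STEM_EXT) +
# rc(mature), flanked by 20 random A/C nt on the left and its reverse
# complement on the right (a paired lower stem, as in real precursors).
# The all-C loop pairs only with G, the A/T-only stem extension next to
# it offers no G or C, and A/C flanks cannot pair among themselves, so
# rerouting any mature base into the loop or flanks always sacrifices
# more designed pairs than it gains: the designed duplex is the strict
# maximum-pairing routing of the mature strand for any mature sequence,
# and folding recovers the intended star locus regardless of the seed.
_STEM_EXT = "ATTA"
_LOOP = "CCCCCCCC"
_FLANK = 20
_FLANK_BASES = np.frombuffer(b"AC", dtype=np.uint8)


@dataclass
class SimConfig:
    """Everything :func:`simulate_pair` needs, with validated probabilities."""

    seed: int
    n_reads: dict[str, int]
    length_distribution: dict[str, dict[int, float]]  # background lengths
    category_mix: dict[str, dict[str, float]]  # background categories
    mirna_spikes: tuple[Spike, ...] = DEFAULT_SPIKES
    hairpin_loci: tuple[HairpinLocus, ...] = DEFAULT_HAIRPINS
    noise: float = 0.0  # per-base substitution rate
    redundancy_by_length: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lib in LIBRARIES:
            for name, vec in (
                ("length_distribution", self.length_distribution[lib]),
                ("category_mix", self.category_mix[lib]),
            ):
                total = sum(vec.values())
                if abs(total - 1.0) > 1e-9 or any(p < 0 for p in vec.values()):
                    raise ValueError(
                        f"{name}[{lib!r}] is not a probability vector (sum={total})"
                    )
            unknown_cats = set(self.category_mix[lib]) - set(BACKGROUND_CATEGORIES)
            if unknown_cats:
                raise ValueError(f"category_mix[{lib!r}]: unknown {unknown_cats}")
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise must be in [0, 1)")
        for locus in self.hairpin_loci:
            if min(locus.mature_depth) < 0 or min(locus.star_depth) < 0:
                raise ValueError("hairpin depths must be >= 0")


@dataclass
class TruthManifest:
    """Ground truth for every generated read and structural element."""

    read_labels: dict[str, list[str]]  # per-library, parallel to the reads
    sequence_category: dict[str, str]
    expected_length_share: dict[str, dict[int, float]]
    expected_category_share: dict[str, dict[str, float]]
    spikes: pd.DataFrame  # family, sequence, tpm per library, log2fc
    loci: pd.DataFrame  # scaffold, mature, star, with_star, expected verdict

    def to_tsv(self, path) -> None:
        rows = [
            {"sequence": seq, "category": cat}
            for seq, cat in sorted(self.sequence_category.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SimResult:
    reads: dict[str, list[RawRead]]
    catalog: ReferenceCatalog
    scaffolds: list[tuple[str, str]]
    truth: TruthManifest


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _build_catalog(rng: np.random.Generator, spikes: Sequence[Spike]) -> ReferenceCatalog:
    sizes = {
        "rRNA": (3, 600),
        "tRNA": (4, 80),
        "snRNA": (3, 150),
        "snoRNA": (3, 120),
        "repeat": (4, 400),
        "mRNA": (5, 500),
    }
    entries: list[CatalogEntry] = []
    for category, (count, length) in sizes.items():
        for i in range(1, count + 1):
            entries.append(
                CatalogEntry(f"{category}_{i}", _random_seq(rng, length), category)
            )
    for sp in spikes:
        entries.append(
            CatalogEntry(
                f"lle-{sp.family}", to_dna(sp.sequence), "miRNA", family=sp.family,
                species="lle",
            )
        )
    return ReferenceCatalog(entries)


def _build_scaffold(rng: np.random.Generator, mature_dna: str) -> tuple[str, int]:
    """EST-like precursor scaffold; returns (sequence, mature offset)."""
    flank = rng.choice(_FLANK_BASES, size=_FLANK).tobytes().decode()
    arm = mature_dna + _STEM_EXT
    scaffold = flank + arm + _LOOP + revcomp(arm) + revcomp(flank)
    return scaffold, _FLANK


def _star_region(mature_offset: int, mature_len: int) -> tuple[int, int]:
    """Scaffold coordinates of the star read (2-nt 3' overhang geometry).

    For the designed stem, the mature's pairing span shifted by +2 —
    independent closed form, not derived from the pipeline's folder.
    """
    a, m = mature_offset, mature_len
    x, l = len(_STEM_EXT), len(_LOOP)
    start = a + m + 2 * x + l + 2
    return start, start + m


def paired_embryo_config(seed: int = 0, n_reads: int = 100_000) -> SimConfig:
    """The default study-structured configuration.

    Dormant-like: redundant length mass peaking at 24 nt with minor
    21/22-nt peaks, ~22% miRNA mass; germinated-like: 21-nt major peak,
    ~36% miRNA mass (mostly germinated-upregulated spikes).  Redundancy
    targets make 24-nt the most diverse, 21/22-nt the most redundant
    classes.
    """
    length_d = {
        18: 0.04, 19: 0.04, 20: 0.05, 21: 0.10, 22: 0.06, 23: 0.05, 24: 0.50,
        25: 0.05, 26: 0.04, 27: 0.03, 28: 0.02, 29: 0.01, 30: 0.01,
    }
    length_g = {
        18: 0.03, 19: 0.03, 20: 0.05, 21: 0.35, 22: 0.06, 23: 0.05, 24: 0.18,
        25: 0.06, 26: 0.05, 27: 0.05, 28: 0.04, 29: 0.03, 30: 0.02,
    }
    mix_d = {
        "rRNA": 0.073, "tRNA": 0.005, "snRNA": 0.003, "snoRNA": 0.003,
        "repeat": 0.005, "mRNA": 0.005, "unknown": 0.906,
    }
    mix_g = {
        "rRNA": 0.081, "tRNA": 0.006, "snRNA": 0.004, "snoRNA": 0.004,
        "repeat": 0.006, "mRNA": 0.007, "unknown": 0.892,
    }
    redundancy = {
        18: 2.0, 19: 2.0, 20: 3.0, 21: 8.0, 22: 12.0, 23: 3.0, 24: 1.6,
        25: 2.0, 26: 2.0, 27: 2.0, 28: 2.0, 29: 2.0, 30: 2.0,
    }
    return SimConfig(
        seed=seed,
        n_reads={"dormant": n_reads, "germinated": n_reads},
        length_distribution={"dormant": length_d, "germinated": length_g},
        category_mix={"dormant": mix_d, "germinated": mix_g},
        redundancy_by_length=redundancy,
    )


def simulate_pair(cfg: SimConfig) -> SimResult:
    """Generate the paired libraries, catalogs, scaffolds and truth manifest.

    Reproducible: a fixed config (including its seed) yields byte-identical
    output.  Per-library reads are a single multinomial draw over all
    components (spikes, hairpin mature/star loci, finite background
    pools), then shuffled.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_cat, rng_scaf, rng_pool, rng_d, rng_g, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )
    catalog = _build_catalog(rng_cat, cfg.mirna_spikes)

    scaffolds: list[tuple[str, str]] = []
    locus_rows = []
    hairpin_components: list[tuple[str, str, dict[str, float]]] = []
    for locus in cfg.hairpin_loci:
        mature = to_dna(locus.mature)
        scaffold, offset = _build_scaffold(rng_scaf, mature)
        scaffolds.append((locus.scaffold_id, scaffold))
        ss_, se_ = _star_region(offset, len(mature))
        star_seq = scaffold[ss_:se_]
        hairpin_components.append(
            (
                mature,
                "unknown",
                {
                    lib: locus.mature_depth[i] / cfg.n_reads[lib]
                    for i, lib in enumerate(LIBRARIES)
                },
            )
        )
        if locus.with_star:
            hairpin_components.append(
                (
                    star_seq,
                    "unknown",
                    {
                        lib: locus.star_depth[i] / cfg.n_reads[lib]
                        for i, lib in enumerate(LIBRARIES)
                    },
                )
            )
        locus_rows.append(
            {
                "scaffold": locus.scaffold_id,
                "mature": mature,
                "star": star_seq if locus.with_star else "",
                "with_star": locus.with_star,
                "expected_verdict": locus.expected_verdict(),
                "mature_depth_dormant": locus.mature_depth[0],
                "mature_depth_germinated": locus.mature_depth[1],
            }
        )

    # component table shared across libraries: (sequence, category, p per lib)
    components: list[tuple[str, str, dict[str, float]]] = []
    spike_rows = []
    for sp in cfg.mirna_spikes:
        p = {lib: sp.tpm(lib) / 1e6 for lib in LIBRARIES}
        components.append((to_dna(sp.sequence), "miRNA", p))
        spike_rows.append(
            {
                "family": sp.family,
                "sequence": to_dna(sp.sequence),
                "tpm_dormant": sp.tpm("dormant"),
                "tpm_germinated": sp.tpm("germinated"),
                "log2fc": sp.log2fc,
            }
        )
    components.extend(hairpin_components)

    fixed_mass = {
        lib: sum(p[lib] for _, _, p in components) for lib in LIBRARIES
    }
    for lib in LIBRARIES:
        if fixed_mass[lib] >= 1.0:
            raise ValueError(
                f"spike + hairpin mass {fixed_mass[lib]:.3f} leaves no "
                f"background mass in library {lib!r}"
            )

    # finite background pools, shared between libraries
    refs_by_cat = {
        c: [e.sequence for e in catalog.by_category(c)]
        for c in BACKGROUND_CATEGORIES
        if c != "unknown"
    }
    for category in BACKGROUND_CATEGORIES:
        lengths = sorted(
            set().union(*(cfg.length_distribution[lib] for lib in LIBRARIES))
        )
        for length in lengths:
            mass = {
                lib: (1.0 - fixed_mass[lib])
                * cfg.category_mix[lib].get(category, 0.0)
                * cfg.length_distribution[lib].get(length, 0.0)
                for lib in LIBRARIES
            }
            expected = max(mass[lib] * cfg.n_reads[lib] for lib in LIBRARIES)
            if expected <= 0:
                continue
            redundancy = cfg.redundancy_by_length.get(length, 1.0)
            pool_size = max(1, int(round(expected / redundancy)))
            pool: list[str] = []
            if category == "unknown":
                for _ in range(pool_size):
                    pool.append(_random_seq(rng_pool, length))
            else:
                refs = refs_by_cat[category]
                for _ in range(pool_size):
                    ref = refs[int(rng_pool.integers(len(refs)))]
                    off = int(rng_pool.integers(len(ref) - length + 1))
                    pool.append(ref[off : off + length])
            for seq in pool:
                components.append(
                    (seq, category, {lib: mass[lib] / pool_size for lib in LIBRARIES})
                )

    sequence_category: dict[str, str] = {}
    for seq, category, _ in components:
        sequence_category.setdefault(seq, category)

    reads: dict[str, list[RawRead]] = {}
    labels: dict[str, list[str]] = {}
    expected_length: dict[str, dict[int, float]] = {}
    expected_category: dict[str, dict[str, float]] = {}
    for lib, rng in (("dormant", rng_d), ("germinated", rng_g)):
        probs = np.array([p[lib] for _, _, p in components])
        probs = probs / probs.sum()  # absorb float rounding (sum is ~1)
        counts = rng.multinomial(cfg.n_reads[lib], probs)
        exp_len: dict[int, float] = {}
        exp_cat: dict[str, float] = {c: 0.0 for c in BACKGROUND_CATEGORIES}
        exp_cat["miRNA"] = 0.0
        for (seq, category, _), p in zip(components, probs):
            exp_len[len(seq)] = exp_len.get(len(seq), 0.0) + p
            exp_cat[category] += p
        expected_length[lib] = exp_len
        expected_category[lib] = exp_cat

        lib_seqs: list[str] = []
        lib_labels: list[str] = []
        for (seq, category, _), n in zip(components, counts):
            lib_seqs.extend([seq] * int(n))
            lib_labels.extend([category] * int(n))
        order = rng.permutation(len(lib_seqs))
        lib_reads: list[RawRead] = []
        shuffled_labels: list[str] = []
        prefix = lib[0].upper()
        for rank, idx in enumerate(order, start=1):
            seq = lib_seqs[idx]
            if cfg.noise > 0.0:
                seq = _add_noise(seq, cfg.noise, rng_noise)
            lib_reads.append(
                RawRead(f"{prefix}{rank:07d}", seq, [40] * len(seq))
            )
            shuffled_labels.append(lib_labels[idx])
        reads[lib] = lib_reads
        labels[lib] = shuffled_labels

    truth = TruthManifest(
        read_labels=labels,
        sequence_category=sequence_category,
        expected_length_share=expected_length,
        expected_category_share=expected_category,
        spikes=pd.DataFrame(spike_rows),
        loci=pd.DataFrame(locus_rows),
    )
    return SimResult(reads=reads, catalog=catalog, scaffolds=scaffolds, truth=truth)


def _add_noise(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()
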