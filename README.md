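# srnaome

Small-RNA-ome profiling for paired sRNA sequencing libraries, built around
the dormant-vs-germinated *Larix leptolepis* (Japanese larch) embryo
contrast: cleaning and collapsing raw reads into unique tags, length-class
and redundancy profiling, hierarchical annotation against reference
catalogs, novel plant miRNA discovery from hairpin precursors with miRNA*
duplex evidence, and threshold-based differential expression.

It is aimed at plant small-RNA researchers working in species without a
genome assembly, where annotation runs against catalog FASTA files
(structural ncRNAs, repeats, known matures with family labels) and novel
miRNA precursors are sought on EST/transcript scaffolds.

## The analysis

**Profiling.** Clean reads (18–30 nt after adapter/quality/length
filtering) are collapsed to unique tags. Per length class *l* the profile
reports redundant reads *r\_l*, nonredundant tags *u\_l*, and the
redundancy frequency *r\_l / u\_l*. A 24-nt-dominant redundant profile
signals heterochromatic siRNA activity; a shift to 21 nt signals
miRNA-dominated regulation.

**Annotation.** Each tag is assigned to one category by ungapped
full-length substring matching, trying categories in precedence order
rRNA > tRNA > snRNA > snoRNA > miRNA > repeat(ra-siRNA) > mRNA; the
homology-based miRNA search tolerates 2 mismatches (configurable), other
categories are exact. Unmatched tags are `unknown`.

**Novel miRNA discovery.** Unannotated tags are located exactly on
transcript scaffolds; windows around each occurrence are folded by nested
base-pair maximization (a Nussinov-style dynamic program with
deterministic traceback); mature/star duplex geometry is checked
(pairing fraction ≥ 0.60, ≤ 4 unpaired mature bases, bulges ≤ 2 nt, loop
clearance), and the miRNA* locus is predicted with the canonical 2-nt 3′
overhangs. A candidate whose predicted star is supported by a sequenced
read (±1 nt at either end) is a **novel miRNA**; otherwise it remains a
**candidate**. ViennaRNA's `RNAfold` can be plugged in as an alternative
folding engine.

**Differential expression.** Abundances are normalised to tags per
million over the library's total clean reads,

    tpm = count / total_clean_reads × 10⁶,

and contrasted as `log2(tpm_D / tpm_G)` with cutoffs +1/−1 for
dormant-up/germinated-up calls. Zero counts are never pseudo-counted: a
sequence seen in only one library is called exclusively expressed there
when it has ≥ 3 reads, and `below_detection` otherwise.

## Worked example

The package ships the published larch novel-miRNA table (19 mature
llemiR entries plus 3 sequenced miRNA* strands, with read counts for the
dormant and germinated libraries and their clean-read totals 16,342,531
and 16,123,435):

```python
from srnaome import larch
from srnaome.diffexpr import expression_table

stats_d, stats_g = larch.library_stats()
table = expression_table(larch.novel_mirna_table(), stats_d, stats_g)
print(table.head(3).to_string(index=False))
print(larch.classify_novel_candidates().value_counts().to_dict())
```

prints

```
     name  count_D  count_G  tpm_D  tpm_G  log2_ratio       call
llemiR-13       10        1   0.61   0.06        3.30 dormant_up
llemiR-14        6        1   0.37   0.06        2.57 dormant_up
llemiR-12        4        1   0.24   0.06        1.98 dormant_up
{'candidate': 16, 'novel': 3}
```

i.e. three matures (llemiR-12/13/14) are upregulated in dormant embryos
at the |log₂| > 1 cutoff, and the three star-supported matures
(llemiR-1/2/3) are classified as novel miRNAs against 16 candidates.
llemiR-3 (5 vs 0 reads) is called `dormant_only` under the ≥3-read
exclusive-detection rule.

The full pipeline on a synthetic pair:

```bash
srnaome simulate --seed 1 --n-reads 100000 --out-dir sim/
srnaome run-all --reads-dormant sim/dormant.fastq \
    --reads-germinated sim/germinated.fastq \
    --catalog sim/catalog.fa --scaffolds sim/scaffolds.fa -o out/
```

writes per-stage TSVs (`profile_*.tsv`, `composition_*.tsv`,
`annotation.tsv`, `hairpins.tsv`, `diffexpr.tsv`, `contrast.tsv`) plus a
JSON run log with per-stage read-count conservation.

## Layout

| module | contents |
| --- | --- |
| `srnaome.io` | FASTA/FASTQ/collapsed-FASTA/catalog I/O, `CollapsedRead` model |
| `srnaome.preprocess` | cleaning filter chain, length/redundancy profiles |
| `srnaome.annotate` | hierarchical catalog matching, composition, families |
| `srnaome.discover` | folding, precursor windows, duplex criteria, star evidence |
| `srnaome.diffexpr` | TPM, log₂ ratios, regulation calls |
| `srnaome.simulate` | ground-truth paired-library generator |
| `srnaome.larch` | packaged published larch reference data |
| `srnaome.pipeline` / `srnaome.cli` | orchestration and the `srnaome` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
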