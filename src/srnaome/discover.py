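"""Novel miRNA discovery from hairpin precursors on EST/transcript scaffolds.

Unannotated sRNAs are located exactly (either strand) on transcript
scaffolds; candidate precursor windows around each occurrence are folded
with a self-contained nested base-pair-maximization dynamic program
(Nussinov-style, deterministic traceback), the mature/star duplex is
checked against stem-loop criteria, the miRNA* locus is predicted with
the canonical 2-nt 3' overhang geometry, and candidates are split into
``novel`` (a sequenced read supports the predicted star within +/-1 nt)
versus ``candidate`` (no star read).

An energy-based folder (ViennaRNA's ``RNAfold`` CLI, when installed) is
available as a pluggable alternative behind the same :class:`FoldResult`
contract via :func:`fold_rnafold`; nothing in the pipeline requires it.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from srnaome.io import CollapsedRead, revcomp, to_dna, to_rna

__all__ = [
    "FoldResult",
    "HairpinCriteria",
    "PrecursorWindow",
    "HairpinCandidate",
    "fold_max_pairing",
    "fold_rnafold",
    "extract_precursor_windows",
    "evaluate_hairpin",
    "classify_novel",
    "discover_mirnas",
    "locus_verdicts",
    "candidates_table",
    "dinucleotide_shuffle",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
#: admissible pairs in DNA encoding of RNA: AU/UA, GC/CG, GU/UG wobble
_PAIRABLE = np.zeros((4, 4), dtype=bool)
for _a, _b in ("AT", "TA", "GC", "CG", "GT", "TG"):
    _PAIRABLE[_CODE[_a], _CODE[_b]] = True


@dataclass
class FoldResult:
    """A nested secondary structure as a partner table.

    ``pairs[i]`` is the partner of position ``i`` (0-based) or ``None``;
    pairing is symmetric and non-crossing, hairpin loops span at least
    ``min_loop`` bases, and only {AU, UA, GC, CG, GU, UG} pairs occur.
    """

    sequence: str
    pairs: list[int | None]
    n_pairs: int

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairs):
            out.append("." if j is None else ("(" if j > i else ")"))
        return "".join(out)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in sequence") from None


def fold_max_pairing(seq: str, min_loop: int = 3) -> FoldResult:
    """Fold *seq* by nested base-pair maximization (dynamic programming).

    The traceback is deterministic: position ``i`` pairs with the
    smallest admissible ``j`` that achieves the optimum, otherwise it is
    left unpaired.  Accepts DNA or RNA characters; anything else raises
    ``ValueError``.  Sequence length must be between 1 and 1000.
    """
    s = to_dna(seq)
    n = len(s)
    if not (1 <= n <= 1000):
        raise ValueError("sequence length must be in [1, 1000]")
    enc = _encode(s)
    can = _PAIRABLE[enc[:, None], enc[None, :]]
    F = np.zeros((n + 1, n + 1), dtype=np.int32)  # F[i, j] inclusive, padded row/col

    for span in range(min_loop + 1, n):
        i = np.arange(n - span)
        j = i + span
        best = np.maximum(F[i + 1, j], F[i, j - 1])
        paired = np.where(can[i, j], F[i + 1, j - 1] + 1, 0)
        best = np.maximum(best, paired)
        for d in range(1, span):  # bifurcation F[i,k] + F[k+1,j], k = i + d
            np.maximum(best, F[i, i + d] + F[i + d + 1, j], out=best)
        F[i, j] = best

    pairs: list[int | None] = [None] * n
    n_pairs = 0
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop or F[i, j] == 0:
            continue
        target = F[i, j]
        paired_here = False
        for jp in range(i + min_loop + 1, j + 1):
            if not can[i, jp]:
                continue
            inner = F[i + 1, jp - 1] if jp - 1 > i else 0
            right = F[jp + 1, j] if jp < j else 0
            if inner + 1 + right == target:
                pairs[i], pairs[jp] = jp, i
                n_pairs += 1
                stack.append((jp + 1, j))
                stack.append((i + 1, jp - 1))
                paired_here = True
                break
        if not paired_here:
            stack.append((i + 1, j))  # every optimum leaves i unpaired
    return FoldResult(s, pairs, n_pairs)


def fold_rnafold(seq: str, min_loop: int = 3) -> FoldResult:
    """Minimum-free-energy fold via the ViennaRNA ``RNAfold`` executable.

    Optional plug-in behind the same contract as :func:`fold_max_pairing`
    (*min_loop* is accepted for interface parity; RNAfold applies its own
    loop rules).  Raises ``RuntimeError`` when RNAfold is unavailable.
    """
    s = to_dna(seq)
    try:
        proc = subprocess.run(
            ["RNAfold", "--noPS"],
            input=to_rna(s) + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except (OSError, subprocess.CalledProcessError) as exc:
        raise RuntimeError(f"RNAfold unavailable or failed: {exc}") from exc
    db = proc.stdout.splitlines()[1].split()[0]
    pairs: list[int | None] = [None] * len(s)
    opens: list[int] = []
    n_pairs = 0
    for i, c in enumerate(db):
        if c == "(":
            opens.append(i)
        elif c == ")":
            j = opens.pop()
            pairs[i], pairs[j] = j, i
            n_pairs += 1
    return FoldResult(s, pairs, n_pairs)


@dataclass
class HairpinCriteria:
    """Stem-loop acceptance thresholds (plant-miRNA annotation practice).

    All values are configurable; they are declared assumptions of this
    pipeline, not reconstructions of any particular study's settings.
    """

    min_loop: int = 3
    max_duplex_mismatch: int = 4  # unpaired mature bases tolerated in the duplex
    max_bulge: int = 2  # largest asymmetric gap inside the duplex
    min_mature_paired_frac: float = 0.60
    min_arm_clearance_from_loop: int = 3  # paired stem nt between mature and loop
    flank: int = 250  # precursor window extension on the star-distal side
    star_tolerance: int = 1  # +/- nt allowed when matching sequenced star reads

    def __post_init__(self) -> None:
        for name in (
            "min_loop",
            "max_duplex_mismatch",
            "max_bulge",
            "min_arm_clearance_from_loop",
            "flank",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PrecursorWindow:
    """A candidate precursor window, oriented 5'->3' on the mature strand.

    ``start``/``end`` are 0-based half-open scaffold coordinates; for
    antisense occurrences the window sequence is the reverse complement
    of the scaffold slice and ``mature_offset`` refers to the oriented
    sequence.
    """

    scaffold_id: str
    start: int
    end: int
    strand: str
    sequence: str
    mature_offset: int
    mature_len: int


def extract_precursor_windows(
    seq: str,
    scaffold_id: str,
    scaffold_seq: str,
    flank: int = 250,
    inner: int = 15,
) -> list[PrecursorWindow]:
    """Candidate windows around each exact occurrence of *seq* on either strand.

    Each occurrence yields two windows testing the mature-on-5'-arm and
    mature-on-3'-arm hypotheses: ``[occ_start - flank, occ_end + inner)``
    and ``[occ_start - inner, occ_end + flank)``, clipped to scaffold
    bounds.  No occurrence yields an empty list.
    """
    seq = to_dna(seq)
    scaffold_seq = to_dna(scaffold_seq)
    L = len(scaffold_seq)
    windows: list[PrecursorWindow] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        pos = scaffold_seq.find(query)
        while pos >= 0:
            occ_start, occ_end = pos, pos + len(query)
            for ws, we in (
                (occ_start - flank, occ_end + inner),
                (occ_start - inner, occ_end + flank),
            ):
                ws, we = max(0, ws), min(L, we)
                frag = scaffold_seq[ws:we]
                if strand == "+":
                    oriented, mo = frag, occ_start - ws
                else:
                    oriented, mo = revcomp(frag), we - occ_end
                windows.append(
                    PrecursorWindow(
                        scaffold_id, ws, we, strand, oriented, mo, len(seq)
                    )
                )
            pos = scaffold_seq.find(query, pos + 1)
    return windows


@dataclass
class HairpinEvaluation:
    status: str  # 'pass' or a machine-readable rejection reason
    arm: str | None = None  # '5p' | '3p'
    star_offset: int | None = None  # oriented window coordinates
    star_len: int | None = None
    fold: FoldResult | None = None

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def _terminal_loop(
    pairs: Sequence[int | None], i: int, j: int
) -> tuple[int, int]:
    """Walk inward from pair (i, j) to the innermost pair before the loop."""
    while True:
        nxt = None
        for a in range(i + 1, j):
            p = pairs[a]
            if p is not None and a < p <= j:
                nxt = (a, p)
                break
        if nxt is None:
            return i, j
        i, j = nxt


def evaluate_hairpin(
    window_seq: str,
    mature_offset: int,
    mature_len: int,
    criteria: HairpinCriteria | None = None,
    fold_fn: Callable[[str, int], FoldResult] | None = None,
) -> HairpinEvaluation:
    """Fold a precursor window and test the mature/star duplex geometry.

    Rejection reasons: ``loop_overlap`` (mature pairs with itself or
    covers the terminal loop), ``low_pairing``, ``duplex_mismatch`` (too
    many unpaired mature bases), ``mixed_arms``, ``duplex_disordered``,
    ``bulge``, ``loop_clearance``.  Clearance is measured from the
    mature's loop-distal end to the terminal loop, so a mature ending
    flush against the loop of an ample stem is acceptable while a mature
    squeezed against the loop on a tiny stem is not.  On a pass, the
    predicted star locus is the mature's pairing span shifted by 2 nt so
    that both duplex strands carry 2-nt 3' overhangs.
    """
    crit = criteria or HairpinCriteria()
    folder = fold_fn or fold_max_pairing
    fold = folder(window_seq, crit.min_loop)
    mo, me = mature_offset, mature_offset + mature_len
    if not (0 <= mo < me <= len(fold.sequence)):
        raise ValueError("mature must lie inside the window")
    partners = [(i, fold.pairs[i]) for i in range(mo, me) if fold.pairs[i] is not None]
    if any(mo <= p < me for _, p in partners):
        return HairpinEvaluation("loop_overlap", fold=fold)
    if len(partners) / mature_len < crit.min_mature_paired_frac:
        return HairpinEvaluation("low_pairing", fold=fold)
    if mature_len - len(partners) > crit.max_duplex_mismatch:
        return HairpinEvaluation("duplex_mismatch", fold=fold)
    ps = [p for _, p in partners]
    if all(p >= me for p in ps):
        arm = "5p"
    elif all(p < mo for p in ps):
        arm = "3p"
    else:
        return HairpinEvaluation("mixed_arms", fold=fold)
    # clean antiparallel duplex: partners strictly decrease along the mature
    for (m1, p1), (m2, p2) in zip(partners, partners[1:]):
        if p2 >= p1:
            return HairpinEvaluation("duplex_disordered", arm=arm, fold=fold)
        gap_m = m2 - m1 - 1
        gap_p = p1 - p2 - 1
        if max(gap_m, gap_p) > crit.max_bulge:
            return HairpinEvaluation("bulge", arm=arm, fold=fold)
    if arm == "5p":
        li, lj = _terminal_loop(fold.pairs, partners[-1][0], partners[-1][1])
        clearance = (li + 1) - mo  # mature start to loop start
    else:
        li, lj = _terminal_loop(fold.pairs, partners[0][1], partners[0][0])
        clearance = me - lj  # loop end to mature end
    if mo < lj and me > li + 1:  # mature span intersects the loop interior
        return HairpinEvaluation("loop_overlap", arm=arm, fold=fold)
    if clearance < crit.min_arm_clearance_from_loop:
        return HairpinEvaluation("loop_clearance", arm=arm, fold=fold)
    lo, hi = min(ps), max(ps)
    return HairpinEvaluation(
        "pass", arm=arm, star_offset=lo + 2, star_len=hi - lo + 1, fold=fold
    )


@dataclass
class HairpinCandidate:
    """One evaluated precursor hypothesis for a mature sequence."""

    mature_seq: str
    scaffold_id: str
    window_start: int
    window_end: int
    strand: str
    evaluation: HairpinEvaluation
    mature_offset: int  # oriented window coordinates
    star_seq_predicted: str | None = None
    star_observed_seq: str | None = None
    star_observed_counts: dict[str, int] = field(default_factory=dict)
    verdict: str = "rejected"  # 'novel' | 'candidate' | 'rejected'

    @property
    def reject_reason(self) -> str | None:
        return None if self.evaluation.passed else self.evaluation.status


def _star_variants(
    window_seq: str, star_offset: int, star_len: int, tol: int
) -> list[str]:
    """Window substrings whose placement is within *tol* nt at either end."""
    out: list[str] = []
    shifts = sorted(range(-tol, tol + 1), key=abs)
    for ds in shifts:
        for de in shifts:
            s, e = star_offset + ds, star_offset + star_len + de
            if 0 <= s < e <= len(window_seq):
                sub = window_seq[s:e]
                if sub not in out:
                    out.append(sub)
    return out


def classify_novel(
    candidates: Iterable[HairpinCandidate],
    collapsed: Mapping[str, CollapsedRead],
    criteria: HairpinCriteria | None = None,
) -> list[HairpinCandidate]:
    """Split passing candidates into ``novel`` vs ``candidate`` by star evidence.

    A sequenced read whose placement matches the predicted star locus
    within the star tolerance (+/-1 nt at either end by default) and has
    at least one read promotes the candidate to ``novel``; otherwise it
    stays ``candidate``.  Rejected candidates are passed through.
    """
    crit = criteria or HairpinCriteria()
    out: list[HairpinCandidate] = []
    for cand in candidates:
        ev = cand.evaluation
        if not ev.passed:
            cand.verdict = "rejected"
            out.append(cand)
            continue
        window_seq = ev.fold.sequence
        s, e = ev.star_offset, ev.star_offset + ev.star_len
        cand.star_seq_predicted = window_seq[max(0, s) : min(len(window_seq), e)]
        cand.verdict = "candidate"
        for variant in _star_variants(window_seq, s, e - s, crit.star_tolerance):
            cr = collapsed.get(variant)
            if cr is not None and cr.total >= 1:
                cand.star_observed_seq = variant
                cand.star_observed_counts = dict(cr.counts)
                cand.verdict = "novel"
                break
        out.append(cand)
    return out


def discover_mirnas(
    unknown: Mapping[str, CollapsedRead],
    scaffolds: Sequence[tuple[str, str]],
    criteria: HairpinCriteria | None = None,
    fold_fn: Callable[[str, int], FoldResult] | None = None,
    min_reads: int = 1,
) -> list[HairpinCandidate]:
    """Full discovery step over a set of unannotated collapsed reads.

    For every unannotated sequence with at least *min_reads* total reads,
    locate exact occurrences on the scaffolds, evaluate both precursor
    window hypotheses per occurrence (keeping the best: first passing
    window, else the first evaluation), then classify by star evidence
    against the same unannotated read set.  The output order is
    deterministic (descending total count, then sequence).
    """
    crit = criteria or HairpinCriteria()
    order = sorted(unknown.items(), key=lambda kv: (-kv[1].total, kv[0]))
    candidates: list[HairpinCandidate] = []
    for seq, cr in order:
        if cr.total < min_reads:
            continue
        for scaffold_id, scaffold_seq in scaffolds:
            windows = extract_precursor_windows(
                seq, scaffold_id, to_dna(scaffold_seq), flank=crit.flank
            )
            # group the two window hypotheses of one (occurrence, strand)
            by_occ: dict[tuple[str, int], list[PrecursorWindow]] = {}
            for w in windows:
                occ = (
                    w.start + w.mature_offset
                    if w.strand == "+"
                    else w.end - w.mature_offset
                )
                by_occ.setdefault((w.strand, occ), []).append(w)
            for wins in by_occ.values():
                chosen: tuple[PrecursorWindow, HairpinEvaluation] | None = None
                for w in wins:
                    ev = evaluate_hairpin(
                        w.sequence, w.mature_offset, w.mature_len, crit, fold_fn
                    )
                    if chosen is None or (ev.passed and not chosen[1].passed):
                        chosen = (w, ev)
                    if ev.passed:
                        break
                w, ev = chosen
                candidates.append(
                    HairpinCandidate(
                        mature_seq=seq,
                        scaffold_id=scaffold_id,
                        window_start=w.start,
                        window_end=w.end,
                        strand=w.strand,
                        evaluation=ev,
                        mature_offset=w.mature_offset,
                    )
                )
    return classify_novel(candidates, unknown, crit)


def locus_verdicts(candidates: Iterable[HairpinCandidate]) -> dict[str, str]:
    """Best verdict per scaffold locus (novel > candidate; rejected ignored)."""
    rank = {"novel": 2, "candidate": 1}
    out: dict[str, str] = {}
    for c in candidates:
        r = rank.get(c.verdict)
        if r is None:
            continue
        if rank.get(out.get(c.scaffold_id, ""), 0) < r:
            out[c.scaffold_id] = c.verdict
    return out


def candidates_table(
    candidates: Sequence[HairpinCandidate], libraries: Sequence[str] = ()
) -> pd.DataFrame:
    """Flatten candidates into the discovery report table."""
    rows = []
    for c in candidates:
        ev = c.evaluation
        row = {
            "mature_seq": c.mature_seq,
            "scaffold": c.scaffold_id,
            "window_start": c.window_start,
            "window_end": c.window_end,
            "strand": c.strand,
            "arm": ev.arm or "",
            "n_pairs": ev.fold.n_pairs if ev.fold else 0,
            "star_seq_predicted": c.star_seq_predicted or "",
        }
        for lib in libraries:
            row[f"star_reads_{lib}"] = c.star_observed_counts.get(lib, 0)
        row["verdict"] = c.verdict
        row["reject_reason"] = c.reject_reason or ""
        rows.append(row)
    cols = [
        "mature_seq",
        "scaffold",
        "window_start",
        "window_end",
        "strand",
        "arm",
        "n_pairs",
        "star_seq_predicted",
        *(f"star_reads_{lib}" for lib in libraries),
        "verdict",
        "reject_reason",
    ]
    return pd.DataFrame(rows, columns=cols)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Shuffle *seq* preserving its dinucleotide composition.

    Random walk over the shuffled dinucleotide edge multigraph with
    rejection when the walk strands edges (retried up to *max_tries*);
    used for shuffle-control experiments on hairpin windows.
    """
    s = to_dna(seq)
    if len(s) < 3:
        return s
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(s, s[1:]):
            edges.setdefault(a, []).append(b)
        for lst in edges.values():
            rng.shuffle(lst)
        walk = [s[0]]
        cur = s[0]
        ok = True
        for _step in range(len(s) - 1):
            nxt_list = edges.get(cur)
            if not nxt_list:
                ok = False
                break
            cur = nxt_list.pop()
            walk.append(cur)
        if ok:
            return "".join(walk)
    return s  # extremely repetitive input: give up, return unshuffled
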