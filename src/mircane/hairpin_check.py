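"""Nine-criteria validation of candidate miRNA precursors.

A candidate (precursor window + secondary structure + the mature match
that seeded it) is accepted only if all nine structural criteria hold:

1. the mature/star duplex lies on a single stem (the structure pairs the
   mature region, and no position inside the star span pairs outside the
   mature region);
2. the mature sits within one arm (it does not span the terminal loop);
3. the mature lies on the same arm (5p/3p) as its homolog in the species
   the query came from (auto-pass when the arm is unknown);
4. the mature has between one and six mismatches with the star;
5. the star is unbroken: no extra unpaired nucleotides (star-side bulges)
   beyond those facing mature mismatches;
6. on the trimmed stem-loop: MFEI above the cutoff (default 0.65),
   negative MFE, and GC content within 30-70%;
7. at most two consecutive mature mismatches;
8. at least two base pairs in the mature/star duplex;
9. the trimmed stem-loop spans at least 60 nt.

Mismatch bookkeeping: a mature position is a *mismatch* when it is
unpaired, except positions lying inside a terminal hairpin loop, which
are not scored against the star (they face no opposite strand).  The
trimmed stem-loop is the minimal well-formed hairpin containing mature,
star and loop: starting from the duplex span, enclosing base pairs are
added outward as long as they continue the same stem (crossing interior
loops and bulges, stopping at branch points).  GC%, MFE, AMFE, MFEI and
the length criterion are evaluated on this trimmed region, matching the
convention of reporting precursor lengths far below the raw scan window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .homology_scan import MatureQuery, PrecursorWindow
from .seqio import gc_percent
from .structure import (DEFAULT_PAIR_WEIGHTS, FoldResult, amfe as _amfe,
                        mfei as _mfei, pair_weight)

CRITERIA = tuple(f"c{i}" for i in range(1, 10))


@dataclass
class CheckConfig:
    """Thresholds for the nine precursor criteria (defaults as published)."""

    mfei_min: float = 0.65
    gc_min: float = 30.0
    gc_max: float = 70.0
    min_duplex_mismatches: int = 1
    max_duplex_mismatches: int = 6
    max_consecutive_mismatches: int = 2
    min_paired: int = 2
    min_stemloop_len: int = 60


@dataclass
class DuplexStats:
    """Pairing statistics of the mature/star duplex.

    ``star_start``/``star_end`` are the inclusive bounds of the span of
    all partners of paired mature positions (``None`` when the mature is
    fully unpaired).  ``foreign_pairs`` counts star-span positions paired
    outside the mature region (a branch interrupting the stem);
    ``star_gaps`` counts unpaired star-span positions, i.e. gaps facing
    mature mismatches plus any star-side bulges.
    """

    star_start: Optional[int]
    star_end: Optional[int]
    paired_count: int
    mismatch_count: int
    max_consecutive_mismatches: int
    mature_arm: str  # 5p | 3p | spans_loop
    foreign_pairs: int
    star_gaps: int

    @property
    def star_contiguous(self) -> bool:
        """True when the star carries no breaks beyond facing gaps."""
        return self.star_start is not None and self.star_gaps <= self.mismatch_count


def _in_terminal_loop(pairing: List[Optional[int]], p: int) -> bool:
    """True if unpaired position ``p`` lies inside a hairpin loop.

    The nearest paired positions on each side must pair with each other;
    dangling ends (no paired position on one side) are not loops.
    """
    left = p - 1
    while left >= 0 and pairing[left] is None:
        left -= 1
    right = p + 1
    while right < len(pairing) and pairing[right] is None:
        right += 1
    if left < 0 or right >= len(pairing):
        return False
    return pairing[left] == right


def locate_star(fold: FoldResult, mature_start: int, mature_len: int) -> DuplexStats:
    """Infer the miRNA* region and duplex statistics from a structure."""
    n = len(fold.residues)
    if not (0 <= mature_start and mature_start + mature_len <= n):
        raise ValueError("mature region outside the folded sequence")
    pairing = fold.pairing
    mature = range(mature_start, mature_start + mature_len)
    mature_set = set(mature)

    partners = [pairing[p] for p in mature if pairing[p] is not None]
    paired_count = len(partners)

    mismatches = []
    for p in mature:
        if pairing[p] is None and not _in_terminal_loop(pairing, p):
            mismatches.append(p)
    mismatch_count = len(mismatches)

    # longest run of consecutive mismatch positions (paired or
    # loop-excluded positions break a run)
    max_run = run = 0
    mismatch_set = set(mismatches)
    for p in mature:
        if p in mismatch_set:
            run += 1
            max_run = max(max_run, run)
        else:
            run = 0

    if paired_count == 0:
        return DuplexStats(None, None, 0, mismatch_count, max_run,
                           "spans_loop", 0, 0)

    if all(pairing[p] > p for p in mature if pairing[p] is not None):
        arm = "5p"
    elif all(pairing[p] < p for p in mature if pairing[p] is not None):
        arm = "3p"
    else:
        arm = "spans_loop"

    star_start, star_end = min(partners), max(partners)
    foreign = 0
    gaps = 0
    for s in range(star_start, star_end + 1):
        if s in mature_set:
            continue
        if pairing[s] is None:
            gaps += 1
        elif pairing[s] not in mature_set:
            foreign += 1
    return DuplexStats(star_start, star_end, paired_count, mismatch_count,
                       max_run, arm, foreign, gaps)


def trim_stemloop(pairing: List[Optional[int]], lo: int, hi: int) -> Tuple[int, int]:
    """Extend a duplex span outward along its stem.

    From the inclusive span ``[lo, hi]``, repeatedly adopt the next
    enclosing base pair provided no branch intervenes (all positions
    between the current span and the enclosing partner are unpaired).
    Returns the inclusive bounds of the trimmed stem-loop.
    """
    n = len(pairing)
    while True:
        p = lo - 1
        while p >= 0 and pairing[p] is None:
            p -= 1
        if p < 0:
            break
        q = pairing[p]
        if q is None or q <= hi:
            break
        if any(pairing[x] is not None for x in range(hi + 1, q)):
            break
        lo, hi = p, q
    return lo, hi


@dataclass
class HairpinReport:
    """Structured verdict for one candidate precursor."""

    window: PrecursorWindow
    fold: FoldResult
    duplex: DuplexStats
    trimmed_start: int
    trimmed_end: int  # inclusive
    gc_percent: float
    mfe_kcal: float
    amfe: float
    mfei: float
    criteria: Dict[str, bool]
    verdict: bool

    @property
    def trimmed_len(self) -> int:
        return self.trimmed_end - self.trimmed_start + 1

    @property
    def failed(self) -> List[str]:
        return [c for c in CRITERIA if not self.criteria[c]]


def _trimmed_energy(fold: FoldResult, lo: int, hi: int) -> float:
    """Model energy of the trimmed region.

    Built-in structures sum their pair weights over pairs inside the
    region; external structures use the file energy when available (the
    published workflow evaluated mfold energies of the trimmed
    precursor), falling back to the built-in weights otherwise.
    """
    if fold.source != "builtin" and fold.mfe_kcal is not None:
        return fold.mfe_kcal
    return sum(
        pair_weight(fold.residues[i], fold.residues[j], DEFAULT_PAIR_WEIGHTS)
        for i, j in fold.pairs()
        if lo <= i and j <= hi
    )


def check(window: PrecursorWindow, fold: FoldResult, query: MatureQuery,
          config: CheckConfig = CheckConfig()) -> HairpinReport:
    """Evaluate a candidate against the nine precursor criteria.

    Failures are recorded in the report, never raised; the verdict is
    accept iff every criterion passes.
    """
    if fold.residues != window.residues:
        raise ValueError("fold was not computed over the window residues")
    stats = locate_star(fold, window.mature_offset, window.mature_len)

    m_lo = window.mature_offset
    m_hi = window.mature_offset + window.mature_len - 1
    if stats.star_start is not None:
        lo = min(m_lo, stats.star_start)
        hi = max(m_hi, stats.star_end)
    else:
        lo, hi = m_lo, m_hi
    lo, hi = trim_stemloop(fold.pairing, lo, hi)

    region = window.residues[lo:hi + 1]
    gc = gc_percent(region)
    mfe = _trimmed_energy(fold, lo, hi)
    region_amfe = _amfe(min(mfe, 0.0), len(region))
    region_mfei = region_amfe / gc if gc > 0 else 0.0

    crit = {
        "c1": stats.paired_count > 0 and stats.foreign_pairs == 0,
        "c2": stats.paired_count > 0 and stats.mature_arm != "spans_loop",
        "c3": query.expected_arm == "unknown"
              or stats.mature_arm == query.expected_arm,
        "c4": config.min_duplex_mismatches <= stats.mismatch_count
              <= config.max_duplex_mismatches,
        "c5": stats.star_contiguous,
        "c6": region_mfei > config.mfei_min and mfe < 0
              and config.gc_min <= gc <= config.gc_max,
        "c7": stats.max_consecutive_mismatches
              <= config.max_consecutive_mismatches,
        "c8": stats.paired_count >= config.min_paired,
        "c9": (hi - lo + 1) >= config.min_stemloop_len,
    }
    return HairpinReport(window, fold, stats, lo, hi, gc, mfe,
                         region_amfe, region_mfei, crit, all(crit.values()))
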