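"""Block-filtered, point-scored prediction of miRNA target sites.

Plant miRNAs guide cleavage of near-perfectly complementary mRNA sites,
so targets can be found by scoring antiparallel miRNA:mRNA duplexes.  The
predictor works in two stages:

**Block pre-filter.**  The miRNA is divided 5'->3' into three blocks of
eight (block 1, positions 1-8), three (block 2, positions 9-11) and
nominally ten nucleotides (block 3, position 12 to the 3' end; miRNAs
shorter or longer than 21 nt absorb the difference in block 3).  A
candidate window passes when the number of non-Watson-Crick positions
per block is at most (2, 0, 3).  Block 2 spans the canonical cleavage
site opposite miRNA position 10, which tolerates no mispairing.  G:U
wobbles count as mismatches at this stage.

**Duplex score.**  Passing windows (and windows one or two nucleotides
longer or shorter, to accommodate bulges) are aligned against the miRNA
by a dynamic program minimising the penalty: Watson-Crick pair 0, G:U
wobble pair 0.5, non-G:U mismatch 1, each bulged nucleotide on either
strand 1.5.  Sites scoring at most 3.5 points are accepted.  Finally,
hits on near-identical transcripts (at least 95% identity) are collapsed
to one target gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from . import redundancy
from .homology_scan import MatureQuery
from .seqio import SequenceRecord

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

#: per-defect penalties, in half-point integer units for exact DP arithmetic
_UNIT_GU = 1       # 0.5 points
_UNIT_MM = 2       # 1.0 point
_UNIT_BULGE = 3    # 1.5 points

BLOCK_CAPS = (2, 0, 3)


def _pair_class(mirna_base: str, site_base: str) -> str:
    if (mirna_base, site_base) in _WC:
        return "wc"
    if (mirna_base, site_base) in _GU:
        return "gu"
    return "mm"


def block_bounds(length: int) -> Tuple[Tuple[int, int], ...]:
    """Half-open block bounds along the miRNA (0-based): 8 / 3 / remainder."""
    if length < 12:
        raise ValueError("miRNA shorter than 12 nt cannot be block-partitioned")
    return ((0, 8), (8, 11), (11, length))


def block_filter(mirna: str, site: str,
                 caps: Tuple[int, int, int] = BLOCK_CAPS,
                 gu_is_block_match: bool = False
                 ) -> Tuple[bool, Tuple[int, int, int]]:
    """Count per-block non-complementary positions of an ungapped duplex.

    ``site`` is the message 5'->3' and must have the miRNA's length; the
    duplex is antiparallel, so miRNA position ``i`` faces site position
    ``L - 1 - i``.  G:U wobbles count as mismatches unless
    ``gu_is_block_match`` is set.
    """
    L = len(mirna)
    if len(site) != L:
        raise ValueError(f"block_filter needs equal lengths, got {L} vs "
                         f"{len(site)} (the pre-filter stage is ungapped)")
    mism = []
    for lo, hi in block_bounds(L):
        count = 0
        for i in range(lo, hi):
            cls = _pair_class(mirna[i], site[L - 1 - i])
            if cls == "mm" or (cls == "gu" and not gu_is_block_match):
                count += 1
        mism.append(count)
    counts = tuple(mism)
    return all(c <= cap for c, cap in zip(counts, caps)), counts


@dataclass(frozen=True)
class DuplexAlignment:
    """An antiparallel miRNA:site alignment with its decomposed score.

    ``columns`` runs along the miRNA 5'->3'; entries are ``wc``, ``gu``,
    ``mm``, ``bulge_mirna`` (unpaired miRNA nucleotide) or
    ``bulge_target`` (unpaired site nucleotide).
    """

    mirna: str
    site: str
    columns: Tuple[str, ...]
    n_gu: int
    n_mismatch: int
    n_bulged: int

    @property
    def score_gu(self) -> float:
        return 0.5 * self.n_gu

    @property
    def score_mismatch(self) -> float:
        return float(self.n_mismatch)

    @property
    def score_bulge(self) -> float:
        return 1.5 * self.n_bulged

    @property
    def score_total(self) -> float:
        return self.score_gu + self.score_mismatch + self.score_bulge


def align_duplex(mirna: str, site_region: str,
                 max_bulges: int = 2) -> DuplexAlignment:
    """Minimum-penalty antiparallel alignment of a miRNA against a site.

    At most ``max_bulges`` bulged nucleotides are allowed in total (two
    bulges already cost 3.0 of the 3.5-point budget, so deeper bulging
    can never rescue a site).  Ties are broken toward fewer bulges, then
    toward bulges closest to the miRNA 5' end.
    """
    diff = len(site_region) - len(mirna)
    if abs(diff) > max_bulges:
        raise ValueError(
            f"site length {len(site_region)} differs from miRNA length "
            f"{len(mirna)} by more than max_bulges={max_bulges}"
        )
    # align the miRNA 5'->3' against the reversed site so that both run
    # in the same direction; t[j] faces mirna[i]
    t = site_region[::-1]
    n, m = len(mirna), len(t)
    INF = 10 ** 9
    # cost[g][j]: best cost for mirna[:i], t[:j] with g bulged nucleotides;
    # primary key the half-point score, encoded * 8 plus bulge count for
    # the fewer-bulges tie-break
    prev = [[INF] * (m + 1) for _ in range(max_bulges + 1)]
    prev[0][0] = 0
    for g in range(1, max_bulges + 1):
        prev[g][0] = INF
    for j in range(1, m + 1):
        for g in range(1, max_bulges + 1):
            prev[g][j] = prev[g - 1][j - 1] + _UNIT_BULGE * 8 + 1
    choice: List[List[List[Optional[str]]]] = [
        [[None] * (m + 1) for _ in range(max_bulges + 1)] for _ in range(n + 1)
    ]
    rows = [prev]
    for i in range(1, n + 1):
        cur = [[INF] * (m + 1) for _ in range(max_bulges + 1)]
        for g in range(max_bulges + 1):
            for j in range(0, m + 1):
                best, move = INF, None
                if j >= 1:
                    cls = _pair_class(mirna[i - 1], t[j - 1])
                    unit = {"wc": 0, "gu": _UNIT_GU, "mm": _UNIT_MM}[cls]
                    cand = prev[g][j - 1] + unit * 8
                    if cand < best:
                        best, move = cand, cls
                if g >= 1:
                    cand = prev[g - 1][j] + _UNIT_BULGE * 8 + 1
                    if cand < best:
                        best, move = cand, "bulge_mirna"
                    if j >= 1:
                        cand = cur[g - 1][j - 1] + _UNIT_BULGE * 8 + 1
                        if cand < best:
                            best, move = cand, "bulge_target"
                cur[g][j] = best
                choice[i][g][j] = move
        rows.append(cur)
        prev = cur
    g_best = min(range(max_bulges + 1), key=lambda g: (prev[g][m], g))
    if prev[g_best][m] >= INF:
        raise ValueError("no alignment within the bulge budget")
    # traceback
    cols: List[str] = []
    i, g, j = n, g_best, m
    while i > 0 or j > 0:
        if i == 0:
            move = "bulge_target"
        else:
            move = choice[i][g][j]
        if move is None and i > 0:
            # only reachable through leading target bulges at i == 0
            move = "bulge_mirna"
        if move in ("wc", "gu", "mm"):
            cols.append(move)
            i, j = i - 1, j - 1
        elif move == "bulge_mirna":
            cols.append(move)
            i, g = i - 1, g - 1
        else:
            cols.append("bulge_target")
            j, g = j - 1, g - 1
    cols.reverse()
    n_gu = cols.count("gu")
    n_mm = cols.count("mm")
    n_bulge = cols.count("bulge_mirna") + cols.count("bulge_target")
    return DuplexAlignment(mirna, site_region, tuple(cols), n_gu, n_mm, n_bulge)


@dataclass(frozen=True)
class TargetHit:
    """An accepted target site on a transcript (0-based half-open)."""

    target_id: str
    site_start: int
    site_end: int
    family: str
    block_mismatches: Tuple[int, int, int]
    alignment: DuplexAlignment
    accepted: bool


def _best_site_at(mirna: str, transcript: str, start: int, threshold: float,
                  max_bulges: int, block_counts: Tuple[int, int, int]
                  ) -> Optional[TargetHit]:
    L = len(mirna)
    best: Optional[Tuple[float, int, DuplexAlignment]] = None
    for d in range(-max_bulges, max_bulges + 1):
        end = start + L + d
        if end > len(transcript) or end <= start:
            continue
        aln = align_duplex(mirna, transcript[start:end], max_bulges)
        key = (aln.score_total, abs(d), d)
        if best is None or key < (best[0], abs(best[1]), best[1]):
            best = (aln.score_total, d, aln)
    if best is None or best[0] > threshold:
        return None
    return TargetHit("", start, start + L + best[1], "",
                     block_counts, best[2], True)


def scan_targets(mirnas: Sequence[MatureQuery],
                 transcripts: Sequence[SequenceRecord],
                 threshold: float = 3.5,
                 max_bulges: int = 2,
                 caps: Tuple[int, int, int] = BLOCK_CAPS,
                 gu_is_block_match: bool = False,
                 collapse_identity: float = 95.0) -> List[TargetHit]:
    """Predict target sites for a set of miRNAs over sense-strand mRNAs.

    Every same-length window is block-filtered; passing windows are
    rescored by :func:`align_duplex` over window lengths within
    ``max_bulges`` of the miRNA length, and sites scoring at most
    ``threshold`` are kept.  Overlapping sites of one miRNA on one
    transcript collapse to the best-scoring one, and near-identical
    transcripts (>= ``collapse_identity`` %) report a single target.
    """
    raw: List[TargetHit] = []
    for query in mirnas:
        mirna = query.residues
        L = len(mirna)
        for rec in transcripts:
            hits_here: List[TargetHit] = []
            for start in range(0, len(rec.residues) - L + 1):
                ok, counts = block_filter(mirna, rec.residues[start:start + L],
                                          caps, gu_is_block_match)
                if not ok:
                    continue
                hit = _best_site_at(mirna, rec.residues, start, threshold,
                                    max_bulges, counts)
                if hit is not None:
                    hits_here.append(TargetHit(
                        rec.id, hit.site_start, hit.site_end, query.family,
                        hit.block_mismatches, hit.alignment, True))
            # collapse overlapping windows of the same site
            hits_here.sort(key=lambda h: (h.alignment.score_total,
                                          h.site_start, h.site_end))
            kept: List[TargetHit] = []
            for h in hits_here:
                if all(h.site_end <= k.site_start or h.site_start >= k.site_end
                       for k in kept):
                    kept.append(h)
            raw.extend(kept)

    if not raw:
        return []
    # one target gene per cluster of near-identical transcripts
    involved = sorted({h.target_id for h in raw})
    by_id = {rec.id: rec for rec in transcripts}
    clusters = redundancy.cluster([by_id[i] for i in involved],
                                  threshold=collapse_identity, strict=False)
    rep_of = {m: c.representative for c in clusters for m in c.members}
    chosen: Dict[Tuple[str, str], TargetHit] = {}
    for h in raw:
        rep = rep_of[h.target_id]
        key = (h.family, rep)
        prev = chosen.get(key)
        if (prev is None
                or (h.alignment.score_total, h.target_id, h.site_start)
                < (prev.alignment.score_total, prev.target_id, prev.site_start)):
            chosen[key] = h
    out = list(chosen.values())
    out.sort(key=lambda h: (h.family, h.target_id, h.site_start))
    return out
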