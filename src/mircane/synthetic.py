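"""Synthetic EST databases with known ground truth.

Every pipeline stage is testable without downloads: this module builds
FASTA-ready databases of decoys (random sequences, GC-extreme sequences,
tandem repeats, MITE-like terminal inverted repeats) with embedded true
precursors — a mature and its star on one arm of a foldable hairpin —
plus engineered miRNA target sites of known penalty, and writes a truth
sidecar recording what the pipeline is expected to report for each
record.

Constructions are letter-aware: designed mismatches, bulges and loops
use nucleotides chosen so they cannot pair elsewhere in the designed
stem, which keeps the maximum-weight fold equal to the intended
structure.  Each construct is verified by folding and checking it at
generation time; a construct whose verification fails is redrawn from
the random stream (deterministically, so a fixed seed always yields
byte-identical output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .hairpin_check import CheckConfig, check
from .homology_scan import MatureQuery, PrecursorWindow
from .seqio import SequenceRecord, reverse_complement
from .structure import fold

log = logging.getLogger(__name__)

_PARTNERS = {"A": "U", "C": "G", "G": "CU", "U": "AG"}


class ConstructionError(ValueError):
    """Raised when a requested construct is infeasible."""


def _nonpairing_letter(avoid: str) -> str:
    """A nucleotide that cannot base-pair with any letter in ``avoid``."""
    for letter in "ACGU":
        if not any(a in _PARTNERS[letter] for a in set(avoid)):
            return letter
    raise ConstructionError(
        f"no nucleotide avoids pairing with all of {sorted(set(avoid))!r}"
    )


def _rand_rna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=n, p=p))


def _rand_mature(rng: np.random.Generator, length: int = 21) -> str:
    return _rand_rna(rng, length)


# --- truth records ---------------------------------------------------------

@dataclass
class TruthRecord:
    """Expected pipeline outcome for one synthetic record."""

    record_id: str
    category: str            # embedded_precursor | knockout_<c#> | decoy_*
    family: str = ""
    expected_verdict: str = "none"   # accept | reject | none (never scanned)
    expected_failed: Tuple[str, ...] = ()
    mature_offset: int = -1
    mature_len: int = 0


def truth_frame(truths: Sequence[TruthRecord]):
    import pandas as pd

    return pd.DataFrame([
        {"record_id": t.record_id, "category": t.category, "family": t.family,
         "expected_verdict": t.expected_verdict,
         "expected_failed": ",".join(t.expected_failed),
         "mature_offset": t.mature_offset, "mature_len": t.mature_len}
        for t in truths
    ])


# --- precursor constructs --------------------------------------------------

def _choose_mismatch_positions(rng: np.random.Generator, mature: str,
                               count: int, max_run: int = 2) -> List[int]:
    """Interior mature positions for designed mismatches.

    Runs are capped at ``max_run`` and each run must admit a star-side
    letter that pairs none of the run's mature letters.
    """
    L = len(mature)
    candidates = list(range(2, L - 2))
    for _ in range(200):
        rng.shuffle(candidates)
        chosen: List[int] = []
        for p in candidates:
            if len(chosen) == count:
                break
            trial = sorted(chosen + [p])
            runs, run = [], [trial[0]]
            for x in trial[1:]:
                if x == run[-1] + 1:
                    run.append(x)
                else:
                    runs.append(run)
                    run = [x]
            runs.append(run)
            if any(len(r) > max_run for r in runs):
                continue
            try:
                for r in runs:
                    _nonpairing_letter("".join(mature[i] for i in r))
            except ConstructionError:
                continue
            chosen.append(p)
        if len(chosen) == count:
            return sorted(chosen)
    raise ConstructionError(
        f"cannot place {count} mismatches with runs <= {max_run} in "
        f"{mature!r}"
    )


def _star_with_mismatches(mature: str, positions: Sequence[int]) -> str:
    """Reverse complement of the mature with designed mismatch columns."""
    L = len(mature)
    star = list(reverse_complement(mature))
    pos = sorted(positions)
    runs: List[List[int]] = []
    for p in pos:
        if runs and p == runs[-1][-1] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    for r in runs:
        letter = _nonpairing_letter("".join(mature[i] for i in r))
        for p in r:
            star[L - 1 - p] = letter
    return "".join(star)


def _loop(rng: np.random.Generator, n: int, boundary: str = "") -> str:
    """Terminal-loop letters that cannot pair the flanking stem ends.

    A/C strings are internally inert (no A:A, A:C or C:C pairs); letters
    whose partners appear at the stem boundary are additionally excluded
    so the loop cannot compete with the designed closing pair.
    """
    allowed = [l for l in "AC"
               if not any(b in _PARTNERS[l] for b in set(boundary))]
    if not allowed:
        allowed = ["A", "C"]
    return "".join(rng.choice(allowed, size=n))


def _verified(builder, rng: np.random.Generator, attempts: int = 25):
    """Redraw a construct until its folded criteria match expectation."""
    last_exc: Optional[Exception] = None
    for _ in range(attempts):
        try:
            result = builder(rng)
        except ConstructionError as exc:
            last_exc = exc
            continue
        record, query, offset, expected_failed = result
        f = fold(record.residues)
        window = PrecursorWindow(record.id, "+", 0, len(record),
                                 record.residues, offset,
                                 len(query.residues), query)
        report = check(window, f, query)
        if tuple(report.failed) == tuple(expected_failed):
            return record, query, offset, report
        last_exc = ConstructionError(
            f"{record.id}: expected failures {list(expected_failed)}, "
            f"fold gave {report.failed}"
        )
    raise ConstructionError(f"construction did not verify: {last_exc}")


def make_precursor(mature: str, mismatches: int, arm: str = "5p",
                   loop_len: int = 6, flanks: Tuple[int, int] = (50, 50),
                   rng: Optional[np.random.Generator] = None,
                   ext_len: int = 14, record_id: str = "precursor",
                   family: str = "synthetic",
                   gc_mode: str = "balanced"
                   ) -> Tuple[SequenceRecord, TruthRecord]:
    """Build a host sequence containing a designed precursor hairpin.

    The hairpin is ``extension + mature + loop + star + rc(extension)``
    (arm ``5p``; the mature and star swap places for ``3p``), where the
    star is the reverse complement of the mature with ``mismatches``
    designed mismatch columns, and the extension stem pushes the trimmed
    stem-loop above the 60-nt minimum.  ``gc_mode`` ``high`` builds a
    GC-extreme stem that violates the GC-content criterion.  The result
    is verified by folding; the truth record carries the expected verdict
    and failed criteria.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if loop_len < 3:
        raise ConstructionError("terminal loop must be at least 3 nt")
    if mismatches > len(mature) - 4:
        raise ConstructionError("more mismatches than placeable positions")
    if arm not in ("5p", "3p"):
        raise ConstructionError(f"arm must be 5p or 3p, not {arm!r}")

    if mismatches == 0:
        expected_failed = ("c4",)
    elif mismatches > 6:
        expected_failed = ("c4",)
    else:
        expected_failed = ()

    def build(r: np.random.Generator):
        positions = (_choose_mismatch_positions(r, mature, mismatches)
                     if mismatches else [])
        star = _star_with_mismatches(mature, positions)
        gc = 0.9 if gc_mode == "high" else 0.5
        ext = _rand_rna(r, ext_len if gc_mode != "high" else ext_len + 6, gc)
        if arm == "5p":
            loop = _loop(r, loop_len, mature[-1] + star[0])
        else:
            loop = _loop(r, loop_len, star[-1] + mature[0])
        if arm == "5p":
            core = ext + mature + loop + star + reverse_complement(ext)
            offset = flanks[0] + len(ext)
        else:
            core = ext + star + loop + mature + reverse_complement(ext)
            offset = flanks[0] + len(ext) + len(star) + loop_len
        seq = _rand_rna(r, flanks[0]) + core + _rand_rna(r, flanks[1])
        record = SequenceRecord(record_id, seq)
        query = MatureQuery(family, mature, expected_arm=arm)
        failed = expected_failed if gc_mode != "high" else ("c6",)
        return record, query, offset, failed

    record, query, offset, report = _verified(build, rng)
    verdict = "accept" if report.verdict else "reject"
    truth = TruthRecord(record.id, "embedded_precursor", family, verdict,
                        tuple(report.failed), offset, len(mature))
    return record, truth


# --- single-criterion knockouts -------------------------------------------

def _knockout_c1(rng: np.random.Generator):
    """Mature paired across two stems separated by a branch hairpin."""
    def build(r):
        mature = _rand_mature(r)
        bulge_pos = [5, 10, 15]
        L = len(mature)
        star_full = list(reverse_complement(mature))
        keep = [i for i in range(L) if (L - 1 - i) not in bulge_pos]
        # star minus the columns facing bulged mature positions,
        # split into the part pairing the mature 3' half and the part
        # pairing the 5' half
        s1 = "".join(star_full[i] for i in keep if (L - 1 - i) < 10)
        s2 = "".join(star_full[i] for i in keep if (L - 1 - i) >= 10)
        branch_stem = "GGCGG"
        branch = branch_stem + "AAA" + reverse_complement(branch_stem)
        ext = _rand_rna(r, 14)
        core = (ext + mature + _loop(r, 3, mature[-1] + s2[0]) + s2 + branch + s1
                + reverse_complement(ext))
        seq = "AC" + core + "CA"
        record = SequenceRecord("ko_c1", seq)
        query = MatureQuery("ko_c1", mature)
        return record, query, 2 + len(ext), ("c1",)

    return _verified(build, rng)


def _knockout_c2(rng: np.random.Generator):
    """Mature spanning the terminal loop of its own hairpin."""
    def build(r):
        s = _rand_rna(r, 9)
        mature = list(s + "AAC" + reverse_complement(s))
        for i in (2, 5):
            partner = mature[20 - i]
            mature[i] = _nonpairing_letter(partner + "".join(
                mature[j] for j in (20 - i,)))
            mature[i] = _nonpairing_letter(mature[20 - i])
        mature = "".join(mature)
        ext = _rand_rna(r, 20)
        seq = "AC" + ext + mature + reverse_complement(ext) + "CA"
        record = SequenceRecord("ko_c2", seq)
        query = MatureQuery("ko_c2", mature)
        return record, query, 2 + len(ext), ("c2",)

    return _verified(build, rng)


def _knockout_c3(rng: np.random.Generator):
    """Valid 3p-arm precursor scanned with a query annotated 5p."""
    def build(r):
        mature = _rand_mature(r)
        positions = _choose_mismatch_positions(r, mature, 3)
        star = _star_with_mismatches(mature, positions)
        ext = _rand_rna(r, 14)
        core = ext + star + _loop(r, 5, star[-1] + mature[0]) + mature + reverse_complement(ext)
        seq = _rand_rna(r, 30) + core + _rand_rna(r, 30)
        record = SequenceRecord("ko_c3", seq)
        query = MatureQuery("ko_c3", mature, expected_arm="5p")
        offset = 30 + len(ext) + len(star) + 5
        return record, query, offset, ("c3",)

    return _verified(build, rng)


def _knockout_c4(rng: np.random.Generator):
    """Perfect duplex: zero mismatches violates the >= 1 requirement."""
    def build(r):
        mature = _rand_mature(r)
        star = reverse_complement(mature)
        ext = _rand_rna(r, 14)
        core = ext + mature + _loop(r, 5, mature[-1] + star[0]) + star + reverse_complement(ext)
        seq = _rand_rna(r, 30) + core + _rand_rna(r, 30)
        record = SequenceRecord("ko_c4", seq)
        return record, MatureQuery("ko_c4", mature), 30 + len(ext), ("c4",)

    return _verified(build, rng)


def _knockout_c5(rng: np.random.Generator):
    """Star-side bulge: a break in the star beyond facing gaps."""
    def build(r):
        mature = _rand_mature(r)
        positions = _choose_mismatch_positions(r, mature, 2)
        star = list(_star_with_mismatches(mature, positions))
        L = len(mature)
        # insert a 2-nt bulge between star columns near the middle,
        # away from the designed mismatch columns
        mid_candidates = [i for i in range(6, L - 6)
                          if all(abs((L - 1 - i) - p) > 2 for p in positions)]
        if not mid_candidates:
            raise ConstructionError("no bulge insertion point")
        at = int(r.choice(mid_candidates))
        facing = mature[max(0, L - 3 - at):L + 1 - at]
        letter = _nonpairing_letter(facing)
        star[at:at] = [letter, letter]
        star = "".join(star)
        ext = _rand_rna(r, 14)
        core = ext + mature + _loop(r, 5, mature[-1] + star[0]) + star + reverse_complement(ext)
        seq = _rand_rna(r, 30) + core + _rand_rna(r, 30)
        record = SequenceRecord("ko_c5", seq)
        return record, MatureQuery("ko_c5", mature), 30 + len(ext), ("c5",)

    return _verified(build, rng)


def _knockout_c6(rng: np.random.Generator):
    """GC-extreme stem: trimmed GC content above the 70% bound."""
    def build(r):
        mature = _rand_rna(r, 21, gc=0.8)
        positions = _choose_mismatch_positions(r, mature, 3)
        star = _star_with_mismatches(mature, positions)
        ext = _rand_rna(r, 20, gc=0.95)
        core = ext + mature + "CCAC"[:4] + star + reverse_complement(ext)
        seq = _rand_rna(r, 30) + core + _rand_rna(r, 30)
        record = SequenceRecord("ko_c6", seq)
        return record, MatureQuery("ko_c6", mature), 30 + len(ext), ("c6",)

    return _verified(build, rng)


def _knockout_c7(rng: np.random.Generator):
    """Three consecutive duplex mismatches (the cap is two)."""
    def build(r):
        mature = list(_rand_mature(r))
        mature[9:12] = ["A", "C", "A"]
        mature = "".join(mature)
        star = _star_with_mismatches(mature, [9, 10, 11])
        ext = _rand_rna(r, 14)
        core = ext + mature + _loop(r, 5, mature[-1] + star[0]) + star + reverse_complement(ext)
        seq = _rand_rna(r, 30) + core + _rand_rna(r, 30)
        record = SequenceRecord("ko_c7", seq)
        return record, MatureQuery("ko_c7", mature), 30 + len(ext), ("c7",)

    return _verified(build, rng)


def _knockout_c8(rng: np.random.Generator):
    """A single base pair in the duplex (the minimum is two).

    Deterministic letter design: an A/G extension stem encloses a mature
    that pairs only through one G:C; the rest of the mature sits in the
    terminal loop, where it is not scored against a star.
    """
    def build(r):
        e1 = "GA" * 10
        mature = "AAG" + "A" * 18
        seq = e1 + mature + "C" + reverse_complement(e1)
        record = SequenceRecord("ko_c8", seq)
        return record, MatureQuery("ko_c8", mature), len(e1), ("c8",)

    return _verified(build, rng)


def _knockout_c9(rng: np.random.Generator):
    """Well-formed hairpin whose stem-loop is shorter than 60 nt."""
    def build(r):
        mature = _rand_mature(r)
        positions = _choose_mismatch_positions(r, mature, 2)
        star = _star_with_mismatches(mature, positions)
        core = mature + _loop(r, 4, mature[-1] + star[0]) + star
        seq = "AAC" + core + "CAA"
        record = SequenceRecord("ko_c9", seq)
        return record, MatureQuery("ko_c9", mature), 3, ("c9",)

    return _verified(build, rng)


_KNOCKOUTS = {
    "c1": _knockout_c1, "c2": _knockout_c2, "c3": _knockout_c3,
    "c4": _knockout_c4, "c5": _knockout_c5, "c6": _knockout_c6,
    "c7": _knockout_c7, "c8": _knockout_c8, "c9": _knockout_c9,
}


def make_criterion_knockout(criterion: str, rng: Optional[np.random.Generator]
                            = None):
    """A candidate failing exactly one criterion.

    Returns ``(record, query, mature_offset, report)`` where the report
    is the verified evaluation (its only failed criterion is
    ``criterion``).
    """
    if criterion not in _KNOCKOUTS:
        raise ValueError(f"unknown criterion {criterion!r}")
    rng = rng if rng is not None else np.random.default_rng(0)
    return _KNOCKOUTS[criterion](rng)


# --- decoys ----------------------------------------------------------------

def make_decoys(rng: np.random.Generator, n_random: int = 160,
                n_low_gc: int = 10, n_high_gc: int = 10,
                n_repeat: int = 10, n_mite: int = 10,
                length_range: Tuple[int, int] = (250, 600)
                ) -> Tuple[List[SequenceRecord], List[TruthRecord]]:
    """Negative controls without any embedded mature miRNA."""
    records, truths = [], []
    counter = 0

    def emit(seq: str, category: str):
        nonlocal counter
        counter += 1
        rid = f"dec_{counter:04d}"
        records.append(SequenceRecord(rid, seq))
        truths.append(TruthRecord(rid, category, expected_verdict="none"))

    lo, hi = length_range
    for _ in range(n_random):
        emit(_rand_rna(rng, int(rng.integers(lo, hi))), "decoy_random")
    for _ in range(n_low_gc):
        emit(_rand_rna(rng, int(rng.integers(lo, hi)), gc=0.15), "decoy_low_gc")
    for _ in range(n_high_gc):
        emit(_rand_rna(rng, int(rng.integers(lo, hi)), gc=0.85), "decoy_high_gc")
    for _ in range(n_repeat):
        unit = _rand_rna(rng, 13)
        reps = int(rng.integers(lo, hi)) // len(unit) + 1
        emit((unit * reps)[:int(rng.integers(lo, hi))], "decoy_repeat")
    for _ in range(n_mite):
        tir = _rand_rna(rng, 40)
        interior = _rand_rna(rng, int(rng.integers(60, 200)))
        flank_l = _rand_rna(rng, int(rng.integers(40, 120)))
        flank_r = _rand_rna(rng, int(rng.integers(40, 120)))
        emit(flank_l + tir + interior + reverse_complement(tir) + flank_r,
             "decoy_mite")
    return records, truths


def make_structured_decoys(rng: np.random.Generator, matures: Sequence[str]
                           ) -> Tuple[List[SequenceRecord], List[TruthRecord]]:
    """Decoys that carry a real mature sequence but fail validation.

    A MITE-like perfect inverted repeat of the mature (zero duplex
    mismatches), a GC-extreme hairpin, and an undersized hairpin; the
    scan recovers all of them, the criteria reject all of them.
    """
    records, truths = [], []
    kinds = ["decoy_mite_mature", "decoy_gc_hairpin", "decoy_short_hairpin"]
    for i, mature in enumerate(matures):
        category = kinds[i % len(kinds)]
        rid = f"sdec_{i + 1:04d}"

        def build(r, mature=mature, category=category, rid=rid):
            if category == "decoy_mite_mature":
                star = reverse_complement(mature)
                ext = _rand_rna(r, 14)
                core = (ext + mature + _loop(r, 40, mature[-1] + star[0])
                        + star + reverse_complement(ext))
                seq = _rand_rna(r, 60) + core + _rand_rna(r, 60)
                offset, must_fail = 60 + len(ext), "c4"
            elif category == "decoy_gc_hairpin":
                positions = _choose_mismatch_positions(r, mature, 3)
                star = _star_with_mismatches(mature, positions)
                ext = _rand_rna(r, 30, gc=0.97)
                core = (ext + mature + _loop(r, 4, mature[-1] + star[0])
                        + star + reverse_complement(ext))
                seq = _rand_rna(r, 40) + core + _rand_rna(r, 40)
                offset, must_fail = 40 + len(ext), "c6"
            else:
                positions = _choose_mismatch_positions(r, mature, 2)
                star = _star_with_mismatches(mature, positions)
                core = mature + _loop(r, 4, mature[-1] + star[0]) + star
                seq = "AAC" + core + "CAA"
                offset, must_fail = 3, "c9"
            return SequenceRecord(rid, seq), offset, must_fail

        last: Optional[Exception] = None
        for _ in range(25):
            try:
                record, offset, must_fail = build(rng)
            except ConstructionError as exc:
                last = exc
                continue
            f = fold(record.residues)
            window = PrecursorWindow(rid, "+", 0, len(record),
                                     record.residues, offset, len(mature),
                                     MatureQuery(rid, mature))
            report = check(window, f, MatureQuery(rid, mature))
            if not report.verdict and must_fail in report.failed:
                break
            last = ConstructionError(
                f"{rid}: {category} did not fail {must_fail}: "
                f"{report.failed}")
        else:
            raise ConstructionError(f"decoy construction failed: {last}")
        records.append(SequenceRecord(rid, record.residues))
        truths.append(TruthRecord(rid, category, family="",
                                  expected_verdict="reject",
                                  expected_failed=tuple(report.failed),
                                  mature_offset=offset,
                                  mature_len=len(mature)))
    return records, truths


# --- full database ---------------------------------------------------------

@dataclass
class SynthSpec:
    """Parameters of a synthetic EST database.

    Defaults emulate the desk-scale study conditions: 20 embedded true
    precursors among 200 decoys of 250-600 nt, mature queries drawn from
    the bundled sugarcane catalog, designed duplex mismatch counts
    cycling over the valid 1-6 range.
    """

    seed: int = 0
    n_embeds: int = 20
    n_random: int = 160
    n_low_gc: int = 10
    n_high_gc: int = 10
    n_repeat: int = 10
    n_mite: int = 10
    decoy_len: Tuple[int, int] = (250, 600)
    flank_len: Tuple[int, int] = (120, 280)
    loop_len: Tuple[int, int] = (4, 9)
    structured_decoys: int = 0


@dataclass
class SynthResult:
    records: List[SequenceRecord]
    truths: List[TruthRecord]
    queries: List[MatureQuery]


def build_database(spec: SynthSpec,
                   matures: Optional[Sequence[MatureQuery]] = None
                   ) -> SynthResult:
    """Assemble embeds + decoys with a truth sidecar, reproducibly."""
    from .catalog import reference_mature_queries

    rng = np.random.default_rng(spec.seed)
    queries = list(matures) if matures is not None else reference_mature_queries()
    records: List[SequenceRecord] = []
    truths: List[TruthRecord] = []
    for i in range(spec.n_embeds):
        q = queries[i % len(queries)]
        mism = 1 + i % 6
        flanks = (int(rng.integers(*spec.flank_len)),
                  int(rng.integers(*spec.flank_len)))
        loop_len = int(rng.integers(spec.loop_len[0], spec.loop_len[1]))
        rec, truth = make_precursor(
            q.residues, mism, arm=q.expected_arm, loop_len=loop_len,
            flanks=flanks, rng=rng, record_id=f"emb_{i + 1:04d}",
            family=q.family)
        records.append(rec)
        truths.append(truth)
    dec_records, dec_truths = make_decoys(
        rng, spec.n_random, spec.n_low_gc, spec.n_high_gc,
        spec.n_repeat, spec.n_mite, spec.decoy_len)
    records.extend(dec_records)
    truths.extend(dec_truths)
    if spec.structured_decoys:
        sd_records, sd_truths = make_structured_decoys(
            rng, [queries[i % len(queries)].residues
                  for i in range(spec.structured_decoys)])
        records.extend(sd_records)
        truths.extend(sd_truths)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    by_id = {t.record_id: t for t in truths}
    truths = [by_id[r.id] for r in records]
    return SynthResult(records, truths, queries)


# --- target sites ----------------------------------------------------------

@dataclass
class TargetTruth:
    transcript_id: str
    family: str
    site_start: int
    site_len: int
    expected_score: float
    expected_block_pass: bool
    expected_accepted: bool


_MM_SUB = {"A": "C", "C": "A", "G": "A", "U": "C"}
_GU_SUB = {"G": "U", "U": "G"}

_WC_SET = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def make_target_site(mature: str, n_gu: int = 0, n_mm: int = 0,
                     n_bulge: int = 0, host_len: int = 300,
                     rng: Optional[np.random.Generator] = None,
                     record_id: str = "target_host", family: str = "synthetic",
                     force_block2: bool = False
                     ) -> Tuple[SequenceRecord, TargetTruth]:
    """Embed a site of engineered duplex penalty into a random host.

    The site starts from the exact reverse complement of the mature and
    receives ``n_gu`` wobbles, ``n_mm`` mismatches (both placed at
    isolated positions in blocks 1 and 3, or in block 2 when
    ``force_block2`` is set) and ``n_bulge`` extra site nucleotides near
    the miRNA 3' tail, so that the optimal alignment penalty is exactly
    ``0.5*n_gu + 1*n_mm + 1.5*n_bulge``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    L = len(mature)
    site = list(reverse_complement(mature))

    if force_block2:
        pool = [9]
    elif n_bulge:
        # bulge-shift damage in the ungapped pre-filter window lands in
        # block 1, so substitution defects go to block 3 first
        pool = [p for p in (12, 15, 18, 1, 4) if p < L]
    else:
        pool = [p for p in (1, 4, 12, 15, 18) if p < L]
    gu_positions = [p for p in pool if mature[p] in "GU"]
    if len(gu_positions) < n_gu:
        raise ConstructionError(
            f"cannot place {n_gu} G:U wobbles: only positions with G or U "
            f"in the miRNA ({gu_positions}) support a wobble"
        )
    chosen_gu = gu_positions[:n_gu]
    mm_positions = [p for p in pool if p not in chosen_gu][:n_mm]
    if len(mm_positions) < n_mm:
        raise ConstructionError(f"cannot place {n_mm} mismatches in the "
                                "available block positions")
    for p in chosen_gu:
        site[L - 1 - p] = _GU_SUB[mature[p]]
    for p in mm_positions:
        site[L - 1 - p] = _MM_SUB[mature[p]]
    score = 0.5 * n_gu + 1.0 * n_mm + 1.5 * n_bulge
    if n_bulge:
        from .oracles import duplex_score_oracle

        # extra site nucleotides near the miRNA 3' tail; pick letters so
        # the optimal alignment penalty stays exactly the designed score
        at = L - 2
        site_seq = None
        for letter in "ACGU":
            trial = site[:at] + [letter] * n_bulge + site[at:]
            if duplex_score_oracle(mature, "".join(trial),
                                   max(2, n_bulge)) == score:
                site_seq = "".join(trial)
                break
        if site_seq is None:
            raise ConstructionError(
                f"no bulge letter keeps the designed penalty {score}")
    else:
        site_seq = "".join(site)

    offset = int(rng.integers(20, host_len - len(site_seq) - 20))
    host = _rand_rna(rng, host_len)
    seq = host[:offset] + site_seq + host[offset + len(site_seq):]

    # expected pipeline outcome, computed independently: every window
    # start near the site is block-counted by hand and rescored with the
    # enumeration oracle (a bulged site can sometimes be matched more
    # cheaply ungapped, in which case the cheaper penalty is the truth)
    from .oracles import duplex_score_oracle

    block_pass = False
    best_score: Optional[float] = None
    for s in range(max(0, offset - 2), offset + 3):
        window = seq[s:s + L]
        if len(window) < L:
            continue
        counts = [0, 0, 0]
        for b, (lo, hi) in enumerate(((0, 8), (8, 11), (11, L))):
            for i in range(lo, hi):
                if (mature[i], window[L - 1 - i]) not in _WC_SET:
                    counts[b] += 1
        if not all(c <= cap for c, cap in zip(counts, (2, 0, 3))):
            continue
        block_pass = True
        for d in range(-2, 3):
            if s + L + d > len(seq) or L + d <= 0:
                continue
            sc = duplex_score_oracle(mature, seq[s:s + L + d], 2)
            if best_score is None or sc < best_score:
                best_score = sc
    expected_score = best_score if best_score is not None else score
    record = SequenceRecord(record_id, seq)
    truth = TargetTruth(record_id, family, offset, len(site_seq),
                        expected_score, block_pass,
                        block_pass and expected_score <= 3.5)
    return record, truth
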