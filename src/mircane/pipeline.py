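"""End-to-end orchestration: scan -> window -> fold -> check -> collapse.

The precursor pipeline reproduces the published discovery order: known
matures are scanned against the database (0-3 edits, both strands),
windows of ~620 nt are extracted around hits, folded (built-in model, or
externally supplied Vienna/CT structures), validated against the nine
precursor criteria, and accepted candidates sharing >95% identity over
the trimmed precursor collapse to single loci.  The target pipeline runs
the block-filtered duplex scorer and collapses targets at >=95% identity.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import redundancy
from .hairpin_check import CheckConfig, HairpinReport, check
from .homology_scan import (MatureQuery, PrecursorWindow, ScanHit,
                            exclusion_screen, extract_window, scan)
from .report import candidate_key
from .seqio import SequenceRecord
from .structure import FoldResult, fold
from .target_predict import TargetHit, scan_targets

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All numeric knobs of the discovery protocol, with the published
    defaults."""

    max_edits: int = 3
    seed_len: int = 7
    flank: int = 300
    min_loop: int = 3
    mfei_min: float = 0.65
    gc_range: Tuple[float, float] = (30.0, 70.0)
    duplex_mismatch_range: Tuple[int, int] = (1, 6)
    max_consec_mm: int = 2
    min_paired: int = 2
    min_stemloop: int = 60
    precursor_identity: float = 95.0   # strict >
    target_threshold: float = 3.5
    target_identity: float = 95.0      # non-strict >=
    block_caps: Tuple[int, int, int] = (2, 0, 3)
    max_bulges: int = 2
    gu_is_block_match: bool = False
    seed: int = 0

    def check_config(self) -> CheckConfig:
        return CheckConfig(
            mfei_min=self.mfei_min,
            gc_min=self.gc_range[0], gc_max=self.gc_range[1],
            min_duplex_mismatches=self.duplex_mismatch_range[0],
            max_duplex_mismatches=self.duplex_mismatch_range[1],
            max_consecutive_mismatches=self.max_consec_mm,
            min_paired=self.min_paired,
            min_stemloop_len=self.min_stemloop,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, tuple):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _plus_strand_trimmed_interval(rep: HairpinReport) -> Tuple[int, int]:
    """Trimmed stem-loop interval in plus-strand record coordinates."""
    win = rep.window
    if win.strand == "+":
        return (win.window_start + rep.trimmed_start,
                win.window_start + rep.trimmed_end + 1)
    return (win.window_end - rep.trimmed_end - 1,
            win.window_end - rep.trimmed_start)


def _merge_same_record(keyed: Dict[str, HairpinReport]) -> List[List[str]]:
    """Group candidate keys whose trimmed regions overlap on one record."""
    by_record: Dict[str, List[str]] = {}
    for key, rep in keyed.items():
        by_record.setdefault(rep.window.db_id, []).append(key)
    groups: List[List[str]] = []
    for keys in by_record.values():
        keys.sort(key=lambda k: _plus_strand_trimmed_interval(keyed[k]))
        current: List[str] = []
        current_end = -1
        for k in keys:
            a, b = _plus_strand_trimmed_interval(keyed[k])
            if current and a >= current_end:
                groups.append(current)
                current = []
            current.append(k)
            current_end = max(current_end, b)
        if current:
            groups.append(current)
    return groups


@dataclass
class PrecursorResult:
    hits: List[ScanHit]
    windows: List[PrecursorWindow]
    reports: List[HairpinReport]
    accepted: List[HairpinReport]
    loci: Dict[str, List[str]]            # locus representative -> member keys
    locus_reports: List[HairpinReport]    # one representative report per locus
    counts: Dict[str, int]
    config_hash: str
    energy_model: str


def run_precursor_pipeline(db: Sequence[SequenceRecord],
                           matures: Sequence[MatureQuery],
                           config: PipelineConfig = PipelineConfig(),
                           exclusion_db: Sequence[SequenceRecord] = (),
                           external_folds: Optional[Dict[str, FoldResult]]
                           = None) -> PrecursorResult:
    """Run the full precursor discovery protocol.

    ``external_folds`` maps window keys (``db_id:start-end:strand``) to
    structures parsed from Vienna/CT files; windows without an entry are
    folded with the built-in model.
    """
    if not matures:
        raise ValueError("empty mature catalog")
    if not db:
        raise ValueError("empty database")
    counts: Dict[str, int] = {"db_records": len(db), "queries": len(matures)}

    hits = scan(db, matures, config.max_edits, config.seed_len)
    counts["scan_hits"] = len(hits)
    log.info("scan: %d hits in %d records", len(hits), len(db))

    by_id = {rec.id: rec for rec in db}
    windows = [extract_window(by_id[h.db_id], h, config.flank) for h in hits]
    if exclusion_db:
        windows = exclusion_screen(windows, exclusion_db, config.max_edits)
    counts["windows"] = len(windows)

    check_cfg = config.check_config()
    reports: List[HairpinReport] = []
    energy_model = "builtin"
    for win in windows:
        wkey = f"{win.db_id}:{win.window_start + 1}-{win.window_end}:{win.strand}"
        ext = (external_folds or {}).get(wkey)
        if ext is not None:
            f = ext
            energy_model = "external"
        else:
            f = fold(win.residues, config.min_loop)
        reports.append(check(win, f, win.query, check_cfg))
    accepted = [r for r in reports if r.verdict]
    counts["checked"] = len(reports)
    counts["accepted_candidates"] = len(accepted)
    counts["rejected_candidates"] = len(reports) - len(accepted)

    for rep in reports:
        if not rep.verdict and rep.window.query is not None:
            hit_edits = next((h.edit_total for h in hits
                              if h.db_id == rep.window.db_id
                              and h.query is rep.window.query), None)
            if hit_edits is not None and hit_edits <= 1:
                log.info("near-miss: %s matches %s with %d edits but fails %s",
                         rep.window.db_id, rep.window.query.family,
                         hit_edits, ",".join(rep.failed))

    # collapse accepted candidates to loci: candidates whose trimmed
    # stem-loops overlap on the same record are one locus (plus- and
    # minus-strand views of one hairpin); across records, trimmed
    # precursors sharing > precursor_identity collapse further
    loci: Dict[str, List[str]] = {}
    locus_reports: List[HairpinReport] = []
    if accepted:
        keyed = {candidate_key(rep): rep for rep in accepted}
        groups = _merge_same_record(keyed)
        reps = {}
        for group in groups:
            rep_key = min(group, key=lambda k: (keyed[k].window.strand != "+",
                                                k))
            reps[rep_key] = group
        seqs = [
            SequenceRecord(key,
                           keyed[key].window.residues[keyed[key].trimmed_start:
                                                      keyed[key].trimmed_end + 1])
            for key in reps
        ]
        clusters = redundancy.cluster(seqs, config.precursor_identity,
                                      strict=True, both_strands=True)
        for cl in clusters:
            members = sorted(m for rep_key in cl.members
                             for m in reps[rep_key])
            loci[cl.representative] = members
            locus_reports.append(keyed[cl.representative])
    counts["accepted_loci"] = len(loci)
    log.info("pipeline: %d candidates -> %d accepted -> %d loci",
             len(reports), len(accepted), len(loci))
    return PrecursorResult(hits, windows, reports, accepted, loci,
                           locus_reports, counts, config.config_hash,
                           energy_model)


@dataclass
class TargetResult:
    hits: List[TargetHit]
    counts: Dict[str, int]
    config_hash: str


def run_target_pipeline(matures: Sequence[MatureQuery],
                        transcripts: Sequence[SequenceRecord],
                        config: PipelineConfig = PipelineConfig()
                        ) -> TargetResult:
    """Predict and collapse miRNA target sites over sense-strand mRNAs."""
    if not matures:
        raise ValueError("empty mature catalog")
    if not transcripts:
        raise ValueError("empty transcript set")
    hits = scan_targets(matures, transcripts,
                        threshold=config.target_threshold,
                        max_bulges=config.max_bulges,
                        caps=config.block_caps,
                        gu_is_block_match=config.gu_is_block_match,
                        collapse_identity=config.target_identity)
    counts = {
        "transcripts": len(transcripts),
        "queries": len(matures),
        "accepted_targets": len(hits),
    }
    log.info("targets: %d accepted sites", len(hits))
    return TargetResult(hits, counts, config.config_hash)
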