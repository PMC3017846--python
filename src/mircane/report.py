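"""Summary statistics and tabular report output.

Report tables are TSV with fixed column orders; coordinates in reports
are 1-based inclusive (miRBase convention), while the library API is
0-based half-open.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd


def summary_stats(values: Iterable[float]) -> Dict[str, float]:
    """n, mean and sample standard deviation (ddof=1) of finite values.

    NaN entries (e.g. the MFEI of an unvalidated locus) are dropped.
    """
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return {"n": 0, "mean": float("nan"), "sd": float("nan")}
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return {"n": int(arr.size), "mean": float(np.mean(arr)), "sd": sd}


def first_nucleotide_counts(sequences: Sequence[str]) -> Dict[str, int]:
    """Count of first nucleotides across mature sequences.

    Plant mature miRNAs are biased toward a 5' uracil, which loads them
    into AGO1; the U fraction is a standard sanity statistic.
    """
    counts: Dict[str, int] = {}
    for s in sequences:
        counts[s[0]] = counts.get(s[0], 0) + 1
    return counts


def precursor_table(reports, loci=None) -> pd.DataFrame:
    """Candidate table mirroring the published precursor summary.

    Columns: family, db_id, strand, arm, mature_start (1-based),
    duplex_mismatches, trimmed_len, gc_percent, mfe, amfe, mfei, verdict,
    failed_criteria, locus.
    """
    locus_of = {}
    if loci is not None:
        for locus_id, member_keys in loci.items():
            for key in member_keys:
                locus_of[key] = locus_id
    rows = []
    for rep in reports:
        win = rep.window
        key = candidate_key(rep)
        rows.append({
            "family": win.query.family,
            "db_id": win.db_id,
            "strand": win.strand,
            "arm": rep.duplex.mature_arm,
            "mature_start": win.window_start + win.mature_offset + 1
            if win.strand == "+" else win.window_end - win.mature_offset
            - win.mature_len + 1,
            "duplex_mismatches": rep.duplex.mismatch_count,
            "trimmed_len": rep.trimmed_len,
            "gc_percent": round(rep.gc_percent, 2),
            "mfe": round(rep.mfe_kcal, 2),
            "amfe": round(rep.amfe, 2),
            "mfei": round(rep.mfei, 3),
            "verdict": "accept" if rep.verdict else "reject",
            "failed_criteria": ",".join(rep.failed),
            "locus": locus_of.get(key, ""),
        })
    return pd.DataFrame(rows)


def candidate_key(rep) -> str:
    win = rep.window
    return (f"{win.db_id}:{win.window_start + 1}-{win.window_end}"
            f":{win.strand}:{win.query.family}")


def target_table(hits) -> pd.DataFrame:
    """Accepted target sites: family, target_id, 1-based coordinates,
    per-block mismatches, defect counts and the decomposed score."""
    rows = []
    for h in hits:
        aln = h.alignment
        rows.append({
            "family": h.family,
            "target_id": h.target_id,
            "site_start": h.site_start + 1,
            "site_end": h.site_end,
            "block1_mm": h.block_mismatches[0],
            "block2_mm": h.block_mismatches[1],
            "block3_mm": h.block_mismatches[2],
            "n_gu": aln.n_gu,
            "n_mismatch": aln.n_mismatch,
            "n_bulged": aln.n_bulged,
            "score": aln.score_total,
        })
    return pd.DataFrame(rows)


def hits_table(hits) -> pd.DataFrame:
    """Scan hits: db_id, strand, 1-based start/end, family, edits."""
    rows = []
    for h in hits:
        rows.append({
            "db_id": h.db_id,
            "strand": h.strand,
            "start": h.start + 1,
            "end": h.end,
            "family": h.query.family,
            "substitutions": h.substitutions,
            "gaps": h.gaps,
        })
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
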