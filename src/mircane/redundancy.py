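"""Collapse near-identical sequences into single loci.

Distinct ESTs frequently sample the same precursor locus or the same
target gene.  Following the discovery protocol, precursor candidates
sharing more than 95% nucleotide identity are treated as one locus
(strict inequality) and predicted targets sharing at least 95% identity
as one gene (non-strict).  Identity is computed from a global
Needleman-Wunsch alignment (match +1, mismatch -1, gap -2) as
``100 * matches / alignment_length``; clusters are single-linkage
connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import networkx as nx
from Bio import Align

from .seqio import SequenceRecord, reverse_complement


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _aligner()


def identity(a: SequenceRecord, b: SequenceRecord,
             both_strands: bool = False) -> float:
    """Percent identity over a global alignment; symmetric in a and b.

    With ``both_strands`` the reverse complement of ``b`` is also tried
    and the higher identity returned (BLAST-style strand-agnostic
    comparison, appropriate for ESTs of arbitrary orientation).
    """
    if not a.residues or not b.residues:
        raise ValueError("identity of empty sequence is undefined")
    best = 0.0
    variants = [b.residues]
    if both_strands:
        variants.append(reverse_complement(b.residues))
    for residues in variants:
        alignment = _ALIGNER.align(a.residues, residues)[0]
        s1, s2 = str(alignment[0]), str(alignment[1])
        matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
        best = max(best, 100.0 * matches / len(s1))
    return best


@dataclass
class Cluster:
    """A single-linkage cluster of near-identical sequences.

    The representative is the longest member; length ties go to the
    lexicographically smallest id.
    """

    representative: str
    members: List[str]
    identities: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def cluster(seqs: Sequence[SequenceRecord], threshold: float = 95.0,
            strict: bool = True, both_strands: bool = False) -> List[Cluster]:
    """Partition sequences into single-linkage identity clusters.

    ``strict`` selects ``identity > threshold`` (precursor collapse);
    otherwise ``identity >= threshold`` (target collapse).  Output is
    ordered by representative id.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    graph = nx.Graph()
    by_id = {}
    for rec in seqs:
        if rec.id in by_id:
            raise ValueError(f"duplicate id {rec.id!r} in cluster input")
        by_id[rec.id] = rec
        graph.add_node(rec.id)
    ids = list(by_id)
    idmat: Dict[str, Dict[str, float]] = {i: {} for i in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pid = identity(by_id[a], by_id[b], both_strands)
            idmat[a][b] = idmat[b][a] = pid
            if (pid > threshold) if strict else (pid >= threshold):
                graph.add_edge(a, b)
    clusters = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        rep = min(members, key=lambda m: (-len(by_id[m]), m))
        clusters.append(Cluster(
            representative=rep,
            members=members,
            identities={m: {n: idmat[m][n] for n in members if n != m}
                        for m in members},
        ))
    clusters.sort(key=lambda c: c.representative)
    return clusters
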