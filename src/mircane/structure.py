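"""RNA secondary structure: built-in folding model and external parsers.

The built-in folder is a Nussinov-style maximum-weight nested-pairing
dynamic program, not a thermodynamic nearest-neighbour model: each pair
contributes a fixed stability weight (G:C -3, A:U -2, G:U -1 kcal/mol by
default) and the optimum minimises the sum under the no-pseudoknot and
minimum-hairpin-loop constraints.  Its energies are therefore on a
different scale from mfold/RNAfold; published MFEI thresholds calibrated
on thermodynamic folders transfer only approximately, which is why the
pipeline also ingests externally computed structures (Vienna dot-bracket
or CT connect files) and exposes the MFEI cutoff as configuration.

Energy indices used downstream:

* AMFE  = (|MFE| / length) * 100   (energy per 100 nt, reported positive)
* MFEI  = AMFE / GC%               (discriminates miRNA precursors from
  other non-coding RNAs; precursor candidates require MFEI above a
  configurable cutoff, 0.65 by default)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, TextIO, Tuple, Union

import numpy as np
from numba import njit

DEFAULT_PAIR_WEIGHTS: Dict[str, float] = {"GC": -3.0, "AU": -2.0, "GU": -1.0}

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


class StructureError(ValueError):
    """Raised for inconsistent or unsupported secondary-structure input."""


def _weight_matrix(weights: Dict[str, float]) -> np.ndarray:
    w = np.zeros((5, 5))
    for pair, e in weights.items():
        a, b = _ENCODE[pair[0]], _ENCODE[pair[1]]
        w[a, b] = e
        w[b, a] = e
    return w


def pair_weight(a: str, b: str,
                weights: Dict[str, float] = DEFAULT_PAIR_WEIGHTS) -> float:
    """Stability weight of a base pair, or 0.0 if the bases cannot pair."""
    key = a + b
    return weights.get(key, weights.get(b + a, 0.0))


@dataclass
class FoldResult:
    """A nested secondary structure with its model energy.

    ``pairing[i]`` is the partner of position ``i`` or ``None``;
    ``mfe_kcal`` is negative for stable structures and may be ``None``
    for external files that omit the energy.
    """

    residues: str
    pairing: List[Optional[int]]
    dot_bracket: str
    mfe_kcal: Optional[float]
    source: str = "builtin"

    def __post_init__(self) -> None:
        n = len(self.residues)
        if len(self.pairing) != n or len(self.dot_bracket) != n:
            raise StructureError("residues, pairing and dot-bracket lengths differ")
        for i, j in enumerate(self.pairing):
            if j is None:
                if self.dot_bracket[i] != ".":
                    raise StructureError(f"position {i + 1} unpaired but "
                                         f"bracket is {self.dot_bracket[i]!r}")
                continue
            if j == i or self.pairing[j] != i:
                raise StructureError(f"pairing map is not an involution at "
                                     f"position {i + 1}")
            if self.dot_bracket[i] not in "()":
                raise StructureError(f"position {i + 1} paired but bracket "
                                     f"is {self.dot_bracket[i]!r}")

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairing) if j is not None and i < j)

    def pairs(self) -> List[Tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.pairing)
                if j is not None and i < j]


def pairing_from_dot_bracket(db: str) -> List[Optional[int]]:
    """Pairing map from a dot-bracket string (no pseudoknot notation)."""
    bad = set(db) - set("().")
    if bad:
        raise StructureError(
            f"unsupported dot-bracket characters {sorted(bad)!r} "
            "(pseudoknot or extended notation is not supported)"
        )
    stack: List[int] = []
    pairing: List[Optional[int]] = [None] * len(db)
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i + 1}")
            j = stack.pop()
            pairing[i], pairing[j] = j, i
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1] + 1}")
    return pairing


def dot_bracket_from_pairing(pairing: Sequence[Optional[int]]) -> str:
    return "".join(
        "." if j is None else ("(" if i < j else ")")
        for i, j in enumerate(pairing)
    )


@njit(cache=True)
def _nussinov_fill(code: np.ndarray, w: np.ndarray, min_loop: int) -> np.ndarray:
    n = code.shape[0]
    e = np.zeros((n + 1, n + 1))
    # e[i, j] covers the half-open region [i, j); e[i, i] = 0
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = e[i + 1, j]
            for k in range(i + min_loop + 1, j):
                wk = w[code[i], code[k]]
                if wk != 0.0:
                    cand = wk + e[i + 1, k] + e[k + 1, j]
                    if cand < best:
                        best = cand
            e[i, j] = best
    return e


def fold(seq: str, min_loop: int = 3,
         weights: Dict[str, float] = DEFAULT_PAIR_WEIGHTS) -> FoldResult:
    """Fold a sequence with the base-pair-weighted nested-pairing model.

    Returns the minimum-energy structure.  Ties are broken
    deterministically: scanning left to right, a position is paired
    whenever a co-optimal structure pairs it, and takes the smallest
    available partner index.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n < min_loop + 2:
        raise StructureError(
            f"sequence of length {n} cannot form a hairpin "
            f"(needs at least {min_loop + 2} nt)"
        )
    code = np.array([_ENCODE.get(c, 4) for c in seq], dtype=np.int8)
    w = _weight_matrix(weights)
    e = _nussinov_fill(code, w, min_loop)
    pairing: List[Optional[int]] = [None] * n
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        target = e[i, j]
        paired = False
        for k in range(i + min_loop + 1, j):
            wk = w[code[i], code[k]]
            if wk != 0.0 and wk + e[i + 1, k] + e[k + 1, j] == target:
                pairing[i], pairing[k] = k, i
                stack.append((i + 1, k))
                stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    mfe = float(e[0, n])
    return FoldResult(seq, pairing, dot_bracket_from_pairing(pairing), mfe,
                      source="builtin")


_VIENNA_ENERGY = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_vienna(path: Union[str, Path, TextIO]) -> FoldResult:
    """Parse the first structure of a Vienna/RNAfold-style file.

    Expected layout: optional ``>name`` header, sequence line, dot-bracket
    line with an optional trailing ``(-12.30)`` energy.  Files holding
    several records are read up to the first complete structure.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        lines = [ln.rstrip("\r\n") for ln in handle]
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    lines = [ln for ln in lines if ln.strip()]
    idx = 0
    if lines and lines[idx].startswith(">"):
        idx += 1
    if len(lines) < idx + 2:
        raise StructureError("Vienna input needs a sequence and a structure line")
    seq = lines[idx].strip().upper().replace("T", "U")
    struct_line = lines[idx + 1].strip()
    energy: Optional[float] = None
    m = _VIENNA_ENERGY.search(struct_line)
    if m:
        energy = float(m.group(1))
        struct_line = struct_line[:m.start()].strip()
    if len(struct_line) != len(seq):
        raise StructureError(
            f"line {idx + 2}: structure length {len(struct_line)} does not "
            f"match sequence length {len(seq)}"
        )
    pairing = pairing_from_dot_bracket(struct_line)
    return FoldResult(seq, pairing, struct_line, energy, source="vienna_file")


def parse_ct(path: Union[str, Path, TextIO]) -> FoldResult:
    """Parse the first structure of a CT (connect) file.

    Standard 6-column format: index, base, previous, next, partner (0 for
    unpaired), original index.  The energy is taken from a ``dG`` or
    ``ENERGY`` token on the header line when present.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        lines = [ln.rstrip("\r\n") for ln in handle if ln.strip()]
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not lines:
        raise StructureError("empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError):
        raise StructureError("line 1: CT header must start with the length")
    energy: Optional[float] = None
    m = re.search(r"(?:dG|ENERGY)\s*=?\s*(-?\d+(?:\.\d+)?)", lines[0],
                  flags=re.IGNORECASE)
    if m:
        energy = float(m.group(1))
    if len(lines) < n + 1:
        raise StructureError(f"CT file declares {n} bases but has "
                             f"{len(lines) - 1} rows")
    seq = []
    partner = [0] * n
    for row_no, ln in enumerate(lines[1:n + 1], start=2):
        cols = ln.split()
        if len(cols) < 6:
            raise StructureError(f"line {row_no}: CT rows need 6 columns")
        i = int(cols[0])
        if i != row_no - 1:
            raise StructureError(f"line {row_no}: index {i} out of order")
        seq.append(cols[1].upper().replace("T", "U"))
        partner[i - 1] = int(cols[4])
    pairing: List[Optional[int]] = [None] * n
    for i0, p in enumerate(partner):
        if p == 0:
            continue
        j0 = p - 1
        if not (0 <= j0 < n) or partner[j0] != i0 + 1:
            raise StructureError(
                f"line {i0 + 2}: position {i0 + 1} pairs {p} but "
                f"{p} does not pair back"
            )
        pairing[i0] = j0
    return FoldResult("".join(seq), pairing, dot_bracket_from_pairing(pairing),
                      energy, source="ct_file")


def write_vienna(folds: Union[FoldResult, Sequence[FoldResult]],
                 path: Union[str, Path, TextIO],
                 names: Optional[Sequence[str]] = None) -> None:
    """Write structures in Vienna format (``>name`` / sequence / brackets)."""
    if isinstance(folds, FoldResult):
        folds = [folds]
    handle = open(path, "w") if isinstance(path, (str, Path)) else path
    try:
        for i, f in enumerate(folds):
            name = names[i] if names else f"structure_{i + 1}"
            handle.write(f">{name}\n{f.residues}\n{f.dot_bracket}")
            if f.mfe_kcal is not None:
                handle.write(f" ({f.mfe_kcal:.2f})")
            handle.write("\n")
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def amfe(mfe_kcal: float, length: int) -> float:
    """Adjusted MFE: energy per 100 nt, reported as a positive number."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if mfe_kcal > 0:
        raise ValueError("AMFE is defined for non-positive MFE values")
    return abs(mfe_kcal) / length * 100.0


def mfei(mfe_kcal: float, length: int, gc_percent: float) -> float:
    """Minimal free energy index: AMFE divided by the GC percentage."""
    if gc_percent <= 0 or gc_percent > 100:
        raise ValueError("MFEI is undefined for GC% outside (0, 100]")
    return amfe(mfe_kcal, length) / gc_percent
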