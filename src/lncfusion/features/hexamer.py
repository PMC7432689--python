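"""Hexamer usage table and log-ratio score.

The table holds two normalized distributions over all 4096 hexamers:
``f_coding`` estimated from in-frame (step-3) hexamers anchored at each
coding transcript's longest-ORF start, and ``f_noncoding`` from step-1
sliding hexamers over noncoding transcripts.  A transcript's score is the
mean natural-log ratio log(f_coding/f_noncoding) over its step-1 hexamer
windows (m = L - 6 + 1 windows; N-containing windows are skipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ..sequence_io import Transcript
from .orf import find_longest_orf

K_HEX = 6
N_HEXAMERS = 4 ** K_HEX
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def hexamer_index(hexamer: str) -> int:
    """Lexicographic index (A<C<G<T) of a 6-mer; -1 if it contains N."""
    idx = 0
    for c in hexamer:
        b = _BASE_INDEX.get(c)
        if b is None:
            return -1
        idx = idx * 4 + b
    return idx


def all_hexamers() -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=K_HEX)]


@dataclass
class HexamerTable:
    f_coding: np.ndarray
    f_noncoding: np.ndarray
    pseudocount: float = 1.0
    k: int = field(default=K_HEX, init=False)

    def __post_init__(self) -> None:
        self.f_coding = np.asarray(self.f_coding, dtype=np.float64)
        self.f_noncoding = np.asarray(self.f_noncoding, dtype=np.float64)
        for name, f in (("f_coding", self.f_coding), ("f_noncoding", self.f_noncoding)):
            if f.shape != (N_HEXAMERS,):
                raise ValueError(f"{name}: expected shape ({N_HEXAMERS},), got {f.shape}")
            if not np.isclose(f.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must sum to 1 (got {f.sum():.12f})")
            if (f <= 0).any():
                raise ValueError(f"{name} must be strictly positive everywhere")

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.f_coding) - np.log(self.f_noncoding)

    def swapped(self) -> "HexamerTable":
        return HexamerTable(self.f_noncoding.copy(), self.f_coding.copy(),
                            self.pseudocount)

    def fingerprint(self) -> float:
        """Cheap content hash for leakage checks."""
        return float(self.f_coding @ self.f_noncoding)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("hexamer\tf_coding\tf_noncoding\n")
            for h, fc, fnc in zip(all_hexamers(), self.f_coding, self.f_noncoding):
                fh.write(f"{h}\t{fc:.12e}\t{fnc:.12e}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HexamerTable":
        fc = np.empty(N_HEXAMERS)
        fnc = np.empty(N_HEXAMERS)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("hexamer"):
                raise ValueError(f"{path}: not a hexamer table TSV")
            n = 0
            for line in fh:
                h, a, b = line.split("\t")
                i = hexamer_index(h)
                fc[i], fnc[i] = float(a), float(b)
                n += 1
        if n != N_HEXAMERS:
            raise ValueError(f"{path}: expected {N_HEXAMERS} rows, got {n}")
        return cls(fc, fnc)


def _count_hexamers(seq: str, start: int, step: int, counts: np.ndarray) -> int:
    n = 0
    for pos in range(start, len(seq) - K_HEX + 1, step):
        i = hexamer_index(seq[pos:pos + K_HEX])
        if i >= 0:
            counts[i] += 1
            n += 1
    return n


def build_hexamer_table(coding: Sequence[Transcript],
                        noncoding: Sequence[Transcript],
                        pseudocount: float = 1.0) -> HexamerTable:
    """Estimate in-frame coding and step-1 noncoding hexamer frequencies.

    Coding counts step by 3 from the longest-ORF start (from position 0
    when no ORF is found); noncoding counts every sliding window.  A
    pseudocount is added to every cell before normalization, so both
    distributions are strictly positive.
    """
    if not coding or not noncoding:
        raise ValueError("both coding and noncoding collections must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")

    c_counts = np.zeros(N_HEXAMERS)
    nc_counts = np.zeros(N_HEXAMERS)
    n_c = 0
    for t in coding:
        orf = find_longest_orf(t)
        n_c += _count_hexamers(t.seq, orf.start if orf.found else 0, 3, c_counts)
    n_nc = 0
    for t in noncoding:
        n_nc += _count_hexamers(t.seq, 0, 1, nc_counts)
    if n_c == 0:
        raise ValueError("coding collection yielded zero valid hexamers")
    if n_nc == 0:
        raise ValueError("noncoding collection yielded zero valid hexamers")

    c_counts += pseudocount
    nc_counts += pseudocount
    return HexamerTable(c_counts / c_counts.sum(), nc_counts / nc_counts.sum(),
                        pseudocount)


def hexamer_score(t: Transcript | str, table: HexamerTable,
                  score_step: int = 1) -> float:
    """Mean log(f_coding/f_noncoding) over hexamer windows.

    ``score_step`` 1 scores every window per the m = L - 6 + 1 definition;
    3 scores in-frame windows only (frame anchored at position 0).
    N-containing windows are skipped; if all windows are skipped, 0.
    """
    seq = t.seq if isinstance(t, Transcript) else t
    if len(seq) < K_HEX:
        raise ValueError(f"sequence shorter than {K_HEX} nt: {len(seq)}")
    if score_step not in (1, 3):
        raise ValueError("score_step must be 1 or 3")
    log_ratio = table.log_ratio
    total = 0.0
    m = 0
    for pos in range(0, len(seq) - K_HEX + 1, score_step):
        i = hexamer_index(seq[pos:pos + K_HEX])
        if i >= 0:
            total += log_ratio[i]
            m += 1
    return total / m if m else 0.0
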