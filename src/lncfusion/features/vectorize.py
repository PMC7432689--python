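"""Modality encodings: OFH vector, k-mer frequency vector, one-hot matrix."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ..sequence_io import Transcript
from .fickett import FickettLookup, fickett_score
from .hexamer import HexamerTable, hexamer_score
from .orf import find_longest_orf

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# One-hot row order follows the listed binary codes:
# A=(1,0,0,0), T=(0,1,0,0), C=(0,0,1,0), G=(0,0,0,1).
_ONEHOT_ROW = {"A": 0, "T": 1, "C": 2, "G": 3}

OFH_DIM = 4
OFH_NAMES = ("l_orf", "orf_coverage", "fickett", "hexamer")


@dataclass(frozen=True)
class OFHVector:
    """[ORF length, ORF coverage, Fickett score, hexamer score]."""

    l_orf: int
    orf_coverage: float
    fickett: float
    hexamer: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.orf_coverage <= 1.0):
            raise ValueError(f"orf_coverage outside [0,1]: {self.orf_coverage}")
        if not np.isfinite([self.l_orf, self.orf_coverage,
                            self.fickett, self.hexamer]).all():
            raise ValueError("OFH vector entries must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.l_orf, self.orf_coverage, self.fickett,
                         self.hexamer], dtype=np.float64)


def ofh_vector(t: Transcript, lookup: FickettLookup, table: HexamerTable,
               score_step: int = 1) -> OFHVector:
    """Compose longest-ORF stats, Fickett score and hexamer score."""
    orf = find_longest_orf(t)
    return OFHVector(
        l_orf=orf.length,
        orf_coverage=orf.length / len(t),
        fickett=fickett_score(t, lookup),
        hexamer=hexamer_score(t, table, score_step=score_step),
    )


def kmer_vector(t: Transcript | str, k: int = 6) -> np.ndarray:
    """Frequencies of all 4^k step-1 k-mer windows, lexicographic A<C<G<T.

    N-containing windows are skipped; frequencies are counts over valid
    windows.  All-zero when no valid window exists (all-N sequences).
    """
    seq = t.seq if isinstance(t, Transcript) else t
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}: {len(seq)} nt")

    codes = np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    n_win = len(seq) - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        col = codes[j:j + n_win]
        valid &= col >= 0
        idx = idx * 4 + np.where(col >= 0, col, 0)

    counts = np.bincount(idx[valid], minlength=4 ** k).astype(np.float64)
    n_valid = int(valid.sum())
    return counts / n_valid if n_valid else counts


def one_hot(t: Transcript | str, maxlen: int = 3000) -> np.ndarray:
    """4 x maxlen binary matrix; 5' truncation / zero right-padding.

    Rows follow the A, T, C, G code order; N columns are all-zero.
    """
    seq = t.seq if isinstance(t, Transcript) else t
    if maxlen < 1:
        raise ValueError(f"maxlen must be >= 1, got {maxlen}")
    mat = np.zeros((4, maxlen), dtype=np.float32)
    for i, c in enumerate(seq[:maxlen]):
        row = _ONEHOT_ROW.get(c)
        if row is not None:
            mat[row, i] = 1.0
    return mat


def kmer_names(k: int) -> list[str]:
    from itertools import product
    return ["".join(p) for p in product("ACGT", repeat=k)]


def feature_table(transcripts: Sequence[Transcript], lookup: FickettLookup,
                  table: HexamerTable, k: int = 6,
                  score_step: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Stacked OFH matrix (n, 4) and k-mer matrix (n, 4^k)."""
    ofh = np.stack([ofh_vector(t, lookup, table, score_step).as_array()
                    for t in transcripts])
    km = np.stack([kmer_vector(t, k) for t in transcripts])
    return ofh, km


def one_hot_batch(transcripts: Sequence[Transcript],
                  maxlen: int = 3000) -> np.ndarray:
    """(n, 4, maxlen) stacked one-hot tensors."""
    return np.stack([one_hot(t, maxlen) for t in transcripts])


def export_feature_tsv(transcripts: Sequence[Transcript], lookup: FickettLookup,
                       table: HexamerTable, path: str | Path, k: int = 6,
                       score_step: int = 1) -> None:
    """TSV: id, the four OFH columns, then one column per k-mer."""
    ofh, km = feature_table(transcripts, lookup, table, k, score_step)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(OFH_NAMES) + "\t" + "\t".join(kmer_names(k)) + "\n")
        for t, o, v in zip(transcripts, ofh, km):
            fh.write(t.id + "\t" + "\t".join(f"{x:.10g}" for x in o)
                     + "\t" + "\t".join(f"{x:.10g}" for x in v) + "\n")
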