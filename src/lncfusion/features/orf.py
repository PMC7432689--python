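"""Longest open reading frame search over the three forward frames."""

from __future__ import annotations

from dataclasses import dataclass

from ..sequence_io import Transcript

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfResult:
    """Longest ATG..stop open reading frame (length includes the stop codon).

    ``start`` is the 0-based index of the A of ATG; ``end`` is exclusive,
    one past the stop codon.  When ``found`` is False all coordinates are 0.
    """

    start: int = 0
    end: int = 0
    frame: int = 0
    found: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def find_longest_orf(t: Transcript | str) -> OrfResult:
    """Longest forward-strand ORF: ATG ... {TAA, TAG, TGA}, no internal
    in-frame stop.  Ties broken by smallest start, then smallest frame.
    """
    seq = t.seq if isinstance(t, Transcript) else t
    L = len(seq)
    best = OrfResult()
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, L - 2, 3):
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == START_CODON:
                    start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - start
                if length > best.length or (
                    length == best.length
                    and best.found
                    and (start, frame) < (best.start, best.frame)
                ):
                    best = OrfResult(start=start, end=pos + 3, frame=frame, found=True)
                start = None
    return best
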