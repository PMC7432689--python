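"""FASTA reading/writing, transcript validation, and labeled-dataset assembly.

Transcripts are normalized to the DNA alphabet ``{A, C, G, T, N}``:
lowercase is uppercased, ``U`` becomes ``T``, and anything else becomes
``N`` (counted and reported as a warning).  Class convention throughout the
package: lncRNA = 1 (positive class), protein-coding = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
_NORMALIZE = {ord("a"): "A", ord("c"): "C", ord("g"): "G", ord("t"): "T",
              ord("u"): "T", ord("U"): "T", ord("n"): "N"}

LNCRNA_LABEL = 1
CODING_LABEL = 0


@dataclass(frozen=True)
class Transcript:
    """A named nucleotide sequence over ``{A, C, G, T, N}``."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: invalid characters {sorted(bad)}; "
                "normalize with normalize_sequence() first"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase, map U->T, and replace foreign characters with N.

    Returns the normalized sequence and the number of replaced characters.
    """
    s = raw.translate(_NORMALIZE).upper()
    n_replaced = 0
    if not VALID_ALPHABET.issuperset(s):
        chars = [c if c in VALID_ALPHABET else "N" for c in s]
        n_replaced = sum(1 for a, b in zip(s, chars) if a != b)
        s = "".join(chars)
    return s, n_replaced


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a FASTA file into normalized :class:`Transcript` records.

    Record ids are the first whitespace-delimited token of the header.
    Multi-line bodies are concatenated.  Empty-sequence records are skipped
    with a warning; non-ACGTUN characters are replaced with N and counted
    in a single per-file warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")

    transcripts: list[Transcript] = []
    n_replaced = 0
    n_empty = 0
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal n_replaced, n_empty
        if header is None:
            return
        seq, rep = normalize_sequence("".join(chunks))
        n_replaced += rep
        if not seq:
            n_empty += 1
            logger.warning("skipping empty-sequence record %r in %s", header, path)
            return
        transcripts.append(Transcript(id=header, seq=seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
        flush()

    if n_replaced:
        logger.warning("%s: replaced %d non-ACGTUN characters with N", path, n_replaced)
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path,
                width: int = 70) -> None:
    """Write transcripts to ``path`` in FASTA format with wrapped bodies."""
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.seq), width):
                fh.write(t.seq[i:i + width] + "\n")


def filter_min_length(transcripts: Sequence[Transcript],
                      min_len: int = 200) -> list[Transcript]:
    """Keep transcripts with length >= ``min_len``, preserving order."""
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    return [t for t in transcripts if len(t) >= min_len]


@dataclass
class LabeledDataset:
    """Parallel transcripts and binary labels (lncRNA = 1, coding = 0)."""

    transcripts: list[Transcript]
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.transcripts) != len(self.labels):
            raise ValueError(
                f"{len(self.transcripts)} transcripts vs {len(self.labels)} labels"
            )
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate transcript id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[tuple[Transcript, int]]:
        return zip(self.transcripts, (int(l) for l in self.labels))

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return LabeledDataset([self.transcripts[i] for i in idx], self.labels[idx])

    def shuffled(self, seed: int) -> "LabeledDataset":
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(self))
        return self.subset(order)

    def class_split(self) -> tuple[list[Transcript], list[Transcript]]:
        """Return (lncRNA-labeled, coding-labeled) transcripts."""
        lnc = [t for t, y in zip(self.transcripts, self.labels) if y == LNCRNA_LABEL]
        pc = [t for t, y in zip(self.transcripts, self.labels) if y == CODING_LABEL]
        return lnc, pc

    def write_manifest(self, path: str | Path) -> None:
        """TSV manifest: id, label, length."""
        with open(path, "w") as fh:
            fh.write("id\tlabel\tlength\n")
            for t, y in self:
                fh.write(f"{t.id}\t{y}\t{len(t)}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read an id->label map from a manifest TSV (id, label[, ...])."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            id_col, lab_col = header.index("id"), header.index("label")
        except ValueError as exc:
            raise ValueError(f"{path}: manifest needs 'id' and 'label' columns") from exc
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(id_col, lab_col):
                continue
            labels[parts[id_col]] = int(parts[lab_col])
    return labels


def assemble_dataset(lnc_path: str | Path, pc_path: str | Path,
                     min_len: int = 200,
                     subsample_per_class: int | None = None,
                     seed: int = 0) -> LabeledDataset:
    """Read both class FASTAs, length-filter, label, and concatenate.

    lncRNA records get label 1, protein-coding records label 0.  When
    ``subsample_per_class`` is given, each class is randomly subsampled to
    that size with ``seed`` (deterministic).
    """
    lnc = filter_min_length(read_fasta(lnc_path), min_len)
    pc = filter_min_length(read_fasta(pc_path), min_len)

    overlap = {t.id for t in lnc} & {t.id for t in pc}
    if overlap:
        raise ValueError(
            f"id(s) present in both classes: {sorted(overlap)[:5]}"
        )

    if subsample_per_class is not None:
        rng = np.random.default_rng(seed)
        if subsample_per_class > min(len(lnc), len(pc)):
            raise ValueError(
                f"subsample_per_class={subsample_per_class} exceeds class size "
                f"({len(lnc)} lncRNA / {len(pc)} coding after filtering)"
            )
        lnc = [lnc[i] for i in sorted(rng.choice(len(lnc), subsample_per_class, replace=False))]
        pc = [pc[i] for i in sorted(rng.choice(len(pc), subsample_per_class, replace=False))]

    transcripts = list(lnc) + list(pc)
    labels = np.concatenate([
        np.full(len(lnc), LNCRNA_LABEL, dtype=np.int64),
        np.full(len(pc), CODING_LABEL, dtype=np.int64),
    ])
    return LabeledDataset(transcripts, labels)
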