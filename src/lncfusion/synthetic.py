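"""Synthetic transcript generator.

Produces two classes with the discriminative structure the classifier
exploits: "coding-like" transcripts carrying one long codon-usage-biased
ORF flanked by random UTRs, and "noncoding-like" transcripts of matched
length drawn i.i.d. at a target GC content and rejection-sampled to have
no long spurious ORF.  Labels follow the package convention:
noncoding-like (lncRNA-like) = 1, coding-like = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np

from .features.orf import STOP_CODONS, find_longest_orf
from .sequence_io import (CODING_LABEL, LNCRNA_LABEL, LabeledDataset,
                          Transcript, write_fasta)

SENSE_CODONS = tuple("".join(p) for p in product("ACGT", repeat=3)
                     if "".join(p) not in STOP_CODONS)

# Hand-fixed skewed codon usage: a small favored subset carries most of the
# mass, giving the coding class a strong hexamer signature without any
# organism-specific table.
_FAVORED = ("GCC", "GAG", "AAG", "CTG", "GAC", "TTC", "ATC", "GTG")
_COMMON = ("GCT", "GAA", "AAA", "CTC", "GAT", "TTT", "ATT", "GTC",
           "AGC", "ACC", "CAG", "CGC", "GGC", "CCC", "TAC", "AAC")


def default_codon_bias() -> dict[str, float]:
    # strongly skewed so the in-frame hexamer signal dominates the coding
    # class's step-1 score despite out-of-frame and UTR windows
    weights = {c: 0.2 for c in SENSE_CODONS}
    for c in _COMMON:
        weights[c] = 2.0
    for c in _FAVORED:
        weights[c] = 80.0
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


@dataclass
class GeneratorConfig:
    n_per_class: int = 500
    length_range: tuple[int, int] = (200, 3000)
    codon_bias: dict[str, float] = field(default_factory=default_codon_bias)
    orf_fraction_range: tuple[float, float] = (0.5, 0.9)
    gc_target: float = 0.5
    max_noncoding_orf: int = 120
    min_coding_orf: int = 150
    seed: int = 0
    max_rejection_attempts: int = 500

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 200 or hi < lo:
            raise ValueError(f"length_range must satisfy 200 <= min <= max, got {self.length_range}")
        f_lo, f_hi = self.orf_fraction_range
        if not (0.0 < f_lo <= f_hi <= 1.0):
            raise ValueError("orf_fraction_range must lie in (0, 1]")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must lie in (0, 1)")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if abs(sum(self.codon_bias.values()) - 1.0) > 1e-9:
            raise ValueError("codon_bias must sum to 1")
        if set(self.codon_bias) - set(SENSE_CODONS):
            raise ValueError("codon_bias may only cover the 61 sense codons")


def _random_utr(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs)) if length else ""


def generate_coding(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> list[Transcript]:
    """5'UTR + ATG + biased sense codons + stop + 3'UTR per transcript.

    The realized longest ORF covers at least the drawn target fraction
    (longer spurious ORFs may arise by chance in the UTRs).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    if int(hi * config.orf_fraction_range[1]) < config.min_coding_orf:
        raise ValueError(
            f"length_range {config.length_range} cannot fit a "
            f">={config.min_coding_orf} nt ORF at fraction "
            f"{config.orf_fraction_range[1]}")
    codons = list(config.codon_bias)
    probs = np.array([config.codon_bias[c] for c in codons])
    stops = sorted(STOP_CODONS)
    out = []
    for i in range(config.n_per_class):
        L = int(rng.integers(lo, hi + 1))
        frac = float(rng.uniform(*config.orf_fraction_range))
        orf_len = max(config.min_coding_orf, int(round(frac * L / 3)) * 3)
        orf_len = min(orf_len, L // 3 * 3)
        n_codons = orf_len // 3 - 2  # minus ATG and stop
        if n_codons < 1:
            raise ValueError(f"length {L} too short for a coding transcript")
        body = "".join(rng.choice(codons, size=n_codons, p=probs))
        orf = "ATG" + body + str(rng.choice(stops))
        utr_total = L - len(orf)
        utr5 = int(rng.integers(0, utr_total + 1))
        seq = (_random_utr(rng, utr5) + orf + _random_utr(rng, utr_total - utr5))
        out.append(Transcript(id=f"coding_{i}", seq=seq))
    return out


def generate_noncoding(config: GeneratorConfig,
                       rng: np.random.Generator | None = None) -> list[Transcript]:
    """i.i.d. sequences at the target GC, rejection-sampled so the longest
    ORF does not exceed ``max_noncoding_orf``."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.length_range
    gc = config.gc_target
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = list("ACGT")
    out = []
    for i in range(config.n_per_class):
        L = int(rng.integers(lo, hi + 1))
        for _ in range(config.max_rejection_attempts):
            seq = "".join(rng.choice(bases, size=L, p=probs))
            if find_longest_orf(seq).length <= config.max_noncoding_orf:
                out.append(Transcript(id=f"noncoding_{i}", seq=seq))
                break
        else:
            raise RuntimeError(
                f"could not sample a length-{L} sequence with longest ORF <= "
                f"{config.max_noncoding_orf} nt in "
                f"{config.max_rejection_attempts} attempts")
    return out


def hexamer_preserving_shuffle(t: Transcript, rng: np.random.Generator) -> Transcript:
    """Hard negative: codon-granularity shuffle of a transcript, destroying
    the single long ORF while keeping local composition."""
    triplets = [t.seq[i:i + 3] for i in range(0, len(t.seq) - 2, 3)]
    rng.shuffle(triplets)
    tail = t.seq[len(triplets) * 3:]
    return Transcript(id=f"{t.id}_shuf", seq="".join(triplets) + tail)


def generate_benchmark(config: GeneratorConfig,
                       out_dir: str | Path | None = None,
                       ) -> tuple[LabeledDataset, dict]:
    """Both classes, shuffled; optionally written as FASTA + labels TSV +
    plain-text manifest recording the full configuration."""
    rng = np.random.default_rng(config.seed)
    coding = generate_coding(config, rng)
    noncoding = generate_noncoding(config, rng)
    transcripts = coding + noncoding
    labels = np.concatenate([
        np.full(len(coding), CODING_LABEL, dtype=np.int64),
        np.full(len(noncoding), LNCRNA_LABEL, dtype=np.int64),
    ])
    data = LabeledDataset(transcripts, labels).shuffled(config.seed)
    manifest = {
        "n_per_class": config.n_per_class,
        "length_range": list(config.length_range),
        "orf_fraction_range": list(config.orf_fraction_range),
        "gc_target": config.gc_target,
        "max_noncoding_orf": config.max_noncoding_orf,
        "min_coding_orf": config.min_coding_orf,
        "seed": config.seed,
        "label_convention": "noncoding-like (lncRNA-like) = 1, coding-like = 0",
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(data.transcripts, out_dir / "benchmark.fasta")
        data.write_manifest(out_dir / "labels.tsv")
        with open(out_dir / "manifest.txt", "w") as fh:
            for k, v in manifest.items():
                fh.write(f"{k}\t{v}\n")
    return data, manifest
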