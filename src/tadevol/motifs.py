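"""Insulator-motif models and occurrence counting.

Motifs are either IUPAC consensus strings or position weight matrices with
a log-odds threshold.  Occurrences are counted on both strands and made
non-overlapping greedily, left to right, on the combined sorted match
list.  ``N`` bases never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .stats import TestResult, signed_rank_test

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A named consensus or PWM motif.

    For PWMs, the match threshold is ``threshold_frac`` of the maximum
    attainable log-odds score against a uniform background.
    """

    name: str
    consensus: Optional[str] = None
    pwm: Optional[np.ndarray] = None  # shape (4, L), columns sum to 1
    threshold_frac: float = 0.6

    def __post_init__(self) -> None:
        if self.consensus is None and self.pwm is None:
            raise ValueError("motif needs a consensus or a PWM")
        if self.consensus is not None and not self.consensus:
            raise ValueError("consensus must be non-empty")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError("PWM must have 4 rows (A, C, G, T)")
            if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-3):
                raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[1]

    @classmethod
    def from_jaspar_pfm(cls, path: str | Path, threshold_frac: float = 0.6) -> "MotifModel":
        """Read a JASPAR-style position frequency matrix (4 count rows,
        optional '>' header)."""
        rows = []
        name = Path(path).stem
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    continue
                nums = [float(x) for x in line.replace("[", " ").replace("]", " ").split()
                        if x not in "ACGT"]
                rows.append(nums)
        counts = np.asarray(rows, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("expected 4 frequency rows")
        pwm = (counts + 0.25) / (counts.sum(axis=0) + 1.0)
        return cls(name, pwm=pwm, threshold_frac=threshold_frac)


def _consensus_matches(seq: str, consensus: str) -> list[int]:
    """Start positions of all (possibly overlapping) consensus matches."""
    L = len(consensus)
    sets = [IUPAC.get(c.upper(), "") for c in consensus]
    out = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if all(b in s for b, s in zip(window, sets)):
            out.append(i)
    return out


def _pwm_matches(seq: str, pwm: np.ndarray, threshold_frac: float) -> list[int]:
    L = pwm.shape[1]
    if len(seq) < L:
        return []
    logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    max_score = logodds.max(axis=0).sum()
    thresh = threshold_frac * max_score
    idx = np.array([BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=int)
    n = len(seq) - L + 1
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = idx[j : j + n]
        valid &= col >= 0
        scores += np.where(col >= 0, logodds[np.clip(col, 0, 3), j], 0.0)
    return [int(i) for i in np.nonzero(valid & (scores >= thresh))[0]]


def find_motif_matches(seq: str, motif: MotifModel) -> list[tuple[int, int, str]]:
    """All (start, end, strand) matches on both strands, sorted by start."""
    seq = seq.upper()
    L = motif.length
    matches: list[tuple[int, int, str]] = []
    if motif.consensus is not None:
        fwd = _consensus_matches(seq, motif.consensus)
        rev = _consensus_matches(seq, revcomp(motif.consensus))
    else:
        fwd = _pwm_matches(seq, motif.pwm, motif.threshold_frac)
        rc = motif.pwm[::-1, ::-1]
        rev = _pwm_matches(seq, rc, motif.threshold_frac)
    matches += [(i, i + L, "+") for i in fwd]
    matches += [(i, i + L, "-") for i in rev]
    matches.sort()
    return matches


def count_motif_occurrences(seq: str, motif: MotifModel) -> int:
    """Number of non-overlapping motif occurrences in ``seq`` (both
    strands; overlaps resolved greedily left to right)."""
    count = 0
    last_end = -1
    for s, e, _strand in find_motif_matches(seq, motif):
        if s >= last_end:
            count += 1
            last_end = e
    return count


def paired_motif_comparison(
    boundary_seqs: Sequence[str],
    ortholog_seqs: Sequence[str],
    motifs: Sequence[MotifModel],
) -> tuple[TestResult, list[tuple[int, int]]]:
    """Paired comparison of total motif occurrences between boundaries and
    their lifted orthologous sequences (two-sided Wilcoxon signed-rank on
    the per-pair differences; zero differences dropped)."""
    if len(boundary_seqs) != len(ortholog_seqs):
        raise ValueError("boundary/ortholog pairing length mismatch")
    counts = []
    for b, o in zip(boundary_seqs, ortholog_seqs):
        cb = sum(count_motif_occurrences(b, m) for m in motifs)
        co = sum(count_motif_occurrences(o, m) for m in motifs)
        counts.append((cb, co))
    diffs = [cb - co for cb, co in counts]
    return signed_rank_test(diffs), counts
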