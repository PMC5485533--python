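"""Per-column conservation of a reference alignment; conserved blocks and
variable loops.

Marker discovery for mini-barcodes rests on one structural property of the
target gene: long stretches that are nearly invariant across the taxonomic
group (candidate primer sites) interrupted by short, highly variable loops
(the diagnostic fragment).  This module quantifies that structure.

The default conservation statistic for a column is the frequency of the
modal unambiguous base (A/C/G/T) among the column's non-gap characters.
Modal frequency maps directly onto consensus-primer mismatch risk: a column
scoring 0.95 means a consensus base mismatches 5% of templates.  Ambiguity
codes contribute to the denominator but never to the modal count — an 'N'
carries no conservation information and should depress, not inflate, the
score.  A normalised Shannon-entropy scorer is available behind the same
contract for users who prefer an information-theoretic profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ContractError
from .refdb import ReferenceLibrary

_BASE_ORDER = "ACGT"


@dataclass
class ConservationProfile:
    """Per-column conservation scores and gap fractions of an alignment."""

    scores: np.ndarray
    gap_fractions: np.ndarray
    n_sequences: int

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.gap_fractions = np.asarray(self.gap_fractions, dtype=float)
        if self.scores.shape != self.gap_fractions.shape:
            raise ContractError("scores and gap_fractions must have equal length")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ContractError("conservation scores must lie in [0, 1]")
        if self.n_sequences < 1:
            raise ContractError("n_sequences must be positive")

    def __len__(self) -> int:
        return self.scores.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(len(self)),
                "score": self.scores,
                "gap_fraction": self.gap_fractions,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConservedBlock:
    """Maximal run of conserved columns, 0-based half-open."""

    start: int
    end: int
    mean_score: float
    min_score: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ContractError("ConservedBlock requires end > start")
        if self.mean_score < self.min_score - 1e-12:
            raise ContractError("mean_score cannot be below min_score")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LoopCandidate:
    """A variable loop flanked by two conserved blocks."""

    left_block: ConservedBlock
    loop_start: int
    loop_end: int
    right_block: ConservedBlock
    loop_mean_score: float

    def __post_init__(self):
        ok = (
            self.left_block.end <= self.loop_start < self.loop_end <= self.right_block.start
        )
        if not ok:
            raise ContractError("loop interval must lie between its flanking blocks")

    @property
    def loop_length(self) -> int:
        return self.loop_end - self.loop_start


def _column_matrix(library: ReferenceLibrary) -> np.ndarray:
    if not library.is_alignment:
        raise ContractError("column_conservation requires an aligned library")
    if len(library) < 2:
        raise ContractError("conservation profiling requires >= 2 sequences")
    return np.array([list(rec.sequence) for rec in library], dtype="U1")


def column_conservation(
    library: ReferenceLibrary,
    statistic: Literal["modal", "entropy"] = "modal",
) -> ConservationProfile:
    """Score each alignment column's conservation.

    ``modal`` (default): frequency of the most common unambiguous base among
    the column's non-gap characters.  ``entropy``: 1 − H/2 with H the Shannon
    entropy (bits) of the A/C/G/T frequencies among unambiguous characters.
    All-gap (or all-ambiguous) columns score 0; all-gap columns have
    gap_fraction 1.
    """
    mat = _column_matrix(library)
    n, L = mat.shape
    counts = np.zeros((4, L), dtype=float)
    for i, b in enumerate(_BASE_ORDER):
        counts[i] = (mat == b).sum(axis=0)
    gap_counts = (mat == "-").sum(axis=0)
    nongap = float(n) - gap_counts
    gap_fractions = gap_counts / float(n)

    scores = np.zeros(L, dtype=float)
    if statistic == "modal":
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(nongap > 0, counts.max(axis=0) / nongap, 0.0)
    elif statistic == "entropy":
        unambig = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(unambig > 0, counts / unambig, 0.0)
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        H = -plogp.sum(axis=0)
        scores = np.where(unambig > 0, 1.0 - H / 2.0, 0.0)
    else:
        raise ContractError(f"unknown conservation statistic: {statistic!r}")
    return ConservationProfile(scores, gap_fractions, n_sequences=n)


def windowed_scores(profile: ConservationProfile, window: int) -> np.ndarray:
    """Sliding arithmetic mean of the scores; output length L − window + 1."""
    L = len(profile)
    if not 1 <= window <= L:
        raise ContractError(f"window must be in [1, {L}], got {window}")
    kernel = np.ones(window) / window
    return np.convolve(profile.scores, kernel, mode="valid")


def find_conserved_blocks(
    profile: ConservationProfile,
    min_len: int = 18,
    min_col_score: float = 0.9,
    max_gap_fraction: float = 0.1,
) -> list[ConservedBlock]:
    """Maximal runs of columns with score >= min_col_score and gap_fraction
    <= max_gap_fraction, of length >= min_len; sorted by start,
    non-overlapping by construction."""
    if min_len < 1:
        raise ContractError("min_len must be >= 1")
    if not (0.0 <= min_col_score <= 1.0 and 0.0 <= max_gap_fraction <= 1.0):
        raise ContractError("thresholds must lie in [0, 1]")
    ok = (profile.scores >= min_col_score) & (profile.gap_fractions <= max_gap_fraction)
    blocks: list[ConservedBlock] = []
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                run = profile.scores[start:i]
                blocks.append(
                    ConservedBlock(start, i, float(run.mean()), float(run.min()))
                )
            start = None
    return blocks


def find_loop_candidates(
    blocks: list[ConservedBlock],
    profile: ConservationProfile,
    min_loop: int = 40,
    max_loop: int = 120,
) -> list[LoopCandidate]:
    """Variable loops between adjacent conserved blocks.

    Every adjacent block pair whose gap has length in [min_loop, max_loop]
    and whose mean score is strictly below both flanks' means yields a
    candidate; candidates are ordered most-variable-first (ascending loop
    mean score, ties by loop start).
    """
    out: list[LoopCandidate] = []
    for left, right in zip(blocks, blocks[1:]):
        loop_len = right.start - left.end
        if not min_loop <= loop_len <= max_loop:
            continue
        loop_mean = float(profile.scores[left.end : right.start].mean())
        if loop_mean >= min(left.mean_score, right.mean_score):
            continue
        out.append(LoopCandidate(left, left.end, right.start, right, loop_mean))
    out.sort(key=lambda c: (c.loop_mean_score, c.loop_start))
    return out


def blocks_to_frame(blocks: list[ConservedBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"start": b.start, "end": b.end, "length": len(b),
             "mean_score": b.mean_score, "min_score": b.min_score}
            for b in blocks
        ],
        columns=["start", "end", "length", "mean_score", "min_score"],
    )


def loops_to_frame(loops: list[LoopCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "loop_start": c.loop_start,
                "loop_end": c.loop_end,
                "loop_length": c.loop_length,
                "loop_mean_score": c.loop_mean_score,
                "left_block_start": c.left_block.start,
                "left_block_end": c.left_block.end,
                "right_block_start": c.right_block.start,
                "right_block_end": c.right_block.end,
            }
            for c in loops
        ],
        columns=[
            "loop_start", "loop_end", "loop_length", "loop_mean_score",
            "left_block_start", "left_block_end",
            "right_block_start", "right_block_end",
        ],
    )
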