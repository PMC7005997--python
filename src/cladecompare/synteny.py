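"""Exact-match synteny: anchors, colinear blocks, breakpoints, and the
mobilome-breakpoint association test.

Anchors are maximal exact matches (MEMs) of a minimum length on both strands,
with "maxmatch" semantics: a match need not be unique in either genome, and
maximality means that extending it one base in either direction breaks the
equality or runs off a sequence end. Anchors chained colinearly within a gap
tolerance form synteny blocks; boundaries between adjacent retained blocks on
the query are synteny breakpoints, flagged as inversions when orientation
flips. Whether breakpoints co-locate with mobilome features (IS elements,
prophages, transposons) is quantified with a circular-rotation permutation
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import GeneAnnotation, reverse_complement

DEFAULT_MIN_MATCH_LEN = 20
DEFAULT_MIN_CLUSTER_LEN = 200
DEFAULT_MAX_GAP = 500
DEFAULT_MARGIN = 2000


@dataclass(frozen=True)
class SyntenyAnchor:
    """One maximal exact match; coordinates 0-based half-open on both
    sequences. For reverse orientation, query [q_start, q_end) equals the
    reverse complement of reference [r_start, r_end)."""

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    orientation: str  # "forward" | "reverse"

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    def verify(self, query: str, ref: str) -> bool:
        q = query[self.q_start : self.q_end]
        r = ref[self.r_start : self.r_end]
        return q == (r if self.orientation == "forward" else reverse_complement(r))


def _maximal_matches(query: str, ref: str, k: int) -> list[tuple[int, int, int]]:
    """All left-maximal seed extensions: (q_start, r_start, length) of every
    maximal exact match of length >= k between two plain strings."""
    index: dict[str, list[int]] = {}
    for j in range(len(ref) - k + 1):
        index.setdefault(ref[j : j + k], []).append(j)
    out: list[tuple[int, int, int]] = []
    nq, nr = len(query), len(ref)
    for i in range(nq - k + 1):
        seed = query[i : i + k]
        positions = index.get(seed)
        if not positions:
            continue
        for j in positions:
            # only extend from the leftmost seed of each match
            if i > 0 and j > 0 and query[i - 1] == ref[j - 1]:
                continue
            qi, rj = i + k, j + k
            while qi < nq and rj < nr and query[qi] == ref[rj]:
                qi += 1
                rj += 1
            out.append((i, j, qi - i))
    return out


def find_anchors(
    query: str, ref: str, min_match_len: int = DEFAULT_MIN_MATCH_LEN
) -> list[SyntenyAnchor]:
    """All maximal exact matches of length >= min_match_len, both strands.

    Uniqueness is not required; every match is reported. Deterministic
    output order: (q_start, r_start, orientation).
    """
    if not query or not ref:
        raise ValueError("both sequences must be non-empty")
    anchors: list[SyntenyAnchor] = []
    for i, j, length in _maximal_matches(query, ref, min_match_len):
        anchors.append(SyntenyAnchor(i, i + length, j, j + length, "forward"))
    rc = reverse_complement(ref)
    m = len(ref)
    for i, j, length in _maximal_matches(query, rc, min_match_len):
        anchors.append(
            SyntenyAnchor(i, i + length, m - j - length, m - j, "reverse")
        )
    anchors.sort(key=lambda a: (a.q_start, a.r_start, a.orientation))
    return anchors


@dataclass
class SyntenyBlock:
    """A chain of colinear same-orientation anchors."""

    anchors: list[SyntenyAnchor] = field(default_factory=list)

    @property
    def orientation(self) -> str:
        return self.anchors[0].orientation

    @property
    def q_start(self) -> int:
        return self.anchors[0].q_start

    @property
    def q_end(self) -> int:
        return self.anchors[-1].q_end

    @property
    def r_start(self) -> int:
        return min(a.r_start for a in self.anchors)

    @property
    def r_end(self) -> int:
        return max(a.r_end for a in self.anchors)

    @property
    def anchored_length(self) -> int:
        return sum(a.length for a in self.anchors)

    def _can_append(self, a: SyntenyAnchor, max_gap: int) -> bool:
        last = self.anchors[-1]
        if a.orientation != last.orientation:
            return False
        q_gap = a.q_start - last.q_end
        if q_gap < 0 or q_gap > max_gap:
            return False
        if a.orientation == "forward":
            r_gap = a.r_start - last.r_end
        else:
            r_gap = last.r_start - a.r_end
        return 0 <= r_gap <= max_gap


def cluster_anchors(
    anchors: Sequence[SyntenyAnchor],
    min_cluster_len: int = DEFAULT_MIN_CLUSTER_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[SyntenyBlock]:
    """Greedy chaining of colinear anchors into blocks.

    Anchors are scanned in query order; each joins the first open block it
    can extend without crossing (query and reference gaps both within
    ``max_gap``, reference coordinates advancing in the block's direction).
    Blocks whose total anchored length falls below ``min_cluster_len`` are
    discarded.
    """
    blocks: list[SyntenyBlock] = []
    for a in sorted(anchors, key=lambda x: (x.q_start, x.r_start)):
        for b in reversed(blocks):
            if b._can_append(a, max_gap):
                b.anchors.append(a)
                break
        else:
            blocks.append(SyntenyBlock([a]))
    return [b for b in blocks if b.anchored_length >= min_cluster_len]


@dataclass
class Breakpoint:
    """Boundary between two adjacent synteny blocks on the query."""

    position: int  # query coordinate: end of the left block
    left_orientation: str
    right_orientation: str

    @property
    def is_inversion(self) -> bool:
        return self.left_orientation != self.right_orientation


def breakpoints(blocks: Sequence[SyntenyBlock], query_length: int) -> list[Breakpoint]:
    """Ordered breakpoints between retained blocks sorted by query start;
    orientation flips are flagged as inversions."""
    ordered = sorted(blocks, key=lambda b: (b.q_start, b.r_start))
    out: list[Breakpoint] = []
    for left, right in zip(ordered, ordered[1:]):
        out.append(Breakpoint(left.q_end, left.orientation, right.orientation))
    return out


@dataclass
class OverlapResult:
    """Mobilome proximity of synteny breakpoints and its permutation p."""

    observed_fraction: Optional[float]
    p_value: Optional[float]
    n_breakpoints: int
    n_mobilome: int
    margin: int
    n_perm: int
    defined: bool

    def report(self) -> str:
        if not self.defined:
            return (
                f"mobilome/breakpoint overlap: undefined "
                f"(breakpoints={self.n_breakpoints}, mobilome features={self.n_mobilome})"
            )
        return (
            f"mobilome/breakpoint overlap: {self.observed_fraction:.3f} of "
            f"{self.n_breakpoints} breakpoints within {self.margin} bp of a "
            f"mobilome feature; circular-permutation p = {self.p_value:.4g} "
            f"({self.n_perm} permutations)"
        )


def mobilome_breakpoint_overlap(
    bps: Sequence[Breakpoint],
    mobilome: Sequence[GeneAnnotation],
    query_length: int,
    margin: int = DEFAULT_MARGIN,
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    """Fraction of breakpoints within ``margin`` bp of a mobilome feature,
    with a circular-rotation permutation p-value.

    The null rotates the mobilome annotation set by a uniform offset around
    the (circular) query, preserving feature spacing; ``p`` uses the add-one
    estimator. With no mobilome features the fraction is 0 and the test is
    flagged undefined.
    """
    n_bp = len(bps)
    if n_bp == 0 or len(mobilome) == 0:
        return OverlapResult(
            0.0 if n_bp else None, None, n_bp, len(mobilome), margin, n_perm, False
        )
    L = query_length
    mask = np.zeros(L, dtype=bool)
    for a in mobilome:
        s, e = a.start - margin, a.end + margin
        idx = np.arange(s, e) % L
        mask[idx] = True
    pos = np.array([bp.position for bp in bps], dtype=int) % L
    observed = float(mask[pos].mean())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        offset = int(rng.integers(0, L))
        # rotating features by +offset == rotating breakpoints by -offset
        stat = float(mask[(pos - offset) % L].mean())
        if stat >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return OverlapResult(observed, p, n_bp, len(mobilome), margin, n_perm, True)


def anchors_table(anchors: Sequence[SyntenyAnchor]) -> pd.DataFrame:
    """Dot-plot coordinates as a frame (the plotting surface is TSV)."""
    return pd.DataFrame(
        [
            {
                "q_start": a.q_start,
                "q_end": a.q_end,
                "r_start": a.r_start,
                "r_end": a.r_end,
                "orientation": a.orientation,
                "length": a.length,
            }
            for a in anchors
        ],
        columns=["q_start", "q_end", "r_start", "r_end", "orientation", "length"],
    )


def blocks_table(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "q_start": b.q_start,
                "q_end": b.q_end,
                "r_start": b.r_start,
                "r_end": b.r_end,
                "orientation": b.orientation,
                "n_anchors": len(b.anchors),
                "anchored_length": b.anchored_length,
            }
            for b in blocks
        ],
        columns=[
            "q_start",
            "q_end",
            "r_start",
            "r_end",
            "orientation",
            "n_anchors",
            "anchored_length",
        ],
    )
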