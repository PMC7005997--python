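"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (full matrix scans, exhaustive
enumeration) kept separate from the package implementation paths they check.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _diagonal_runs(q: np.ndarray, r: np.ndarray, min_len: int):
    """Maximal equal runs along every diagonal of the q-vs-r match matrix;
    yields (q_start, r_start, length)."""
    nq, nr = q.size, r.size
    for d in range(-(nq - 1), nr):
        if d >= 0:
            i0, j0 = 0, d
            m = min(nq, nr - d)
        else:
            i0, j0 = -d, 0
            m = min(nq + d, nr)
        if m < min_len:
            continue
        eq = q[i0 : i0 + m] == r[j0 : j0 + m]
        # run-length encode
        padded = np.concatenate([[False], eq, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                yield i0 + int(s), j0 + int(s), int(e - s)


def mem_set(query: str, ref: str, min_len: int) -> set[tuple[int, int, int, int, str]]:
    """All maximal exact matches >= min_len on both strands, as
    (q_start, q_end, r_start, r_end, orientation) tuples."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    out: set[tuple[int, int, int, int, str]] = set()
    for i, j, L in _diagonal_runs(q, r, min_len):
        out.add((i, i + L, j, j + L, "forward"))
    rc = np.frombuffer(revcomp(ref).encode(), dtype=np.uint8)
    m = len(ref)
    for i, j, L in _diagonal_runs(q, rc, min_len):
        out.add((i, i + L, m - j - L, m - j, "reverse"))
    return out


def hamming_best_window(fragment: str, ref: str) -> tuple[int, float, str]:
    """Best placement of a fragment on a reference by exhaustive Hamming scan
    over every offset on both strands: (start, identity_fraction, strand)."""
    f = np.frombuffer(fragment.encode(), dtype=np.uint8)
    best = (-1, -1.0, "?")
    for strand, seq in (("+", ref), ("-", revcomp(ref))):
        r = np.frombuffer(seq.encode(), dtype=np.uint8)
        if r.size < f.size:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(r, f.size)
        ident = (windows == f).mean(axis=1)
        i = int(np.argmax(ident))
        if ident[i] > best[1]:
            start = i if strand == "+" else len(ref) - i - f.size
            best = (start, float(ident[i]), strand)
    return best


def branch_counts_by_enumeration(leaf_sets, matrix) -> dict[frozenset, tuple[int, int]]:
    """For each branch leaf-set D: (#clusters present in exactly D,
    #clusters absent from exactly D), by scanning every cluster's
    presence pattern."""
    genomes = list(matrix.columns)
    patterns = []
    for _, row in matrix.iterrows():
        patterns.append(frozenset(g for g in genomes if row[g] >= 1))
    out = {}
    for D in leaf_sets:
        comp = frozenset(genomes) - D
        present = sum(1 for p in patterns if p == D)
        absent = sum(1 for p in patterns if p == comp)
        out[D] = (present, absent)
    return out


def core_sets_by_scan(matrix) -> tuple[set, set]:
    """(core, single-copy core) cluster ids by explicit row scans."""
    core, single = set(), set()
    for cid, row in matrix.iterrows():
        vals = list(row)
        if all(v >= 1 for v in vals):
            core.add(cid)
        if all(v == 1 for v in vals):
            single.add(cid)
    return core, single


def unique_by_scan(matrix) -> dict[str, int]:
    counts = {g: 0 for g in matrix.columns}
    for _, row in matrix.iterrows():
        present = [g for g in matrix.columns if row[g] >= 1]
        if len(present) == 1:
            counts[present[0]] += 1
    return counts
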