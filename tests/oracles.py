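"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's search/index code paths (and
edlib): the edit-distance oracle is a dense semi-global DP in numpy, the
stats oracle a naive sort-and-scan, and the k-mer presence oracle a
string-set scan.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def semiglobal_edit_distance(query: str, target: str) -> int:
    """Minimum edit distance of *query* against any substring of
    *target* (full query must align). Dense DP, exhaustive over all
    start/end positions."""
    m, n = len(query), len(target)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    prev = np.zeros(n + 1, dtype=np.int32)
    idx = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        qc = ord(query[i - 1])
        sub = (t != qc).astype(np.int32)
        tmp = np.empty(n + 1, dtype=np.int32)
        tmp[0] = i
        tmp[1:] = np.minimum(prev[:-1] + sub, prev[1:] + 1)
        # horizontal gap edges cost 1 per step: prefix-min relaxation
        prev = np.minimum.accumulate(tmp - idx) + idx
    return int(prev.min())


def best_infix_hit(query: str, target: str) -> tuple[int, str]:
    """(min edit distance, strand) over both strands of *target*."""
    fwd = semiglobal_edit_distance(query, target)
    rev = semiglobal_edit_distance(query[::-1].translate(_COMP), target)
    return (fwd, "+") if fwd <= rev else (rev, "-")


def naive_assembly_stats(lengths, xx: float, genome_size: int | None = None):
    """(Nxx, Lxx) by literal cumulative walk; None when unreachable."""
    arr = sorted(lengths, reverse=True)
    quota = xx * (genome_size if genome_size is not None else sum(arr))
    cum = 0
    for rank, ln in enumerate(arr, start=1):
        cum += ln
        if cum >= quota:
            return ln, rank
    return None, None


def naive_presence_bits(marker: str, panel: dict[str, str], k: int, e: float) -> int:
    """Index-free presence profile: per cultivar, scan the marker's
    k-mers against a plain python set of the cultivar's k-mer strings
    (both strands)."""
    windows = [
        marker[i : i + k]
        for i in range(len(marker) - k + 1)
        if "N" not in marker[i : i + k]
    ]
    if not windows:
        return -1
    bits = 0
    for ci, (name, seq) in enumerate(panel.items()):
        kset = set()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                kset.add(w)
        found = sum(
            (w in kset) or (w[::-1].translate(_COMP) in kset) for w in windows
        )
        if found >= e * len(windows):
            bits |= 1 << ci
    return bits
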