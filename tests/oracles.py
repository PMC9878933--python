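"""Slow, independent reference implementations used only by the tests.

These deliberately avoid the production code paths: plain-Python segment
extraction over every diagonal (vs seeded numpy extension), a numpy
sliding-window scan for short-query matches (vs edlib), and
networkx/BFS connected components (vs union-find).
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def _py_segments(match, match_score=1.0, mismatch_cost=3.0, min_score=25.0):
    """All disjoint maximal-scoring segments, best-first, plain Python."""
    score = [match_score if m else -mismatch_cost for m in match]
    masked = [False] * len(score)
    segments = []
    while True:
        best = (0.0, -1, -1)
        running = 0.0
        start = 0
        for i, s in enumerate(score):
            if masked[i]:
                running, start = 0.0, i + 1
                continue
            running += s
            if running <= 0:
                running, start = 0.0, i + 1
            elif running > best[0]:
                best = (running, start, i + 1)
        if best[0] < min_score:
            break
        _, i, j = best
        segments.append((i, j, sum(1 for x in match[i:j] if x)))
        for p in range(i, j):
            masked[p] = True
    return segments


def exhaustive_match(seq_a: str, seq_b: str, min_score=25.0):
    """Every-diagonal, both-strand ungapped comparison (identity %, coverage %
    of the shorter sequence).  O(n*m); fixtures must stay small."""
    la, lb = len(seq_a), len(seq_b)
    a = np.frombuffer(seq_a.encode(), np.uint8)
    short_is_a = la <= lb
    intervals = []
    matches = total = 0
    for reverse in (False, True):
        sb = revcomp(seq_b) if reverse else seq_b
        b = np.frombuffer(sb.encode(), np.uint8)
        for d in range(-(lb - 1), la):
            a0, b0 = max(d, 0), max(-d, 0)
            length = min(la - a0, lb - b0)
            if length < 1:
                continue
            m = (a[a0:a0 + length] == b[b0:b0 + length]).tolist()
            for s, e, nm in _py_segments(m, min_score=min_score):
                matches += nm
                total += e - s
                if short_is_a:
                    intervals.append((a0 + s, a0 + e))
                elif reverse:
                    intervals.append((lb - (b0 + e), lb - (b0 + s)))
                else:
                    intervals.append((b0 + s, b0 + e))
    covered, last = 0, -1
    for s, e in sorted(intervals):
        s = max(s, last)
        if e > s:
            covered += e - s
            last = e
    shorter = la if short_is_a else lb
    identity = 100.0 * matches / total if total else 0.0
    return identity, 100.0 * covered / shorter


def sliding_window_best(query: str, target: str):
    """Best ungapped full-query placement on either strand.

    Returns (n_mismatches, start, strand).  Forward wins ties, then the
    leftmost placement — the same preference order the site matcher uses.
    """
    q = np.frombuffer(query.encode(), np.uint8)
    t = np.frombuffer(target.encode(), np.uint8)
    if len(q) > len(t):
        return None
    best = None
    for strand, qq in (("+", q), ("-", np.frombuffer(revcomp(query).encode(), np.uint8))):
        windows = np.lib.stride_tricks.sliding_window_view(t, len(qq))
        mism = (windows != qq).sum(axis=1)
        i = int(np.argmin(mism))
        cand = (int(mism[i]), 0 if strand == "+" else 1, i, strand)
        if best is None or cand[:2] < best[:2]:
            best = cand
    return best[0], best[2], best[3]


def brute_components(node_ids, passing_pairs):
    """Connected components by BFS over an adjacency list."""
    adj = {n: set() for n in node_ids}
    for a, b in passing_pairs:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for n in sorted(node_ids):
        if n in seen:
            continue
        stack, comp = [n], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x] - seen)
        comps.append(sorted(comp))
    return sorted(comps)
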