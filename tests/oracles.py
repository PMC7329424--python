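"""Independent brute-force oracles the implementation is checked against.

These deliberately avoid the package's hash table and traversal code:
mapping scores are computed by directly comparing read sketches to
every reference window's sketch, and UMI clusters by materializing the
full directed edge matrix and reachability.
"""

from __future__ import annotations

import numpy as np

from dropsketch import Params, SequenceRecord
from dropsketch.reference_db import sketch_window, window_spans, WindowSpan


def brute_force_scores(
    transcripts: list[SequenceRecord],
    read_seq: str,
    params: Params,
) -> dict[int, int]:
    """Per-transcript mapping scores without a hash table.

    Sketches every reference window directly, counts feature sharing
    against every read-window sketch (a feature occurring in two read
    windows counts twice), drops features whose total location count
    exceeds max_locations, and takes the best sum over any r
    consecutive reference windows by exhaustive enumeration.
    """
    # all reference window sketches, plus global feature occurrence counts
    ref_sketches: dict[int, list[list[int]]] = {}
    occurrences: dict[int, int] = {}
    for ti, rec in enumerate(transcripts):
        spans = window_spans(len(rec.sequence), params)
        sketches = [sketch_window(rec.sequence, sp, params) for sp in spans]
        ref_sketches[ti] = sketches
        for sk in sketches:
            for f in sk:
                occurrences[f] = occurrences.get(f, 0) + 1

    if len(read_seq) < params.k:
        return {}
    read_spans = window_spans(len(read_seq), params)
    read_features: list[int] = []
    for sp in read_spans:
        read_features.extend(sketch_window(read_seq, sp, params))

    scores: dict[int, int] = {}
    for ti, sketches in ref_sketches.items():
        hits = np.zeros(len(sketches), dtype=int)
        for wi, sk in enumerate(sketches):
            members = set(sk)
            for f in read_features:
                if occurrences.get(f, 0) > params.max_locations:
                    continue
                if f in members:
                    hits[wi] += 1
        best = 0
        for start in range(len(sketches)):
            best = max(best, int(hits[start : start + params.r].sum()))
        if best > 0:
            scores[ti] = best
    return scores


def brute_force_molecules(counts: dict[str, int], factor: int) -> int:
    """Directional UMI cluster count via explicit edge matrix + reachability."""
    umis = sorted(counts, key=lambda u: (-counts[u], u))
    n = len(umis)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = umis[i], umis[j]
            if sum(x != y for x, y in zip(a, b)) == 1 and counts[a] >= factor * counts[b] - 1:
                adj[i, j] = True
    visited = np.zeros(n, dtype=bool)
    clusters = 0
    for i in range(n):
        if visited[i]:
            continue
        clusters += 1
        frontier = [i]
        visited[i] = True
        while frontier:
            u = frontier.pop()
            for v in range(n):
                if adj[u, v] and not visited[v]:
                    visited[v] = True
                    frontier.append(v)
    return clusters
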