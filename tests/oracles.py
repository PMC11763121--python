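"""Naive reference implementations used as independent oracles in tests.

Everything here is written with plain Python loops and no shared code with
the package internals (beyond the frequency tables themselves, which are the
scoring contract): exhaustive window enumeration with greedy selection for
the scanner, and breadth-first single-linkage clustering for repeats.
"""

import math
from collections import Counter

from dhnscan.scoring import AA_INDEX


def lookup_score(sequence, start, table):
    return sum(
        table.freqs[p, AA_INDEX[sequence[start + p]]]
        for p in range(table.length)
    )


def s_block_score(segment, s_table):
    total = sum(s_table.first5[p, AA_INDEX[segment[p]]] for p in range(5))
    inner = segment[5:-2]
    if inner:
        total += 3.0 * sum(s_table.interior[AA_INDEX[c]] for c in inner) / len(inner)
    total += s_table.last2[0, AA_INDEX[segment[-2]]]
    total += s_table.last2[1, AA_INDEX[segment[-1]]]
    return total


def oracle_scan(sequence, tables, cfg):
    """Exhaustive enumeration + greedy selection, H->Y->F->S->K with masking.

    Returns a set of (segment_type, start, end) triples.
    """
    n = len(sequence)
    taken = [False] * n

    def free(s, e):
        return not any(taken[s:e])

    def claim(s, e):
        for i in range(s, e):
            taken[i] = True

    hits = set()

    def greedy(cands, seg_type):
        for sc, s, e in sorted(cands, key=lambda c: (-round(c[0], 9), c[1])):
            if free(s, e):
                claim(s, e)
                hits.add((seg_type, s, e))

    for seg in ("H", "Y", "F"):
        table = tables[seg]
        thr = cfg.threshold(seg)
        cands = []
        for s in range(n - table.length + 1):
            if not free(s, s + table.length):
                continue
            sc = lookup_score(sequence, s, table)
            if sc >= thr:
                cands.append((sc, s, s + table.length))
        greedy(cands, seg)

    # S: seed on first-5 score, anchor at the first serine, extend until two
    # consecutive non-S (a terminating acidic pair is retained)
    s_table = tables["S"]
    thr = cfg.s_threshold
    cands = []
    seen = set()
    for w in range(n - 4):
        if not free(w, w + 5):
            continue
        sc5 = sum(s_table.first5[p, AA_INDEX[sequence[w + p]]] for p in range(5))
        if sc5 < cfg.s_seed_fraction * thr:
            continue
        firsts = [i for i in range(w, w + 5) if sequence[i] == "S"]
        if not firsts:
            continue
        s = firsts[0]
        if s + 5 > n or not free(s, s + 5):
            continue
        limit = s
        while limit < n and not taken[limit]:
            limit += 1
        e = s + 5
        while e < limit:
            e += 1
            a, b = sequence[e - 2], sequence[e - 1]
            if a != "S" and b != "S":
                if not (a in "DE" and b in "DE"):
                    e -= 2
                break
        if e - s < 7 or (s, e) in seen:
            continue
        seen.add((s, e))
        sc = s_block_score(sequence[s:e], s_table)
        if sc >= thr:
            cands.append((sc, s, e))
    greedy(cands, "S")

    # K: dual tables, better score wins per window
    cands = []
    for s in range(n - 15 + 1):
        if not free(s, s + 15):
            continue
        sc = max(
            lookup_score(sequence, s, tables["K"]),
            lookup_score(sequence, s, tables["Kvariant"]),
        )
        if sc >= cfg.k_threshold:
            cands.append((sc, s, s + 15))
    greedy(cands, "K")
    return hits


def oracle_repeats(sequence, seed_length, min_identity=0.8, min_copies=3):
    """Naive all-pairs single-linkage repeat families.

    Returns a sorted list of (copies tuple, consensus) pairs, mirroring the
    documented algorithm step by step with plain loops.
    """
    n = len(sequence)
    if n < seed_length * min_copies:
        return []
    min_matches = math.ceil(min_identity * seed_length)
    starts = list(range(n - seed_length + 1))
    windows = {s: sequence[s:s + seed_length] for s in starts}

    def matches(a, b):
        return sum(x == y for x, y in zip(a, b))

    adjacency = {s: [] for s in starts}
    for i, a in enumerate(starts):
        for b in starts[i + 1:]:
            if matches(windows[a], windows[b]) >= min_matches:
                adjacency[a].append(b)
                adjacency[b].append(a)

    unvisited = set(starts)
    components = []
    while unvisited:
        root = min(unvisited)
        queue, comp = [root], []
        unvisited.discard(root)
        while queue:
            node = queue.pop()
            comp.append(node)
            for other in adjacency[node]:
                if other in unvisited:
                    unvisited.discard(other)
                    queue.append(other)
        components.append(sorted(comp))

    def consensus_of(seqs):
        out = []
        for column in zip(*seqs):
            counts = Counter(column)
            best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
            out.append(best[0])
        return "".join(out)

    families = []
    for comp in components:
        if len(comp) < min_copies:
            continue
        chosen, prev_end = [], -1
        for s in comp:
            if s >= prev_end:
                chosen.append(s)
                prev_end = s + seed_length
        if len(chosen) < min_copies:
            continue
        cons = consensus_of([windows[s] for s in chosen])
        kept = [s for s in chosen if matches(windows[s], cons) >= min_matches]
        if len(kept) < min_copies:
            continue
        seqs = [windows[s] for s in kept]
        cons = consensus_of(seqs)
        min_ident = min(matches(q, cons) / seed_length for q in seqs)
        families.append(
            (tuple((s, s + seed_length) for s in kept), cons, min_ident)
        )

    families.sort(key=lambda f: (-len(f[0]), -round(f[2], 9), f[0][0][0]))
    kept_families = []
    for copies, cons, ident in families:
        clash = any(
            s < e2 and s2 < e
            for s, e in copies
            for other, _, _ in kept_families
            for s2, e2 in other
        )
        if not clash:
            kept_families.append((copies, cons, ident))
    kept_families.sort(key=lambda f: f[0][0][0])
    return [(copies, cons) for copies, cons, _ in kept_families]


def random_dhn_like(rng, max_len=200):
    """A random test sequence seeded with mutated motifs and serine runs."""
    from dhnscan.synthetic import CANONICAL_SEGMENTS

    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    parts = []
    length = 0
    while length < max_len:
        roll = rng.random()
        if roll < 0.45:
            piece = "".join(
                rng.choice(list(alphabet), size=int(rng.integers(3, 15)))
            )
        elif roll < 0.85:
            seg = list(CANONICAL_SEGMENTS[
                str(rng.choice(["K", "Kvariant", "Y", "F", "H", "S"]))
            ])
            for _ in range(int(rng.integers(0, 5))):
                seg[int(rng.integers(0, len(seg)))] = str(
                    rng.choice(list(alphabet))
                )
            piece = "".join(seg)
        else:
            piece = "S" * int(rng.integers(3, 10)) + str(
                rng.choice(list("DE"))
            )
        parts.append(piece)
        length += len(piece)
    return "".join(parts)[:max_len]
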