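"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the quantity under test from the documented model
semantics by direct enumeration or elementary string/interval operations,
deliberately avoiding the package's dynamic-programming / sweep code paths.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from famfinder.hmm import AA, ProfileHMM


def enum_forward_posterior(h: ProfileHMM, seq: str):
    """Exhaustive path enumeration of the profile-HMM generative model.

    Returns ``(bit_score, post_match, post_insert)`` where the posteriors are
    (L, M) state marginals.  Tractable only for tiny profiles/sequences.
    """
    L, M = len(seq), h.M
    r = L / (L + 2.0)
    idx = [AA.index(c) if c in AA else None for c in seq]
    eo = h.match_emissions / h.background[None, :]
    tme = h.tme
    post_m = np.zeros((L, M))
    post_i = np.zeros((L, M))
    total = 0.0

    def finish(i, p, marks):
        nonlocal total
        w = p * r ** (L - i) * (1.0 - r)
        total += w
        for ri, st, k in marks:
            (post_m if st == "M" else post_i)[ri, k] += w

    def go_m(k, i, p, marks):
        if i >= L:
            return
        p2 = p * (1.0 if idx[i] is None else eo[k, idx[i]])
        marks2 = marks + [(i, "M", k)]
        finish(i + 1, p2 * tme[k], marks2)
        if k < M - 1:
            go_m(k + 1, i + 1, p2 * h.tmm[k], marks2)
            go_i(k, i + 1, p2 * h.tmi[k], marks2)
            go_d(k + 1, i + 1, p2 * h.tmd[k], marks2)

    def go_i(k, i, p, marks):
        if i >= L:
            return
        marks2 = marks + [(i, "I", k)]
        go_m(k + 1, i + 1, p * h.tim[k], marks2)
        go_i(k, i + 1, p * h.tii[k], marks2)

    def go_d(k, i, p, marks):
        if k == M - 1:
            finish(i, p, marks)
            return
        go_m(k + 1, i, p * h.tdm[k], marks)
        go_d(k + 1, i, p * h.tdd[k], marks)

    for i0 in range(L):
        entry = r**i0 * (1.0 - r) / M
        for k in range(M):
            go_m(k, i0, entry, [])

    bits = math.log2(total) - (L * math.log2(r) + math.log2(1.0 - r))
    return bits, post_m / total, post_i / total


def enum_forward_normalized(h: ProfileHMM, seq: str):
    """Length-conditioned bit score by enumeration: the raw enumeration score
    minus the enumeration score of an all-wildcard sequence of equal length."""
    bits, pm, pi = enum_forward_posterior(h, seq)
    bits0, _, _ = enum_forward_posterior(h, "?" * len(seq))
    return bits - bits0, pm, pi


def split_orfs(aa: str, min_len: int) -> list[tuple[int, int, str]]:
    """Stop-codon segmentation by explicit scanning (not str.split)."""
    out = []
    start = None
    for i, c in enumerate(aa + "*"):
        if c == "*":
            if start is not None and i - start >= min_len:
                out.append((start, i, aa[start:i]))
            start = None
        elif start is None:
            start = i
    return out


def overlap_components(intervals: list[tuple[int, int]]) -> list[set[int]]:
    """Connected components of the interval-overlap graph, by pairwise checks."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a[0] < b[1] and b[0] < a[1]:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def bitmap_nucleotide_counts(pred, truth, span: int):
    """Per-base TP/FP/FN via explicit boolean bitmaps, strand-aware.

    ``pred`` and ``truth`` are lists of (strand, [(start, end), ...]).
    """
    tp = fp = fn = 0
    for strand in "+-":
        p = np.zeros(span, bool)
        t = np.zeros(span, bool)
        for st, exons in pred:
            if st == strand:
                for s, e in exons:
                    p[s:e] = True
        for st, exons in truth:
            if st == strand:
                for s, e in exons:
                    t[s:e] = True
        tp += int(np.sum(p & t))
        fp += int(np.sum(p & ~t))
        fn += int(np.sum(~p & t))
    return tp, fp, fn


def exact_exon_counts(pred, truth):
    """Exact-boundary exon matching via set operations."""
    ps = {(st, s, e) for st, exons in pred for s, e in exons}
    ts = {(st, s, e) for st, exons in truth for s, e in exons}
    tp = len(ps & ts)
    return tp, len(ps) - tp, len(ts) - tp


def translate_codons(nt: str, table: dict[str, str]) -> str:
    """Codon-by-codon translation oracle using an externally supplied table."""
    return "".join(
        table.get(nt[i : i + 3], "X") for i in range(0, len(nt) - len(nt) % 3, 3)
    )


def chain_hits(hits, max_gap, tol):
    """Reference chaining of one (family, seq, strand) hit group.

    Sorts hits in transcription order and links consecutive hits whose
    genomic gap and profile-segment order satisfy the documented merge rule;
    returns chains as tuples of hit identities.
    """
    if not hits:
        return []
    minus = hits[0].strand == "-"
    ordered = sorted(
        hits, key=(lambda h: (-h.end, -h.start)) if minus else (lambda h: (h.start, h.end))
    )

    def linked(a, b):
        gap = (a.start - b.end) if minus else (b.start - a.end)
        p_ok = (
            b.profile_interval[0] >= a.profile_interval[1] - tol
            and b.profile_interval[1] > a.profile_interval[1]
        )
        return 0 <= gap <= max_gap and p_ok

    chains = [[ordered[0]]]
    for h in ordered[1:]:
        if linked(chains[-1][-1], h):
            chains[-1].append(h)
        else:
            chains.append([h])
    return [tuple(id(x) for x in c) for c in chains]


def find_all(pattern, seq):
    import re

    return [m.start() for m in re.finditer(f"(?={pattern})", seq)]


def brute_force_models(seq, blocks, min_intron, max_intron, slack=9):
    """Enumerate (exon structures) of all valid one/two-exon models by
    regex + itertools, mirroring the documented builder semantics."""
    import re

    stops = {"TAA", "TAG", "TGA"}

    def starts_for(anchor):
        found = []
        p = anchor
        while p >= 0:
            c = seq[p : p + 3]
            if c == "ATG":
                found.append((p, True))
            elif c in stops:
                break
            p -= 3
        return found or [(anchor, False)]

    def first_stop(s, frm):
        p = frm
        while p + 3 <= len(s):
            if s[p : p + 3] in stops:
                return p + 3, True
            p += 3
        return frm + (len(s) - frm) // 3 * 3, False

    out = set()
    blocks = sorted(blocks)
    if len(blocks) > 2:
        blocks = sorted(sorted(blocks, key=lambda b: b[0] - b[1])[:2])
    # single exon
    if len({b[0] % 3 for b in blocks}) == 1:
        span_s, span_e = blocks[0][0], blocks[-1][1]
        span_e = span_s + (span_e - span_s) // 3 * 3
        for st, _found in starts_for(span_s):
            end, _ = first_stop(seq, span_e)
            if end > st:
                out.add(((st, end),))
    # two exon
    gts = find_all("GT", seq)
    ags = [p + 2 for p in find_all("AG", seq)]
    if len(blocks) == 2:
        b1, b2 = blocks
        donors = [d for d in gts if max(b1[0] + 3, b1[1] - slack) <= d < b2[0]]
        accs = [a for a in ags if b1[1] <= a <= b2[0] + slack]
        cong = lambda d, a: ((d - b1[0]) + (b2[0] - a)) % 3 == 0
        tail_end = b2[1]
        anchor = b1[0]
    else:
        (b,) = blocks
        donors = [d for d in gts if b[0] + 3 <= d < b[1] - 3]
        accs = [a for a in ags if a <= b[1] - 3]
        cong = lambda d, a: (a - d) % 3 == 0
        tail_end = b[1]
        anchor = b[0]
    for d in donors:
        for a in accs:
            if not (min_intron <= a - d <= max_intron) or not cong(d, a):
                continue
            for st, _found in starts_for(anchor):
                len1 = d - st
                comb = seq[st:d] + seq[a:]
                frm = len1 + (tail_end - a)
                frm -= frm % 3
                end, _ = first_stop(comb, frm)
                if end <= len1:
                    continue
                out.add(((st, d), (a, a + end - len1)))
    return out
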