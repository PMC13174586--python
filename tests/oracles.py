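"""Naive reference implementations used as independent oracles.

Everything here is written as plain double loops over residue pairs,
with no shared code with the package internals, so the vectorized
production implementations can be checked against them.
"""

from __future__ import annotations

import math


def local_score(p: float, cutoff: float = 12.0) -> float:
    return (cutoff - p) / cutoff if p <= cutoff else 0.0


def lis(pae, idx_a, idx_b, cutoff: float = 12.0):
    scores = []
    pairs = set()
    for src, dst in ((idx_a, idx_b), (idx_b, idx_a)):
        for i in src:
            for j in dst:
                if pae[i][j] <= cutoff:
                    pairs.add((i, j))
                    scores.append(local_score(pae[i][j], cutoff))
    return (sum(scores) / len(scores) if scores else 0.0), pairs


def clis(pae, idx_a, idx_b, contact_pairs, cutoff: float = 12.0):
    undirected = {frozenset(p) for p in contact_pairs}
    scores = []
    pairs = set()
    for src, dst in ((idx_a, idx_b), (idx_b, idx_a)):
        for i in src:
            for j in dst:
                if pae[i][j] <= cutoff and frozenset((i, j)) in undirected:
                    pairs.add((i, j))
                    scores.append(local_score(pae[i][j], cutoff))
    return (sum(scores) / len(scores) if scores else 0.0), pairs


def ilis(lis_value: float, clis_value: float) -> float:
    return math.sqrt(lis_value * clis_value)


def lir_sets(pae, idx_a, idx_b, contact_pairs, cutoff: float = 12.0):
    _, pairs = lis(pae, idx_a, idx_b, cutoff)
    _, cpairs = clis(pae, idx_a, idx_b, contact_pairs, cutoff)
    members = {i for p in pairs for i in p}
    cmembers = {i for p in cpairs for i in p}
    sa, sb = set(idx_a), set(idx_b)
    return members & sa, members & sb, cmembers & sa, cmembers & sb


def d0(n: int) -> float:
    return max(1.0, 1.24 * (max(n, 16) - 15) ** (1.0 / 3.0) - 1.8)


def ipsae(pae, idx_a, idx_b, cutoff: float = 10.0) -> float:
    best = 0.0
    for src, dst in ((idx_a, idx_b), (idx_b, idx_a)):
        for i in src:
            partners = [j for j in dst if pae[i][j] < cutoff]
            if not partners:
                continue
            scale = d0(len(partners))
            score = sum(1.0 / (1.0 + (pae[i][j] / scale) ** 2) for j in partners)
            best = max(best, score / len(partners))
    return best


def actifptm(pae, idx_a, idx_b, contact_pairs) -> float:
    members = {i for p in contact_pairs for i in p}
    iface_a = sorted(members & set(idx_a))
    iface_b = sorted(members & set(idx_b))
    n = len(iface_a) + len(iface_b)
    if n == 0:
        return 0.0
    scale = d0(n)
    best = 0.0
    for src, dst in ((iface_a, iface_b), (iface_b, iface_a)):
        for i in src:
            if not dst:
                continue
            terms = [1.0 / (1.0 + (pae[i][j] / scale) ** 2) for j in dst]
            best = max(best, sum(terms) / len(terms))
    return best


def contacts(coords, idx_a, idx_b, cutoff: float = 8.0):
    pairs = set()
    for i in idx_a:
        for j in idx_b:
            dist = math.dist(coords[i], coords[j])
            if dist <= cutoff:
                pairs.add((i, j))
    return pairs


def intra_profile(pae, idx, cutoff: float = 12.0):
    values = []
    for i in idx:
        scores = [
            local_score(pae[i][j], cutoff)
            for j in idx
            if j != i and pae[i][j] <= cutoff
        ]
        values.append(sum(scores) / len(scores) if scores else 0.0)
    return values
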