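"""Independent reference implementations used as test oracles.

Each routine is deliberately written from the definition (quadratic DP,
exhaustive argmax/subset enumeration, breadth-first search) with no code
shared with the package, so agreement is evidence and not tautology.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _subst(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_BLOSUM62[a, b])


def sw_oracle(seq_a: str, seq_b: str, gap_open: float = 11.0,
              gap_extend: float = 1.0) -> float:
    """Quadratic Gotoh local alignment; a gap of length k costs open + k*extend.

    H ends in a substitution at (i, j), E/F end in a gap in either sequence,
    all floored at the empty alignment (score 0).
    """
    n, m = len(seq_a), len(seq_b)
    neg = float("-inf")
    best = 0.0
    h_prev = [0.0] * (m + 1)
    e_prev = [neg] * (m + 1)
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        e_cur = [neg] * (m + 1)
        f = neg
        for j in range(1, m + 1):
            e_cur[j] = max(e_prev[j] - gap_extend, h_prev[j] - gap_open - gap_extend)
            f = max(f - gap_extend, h_cur[j - 1] - gap_open - gap_extend)
            diag = h_prev[j - 1] + _subst(seq_a[i - 1], seq_b[j - 1])
            h_cur[j] = max(0.0, diag, e_cur[j], f)
            best = max(best, h_cur[j])
        h_prev, e_prev = h_cur, e_cur
    return best


def argmax_best_hit(gene: str, pool, scores: dict[tuple[str, str], float]):
    """Exhaustive best hit with the smallest-target tie rule; None if no hits."""
    cands = [(t, scores[(gene, t)]) for t in pool if (gene, t) in scores]
    if not cands:
        return None
    return min(cands, key=lambda h: (-h[1], h[0]))


def double_argmax_brh(genes_a, genes_b, scores) -> set[tuple[str, str]]:
    """Reciprocal best hits by brute force."""
    out = set()
    for ga in genes_a:
        hit = argmax_best_hit(ga, genes_b, scores)
        if hit is None:
            continue
        back = argmax_best_hit(hit[0], genes_a, scores)
        if back is not None and back[0] == ga:
            out.add((ga, hit[0]))
    return out


def bfs_components(nodes, edges) -> set[frozenset]:
    """Breadth-first connected components."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for n in sorted(nodes):
        if n in seen:
            continue
        comp, queue = set(), deque([n])
        seen.add(n)
        while queue:
            x = queue.popleft()
            comp.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    queue.append(y)
        comps.append(frozenset(comp))
    return set(comps)


def bruteforce_best_combination(refog, predicted):
    """Exhaustive search over all nonempty subsets of overlapping OGs.

    Maximises F1 of the union; ties prefer fewer OGs then smaller id tuples.
    Returns (chosen og_ids, union).
    """
    candidates = sorted(
        (og for og in predicted if refog & og.members), key=lambda og: og.og_id
    )
    best_key, best = None, ([], frozenset())
    for r in range(1, len(candidates) + 1):
        for combo in combinations(candidates, r):
            union = frozenset().union(*(og.members for og in combo))
            inter = len(refog & union)
            p = inter / len(union)
            rec = inter / len(refog)
            f1 = 2 * p * rec / (p + rec) if p + rec > 0 else 0.0
            key = (-f1, len(combo), tuple(og.og_id for og in combo))
            if best_key is None or key < best_key:
                best_key, best = key, ([og.og_id for og in combo], union)
    return best


def bottom_s_sketch_oracle(seq: str, k: int, s: int, seed: int, hash_fn):
    """Hash every k-mer (string canonicalisation, manual packing), sort, take s."""
    rc = str.maketrans("ACGT", "TGCA")
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    hashes = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(c not in code for c in kmer):
            continue
        canon = min(kmer, kmer.translate(rc)[::-1])
        packed = 0
        for ch in canon:
            packed = (packed << 2) | code[ch]
        hashes.add(hash_fn(packed, seed))
    return tuple(sorted(hashes)[:s])
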