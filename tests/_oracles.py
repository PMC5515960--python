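"""Independent brute-force oracles used by the test suite.

Each function here re-derives a quantity by the most direct method
available (exhaustive enumeration, nested loops, exact rational
arithmetic) so the optimized implementations can be checked against it.
"""

from __future__ import annotations

import math
from fractions import Fraction

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def bfs_overlap_clusters(models) -> set[frozenset[str]]:
    """Connected components of the same-strand span-overlap graph, by BFS."""
    ids = [m.id for m in models]
    by_id = {m.id: m for m in models}
    adj = {i: [] for i in ids}
    for i, a in enumerate(models):
        for b in models[i + 1 :]:
            if (
                a.scaffold == b.scaffold
                and a.strand == b.strand
                and a.interval.start < b.interval.end
                and b.interval.start < a.interval.end
            ):
                adj[a.id].append(b.id)
                adj[b.id].append(a.id)
    seen: set[str] = set()
    clusters: set[frozenset[str]] = set()
    for start in ids:
        if start in seen:
            continue
        queue, component = [start], {start}
        seen.add(start)
        while queue:
            node = queue.pop()
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    component.add(nb)
                    queue.append(nb)
        clusters.add(frozenset(component))
    return clusters


def cis_pairs_bruteforce(units, genes, min_frac=0.10, rule="any") -> set[tuple[str, str]]:
    """All-pairs cis admission check."""
    out = set()
    for gene in genes:
        for unit in units:
            if unit.contains_gene or unit.scaffold != gene.scaffold:
                continue
            if unit.strand == gene.strand:
                continue
            ov = min(gene.interval.end, unit.span.end) - max(
                gene.interval.start, unit.span.start
            )
            if ov <= 0:
                continue
            fs = ov / gene.interval.length
            fn = ov / unit.span.length
            ok = (fs >= min_frac or fn >= min_frac) if rule == "any" else (
                fs >= min_frac and fn >= min_frac
            )
            if ok:
                out.add((gene.id, unit.id))
    return out


def complementary_regions_bruteforce(
    a: str, b: str, min_len: int, seed_len: int = 12, identity_floor: float = 0.8
):
    """Per-diagonal scan, no k-mer indexing: same region definition, found by
    nested loops. Returns a set of (a_start, a_end, b_start, b_end)."""
    rcb = "".join(COMPLEMENT[c] for c in reversed(b.upper()))
    a = a.upper()
    found = set()
    for d in range(-(len(rcb) - 1), len(a)):
        j0, j1 = max(0, -d), min(len(rcb), len(a) - d)
        if j1 - j0 < seed_len:
            continue
        match = [a[j + d] == rcb[j] and a[j + d] != "N" for j in range(j0, j1)]
        # exact runs
        runs = []
        s = 0
        for i in range(1, len(match) + 1):
            if i == len(match) or match[i] != match[s]:
                runs.append((match[s], s, i))
                s = i
        for idx, (val, rs, re_) in enumerate(runs):
            if not val or re_ - rs < seed_len:
                continue
            start, end, matches = rs, re_, re_ - rs
            lo, hi = idx, idx
            moved = True
            while moved:
                moved = False
                for direction, edge in ((+1, hi), (-1, lo)):
                    g, n = edge + direction, edge + 2 * direction
                    if 0 <= g < len(runs) and 0 <= n < len(runs):
                        gv, g0, g1 = runs[g]
                        nv, n0, n1 = runs[n]
                        if (not gv) and g1 - g0 == 1 and nv:
                            ns, ne = min(start, n0), max(end, n1)
                            nm = matches + (n1 - n0)
                            if nm / (ne - ns) >= identity_floor:
                                start, end, matches = ns, ne, nm
                                if direction > 0:
                                    hi = n
                                else:
                                    lo = n
                                moved = True
            if end - start >= min_len:
                aj0, aj1 = j0 + start + d, j0 + end + d
                found.add((aj0, aj1, len(b) - (j0 + end), len(b) - (j0 + start)))
    return found


def max_orf_bruteforce(seq: str) -> int:
    """Enumerate every ATG...stop pair in frames 0/1/2 directly."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        for ci, codon in enumerate(codons):
            if codon != "ATG":
                continue
            for cj in range(ci + 1, len(codons)):
                if codons[cj] in stops:
                    best = max(best, cj - ci)
                    break
    return best


def hypergeom_tail_exact(total: int, n_in_term: int, draws: int, x: int) -> Fraction:
    """P(X >= x) by exact rational enumeration."""
    denom = math.comb(total, draws)
    num = sum(
        math.comb(n_in_term, k) * math.comb(total - n_in_term, draws - k)
        for k in range(x, min(n_in_term, draws) + 1)
    )
    return Fraction(num, denom)


def bh_stepup(pvalues):
    """Textbook BH step-up: q_i = min over j with p_j >= p_i of p_(j) * m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
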