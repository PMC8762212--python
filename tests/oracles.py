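"""Independent brute-force oracles used by the test suite.

Deliberately simple, separately-coded implementations of the operations
they check: a character-by-character Hamming scan aligner, a plain
triple-loop duplex DP, a window-by-window seed-site scan and an
enumeration-based hypergeometric tail.
"""

from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def hamming_hits(insert, seqs):
    """All (gene_id, start, end, mm) placements with mm <= 1; 1-based."""
    k = len(insert)
    hits = []
    for gid, s in seqs.items():
        for off in range(len(s) - k + 1):
            mm = 0
            for a, b in zip(insert, s[off : off + k]):
                if a != b:
                    mm += 1
                    if mm > 1:
                        break
            if mm <= 1:
                hits.append((gid, off + 1, off + k, mm))
    return hits


def tiered_hits(insert, matures, precursors):
    """Two-pass best-tier selection: mature 0mm > mature 1mm > precursor."""
    for seqs, source in ((matures, "mature"), (precursors, "precursor")):
        hits = hamming_hits(insert, seqs)
        for want in (0, 1):
            tier = [(g, s, e, mm, source) for g, s, e, mm in hits if mm == want]
            if tier:
                return tier
    return []


def seed_sites_bruteforce(utr, tsrna):
    """Every 6-window compared against the seed complement, with typing."""
    seed = tsrna[1:7]
    core = "".join(_COMP[c] for c in reversed(seed))
    out = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != core:
            continue
        m8 = i > 0 and len(tsrna) >= 8 and utr[i - 1] == _COMP[tsrna[7]]
        a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        kind = {(True, True): "8mer", (True, False): "7mer-m8",
                (False, True): "7mer-A1", (False, False): "6mer"}[(m8, a1)]
        out.append((i + 1, kind))
    return out


def duplex_dp_oracle(ts, window, match=5.0, wobble=1.0, mismatch=-3.0,
                     gap_open=-8.0, gap_extend=-2.0, seed_weight=2.0,
                     seed_span=(2, 8)):
    """Plain-loop local affine alignment of ts vs the reversed window."""
    win = window[::-1]
    n, m = len(ts), len(win)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        w = seed_weight if seed_span[0] <= i <= seed_span[1] else 1.0
        for j in range(1, m + 1):
            a, b = ts[i - 1], win[j - 1]
            if b == _COMP[a]:
                s = match
            elif (a, b) in (("G", "T"), ("T", "G")):
                s = wobble
            else:
                s = mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1], 0.0) + w * s
            X[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1] + gap_extend)
            Y[i][j] = max(M[i - 1][j] + gap_open, Y[i - 1][j] + gap_extend)
            best = max(best, M[i][j])
    return best


def hypergeom_tail_enumeration(N, K, n, k):
    """P(overlap >= k) by enumerating all C(N, n) draws."""
    universe = range(N)
    inside = set(range(K))
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(inside.intersection(draw)) >= k:
            hits += 1
    return hits / total


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
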