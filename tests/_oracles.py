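"""Independent brute-force oracles used only by the test suite.

Each oracle is deliberately naive (quadratic DP, position-by-position scans,
exact-rational enumeration) and shares no code with the implementation paths
it checks.
"""

from fractions import Fraction
from math import comb


def gotoh_local_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Reference quadratic-time Smith-Waterman with affine gaps.

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


_COMP = str.maketrans("ACGTN", "TGCAN")


def brute_force_sites(protospacer: str, contig: str, seq: str, max_mm: int):
    """Position-by-position protospacer scan on both strands (NGG PAM).

    Returns a set of (contig, start, strand, mismatches) with start the
    forward-strand 0-based protospacer start.
    """
    found = set()

    def scan(s: str, strand: str, L: int):
        for i in range(len(s) - 23 + 1):
            window = s[i : i + 20]
            pam = s[i + 20 : i + 23]
            if pam[0] == "N" or pam[1] != "G" or pam[2] != "G":
                continue
            mm = 0
            for x, y in zip(window, protospacer):
                if x != y or x == "N":
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm:
                start = i if strand == "+" else L - i - 20
                found.add((contig, start, strand, mm))

    rc = seq.translate(_COMP)[::-1]
    scan(seq, "+", len(seq))
    scan(rc, "-", len(seq))
    return found


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational two-sided Fisher p by enumerating all tables with the
    observed margins; tables with point probability <= observed contribute
    (exact integer tie comparison)."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = comb(r1, a) * comb(r2, c)
    num = sum(w for w in weights if w <= w_obs)
    return Fraction(num, sum(weights))
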