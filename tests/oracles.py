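"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the scanner oracle
is regex-free, the exact-test oracles enumerate the full null support.
"""

from __future__ import annotations

import itertools
from math import comb

from groupscan.motifs import IUPAC, MotifMatch

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "D": "H", "H": "D", "V": "B",
    "N": "N",
}


def oracle_scan(seq: str, pattern: str, both_strands: bool) -> list[MotifMatch]:
    """Sliding-window IUPAC matcher; N in the subject matches nothing."""
    seq = seq.upper()

    def hits(pat: str, strand: str) -> list[MotifMatch]:
        out = []
        for i in range(len(seq) - len(pat) + 1):
            if all(
                seq[i + j] in IUPAC[pat[j]] and seq[i + j] != "N"
                for j in range(len(pat))
            ):
                out.append(MotifMatch(i, strand))
        return out

    res = hits(pattern.upper(), "+")
    if both_strands:
        rc = "".join(_COMPLEMENT[c] for c in reversed(pattern.upper()))
        res += hits(rc, "-")
    return sorted(res, key=lambda h: (h.position, h.strand))


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration, point-probability two-sided."""
    r1, r2 = a + b, c + d
    c1 = a + c
    weights = {
        x: comb(r1, x) * comb(r2, c1 - x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    total = sum(weights.values())
    obs = weights[a]
    return sum(w for w in weights.values() if w <= obs) / total


def mw_oracle(x, y) -> float:
    """Exact two-sided Mann-Whitney p by full arrangement enumeration."""
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    combined = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    stat = min(u_obs, nx * ny - u_obs)
    count = total = 0
    for subset in itertools.combinations(range(nx + ny), nx):
        u = sum(i + 1 for i in subset) - nx * (nx + 1) / 2
        total += 1
        if min(u, nx * ny - u) <= stat + 1e-9:
            count += 1
    return count / total
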