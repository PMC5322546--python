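"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a structurally different route
(exhaustive enumeration, closed forms, third-party libraries) than the
package implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import permutations

from Bio.Data import CodonTable

# ---------------------------------------------------------------------------
# exhaustive chain search (synteny oracle)


def _oracle_chain_score(chain, orientation, gap_penalty):
    score = float(len(chain))
    for p, c in zip(chain, chain[1:]):
        da = c[0] - p[0] - 1
        db = (c[1] - p[1] - 1) if orientation == "same" else (p[1] - c[1] - 1)
        score -= gap_penalty * (da + db)
    return score


def _all_chains(points, orientation, max_gap):
    """Every strictly monotone chain (as rank-pair tuples) under the gap
    constraint, by depth-first extension."""
    pts = sorted(points)
    chains = []

    def ok(p, c):
        da = c[0] - p[0]
        if not 1 <= da <= max_gap + 1:
            return False
        db = c[1] - p[1] if orientation == "same" else p[1] - c[1]
        return 1 <= db <= max_gap + 1

    def extend(chain):
        chains.append(tuple(chain))
        last = chain[-1]
        for p in pts:
            if p > last and ok(last, p):
                chain.append(p)
                extend(chain)
                chain.pop()

    for p in pts:
        extend([p])
    return chains


def exhaustive_chain_blocks(points, min_anchors, max_gap, gap_penalty):
    """Greedy best-chain peeling by brute-force enumeration.

    ``points`` are (rank_a, rank_b) pairs on one chromosome pair.
    Returns a list of (orientation, chain-tuple) in extraction order,
    mirroring the tie rules: highest score, "same" orientation first,
    then lexicographically smallest chain.
    """
    remaining = set(points)
    out = []
    while remaining:
        candidates = []
        for pref, orientation in ((0, "same"), (1, "inverted")):
            for chain in _all_chains(remaining, orientation, max_gap):
                candidates.append(
                    (_oracle_chain_score(chain, orientation, gap_penalty), pref, chain, orientation)
                )
        if not candidates:
            break
        best = max(c[0] for c in candidates)
        # float-tolerant tie grouping: genuinely distinct scores differ
        # by at least one gap-penalty unit
        ties = [c for c in candidates if c[0] >= best - 1e-9]
        ties.sort(key=lambda c: (c[1], c[2]))
        _, _, chain, orientation = ties[0]
        if len(chain) < min_anchors:
            break
        out.append((orientation, chain))
        remaining -= set(chain)
    return out


# ---------------------------------------------------------------------------
# Fisher / hypergeometric oracle (exact rational arithmetic)


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X hypergeometric with margins of the 2x2 table
    [[a, b], [c, d]]: draws of size a+b from a population of a+b+c+d
    with a+c successes."""
    n = a + b
    K = a + c
    N = a + b + c + d
    num = sum(math.comb(K, k) * math.comb(N - K, n - k) for k in range(a, min(n, K) + 1))
    return float(Fraction(num, math.comb(N, n)))


# ---------------------------------------------------------------------------
# NG86 brute-force oracle: same conventions, independent derivation
# (genetic code from Bio.Data, per-codon counting written from scratch)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_ORACLE_AA = dict(_TABLE.forward_table)
_ORACLE_STOPS = set(_TABLE.stop_codons)


def oracle_sites(codon: str) -> tuple[float, float]:
    syn = non = 0
    aa = _ORACLE_AA[codon]
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _ORACLE_STOPS:
                non += 1
            elif _ORACLE_AA[alt] == aa:
                syn += 1
            else:
                non += 1
    norm = 3.0 / (syn + non)
    return syn * norm, non * norm


def oracle_diffs(c1: str, c2: str) -> tuple[float, float]:
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    syn_tot = non_tot = 0.0
    valid = 0
    fallback = []
    for order in permutations(positions):
        cur = c1
        syn = non = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _ORACLE_STOPS:
                through_stop = True
                non += 1
            elif _ORACLE_AA.get(cur, "*") == _ORACLE_AA.get(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        fallback.append((syn, non))
        if not through_stop:
            syn_tot += syn
            non_tot += non
            valid += 1
    if valid == 0:
        syn_tot = sum(s for s, _ in fallback)
        non_tot = sum(n for _, n in fallback)
        valid = len(fallback)
    return syn_tot / valid, non_tot / valid


def oracle_ng86(codons_a, codons_b) -> tuple[float, float]:
    """(Ka, Ks) by direct per-codon counting plus Jukes-Cantor."""
    s_sites = n_sites = s_diff = n_diff = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        sd, nd = oracle_diffs(ca, cb)
        s_diff += sd
        n_diff += nd

    def jc(p):
        arg = 1 - 4 * p / 3
        return -0.75 * math.log(arg) if arg > 0 else float("nan")

    return jc(n_diff / n_sites), jc(s_diff / s_sites)
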