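"""Pairwise Ka/Ks by the Nei–Gojobori (1986) counting method, codon
alignment cleaning, a small codon-aware global aligner for fixtures,
and per-duplication-mode divergence summaries.

NG86 in brief: each codon contributes synonymous (S) and nonsynonymous
(N) *sites* according to the fraction of its nine single-nucleotide
neighbours that preserve the amino acid (mutations creating stop codons
count as nonsynonymous, so N + S = 3 per codon).  Observed differences
between a codon pair are partitioned into synonymous/nonsynonymous
counts by averaging over all substitution orderings, excluding pathways
that pass through a stop codon (renormalized).  The proportions
p = differences/sites are corrected for multiple hits with the
Jukes–Cantor formula d = -3/4 ln(1 - 4p/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product
from typing import Iterable, Mapping

import numpy as np

_BASES = "TCAG"
_CODONS = ["".join(c) for c in product(_BASES, repeat=3)]
# standard nuclear genetic code, NCBI table 1
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE: dict[str, str] = {c: a for c, a in zip(_CODONS, _AA)}
STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")


def _site_counts() -> dict[str, tuple[float, float]]:
    """Per-codon (S, N) site counts, normalized so S + N = 3."""
    table = {}
    for codon, aa in GENETIC_CODE.items():
        if aa == "*":
            continue
        s = n = 0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if GENETIC_CODE[alt] == aa and alt not in STOP_CODONS:
                    s += 1
                else:
                    n += 1
        table[codon] = (3.0 * s / (s + n), 3.0 * n / (s + n))
    return table


_SITES = _site_counts()


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts between two
    codons over all substitution orderings, skipping pathways through
    stop codons (renormalized over the valid pathways)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        cur = c1
        s = n = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if valid:
            total_s += s
            total_n += n
            n_valid += 1
    if n_valid == 0:
        # every ordering passes through a stop; fall back to the
        # unfiltered average (stop intermediates scored nonsynonymous)
        # so the differences are not silently lost
        for order in permutations(diff_pos):
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt not in STOP_CODONS and GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    total_s += 1
                else:
                    total_n += 1
                cur = nxt
            n_valid += 1
    return total_s / n_valid, total_n / n_valid


_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


@dataclass(frozen=True)
class CodonAlignment:
    """A cleaned, gap-free, stop-free pairwise codon alignment."""

    gene_a: str
    gene_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KaKsResult:
    gene_a: str
    gene_b: str
    ka: float  # NaN when undefined
    ks: float  # NaN when undefined
    omega: float  # NaN when undefined (Ks == 0 or either rate undefined)
    n_codons: int
    s_sites: float
    n_sites: float
    flags: tuple[str, ...] = ()
    method: str = "NG86"

    @property
    def defined(self) -> bool:
        return self.ka == self.ka and self.ks == self.ks


def clean_codon_alignment(
    gene_a: str, gene_b: str, aligned_a: str, aligned_b: str
) -> CodonAlignment:
    """Drop codon columns containing a gap or a stop codon in either
    sequence; anything non-ACGT in a column also drops it."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    if len(aligned_a) % 3 != 0:
        raise ValueError(f"alignment length {len(aligned_a)} is not a multiple of 3")
    ca, cb = [], []
    n_removed = 0
    for i in range(0, len(aligned_a), 3):
        a = aligned_a[i : i + 3].upper()
        b = aligned_b[i : i + 3].upper()
        if "-" in a or "-" in b or a in STOP_CODONS or b in STOP_CODONS:
            n_removed += 1
            continue
        if any(ch not in "ACGT" for ch in a + b):
            n_removed += 1
            continue
        ca.append(a)
        cb.append(b)
    return CodonAlignment(gene_a=gene_a, gene_b=gene_b, codons_a=tuple(ca), codons_b=tuple(cb))


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes–Cantor multiple-hit correction; returns (d, defined)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return float("nan"), False
    return -0.75 * math.log(arg), True


def kaks_ng86(alignment: CodonAlignment) -> KaKsResult:
    """NG86 Ka, Ks and omega for one cleaned codon alignment.

    Sites are averaged over both sequences; saturation (p >= 3/4) or a
    non-positive log argument leaves the corresponding rate NaN with a
    flag, never silently zero.
    """
    if alignment.n_codons < 1:
        raise ValueError("empty alignment")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        sa, na = _SITES[ca]
        sb, nb = _SITES[cb]
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        key = (ca, cb) if ca <= cb else (cb, ca)
        if key not in _PATH_CACHE:
            _PATH_CACHE[key] = _pathway_counts(*key)
        sd, nd = _PATH_CACHE[key]
        s_diff += sd
        n_diff += nd
    flags: list[str] = []
    ps = s_diff / s_sites if s_sites > 0 else 0.0
    pn = n_diff / n_sites if n_sites > 0 else 0.0
    ks, ks_ok = _jc_correct(ps)
    ka, ka_ok = _jc_correct(pn)
    if not ks_ok:
        flags.append("ks_saturated")
    if not ka_ok:
        flags.append("ka_saturated")
    if ks_ok and ks > 0 and ka_ok:
        omega = ka / ks
    else:
        omega = float("nan")
        if ks_ok and ks == 0:
            flags.append("omega_undefined_ks_zero")
    return KaKsResult(
        gene_a=alignment.gene_a,
        gene_b=alignment.gene_b,
        ka=ka,
        ks=ks,
        omega=omega,
        n_codons=alignment.n_codons,
        s_sites=s_sites,
        n_sites=n_sites,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# fixture aligner: simple global codon-aware Needleman–Wunsch.  Real
# analyses are expected to consume pre-aligned CDS; this exists so the
# simulator and tests can handle length-changing events (transposition
# truncation/deletions) without an external aligner.


def align_codons(
    seq_a: str, seq_b: str, gap_penalty: float = -4.0
) -> tuple[str, str]:
    """Global alignment at codon resolution; gaps are whole codons.

    Codon match score = (#identical nucleotides)*2 - 3, i.e. +3 for an
    identical codon, -3 for a fully different one.  Ties prefer
    diagonal, then a gap in ``seq_b``, for determinism.
    """
    if len(seq_a) % 3 or len(seq_b) % 3:
        raise ValueError("sequences must be in frame (length divisible by 3)")
    a = [seq_a[i : i + 3] for i in range(0, len(seq_a), 3)]
    b = [seq_b[i : i + 3] for i in range(0, len(seq_b), 3)]
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up(gap in b), 2 left(gap in a)
    score[:, 0] = np.arange(n + 1) * gap_penalty
    score[0, :] = np.arange(m + 1) * gap_penalty
    move[1:, 0] = 1
    move[0, 1:] = 2
    match = np.empty((n, m))
    for i in range(n):
        ai = a[i]
        for j in range(m):
            bj = b[j]
            match[i, j] = 2 * sum(x == y for x, y in zip(ai, bj)) - 3
    for i in range(1, n + 1):
        srow = score[i - 1]
        for j in range(1, m + 1):
            d = srow[j - 1] + match[i - 1, j - 1]
            u = srow[j] + gap_penalty
            l = score[i, j - 1] + gap_penalty
            if d >= u and d >= l:
                score[i, j], move[i, j] = d, 0
            elif u >= l:
                score[i, j], move[i, j] = u, 1
            else:
                score[i, j], move[i, j] = l, 2
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif mv == 1:
            out_a.append(a[i - 1])
            out_b.append("---")
            i -= 1
        else:
            out_a.append("---")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


# ---------------------------------------------------------------------------
# per-mode aggregation


@dataclass
class ModeDivergence:
    mode: str
    n_pairs: int
    mean_ka: float
    mean_ks: float
    ratio_of_means: float  # mean Ka / mean Ks (the tabulated convention)
    mean_of_ratios: float  # mean of per-pair omega over defined pairs


def group_divergence(
    kaks_results: Iterable[KaKsResult],
    pair_modes: Mapping[tuple[str, str], str],
) -> dict[str, ModeDivergence]:
    """Aggregate Ka/Ks by duplication mode.

    ``pair_modes`` assigns each analyzed (unordered) gene pair to exactly
    one mode class.  Both the ratio of mode means (the convention behind
    tabulated per-mode Ka/Ks) and the mean of per-pair ratios are
    reported; empty modes are absent from the result, never zero.
    Rounding is left to report time.
    """
    groups: dict[str, list[KaKsResult]] = {}
    for r in kaks_results:
        mode = pair_modes.get((r.gene_a, r.gene_b), pair_modes.get((r.gene_b, r.gene_a)))
        if mode is None:
            continue
        groups.setdefault(mode, []).append(r)
    out = {}
    for mode, results in groups.items():
        defined = [r for r in results if r.defined]
        if not defined:
            continue
        mean_ka = sum(r.ka for r in defined) / len(defined)
        mean_ks = sum(r.ks for r in defined) / len(defined)
        omegas = [r.omega for r in defined if r.omega == r.omega]
        out[mode] = ModeDivergence(
            mode=mode,
            n_pairs=len(defined),
            mean_ka=mean_ka,
            mean_ks=mean_ks,
            ratio_of_means=mean_ka / mean_ks if mean_ks > 0 else float("nan"),
            mean_of_ratios=sum(omegas) / len(omegas) if omegas else float("nan"),
        )
    return out


@dataclass
class ModeLengthDivergence:
    mode: str
    n_pairs: int
    mean_abs_diff: float
    sd_abs_diff: float
    mean_pair_length: float
    sd_pair_length: float


def cds_length_divergence(
    pair_modes: Mapping[tuple[str, str], str],
    cds_lengths: Mapping[str, int],
) -> dict[str, ModeLengthDivergence]:
    """Per-mode distribution of |CDS length difference| and pair mean
    length; pairs with a missing length are skipped with a warning."""
    import warnings

    groups: dict[str, list[tuple[float, float]]] = {}
    for (a, b), mode in pair_modes.items():
        if a not in cds_lengths or b not in cds_lengths:
            warnings.warn(f"pair ({a}, {b}) lacks cds_length; skipped", stacklevel=2)
            continue
        la, lb = cds_lengths[a], cds_lengths[b]
        groups.setdefault(mode, []).append((abs(la - lb), (la + lb) / 2.0))
    out = {}
    for mode, vals in groups.items():
        diffs = np.array([v[0] for v in vals], dtype=float)
        means = np.array([v[1] for v in vals], dtype=float)
        out[mode] = ModeLengthDivergence(
            mode=mode,
            n_pairs=len(vals),
            mean_abs_diff=float(diffs.mean()),
            sd_abs_diff=float(diffs.std(ddof=1)) if len(vals) > 1 else 0.0,
            mean_pair_length=float(means.mean()),
            sd_pair_length=float(means.std(ddof=1)) if len(vals) > 1 else 0.0,
        )
    return out


def kaks_for_pairs(
    pairs: Iterable[tuple[str, str]],
    sequences: Mapping[str, str],
) -> list[KaKsResult]:
    """Convenience: align (if needed), clean and score a list of CDS pairs.

    Equal-length pairs are compared position-wise; unequal-length pairs go
    through the codon-aware fixture aligner.
    """
    results = []
    for a, b in pairs:
        sa, sb = sequences[a], sequences[b]
        if len(sa) != len(sb):
            sa, sb = align_codons(sa, sb)
        aln = clean_codon_alignment(a, b, sa, sb)
        if aln.n_codons == 0:
            continue
        results.append(kaks_ng86(aln))
    return results
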