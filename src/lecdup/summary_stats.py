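"""Summary statistics: retention scores, tandem-array statistics,
ohnolog-enrichment Fisher tests and duplicate-fraction reports.

Rounding convention throughout: percentages round half-up to integers,
array-size averages half-up to one decimal, Ka/Ks to two decimals —
applied only at report time; raw counts and exact fractions are always
preserved alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact

from .dup_classifier import DuplicationCall, TandemArray


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 -> 1), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    v = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(v) if decimals else int(v)


@dataclass(frozen=True)
class RetentionReport:
    species: str
    n_reference_targets: int
    n_retained: int
    score: int  # percent, rounded half-up
    fraction: float  # exact


def retention_score(
    reference_targets: Iterable[str] | int,
    retained: Iterable[str] | int,
    species: str = "",
) -> RetentionReport:
    """Percentage of reference family members retained (e.g. with a
    syntenic ortholog) in a comparison species.

    Accepts gene sets or plain counts; with sets, ``retained`` must be a
    subset of the reference.
    """
    if isinstance(reference_targets, int):
        n_ref, n_ret = reference_targets, int(retained)  # type: ignore[arg-type]
    else:
        ref = set(reference_targets)
        ret = set(retained)  # type: ignore[arg-type]
        if not ret <= ref:
            raise ValueError("retained genes must be a subset of the reference targets")
        n_ref, n_ret = len(ref), len(ret)
    if n_ref == 0:
        raise ValueError("empty reference target set")
    if not 0 <= n_ret <= n_ref:
        raise ValueError("retained count outside [0, reference count]")
    frac = n_ret / n_ref
    return RetentionReport(
        species=species,
        n_reference_targets=n_ref,
        n_retained=n_ret,
        score=int(round_half_up(100.0 * frac)),
        fraction=frac,
    )


@dataclass(frozen=True)
class TandemStats:
    species: str
    n_universe: int
    n_tandem_members: int
    fraction_pct: int  # round-half-up percent
    n_arrays: int
    mean_array_size: float  # round-half-up, 1 decimal
    largest_array: int


def tandem_stats(
    arrays: Iterable[TandemArray],
    target_gene_universe: Iterable[str],
    species: str = "",
) -> TandemStats:
    """Tandem-duplicate counts over a gene universe: member count and
    fraction, number of arrays, average and largest array size.
    Arrays are restricted to members inside the universe."""
    universe = set(target_gene_universe)
    member_lists = []
    for arr in arrays:
        members = [m for m in arr.members if m in universe]
        if len(members) >= 2:
            member_lists.append(members)
    n_members = sum(len(m) for m in member_lists)
    n_arrays = len(member_lists)
    return TandemStats(
        species=species,
        n_universe=len(universe),
        n_tandem_members=n_members,
        fraction_pct=(
            int(round_half_up(100.0 * n_members / len(universe))) if universe else 0
        ),
        n_arrays=n_arrays,
        mean_array_size=round_half_up(n_members / n_arrays, 1) if n_arrays else 0.0,
        largest_array=max((len(m) for m in member_lists), default=0),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    species: str
    target_ohnolog: int
    target_other: int
    background_ohnolog: int
    background_other: int
    odds_ratio: float
    p_value: float
    alpha: float
    significant: bool


def ohnolog_enrichment(
    target_counts: tuple[int, int],
    genome_counts: tuple[int, int],
    alpha: float = 0.01,
    species: str = "",
    background_excludes_targets: bool = True,
) -> EnrichmentResult:
    """One-sided Fisher's exact test for over-retention of ohnologs
    among target genes relative to the genome-wide background.

    ``target_counts`` = (ohnolog, non-ohnolog) among target genes;
    ``genome_counts`` = genome-wide (ohnolog, non-ohnolog).  By default
    the target genes are removed from the background cells so the 2x2
    table is disjoint.  p is the hypergeometric upper tail of the
    observed target-ohnolog count.
    """
    t_ohno, t_other = target_counts
    g_ohno, g_other = genome_counts
    if background_excludes_targets:
        g_ohno -= t_ohno
        g_other -= t_other
    if min(t_ohno, t_other, g_ohno, g_other) < 0:
        raise ValueError("negative cell in the 2x2 table")
    if t_ohno + t_other == 0:
        raise ValueError("no target genes")
    odds, p = fisher_exact([[t_ohno, t_other], [g_ohno, g_other]], alternative="greater")
    return EnrichmentResult(
        species=species,
        target_ohnolog=t_ohno,
        target_other=t_other,
        background_ohnolog=g_ohno,
        background_other=g_other,
        odds_ratio=float(odds),
        p_value=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
    )


@dataclass(frozen=True)
class FractionReport:
    species: str
    n_genes: int
    n_duplicates: int
    duplicate_pct: int
    mode_counts: Mapping[str, int]  # gene-level, non-exclusive
    mode_pcts: Mapping[str, int]
    venn: Mapping[frozenset, int]


def fraction_report(
    calls: Mapping[str, DuplicationCall],
    venn: Mapping[frozenset, int],
    species: str = "",
) -> FractionReport:
    """Per-species duplicate fractions: overall duplicate percentage,
    per-mode gene-level percentages (non-exclusive) and Venn cells."""
    n_genes = len(calls)
    n_dup = sum(1 for c in calls.values() if not c.singleton)
    mode_counts = {m: 0 for m in ("tandem", "ohnolog", "gtd", "td_alpha")}
    for c in calls.values():
        for m in c.labels:
            mode_counts[m] = mode_counts.get(m, 0) + 1
    pct = lambda k: int(round_half_up(100.0 * k / n_genes)) if n_genes else 0
    return FractionReport(
        species=species,
        n_genes=n_genes,
        n_duplicates=n_dup,
        duplicate_pct=pct(n_dup),
        mode_counts=mode_counts,
        mode_pcts={m: pct(k) for m, k in mode_counts.items()},
        venn=dict(venn),
    )


def pooled_fraction_report(reports: Sequence[FractionReport]) -> FractionReport:
    """Sigma row: counts summed over species, percentages recomputed
    from the pooled counts."""
    n_genes = sum(r.n_genes for r in reports)
    n_dup = sum(r.n_duplicates for r in reports)
    modes = sorted({m for r in reports for m in r.mode_counts})
    mode_counts = {m: sum(r.mode_counts.get(m, 0) for r in reports) for m in modes}
    venn: dict[frozenset, int] = {}
    for r in reports:
        for cell, k in r.venn.items():
            venn[cell] = venn.get(cell, 0) + k
    pct = lambda k: int(round_half_up(100.0 * k / n_genes)) if n_genes else 0
    return FractionReport(
        species="SIGMA",
        n_genes=n_genes,
        n_duplicates=n_dup,
        duplicate_pct=pct(n_dup),
        mode_counts=mode_counts,
        mode_pcts={m: pct(k) for m, k in mode_counts.items()},
        venn=venn,
    )
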