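"""Ortholog/paralog/anchor gene sets from similarity hits, and
domain-composition family classification.

Reciprocal best hits (RBH) are the standard orthology proxy: gene *a* in
species A and gene *b* in species B form a pair iff each is the other's
best hit.  "Best" is made deterministic by the tie rule lowest e-value ->
highest bitscore -> lexicographically smallest subject id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation_io import SimilarityHit


@dataclass(frozen=True)
class RBHPair:
    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    evalue_ab: float
    evalue_ba: float


@dataclass(frozen=True)
class FamilyLabel:
    gene_id: str
    label: str  # LecRK | LecRP | LecP | non_target
    basis: frozenset[str]


def filter_hits(
    hits: Iterable[SimilarityHit],
    e_max: float,
    length_window: tuple[float, float] | None = None,
) -> list[SimilarityHit]:
    """Keep hits with evalue <= e_max and, when windowed, a query/subject
    length ratio inside [low, high].

    The three hit-set variants used for RBH building (length-filtered
    protein, unfiltered protein, unfiltered CDS) are all reachable by
    parameter choice: pass ``length_window=(0.5, 2)`` or ``None``.
    Idempotent by construction.
    """
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if length_window is not None:
        low, high = length_window
        if not low < high:
            raise ValueError("length window low must be < high")
    out = []
    for h in hits:
        if h.evalue > e_max:
            continue
        if length_window is not None:
            if h.query_length is None or h.subject_length is None:
                raise ValueError(
                    f"hit {h.query_id}/{h.subject_id} lacks sequence lengths; "
                    "length-window filtering needs the qlen/slen hit columns"
                )
            ratio = h.query_length / h.subject_length
            if not (low <= ratio <= high):
                continue
        out.append(h)
    return out


def _hit_rank_key(h: SimilarityHit) -> tuple:
    # lowest e-value, then highest bitscore, then smallest subject id
    return (h.evalue, -h.bitscore, h.subject_id)


def best_hits(hits: Iterable[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best subject per query under the deterministic tie rule."""
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank_key(h) < _hit_rank_key(cur):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[SimilarityHit],
    hits_ba: Iterable[SimilarityHit],
    e_max: float,
    species_a: str = "A",
    species_b: str = "B",
) -> list[RBHPair]:
    """Mutual best hits between two gene sets.

    Each gene appears in at most one pair.  Raises if the two hit sets
    share query genes (overlapping species labels).
    """
    hits_ab = filter_hits(hits_ab, e_max)
    hits_ba = filter_hits(hits_ba, e_max)
    queries_ab = {h.query_id for h in hits_ab}
    queries_ba = {h.query_id for h in hits_ba}
    if queries_ab & queries_ba:
        raise ValueError(
            "hit sets share query genes; the two directions must come from "
            "different species"
        )
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    pairs = []
    for a, hab in sorted(best_ab.items()):
        b = hab.subject_id
        hba = best_ba.get(b)
        if hba is not None and hba.subject_id == a:
            pairs.append(
                RBHPair(
                    gene_a=a,
                    gene_b=b,
                    species_a=species_a,
                    species_b=species_b,
                    evalue_ab=hab.evalue,
                    evalue_ba=hba.evalue,
                )
            )
    return pairs


def build_anchor_pool(
    rbh_pairs: Iterable[RBHPair],
    ohnolog_pairs: Iterable[tuple[str, str]],
) -> set[str]:
    """Union of genes appearing in the RBH set or the ohnolog pair set.

    The pooled "anchor" genes seed the paralog screen below.
    """
    pool: set[str] = set()
    for p in rbh_pairs:
        pool.add(p.gene_a)
        pool.add(p.gene_b)
    for a, b in ohnolog_pairs:
        pool.add(a)
        pool.add(b)
    return pool


def paralog_screen(
    candidate_genes: Iterable[str],
    hits_vs_reference: Iterable[SimilarityHit],
    anchor_pool: set[str],
    reference_targets: set[str],
) -> set[str]:
    """Anchor paralogs: candidates whose single best reference subject is a
    reference target gene, and which are not already in the anchor pool.

    Mimics a max-target-sequences-1 query: only the best subject per query
    (RBH tie rule) is considered.
    """
    candidates = set(candidate_genes)
    best = best_hits(hits_vs_reference)
    out = set()
    for q in candidates:
        h = best.get(q)
        if h is None or q in anchor_pool:
            continue
        if h.subject_id in reference_targets:
            out.add(q)
    return out


_KNOWN_DOMAINS = {"lectin_L", "kinase", "TM", "signal_peptide"}


def classify_family(domain_table: Mapping[str, Sequence[str]]) -> list[FamilyLabel]:
    """Classify genes by lectin-family domain configuration.

    lectin + kinase -> LecRK (receptor kinase); lectin + TM, no kinase ->
    LecRP (receptor protein); lectin only -> LecP; no lectin -> non_target.
    Exactly one label per gene.  Unknown domain labels are ignored with a
    warning (duplicated domains, e.g. two kinase domains, do not change
    the label).
    """
    labels = []
    unknown: set[str] = set()
    for gene_id in domain_table:
        domains = set(domain_table[gene_id])
        unknown |= domains - _KNOWN_DOMAINS
        known = domains & _KNOWN_DOMAINS
        if "lectin_L" not in known:
            label = "non_target"
        elif "kinase" in known:
            label = "LecRK"
        elif "TM" in known:
            label = "LecRP"
        else:
            label = "LecP"
        labels.append(FamilyLabel(gene_id=gene_id, label=label, basis=frozenset(known)))
    if unknown:
        warnings.warn(f"ignored unknown domain labels: {sorted(unknown)}", stacklevel=2)
    return labels
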