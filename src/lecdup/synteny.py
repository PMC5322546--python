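"""Collinear block detection by dynamic-programming chaining, block
merging, syntenic-depth filtering, and ohnolog calling.

The chaining model: an anchor is a pair of genes (one per genome, or two
in one genome for self-comparison) connected by a filtered similarity
hit.  A block is a chain of anchors whose ranks increase strictly on
side A and increase (same orientation) or decrease (inverted) strictly
on side B, with at most ``max_gap`` intervening genes between successive
anchors on either side.  Chain score is one point per anchor minus a
linear gap penalty; chains are extracted greedily, best score first,
each anchor used at most once.  Chains shorter than ``min_anchors``
(default 5 collinear genes to seed a block) are discarded.

Within-genome self-comparison with the identity diagonal removed turns
the same machinery into an ohnolog detector: anchors of retained blocks
are paralog pairs created by whole-genome duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Mapping, Sequence

from .annotation_io import GenomeAnnotation, SimilarityHit


@dataclass(frozen=True)
class SyntenyAnchor:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    chrom_a: str
    chrom_b: str
    ks: float | None = None


@dataclass
class SyntenyBlock:
    block_id: int
    anchors: list[SyntenyAnchor]
    orientation: str  # same | inverted
    score: float
    median_ks: float | None = None
    epoch: str = "unassigned"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)


@dataclass(frozen=True)
class OhnologPair:
    gene_a: str
    gene_b: str
    block_id: int
    within_species: bool
    epoch: str = "unassigned"


DEFAULT_MIN_ANCHORS = 5
DEFAULT_MAX_GAP = 20
DEFAULT_MERGE_DISTANCE = 350
DEFAULT_MAX_DEPTH = 3
DEFAULT_GAP_PENALTY = 0.05

#: Ks intervals for assigning blocks to polyploidy epochs.  These are
#: deliberately user-tunable: absolute Ks scales depend on the lineage's
#: substitution rate, and reports flag epoch assignments as bin-dependent.
DEFAULT_EPOCH_BINS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "beta": (1.0, 2.2),
    "gamma": (2.2, float("inf")),
}


def _chain_score(anchors: Sequence[SyntenyAnchor], orientation: str, gap_penalty: float) -> float:
    score = float(len(anchors))
    for prev, cur in zip(anchors, anchors[1:]):
        da = cur.rank_a - prev.rank_a - 1
        db = (cur.rank_b - prev.rank_b - 1) if orientation == "same" else (prev.rank_b - cur.rank_b - 1)
        score -= gap_penalty * (da + db)
    return score


def _step_ok(prev: SyntenyAnchor, cur: SyntenyAnchor, orientation: str, max_gap: int) -> bool:
    da = cur.rank_a - prev.rank_a
    if not 1 <= da <= max_gap + 1:
        return False
    db = cur.rank_b - prev.rank_b if orientation == "same" else prev.rank_b - cur.rank_b
    return 1 <= db <= max_gap + 1


def _best_chain(
    anchors: list[SyntenyAnchor], orientation: str, max_gap: int, gap_penalty: float
) -> tuple[float, list[SyntenyAnchor]] | None:
    """Maximum-score chain in one orientation; ties broken toward the
    lexicographically smallest (rank_a, rank_b) anchor sequence."""
    if not anchors:
        return None
    order = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    # DP over anchors in rank order; store (score, chain-rank-tuple, chain)
    best: list[tuple[float, tuple, list[SyntenyAnchor]]] = []
    for i, cur in enumerate(order):
        cand_score, cand_key, cand_chain = 1.0, ((cur.rank_a, cur.rank_b),), [cur]
        for j in range(i):
            prev = order[j]
            if not _step_ok(prev, cur, orientation, max_gap):
                continue
            da = cur.rank_a - prev.rank_a - 1
            db = (cur.rank_b - prev.rank_b - 1) if orientation == "same" else (prev.rank_b - cur.rank_b - 1)
            s = best[j][0] + 1.0 - gap_penalty * (da + db)
            key = best[j][1] + ((cur.rank_a, cur.rank_b),)
            if s > cand_score + 1e-12 or (abs(s - cand_score) <= 1e-12 and key < cand_key):
                cand_score, cand_key, cand_chain = s, key, best[j][2] + [cur]
        best.append((cand_score, cand_key, cand_chain))
    # tie-break: highest score, then lexicographically smallest chain
    top_score = max(t[0] for t in best)
    ties = [t for t in best if abs(t[0] - top_score) <= 1e-12]
    ties.sort(key=lambda t: t[1])
    score, _, chain = ties[0]
    return score, chain


def chain_blocks(
    anchors: Iterable[SyntenyAnchor],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> list[SyntenyBlock]:
    """Greedy extraction of maximal-scoring collinear chains.

    Per chromosome pair, repeatedly find the best-scoring chain over the
    remaining anchors (considering both orientations; ties prefer "same",
    then the earlier-starting chain), emit it if it has at least
    ``min_anchors`` anchors, and remove its anchors.
    """
    if min_anchors < 1 or max_gap < 0 or gap_penalty < 0:
        raise ValueError("chaining parameters must be positive")
    groups: dict[tuple[str, str], list[SyntenyAnchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks: list[SyntenyBlock] = []
    bid = 0
    for key in sorted(groups):
        remaining = groups[key]
        while remaining:
            candidates = []
            for orientation in ("same", "inverted"):
                res = _best_chain(remaining, orientation, max_gap, gap_penalty)
                if res is not None:
                    candidates.append((res[0], 0 if orientation == "same" else 1, orientation, res[1]))
            if not candidates:
                break
            # float-tolerant tie grouping ("same" orientation first, then
            # earliest chain); distinct scores differ by >= a penalty unit
            top = max(t[0] for t in candidates)
            ties = [t for t in candidates if t[0] >= top - 1e-9]
            ties.sort(key=lambda t: (t[1], [(a.rank_a, a.rank_b) for a in t[3]]))
            score, _, orientation, chain = ties[0]
            if len(chain) < min_anchors:
                break
            blocks.append(SyntenyBlock(block_id=bid, anchors=chain, orientation=orientation, score=score))
            bid += 1
            used = {(a.rank_a, a.rank_b) for a in chain}
            remaining = [a for a in remaining if (a.rank_a, a.rank_b) not in used]
    return blocks


def _mergeable(b1: SyntenyBlock, b2: SyntenyBlock, max_merge_distance: int) -> bool:
    """b2 continues b1 in the same direction within the merge distance."""
    if b1.orientation != b2.orientation:
        return False
    if (b1.anchors[0].chrom_a, b1.anchors[0].chrom_b) != (b2.anchors[0].chrom_a, b2.anchors[0].chrom_b):
        return False
    end_a = b1.anchors[-1].rank_a
    start_a = b2.anchors[0].rank_a
    if not 0 < start_a - end_a <= max_merge_distance:
        return False
    if b1.orientation == "same":
        gap_b = b2.anchors[0].rank_b - b1.anchors[-1].rank_b
    else:
        gap_b = b1.anchors[-1].rank_b - b2.anchors[0].rank_b
    return 0 < gap_b <= max_merge_distance


def merge_blocks(
    blocks: Iterable[SyntenyBlock],
    max_merge_distance: int = DEFAULT_MERGE_DISTANCE,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> list[SyntenyBlock]:
    """Merge neighboring same-orientation blocks whose facing ends are
    within ``max_merge_distance`` ranks on both sides; repeats to fixpoint.
    """
    blocks = [replace(b, anchors=list(b.anchors)) for b in blocks]
    changed = True
    while changed:
        changed = False
        blocks.sort(key=lambda b: (b.anchors[0].chrom_a, b.anchors[0].chrom_b, b.anchors[0].rank_a))
        out: list[SyntenyBlock] = []
        for b in blocks:
            merged = False
            for prev in out:
                if _mergeable(prev, b, max_merge_distance):
                    prev.anchors.extend(b.anchors)
                    prev.anchors.sort(
                        key=lambda a: (a.rank_a, a.rank_b if prev.orientation == "same" else -a.rank_b)
                    )
                    prev.score = _chain_score(prev.anchors, prev.orientation, gap_penalty)
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(b)
        blocks = out
    return blocks


def apply_quota(
    blocks: Iterable[SyntenyBlock],
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> list[SyntenyBlock]:
    """Retention cap: each gene may be covered by at most ``max_depth``
    blocks (kept by descending block score, ties toward earlier blocks);
    anchors of a gene's excess blocks are removed, and blocks falling
    below ``min_anchors`` are dropped.
    """
    blocks = [replace(b, anchors=list(b.anchors)) for b in blocks]
    coverage: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        for a in b.anchors:
            coverage.setdefault(a.gene_a, []).append(b)
            coverage.setdefault(a.gene_b, []).append(b)
    order = {id(b): i for i, b in enumerate(blocks)}
    demoted: dict[int, set[str]] = {}
    for gene, covering in coverage.items():
        uniq = {id(b): b for b in covering}.values()
        ranked = sorted(uniq, key=lambda b: (-b.score, b.anchors[0].rank_a, order[id(b)]))
        for b in ranked[max_depth:]:
            demoted.setdefault(id(b), set()).add(gene)
    out = []
    for b in blocks:
        drop = demoted.get(id(b), set())
        if drop:
            b.anchors = [a for a in b.anchors if a.gene_a not in drop and a.gene_b not in drop]
            b.score = _chain_score(b.anchors, b.orientation, gap_penalty) if b.anchors else 0.0
        if len(b.anchors) >= min_anchors:
            out.append(b)
    return out


def collapse_tandem_anchors(anchors: list[SyntenyAnchor], window: int = 10) -> list[SyntenyAnchor]:
    """Collapse local duplicate runs to one representative per axis.

    When several anchors share the same gene on one axis and sit within
    ``window`` ranks of each other on the opposite axis (a tandem array
    hitting a single partner), only the lowest-rank member is kept, so
    tandem arrays do not inflate block depth.
    """
    def collapse(items: list[SyntenyAnchor], shared: str) -> list[SyntenyAnchor]:
        grouped: dict[str, list[SyntenyAnchor]] = {}
        for a in items:
            grouped.setdefault(getattr(a, shared), []).append(a)
        kept = []
        other_rank = "rank_b" if shared == "gene_a" else "rank_a"
        for group in grouped.values():
            group.sort(key=lambda a: getattr(a, other_rank))
            rep = group[0]
            for a in group[1:]:
                if getattr(a, other_rank) - getattr(rep, other_rank) <= window:
                    continue  # same local run; keep representative
                kept.append(rep)
                rep = a
            kept.append(rep)
        return kept

    by_chrom: dict[tuple[str, str], list[SyntenyAnchor]] = {}
    for a in anchors:
        by_chrom.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    out: list[SyntenyAnchor] = []
    for group in by_chrom.values():
        out.extend(collapse(collapse(group, "gene_a"), "gene_b"))
    out.sort(key=lambda a: (a.chrom_a, a.chrom_b, a.rank_a, a.rank_b))
    return out


DEFAULT_SELF_DIAGONAL_WINDOW = 40


def anchors_from_hits(
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
    hits: Iterable[SimilarityHit],
    ks_values: Mapping[tuple[str, str], float] | None = None,
    self_diagonal_window: int = DEFAULT_SELF_DIAGONAL_WINDOW,
) -> list[SyntenyAnchor]:
    """Turn filtered similarity hits into synteny anchors.

    For self-comparison (same annotation on both sides) the identity
    diagonal is excluded and anchors are normalized to an unordered
    representation (chrom_a <= chrom_b; rank_a < rank_b on the same
    chromosome), so the trivial self-block cannot form.  Same-chromosome
    anchors within ``self_diagonal_window`` ranks of the diagonal are
    also dropped: that band is tandem-array structure, which would
    otherwise chain into spurious intra-array "blocks".
    """
    self_cmp = annotation_a is annotation_b or annotation_a.species == annotation_b.species
    seen: set[tuple[str, str]] = set()
    anchors = []
    for h in hits:
        if h.query_id not in annotation_a or h.subject_id not in annotation_b:
            raise KeyError(
                f"hit references gene(s) absent from the annotations: "
                f"{h.query_id}/{h.subject_id}"
            )
        ga = annotation_a.get(h.query_id)
        gb = annotation_b.get(h.subject_id)
        if self_cmp:
            if ga.gene_id == gb.gene_id:
                continue
            if (
                ga.chromosome == gb.chromosome
                and abs(ga.rank - gb.rank) <= self_diagonal_window
            ):
                continue
            if (gb.chromosome, gb.rank) < (ga.chromosome, ga.rank):
                ga, gb = gb, ga
            key = (ga.gene_id, gb.gene_id)
            if key in seen:
                continue
            seen.add(key)
        ks = None
        if ks_values is not None:
            ks = ks_values.get((ga.gene_id, gb.gene_id), ks_values.get((gb.gene_id, ga.gene_id)))
        anchors.append(
            SyntenyAnchor(
                gene_a=ga.gene_id,
                gene_b=gb.gene_id,
                rank_a=ga.rank,
                rank_b=gb.rank,
                chrom_a=ga.chromosome,
                chrom_b=gb.chromosome,
                ks=ks,
            )
        )
    return anchors


def date_block(
    block: SyntenyBlock,
    ks_values: Mapping[tuple[str, str], float] | None = None,
    epoch_bins: Mapping[str, tuple[float, float]] = DEFAULT_EPOCH_BINS,
) -> str:
    """Assign a block to a polyploidy epoch by its median anchor Ks.

    Ks comes from anchor annotations or from the supplied pair->Ks map;
    a block with no Ks, or whose median falls outside every bin, stays
    ``unassigned``.  Bins are half-open [low, high).
    """
    ks_list = []
    for a in block.anchors:
        ks = a.ks
        if ks is None and ks_values is not None:
            ks = ks_values.get((a.gene_a, a.gene_b), ks_values.get((a.gene_b, a.gene_a)))
        if ks is not None and ks == ks:  # drop NaN
            ks_list.append(ks)
    if not ks_list:
        block.median_ks = None
        block.epoch = "unassigned"
        return block.epoch
    m = median(ks_list)
    block.median_ks = m
    block.epoch = "unassigned"
    for name in epoch_bins:
        low, high = epoch_bins[name]
        if low <= m < high:
            block.epoch = name
            break
    return block.epoch


def call_ohnologs(
    annotation_a: GenomeAnnotation,
    annotation_b_or_self: GenomeAnnotation,
    filtered_hits: Iterable[SimilarityHit],
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    max_gap: int = DEFAULT_MAX_GAP,
    max_merge_distance: int = DEFAULT_MERGE_DISTANCE,
    max_depth: int = DEFAULT_MAX_DEPTH,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    ks_values: Mapping[tuple[str, str], float] | None = None,
    epoch_bins: Mapping[str, tuple[float, float]] | None = None,
    tandem_collapse_window: int = 0,
    self_diagonal_window: int = DEFAULT_SELF_DIAGONAL_WINDOW,
) -> tuple[list[OhnologPair], list[SyntenyBlock]]:
    """Full block pipeline: anchors -> chain -> merge -> quota -> pairs.

    Every anchor pair of every retained block becomes an ohnolog pair
    (within-species self-comparison) or a syntenic ortholog pair
    (cross-species).  Within-species pairs are unordered and deduplicated.

    Tandem runs are handled by the chain DP itself: anchors sharing a
    rank on either axis cannot co-occur in one strictly monotone chain,
    so the member that best continues the diagonal is selected.  An
    explicit lowest-rank pre-collapse (``tandem_collapse_window`` > 0)
    is available but off by default — it can misassign the syntenic
    representative when a recent duplicate precedes it in rank.
    """
    within = annotation_a is annotation_b_or_self or (
        annotation_a.species == annotation_b_or_self.species
    )
    anchors = anchors_from_hits(
        annotation_a, annotation_b_or_self, filtered_hits, ks_values,
        self_diagonal_window=self_diagonal_window if within else 0,
    )
    if tandem_collapse_window:
        anchors = collapse_tandem_anchors(anchors, window=tandem_collapse_window)
    blocks = chain_blocks(anchors, min_anchors=min_anchors, max_gap=max_gap, gap_penalty=gap_penalty)
    blocks = merge_blocks(blocks, max_merge_distance=max_merge_distance, gap_penalty=gap_penalty)
    blocks = apply_quota(blocks, max_depth=max_depth, min_anchors=min_anchors)
    if epoch_bins is not None or ks_values is not None:
        for b in blocks:
            date_block(b, ks_values, epoch_bins or DEFAULT_EPOCH_BINS)
    pairs: list[OhnologPair] = []
    seen: set[tuple[str, str]] = set()
    for b in blocks:
        for a in b.anchors:
            ga, gb = a.gene_a, a.gene_b
            if within and gb < ga:
                ga, gb = gb, ga
            if within:
                if (ga, gb) in seen:
                    continue
                seen.add((ga, gb))
            pairs.append(
                OhnologPair(gene_a=ga, gene_b=gb, block_id=b.block_id, within_species=within, epoch=b.epoch)
            )
    return pairs, blocks


def write_blocks(blocks: Iterable[SyntenyBlock], path) -> None:
    """Block table TSV: one row per block with its anchor pair list."""
    import pandas as pd

    rows = []
    for b in blocks:
        rows.append(
            dict(
                block_id=b.block_id,
                chrom_a=b.anchors[0].chrom_a,
                chrom_b=b.anchors[0].chrom_b,
                orientation=b.orientation,
                n_anchors=b.n_anchors,
                score=round(b.score, 3),
                median_ks="" if b.median_ks is None else round(b.median_ks, 4),
                epoch=b.epoch,
                anchor_pairs=";".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors),
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
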