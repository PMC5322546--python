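"""Assignment of duplication modes per gene: tandem arrays, gene
transposition duplicates (GTD) with ancestral/novel polarization, and
tandem-duplicated ohnologs (TD-alpha).

Definitions implemented here:

* Tandem arrays are connected components of the graph whose edges join
  same-chromosome gene pairs that share a qualifying similarity hit and
  are separated by at most ``max_spacers`` intervening genes (so two
  members ten spacers apart bridged by a middle member form one array).
* A GTD call pairs a gene with its closest strong homolog (e <= 1e-30)
  once every homolog reachable through chains of tandem/ohnolog
  relations has been discounted: transposition is the residual mode.
* TD-alpha: a gene that is both a member of a tandem array and a
  participant in an ohnolog pair of the chosen polyploidy epoch —
  tandem duplication layered on a whole-genome duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation_io import GeneModel, GenomeAnnotation, SimilarityHit
from .synteny import OhnologPair


@dataclass
class TandemArray:
    array_id: int
    chromosome: str
    members: list[str]  # rank order
    pair_orientations: list[str]  # per adjacent member pair

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GTDPair:
    transposed_gene: str
    partner_gene: str
    evalue: float
    polarization: str = "unresolved"  # partner_ancestral | transposed_ancestral | unresolved
    votes: dict = field(default_factory=dict)


@dataclass
class DuplicationCall:
    gene_id: str
    labels: set[str] = field(default_factory=set)
    partners: dict[str, list[str]] = field(default_factory=dict)
    array_id: int | None = None

    @property
    def singleton(self) -> bool:
        return not self.labels


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _adjacent_orientation(g1: GeneModel, g2: GeneModel) -> str:
    """Orientation label for an adjacent pair, g1 upstream of g2.

    Parallel strands duplicate head-to-tail (the unequal-crossing-over
    signature); (-,+) face head-to-head; (+,-) tail-to-tail.
    """
    if g1.strand == g2.strand:
        return "head_to_tail"
    if g1.strand == "-" and g2.strand == "+":
        return "head_to_head"
    return "tail_to_tail"


DEFAULT_MAX_SPACERS = 10
DEFAULT_GTD_EMAX = 1e-30


def find_tandem_arrays(
    annotation: GenomeAnnotation,
    filtered_hits: Iterable[SimilarityHit],
    max_spacers: int = DEFAULT_MAX_SPACERS,
) -> list[TandemArray]:
    """Tandem arrays as connected components of the spacer-bounded
    same-chromosome homology graph; members reported in rank order with
    adjacent-pair orientation labels."""
    uf = _UnionFind()
    for h in filtered_hits:
        if h.query_id not in annotation or h.subject_id not in annotation:
            continue
        ga, gb = annotation.get(h.query_id), annotation.get(h.subject_id)
        if ga.chromosome != gb.chromosome or ga.gene_id == gb.gene_id:
            continue
        spacers = abs(ga.rank - gb.rank) - 1
        if spacers <= max_spacers:
            uf.union(ga.gene_id, gb.gene_id)
    components: dict[str, list[str]] = {}
    for gid in uf.parent:
        components.setdefault(uf.find(gid), []).append(gid)
    arrays: list[TandemArray] = []
    comps = [sorted(m, key=lambda g: annotation.get(g).rank) for m in components.values() if len(m) >= 2]
    comps.sort(key=lambda m: (annotation.get(m[0]).chromosome, annotation.get(m[0]).rank))
    for i, members in enumerate(comps):
        genes = [annotation.get(g) for g in members]
        arrays.append(
            TandemArray(
                array_id=i,
                chromosome=genes[0].chromosome,
                members=members,
                pair_orientations=[
                    _adjacent_orientation(g1, g2) for g1, g2 in zip(genes, genes[1:])
                ],
            )
        )
    return arrays


def _hit_order_key(h: SimilarityHit) -> tuple:
    return (h.evalue, -h.bitscore, h.subject_id)


def call_gtd(
    genes: Iterable[str],
    all_vs_all_hits: Iterable[SimilarityHit],
    ohnolog_pairs: Iterable[OhnologPair],
    tandem_arrays: Iterable[TandemArray],
    e_max: float = DEFAULT_GTD_EMAX,
) -> list[GTDPair]:
    """Score each gene's closest unexplained homolog as its GTD partner.

    A homolog is *explained* when it is reachable from the gene through
    the union of tandem-array and ohnolog edges (duplication already
    accounted for by chains of tandem/whole-genome events).  Only hits
    at ``e_max`` (default 1e-30, a deliberately stricter threshold than
    homology filtering) qualify; closest = lowest e-value, ties by
    bitscore then id.
    """
    uf = _UnionFind()
    gene_set = set(genes)
    for arr in tandem_arrays:
        for m1, m2 in zip(arr.members, arr.members[1:]):
            uf.union(m1, m2)
    for p in ohnolog_pairs:
        uf.union(p.gene_a, p.gene_b)
    best: dict[str, SimilarityHit] = {}
    for h in all_vs_all_hits:
        if h.evalue > e_max or h.query_id == h.subject_id:
            continue
        if h.query_id not in gene_set or h.subject_id not in gene_set:
            continue
        if uf.find(h.query_id) == uf.find(h.subject_id):
            continue  # explained by tandem/ohnolog chain
        cur = best.get(h.query_id)
        if cur is None or _hit_order_key(h) < _hit_order_key(cur):
            best[h.query_id] = h
    return [
        GTDPair(transposed_gene=q, partner_gene=h.subject_id, evalue=h.evalue)
        for q, h in sorted(best.items())
    ]


def _gap_runs(aligned: str) -> list[int]:
    runs, cur = [], 0
    for ch in aligned:
        if ch == "-":
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


def polarize_gtd(
    pair: GTDPair,
    aligned_transposed: str,
    aligned_partner: str,
    gene_models: Mapping[str, GeneModel],
) -> GTDPair:
    """Vote on which copy is ancestral.

    Four criteria, each voting for one copy when it discriminates:
    fewer InDel events (gap runs in its own aligned sequence, i.e. a
    deletion-attribution convention), shorter maximum InDel length,
    longer CDS, longer mean exon length (skipped when either copy lacks
    exon structure).  Majority wins; a tie or no informative criterion
    leaves the pair unresolved.
    """
    if len(aligned_transposed) != len(aligned_partner) or not aligned_transposed:
        raise ValueError("pair is unaligned; upstream alignment failed")
    t, p = pair.transposed_gene, pair.partner_gene
    runs_t, runs_p = _gap_runs(aligned_transposed), _gap_runs(aligned_partner)
    gm_t, gm_p = gene_models.get(t), gene_models.get(p)

    votes: dict[str, str] = {}

    def vote(name: str, val_t, val_p, smaller_wins: bool) -> None:
        if val_t is None or val_p is None or val_t == val_p:
            return
        t_wins = (val_t < val_p) == smaller_wins
        votes[name] = "transposed" if t_wins else "partner"

    vote("indel_events", len(runs_t), len(runs_p), smaller_wins=True)
    vote("max_indel_length", max(runs_t, default=0), max(runs_p, default=0), smaller_wins=True)
    vote(
        "cds_length",
        gm_t.cds_length if gm_t else None,
        gm_p.cds_length if gm_p else None,
        smaller_wins=False,
    )
    if gm_t and gm_p and gm_t.exon_lengths and gm_p.exon_lengths:
        vote(
            "mean_exon_length",
            sum(gm_t.exon_lengths) / len(gm_t.exon_lengths),
            sum(gm_p.exon_lengths) / len(gm_p.exon_lengths),
            smaller_wins=False,
        )
    n_t = sum(1 for v in votes.values() if v == "transposed")
    n_p = sum(1 for v in votes.values() if v == "partner")
    if n_t > n_p:
        pair.polarization = "transposed_ancestral"
    elif n_p > n_t:
        pair.polarization = "partner_ancestral"
    else:
        pair.polarization = "unresolved"
    pair.votes = votes
    return pair


def call_td_alpha(
    tandem_arrays: Iterable[TandemArray],
    ohnolog_pairs: Iterable[OhnologPair],
    epoch_filter: str = "alpha",
    semantics: str = "array",
) -> tuple[set[str], list[tuple[str, str, int]]]:
    """TD-alpha genes: tandem duplication layered on a polyploidy copy.

    With the default ``semantics="array"``, every member of a tandem
    array that contains an ohnolog-pair participant (of the chosen
    epoch) is TD-alpha — the copies belonging to a tandem-duplicated
    ohnolog count along with the ohnolog itself.  This is robust to
    which array member happens to carry the syntenic anchor, an
    assignment that is genuinely unidentifiable from pairwise data when
    several members are equidistant from the partner.
    ``semantics="gene"`` restricts the set to the strict intersection
    (tandem member that itself participates in an ohnolog pair).

    ``epoch_filter="any"`` accepts every ohnolog pair (runs without Ks
    dating); otherwise pairs must carry the requested epoch.
    Returns the gene set and a (gene, ohnolog partner, array_id) report
    listing the anchoring ohnolog pairs.
    """
    if semantics not in ("array", "gene"):
        raise ValueError("semantics must be 'array' or 'gene'")
    arrays = list(tandem_arrays)
    array_of: dict[str, int] = {}
    for arr in arrays:
        for m in arr.members:
            array_of[m] = arr.array_id
    anchored: set[str] = set()
    report: list[tuple[str, str, int]] = []
    for p in ohnolog_pairs:
        if epoch_filter != "any" and p.epoch != epoch_filter:
            continue
        for g, partner in ((p.gene_a, p.gene_b), (p.gene_b, p.gene_a)):
            if g in array_of:
                anchored.add(g)
                report.append((g, partner, array_of[g]))
    if semantics == "gene":
        return anchored, sorted(report)
    hit_arrays = {array_of[g] for g in anchored}
    genes = {m for arr in arrays if arr.array_id in hit_arrays for m in arr.members}
    return genes, sorted(report)


def assemble_calls(
    genes: Iterable[str],
    tandem_arrays: Iterable[TandemArray],
    ohnolog_pairs: Iterable[OhnologPair],
    gtd_pairs: Iterable[GTDPair],
    td_alpha_genes: set[str] | None = None,
) -> tuple[dict[str, DuplicationCall], dict[frozenset, int]]:
    """Merge all mode calls into per-gene labels plus Venn partition
    counts over {tandem, ohnolog, gtd}.

    Labels are non-exclusive.  The Venn cells partition the non-singleton
    genes (inclusion–exclusion identity holds by construction); genes
    with no label are singletons.  A partner gene outside the supplied
    gene universe is a hard error.
    """
    universe = set(genes)
    calls = {g: DuplicationCall(gene_id=g) for g in sorted(universe)}

    def check(g: str) -> None:
        if g not in universe:
            raise KeyError(f"partner gene {g} absent from the gene universe")

    for arr in tandem_arrays:
        for m in arr.members:
            check(m)
            calls[m].labels.add("tandem")
            calls[m].array_id = arr.array_id
            calls[m].partners.setdefault("tandem", []).extend(
                x for x in arr.members if x != m
            )
    for p in ohnolog_pairs:
        check(p.gene_a)
        check(p.gene_b)
        for g, partner in ((p.gene_a, p.gene_b), (p.gene_b, p.gene_a)):
            calls[g].labels.add("ohnolog")
            calls[g].partners.setdefault("ohnolog", []).append(partner)
    for gp in gtd_pairs:
        check(gp.transposed_gene)
        check(gp.partner_gene)
        calls[gp.transposed_gene].labels.add("gtd")
        calls[gp.transposed_gene].partners.setdefault("gtd", []).append(gp.partner_gene)
    if td_alpha_genes:
        for g in td_alpha_genes:
            check(g)
            calls[g].labels.add("td_alpha")

    venn: dict[frozenset, int] = {}
    for c in calls.values():
        cell = frozenset(c.labels & {"tandem", "ohnolog", "gtd"})
        if cell:
            venn[cell] = venn.get(cell, 0) + 1
    return calls, venn


def pair_mode_assignment(
    calls: Mapping[str, DuplicationCall],
) -> dict[tuple[str, str], str]:
    """Assign each analyzed duplicate pair to exactly one mode class.

    Ohnolog pairs with a TD-alpha member are the ``td_alpha`` class;
    remaining tandem pairs, ohnolog pairs and GTD pairs follow, in that
    precedence.  Pairs are unordered (a <= b).
    """
    modes: dict[tuple[str, str], str] = {}

    def put(a: str, b: str, mode: str) -> None:
        key = (a, b) if a <= b else (b, a)
        modes.setdefault(key, mode)

    for c in calls.values():
        for p in c.partners.get("ohnolog", []):
            if "td_alpha" in c.labels or "td_alpha" in calls[p].labels:
                put(c.gene_id, p, "td_alpha")
    for c in calls.values():
        for p in c.partners.get("tandem", []):
            put(c.gene_id, p, "tandem")
    for c in calls.values():
        for p in c.partners.get("ohnolog", []):
            put(c.gene_id, p, "ohnolog")
    for c in calls.values():
        for p in c.partners.get("gtd", []):
            put(c.gene_id, p, "gtd")
    return modes


def write_calls(calls: Mapping[str, DuplicationCall], gtd_pairs: Sequence[GTDPair], path) -> None:
    import pandas as pd

    polar = {p.transposed_gene: p.polarization for p in gtd_pairs}
    rows = []
    for g, c in calls.items():
        rows.append(
            dict(
                gene_id=g,
                labels=",".join(sorted(c.labels)) or "singleton",
                array_id="" if c.array_id is None else c.array_id,
                tandem_partners=",".join(sorted(set(c.partners.get("tandem", [])))),
                ohnolog_partners=",".join(sorted(set(c.partners.get("ohnolog", [])))),
                gtd_partners=",".join(sorted(set(c.partners.get("gtd", [])))),
                gtd_polarization=polar.get(g, ""),
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
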