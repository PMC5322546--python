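"""Genome-evolution simulator with known truth.

The simulator produces everything the classification pipeline consumes
— a gene annotation, CDS sequences, and an all-vs-all similarity table
— from an explicit event history, so every downstream call can be
scored against truth:

* an ancestral multi-chromosome gene order with random codon sequences;
* one or more rounds of whole-genome duplication (WGD) followed by
  per-gene fractionation (copy loss);
* tandem duplication inserting copies 0–2 gene spacers downstream of
  the source, in direct (head-to-tail) or inverted orientation;
* gene transposition duplication (GTD) copying a gene to a distant
  locus, with the novel copy optionally truncated and hit by codon
  deletions (the asymmetry the ancestral/novel polarization criteria
  rely on);
* codon-sequence divergence under a proposal/acceptance substitution
  scheme whose synonymous clock is mode-independent while the
  nonsynonymous rate is scaled by a per-mode omega, so per-mode mean
  Ka/Ks contrasts are recoverable by NG86.

All randomness flows from one seed; identical configs give identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np

from .annotation_io import GeneModel, GenomeAnnotation, SimilarityHit
from .molevol import GENETIC_CODE

_BASES = "TCAG"
_AA_OF = np.array(
    [GENETIC_CODE["".join(_BASES[i] for i in (a, b, c))] for a in range(4) for b in range(4) for c in range(4)]
)
_IS_STOP = _AA_OF == "*"
_NONSTOP_CODONS = np.flatnonzero(~_IS_STOP)


@dataclass
class WGDRound:
    """One polyploidy round: per-gene copy retention probability and the
    round's age on the substitution-clock time scale."""

    retention_prob: float = 0.6
    divergence_time: float = 0.4


@dataclass
class SimConfig:
    """Study conditions for one simulated genome.

    Rates are per 100 genes; ages are in units of the substitution
    clock (``background_divergence`` proposal events per site per unit
    time).  ``omega_by_context`` scales the nonsynonymous acceptance
    rate for genes according to the most recent duplication event they
    took part in.
    """

    seed: int = 0
    n_chromosomes: int = 5
    n_ancestral_genes: int = 500
    wgd_rounds: list[WGDRound] = field(default_factory=lambda: [WGDRound()])
    tandem_rate: float = 2.0  # expected arrays per 100 genes
    tandem_size_geom_p: float = 0.6  # geometric parameter for extra copies
    inverted_orientation_prob: float = 0.1
    tandem_age: float = 0.25
    gtd_rate: float = 1.0  # expected transpositions per 100 genes
    gtd_age: float = 0.15
    gtd_min_rank_distance: int = 50
    novel_copy_truncation_prob: float = 0.7
    novel_copy_indel_rate: float = 1.5  # expected deletion events per novel copy
    omega_by_context: dict[str, float] = field(
        default_factory=lambda: {
            "background": 1.0,
            "ohnolog": 1.1,
            "tandem": 1.2,
            "gtd": 0.9,
        }
    )
    background_divergence: float = 0.8  # substitution proposals / site / time
    min_codons: int = 100
    max_codons: int = 500

    def validate(self) -> None:
        probs = [self.inverted_orientation_prob, self.novel_copy_truncation_prob,
                 self.tandem_size_geom_p] + [r.retention_prob for r in self.wgd_rounds]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.tandem_rate, self.gtd_rate, self.background_divergence,
               self.novel_copy_indel_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if self.n_ancestral_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")


@dataclass
class TruthRecord:
    gene_id: str
    origin: str  # ancestral | wgd_copy | tandem_copy | gtd_copy
    partner_id: str | None
    event_time: float | None
    wgd_round: int | None = None
    array_event: int | None = None
    ancestral_flag: bool | None = None  # GTD pairs: True for the seed locus


@dataclass
class _SimGene:
    gene_id: str
    strand: str
    n_codons: int
    exon_count: int
    parent_id: str | None = None
    birth_age: float | None = None  # None for ancestral genes
    origin: str = "ancestral"
    wgd_round: int | None = None
    array_event: int | None = None
    # omega timeline: (age, omega) changes, newest appended last
    omega_changes: list[tuple[float, float]] = field(default_factory=list)
    # structural ops applied to the copied sequence at birth
    birth_ops: list[tuple] = field(default_factory=list)


@dataclass
class SimGenome:
    """Mutable simulation state: gene order per chromosome plus per-gene
    lineage records.  Sequences are attached by :func:`evolve_sequences`."""

    config: SimConfig
    chromosomes: dict[str, list[str]]
    genes: dict[str, _SimGene]
    events_applied: bool = False
    n_fractionated: int = 0
    n_copies_made: int = 0
    sequences: dict[str, np.ndarray] | None = None

    # -- bookkeeping ---------------------------------------------------

    def _lineage(self, gene_id: str) -> list[tuple[str, float | None]]:
        chain = []
        cur: str | None = gene_id
        while cur is not None:
            g = self.genes[cur]
            chain.append((cur, g.birth_age))
            cur = g.parent_id
        return chain

    def divergence_age(self, a: str, b: str) -> float:
        """Age at which the lineages of two genes split (0 if a == b)."""
        if a == b:
            return 0.0
        ca, cb = self._lineage(a), self._lineage(b)
        in_b = {gid: i for i, (gid, _) in enumerate(cb)}
        ages: list[float] = []
        common_idx = None
        for gid, age in ca:
            if gid in in_b:
                common_idx = in_b[gid]
                break
            if age is not None:
                ages.append(age)
        if common_idx is None:
            raise ValueError(f"{a} and {b} are not in the same family")
        ages.extend(age for _, age in cb[:common_idx] if age is not None)
        return max(ages) if ages else 0.0

    def family_root(self, gene_id: str) -> str:
        return self._lineage(gene_id)[-1][0]

    def omega_at(self, gene_id: str, age_interval: tuple[float, float]) -> float:
        """Omega active during (hi, lo); changes at age >= hi apply."""
        hi, _lo = age_interval
        omega = self.config.omega_by_context["background"]
        for age, w in self.genes[gene_id].omega_changes:
            if age >= hi - 1e-12:
                omega = w
        return omega

    def mean_omega_pair(self, a: str, b: str) -> float:
        """Time-averaged omega over both branches since the pair split —
        the expected Ka/Ks of the pair under the simulation scheme."""
        div = self.divergence_age(a, b)
        if div == 0:
            return float("nan")
        breakpoints = sorted(
            {div, 0.0}
            | {age for g in (a, b) for age, _ in self.genes[g].omega_changes if age < div}
        , reverse=True)
        total = 0.0
        for hi, lo in zip(breakpoints, breakpoints[1:]):
            total += (hi - lo) * (self.omega_at(a, (hi, lo)) + self.omega_at(b, (hi, lo)))
        return total / (2.0 * div)

    # -- exports -------------------------------------------------------

    def to_annotation(self, species: str = "sim") -> GenomeAnnotation:
        intron, intergenic = 50, 200
        models = []
        for chrom in sorted(self.chromosomes):
            cursor = 0
            for rank, gid in enumerate(self.chromosomes[chrom]):
                g = self.genes[gid]
                cds = 3 * g.n_codons
                exons = _split_exons(cds, g.exon_count)
                span = cds + intron * (len(exons) - 1)
                models.append(
                    GeneModel(
                        gene_id=gid,
                        chromosome=chrom,
                        start=cursor,
                        end=cursor + span,
                        strand=g.strand,
                        rank=rank,
                        cds_length=cds,
                        exon_lengths=exons,
                        species=species,
                    )
                )
                cursor += span + intergenic
        return GenomeAnnotation(species, models)

    def truth_records(self) -> list[TruthRecord]:
        recs = []
        for gid in sorted(self.genes):
            g = self.genes[gid]
            recs.append(
                TruthRecord(
                    gene_id=gid,
                    origin=g.origin,
                    partner_id=g.parent_id,
                    event_time=g.birth_age,
                    wgd_round=g.wgd_round,
                    array_event=g.array_event,
                    ancestral_flag=False if g.origin == "gtd_copy" else None,
                )
            )
        return recs


def _split_exons(cds_length: int, n_exons: int) -> tuple[int, ...]:
    n_exons = max(1, min(n_exons, cds_length // 3))
    base, rem = divmod(cds_length, n_exons)
    return tuple(base + (1 if i < rem else 0) for i in range(n_exons))


def simulate_ancestor(config: SimConfig, rng: np.random.Generator | None = None) -> SimGenome:
    """Ancestral genome: genes split over chromosomes, random strands,
    CDS lengths 3 x Uniform[min_codons, max_codons] codons."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, k = config.n_ancestral_genes, config.n_chromosomes
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    genes: dict[str, _SimGene] = {}
    chromosomes: dict[str, list[str]] = {}
    gi = 0
    for ci, size in enumerate(sizes):
        chrom = f"chr{ci + 1:02d}"
        order = []
        for _ in range(size):
            gid = f"g{gi:04d}"
            gi += 1
            genes[gid] = _SimGene(
                gene_id=gid,
                strand="+" if rng.random() < 0.5 else "-",
                n_codons=int(rng.integers(config.min_codons, config.max_codons + 1)),
                exon_count=int(rng.integers(1, 6)),
            )
            order.append(gid)
        chromosomes[chrom] = order
    return SimGenome(config=config, chromosomes=chromosomes, genes=genes)


def _all_gene_ids(sim: SimGenome) -> list[str]:
    return [gid for chrom in sorted(sim.chromosomes) for gid in sim.chromosomes[chrom]]


def apply_history(sim: SimGenome, rng: np.random.Generator | None = None) -> SimGenome:
    """Apply WGD rounds, tandem duplications and transpositions in
    chronological (oldest-first) order, recording lineage and omega
    context for every gene.  Structural only; sequences come from
    :func:`evolve_sequences`."""
    config = sim.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    phases: list[tuple[float, str, object]] = [
        (r.divergence_time, "wgd", i) for i, r in enumerate(config.wgd_rounds)
    ]
    phases.append((config.tandem_age, "td", None))
    phases.append((config.gtd_age, "gtd", None))
    phases.sort(key=lambda t: (-t[0], t[1]))
    omega = config.omega_by_context
    for age, kind, payload in phases:
        if kind == "wgd":
            ridx = int(payload)  # type: ignore[arg-type]
            rnd = config.wgd_rounds[ridx]
            # snapshot: earlier-round copies duplicate again, as in real polyploidy
            for chrom in sorted(sim.chromosomes):
                new_chrom = f"{chrom}_w{ridx + 1}"
                new_order = []
                for gid in sim.chromosomes[chrom]:
                    sim.n_copies_made += 1
                    if rng.random() >= rnd.retention_prob:
                        sim.n_fractionated += 1
                        continue
                    cid = f"{gid}.w{ridx + 1}"
                    src = sim.genes[gid]
                    sim.genes[cid] = _SimGene(
                        gene_id=cid,
                        strand=src.strand,
                        n_codons=src.n_codons,
                        exon_count=src.exon_count,
                        parent_id=gid,
                        birth_age=age,
                        origin="wgd_copy",
                        wgd_round=ridx + 1,
                        omega_changes=[(age, omega.get("ohnolog", 1.0))],
                    )
                    src.omega_changes.append((age, omega.get("ohnolog", 1.0)))
                    new_order.append(cid)
                if new_order:
                    sim.chromosomes[new_chrom] = new_order
        elif kind == "td":
            gene_ids = _all_gene_ids(sim)
            n_events = rng.poisson(config.tandem_rate / 100.0 * len(gene_ids))
            sources = rng.choice(len(gene_ids), size=min(n_events, len(gene_ids)), replace=False)
            for ev, si in enumerate(sources):
                src_id = gene_ids[int(si)]
                src = sim.genes[src_id]
                chrom = next(c for c, order in sim.chromosomes.items() if src_id in order)
                n_copies = int(rng.geometric(config.tandem_size_geom_p))
                src.omega_changes.append((age, omega.get("tandem", 1.0)))
                src.array_event = ev if src.array_event is None else src.array_event
                for j in range(n_copies):
                    cid = f"{src_id}.t{ev}_{j}"
                    strand = src.strand
                    if rng.random() < config.inverted_orientation_prob:
                        strand = "+" if strand == "-" else "-"
                    sim.genes[cid] = _SimGene(
                        gene_id=cid,
                        strand=strand,
                        n_codons=src.n_codons,
                        exon_count=src.exon_count,
                        parent_id=src_id,
                        birth_age=age,
                        origin="tandem_copy",
                        array_event=ev,
                        omega_changes=[(age, omega.get("tandem", 1.0))],
                    )
                    sim.n_copies_made += 1
                    order = sim.chromosomes[chrom]
                    idx = order.index(src_id)
                    spacers = int(rng.integers(0, 3))
                    order.insert(min(idx + 1 + spacers, len(order)), cid)
        else:  # gtd
            gene_ids = _all_gene_ids(sim)
            n_events = rng.poisson(config.gtd_rate / 100.0 * len(gene_ids))
            sources = rng.choice(len(gene_ids), size=min(n_events, len(gene_ids)), replace=False)
            for ev, si in enumerate(sources):
                src_id = gene_ids[int(si)]
                src = sim.genes[src_id]
                src_chrom = next(c for c, order in sim.chromosomes.items() if src_id in order)
                cid = f"{src_id}.d{ev}"
                n_codons = src.n_codons
                ops: list[tuple] = []
                if rng.random() < config.novel_copy_truncation_prob:
                    k = int(n_codons * rng.uniform(0.1, 0.3))
                    if n_codons - k >= 30:
                        ops.append(("truncate", k))
                        n_codons -= k
                for _ in range(int(rng.poisson(config.novel_copy_indel_rate))):
                    run = 1 + int(rng.poisson(1.0))
                    if n_codons - run < 30:
                        continue
                    pos = int(rng.integers(0, n_codons - run))
                    ops.append(("delete", pos, run))
                    n_codons -= run
                # distant target locus: random chromosome; same-chromosome
                # placements must be >= gtd_min_rank_distance ranks away
                chroms = sorted(sim.chromosomes)
                for _attempt in range(100):
                    tchrom = chroms[int(rng.integers(0, len(chroms)))]
                    order = sim.chromosomes[tchrom]
                    tidx = int(rng.integers(0, len(order) + 1))
                    if tchrom != src_chrom:
                        break
                    if abs(tidx - order.index(src_id)) >= config.gtd_min_rank_distance:
                        break
                else:
                    continue  # no distant locus available; event skipped
                sim.genes[cid] = _SimGene(
                    gene_id=cid,
                    strand="+" if rng.random() < 0.5 else "-",
                    n_codons=n_codons,
                    exon_count=src.exon_count,
                    parent_id=src_id,
                    birth_age=age,
                    origin="gtd_copy",
                    omega_changes=[(age, omega.get("gtd", 1.0))],
                    birth_ops=ops,
                )
                src.omega_changes.append((age, omega.get("gtd", 1.0)))
                sim.n_copies_made += 1
                sim.chromosomes[tchrom].insert(tidx, cid)
    sim.events_applied = True
    return sim


def _random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    codons = _NONSTOP_CODONS[rng.integers(0, _NONSTOP_CODONS.size, size=n_codons)]
    seq = np.empty(3 * n_codons, dtype=np.uint8)
    seq[0::3] = codons // 16
    seq[1::3] = (codons // 4) % 4
    seq[2::3] = codons % 4
    return seq


def _evolve_segment(
    seq: np.ndarray, omega: float, dt: float, rate: float, rng: np.random.Generator
) -> None:
    """Proposal/acceptance codon substitution over one time interval.

    Proposals arrive at ``rate * max(1, omega)`` per site; synonymous
    proposals are accepted with probability 1/max(1, omega) and
    nonsynonymous ones with omega/max(1, omega), so the realized
    synonymous clock is omega-independent while Ka/Ks tracks omega.
    Stop codons are never created.
    """
    if dt <= 0 or rate <= 0:
        return
    boost = max(1.0, omega)
    lam = rate * boost * dt * seq.size
    n = int(rng.poisson(lam))
    if n == 0:
        return
    positions = rng.integers(0, seq.size, size=n)
    offsets = rng.integers(1, 4, size=n)
    accept_u = rng.random(size=n)
    a_s = 1.0 / boost
    a_n = omega / boost
    for pos, off, u in zip(positions, offsets, accept_u):
        old = seq[pos]
        new = (old + off) % 4
        c0 = pos - pos % 3
        n0, n1, n2 = seq[c0], seq[c0 + 1], seq[c0 + 2]
        old_idx = 16 * n0 + 4 * n1 + n2
        which = pos - c0
        parts = [n0, n1, n2]
        parts[which] = new
        new_idx = 16 * parts[0] + 4 * parts[1] + parts[2]
        if _IS_STOP[new_idx]:
            continue
        if _AA_OF[old_idx] == _AA_OF[new_idx]:
            if u < a_s:
                seq[pos] = new
        elif u < a_n:
            seq[pos] = new


def evolve_sequences(sim: SimGenome, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Replay the event history on sequences: ancestral CDS are drawn,
    copies split off at their birth ages (with any recorded truncation/
    deletion ops), and every extant lineage accumulates substitutions
    down to the present under its omega timeline."""
    config = sim.config
    if not sim.events_applied:
        raise ValueError("apply_history must run before evolve_sequences")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    by_birth: dict[float, list[_SimGene]] = {}
    for g in sim.genes.values():
        if g.birth_age is not None:
            by_birth.setdefault(g.birth_age, []).append(g)
    ages = sorted(by_birth, reverse=True)
    seqs: dict[str, np.ndarray] = {
        gid: _random_cds(g.n_codons, rng)
        for gid, g in sorted(sim.genes.items())
        if g.birth_age is None
    }
    rate = config.background_divergence
    cur_age = ages[0] if ages else 0.0
    for next_age in list(ages) + [0.0]:
        if next_age < cur_age:
            for gid in sorted(seqs):
                w = sim.omega_at(gid, (cur_age, next_age))
                _evolve_segment(seqs[gid], w, cur_age - next_age, rate, rng)
            cur_age = next_age
        for g in sorted(by_birth.get(next_age, []), key=lambda g: g.gene_id):
            seq = seqs[g.parent_id].copy()
            for op in g.birth_ops:
                if op[0] == "truncate":
                    seq = seq[: seq.size - 3 * op[1]]
                else:
                    _, pos, run = op
                    seq = np.delete(seq, slice(3 * pos, 3 * (pos + run)))
            assert seq.size == 3 * g.n_codons
            seqs[g.gene_id] = seq
    sim.sequences = seqs
    return {gid: "".join(_BASES[b] for b in seq) for gid, seq in sorted(seqs.items())}


# ---------------------------------------------------------------------------
# similarity-hit emission and truth labels


def emit_hits(sim: SimGenome, rng: np.random.Generator | None = None) -> list[SimilarityHit]:
    """All-vs-all similarity table derived from the true gene families.

    Hits join genes of the same family (shared ancestral root) in both
    directions.  E-values decay with lineage divergence age on a scale
    tuned so that recent duplicates (tandem, transposition) score far
    below 1e-30 while whole-genome duplicates land between 1e-30 and
    1e-10 — mirroring how a strict transposition-partner threshold
    separates recent copies from old polyploids in real screens.
    """
    if rng is None:
        rng = np.random.default_rng(sim.config.seed + 3)
    families: dict[str, list[str]] = {}
    for gid in sorted(sim.genes):
        families.setdefault(sim.family_root(gid), []).append(gid)
    seqs = sim.sequences
    hits: list[SimilarityHit] = []
    for root in sorted(families):
        members = families[root]
        if len(members) < 2:
            continue
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                div = sim.divergence_age(a, b)
                log10e = -12.0 - 88.0 * math.exp(-6.0 * div)
                log10e += float(np.clip(rng.normal(0.0, 1.5), -4.0, 4.0))
                evalue = 10.0 ** max(log10e, -180.0)
                la, lb = 3 * sim.genes[a].n_codons, 3 * sim.genes[b].n_codons
                if seqs is not None:
                    m = min(len(seqs[a]), len(seqs[b]))
                    identity = 100.0 * float(np.mean(seqs[a][:m] == seqs[b][:m]))
                else:
                    identity = 100.0 * math.exp(-div)
                bitscore = max(60.0, 2.0 * min(la, lb) / 3.0 * math.exp(-div))
                for q, s, ql, sl in ((a, b, la, lb), (b, a, lb, la)):
                    hits.append(
                        SimilarityHit(
                            query_id=q,
                            subject_id=s,
                            identity=round(identity, 2),
                            align_length=min(la, lb),
                            evalue=evalue,
                            bitscore=round(bitscore, 1),
                            query_length=ql,
                            subject_length=sl,
                        )
                    )
    return hits


@dataclass
class TruthLabels:
    """Gene-level truth for scoring the classifier."""

    tandem: set[str]
    ohnolog: set[str]
    gtd: set[str]
    td_alpha: set[str]
    ohnolog_pairs: set[frozenset]
    gtd_pairs: set[frozenset]
    tandem_arrays: list[list[str]]


def truth_labels(sim: SimGenome, max_spacers: int = 10) -> TruthLabels:
    """Derive truth labels from the event history and final gene order.

    Ohnolog and GTD truth are event-based (surviving WGD pairs and
    transposition pairs).  Tandem truth is configurational: family
    members within ``max_spacers`` intervening genes on one chromosome
    are tandem neighbours regardless of which event put them there (a
    transposed copy landing beside a relative is genuinely a proximal
    duplicate).  TD-alpha truth covers every member of a tandem array
    that contains a surviving-WGD-pair participant: the copies belonging
    to a tandem-duplicated ohnolog count along with the ohnolog itself.
    """
    extant = set(sim.genes)
    ohnolog_pairs: set[frozenset] = set()
    gtd_pairs: set[frozenset] = set()
    for gid, g in sim.genes.items():
        if g.parent_id is None or g.parent_id not in extant:
            continue
        if g.origin == "wgd_copy":
            ohnolog_pairs.add(frozenset((gid, g.parent_id)))
        elif g.origin == "gtd_copy":
            gtd_pairs.add(frozenset((gid, g.parent_id)))
    roots = {gid: sim.family_root(gid) for gid in sim.genes}
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for chrom in sim.chromosomes:
        order = sim.chromosomes[chrom]
        for i, a in enumerate(order):
            for j in range(i + 1, min(i + max_spacers + 2, len(order))):
                b = order[j]
                if roots[a] == roots[b]:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
    comps: dict[str, list[str]] = {}
    for gid in parent:
        comps.setdefault(find(gid), []).append(gid)
    arrays = [sorted(m) for m in comps.values() if len(m) >= 2]
    tandem = {g for arr in arrays for g in arr}
    ohnolog = {g for p in ohnolog_pairs for g in p}
    gtd = {g for p in gtd_pairs for g in p}
    td_alpha = {
        m for arr in arrays if any(g in ohnolog for g in arr) for m in arr
    }
    return TruthLabels(
        tandem=tandem,
        ohnolog=ohnolog,
        gtd=gtd,
        td_alpha=td_alpha,
        ohnolog_pairs=ohnolog_pairs,
        gtd_pairs=gtd_pairs,
        tandem_arrays=sorted(arrays),
    )


@dataclass
class SimOutput:
    """Everything one simulation run hands to the pipeline."""

    sim: SimGenome
    annotation: GenomeAnnotation
    sequences: dict[str, str]
    hits: list[SimilarityHit]
    truth: TruthLabels


def simulate(config: SimConfig | None = None, seed: int | None = None) -> SimOutput:
    """Run the full simulator: ancestor, event history, sequences, hits."""
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    sim = simulate_ancestor(config)
    apply_history(sim)
    seq_strings = evolve_sequences(sim)
    hits = emit_hits(sim)
    return SimOutput(
        sim=sim,
        annotation=sim.to_annotation(),
        sequences=seq_strings,
        hits=hits,
        truth=truth_labels(sim),
    )


def write_truth(sim: SimGenome, path) -> None:
    import pandas as pd

    labels = truth_labels(sim)
    rows = []
    for rec in sim.truth_records():
        lbls = [m for m in ("tandem", "ohnolog", "gtd", "td_alpha") if rec.gene_id in getattr(labels, m)]
        rows.append(
            dict(
                gene_id=rec.gene_id,
                origin=rec.origin,
                partner_id=rec.partner_id or "",
                event_time="" if rec.event_time is None else rec.event_time,
                wgd_round="" if rec.wgd_round is None else rec.wgd_round,
                true_labels=",".join(lbls) or "singleton",
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
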