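"""Annotation, similarity-hit and sequence I/O.

Everything downstream of this module reasons about genes in *rank space*:
each gene gets an integer order index along its chromosome, and all
"intervening gene" computations (tandem spacers, synteny gaps, block
merging distances) are counted in ranks, not base pairs.

Internal coordinates are 0-based half-open.  GFF3 (1-based closed) and
BED (0-based half-open) are converted at the boundary on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
from Bio import SeqIO


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene in internal (0-based half-open) coordinates.

    ``rank`` is the 0-based order index of the gene along its chromosome,
    assigned by ascending start coordinate (ties: ascending end, then
    lexicographic gene id).  ``cds_length`` is the total coding length in
    base pairs; ``exon_lengths`` is optional and may be empty.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int
    cds_length: int = 0
    exon_lengths: tuple[int, ...] = ()
    species: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} !< end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.cds_length < 0:
            raise AnnotationError(f"gene {self.gene_id}: negative cds_length")
        if self.exon_lengths and self.cds_length > (self.end - self.start):
            raise AnnotationError(
                f"gene {self.gene_id}: cds_length exceeds gene span "
                "although exon structure is present"
            )


class GenomeAnnotation:
    """A species' gene set, indexed by gene id and by (chromosome, rank)."""

    def __init__(self, species: str, genes: Iterable[GeneModel]):
        self.species = species
        self._by_id: dict[str, GeneModel] = {}
        self._by_pos: dict[tuple[str, int], GeneModel] = {}
        for g in genes:
            if g.gene_id in self._by_id:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            self._by_id[g.gene_id] = g
            self._by_pos[(g.chromosome, g.rank)] = g
        # ranks per chromosome must form 0..n-1 with no gaps
        per_chrom: dict[str, list[int]] = {}
        for g in self._by_id.values():
            per_chrom.setdefault(g.chromosome, []).append(g.rank)
        for chrom, ranks in per_chrom.items():
            if sorted(ranks) != list(range(len(ranks))):
                raise AnnotationError(f"{chrom}: ranks are not a gap-free 0..n-1 run")
        self._chrom_sizes = {c: len(r) for c, r in per_chrom.items()}

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __iter__(self) -> Iterator[GeneModel]:
        for chrom in sorted(self._chrom_sizes):
            for rank in range(self._chrom_sizes[chrom]):
                yield self._by_pos[(chrom, rank)]

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def at(self, chromosome: str, rank: int) -> GeneModel:
        return self._by_pos[(chromosome, rank)]

    @property
    def chromosomes(self) -> dict[str, int]:
        """Chromosome name -> number of genes."""
        return dict(self._chrom_sizes)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self]


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity record (BLAST outfmt-6-like)."""

    query_id: str
    subject_id: str
    identity: float
    align_length: int
    evalue: float
    bitscore: float
    query_length: int | None = None
    subject_length: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise AnnotationError(
                f"hit {self.query_id}/{self.subject_id}: negative e-value"
            )


# ---------------------------------------------------------------------------
# readers


def _assign_ranks(rows: list[dict], species: str) -> list[GeneModel]:
    seen: set[str] = set()
    for r in rows:
        if r["gene_id"] in seen:
            raise AnnotationError(f"duplicate gene_id {r['gene_id']}")
        seen.add(r["gene_id"])
    genes: list[GeneModel] = []
    by_chrom: dict[str, list[dict]] = {}
    for r in rows:
        by_chrom.setdefault(r["chromosome"], []).append(r)
    for chrom, crows in by_chrom.items():
        crows.sort(key=lambda r: (r["start"], r["end"], r["gene_id"]))
        for rank, r in enumerate(crows):
            genes.append(
                GeneModel(
                    gene_id=r["gene_id"],
                    chromosome=chrom,
                    start=r["start"],
                    end=r["end"],
                    strand=r["strand"],
                    rank=rank,
                    cds_length=r.get("cds_length", 0),
                    exon_lengths=tuple(r.get("exon_lengths", ())),
                    species=species,
                )
            )
    return genes


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates {cols[3]!r}/{cols[4]!r}"
                ) from exc
            if start > end:
                raise AnnotationError(f"{path}:{lineno}: start > end")


def _read_gff3(path: Path, species: str) -> list[dict]:
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
        force_gff=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        cds = [c for c in db.children(feat, featuretype="CDS")]
        exon_lengths = tuple(c.end - c.start + 1 for c in sorted(cds, key=lambda c: c.start))
        rows.append(
            dict(
                gene_id=gene_id,
                chromosome=feat.seqid,
                start=feat.start - 1,  # 1-based closed -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                cds_length=sum(exon_lengths),
                exon_lengths=exon_lengths,
            )
        )
    return rows


def _read_bed(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise AnnotationError(f"{path}:{lineno}: BED needs >= 4 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "+"
            rows.append(
                dict(
                    gene_id=cols[3],
                    chromosome=cols[0],
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return rows


def _read_tsv(path: Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: TSV missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        row = dict(
            gene_id=str(r["gene_id"]),
            chromosome=str(r["chromosome"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r["strand"]),
        )
        if "cds_length" in df.columns and not pd.isna(r["cds_length"]):
            row["cds_length"] = int(r["cds_length"])
        if "exon_lengths" in df.columns and not pd.isna(r["exon_lengths"]):
            row["exon_lengths"] = tuple(
                int(x) for x in str(r["exon_lengths"]).split(",") if x
            )
        rows.append(row)
    return rows


def read_annotation(path: str | Path, format: str = "gff3", species: str = "") -> GenomeAnnotation:
    """Read a gene annotation (``gff3``, ``bed`` or ``tsv``) into rank space."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gff3":
        rows = _read_gff3(path, species)
    elif format == "bed":
        rows = _read_bed(path)
    elif format == "tsv":
        rows = _read_tsv(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not species:
        species = path.stem
    return GenomeAnnotation(species, _assign_ranks(rows, species))


def write_annotation(annotation: GenomeAnnotation, path: str | Path, format: str = "gff3") -> None:
    """Write an annotation back out (GFF3 with CDS children, or TSV)."""
    path = Path(path)
    if format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in annotation:
                attrs = f"ID={g.gene_id}"
                fh.write(
                    f"{g.chromosome}\tlecdup\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                pos = g.start
                for i, ex in enumerate(g.exon_lengths):
                    fh.write(
                        f"{g.chromosome}\tlecdup\tCDS\t{pos + 1}\t{pos + ex}\t.\t"
                        f"{g.strand}\t0\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                    )
                    pos += ex + 50  # fixed intron spacer on write
    elif format == "tsv":
        recs = [
            dict(
                gene_id=g.gene_id,
                chromosome=g.chromosome,
                start=g.start,
                end=g.end,
                strand=g.strand,
                rank=g.rank,
                cds_length=g.cds_length,
                exon_lengths=",".join(map(str, g.exon_lengths)),
            )
            for g in annotation
        ]
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown annotation format {format!r}")


_HIT_COLS = [
    "query_id", "subject_id", "identity", "align_length", "mismatch",
    "gapopen", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path) -> list[SimilarityHit]:
    """Read a tab-separated similarity table (BLAST outfmt 6 column order).

    The common ``std qlen slen`` 13/14-column dialect is recognized; any
    further columns are ignored.  Self-hits (query == subject) are dropped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 12:
        raise AnnotationError(f"{path}: expected >= 12 columns, got {df.shape[1]}")
    df = df.rename(columns=dict(enumerate(_HIT_COLS)))
    for col in ("evalue", "bitscore", "identity"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~pd.to_numeric(df[col], errors="coerce").notna()]
            raise AnnotationError(
                f"{path}: non-numeric {col} at row {bad.index[0] + 1}"
            )
    has_lens = df.shape[1] >= 14
    hits: list[SimilarityHit] = []
    n_self = 0
    for row in df.itertuples(index=False):
        q, s = str(row[0]), str(row[1])
        if q == s:
            n_self += 1
            continue
        hits.append(
            SimilarityHit(
                query_id=q,
                subject_id=s,
                identity=float(row[2]),
                align_length=int(row[3]),
                evalue=float(row[10]),
                bitscore=float(row[11]),
                query_length=int(row[12]) if has_lens else None,
                subject_length=int(row[13]) if has_lens else None,
            )
        )
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-hits", stacklevel=2)
    return hits


def write_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the 14-column (std + qlen slen) tab-separated dialect."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity:.2f}\t{h.align_length}\t"
                f"0\t0\t1\t{h.align_length}\t1\t{h.align_length}\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\t"
                f"{h.query_length or 0}\t{h.subject_length or 0}\n"
            )


def read_fasta(path: str | Path, nucleotide: bool = True) -> dict[str, str]:
    """Read FASTA into {id: sequence}; ids are the first header token.

    Sequences are uppercased; in nucleotide mode U is converted to T.
    A duplicate id is a hard error; an empty sequence is kept with a warning.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AnnotationError(f"{path}: duplicate sequence id {rec.id}")
        seq = str(rec.seq).upper()
        if nucleotide:
            seq = seq.replace("U", "T")
        if not seq:
            warnings.warn(f"{path}: empty sequence for {rec.id}", stacklevel=2)
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for gid in seqs:
            fh.write(f">{gid}\n")
            s = seqs[gid]
            for i in range(0, max(len(s), 1), width):
                fh.write(s[i : i + width] + "\n")
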