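"""End-to-end duplicate classification over one genome.

Glues the module pipeline together in the standard order: hit filtering
-> tandem arrays -> self-synteny ohnolog calling -> TD-alpha ->
residual transposition calls -> assembled per-gene labels, so examples,
the CLI and evaluation code share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .annotation_io import GenomeAnnotation, SimilarityHit
from .dup_classifier import (
    DuplicationCall,
    GTDPair,
    TandemArray,
    assemble_calls,
    call_gtd,
    call_td_alpha,
    find_tandem_arrays,
)
from .homology import filter_hits
from .synteny import OhnologPair, SyntenyBlock, call_ohnologs


@dataclass
class ClassifierParams:
    homology_emax: float = 1e-10
    max_spacers: int = 10
    min_anchors: int = 5
    max_gap: int = 20
    max_merge_distance: int = 350
    max_depth: int = 3
    gtd_emax: float = 1e-30
    td_alpha_epoch: str = "any"  # "alpha" when Ks dating is enabled


@dataclass
class ClassificationResult:
    calls: dict[str, DuplicationCall]
    venn: dict[frozenset, int]
    tandem_arrays: list[TandemArray]
    ohnolog_pairs: list[OhnologPair]
    gtd_pairs: list[GTDPair]
    td_alpha_genes: set[str]
    blocks: list[SyntenyBlock] = field(default_factory=list)

    def label_set(self, label: str) -> set[str]:
        return {g for g, c in self.calls.items() if label in c.labels}


def classify_genome(
    annotation: GenomeAnnotation,
    hits: Iterable[SimilarityHit],
    params: ClassifierParams | None = None,
    ks_values: Mapping[tuple[str, str], float] | None = None,
    epoch_bins: Mapping[str, tuple[float, float]] | None = None,
) -> ClassificationResult:
    """Classify every gene of one genome into duplication modes using
    its all-vs-all self-similarity hits."""
    if params is None:
        params = ClassifierParams()
    hits = list(hits)
    filtered = filter_hits(hits, e_max=params.homology_emax)
    arrays = find_tandem_arrays(annotation, filtered, max_spacers=params.max_spacers)
    ohnolog_pairs, blocks = call_ohnologs(
        annotation,
        annotation,
        filtered,
        min_anchors=params.min_anchors,
        max_gap=params.max_gap,
        max_merge_distance=params.max_merge_distance,
        max_depth=params.max_depth,
        ks_values=ks_values,
        epoch_bins=epoch_bins,
    )
    td_alpha_genes, _report = call_td_alpha(arrays, ohnolog_pairs, epoch_filter=params.td_alpha_epoch)
    gtd_pairs = call_gtd(
        annotation.gene_ids(), hits, ohnolog_pairs, arrays, e_max=params.gtd_emax
    )
    calls, venn = assemble_calls(
        annotation.gene_ids(), arrays, ohnolog_pairs, gtd_pairs, td_alpha_genes
    )
    return ClassificationResult(
        calls=calls,
        venn=venn,
        tandem_arrays=arrays,
        ohnolog_pairs=ohnolog_pairs,
        gtd_pairs=gtd_pairs,
        td_alpha_genes=td_alpha_genes,
        blocks=blocks,
    )


def precision_recall_f1(predicted: set, truth: set) -> tuple[float, float, float]:
    """Set-level precision/recall/F1 (1.0 on two empty sets)."""
    if not predicted and not truth:
        return 1.0, 1.0, 1.0
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)


def score_against_truth(result: ClassificationResult, truth) -> dict[str, dict[str, float]]:
    """Per-mode gene-level precision/recall/F1 against simulator truth."""
    scores = {}
    for mode in ("tandem", "ohnolog", "gtd", "td_alpha"):
        pred = result.label_set(mode)
        true = getattr(truth, mode)
        p, r, f1 = precision_recall_f1(pred, true)
        scores[mode] = dict(precision=p, recall=r, f1=f1, n_pred=len(pred), n_true=len(true))
    pred_pairs = {frozenset((p.gene_a, p.gene_b)) for p in result.ohnolog_pairs}
    p, r, f1 = precision_recall_f1(pred_pairs, truth.ohnolog_pairs)
    scores["ohnolog_pairs"] = dict(precision=p, recall=r, f1=f1,
                                   n_pred=len(pred_pairs), n_true=len(truth.ohnolog_pairs))
    return scores
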