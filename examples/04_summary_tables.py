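"""Summary statistics: retention, tandem arrays, enrichment, fractions.

Runs the reporting layer on one simulated genome: duplicate fractions
with Venn partitions over {tandem, ohnolog, gtd}, tandem-array
statistics, an ohnolog-enrichment Fisher test for a target gene subset,
and a retention score.
"""

import lecdup
from lecdup.summary_stats import (
    fraction_report,
    ohnolog_enrichment,
    retention_score,
    tandem_stats,
)

out = lecdup.simulate(seed=1)
res = lecdup.classify_genome(out.annotation, out.hits)

rep = fraction_report(res.calls, res.venn, species="sim")
print(f"{rep.n_genes} genes, {rep.n_duplicates} duplicates ({rep.duplicate_pct} %)")
for mode, pct in rep.mode_pcts.items():
    print(f"  {mode:9s} {rep.mode_counts[mode]:4d} genes  {pct:3d} %")
print("Venn cells:", {"+".join(sorted(c)): n for c, n in sorted(rep.venn.items(), key=str)})

ts = tandem_stats(res.tandem_arrays, out.annotation.gene_ids(), species="sim")
print(f"tandem: {ts.n_tandem_members} genes in {ts.n_arrays} arrays "
      f"(mean {ts.mean_array_size}, largest {ts.largest_array})")

# enrichment of ohnologs among tandem-array genes vs the genome
target = res.label_set("tandem")
t_ohno = len(target & res.label_set("ohnolog"))
g_ohno = len(res.label_set("ohnolog"))
enr = ohnolog_enrichment(
    (t_ohno, len(target) - t_ohno), (g_ohno, rep.n_genes - g_ohno), species="sim"
)
print(f"ohnolog enrichment among tandem genes: odds={enr.odds_ratio:.2f} "
      f"p={enr.p_value:.3g} significant={enr.significant}")

# retention: how many ancestral genes kept their WGD copy
ret = retention_score(out.sim.config.n_ancestral_genes, len(out.truth.ohnolog_pairs))
print(f"retention: {ret.n_retained}/{ret.n_reference_targets} = {ret.score} %")
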