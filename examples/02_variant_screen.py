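"""Concordance screen of a simulated resequencing panel.

Simulates a fine-mapped interval with a planted cluster of perfectly
QTL-concordant SNPs among imperfectly differentiated variants plus
missingness, low site quality and repetitive flanks; then runs the filter
chain, scores QTL concordance, and reports the perfect cluster.
"""
from stickleqtl import screen, simulate

params = simulate.VariantPanelParams(
    interval_bp=100_000,
    n_differentiated=80,
    n_perfect=10,
    cluster_span_bp=4_400,
    genome_bp=300_000,
    missing_rate=0.05,
    repeat_fraction=0.08,
    seed=7,
)
variants, panel, genome, truth = simulate.simulate_variant_panel(params)
print(f"panel: {len(variants)} differentiated variants, "
      f"{len(panel.group('QTL_pos'))} QTL_pos vs {len(panel.group('QTL_neg'))} QTL_neg samples")

res = screen.run_screen(variants, panel, genome)
print("\nfilter tally (variants removed per rule, in order):")
for rule, n in res["tally"].items():
    print(f"  {rule}: {n}")
print(f"retained: {len(res['retained'])}")

report = res["cluster"]
print(f"\nperfectly concordant variants (score = 1.0): {report.count}"
      f" ({report.snp_count} SNPs, {report.indel_count} indels)")
print(f"cluster span: {report.span_bp} bp"
      f" [{report.min_pos}-{report.max_pos}]")
print(f"planted truth recovered: "
      f"{sorted(k[1] for k in report.variants) == truth['perfect_positions']}")
print("\nA concordance score of 1.0 means the variant allele is present on")
print("every called QTL-positive chromosome and absent from every")
print("QTL-negative one; the tight positional cluster of such variants is")
print("the candidate causal haplotype.")
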