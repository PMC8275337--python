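"""Genome-masked benchmark: GCN classification vs CNN-only.

Runs the standard synthetic scenario (4 families x 6 genomes, 20%
shared gene pool, one genome per family masked from training, 10
contigs of 4-8 kbp per masked genome) for one seed and prints the
macro metrics of the full knowledge-graph + GCN classifier next to the
CNN-only diagnostic.  Takes a couple of minutes on one CPU.
"""

from phagraph.pipeline import BenchmarkScenario, run_benchmark

result = run_benchmark(BenchmarkScenario(), seed=1)

print(f"{'':16s} {'macro-acc':>10s} {'macro-prec':>11s} {'macro-rec':>10s}")
for name, rep in [("GCN (full)", result.gcn_report), ("CNN-only", result.cnn_report)]:
    print(f"{name:16s} {rep.macro_accuracy:10.3f} {rep.macro_precision:11.3f} "
          f"{rep.macro_recall:10.3f}")
print(f"\nclassified: {result.classified_fraction:.0%} of "
      f"{len(result.truth)} contigs "
      f"({result.n_rejected} rejected)")
print("The knowledge graph lifts precision and recall over the CNN alone "
      "because contigs borrow evidence from their gene-sharing neighbors.")
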