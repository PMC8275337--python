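"""Out-of-scope detection: contigs from unseen families are rejected.

Builds a reference set of 4 families, then samples contigs from novel
families whose gene pools are disjoint from every reference cluster.
Because such contigs share no protein cluster with any reference, they
get no edge into the knowledge graph and receive no family label —
instead of being forced into the closest known family.
"""

from phagraph.pipeline import rejection_experiment

result = rejection_experiment(seed=1)
print(f"novel-family contigs tested : {result['n_contigs']}")
print(f"rejected (no prediction)    : {result['n_rejected']}")
print(f"rejection rate              : {result['rejection_rate']:.2%}")
print("\nA rejection rate near 100% means the classifier refuses to label "
      "sequences outside its training families rather than mislabeling them.")
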