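# phagraph

Family-level taxonomic classification of phage contigs with a
gene-sharing knowledge graph and a graph convolutional network (GCN).

Metagenomic assembly produces phage-like contigs far faster than they
can be classified: reference genomes are scarce, and phages in
different families share protein homologs, so homology search alone is
often ambiguous or silent.  `phagraph` treats the problem as
semi-supervised node classification.  Labeled reference genomes and
unlabeled query contigs become nodes of one graph; a GCN trained
transductively on that graph labels the contigs, and contigs with no
edge into the reference graph are *rejected* rather than forced into
the nearest family — which makes the method usable for targeted
detection as well as classification.

## The model

**Nodes** carry sequence-composition features learned by a CNN: each
2 kbp window is embedded with a skip-gram 3-mer model (M ∈ ℝ^2000×100),
convolved and pooled, and the first dense layer's ReLU output (512
units) is averaged over windows, so contigs of any length map to
fixed-size vectors.

**Edges** encode shared gene content.  Contig six-frame translations
are aligned against the reference proteins (best frame per contig
kept), the alignment graph is Markov-clustered into protein clusters,
and every sequence pair sharing c of the n clusters is scored with

* P_weight = −log₁₀( P(y ≥ c) · C(N, 2) ), the hypergeometric tail
  probability that sequences with a and b clusters share at least c,
  scaled by the number of sequence pairs, and
* E_weight = −log₁₀ of the mean E-value of the shared-protein
  alignments (kept for each node's top-5 partners; 0 when no alignment
  exists, e.g. between two contigs).

An edge exists iff P_weight + E_weight > τ (τ = 1).  The GCN

    H^(l+1) = ReLU( D̃^(-1/2) (G + I) D̃^(-1/2) H^(l) W^(l) ),
    Out     = softmax(H^(2) W^(2))

is trained with squared-error loss on the labeled nodes only; unlabeled
contigs participate in message passing and take the argmax of their
softmax row after training.

Everything — skip-gram, CNN, Markov clustering, seeded Smith–Waterman
with Karlin–Altschul E-values, GCN — is implemented in numpy/scipy
(numba for the alignment inner loop), with a pluggable external
backend for BLAST/DIAMOND tabular alignments.

## Worked example

`examples/gene_sharing_graph.py` builds two genomes from each of two
synthetic families, clusters their proteins and scores every pair:

```
21 proteins -> 9 clusters of >= 2 members

pair                                       c  P_weight  E_weight edge
family_0_g0 -- family_0_g1                 4      1.32     89.51 True
family_1_g0 -- family_1_g1                 5      1.32     69.86 True
```

Each same-family pair shares its family's gene clusters (c = 4 and 5
of n = 9), giving a positive P_weight and a large E_weight (their
shared proteins align at E ≈ 1e−90 and 1e−70), so both pairs clear the
τ = 1 edge threshold; no cross-family pair shares a cluster, so no
cross-family edge exists.  An unlabeled contig in that position would
be rejected as out of scope.

Other examples: `classify_contigs.py` (train + classify end to end,
printing per-contig predictions and confidences),
`synthetic_benchmark.py` (genome-masked benchmark comparing the GCN
with the CNN-only diagnostic), `rejection_of_novel_families.py`
(out-of-scope rejection rate).

A thin CLI wraps the same functions:

```bash
phagraph train    --refs refs.fa --labels labels.tsv --proteins prots.fa --out ckpt.npz
phagraph classify --contigs contigs.fa --refs refs.fa --labels labels.tsv \
                  --proteins prots.fa --ckpt ckpt.npz --out results/
phagraph benchmark --seed 1 --out report/
```

`classify` writes `predictions.tsv` (one row per input contig with a
family and softmax scores, or a rejection reason), `edge_scores.tsv`
(per-pair c, P_weight, E_weight, edge flag) and `rejected.tsv`.

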