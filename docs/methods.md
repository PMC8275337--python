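# Methods

`phagraph` assigns family-level taxonomic labels to phage contigs by
semi-supervised node classification on a *knowledge graph* whose nodes
are sequences (labeled reference genomes and unlabeled query contigs)
and whose edges encode statistically significant shared gene content.
This note describes the model, its assumptions, the tunable parameters,
the synthetic data used to validate it, and the numerical choices made
where the design was open.

## The model

### Node features: skip-gram embedding + CNN

Every sequence is cut into 2 kbp windows.  A skip-gram model over
3-mers is trained first: the 3-mer at position *i* predicts the 3-mers
at positions *i + j* for 1 ≤ |j| ≤ *m* (default *m* = 2), so 3-mers
that occur in similar local contexts get similar 100-dimensional
vectors.  Because the vocabulary has only 4³ = 64 words, the objective
is the exact softmax cross-entropy rather than a sampled approximation
— with 64 output classes the full softmax is cheap, exact, and has one
fewer hyperparameter.

A window then becomes an embedded matrix **M** ∈ ℝ^(2000×100) (one row
per 3-mer position; rows for 3-mers containing N are zero, and the
1998 3-mer rows are zero-padded to the stated 2000×100 shape).  The CNN
applies `n_conv` filters of height `d1` across the rows (ReLU), max-
pools each filter over positions, and passes the pooled vector through
two ReLU dense layers and a softmax over families.  Training minimises
cross-entropy on reference segments, each labeled with its genome's
family; segments are taken every `stride_train` nt (default 50).

In *encoding mode* the softmax head is dropped: the ReLU output of the
first dense layer (`feature_dim`, default 512) is the node feature, and
a contig's windows are averaged so contigs of any length map to vectors
of the same size.  Encoding uses non-overlapping windows by default
(stride = window): the training stride exists to augment the training
set, while overlapping windows at encoding time would over-weight
interior sequence.  The CNN softmax itself is kept only as a
diagnostic classifier (`cnn_predict_contig`, CLI `encode`).

### Edges: shared protein clusters

Proteins come from two sources: reference genomes supply their
annotated protein sets; contigs are translated in all six reading
frames, split at stop codons, with fragments shorter than 12 aa
discarded.  Contig translations are aligned against the reference
proteins, and reference proteins all-against-all (so clusters span
references); contig-vs-contig protein alignment is not performed.  For
each contig, only hits in its best frame — the frame attaining the
smallest E-value, ties broken by larger bitscore then smaller frame
index — are kept.  The retained hits define a weighted protein graph
(edge weight −log₁₀ E, E-values floored at 1e−200), which Markov
clustering partitions into protein clusters; clusters with fewer than
two members are discarded.  Two sequences "share a protein" when each
contains a member of the same retained cluster.

For a candidate pair (at least one shared cluster) with *a* and *b*
clusters sharing *c* of the *n* total clusters:

* **P-weight** = −log₁₀( P(y ≥ c) · C(N, 2) ), where P(y ≥ c) is the
  hypergeometric upper tail (every cluster equally likely) and N is the
  number of sequences in the run.  It is the negative log of the
  *expected number of sequence pairs* sharing at least c clusters by
  chance; values above 0 mean "fewer than one such pair expected".
* **E-weight**: S(A, B) = −log₁₀ of the arithmetic mean E-value over
  the shared-protein alignments between A and B (0 if there are none —
  in particular for contig–contig pairs, which have no alignments).
  The arithmetic mean is dominated by the *worst* shared protein, so a
  single strong hit cannot mask several weak ones.  Each node keeps its
  E-weight only for its top 5 partners ranked by S (an edge survives if
  kept from either endpoint; ties at the cut break by partner id).

An edge exists iff P-weight + E-weight > τ (strictly; τ = 1).  The two
weights are complementary: long contigs share many clusters and get
large P-weights; short contigs may share only one or two proteins, and
then the E-weight decides whether those proteins are similar enough.

### Rejection

An unlabeled contig whose connected component contains no reference
node receives no prediction.  This is deliberately stronger than
"isolated": two contigs from the same novel genome can share clusters
with *each other* without any link to the references, and force-
labeling such a label-free component would defeat out-of-scope
detection.  Rejection reasons are reported (`too_short` for contigs
under one window, `no_edges` otherwise), and classified + rejected
always equals the input count.

### Classifier: two-layer GCN

With binary adjacency G, the propagation operator is the symmetric
normalisation Â = D̃^(−1/2)(G + I)D̃^(−1/2).  The network is

    H1 = ReLU(Â H0 W0),  H2 = ReLU(Â H1 W1),  Out = softmax(H2 W2)

with hidden widths 512 → 128 → 32 → n_label and no bias terms.  (An
alternative right-exponent +1/2 normalisation is available behind
`literal_normalization`, but the symmetric operator is the standard
spectral form and the default.)  Training is transductive: labeled and
unlabeled nodes all participate in the forward pass; the loss is the
squared error between softmax rows and one-hot labels, summed over
labeled nodes only, minimised by Adam (lr 0.01, up to 200 epochs,
early stop after 20 epochs without improvement, best weights
restored).  Because squared error through a softmax has vanishing
gradients once an unlucky initialisation saturates, the fit restarts
from three derived seeds and keeps the run with the lowest training
loss.  Node features are scaled by their global maximum before
training so activations start in a sane range.  After training the
parameters are frozen and each in-graph unlabeled node takes the
argmax of its softmax row (ties → lowest class index, flagged).

A new contig set means a new graph and retraining: the model is
transductive by design, matching the per-run graph construction.

## Internal aligner

The alignment step is pluggable.  The `external` backend parses
standard BLAST tabular (outfmt 6) files produced by any aligner (e.g.
DIAMOND).  The `internal` backend is a seeded Smith–Waterman aligner:
candidate pairs need two exact 3-mer matches on the same diagonal
(words containing X/B/Z never seed); each candidate pair is then scored
with a full affine-gap Smith–Waterman matrix (BLOSUM62, gap open 11,
extend 1, a gap of length L costing 11 + L), so the optimal local score
is exact whenever a seed exists.  E-values use the Karlin–Altschul form
E = K·m·n·exp(−λS) with λ = 0.267, K = 0.041 (the standard gapped
BLOSUM62-11-1 parameters) and search space |query| × Σ|subjects|; hits
with E ≥ 1e−5 are discarded, and E-values of 0 (or underflow) are
floored at 1e−200 so logs stay finite.

## Markov clustering

MCL runs on the column-stochastic transition matrix of the protein
graph with self-loops equal to each node's maximum incident weight
(stabilises attractors on strongly weighted graphs).  Expansion is the
matrix square; inflation raises entries to the power r = 2.0 (the
canonical default) and renormalises columns; entries below 1e−8 are
pruned for sparsity.  Iteration stops when the matrix changes by less
than 1e−6 (or after 100 iterations, with a warning).  Attractors are
nodes with positive mass on their own row; a cluster is the support of
an attractor row, and overlapping attractor systems are merged.  MCL
weights are −log₁₀ E rather than raw E-values: a random walk needs
strong alignments to carry *large* transition probability, whereas raw
E-values would make the best alignments nearly invisible.

## Synthetic data

The generator reproduces the two signals the classifier uses, with
explicit control over the confound between them:

* **Gene sharing.**  A family is a pool of genes (random proteins of
  100–300 aa).  A configurable fraction (default 20%) of each family's
  genes are copies of a common shared pool, each family's copy
  diverging by 20% substitutions — clearly alignable, far from
  identical, emulating the cross-family homologs that make alignment-
  only classification ambiguous.  Within a family, each genome carries
  its own 3%-mutated copy of each gene, so every gene founds a protein
  cluster spanning the family's genomes.
* **Composition.**  Each family draws a trinucleotide profile from a
  Dirichlet(0.5) prior.  Genes are reverse-translated choosing
  synonymous codons in proportion to the family profile, and intergenic
  spacers are sampled from it directly, so the CNN has a genuine
  nucleotide signal.

A genome reverse-translates a ≥70% random subset of its family's genes
joined by composition-sampled spacers.  All genes sit on the forward
strand in one reading frame (spacer lengths are multiples of 3) and
every spacer is flanked by in-frame stop codons, so six-frame
translation recovers each planted protein exactly.  Contigs are windows
with uniformly random start and length.

What this does *not* emulate: sequencing error and assembly artifacts,
genes on both strands or in multiple frames (real contigs violate the
single-best-frame assumption more often), skewed family sizes, real
protein families' length and composition structure, and divergence
levels varying by gene.  Passing the benchmark therefore shows the
pipeline's machinery is sound and its statistics calibrated on data
with the assumed structure — not that real-data accuracy will match.

## Benchmark scenario and problem sizes

The standard evaluation scenario uses 4 families × 6 genomes (8–12
kbp, 10 genes each, 20% shared pool), masks one genome per family from
all training (genome-masking: test contigs represent novel species),
and samples 10 contigs of 4–8 kbp per masked genome.  Metrics are the
macro-averaged accuracy, precision and recall with one-vs-rest counts;
an unclassified contig counts as FN for its true class and TN for the
others, and a never-predicted class has precision 0.  For this
desk-scale scenario the CNN uses 16 filters, training stride 100 and 4
epochs (the package defaults are 64 filters, stride 50, 10 epochs);
the knowledge-graph and GCN stages run at their defaults.  Results are
averaged over three seeds.

## Numerical choices and degenerate inputs

* Log base 10 throughout the weight formulas, matching E-value
  conventions; configurable.
* P-weight is capped at 300 when the hypergeometric tail underflows;
  internally the tail is computed in log space so the cap is rarely
  reached.  P-weight may legitimately be negative (insignificant
  overlap).
* Strict inequality at τ: a pair summing exactly to τ gets no edge.
* A contig shorter than one window cannot be encoded and is rejected
  as `too_short` before any alignment.
* Segmentation drops a trailing residue shorter than the window
  rather than padding; windows are 0-based half-open.
* All stages draw their seeds from one run seed via a fan-out
  generator; identical seed + inputs give bit-identical checkpoints,
  graphs and predictions.

## Known limitations

* The best-frame rule keeps one reading frame per contig; contigs with
  genes in several frames (common in real data) lose the minority
  frames' evidence.
* The hypergeometric model assumes all protein clusters are equally
  likely; cluster size and label entropy are ignored.
* The GCN is transductive — every new contig batch retrains the model.
* The internal aligner is built for desk-scale validation, not for
  large reference databases; use the external backend with DIAMOND or
  BLAST for production runs.
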