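"""End-to-end orchestration: train the encoder, classify contigs,
run the synthetic benchmark.

The classify path mirrors the full pipeline: encode nodes with the CNN,
six-frame-translate contigs, align all proteins, pick each contig's best
frame, Markov-cluster the alignment graph, score sequence pairs
(P-weight + E-weight), assemble the knowledge graph, train the GCN
transductively and read off predictions for the unlabeled nodes.  Every
input contig appears in the output exactly once, either with a family
label or with a rejection reason (``too_short`` or ``no_edges``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .align import align_proteins, best_frame_filter
from .cluster import build_protein_graph, markov_cluster
from .encoder import (
    CNNEncoder,
    cnn_predict_contig,
    encode_contig,
    train_cnn,
    train_embedding,
)
from .gcn import Prediction, predict, train_gcn
from .graph import build_knowledge_graph, score_edges, top_k_edge_filter
from .metrics import UNCLASSIFIED, EvalReport, evaluate
from .sequence_io import Contig, ProteinRecord, segment_contig, six_frame_translate
from .synthetic import (
    ReferenceGenome,
    generate_families,
    generate_genome,
    genome_masked_split,
    sample_contigs,
)

__all__ = [
    "RunConfig",
    "BenchmarkScenario",
    "ClassifyResult",
    "BenchmarkResult",
    "run_train",
    "run_classify",
    "run_benchmark",
    "rejection_experiment",
]

logger = logging.getLogger("phagraph")


def fanout_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` per-stage seeds (< 2^31) from one global seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclass
class RunConfig:
    """All stage parameters of a run; defaults follow the method's
    stated defaults where it states them."""

    window: int = 2000
    stride_train: int = 50
    stride_encode: int | None = None  # None = non-overlapping windows
    min_protein_len: int = 12
    # embedding
    emb_m: int = 2
    emb_dim: int = 100
    emb_epochs: int = 3
    # CNN
    d1: int = 8
    n_conv: int = 64
    feature_dim: int = 512
    hidden2: int = 256
    cnn_epochs: int = 10
    cnn_lr: float = 1e-3
    cnn_batch: int = 64
    # alignment / clustering
    evalue_max: float = 1e-5
    backend: str = "internal"
    inflation: float = 2.0
    # knowledge graph
    tau: float = 1.0
    top_k: int = 5
    # GCN
    gcn_hidden: tuple[int, int] = (128, 32)
    gcn_epochs: int = 200
    gcn_lr: float = 1e-2
    gcn_patience: int = 20
    seed: int = 0


@dataclass
class ClassifyResult:
    predictions: pd.DataFrame  # one row per input contig
    edge_scores: pd.DataFrame
    rejected: dict[str, str]  # contig id -> reason
    raw_predictions: list[Prediction] = field(default_factory=list)
    cluster_table: list[tuple[int, str, str]] = field(default_factory=list)
    graph_edges: list[tuple[str, str]] = field(default_factory=list)


def run_train(references: Sequence[ReferenceGenome], config: RunConfig) -> CNNEncoder:
    """Train the skip-gram embedding and the CNN on labeled references."""
    families = {g.family for g in references}
    if len(families) < 2:
        raise ValueError("need references from at least 2 families")
    s_emb, s_cnn = fanout_seeds(config.seed, 2)
    corpus = [g.seq for g in references]
    logger.info("training 3-mer embedding on %d reference genomes", len(references))
    emb = train_embedding(
        corpus, m=config.emb_m, dim=config.emb_dim, seed=s_emb, epochs=config.emb_epochs
    )
    segments, labels = [], []
    for g in references:
        for seg in segment_contig(g.as_contig(), window=config.window, stride=config.stride_train):
            segments.append(seg)
            labels.append(g.family)
    counts = pd.Series(labels).value_counts().to_dict()
    logger.info("training CNN on %d segments (%s)", len(segments), counts)
    model = train_cnn(
        segments,
        labels,
        emb,
        window=config.window,
        d1=config.d1,
        n_conv=config.n_conv,
        feature_dim=config.feature_dim,
        hidden2=config.hidden2,
        epochs=config.cnn_epochs,
        lr=config.cnn_lr,
        batch_size=config.cnn_batch,
        seed=s_cnn,
    )
    logger.info("CNN loss %.4f -> %.4f", model.history[0], model.history[-1])
    return model


def _edge_frame(scores, tau: float) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_a": s.seq_a,
                "seq_b": s.seq_b,
                "c": s.c,
                "n_shared_hits": s.n_shared_hits,
                "p_weight": s.p_weight,
                "e_weight": s.e_weight,
                "edge": int(s.p_weight + s.e_weight > tau),
            }
            for s in scores
        ]
    )


def run_classify(
    contigs: Sequence[Contig],
    references: Sequence[ReferenceGenome],
    model: CNNEncoder,
    config: RunConfig,
    alignment_file=None,
) -> ClassifyResult:
    """Classify contigs against labeled references with the full pipeline."""
    if not contigs:
        raise ValueError("empty contig input")
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids")
    labels = {g.id: g.family for g in references}
    rejected: dict[str, str] = {}

    usable = []
    for c in contigs:
        if c.length < config.window:
            rejected[c.id] = "too_short"
        else:
            usable.append(c)
    logger.info("%d/%d contigs long enough to encode", len(usable), len(contigs))

    # node features
    features: dict[str, np.ndarray] = {}
    for g in references:
        features[g.id] = encode_contig(g.as_contig(), model, stride=config.stride_encode)
    for c in usable:
        features[c.id] = encode_contig(c, model, stride=config.stride_encode)

    # proteins and alignment: contig translations against the reference
    # proteins, plus reference-vs-reference so clusters span references
    ref_proteins: list[ProteinRecord] = []
    for g in references:
        ref_proteins.extend(g.proteins)
    contig_proteins: list[ProteinRecord] = []
    for c in usable:
        contig_proteins.extend(six_frame_translate(c, min_len=config.min_protein_len))
    registry = {p.id: p for p in ref_proteins + contig_proteins}
    logger.info(
        "aligning %d contig translations against %d reference proteins (%s backend)",
        len(contig_proteins),
        len(ref_proteins),
        config.backend,
    )
    if config.backend == "external":
        hits = align_proteins(
            ref_proteins + contig_proteins,
            evalue_max=config.evalue_max,
            backend="external",
            alignment_file=alignment_file,
        )
    else:
        hits = align_proteins(ref_proteins, evalue_max=config.evalue_max)
        if contig_proteins:
            hits += align_proteins(
                contig_proteins, ref_proteins, evalue_max=config.evalue_max
            )
    hits = best_frame_filter(hits, registry)
    logger.info("%d hits after best-frame filter", len(hits))

    pgraph = build_protein_graph(hits)
    if pgraph.number_of_nodes() == 0:
        for c in usable:
            rejected[c.id] = "no_edges"
        preds = [Prediction(cid, UNCLASSIFIED, None) for cid in rejected]
        return ClassifyResult(
            predictions=_prediction_frame(contigs, preds, rejected, model.class_names),
            edge_scores=pd.DataFrame(),
            rejected=rejected,
            raw_predictions=preds,
        )
    clusters = markov_cluster(
        pgraph,
        inflation=config.inflation,
        parent_of={pid: p.parent_id for pid, p in registry.items()},
    )
    logger.info("%d protein clusters retained", clusters.n)

    seq_ids = list(labels) + [c.id for c in usable]
    scores = score_edges(seq_ids, clusters, hits)
    scores = top_k_edge_filter(scores, k=config.top_k)
    kg = build_knowledge_graph(features, labels, scores, tau=config.tau)
    for cid in kg.rejected:
        rejected[cid] = "no_edges"
    logger.info(
        "knowledge graph: %d nodes, %d edges, %d rejected contigs",
        kg.n_nodes,
        int(kg.adjacency.sum() // 2),
        len(kg.rejected),
    )

    n_unlabeled = sum(l is None for l in kg.labels)
    if n_unlabeled:
        s_gcn = fanout_seeds(config.seed, 3)[2]
        gcn = train_gcn(
            kg,
            hidden_dims=config.gcn_hidden,
            epochs=config.gcn_epochs,
            lr=config.gcn_lr,
            seed=s_gcn,
            patience=config.gcn_patience,
        )
        preds = predict(kg, gcn)
    else:
        preds = [Prediction(cid, UNCLASSIFIED, None) for cid in kg.rejected]
    parent_of = {pid: p.parent_id for pid, p in registry.items()}
    return ClassifyResult(
        predictions=_prediction_frame(contigs, preds, rejected, model.class_names),
        edge_scores=_edge_frame(scores, config.tau),
        rejected=rejected,
        raw_predictions=preds,
        cluster_table=clusters.to_table(parent_of),
        graph_edges=kg.to_edgelist(),
    )


def _prediction_frame(
    contigs: Sequence[Contig],
    preds: Sequence[Prediction],
    rejected: dict[str, str],
    class_names: Sequence[str],
) -> pd.DataFrame:
    by_id = {p.seq_id: p for p in preds if not p.is_reference}
    rows = []
    for c in contigs:
        p = by_id.get(c.id)
        if c.id in rejected or p is None:
            rows.append(
                {
                    "contig_id": c.id,
                    "status": "rejected",
                    "reason": rejected.get(c.id, "no_edges"),
                    "predicted_family": UNCLASSIFIED,
                    "max_score": np.nan,
                    **{f"score_{k}": np.nan for k in class_names},
                }
            )
        else:
            scores = dict(zip(class_names, p.scores)) if p.scores is not None else {}
            rows.append(
                {
                    "contig_id": c.id,
                    "status": "classified",
                    "reason": "",
                    "predicted_family": p.label,
                    "max_score": float(max(scores.values())) if scores else np.nan,
                    **{f"score_{k}": float(v) for k, v in scores.items()},
                }
            )
    frame = pd.DataFrame(rows)
    assert len(frame) == len(contigs), "every contig must appear exactly once"
    return frame


@dataclass
class BenchmarkScenario:
    """The standard synthetic benchmark: 4 families of 6 genomes with a
    20% shared gene pool, one genome per family masked from training,
    10 contigs of 4-8 kbp per masked genome."""

    n_families: int = 4
    genomes_per_family: int = 6
    genes_per_family: int = 10
    shared_fraction: float = 0.2
    protein_length: tuple[int, int] = (100, 300)
    genome_length: tuple[int, int] = (8000, 12000)
    test_per_family: int = 1
    contigs_per_genome: int = 10
    contig_length: tuple[int, int] = (4000, 8000)
    config: RunConfig = field(
        default_factory=lambda: RunConfig(
            stride_train=100, n_conv=16, cnn_epochs=4, emb_epochs=2
        )
    )


@dataclass
class BenchmarkResult:
    gcn_report: EvalReport
    cnn_report: EvalReport
    truth: dict[str, str]
    gcn_predictions: dict[str, str]
    cnn_predictions: dict[str, str]
    classify_result: ClassifyResult
    n_rejected: int

    @property
    def classified_fraction(self) -> float:
        return 1.0 - self.n_rejected / len(self.truth)


def make_dataset(
    scenario: BenchmarkScenario, seed: int
) -> tuple[list[ReferenceGenome], list[ReferenceGenome], list[Contig], dict[str, str]]:
    """Generate genomes, perform the genome-masked split and sample test
    contigs.  Returns (train genomes, test genomes, contigs, truth)."""
    s_fam, s_gen, s_split, s_contig = fanout_seeds(seed, 4)
    families = generate_families(
        n_families=scenario.n_families,
        genes_per_family=scenario.genes_per_family,
        shared_fraction=scenario.shared_fraction,
        seed=s_fam,
        protein_length=scenario.protein_length,
        genome_length=scenario.genome_length,
    )
    genomes = []
    for fi, fam in enumerate(families):
        for gi in range(scenario.genomes_per_family):
            genomes.append(
                generate_genome(fam, seed=s_gen + fi * 1000 + gi, index=gi)
            )
    train, test = genome_masked_split(genomes, scenario.test_per_family, seed=s_split)
    contigs, truth = [], {}
    for ti, g in enumerate(test):
        for c in sample_contigs(
            g, scenario.contig_length, scenario.contigs_per_genome, seed=s_contig + ti
        ):
            contigs.append(c)
            truth[c.id] = g.family
    return train, test, contigs, truth


def run_benchmark(scenario: BenchmarkScenario, seed: int) -> BenchmarkResult:
    """Generate data, train, classify, and evaluate GCN vs CNN-only."""
    config = replace(scenario.config, seed=seed)
    train, test, contigs, truth = make_dataset(scenario, seed)
    model = run_train(train, config)
    result = run_classify(contigs, train, model, config)

    classes = sorted({g.family for g in train})
    gcn_pred = dict(
        zip(result.predictions["contig_id"], result.predictions["predicted_family"])
    )
    cnn_pred = {
        c.id: model.class_names[int(np.argmax(cnn_predict_contig(c, model)))]
        for c in contigs
    }
    return BenchmarkResult(
        gcn_report=evaluate(gcn_pred, truth, classes),
        cnn_report=evaluate(cnn_pred, truth, classes),
        truth=truth,
        gcn_predictions=gcn_pred,
        cnn_predictions=cnn_pred,
        classify_result=result,
        n_rejected=len(result.rejected),
    )


def rejection_experiment(
    seed: int,
    n_ref_families: int = 4,
    ref_genomes_per_family: int = 3,
    n_novel_families: int = 2,
    novel_genomes_per_family: int = 10,
    contig_length: tuple[int, int] = (4000, 8000),
    config: RunConfig | None = None,
) -> dict:
    """Out-of-scope detection: contigs from families whose proteins are
    disjoint from every reference cluster should receive no prediction.

    One contig is sampled per novel genome (so out-of-family contigs do
    not trivially share proteins through overlap), the gene-sharing
    graph is built exactly as in classification, and the rejection rate
    is the fraction of novel contigs left without an edge into any
    reference component.  Node features are not needed to decide
    rejection, so the CNN stage is skipped.
    """
    config = config or RunConfig()
    s_ref, s_novel, s_contig = fanout_seeds(seed, 3)
    ref_families = generate_families(
        n_families=n_ref_families, seed=s_ref, shared_fraction=0.2
    )
    references = [
        generate_genome(fam, seed=s_ref + fi * 100 + gi, index=gi)
        for fi, fam in enumerate(ref_families)
        for gi in range(ref_genomes_per_family)
    ]
    novel_families = generate_families(
        n_families=n_novel_families, seed=s_novel, shared_fraction=0.0
    )
    novel_contigs: list[Contig] = []
    for fi, fam in enumerate(novel_families):
        for gi in range(novel_genomes_per_family):
            g = generate_genome(fam, seed=s_novel + fi * 100 + gi, index=gi)
            novel_contigs.extend(
                sample_contigs(g, contig_length, 1, seed=s_contig + fi * 100 + gi,
                               id_prefix=f"novel_{fi}_{gi}")
            )

    labels = {g.id: g.family for g in references}
    ref_proteins = [p for g in references for p in g.proteins]
    contig_proteins = [
        p
        for c in novel_contigs
        for p in six_frame_translate(c, min_len=config.min_protein_len)
    ]
    registry = {p.id: p for p in ref_proteins + contig_proteins}
    hits = align_proteins(ref_proteins, evalue_max=config.evalue_max)
    if contig_proteins:
        hits += align_proteins(contig_proteins, ref_proteins, evalue_max=config.evalue_max)
    hits = best_frame_filter(hits, registry)
    pgraph = build_protein_graph(hits)
    if pgraph.number_of_nodes() == 0:
        n_rej = len(novel_contigs)
    else:
        clusters = markov_cluster(
            pgraph,
            inflation=config.inflation,
            parent_of={pid: p.parent_id for pid, p in registry.items()},
        )
        seq_ids = list(labels) + [c.id for c in novel_contigs]
        scores = top_k_edge_filter(score_edges(seq_ids, clusters, hits), k=config.top_k)
        dummy = {sid: np.zeros(1) for sid in seq_ids}
        kg = build_knowledge_graph(dummy, labels, scores, tau=config.tau)
        n_rej = len(kg.rejected)
    return {
        "n_contigs": len(novel_contigs),
        "n_rejected": n_rej,
        "rejection_rate": n_rej / len(novel_contigs),
    }
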