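"""All-against-all protein alignment behind a hit-list contract.

Two backends produce the same :class:`AlignmentHit` records:

* ``internal`` — an exact-3-mer two-hit seeded Smith–Waterman aligner
  (BLOSUM62, gap open 11 / extend 1, Karlin–Altschul E-values with fixed
  lambda = 0.267, K = 0.041 and search space ``|q| * sum(|s|)``).  For
  every seeded pair the full dynamic-programming matrix is evaluated, so
  the optimal local score is exact.
* ``external`` — a parser for BLAST tabular (outfmt 6) files produced by
  a user-run aligner such as DIAMOND.

Hits with E-value at or above the threshold are discarded, as are
self-hits.  The best-frame filter keeps, per contig, only hits whose
contig-derived protein lies in the frame with the most significant
alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .sequence_io import ProteinRecord

__all__ = [
    "AlignmentHit",
    "align_proteins",
    "parse_blast_tabular",
    "best_frame_filter",
    "smith_waterman_score",
    "evalue_from_score",
]

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1
EVALUE_FLOOR = 1e-200

_AA = "ARNDCQEGHILKMFPSTWYVBZX"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_N_AA = len(_AA)


def _blosum62_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((_N_AA, _N_AA), dtype=np.int64)
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            mat[i, j] = int(blosum[a, b])
    return mat


BLOSUM62 = _blosum62_matrix()


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    query_parent: str
    subject_parent: str

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be positive (floor zero E-values first)")


def encode_protein(aa_seq: str) -> np.ndarray:
    """Map an amino-acid string onto BLOSUM62 row indices (unknown -> X)."""
    x = _AA_INDEX["X"]
    return np.array([_AA_INDEX.get(a, x) for a in aa_seq], dtype=np.int64)


@njit(cache=True)
def _sw_score(a: np.ndarray, b: np.ndarray, mat: np.ndarray, gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score, affine gaps: a gap of length L costs
    gap_open + gap_extend * L (BLAST convention)."""
    n, m = len(a), len(b)
    NEG = -10**9
    h_prev = np.zeros(m + 1, dtype=np.int64)
    e_row = np.full(m + 1, NEG, dtype=np.int64)  # gap in a (along b)
    best = 0
    h_curr = np.zeros(m + 1, dtype=np.int64)
    f_prev = np.full(m + 1, NEG, dtype=np.int64)  # gap in b (along a)
    for i in range(1, n + 1):
        h_curr[0] = 0
        f_curr = np.full(m + 1, NEG, dtype=np.int64)
        e = NEG
        for j in range(1, m + 1):
            diag = h_prev[j - 1] + mat[a[i - 1], b[j - 1]]
            e = max(e - gap_extend, h_curr[j - 1] - gap_open - gap_extend)
            f = max(f_prev[j] - gap_extend, h_prev[j] - gap_open - gap_extend)
            f_curr[j] = f
            h = diag
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_curr[j] = h
            if h > best:
                best = h
        h_prev, h_curr = h_curr, h_prev
        f_prev = f_curr
    return best


def smith_waterman_score(
    aa_a: str,
    aa_b: str,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> int:
    """Exact optimal local-alignment score of two proteins under BLOSUM62."""
    return int(_sw_score(encode_protein(aa_a), encode_protein(aa_b), BLOSUM62, gap_open, gap_extend))


def evalue_from_score(score: int, query_len: int, subject_space: int) -> float:
    """Karlin–Altschul expected number of chance alignments with >= score."""
    e = KA_K * query_len * subject_space * math.exp(-KA_LAMBDA * score)
    return max(e, EVALUE_FLOOR)


def bitscore_from_score(score: int) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)


def _kmer_ids(codes: np.ndarray, k: int = 3) -> np.ndarray:
    """Integer ids of the k-mers of an index-encoded protein; words
    containing X/B/Z are marked -1 so they never seed."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    n20 = 20  # only the 20 canonical residues seed
    valid = codes < n20
    ids = np.zeros(len(codes) - k + 1, dtype=np.int64)
    ok = np.ones(len(codes) - k + 1, dtype=bool)
    for off in range(k):
        seg = codes[off : off + len(ids)]
        ids = ids * n20 + np.minimum(seg, n20 - 1)
        ok &= valid[off : off + len(ids)]
    ids[~ok] = -1
    return ids


def _seed_pairs(encoded: list[np.ndarray], k: int = 3) -> set[tuple[int, int]]:
    """Candidate pairs: two exact k-mer matches on the same diagonal.

    Returns index pairs (i, j) with i < j.
    """
    kmers = []
    prots = []
    poss = []
    for idx, codes in enumerate(encoded):
        ids = _kmer_ids(codes, k)
        keep = ids >= 0
        kmers.append(ids[keep])
        prots.append(np.full(int(keep.sum()), idx, dtype=np.int64))
        poss.append(np.nonzero(keep)[0].astype(np.int64))
    if not kmers:
        return set()
    kmer_arr = np.concatenate(kmers)
    prot_arr = np.concatenate(prots)
    pos_arr = np.concatenate(poss)
    order = np.argsort(kmer_arr, kind="stable")
    kmer_arr, prot_arr, pos_arr = kmer_arr[order], prot_arr[order], pos_arr[order]
    bounds = np.nonzero(np.diff(kmer_arr))[0] + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(kmer_arr)]))

    max_len = max((len(c) for c in encoded), default=0) + 1
    n_prot = len(encoded)
    hit_keys: list[np.ndarray] = []
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        p = prot_arr[s:e]
        q = pos_arr[s:e]
        pi, pj = np.meshgrid(p, p, indexing="ij")
        qi, qj = np.meshgrid(q, q, indexing="ij")
        sel = pi < pj
        if not sel.any():
            continue
        pi, pj, qi, qj = pi[sel], pj[sel], qi[sel], qj[sel]
        diag = qi - qj + max_len  # shift to non-negative
        key = (pi * n_prot + pj) * (2 * max_len) + diag
        hit_keys.append(key)
    if not hit_keys:
        return set()
    keys = np.concatenate(hit_keys)
    uniq, counts = np.unique(keys, return_counts=True)
    two_hit = uniq[counts >= 2] // (2 * max_len)
    pairs = {(int(v // n_prot), int(v % n_prot)) for v in two_hit}
    return pairs


def align_proteins(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord] | None = None,
    evalue_max: float = 1e-5,
    backend: str = "internal",
    alignment_file: str | Path | None = None,
) -> list[AlignmentHit]:
    """All-against-all protein alignment returning significant hits.

    With ``subjects=None`` (or the same list as ``queries``) the search is
    a symmetric all-against-all and each pair is reported once.  The
    ``external`` backend reads a BLAST tabular file instead of aligning.
    """
    if backend == "external":
        if alignment_file is None:
            raise ValueError("external backend requires alignment_file")
        meta = {p.id: p for p in list(queries) + list(subjects or [])}
        return parse_blast_tabular(alignment_file, meta, evalue_max=evalue_max)
    if backend != "internal":
        raise ValueError(f"unknown backend {backend!r}")

    symmetric = subjects is None or subjects is queries
    pool: list[ProteinRecord] = list(queries) if symmetric else list(queries) + list(subjects)
    if not pool:
        raise ValueError("empty protein input")
    n_query = len(queries)
    encoded = [encode_protein(p.aa_seq) for p in pool]
    subject_space = sum(len(p.aa_seq) for p in (pool if symmetric else subjects))

    hits: list[AlignmentHit] = []
    for i, j in sorted(_seed_pairs(encoded)):
        if not symmetric:
            # orient as (query, subject); skip within-set pairs
            if i < n_query and j < n_query:
                continue
            if i >= n_query and j >= n_query:
                continue
            qi, sj = (i, j) if i < n_query else (j, i)
        else:
            qi, sj = i, j
        pq, ps = pool[qi], pool[sj]
        if pq.id == ps.id:
            continue
        score = int(_sw_score(encoded[qi], encoded[sj], BLOSUM62, GAP_OPEN, GAP_EXTEND))
        ev = evalue_from_score(score, len(pq.aa_seq), subject_space)
        if ev < evalue_max:
            hits.append(
                AlignmentHit(
                    query_id=pq.id,
                    subject_id=ps.id,
                    evalue=ev,
                    bitscore=bitscore_from_score(score),
                    query_parent=pq.parent_id,
                    subject_parent=ps.parent_id,
                )
            )
    return hits


BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def parse_blast_tabular(
    path: str | Path,
    proteins: Mapping[str, ProteinRecord],
    evalue_max: float = 1e-5,
) -> list[AlignmentHit]:
    """Parse BLAST/DIAMOND tabular output (outfmt 6, 12 columns)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 tab-separated columns")
            qid, sid = fields[0], fields[1]
            try:
                ev = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable numeric field") from exc
            if qid == sid:
                continue
            ev = max(ev, EVALUE_FLOOR)
            if ev >= evalue_max:
                continue
            try:
                qp = proteins[qid].parent_id
                sp = proteins[sid].parent_id
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: unknown protein id {exc}") from exc
            hits.append(AlignmentHit(qid, sid, ev, bits, qp, sp))
    return hits


def best_frame_filter(
    hits: Iterable[AlignmentHit],
    proteins: Mapping[str, ProteinRecord],
) -> list[AlignmentHit]:
    """Keep, per contig, only hits in that contig's best reading frame.

    The best frame is the one whose hits attain the smallest E-value
    (E-value ties — e.g. at the floor — broken by the larger bitscore,
    then by the smaller frame index).  Reference-derived proteins are
    unaffected.  A hit survives only if every contig-derived endpoint is
    in its contig's best frame.
    """
    best: dict[str, tuple[float, float, int]] = {}
    hit_list = list(hits)
    for h in hit_list:
        for pid in (h.query_id, h.subject_id):
            p = proteins[pid]
            if p.source != "contig":
                continue
            cur = best.get(p.parent_id)
            cand = (h.evalue, -h.bitscore, p.frame)
            if cur is None or cand < cur:
                best[p.parent_id] = cand
    out = []
    for h in hit_list:
        ok = True
        for pid in (h.query_id, h.subject_id):
            p = proteins[pid]
            if p.source == "contig" and p.frame != best[p.parent_id][2]:
                ok = False
                break
        if ok:
            out.append(h)
    return out
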