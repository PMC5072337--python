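"""Greedy identity clustering of the current homolog set.

Each search iteration divides the homologs into groups at a 40% identity
cutoff before profile building.  Identity between two sequences is defined
on their optimal global alignment under BLOSUM62 with affine gaps (open 11,
extend 1): the number of identically aligned residue pairs divided by the
length of the shorter sequence, so fragments of a member still cluster with
it.  Among score-optimal alignments the one with the most identities is
used, which makes the value well defined and symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .formats import ProteinRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_NEG_INF = float("-inf")

GAP_OPEN = 11.0    # cost of the first residue of a gap
GAP_EXTEND = 1.0   # cost of each further residue


def _score_matrix(a: str, b: str) -> np.ndarray:
    alpha = _BLOSUM62.alphabet
    idx = {ch: alpha.index(ch) for ch in set(a) | set(b)}
    mat = np.asarray(_BLOSUM62)
    ia = np.array([idx[ch] for ch in a])
    ib = np.array([idx[ch] for ch in b])
    return mat[np.ix_(ia, ib)]


# (score, identity-count) pairs are encoded as score*_K + count, which makes
# lexicographic comparison plain numeric comparison: BLOSUM62 entries and the
# gap costs are integers, so score differences are >= 1 encoding unit = _K,
# while counts stay below _K.  Exact in float64 for sequences < 4096 residues.
_K = 4096.0


def pairwise_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Fraction of identical aligned pairs over the shorter sequence length.

    Computed on a global Needleman-Wunsch/Gotoh alignment under BLOSUM62
    (gap open 11, extend 1; end gaps penalized).  The DP maximizes
    (score, identities) lexicographically, so among all score-optimal
    alignments the maximal identity count is reported; this makes the value
    well defined and symmetric.
    """
    sa = a.residues if isinstance(a, ProteinRecord) else a
    sb = b.residues if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("empty sequence")
    if max(len(sa), len(sb)) >= _K:
        raise ValueError("sequences longer than 4095 residues are not supported")
    n, m = len(sa), len(sb)
    sub = _score_matrix(sa, sb) * _K
    arr_b = np.frombuffer(sb.encode(), dtype=np.uint8)
    arr_a = np.frombuffer(sa.encode(), dtype=np.uint8)
    ident = (arr_a[:, None] == arr_b[None, :]).astype(float)
    diag = sub + ident

    open_k, ext_k = GAP_OPEN * _K, GAP_EXTEND * _K
    j_idx = np.arange(m + 1, dtype=float)

    M = np.full(m + 1, _NEG_INF)
    X = np.full(m + 1, _NEG_INF)
    Y = np.full(m + 1, _NEG_INF)
    M[0] = 0.0
    Y[1:] = -open_k - ext_k * np.arange(m)
    for i in range(n):
        newX = np.maximum(np.maximum(M - open_k, X - ext_k), Y - open_k)
        newM = np.full(m + 1, _NEG_INF)
        newM[1:] = np.maximum(np.maximum(M[:-1], X[:-1]), Y[:-1]) + diag[i]
        # Y[j] = max_{k<=j-1} E[k] - open_k - (j-1-k)*ext_k, via cummax
        E = np.maximum(newM, newX)
        A = np.maximum.accumulate(E + j_idx * ext_k)
        newY = np.full(m + 1, _NEG_INF)
        newY[1:] = A[:-1] - open_k - (j_idx[1:] - 1.0) * ext_k
        M, X, Y = newM, newX, newY
    best = max(M[m], X[m], Y[m])
    count = best - _K * np.floor(best / _K)
    return float(count) / min(n, m)


@dataclass
class SequenceCluster:
    """One identity cluster; the representative is the longest member."""

    representative_id: str
    member_ids: list[str]
    threshold: float


def greedy_cluster(records: list[ProteinRecord], threshold: float
                   ) -> list[SequenceCluster]:
    """Greedy incremental clustering at the given identity threshold.

    Records are processed by descending length (ties by ascending id); each
    joins the first existing cluster whose representative it matches at
    >= threshold, otherwise it founds a new cluster.  Representatives are
    therefore mutually < threshold identical.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(records, key=lambda r: (-len(r.residues), r.id))
    clusters: list[SequenceCluster] = []
    reps: dict[str, ProteinRecord] = {}
    for rec in order:
        placed = False
        for cl in clusters:
            if pairwise_identity(rec, reps[cl.representative_id]) >= threshold:
                cl.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(rec.id, [rec.id], threshold))
            reps[rec.id] = rec
    return clusters


def write_clusters_tsv(clusters: list[SequenceCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative_id\tmember_id\n")
        for i, cl in enumerate(clusters):
            for mid in cl.member_ids:
                fh.write(f"{i}\t{cl.representative_id}\t{mid}\n")
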