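"""Tree-based subfamily classification and the presence/absence matrix.

The grown master alignment is trimmed of gappy columns, pairwise distances
are computed as Poisson-corrected p-distances over mutually ungapped
columns, and an unrooted tree is built by canonical neighbor joining.
Unlabeled leaves inherit subfamily labels from reference leaves: after
midpoint rooting, each leaf is assigned the majority reference label of the
smallest clade containing it and at least one reference, provided the
majority reaches 75%; otherwise the leaf stays unclassified.  Tandem
two-domain proteins contribute two leaves (``id#N`` and ``id#C``), each
classified independently.  The proteome-by-subfamily presence/absence
matrix summarizes which genomes encode which family members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .formats import Alignment

#: Poisson correction saturates here: d = 5 whenever p >= 1 - e^-5.
D_MAX = 5.0
MAJORITY_THRESHOLD = 0.75


def trim_alignment(aln: Alignment, max_gap_fraction: float = 0.5
                   ) -> tuple[Alignment, list[int]]:
    """Drop columns with gap fraction > ``max_gap_fraction``.

    Returns the trimmed alignment and the kept source-column indices (the
    old -> new map), so per-column annotation such as zipper masks can be
    carried over.
    """
    if aln.n_rows == 0:
        raise ValueError("empty alignment")
    rows = list(aln.rows.values())
    n = len(rows)
    kept = [c for c in range(aln.n_cols)
            if sum(r[c] == "-" for r in rows) / n <= max_gap_fraction]
    if not kept:
        raise ValueError("trimming removed every column")
    trimmed = Alignment({rid: "".join(row[c] for c in kept)
                         for rid, row in aln.rows.items()})
    return trimmed, kept


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray   # symmetric, zero diagonal, substitutions/site

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p), capped at D_MAX."""
    if p >= 1.0 - math.exp(-D_MAX):
        return D_MAX
    return -math.log(1.0 - p)


def distance_matrix(aln: Alignment, min_shared: int = 10) -> DistanceMatrix:
    """Pairwise Poisson-corrected distances over mutually ungapped columns."""
    ids = list(aln.rows)
    if len(ids) < 3:
        raise ValueError("need >= 3 rows for a distance matrix")
    arr = np.array([[ord(c) for c in aln.rows[i]] for i in ids])
    present = arr != ord("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        shared = present[i] & present[i + 1:]
        n_shared = shared.sum(axis=1)
        too_few = np.nonzero(n_shared < min_shared)[0]
        if too_few.size:
            j = i + 1 + int(too_few[0])
            raise ValueError(f"rows {ids[i]!r} and {ids[j]!r} share only "
                             f"{int(n_shared[too_few[0]])} ungapped columns "
                             f"(< {min_shared})")
        diff = (arr[i] != arr[i + 1:]) & shared
        p = diff.sum(axis=1) / n_shared
        d[i, i + 1:] = [poisson_distance(float(x)) for x in p]
    d = d + d.T
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Neighbor joining

def build_nj(dist: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the smallest (i, j) index pair in node-creation
    order; negative branch lengths are floored at zero with the deficit
    moved to the sister branch.  The result is an unrooted dendropy tree
    (seed node of degree 3 for >= 3 taxa).
    """
    n0 = len(dist.ids)
    if n0 < 3:
        raise ValueError("need >= 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in dist.ids:
        nd = dendropy.Node(taxon=taxa.new_taxon(lab))
        nodes.append(nd)
    D = dist.values.astype(float).copy()
    active = list(range(n0))

    def floor_pair(bi: float, bj: float) -> tuple[float, float]:
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        return max(bi, 0.0), max(bj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        Q[np.tril_indices(m)] = np.inf
        # smallest Q; ties -> smallest (i, j) pair in creation order
        qmin = Q.min()
        ties = np.argwhere(Q == qmin)
        a, b = min(ties, key=lambda ab: (active[ab[0]], active[ab[1]]))
        a, b = int(a), int(b)
        i, j = active[a], active[b]
        dij = D[i, j]
        bi = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        bj = dij - bi
        bi, bj = floor_pair(bi, bj)
        parent = dendropy.Node()
        parent.add_child(nodes[i]); nodes[i].edge.length = bi
        parent.add_child(nodes[j]); nodes[j].edge.length = bj
        u = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # three-point formulas for the final star
    bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    center = dendropy.Node()
    for idx, bl in ((i, bi), (j, bj), (k, bk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(bl, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Subfamily assignment

@dataclass(frozen=True)
class SubfamilyAssignment:
    leaf_id: str
    subfamily: str          # label or "unclassified"
    support: float          # assigning label's fraction of clade references


def assign_subfamilies(tree: dendropy.Tree,
                       reference_labels: dict[str, str],
                       majority: float = MAJORITY_THRESHOLD
                       ) -> list[SubfamilyAssignment]:
    """Label every leaf from reference leaves by smallest enclosing clade.

    The tree is midpoint-rooted (solely to define nested clades); each
    unlabeled leaf takes the majority reference label of the smallest
    ancestral clade containing at least one reference leaf, with support =
    that label's fraction among the clade's references; below the majority
    threshold the leaf is "unclassified".  Reference leaves assign
    themselves with support 1.
    """
    if not reference_labels:
        raise ValueError("empty reference set")
    work = tree.clone(depth=1)
    work.reroot_at_midpoint(update_bipartitions=True)

    leaves = sorted(lf.taxon.label for lf in work.leaf_node_iter())
    leaf_idx = {name: i for i, name in enumerate(leaves)}
    n_leaves = len(leaves)
    total_refs: dict[str, int] = {}
    for name in leaves:
        lab = reference_labels.get(name)
        if lab is not None:
            total_refs[lab] = total_refs.get(lab, 0) + 1

    # clade bitmask + reference counts per node, postorder; every edge of
    # the (rooted) tree then defines a split clade vs complement
    masks: dict[int, int] = {}
    counts: dict[int, dict[str, int]] = {}
    clades: list[tuple[int, int, dict[str, int]]] = []  # (size, mask, refs)
    for nd in work.postorder_node_iter():
        if nd.is_leaf():
            name = nd.taxon.label
            m = 1 << leaf_idx[name]
            lab = reference_labels.get(name)
            c = {lab: 1} if lab is not None else {}
        else:
            m = 0
            c = {}
            for ch in nd.child_nodes():
                m |= masks[id(ch)]
                for lab, k in counts[id(ch)].items():
                    c[lab] = c.get(lab, 0) + k
        masks[id(nd)] = m
        counts[id(nd)] = c
        size = m.bit_count()
        if 0 < size < n_leaves:
            clades.append((size, m, c))

    out: list[SubfamilyAssignment] = []
    for name in leaves:
        if name in reference_labels:
            out.append(SubfamilyAssignment(name, reference_labels[name], 1.0))
            continue
        bit = 1 << leaf_idx[name]
        # smallest split side containing this leaf and >= 1 reference
        best: tuple[int, dict[str, int]] | None = None
        for size, m, c in clades:
            if m & bit:
                side_size, refs = size, c
            else:
                side_size = n_leaves - size
                refs = {lab: total_refs[lab] - c.get(lab, 0)
                        for lab in total_refs if total_refs[lab] - c.get(lab, 0) > 0}
            if refs and (best is None or side_size < best[0]):
                best = (side_size, refs)
        if best is None:
            out.append(SubfamilyAssignment(name, "unclassified", 0.0))
            continue
        cnt = best[1]
        total = sum(cnt.values())
        best_lab = max(sorted(cnt), key=lambda k: cnt[k])
        frac = cnt[best_lab] / total
        if frac >= majority:
            out.append(SubfamilyAssignment(name, best_lab, frac))
        else:
            out.append(SubfamilyAssignment(name, "unclassified", frac))
    out.sort(key=lambda a: a.leaf_id)
    return out


# ---------------------------------------------------------------------------
# Presence / absence

def presence_absence(assignments: list[SubfamilyAssignment],
                     proteome_map: dict[str, str]) -> pd.DataFrame:
    """Proteome-by-subfamily 0/1 matrix (the genomic distribution summary).

    Tandem leaves ``id#N``/``id#C`` credit their source record's proteome.
    Every proteome in ``proteome_map`` appears as a row even if all-absent;
    unclassified leaves contribute nothing.
    """
    subfams = sorted({a.subfamily for a in assignments if a.subfamily != "unclassified"})
    proteomes = sorted(set(proteome_map.values()))
    mat = pd.DataFrame(0, index=proteomes, columns=subfams, dtype=int)
    for a in assignments:
        if a.subfamily == "unclassified":
            continue
        base = a.leaf_id.split("#")[0]
        key = a.leaf_id if a.leaf_id in proteome_map else base
        if key not in proteome_map:
            raise ValueError(f"leaf {a.leaf_id!r} has no known proteome")
        mat.loc[proteome_map[key], a.subfamily] = 1
    mat.index.name = "proteome_id"
    return mat


# ---------------------------------------------------------------------------
# End-to-end classification of a finished search

@dataclass
class ClassificationResult:
    tree: dendropy.Tree
    assignments: list[SubfamilyAssignment]
    matrix: pd.DataFrame
    leaf_alignment: Alignment
    architectures: list      # DomainArchitecture per homolog


def classify_homologs(master_alignment: Alignment, match_columns: list[int],
                      db: dict[str, "object"], reference_labels: dict[str, str],
                      proteome_map: dict[str, str], seed: int = 0,
                      pseudocount_weight: float = 1.0,
                      max_gap_fraction: float = 0.5) -> ClassificationResult:
    """Trim, split tandems, build the tree and assign subfamilies.

    Every homolog row of the master alignment becomes a leaf; records whose
    score-mask-rescore architecture shows two family domains are replaced
    by two leaves ``id#N`` and ``id#C``, each half re-attached to the
    master profile independently.  Reference labels seed the clade-based
    assignment; the presence/absence matrix is computed over
    ``proteome_map`` (ids without a proteome entry, e.g. external seed
    rows, are excluded from the matrix but still classified).
    """
    from .formats import ProteinRecord
    from .iterpipe import attach_to_master
    from .motifarch import split_tandem
    from .profilehmm import build_profile, calibrate

    profile = build_profile(master_alignment, pseudocount_weight=pseudocount_weight,
                            profile_id="classify_master",
                            match_columns=match_columns)
    calibrate(profile, seed=seed)

    rows: dict[str, str] = {}
    architectures = []
    for rid in master_alignment.rows:
        rec = db.get(rid)
        if rec is None:
            rec = ProteinRecord(id=rid,
                                residues=master_alignment.rows[rid].replace("-", ""))
        arch = split_tandem(rec, profile, db_size=max(len(db), 1))
        architectures.append(arch)
        if arch.n_tim17_domains == 2:
            for tag, (s, e) in zip(("N", "C"), arch.domain_envelopes):
                half = ProteinRecord(id=f"{rid}#{tag}", residues=rec.residues[s:e])
                base = Alignment({k: v for k, v in master_alignment.rows.items()
                                  if k != rid})
                attached = attach_to_master(base, half, profile)
                rows[half.id] = attached.rows[half.id]
        else:
            rows[rid] = master_alignment.rows[rid]

    leaf_aln = Alignment(rows)
    trimmed, _kept = trim_alignment(leaf_aln, max_gap_fraction=max_gap_fraction)
    dm = distance_matrix(trimmed)
    tree = build_nj(dm)
    assignments = assign_subfamilies(tree, reference_labels)
    pa_map = dict(proteome_map)
    pa_assignments = [a for a in assignments
                      if a.leaf_id.split("#")[0] in pa_map or a.leaf_id in pa_map]
    matrix = presence_absence(pa_assignments, pa_map)
    return ClassificationResult(tree=tree, assignments=assignments, matrix=matrix,
                                leaf_alignment=leaf_aln,
                                architectures=architectures)


def write_assignments_tsv(assignments: list[SubfamilyAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("leaf_id\tsubfamily\tsupport\n")
        for a in assignments:
            fh.write(f"{a.leaf_id}\t{a.subfamily}\t{a.support:.3f}\n")
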