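"""Synthetic membrane-protein superfamilies with known truth.

The generator emulates the statistical situation of a profile-based search
for a polytopic inner-membrane family: an ancestral protein of alternating
hydrophilic loops and hydrophobic transmembrane (TM) helices, glycine-zipper
motifs (GxxxGxxxG) inside the helices, and a conserved positive/negative
residue pair in the loop between helices 2 and 3.  Descendants diverge along
a random bifurcating tree under a Poisson substitution model (uniform
replacement among the 19 alternatives); zipper glycines and the charged pair
evolve at 1/10 the background rate.  Single-residue indels occur in loops at
0.1x the substitution rate; TM helices never gain or lose residues.

Around the family the benchmark places three confounds:

* decoys — i.i.d. random proteins whose ONLY shared feature with the family
  is 2-4 exact glycine zippers,
* background — i.i.d. random proteins with no implanted structure,
* tandems — two family domains concatenated with a random hydrophilic
  linker, emulating two-domain (Tmem135-like) proteins.

Everything is driven by one integer seed through a single numpy generator,
so identical specs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import AMINO_ACIDS, Alignment, ProteinRecord, write_alignment, write_fasta

HYDROPHOBIC = "LIVFAMG"
HYDROPHOBIC_WEIGHTS = np.array([0.25, 0.15, 0.15, 0.10, 0.15, 0.05, 0.15])
HYDROPHILIC = "".join(sorted(set(AMINO_ACIDS) - set(HYDROPHOBIC)))  # 13 residues

#: Relative substitution rate at conserved motif positions (zipper G's and
#: the charged loop pair).
CONSERVED_RATE = 0.1
#: Indel rate in loops, relative to the substitution rate.
LOOP_INDEL_RATE = 0.1


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of one simulated superfamily.

    Divergences are expected substitutions/site along the path between two
    members: ``intra_sub_divergence`` within a subfamily (each member sits at
    half that depth below the subfamily ancestor), ``inter_sub_divergence``
    between subfamily ancestors.
    """

    n_subfamilies: int = 3
    members_per_subfamily: int = 20
    n_tm_helices: int = 4
    tm_len: int = 20
    loop_len: int = 20
    zippers_per_helix: int = 1
    inter_sub_divergence: float = 1.0
    intra_sub_divergence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subfamilies", "members_per_subfamily", "n_tm_helices",
                     "tm_len", "loop_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.zippers_per_helix < 0:
            raise ValueError("zippers_per_helix must be >= 0")
        if self.inter_sub_divergence < 0 or self.intra_sub_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if self.zippers_per_helix >= 1 and self.tm_len < 9:
            raise ValueError("a GxxxGxxxG zipper cannot fit in tm_len < 9")
        if self.zippers_per_helix * 9 > self.tm_len:
            raise ValueError("zippers_per_helix * 9 exceeds tm_len")


@dataclass
class SyntheticTruth:
    """Ground-truth labels: the acceptance surface of the whole pipeline."""

    #: record id -> one of {"subfamily_<k>", "decoy", "background", "tandem"}
    labels: dict[str, str] = field(default_factory=dict)
    #: record id -> proteome id (filled by the benchmark writer)
    proteomes: dict[str, str] = field(default_factory=dict)
    tree_newick: str = ""
    alignment: Alignment | None = None
    #: alignment column indices of the ancestral zipper glycines
    zipper_columns: list[int] = field(default_factory=list)
    #: record id -> list of (start, end) true TM helix spans, 0-based half-open
    tm_segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    #: tandem id -> (first member id, second member id)
    tandem_parts: dict[str, tuple[str, str]] = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> None:
        overlap = set(self.labels) & set(other.labels)
        if overlap:
            raise ValueError(f"duplicate truth ids: {sorted(overlap)[:5]}")
        self.labels.update(other.labels)
        self.proteomes.update(other.proteomes)
        self.tm_segments.update(other.tm_segments)
        self.tandem_parts.update(other.tandem_parts)


# ---------------------------------------------------------------------------
# Ancestral architecture

@dataclass
class _Site:
    key: tuple[int, int]      # (ancestral anchor, insertion counter); sortable
    residue: str
    role: str                 # "loop" | "tm"
    rate: float               # relative substitution rate


def _sample(rng: np.random.Generator, alphabet: str, p=None) -> str:
    return alphabet[int(rng.choice(len(alphabet), p=p))]


def _build_ancestor(spec: SyntheticFamilySpec, rng: np.random.Generator
                    ) -> tuple[list[_Site], list[int]]:
    """The ancestral sequence plus the anchors of its zipper glycines."""
    sites: list[_Site] = []
    zipper_anchors: list[int] = []
    pos = 0
    non_g_hydrophobic = HYDROPHOBIC.replace("G", "")
    ng_w = HYDROPHOBIC_WEIGHTS[[i for i, a in enumerate(HYDROPHOBIC) if a != "G"]]
    ng_w = ng_w / ng_w.sum()

    def add_loop(charged: bool) -> None:
        nonlocal pos
        charged_at = {}
        if charged:
            # one positive, one negative fixed site; keep them interior
            lo, hi = 2, max(3, spec.loop_len - 2)
            i_pos = int(rng.integers(lo, hi))
            i_neg = int(rng.integers(lo, hi))
            while i_neg == i_pos:
                i_neg = int(rng.integers(lo, hi))
            charged_at = {i_pos: "R", i_neg: "D"}
        for i in range(spec.loop_len):
            if i in charged_at:
                sites.append(_Site((pos, 0), charged_at[i], "loop", CONSERVED_RATE))
            else:
                sites.append(_Site((pos, 0), _sample(rng, HYDROPHILIC), "loop", 1.0))
            pos += 1

    def add_helix() -> None:
        nonlocal pos
        helix = [_sample(rng, HYDROPHOBIC, HYDROPHOBIC_WEIGHTS)
                 for _ in range(spec.tm_len)]
        rates = [1.0] * spec.tm_len
        if spec.zippers_per_helix:
            # non-overlapping zippers, evenly spread over the helix
            span = spec.tm_len // spec.zippers_per_helix
            for z in range(spec.zippers_per_helix):
                off = z * span + (span - 9) // 2
                for g in (off, off + 4, off + 8):
                    helix[g] = "G"
                    rates[g] = CONSERVED_RATE
                for x in range(off, off + 9):
                    if rates[x] == 1.0 and helix[x] == "G":
                        helix[x] = _sample(rng, non_g_hydrophobic, ng_w)
        for i, (res, rate) in enumerate(zip(helix, rates)):
            sites.append(_Site((pos, 0), res, "tm", rate))
            if rate == CONSERVED_RATE:
                zipper_anchors.append(pos)
            pos += 1

    # loop - (helix - loop) * n ; the loop after helix 2 carries the charges
    add_loop(charged=False)
    for h in range(spec.n_tm_helices):
        add_helix()
        add_loop(charged=(h == 1 and spec.n_tm_helices >= 3))
    return sites, zipper_anchors


# ---------------------------------------------------------------------------
# Evolution along a tree

class _InsertCounter:
    def __init__(self) -> None:
        self.n = 0

    def next(self) -> int:
        self.n += 1
        return self.n


def _evolve_branch(sites: list[_Site], t: float, rng: np.random.Generator,
                   counter: _InsertCounter) -> list[_Site]:
    """One branch of length ``t`` expected substitutions/site."""
    out: list[_Site] = []
    for s in sites:
        res = s.residue
        n_sub = int(rng.poisson(t * s.rate))
        for _ in range(n_sub):
            alt = AMINO_ACIDS.replace(res, "")
            res = alt[int(rng.integers(len(alt)))]
        new = _Site(s.key, res, s.role, s.rate)
        deleted = False
        inserted: list[_Site] = []
        if s.role == "loop" and s.rate == 1.0:
            for _ in range(int(rng.poisson(t * LOOP_INDEL_RATE))):
                if rng.random() < 0.5:
                    deleted = True
                else:
                    inserted.append(_Site((s.key[0], counter.next()),
                                          _sample(rng, HYDROPHILIC), "loop", 1.0))
        if not deleted:
            out.append(new)
        out.extend(inserted)
    return out


@dataclass
class _Node:
    name: str | None
    length: float
    children: list["_Node"] = field(default_factory=list)

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def _random_ultrametric(names: list[str], height: float, length_to_parent: float,
                        rng: np.random.Generator) -> _Node:
    """Random bifurcating ultrametric tree: all leaves at depth ``height``."""
    if len(names) == 1:
        return _Node(names[0], length_to_parent + height)
    k = int(rng.integers(1, len(names)))
    idx = rng.permutation(len(names))
    left = [names[i] for i in sorted(idx[:k])]
    right = [names[i] for i in sorted(idx[k:])]
    child_height = height * float(rng.uniform(0.3, 0.9))
    node = _Node(None, length_to_parent)
    node.children = [
        _random_ultrametric(left, child_height, height - child_height, rng),
        _random_ultrametric(right, child_height, height - child_height, rng),
    ]
    return node


def _walk(node: _Node, sites: list[_Site], rng: np.random.Generator,
          counter: _InsertCounter, leaves: dict[str, list[_Site]]) -> None:
    evolved = _evolve_branch(sites, node.length, rng, counter)
    if not node.children:
        leaves[node.name] = evolved
        return
    for child in node.children:
        _walk(child, evolved, rng, counter, leaves)


# ---------------------------------------------------------------------------
# Public generators

def generate_superfamily(spec: SyntheticFamilySpec
                         ) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Simulate one superfamily and its ground truth.

    Returns ungapped records (ids ``sf<k>_m<j>``) plus a
    :class:`SyntheticTruth` holding the true tree, the true alignment in a
    common column space (indels create gap columns), the alignment columns
    of the ancestral zipper glycines, and per-record true TM spans.
    """
    rng = np.random.default_rng(spec.seed)
    sites, zipper_anchors = _build_ancestor(spec, rng)

    # backbone: subfamily ancestors all at inter/2 from a central point;
    # for 3 subfamilies this is the unrooted binary star
    root = _Node(None, 0.0)
    for k in range(spec.n_subfamilies):
        names = [f"sf{k + 1}_m{j + 1:02d}" for j in range(spec.members_per_subfamily)]
        if len(names) == 1:
            sub = _Node(names[0], spec.inter_sub_divergence / 2
                        + spec.intra_sub_divergence / 2)
        else:
            sub = _random_ultrametric(names, spec.intra_sub_divergence / 2,
                                      spec.inter_sub_divergence / 2, rng)
        root.children.append(sub)

    counter = _InsertCounter()
    leaves: dict[str, list[_Site]] = {}
    _walk(root, sites, rng, counter, leaves)

    # common column space: sorted union of site keys over all leaves
    all_keys = sorted({s.key for ss in leaves.values() for s in ss})
    col_of = {key: i for i, key in enumerate(all_keys)}

    truth = SyntheticTruth(tree_newick=root.newick()[:-len(":0.000000")] + ";")
    rows: dict[str, str] = {}
    records: list[ProteinRecord] = []
    for k in range(spec.n_subfamilies):
        for j in range(spec.members_per_subfamily):
            name = f"sf{k + 1}_m{j + 1:02d}"
            ss = leaves[name]
            row = ["-"] * len(all_keys)
            for s in ss:
                row[col_of[s.key]] = s.residue
            rows[name] = "".join(row)
            seq = "".join(s.residue for s in ss)
            records.append(ProteinRecord(id=name, residues=seq,
                                         group_label=f"subfamily_{k + 1}"))
            truth.labels[name] = f"subfamily_{k + 1}"
            # true TM spans in the leaf's own ungapped coordinates
            spans: list[tuple[int, int]] = []
            start = None
            for i, s in enumerate(ss):
                if s.role == "tm" and start is None:
                    start = i
                elif s.role != "tm" and start is not None:
                    spans.append((start, i))
                    start = None
            if start is not None:
                spans.append((start, len(ss)))
            truth.tm_segments[name] = spans
    truth.alignment = Alignment(rows)
    truth.zipper_columns = [col_of[(a, 0)] for a in zipper_anchors]
    return records, truth


def generate_decoys(n: int, seed: int, length: int = 200,
                    id_prefix: str = "decoy") -> list[ProteinRecord]:
    """Random proteins sharing ONLY the glycine-zipper motif with the family.

    Each decoy is i.i.d. uniform over the 20 residues with 2-4 exact
    GxxxGxxxG motifs implanted at non-overlapping positions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 9:
        raise ValueError("decoy length must fit at least one zipper")
    rng = np.random.default_rng(seed)
    out: list[ProteinRecord] = []
    for i in range(n):
        seq = [AMINO_ACIDS[int(c)] for c in rng.integers(0, 20, size=length)]
        n_zip = int(rng.integers(2, 5))
        placed: list[int] = []
        tries = 0
        while len(placed) < n_zip and tries < 200:
            tries += 1
            p = int(rng.integers(0, length - 8))
            if all(abs(p - q) >= 9 for q in placed):
                placed.append(p)
        for p in placed:
            for g in (p, p + 4, p + 8):
                seq[g] = "G"
        out.append(ProteinRecord(id=f"{id_prefix}_{i + 1:03d}",
                                 residues="".join(seq)))
    return out


def generate_background(n: int, seed: int, length_range: tuple[int, int] = (100, 400),
                        id_prefix: str = "bg") -> list[ProteinRecord]:
    """Plain i.i.d. random proteins with no implanted structure."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(AMINO_ACIDS[int(c)] for c in rng.integers(0, 20, size=length))
        out.append(ProteinRecord(id=f"{id_prefix}_{i + 1:04d}", residues=seq))
    return out


def generate_tandem(records: Sequence[ProteinRecord], seed: int,
                    n: int | None = None, id_prefix: str = "tandem"
                    ) -> tuple[list[ProteinRecord], dict[str, tuple[str, str]]]:
    """Concatenate pairs of distinct family members with a random linker.

    Emulates two-domain proteins: each output is memberA + linker(10-30
    hydrophilic residues) + memberB.  Returns the records and a map
    tandem id -> (first id, second id).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 family records to build tandems")
    rng = np.random.default_rng(seed)
    if n is None:
        n = 1
    out: list[ProteinRecord] = []
    parts: dict[str, tuple[str, str]] = {}
    for i in range(n):
        ia, ib = rng.choice(len(records), size=2, replace=False)
        a, b = records[int(ia)], records[int(ib)]
        linker = "".join(_sample(rng, HYDROPHILIC)
                         for _ in range(int(rng.integers(10, 31))))
        tid = f"{id_prefix}_{i + 1:02d}"
        out.append(ProteinRecord(id=tid, residues=a.residues + linker + b.residues,
                                 description=f"{a.id}+{b.id}"))
        parts[tid] = (a.id, b.id)
    return out, parts


# ---------------------------------------------------------------------------
# Benchmark writer

@dataclass(frozen=True)
class BenchmarkConfig:
    """Composition of the default desk-scale benchmark."""

    n_proteomes: int = 3
    family: SyntheticFamilySpec = field(default_factory=SyntheticFamilySpec)
    members_per_subfamily_per_proteome: int = 20
    decoys_per_proteome: int = 20
    background_per_proteome: int = 200
    tandems_per_proteome: int = 2
    decoy_length: int = 200
    background_length_range: tuple[int, int] = (100, 400)
    seed: int = 1


def generate_benchmark(config: BenchmarkConfig, out_dir: str | Path | None = None,
                       force: bool = False
                       ) -> tuple[dict[str, list[ProteinRecord]], SyntheticTruth]:
    """Build the proteome databases and the truth table.

    Family members are distributed round-robin over proteomes so every
    proteome carries every subfamily.  If ``out_dir`` is given, one FASTA
    per proteome plus ``truth.tsv``, the true alignment and the true tree
    are written there (refusing to overwrite a non-empty directory unless
    ``force``).
    """
    n_members = config.members_per_subfamily_per_proteome * config.n_proteomes
    spec = replace(config.family, members_per_subfamily=n_members,
                   seed=config.seed)
    fam_records, truth = generate_superfamily(spec)

    proteomes: dict[str, list[ProteinRecord]] = {
        f"proteome_{p + 1}": [] for p in range(config.n_proteomes)
    }
    by_id = {r.id: r for r in fam_records}
    # round-robin family members: member j of every subfamily -> proteome j mod P
    for k in range(spec.n_subfamilies):
        for j in range(n_members):
            pid = f"proteome_{j % config.n_proteomes + 1}"
            rid = f"sf{k + 1}_m{j + 1:02d}"
            rec = by_id[rid]
            proteomes[pid].append(replace(rec, proteome_id=pid))
            truth.proteomes[rid] = pid

    for p in range(config.n_proteomes):
        pid = f"proteome_{p + 1}"
        members = [r for r in proteomes[pid] if truth.labels[r.id].startswith("subfamily")]
        if config.tandems_per_proteome and len(members) >= 2:
            tds, parts = generate_tandem(members, seed=config.seed * 1000 + 7 * (p + 1),
                                         n=config.tandems_per_proteome,
                                         id_prefix=f"tandem_p{p + 1}")
            for t in tds:
                proteomes[pid].append(replace(t, proteome_id=pid))
                truth.labels[t.id] = "tandem"
                truth.proteomes[t.id] = pid
            truth.tandem_parts.update(parts)
        if config.decoys_per_proteome:
            dec = generate_decoys(config.decoys_per_proteome,
                                  seed=config.seed * 1000 + 13 * (p + 1),
                                  length=config.decoy_length,
                                  id_prefix=f"decoy_p{p + 1}")
            for d in dec:
                proteomes[pid].append(replace(d, proteome_id=pid))
                truth.labels[d.id] = "decoy"
                truth.proteomes[d.id] = pid
        if config.background_per_proteome:
            bg = generate_background(config.background_per_proteome,
                                     seed=config.seed * 1000 + 29 * (p + 1),
                                     length_range=config.background_length_range,
                                     id_prefix=f"bg_p{p + 1}")
            for b in bg:
                proteomes[pid].append(replace(b, proteome_id=pid))
                truth.labels[b.id] = "background"
                truth.proteomes[b.id] = pid

    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not force:
            raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid in sorted(proteomes):
            write_fasta(proteomes[pid], out_dir / f"{pid}.fasta")
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("record_id\tproteome_id\tlabel\tsubfamily\n")
            for rid in sorted(truth.labels):
                label = truth.labels[rid]
                sub = label if label.startswith("subfamily") else ""
                fh.write(f"{rid}\t{truth.proteomes[rid]}\t{label}\t{sub}\n")
        write_alignment(truth.alignment, out_dir / "true_alignment.afa")
        with open(out_dir / "true_tree.nwk", "w") as fh:
            fh.write(truth.tree_newick + "\n")
        with open(out_dir / "zipper_columns.txt", "w") as fh:
            fh.write(",".join(map(str, truth.zipper_columns)) + "\n")
    return proteomes, truth


def seed_alignment(truth: SyntheticTruth, subfamily: str = "subfamily_1",
                   n_rows: int = 5) -> Alignment:
    """A seed alignment for the iterative search: the first ``n_rows`` members
    of one subfamily, cut from the true alignment with all-gap columns removed."""
    ids = sorted(i for i, lab in truth.labels.items() if lab == subfamily)[:n_rows]
    if len(ids) < 2:
        raise ValueError(f"fewer than 2 members of {subfamily}")
    sub = truth.alignment.subset(ids)
    keep = [c for c in range(sub.n_cols)
            if any(sub.rows[i][c] != "-" for i in ids)]
    return Alignment({i: "".join(sub.rows[i][c] for c in keep) for i in ids})
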