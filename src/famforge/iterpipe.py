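"""The iterative family-expansion loop.

Starting from a seed alignment of trusted family members, each iteration:

1. divides the current homolog set into groups at a 40% identity cutoff,
2. builds and calibrates a search profile per group (group alignments are
   the master rows of the group members, so all profiles share the master's
   fixed column frame),
3. searches the proteome database at e-value <= 1 (a deliberately shallow
   net),
4. validates every new hit against the evolving master profile with its
   glycine-zipper columns masked, accepting at masked probability >= 0.9,
5. attaches accepted hits to the master alignment.

The loop runs for at most ``n_iter`` iterations (10 by default) or until a
fixed point (an iteration that adds nothing).  Master columns are pinned to
the seed's match columns for the whole run, so zipper masks and envelopes
stay in one coordinate frame; the master profile itself is rebuilt from the
grown alignment every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clusterseq import greedy_cluster
from .formats import Alignment, ProteinRecord
from .profcomp import (self_calibrate_master, validate_candidate,
                       zipper_mask_for_profile)
from .profilehmm import (PositionProfile, build_profile, calibrate,
                         profile_from_sequence, score_sequence, search_db)


@dataclass
class PipelineParams:
    """All thresholds of the iterative search."""

    identity_threshold: float = 0.40
    e_cutoff: float = 1.0
    prob_threshold: float = 0.9
    n_iter: int = 10
    pseudocount_weight: float = 1.0
    n_shuffles: int = 200
    g_fraction: float = 0.7
    calib_per_class: int = 30
    #: validate against the original seed master instead of the evolving one
    pin_seed_master: bool = False
    seed: int = 0


@dataclass
class IterationLog:
    iteration: int
    n_homologs: int
    n_clusters: int
    n_candidates: int
    n_added: int
    n_rejected: int
    added_ids: list[str] = field(default_factory=list)


@dataclass
class IterationState:
    """The growing homolog set and its master alignment."""

    iteration: int
    homolog_ids: set[str]
    master_alignment: Alignment
    match_columns: list[int]            # pinned, seed-defined
    #: per-row insert-state residues: row id -> {profile column -> residues}
    insertions: dict[str, dict[int, str]] = field(default_factory=dict)
    log: list[IterationLog] = field(default_factory=list)


def init_state(seed_alignment: Alignment) -> IterationState:
    if seed_alignment.n_rows < 2:
        raise ValueError("seed alignment needs >= 2 rows")
    rows = list(seed_alignment.rows.values())
    match_columns = [
        c for c in range(seed_alignment.n_cols)
        if sum(r[c] == "-" for r in rows) / len(rows) < 0.5
    ]
    if not match_columns:
        raise ValueError("seed alignment has no match columns")
    return IterationState(iteration=0, homolog_ids=set(seed_alignment.rows),
                          master_alignment=seed_alignment,
                          match_columns=match_columns)


def build_master_profile(state: IterationState, params: PipelineParams,
                         masked: bool = True) -> PositionProfile:
    """The master profile on the pinned column frame, zipper-masked."""
    prof = build_profile(state.master_alignment,
                         pseudocount_weight=params.pseudocount_weight,
                         profile_id="master",
                         match_columns=state.match_columns)
    if masked:
        prof.masked_columns = zipper_mask_for_profile(
            prof, state.master_alignment, g_fraction=params.g_fraction)
    return prof


def attach_to_master(master: Alignment, new_seq: ProteinRecord,
                     master_profile: PositionProfile,
                     insertions_out: dict[int, str] | None = None) -> Alignment:
    """Align a validated sequence to the master's match columns.

    The new row carries residues only at master columns reached by match
    states of the best local alignment; insert-state residues are recorded
    in ``insertions_out`` (keyed by the preceding profile column) and get no
    new master columns.  Existing rows and the column count are unchanged.
    """
    if new_seq.id in master.rows:
        raise ValueError(f"row {new_seq.id!r} already in master alignment")
    res = score_sequence(master_profile, new_seq, traceback=True)
    if not res.matches:
        raise ValueError(f"sequence {new_seq.id!r} has no positive-scoring "
                         "alignment to the master profile")
    row = ["-"] * master.n_cols
    for prof_col, seq_pos in res.matches:
        row[master_profile.source_columns[prof_col]] = new_seq.residues[seq_pos]
    if insertions_out is not None:
        for prof_col, positions in res.insertions.items():
            insertions_out[prof_col] = "".join(
                new_seq.residues[p].lower() for p in positions)
    new_rows = dict(master.rows)
    new_rows[new_seq.id] = "".join(row)
    return Alignment(new_rows)


def _median_length(db: list[ProteinRecord]) -> int:
    return int(np.median([len(r.residues) for r in db]))


def run_iteration(state: IterationState, db: list[ProteinRecord],
                  params: PipelineParams) -> IterationState:
    """One round of cluster -> search -> validate -> attach."""
    if not state.homolog_ids:
        raise ValueError("empty homolog set")
    by_id = {r.id: r for r in db}
    missing = sorted(state.homolog_ids - set(by_id))
    homolog_records = [by_id[i] for i in sorted(state.homolog_ids) if i in by_id]
    # seed rows may not be db records; reconstruct them from the master
    for rid in missing:
        homolog_records.append(
            ProteinRecord(id=rid,
                          residues=state.master_alignment.rows[rid].replace("-", "")))
    it = state.iteration + 1

    clusters = greedy_cluster(homolog_records, params.identity_threshold)

    master = build_master_profile(state, params)
    self_calibrate_master(master, state.master_alignment,
                          seed=_derive_seed(params.seed, it, 0),
                          n_per_class=params.calib_per_class)
    validation_master = master
    if params.pin_seed_master and state.log:
        # rebuild from the seed rows only (first state's rows)
        seed_ids = sorted(state.homolog_ids -
                          {i for lg in state.log for i in lg.added_ids})
        seed_state = replace(state,
                             master_alignment=state.master_alignment.subset(seed_ids))
        validation_master = build_master_profile(seed_state, params)
        self_calibrate_master(validation_master, seed_state.master_alignment,
                              seed=_derive_seed(params.seed, it, 1),
                              n_per_class=params.calib_per_class)

    target_len = _median_length(db)
    rec_by_id = {r.id: r for r in homolog_records}
    candidates: set[str] = set()
    for ci, cl in enumerate(clusters):
        if len(cl.member_ids) >= 2:
            order = [cl.representative_id] + [m for m in cl.member_ids
                                              if m != cl.representative_id]
            cluster_aln = state.master_alignment.subset(order)
            prof = build_profile(cluster_aln,
                                 pseudocount_weight=params.pseudocount_weight,
                                 profile_id=f"iter{it}_cluster{ci}",
                                 match_columns=state.match_columns)
        else:
            prof = profile_from_sequence(rec_by_id[cl.representative_id],
                                         background=master.background)
            prof.profile_id = f"iter{it}_cluster{ci}"
        calibrate(prof, n_shuffles=params.n_shuffles, target_len=target_len,
                  seed=_derive_seed(params.seed, it, 100 + ci))
        for hit in search_db(prof, db, e_cutoff=params.e_cutoff):
            if hit.target_id not in state.homolog_ids:
                candidates.add(hit.target_id)

    added: list[str] = []
    rejected = 0
    new_master_aln = state.master_alignment
    new_insertions = dict(state.insertions)
    attach_profile = build_master_profile(state, params, masked=False)
    for cid in sorted(candidates):
        cand = profile_from_sequence(by_id[cid])
        ok, _score = validate_candidate(cand, validation_master,
                                        threshold=params.prob_threshold)
        if not ok:
            rejected += 1
            continue
        ins: dict[int, str] = {}
        new_master_aln = attach_to_master(new_master_aln, by_id[cid],
                                          attach_profile, insertions_out=ins)
        if ins:
            new_insertions[cid] = ins
        added.append(cid)

    log = IterationLog(iteration=it, n_homologs=len(state.homolog_ids) + len(added),
                       n_clusters=len(clusters), n_candidates=len(candidates),
                       n_added=len(added), n_rejected=rejected, added_ids=added)
    return IterationState(iteration=it,
                          homolog_ids=state.homolog_ids | set(added),
                          master_alignment=new_master_aln,
                          match_columns=state.match_columns,
                          insertions=new_insertions,
                          log=state.log + [log])


def run_pipeline(seed_alignment: Alignment, db: list[ProteinRecord],
                 params: PipelineParams | None = None) -> IterationState:
    """Iterate to a fixed point or for ``params.n_iter`` rounds."""
    params = params or PipelineParams()
    state = init_state(seed_alignment)
    for _ in range(params.n_iter):
        state = run_iteration(state, db, params)
        if state.log[-1].n_added == 0:
            break
    return state


def _derive_seed(base: int, iteration: int, stream: int) -> int:
    ss = np.random.SeedSequence([base, iteration, stream])
    return int(ss.generate_state(1)[0] % (2**31))


def write_log_tsv(state: IterationState, path) -> None:
    with open(path, "w") as fh:
        fh.write("iteration\tn_homologs\tn_clusters\tn_candidates\tn_added\t"
                 "n_rejected\tadded_ids\n")
        for lg in state.log:
            fh.write(f"{lg.iteration}\t{lg.n_homologs}\t{lg.n_clusters}\t"
                     f"{lg.n_candidates}\t{lg.n_added}\t{lg.n_rejected}\t"
                     f"{','.join(lg.added_ids)}\n")
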