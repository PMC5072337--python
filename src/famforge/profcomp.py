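"""Profile-profile comparison with masking: the validation step.

Candidate profiles are aligned column-against-column to the master family
profile by local dynamic programming; the column-pair score is the
co-emission log-odds against the master's background,

    s(i, j) = log2( sum_a q_i(a) * m_j(a) / bg(a) ),

so two columns score high when they concentrate probability on the same
residues beyond what the background explains.  Masked master columns (the
glycine-zipper positions) contribute nothing to any pairing, which is the
control used to separate genuine family membership from zipper-only
look-alikes: a candidate whose entire similarity sits in the zipper loses
it under masking, while a true homolog keeps most of its score.

Raw scores are mapped to P(homolog) through a two-parameter logistic
calibrated by maximum likelihood on labeled true/decoy profiles; the 90%
acceptance threshold is applied on the masked probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .formats import Alignment
from .profilehmm import DPResult, PositionProfile, local_dp


@dataclass
class ProfilePairScore:
    """Evidence from comparing a candidate profile to the master."""

    query_profile_id: str
    master_profile_id: str
    raw_score: float            # unmasked bits
    probability: float          # P(homolog) from the unmasked score
    masked_probability: float   # P(homolog) with zipper columns masked
    motif_contribution: float   # raw_score - masked raw score, in bits


def coemission_matrix(q: PositionProfile, m: PositionProfile) -> np.ndarray:
    """(q_cols, m_cols) co-emission log-odds.

    Masked columns (of either profile) are clipped to min(0, score), so
    masking strictly removes similarity and never creates chance bridges.
    """
    s = np.log2(q.columns @ (m.columns / m.background[None, :]).T)
    if m.masked_columns:
        idx = sorted(m.masked_columns)
        s[:, idx] = np.minimum(s[:, idx], 0.0)
    if q.masked_columns:
        idx = sorted(q.masked_columns)
        s[idx, :] = np.minimum(s[idx, :], 0.0)
    return s


def align_profiles(q: PositionProfile, m: PositionProfile,
                   traceback: bool = False) -> tuple[float, DPResult]:
    """Local column-against-column alignment of two profiles.

    Returns the raw score in bits and the DP result (column pairs are in
    ``result.matches`` when ``traceback``).  Gap costs are shared with the
    sequence-vs-profile search.
    """
    if q.n_cols == 0 or m.n_cols == 0:
        raise ValueError("empty profile")
    # DP rows iterate over the query profile, columns over the master
    res = local_dp(coemission_matrix(q, m), traceback=traceback)
    return res.score, res


@dataclass
class ProbabilityMap:
    """Two-parameter logistic link: P(homolog) = sigmoid(slope*(score - mid))."""

    slope: float
    midpoint: float

    def __call__(self, score: float) -> float:
        return float(expit(self.slope * (score - self.midpoint)))


def fit_logistic(scores: np.ndarray, labels: np.ndarray,
                 ridge: float = 1e-4) -> ProbabilityMap:
    """Maximum-likelihood logistic fit of label on score.

    A tiny ridge penalty on the slope keeps the optimum finite when the two
    classes are perfectly separated (the usual case for well-behaved
    masters); it moves recovered parameters by far less than their
    sampling error.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate calibration input: all scores equal")
    scale = max(scores.std(), 1e-9)

    def nll(params):
        slope, mid = params
        z = slope * (scores - mid)
        # log(1+exp(-z)) stable
        loss = np.logaddexp(0.0, -z) * labels + np.logaddexp(0.0, z) * (1 - labels)
        return loss.sum() + ridge * (slope * scale) ** 2

    x0 = np.array([1.0 / scale, float(scores.mean())])
    best = None
    for x_init in (x0, x0 * [5.0, 1.0], x0 * [0.2, 1.0]):
        r = minimize(nll, x_init, method="Nelder-Mead",
                     options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or r.fun < best.fun:
            best = r
    slope, mid = best.x
    if slope < 0:
        raise ValueError("calibration input not separable in the right direction")
    return ProbabilityMap(slope=float(slope), midpoint=float(mid))


def calibrate_probability(master: PositionProfile,
                          decoy_profiles: list[PositionProfile],
                          true_profiles: list[PositionProfile],
                          ridge: float = 1e-4) -> ProbabilityMap:
    """Calibrate the raw-score -> P(homolog) map for a master profile.

    Scores every labeled profile against the MASKED master and fits the
    logistic by maximum likelihood.  Requires >= 20 profiles per class.
    The map is stored on the master as ``master.probability_map``.
    """
    if len(decoy_profiles) < 20 or len(true_profiles) < 20:
        raise ValueError("need >= 20 decoy and >= 20 true profiles")
    scores, labels = [], []
    for p in decoy_profiles:
        scores.append(align_profiles(p, master)[0])
        labels.append(0.0)
    for p in true_profiles:
        scores.append(align_profiles(p, master)[0])
        labels.append(1.0)
    pmap = fit_logistic(np.array(scores), np.array(labels), ridge=ridge)
    master.probability_map = pmap  # type: ignore[attr-defined]
    return pmap


DIVERGENCE_LADDER = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5)


def self_calibrate_master(master: PositionProfile, master_aln: Alignment,
                          seed: int, n_per_class: int = 30,
                          divergences: tuple[float, ...] = DIVERGENCE_LADDER,
                          ridge: float = 1e-4) -> ProbabilityMap:
    """Calibrate a master's probability map without external truth labels.

    Positive examples are single-sequence profiles of master rows mutated
    along a divergence ladder (uniform replacement among the 19
    alternatives, Poisson counts per site), which emulates remote homologs
    of the family at known distances.  Negative examples are i.i.d. random
    sequences with implanted glycine zippers, the zipper-only confound.
    Both are scored against the masked master and a logistic link is
    fitted; the map is stored on the master.
    """
    from . import synthdata  # deferred: synthdata does not import profcomp
    from .formats import AMINO_ACIDS, ProteinRecord
    from .profilehmm import profile_from_sequence

    rng = np.random.default_rng(seed)
    row_seqs = [r.replace("-", "") for r in master_aln.rows.values()]
    trues = []
    i = 0
    while len(trues) < n_per_class:
        base = row_seqs[i % len(row_seqs)]
        d = divergences[i % len(divergences)]
        seq = []
        for ch in base:
            n_sub = int(rng.poisson(d))
            for _ in range(n_sub):
                alt = AMINO_ACIDS.replace(ch, "") if ch in AMINO_ACIDS else AMINO_ACIDS
                ch = alt[int(rng.integers(len(alt)))]
            seq.append(ch)
        rec = ProteinRecord(id=f"calib_true_{i}", residues="".join(seq))
        trues.append(profile_from_sequence(rec))
        i += 1
    median_len = int(np.median([len(s) for s in row_seqs]))
    decoys = [
        profile_from_sequence(d)
        for d in synthdata.generate_decoys(n_per_class,
                                           seed=int(rng.integers(2**31)),
                                           length=max(median_len, 30),
                                           id_prefix="calib_decoy")
    ]
    return calibrate_probability(master, decoys, trues, ridge=ridge)


# ---------------------------------------------------------------------------
# Zipper-column detection

def detect_zipper_columns(aln: Alignment, g_fraction: float = 0.7,
                          expand: bool = False) -> set[int]:
    """Alignment columns forming glycine-zipper (GxxxGxxxG) anchor triplets.

    A match column (gap fraction < 50%) is glycine-rich if >= ``g_fraction``
    of its non-gap residues are G.  Spacing is measured in ungapped
    consensus coordinates, i.e. positions along the match-column sequence:
    an anchor triplet is (c, c+4±1, c+8±2) of glycine-rich match columns,
    absorbing alignment jitter from loop indels.  Returns the alignment
    column indices of all anchor glycines, or with ``expand`` the anchors
    plus the intervening match columns (the span that gets masked).
    """
    if aln.n_rows == 0:
        return set()
    rows = list(aln.rows.values())
    n = len(rows)
    match_cols = [c for c in range(aln.n_cols)
                  if sum(r[c] == "-" for r in rows) / n < 0.5]
    rich = []
    for c in match_cols:
        residues = [r[c] for r in rows if r[c] != "-"]
        rich.append(sum(ch == "G" for ch in residues) / len(residues) >= g_fraction)
    found: set[int] = set()
    spans: list[tuple[int, int]] = []  # in match-column coordinates
    for p in range(len(match_cols)):
        if not rich[p]:
            continue
        for d1 in (4, 3, 5):
            p2 = p + d1
            if p2 >= len(match_cols) or not rich[p2]:
                continue
            for d2 in (8, 7, 9, 6, 10):
                p3 = p + d2
                if p3 <= p2 or p3 >= len(match_cols) or not rich[p3]:
                    continue
                found.update((match_cols[p], match_cols[p2], match_cols[p3]))
                spans.append((p, p3))
    if expand:
        expanded: set[int] = set()
        for a, b in spans:
            expanded.update(match_cols[a:b + 1])
        return expanded
    return found


def zipper_mask_for_profile(profile: PositionProfile, aln: Alignment,
                            g_fraction: float = 0.7) -> set[int]:
    """Masked-column set for a profile, in profile-column indices.

    Detects zipper spans on the profile's source alignment (anchors plus
    intervening columns) and converts source-column indices to profile
    columns.
    """
    src = detect_zipper_columns(aln, g_fraction=g_fraction, expand=True)
    src_to_prof = {c: i for i, c in enumerate(profile.source_columns)}
    return {src_to_prof[c] for c in src if c in src_to_prof}


# ---------------------------------------------------------------------------
# Validation

def validate_candidate(candidate: PositionProfile, master: PositionProfile,
                       threshold: float = 0.9) -> tuple[bool, ProfilePairScore]:
    """Accept a candidate iff its probability against the MASKED master
    passes the threshold.

    The master must carry ``masked_columns`` and a calibrated probability
    map.  The returned record also holds the unmasked probability and the
    motif contribution (unmasked minus masked raw score) for reporting.
    """
    pmap = getattr(master, "probability_map", None)
    if pmap is None:
        raise ValueError(f"master {master.profile_id!r} has no probability map; "
                         "run calibrate_probability first")
    masked_raw, _ = align_profiles(candidate, master)
    unmasked = master.masked_copy(set())
    raw, _ = align_profiles(candidate, unmasked)
    score = ProfilePairScore(
        query_profile_id=candidate.profile_id,
        master_profile_id=master.profile_id,
        raw_score=raw,
        probability=pmap(raw),
        masked_probability=pmap(masked_raw),
        motif_contribution=raw - masked_raw,
    )
    return score.masked_probability >= threshold, score


def write_validation_tsv(results: list[tuple[bool, ProfilePairScore]], path) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\traw_score\tprobability\tmasked_probability\t"
                 "motif_contribution\taccepted\n")
        for accepted, s in results:
            fh.write(f"{s.query_profile_id}\t{s.raw_score:.3f}\t{s.probability:.4f}\t"
                     f"{s.masked_probability:.4f}\t{s.motif_contribution:.3f}\t"
                     f"{int(accepted)}\n")
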