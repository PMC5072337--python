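"""Position profiles: building, scoring, calibration, database search.

A profile is a per-column residue frequency model built from a cluster
alignment.  Sequences are scored against it by local dynamic programming
over match/insert/delete states with fixed affine gap costs; per-column
emission scores are log2 odds against the profile background, and masked
columns contribute nothing (used downstream to silence glycine zippers).
Raw bit scores are turned into e-values by fitting a Gumbel (extreme value)
distribution to scores of random background-composition sequences.

The architecture is deliberately a plain local-alignment profile with fixed
gap costs rather than a full profile HMM with learned transitions: what the
iterative search needs is a calibrated ranking, and fixed costs keep every
score checkable against brute-force path enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import gumbel_r

from .formats import AMINO_ACIDS, Alignment, ProteinRecord

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_X_INDEX = 20  # 'X' scores as background (log-odds 0) everywhere

GAP_OPEN_BITS = 4.0
GAP_EXTEND_BITS = 0.25
BACKGROUND_FLOOR = 1e-4


@dataclass
class Calibration:
    """Gumbel null model of bit scores: lam = 1/scale (1/bits), mu in bits."""

    lam: float
    mu: float

    def evalue(self, score: float, db_size: int) -> float:
        return float(db_size) * float(gumbel_r.sf(score, loc=self.mu, scale=1.0 / self.lam))


@dataclass
class PositionProfile:
    """Per-column residue frequency model with background and optional mask."""

    profile_id: str
    columns: np.ndarray                 # (n_cols, 20) frequencies, rows sum to 1
    background: np.ndarray              # (20,) frequencies
    match_mask: np.ndarray              # bool per source-alignment column
    source_columns: list[int]           # source alignment column of each profile column
    masked_columns: set[int] = field(default_factory=set)  # profile column indices
    source_alignment_id: str = ""
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile column frequencies must sum to 1")
        if (self.columns <= 0).any():
            raise ValueError("profile frequencies must be positive (pseudocounts)")
        bad = {c for c in self.masked_columns if not 0 <= c < self.n_cols}
        if bad:
            raise ValueError(f"masked columns outside profile: {sorted(bad)}")

    @property
    def n_cols(self) -> int:
        return self.columns.shape[0]

    def emission_bits(self) -> np.ndarray:
        """(n_cols, 21) log2-odds emission scores; column 20 is 'X' = 0.

        Masked columns are clipped to min(0, score): masking removes signal
        but never adds it, so a masked score can only drop.  A fully masked
        profile scores 0 against everything (local floor).
        """
        e = np.zeros((self.n_cols, 21))
        e[:, :20] = np.log2(self.columns / self.background[None, :])
        if self.masked_columns:
            idx = sorted(self.masked_columns)
            e[idx, :] = np.minimum(e[idx, :], 0.0)
        return e

    def masked_copy(self, masked_columns: set[int]) -> "PositionProfile":
        return PositionProfile(
            profile_id=self.profile_id, columns=self.columns,
            background=self.background, match_mask=self.match_mask,
            source_columns=self.source_columns,
            masked_columns=set(masked_columns),
            source_alignment_id=self.source_alignment_id,
            calibration=self.calibration)

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.columns.argmax(axis=1))


def position_based_weights(aln: Alignment, match_columns: list[int]) -> np.ndarray:
    """Henikoff position-based sequence weights over the match columns.

    In each column every distinct symbol (gap counts as a symbol) shares
    weight equally among the sequences carrying it; weights sum to 1.
    """
    rows = list(aln.rows.values())
    n = len(rows)
    w = np.zeros(n)
    for c in match_columns:
        col = [r[c] for r in rows]
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        n_types = len(counts)
        for i, ch in enumerate(col):
            w[i] += 1.0 / (n_types * counts[ch])
    total = w.sum()
    if total <= 0:
        return np.full(n, 1.0 / n)
    return w / total


def alignment_background(aln: Alignment) -> np.ndarray:
    """Overall residue frequencies of the alignment, floored and renormalized."""
    counts = np.zeros(20)
    for row in aln.rows.values():
        for ch in row:
            i = AA_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
    freq = counts / counts.sum() if counts.sum() else np.full(20, 1 / 20)
    freq = np.maximum(freq, BACKGROUND_FLOOR)
    return freq / freq.sum()


def build_profile(aln: Alignment, pseudocount_weight: float = 1.0,
                  profile_id: str | None = None,
                  match_columns: list[int] | None = None,
                  background: np.ndarray | None = None) -> PositionProfile:
    """Build a position profile from an alignment of >= 2 rows.

    Match columns are those with < 50% gap characters (or a pinned list);
    per-column frequencies are position-weighted counts plus
    background-proportional pseudocounts of total weight
    ``pseudocount_weight``.
    """
    if aln.n_rows < 2:
        raise ValueError("profile building needs an alignment of >= 2 rows")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    n_cols_src = aln.n_cols
    rows = list(aln.rows.values())
    if match_columns is None:
        match_columns = [
            c for c in range(n_cols_src)
            if sum(r[c] == "-" for r in rows) / len(rows) < 0.5
        ]
    if not match_columns:
        raise ValueError("alignment has no match columns (all too gappy)")
    mask = np.zeros(n_cols_src, dtype=bool)
    mask[match_columns] = True

    if background is None:
        background = alignment_background(aln)
    weights = position_based_weights(aln, match_columns)

    cols = np.zeros((len(match_columns), 20))
    for k, c in enumerate(match_columns):
        counts = np.zeros(20)
        for i, r in enumerate(rows):
            idx = AA_INDEX.get(r[c])
            if idx is not None:
                counts[idx] += weights[i]
        total = counts.sum()
        freq = (counts + pseudocount_weight * background) / (total + pseudocount_weight)
        cols[k] = freq / freq.sum()
    return PositionProfile(
        profile_id=profile_id or f"profile_{id(aln):x}",
        columns=cols, background=background, match_mask=mask,
        source_columns=list(match_columns),
        source_alignment_id=profile_id or "")


def profile_from_sequence(seq: ProteinRecord, pseudocount_weight: float = 1.0,
                          background: np.ndarray | None = None) -> PositionProfile:
    """A single-sequence profile (delta distributions plus pseudocounts).

    Used to represent one candidate hit in profile-profile validation.
    """
    if background is None:
        background = np.full(20, 1 / 20.0)
    n = len(seq.residues)
    cols = np.zeros((n, 20))
    for i, ch in enumerate(seq.residues):
        counts = np.zeros(20)
        idx = AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] = 1.0
        freq = (counts + pseudocount_weight * background) / (counts.sum() + pseudocount_weight)
        cols[i] = freq / freq.sum()
    return PositionProfile(
        profile_id=f"seq:{seq.id}", columns=cols, background=background,
        match_mask=np.ones(n, dtype=bool), source_columns=list(range(n)))


# ---------------------------------------------------------------------------
# Local dynamic programming core

@dataclass
class DPResult:
    score: float
    env_start: int          # 0-based, half-open envelope on the target
    env_end: int
    #: (profile_column, target_position) pairs of match states, in order
    matches: list[tuple[int, int]] = field(default_factory=list)
    #: target positions consumed as insertions, keyed by preceding column
    insertions: dict[int, list[int]] = field(default_factory=dict)


def local_dp(emissions: np.ndarray, gap_open: float = GAP_OPEN_BITS,
             gap_extend: float = GAP_EXTEND_BITS,
             traceback: bool = False) -> DPResult:
    """Best local alignment of a column-emission matrix to a target.

    ``emissions[i, j]`` is the score of matching profile column ``i`` to
    target position ``j``.  Alignments start and end in a match state;
    insertions (target residues between columns) and deletions (skipped
    columns) cost ``gap_open`` for the first position and ``gap_extend``
    for each further one, and may not abut each other.  A non-positive best
    score is reported as 0 with an empty alignment.
    """
    n, L = emissions.shape
    NEG = float("-inf")
    M = np.full((n + 1, L + 1), NEG)
    X = np.full((n + 1, L + 1), NEG)   # insertion: consumes target
    Y = np.full((n + 1, L + 1), NEG)   # deletion: consumes column
    j_ext = np.arange(L + 1) * gap_extend
    for i in range(1, n + 1):
        np.maximum(M[i - 1] - gap_open, Y[i - 1] - gap_extend, out=Y[i])
        M[i, 1:] = emissions[i - 1] + np.maximum(
            0.0, np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1]))
        # X within-row: X[i][j] = max(M[i][j-1]-open, X[i][j-1]-ext)
        A = np.maximum.accumulate(M[i] + j_ext)
        X[i, 1:] = A[:-1] - gap_open - j_ext[:-1]
    flat = int(np.argmax(M))
    bi, bj = divmod(flat, L + 1)
    best = float(M[bi, bj])
    if best <= 0.0 or n == 0 or L == 0:
        return DPResult(score=0.0, env_start=0, env_end=min(1, L))
    matches: list[tuple[int, int]] = []
    insertions: dict[int, list[int]] = {}
    i, j, state = bi, bj, "M"
    tol = 1e-9
    while True:
        if state == "M":
            matches.append((i - 1, j - 1))
            prev = emissions[i - 1, j - 1]
            rest = M[i, j] - prev
            if abs(rest) <= tol:
                break  # local start
            if abs(M[i - 1, j - 1] - rest) <= tol:
                i, j, state = i - 1, j - 1, "M"
            elif abs(X[i - 1, j - 1] - rest) <= tol:
                i, j, state = i - 1, j - 1, "X"
            elif abs(Y[i - 1, j - 1] - rest) <= tol:
                i, j, state = i - 1, j - 1, "Y"
            else:  # float slack: pick the closest
                cands = [(abs(M[i-1, j-1] - rest), "M"), (abs(X[i-1, j-1] - rest), "X"),
                         (abs(Y[i-1, j-1] - rest), "Y"), (abs(rest), "break")]
                cands.sort()
                if cands[0][1] == "break":
                    break
                state = cands[0][1]
                i, j = i - 1, j - 1
        elif state == "X":
            insertions.setdefault(i - 1, []).append(j - 1)
            if abs(M[i, j - 1] - gap_open - X[i, j]) <= tol:
                j, state = j - 1, "M"
            else:
                j = j - 1
        else:  # Y
            if abs(M[i - 1, j] - gap_open - Y[i, j]) <= tol:
                i, state = i - 1, "M"
            else:
                i = i - 1
    matches.reverse()
    for v in insertions.values():
        v.reverse()
    env_start = matches[0][1]
    env_end = matches[-1][1] + 1
    return DPResult(score=best, env_start=env_start, env_end=env_end,
                    matches=matches, insertions=insertions)


def _seq_indices(residues: str) -> np.ndarray:
    return np.array([AA_INDEX.get(ch, _X_INDEX) for ch in residues])


def score_sequence(profile: PositionProfile, seq: ProteinRecord,
                   traceback: bool = False) -> DPResult:
    """Best local alignment of a sequence to the profile (bits + envelope)."""
    e = profile.emission_bits()
    emissions = e[:, _seq_indices(seq.residues)]
    return local_dp(emissions, traceback=traceback)


# ---------------------------------------------------------------------------
# Calibration and search

def random_background_sequences(background: np.ndarray, n: int, length: int,
                                rng: np.random.Generator) -> list[str]:
    """i.i.d. sequences drawn from a residue background distribution."""
    draws = rng.choice(20, size=(n, length), p=background)
    return ["".join(AMINO_ACIDS[i] for i in row) for row in draws]


def calibrate(profile: PositionProfile, n_shuffles: int = 200,
              target_len: int = 200, seed: int = 0) -> Calibration:
    """Fit a Gumbel null to scores of random background-composition sequences.

    Stores (lam = 1/scale, mu = location) on the profile and returns it.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a stable fit")
    rng = np.random.default_rng(seed)
    seqs = random_background_sequences(profile.background, n_shuffles, target_len, rng)
    e = profile.emission_bits()
    scores = np.array([
        local_dp(e[:, _seq_indices(s)]).score for s in seqs
    ])
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate null score distribution (all scores equal)")
    mu, beta = gumbel_r.fit(scores)
    cal = Calibration(lam=float(1.0 / beta), mu=float(mu))
    profile.calibration = cal
    return cal


@dataclass(frozen=True)
class SearchHit:
    """Calibrated evidence that a database sequence matches a profile."""

    profile_id: str
    target_id: str
    bit_score: float
    e_value: float
    env_start: int
    env_end: int


def search_db(profile: PositionProfile, db: list[ProteinRecord],
              e_cutoff: float = 1.0) -> list[SearchHit]:
    """Score every database sequence; keep hits with e-value <= cutoff.

    The database size for the e-value is the number of sequences searched
    in this call.  Results are sorted by ascending e-value, then target id.
    """
    if profile.calibration is None:
        raise ValueError(f"profile {profile.profile_id!r} is not calibrated")
    db_size = len(db)
    e = profile.emission_bits()
    hits: list[SearchHit] = []
    for rec in db:
        res = local_dp(e[:, _seq_indices(rec.residues)], traceback=True)
        ev = profile.calibration.evalue(res.score, db_size)
        if ev <= e_cutoff:
            hits.append(SearchHit(profile.profile_id, rec.id, res.score, ev,
                                  res.env_start, res.env_end))
    hits.sort(key=lambda h: (h.e_value, h.target_id))
    return hits


def write_hits_tsv(hits: list[SearchHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("profile_id\ttarget_id\tbit_score\te_value\tenv_start\tenv_end\n")
        for h in hits:
            fh.write(f"{h.profile_id}\t{h.target_id}\t{h.bit_score:.3f}\t"
                     f"{h.e_value:.6g}\t{h.env_start}\t{h.env_end}\n")


# ---------------------------------------------------------------------------
# Plain-text profile serialization

def save_profile(profile: PositionProfile, path: str | Path) -> None:
    """Documented plain-text format: header lines, background, one line/column."""
    with open(path, "w") as fh:
        fh.write(f"# famforge profile v1\nid\t{profile.profile_id}\n")
        fh.write(f"alphabet\t{AMINO_ACIDS}\n")
        if profile.calibration is not None:
            fh.write(f"calibration\t{profile.calibration.lam!r}\t{profile.calibration.mu!r}\n")
        if profile.masked_columns:
            fh.write("masked\t" + ",".join(map(str, sorted(profile.masked_columns))) + "\n")
        fh.write("source_columns\t" + ",".join(map(str, profile.source_columns)) + "\n")
        fh.write("background\t" + "\t".join(repr(float(x)) for x in profile.background) + "\n")
        for i in range(profile.n_cols):
            fh.write(f"col {i}\t" + "\t".join(repr(float(x)) for x in profile.columns[i]) + "\n")


def load_profile(path: str | Path) -> PositionProfile:
    pid, cal, masked, src_cols, bg = "", None, set(), [], None
    cols = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tag, *vals = line.split("\t")
            if tag == "id":
                pid = vals[0]
            elif tag == "calibration":
                cal = Calibration(lam=float(vals[0]), mu=float(vals[1]))
            elif tag == "masked":
                masked = {int(x) for x in vals[0].split(",")}
            elif tag == "source_columns":
                src_cols = [int(x) for x in vals[0].split(",")]
            elif tag == "background":
                bg = np.array([float(x) for x in vals])
            elif tag.startswith("col "):
                cols.append([float(x) for x in vals])
    columns = np.array(cols)
    n_src = (max(src_cols) + 1) if src_cols else columns.shape[0]
    mask = np.zeros(n_src, dtype=bool)
    mask[src_cols] = True
    return PositionProfile(profile_id=pid, columns=columns, background=bg,
                           match_mask=mask, source_columns=src_cols,
                           masked_columns=masked, calibration=cal)
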