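"""Motif scanning, transmembrane prediction, and domain architecture.

Two PROSITE-style patterns are scanned: the 31-position PRAT motif
``[GA]-x-x-[FY]-x(10)-R-x(3)-D-x(6)-[GAS]-G-x(3)-G`` proposed to unite
preprotein and amino-acid transporters, and the 9-residue glycine zipper
``GxxxGxxxG``.  ``x`` matches any residue including the unknown residue X.

Transmembrane segments are predicted from Kyte-Doolittle hydropathy with a
sliding window: a residue is membrane-flagged when it lies inside at least
one full window whose mean hydropathy exceeds the threshold; maximal runs
of flagged residues are merged across short gaps and filtered by a minimum
length.  Tandem two-domain proteins are split by scoring against the family
profile, hard-masking the best envelope and rescoring, mirroring the
separate N-/C-terminal treatment of two-domain family members.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats import ProteinRecord
from .profilehmm import DPResult, PositionProfile, score_sequence

PRAT_PATTERN = r"[GA]..[FY].{10}R.{3}D.{6}[GAS]G.{3}G"
PRAT_LEN = 31
ZIPPER_PATTERN = r"G...G...G"
ZIPPER_LEN = 9

_PRAT_RE = re.compile(r"(?=(" + PRAT_PATTERN + r"))")
_ZIPPER_RE = re.compile(r"(?=(" + ZIPPER_PATTERN + r"))")

#: Kyte-Doolittle hydropathy values; X (unknown) scores 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


@dataclass(frozen=True)
class MotifMatch:
    motif_name: str            # "PRAT" | "GLY_ZIPPER"
    start: int                 # 0-based
    end: int                   # exclusive
    matched_span: str


def _scan(seq: ProteinRecord | str, regex: re.Pattern, name: str) -> list[MotifMatch]:
    s = seq.residues if isinstance(seq, ProteinRecord) else seq
    out = []
    for m in regex.finditer(s):
        span = m.group(1)
        out.append(MotifMatch(name, m.start(), m.start() + len(span), span))
    return out


def scan_prat(seq: ProteinRecord | str) -> list[MotifMatch]:
    """All (possibly overlapping) windows matching the 31-position PRAT motif."""
    return _scan(seq, _PRAT_RE, "PRAT")


def scan_zipper(seq: ProteinRecord | str) -> list[MotifMatch]:
    """All (possibly overlapping) glycine-zipper (GxxxGxxxG) windows."""
    return _scan(seq, _ZIPPER_RE, "GLY_ZIPPER")


@dataclass(frozen=True)
class TMSegment:
    start: int
    end: int                   # exclusive
    mean_hydropathy: float     # Kyte-Doolittle units over the segment

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty TM segment")


def predict_tm(seq: ProteinRecord | str, window: int = 19, threshold: float = 1.6,
               min_tm_len: int = 15, merge_gap: int = 3) -> list[TMSegment]:
    """Hydropathy-based transmembrane segment prediction.

    Window means are computed at every full-window position; all residues
    of an above-threshold window are flagged, maximal flagged runs
    separated by <= ``merge_gap`` residues are merged, and runs shorter
    than ``min_tm_len`` are dropped.  A sequence shorter than the window
    yields an empty prediction with a warning.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    s = seq.residues if isinstance(seq, ProteinRecord) else seq
    n = len(s)
    if n < window:
        warnings.warn(f"sequence shorter than hydropathy window ({n} < {window}); "
                      "no prediction", stacklevel=2)
        return []
    h = np.array([KYTE_DOOLITTLE[ch] for ch in s])
    means = np.convolve(h, np.ones(window) / window, mode="valid")  # n-window+1
    flagged = np.zeros(n, dtype=bool)
    for start in np.nonzero(means > threshold)[0]:
        flagged[start:start + window] = True
    # maximal runs
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j < n and flagged[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [TMSegment(a, b, float(h[a:b].mean()))
            for a, b in merged if b - a >= min_tm_len]


@dataclass
class DomainArchitecture:
    """How many family domains a protein carries, and its TM layout."""

    record_id: str
    tm_segments: list[TMSegment]
    n_tim17_domains: int
    domain_envelopes: list[tuple[int, int]]
    flags: set[str] = field(default_factory=set)   # {extra_cterm_tm, two_tm_only}


def split_tandem(seq: ProteinRecord, family_profile: PositionProfile,
                 e_cutoff: float = 1.0, max_overlap: int = 10,
                 db_size: int = 1000,
                 tm_params: dict | None = None) -> DomainArchitecture:
    """Detect one vs two family domains by score-mask-rescore.

    The best envelope against the calibrated family profile is recorded and
    hard-masked (residues replaced by X); if the rescored sequence yields a
    second envelope at e-value <= ``e_cutoff`` that overlaps the first by
    < ``max_overlap`` residues, the protein carries two domains, reported
    in N->C order.  ``db_size`` sets the e-value scale and should be the
    size of the database the homolog was found in.  Flags: ``two_tm_only``
    when exactly two TM segments are predicted, ``extra_cterm_tm`` when a
    TM segment lies entirely after the last domain envelope.
    """
    if family_profile.calibration is None:
        raise ValueError("family profile must be calibrated")
    first = score_sequence(family_profile, seq, traceback=True)
    if (not first.matches
            or family_profile.calibration.evalue(first.score, db_size) > e_cutoff):
        raise ValueError(f"record {seq.id!r} has no envelope passing "
                         f"e <= {e_cutoff} against the family profile")
    envelopes = [(first.env_start, first.env_end)]
    masked_res = (seq.residues[:first.env_start]
                  + "X" * (first.env_end - first.env_start)
                  + seq.residues[first.env_end:])
    second = score_sequence(family_profile,
                            ProteinRecord(id=seq.id + "#rescan", residues=masked_res),
                            traceback=True)
    if second.matches and family_profile.calibration.evalue(
            second.score, db_size) <= e_cutoff:
        ov = _overlap(envelopes[0], (second.env_start, second.env_end))
        if ov < max_overlap:
            envelopes.append((second.env_start, second.env_end))
    envelopes.sort()
    tms = predict_tm(seq, **(tm_params or {}))
    flags: set[str] = set()
    if len(tms) == 2:
        flags.add("two_tm_only")
    if tms and envelopes and any(t.start >= envelopes[-1][1] for t in tms):
        flags.add("extra_cterm_tm")
    return DomainArchitecture(record_id=seq.id, tm_segments=tms,
                              n_tim17_domains=len(envelopes),
                              domain_envelopes=envelopes, flags=flags)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def write_motifs_tsv(matches: dict[str, list[MotifMatch]], path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tmotif\tstart\tend\tspan\n")
        for rid in sorted(matches):
            for m in matches[rid]:
                fh.write(f"{rid}\t{m.motif_name}\t{m.start}\t{m.end}\t{m.matched_span}\n")


def write_architecture_tsv(archs: list[DomainArchitecture], path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\tn_domains\tn_tm\tflags\tenvelopes\n")
        for a in archs:
            env = ";".join(f"{s}-{e}" for s, e in a.domain_envelopes)
            fh.write(f"{a.record_id}\t{a.n_tim17_domains}\t{len(a.tm_segments)}\t"
                     f"{','.join(sorted(a.flags))}\t{env}\n")
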