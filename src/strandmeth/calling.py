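"""Clone alignment, per-CpG methylation calling, conversion QC, matrices.

A sequenced clone is one BS-converted DNA molecule.  After alignment to
its amplicon's reference, each CpG C column is read as C (methylated,
the base was protected) or T (unmethylated, the base was converted);
anything else — gap, N, another base — is an ambiguous call.  Non-CpG C
columns, which should all read T after complete conversion, provide the
per-clone conversion-efficiency QC statistic.

Alignment is a global affine-gap Needleman-Wunsch/Gotoh against the
untreated reference with a bisulfite-asymmetric substitution scheme:
a read T opposite a reference C is a full match (expected conversion at
non-CpG sites; the unmethylated state at CpG sites), so neither
methylation state nor conversion status is penalized.  Clone
orientation is auto-detected by also scoring the reverse complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon import Amplicon, reverse_complement

__all__ = [
    "AlignmentParams",
    "CloneAlignment",
    "CloneProfile",
    "MethylationMatrix",
    "EmptyMatrixError",
    "align_clone",
    "call_cpg_states",
    "conversion_efficiency",
    "build_matrix",
    "call_dataset",
    "METHYLATED",
    "UNMETHYLATED",
    "AMBIGUOUS",
]

# Per-CpG call encoding used in call vectors (float arrays): 1 methylated,
# 0 unmethylated, NaN ambiguous.
METHYLATED = 1.0
UNMETHYLATED = 0.0
AMBIGUOUS = float("nan")

_NEG = -(10**9)


@dataclass(frozen=True)
class AlignmentParams:
    """Pinned alignment scoring parameters.

    Match 2 / mismatch -3 / gap open -5 (covers the first gap base) /
    gap extend -2, with the asymmetric bisulfite C/T rules; clones whose
    best alignment identity falls below ``identity_floor`` are flagged
    unalignable.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    identity_floor: float = 0.80


DEFAULT_PARAMS = AlignmentParams()


def _score_matrix(ref: str, read: str, params: AlignmentParams) -> np.ndarray:
    """Position-wise substitution scores; ref C vs read T is a match."""
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    read_arr = np.frombuffer(read.encode(), dtype="S1")
    eq = ref_arr[:, None] == read_arr[None, :]
    bs = (ref_arr == b"C")[:, None] & (read_arr == b"T")[None, :]
    return np.where(eq | bs, params.match, params.mismatch).astype(np.int64)


def _gotoh(ref: str, read: str, params: AlignmentParams):
    """Global affine-gap DP; returns (score, M, X, Y) matrices.

    States: M = ref[i-1] aligned to read[j-1]; X = ref base vs gap;
    Y = read base vs gap.  Row-wise vectorized; the within-row gap
    recursion for Y is solved with a running-maximum scan.
    """
    n, m = len(ref), len(read)
    go, ge = params.gap_open, params.gap_extend
    S = _score_matrix(ref, read, params)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    M[0, 0] = 0
    if n:
        X[1:, 0] = go + ge * np.arange(n)
    if m:
        Y[0, 1:] = go + ge * np.arange(m)

    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        X[i, 1:] = np.maximum(M[i - 1, 1:], np.maximum(X[i - 1, 1:] + (ge - go), Y[i - 1, 1:])) + go
        X[i, 0] = go + ge * (i - 1)
        # Y[i,j] = max_{k<j} max(M,X)[i,k] + go + (j-1-k)*ge  (extending an
        # existing Y never beats this since go < ge <= 0)
        mx = np.maximum(M[i], X[i])
        scan = np.maximum.accumulate(mx[:-1] - ge * np.arange(m))
        Y[i, 1:] = scan + go + ge * (js - 1)
    score = int(max(M[n, m], X[n, m], Y[n, m]))
    return score, M, X, Y


def _traceback(ref: str, read: str, params: AlignmentParams, M, X, Y):
    """Recover one optimal alignment path from the DP matrices."""
    go, ge = params.gap_open, params.gap_extend
    S = _score_matrix(ref, read, params)
    i, j = len(ref), len(read)
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ref_aln: list[str] = []
    read_aln: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            ref_aln.append(ref[i - 1])
            read_aln.append(read[j - 1])
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
            # prev must equal the max by construction
            assert max(M[i, j], X[i, j], Y[i, j]) == prev
        elif state == 1:  # X: ref vs gap
            ref_aln.append(ref[i - 1])
            read_aln.append("-")
            target_ext = X[i, j] - ge
            target_open = X[i, j] - go
            i -= 1
            if i == 0 and j == 0:
                break
            if X[i, j] == target_ext:
                state = 1
            elif M[i, j] == target_open:
                state = 0
            elif Y[i, j] == target_open:
                state = 2
            else:  # boundary column
                state = 1
        else:  # Y: read vs gap
            read_aln.append(read[j - 1])
            ref_aln.append("-")
            target_ext = Y[i, j] - ge
            target_open = Y[i, j] - go
            j -= 1
            if i == 0 and j == 0:
                break
            if Y[i, j] == target_ext:
                state = 2
            elif M[i, j] == target_open:
                state = 0
            elif X[i, j] == target_open:
                state = 1
            else:
                state = 2
    return "".join(reversed(ref_aln)), "".join(reversed(read_aln))


@dataclass
class CloneAlignment:
    """Global alignment of one clone against its amplicon reference."""

    amplicon: Amplicon
    score: int
    ref_aln: str
    read_aln: str
    orientation: str  # "forward" | "reverse"
    identity: float
    passed_floor: bool
    ref_to_read: np.ndarray = field(repr=False)  # per ref position: aligned read char

    @property
    def flag(self) -> str | None:
        return None if self.passed_floor else "unalignable clone"


def _is_match(r: str, q: str) -> bool:
    return r == q or (r == "C" and q == "T")


def align_clone(
    clone_seq: str,
    amplicon: Amplicon,
    model_assumption: str = "unmeth_ref",
    params: AlignmentParams = DEFAULT_PARAMS,
) -> CloneAlignment:
    """Globally align a clone to its amplicon with bisulfite-aware scoring.

    Both the clone and its reverse complement are scored and the better
    orientation kept (plasmid inserts can be sequenced in either
    direction).  ``model_assumption`` names the conversion state assumed
    for the reference (the asymmetric scheme makes scoring identical
    under either assumption; the label is carried for reporting).
    Alignments with identity below ``params.identity_floor`` are flagged
    unalignable rather than rejected, so the caller can log the reason.
    """
    if not clone_seq:
        raise ValueError("clone_seq must be non-empty")
    if model_assumption not in ("unmeth_ref", "meth_ref"):
        raise ValueError("model_assumption must be 'unmeth_ref' or 'meth_ref'")
    ref = amplicon.ref_seq
    candidates = []
    for orientation, read in (
        ("forward", clone_seq.upper()),
        ("reverse", reverse_complement(clone_seq)),
    ):
        score, M, X, Y = _gotoh(ref, read, params)
        candidates.append((score, orientation, read, M, X, Y))
    score, orientation, read, M, X, Y = max(candidates, key=lambda c: c[0])
    ref_aln, read_aln = _traceback(ref, read, params, M, X, Y)

    matches = sum(
        1 for r, q in zip(ref_aln, read_aln) if r != "-" and q != "-" and _is_match(r, q)
    )
    identity = matches / len(ref_aln) if ref_aln else 0.0

    ref_to_read = np.full(len(ref), "-", dtype="<U1")
    ri = 0
    for r, q in zip(ref_aln, read_aln):
        if r != "-":
            ref_to_read[ri] = q
            ri += 1
    return CloneAlignment(
        amplicon=amplicon,
        score=score,
        ref_aln=ref_aln,
        read_aln=read_aln,
        orientation=orientation,
        identity=identity,
        passed_floor=identity >= params.identity_floor,
        ref_to_read=ref_to_read,
    )


def call_cpg_states(alignment: CloneAlignment, amplicon: Amplicon | None = None) -> np.ndarray:
    """Per-CpG methylation calls from an alignment.

    Read C at the CpG C column -> methylated (1.0); read T ->
    unmethylated (0.0); gap, N or any other base -> ambiguous (NaN).
    """
    amp = amplicon or alignment.amplicon
    calls = np.full(amp.n_cpg, AMBIGUOUS)
    for k, p in enumerate(amp.cpg_positions):
        base = alignment.ref_to_read[p]
        if base == "C":
            calls[k] = METHYLATED
        elif base == "T":
            calls[k] = UNMETHYLATED
    return calls


def conversion_efficiency(
    alignment: CloneAlignment, amplicon: Amplicon | None = None
) -> float | None:
    """Fraction of non-CpG reference Cs read as T.

    Only columns read as C or T are assessable (gaps, Ns and other bases
    are excluded from the denominator).  Returns None when no column is
    assessable; such clones fail QC with reason "no assessable Cs".
    """
    amp = amplicon or alignment.amplicon
    n_converted = 0
    n_assessable = 0
    for p in amp.non_cpg_c_positions():
        base = alignment.ref_to_read[p]
        if base == "T":
            n_converted += 1
            n_assessable += 1
        elif base == "C":
            n_assessable += 1
    if n_assessable == 0:
        return None
    return n_converted / n_assessable


@dataclass
class CloneProfile:
    """One clone's calls plus QC status."""

    clone_id: str
    group: tuple[str, str, str, str]  # donor, population, region, strand
    calls: np.ndarray
    conversion_efficiency: float | None
    qc_pass: bool
    exclusion_reason: str | None = None
    alignment_identity: float | None = None
    orientation: str | None = None

    @property
    def n_methylated(self) -> int:
        return int(np.nansum(self.calls == METHYLATED))

    @property
    def n_unmethylated(self) -> int:
        return int(np.nansum(self.calls == UNMETHYLATED))

    @property
    def n_ambiguous(self) -> int:
        return int(np.isnan(self.calls).sum())


class EmptyMatrixError(ValueError):
    """No QC-passing clones remain for a group."""


@dataclass
class MethylationMatrix:
    """QC-passing clones x CpG calls for one group, with percentages.

    ``percent[i] = 100 * methylated_i / (methylated_i + unmethylated_i)``;
    ambiguous calls are excluded from numerator and denominator, and the
    per-CpG denominators are recorded.
    """

    group: tuple[str, str, str, str]
    clone_ids: list[str]
    calls: np.ndarray  # clones x CpGs, values {1, 0, NaN}

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]

    @property
    def n_cpg(self) -> int:
        return self.calls.shape[1]

    @property
    def denominators(self) -> np.ndarray:
        return (~np.isnan(self.calls)).sum(axis=0)

    @property
    def percent(self) -> np.ndarray:
        den = self.denominators
        num = np.nansum(self.calls, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, 100.0 * num / den, np.nan)

    def to_frame(self) -> pd.DataFrame:
        donor, pop, region, strand = self.group
        return pd.DataFrame(
            {
                "donor": donor,
                "population": pop,
                "region": region,
                "strand": strand,
                "cpg": np.arange(1, self.n_cpg + 1),
                "percent_methylation": self.percent,
                "n_called": self.denominators,
                "n_clones": self.n_clones,
            }
        )

    def lollipop_frame(self) -> pd.DataFrame:
        """One row per clone, one {1, 0, NA} column per CpG ordinal."""
        df = pd.DataFrame(
            self.calls, columns=[f"CpG_{i + 1}" for i in range(self.n_cpg)]
        ).astype(object)
        df = df.map(lambda v: pd.NA if np.isnan(v) else int(v))
        df.insert(0, "clone_id", self.clone_ids)
        return df

    def lollipop_text(self, filled: str = "●", empty: str = "○", gap: str = "·") -> str:
        """Text lollipop rendering: one clone per line, one glyph per CpG."""
        lines = []
        for cid, row in zip(self.clone_ids, self.calls):
            glyphs = "".join(
                gap if np.isnan(v) else (filled if v == METHYLATED else empty) for v in row
            )
            lines.append(f"{cid}\t{glyphs}")
        return "\n".join(lines)


def build_matrix(
    clone_profiles: Sequence[CloneProfile], qc_threshold: float = 0.95
) -> MethylationMatrix:
    """Assemble a group's methylation matrix from QC-passing clones.

    Clones whose conversion efficiency is below ``qc_threshold`` (or
    undefined), or which failed alignment, are dropped.  Raises
    :class:`EmptyMatrixError` when nothing passes.
    """
    if not clone_profiles:
        raise EmptyMatrixError("no clone profiles supplied")
    groups = {p.group for p in clone_profiles}
    if len(groups) != 1:
        raise ValueError(f"profiles span multiple groups: {sorted(groups)}")
    passing = [
        p
        for p in clone_profiles
        if p.qc_pass
        and p.conversion_efficiency is not None
        and p.conversion_efficiency >= qc_threshold
    ]
    if not passing:
        raise EmptyMatrixError(f"all clones failed QC for group {groups.pop()}")
    calls = np.vstack([p.calls for p in passing])
    return MethylationMatrix(
        group=passing[0].group,
        clone_ids=[p.clone_id for p in passing],
        calls=calls,
    )


def profile_clone(
    clone_id: str,
    clone_seq: str,
    group: tuple[str, str, str, str],
    amplicon: Amplicon,
    qc_threshold: float = 0.95,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> CloneProfile:
    """Align, call and QC a single clone."""
    aln = align_clone(clone_seq, amplicon, params=params)
    if not aln.passed_floor:
        return CloneProfile(
            clone_id=clone_id,
            group=group,
            calls=np.full(amplicon.n_cpg, AMBIGUOUS),
            conversion_efficiency=None,
            qc_pass=False,
            exclusion_reason=f"unalignable clone (identity {aln.identity:.3f} < {params.identity_floor})",
            alignment_identity=aln.identity,
            orientation=aln.orientation,
        )
    calls = call_cpg_states(aln)
    eff = conversion_efficiency(aln)
    if eff is None:
        return CloneProfile(
            clone_id=clone_id,
            group=group,
            calls=calls,
            conversion_efficiency=None,
            qc_pass=False,
            exclusion_reason="no assessable Cs",
            alignment_identity=aln.identity,
            orientation=aln.orientation,
        )
    if eff < qc_threshold:
        return CloneProfile(
            clone_id=clone_id,
            group=group,
            calls=calls,
            conversion_efficiency=eff,
            qc_pass=False,
            exclusion_reason=f"incomplete conversion (efficiency {eff:.3f} < {qc_threshold})",
            alignment_identity=aln.identity,
            orientation=aln.orientation,
        )
    return CloneProfile(
        clone_id=clone_id,
        group=group,
        calls=calls,
        conversion_efficiency=eff,
        qc_pass=True,
        alignment_identity=aln.identity,
        orientation=aln.orientation,
    )


def call_dataset(
    clones: Iterable[tuple[str, str]],
    sample_sheet: pd.DataFrame,
    amplicons: Mapping[tuple[str, str], Amplicon],
    qc_threshold: float = 0.95,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[dict[tuple[str, str, str, str], MethylationMatrix], dict, list[CloneProfile]]:
    """Run the calling stage over a whole clone set.

    Returns (matrices by group, QC report, all clone profiles).  Every
    input clone is accounted for: the QC report's called + excluded
    counts sum to the number of records, and clones missing from the
    sample sheet are listed as excluded with a reason.
    """
    sheet = sample_sheet.set_index("clone_id")
    by_group: dict[tuple[str, str, str, str], list[CloneProfile]] = {}
    profiles: list[CloneProfile] = []
    qc_clones = []
    n_records = 0
    for clone_id, seq in clones:
        n_records += 1
        if clone_id not in sheet.index:
            qc_clones.append(
                {
                    "clone_id": clone_id,
                    "qc_pass": False,
                    "conversion_efficiency": None,
                    "exclusion_reason": "clone not in sample sheet",
                }
            )
            continue
        row = sheet.loc[clone_id]
        group = (str(row["donor"]), str(row["population"]), str(row["region"]), str(row["strand"]))
        amp = amplicons.get((group[2], group[3]))
        if amp is None:
            qc_clones.append(
                {
                    "clone_id": clone_id,
                    "qc_pass": False,
                    "conversion_efficiency": None,
                    "exclusion_reason": f"no reference amplicon for {group[2]}|{group[3]}",
                }
            )
            continue
        prof = profile_clone(clone_id, seq, group, amp, qc_threshold, params)
        profiles.append(prof)
        by_group.setdefault(group, []).append(prof)
        qc_clones.append(
            {
                "clone_id": clone_id,
                "group": list(group),
                "qc_pass": prof.qc_pass,
                "conversion_efficiency": prof.conversion_efficiency,
                "alignment_identity": prof.alignment_identity,
                "orientation": prof.orientation,
                "exclusion_reason": prof.exclusion_reason,
            }
        )

    matrices: dict[tuple[str, str, str, str], MethylationMatrix] = {}
    empty_groups = []
    for group, profs in by_group.items():
        try:
            matrices[group] = build_matrix(profs, qc_threshold)
        except EmptyMatrixError:
            empty_groups.append(group)
            warnings.warn(f"all clones failed QC for group {group}")
    n_called = sum(1 for c in qc_clones if c["qc_pass"])
    report = {
        "n_records": n_records,
        "n_called": n_called,
        "n_excluded": n_records - n_called,
        "qc_threshold": qc_threshold,
        "identity_floor": params.identity_floor,
        "empty_groups": [list(g) for g in empty_groups],
        "clones": qc_clones,
    }
    return matrices, report, profiles
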