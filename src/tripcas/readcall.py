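"""Amplicon read parsing, semi-global alignment and repair-outcome calling.

Reads from a Cas9-targeted barcoded reporter carry, in order: a 16-nt unique
molecular identifier (UID), a constant anchor, the reporter barcode, a second
anchor, the 5-nt promoter index, and the amplified target region containing
the 20-nt protospacer plus NGG PAM.  This module recovers those parts,
aligns the target portion against the wild-type amplicon with a semi-global
affine-gap scheme (match +2, mismatch -2, gap open -5, gap extend -0.5,
additive initial score 30) and classifies each read's repair outcome as
wild-type, deletion, insertion or complex.

Coordinates follow the PAM-relative convention used throughout the package:
nucleotide ``k`` is the k-th base upstream of the PAM on the non-target
strand (ntDNA, the strand carrying protospacer+PAM), 1-based with position 1
abutting the PAM.  Junction ``j|j+1`` is the phosphodiester bond between
positions ``j`` and ``j+1``; the canonical blunt Cas9 cut is at 3|4.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignmentError",
    "AlignmentParams",
    "AlignmentResult",
    "GuideTarget",
    "TargetFrame",
    "MutationCall",
    "ParsedRead",
    "ReadLayout",
    "revcomp",
    "align_semi_global",
    "call_mutation",
    "parse_amplicon",
    "parse_batch",
    "call_reads",
    "collapse_uids",
    "deletion_window",
    "insertion_window",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

OUTCOMES = ("wild_type", "deletion", "insertion", "complex")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs (empty or non-ACGTN sequences)."""


# ---------------------------------------------------------------------------
# Guide / coordinate frame
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuideTarget:
    """A protospacer/PAM pair with PAM-relative coordinate helpers.

    ``orientation`` states how the protospacer+PAM lies in the reporter
    amplicon: ``"sense"`` if the amplicon top strand is the ntDNA view,
    ``"antisense"`` if the ntDNA is the amplicon's reverse complement.
    """

    protospacer: str
    pam: str
    name: str = "guide"
    orientation: str = "sense"

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError("PAM must match NGG")
        if any(c not in "ACGT" for c in self.protospacer + self.pam):
            raise ValueError("guide sequences must be over ACGT")
        if self.orientation not in ("sense", "antisense"):
            raise ValueError("orientation must be sense or antisense")

    @property
    def ntdna(self) -> str:
        """Non-target strand view (protospacer+PAM, 5'->3')."""
        return self.protospacer + self.pam

    @property
    def tdna(self) -> str:
        """Target strand view (guide-bound strand, 5'->3')."""
        return revcomp(self.ntdna)

    def base(self, k: int) -> str:
        """Nucleotide ``k`` upstream of the PAM on the ntDNA (1-based)."""
        if not 1 <= k <= 20:
            raise ValueError("position must be within the protospacer (1..20)")
        return self.ntdna[20 - k]

    @property
    def nucleotide4(self) -> str:
        """The staggered-model template base (ntDNA position 4)."""
        return self.base(4)

    def frame(self, reference: str) -> "TargetFrame":
        """Locate this guide in a reference amplicon; must occur exactly once."""
        probe = self.ntdna if self.orientation == "sense" else revcomp(self.ntdna)
        if reference.count(probe) != 1:
            raise ValueError(
                f"protospacer+PAM for {self.name} must occur exactly once in reference"
            )
        if self.orientation == "sense":
            ntref = reference
        else:
            ntref = revcomp(reference)
        pam_index = ntref.index(self.ntdna) + 20
        return TargetFrame(guide=self, reference=reference, ntref=ntref, pam_index=pam_index)


@dataclass(frozen=True)
class TargetFrame:
    """PAM-relative coordinates of one guide inside one reference amplicon.

    ``ntref`` is the reference in ntDNA orientation; ``pam_index`` is the
    0-based index of the first PAM base within ``ntref``.
    """

    guide: GuideTarget
    reference: str
    ntref: str
    pam_index: int

    def junction_to_bond(self, j: int) -> int:
        """String bond index in ``ntref`` for junction ``j|j+1``.

        A bond index ``i`` sits between ``ntref[i-1]`` and ``ntref[i]``;
        inserting at string index ``i`` places a base on that bond.
        """
        return self.pam_index - j

    def bond_to_junction(self, bond: int) -> int:
        return self.pam_index - bond

    def position_base(self, k: int) -> str:
        """Base at position ``k`` upstream of the PAM in ``ntref`` (k may
        be <=0, indexing into the PAM and downstream)."""
        return self.ntref[self.pam_index - k]

    @property
    def cut_bond(self) -> int:
        """Bond index of the canonical blunt cut (junction 3|4) in ``ntref``."""
        return self.junction_to_bond(3)

    # -- conversion of reference-orientation coordinates into the nt frame --

    def ref_bond_to_nt(self, bond: int) -> int:
        if self.guide.orientation == "sense":
            return bond
        return len(self.reference) - bond

    def ref_interval_to_nt(self, start: int, end: int) -> tuple[int, int]:
        if self.guide.orientation == "sense":
            return start, end
        n = len(self.reference)
        return n - end, n - start

    def protospacer_ref_span(self) -> tuple[int, int]:
        """(start, end) of protospacer+PAM in reference orientation."""
        start_nt = self.pam_index - 20
        end_nt = self.pam_index + 3
        if self.guide.orientation == "sense":
            return start_nt, end_nt
        n = len(self.reference)
        return n - end_nt, n - start_nt


# ---------------------------------------------------------------------------
# Semi-global affine alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring weights for the semi-global aligner.

    The first column of a gap is charged ``gap_open``; each subsequent
    column ``gap_extend``.  ``initial_score`` is a pure additive offset kept
    for score comparability; it never changes the argmax.
    """

    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -0.5
    initial_score: float = 30.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.mismatch <= 0.0 <= self.match):
            raise ValueError("require gap_open <= mismatch <= 0 <= match")
        if self.gap_extend > 0:
            raise ValueError("gap_extend must be non-positive")


_NEG = -1.0e30
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str, label: str) -> np.ndarray:
    if not seq:
        raise AlignmentError(f"{label} sequence is empty")
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise AlignmentError(f"{label} contains non-ACGTN symbol {exc.args[0]!r}") from None


def _fill_dp_py(q, r, match, mismatch, gap_open, gap_extend):
    """Gotoh affine DP with free reference end-gaps (query fitted into ref).

    States: M (q[i-1] aligned to r[j-1]), X (gap in reference: query base
    unmatched), Y (gap in query: reference base deleted).
    """
    n = q.shape[0]
    m = r.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    for j in range(m + 1):
        M[0, j] = 0.0  # free leading reference skip
    for i in range(1, n + 1):
        X[i, 0] = max(M[i - 1, 0] + gap_open, X[i - 1, 0] + gap_extend)
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == r[j - 1] and qi != 4) else mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return M, X, Y


try:  # optional JIT; semantics identical to the Python path
    from numba import njit as _njit

    _fill_dp = _njit(cache=False)(_fill_dp_py)
    _fill_dp(np.zeros(1, np.int8), np.zeros(1, np.int8), 2.0, -2.0, -5.0, -0.5)
except Exception:  # pragma: no cover - exercised only without numba
    _fill_dp = _fill_dp_py


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal semi-global alignment with 3'-normalized indel operations.

    ``ops`` lists indels as ``("del", ref_start, lost_seq)`` and
    ``("ins", ref_bond, inserted_seq)`` in reference coordinates after
    shifting every indel to its 3'-most equivalent placement.
    ``substitutions`` lists ``(ref_pos, ref_base, query_base)``.
    """

    score: float
    query: str
    reference: str
    ref_start: int
    ref_end: int
    aligned_query: str
    aligned_reference: str
    ops: tuple
    substitutions: tuple

    @property
    def n_gap_columns(self) -> int:
        return self.aligned_query.count("-") + self.aligned_reference.count("-")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)


def _traceback(q, r, M, X, Y, gap_open):
    n = q.shape[0]
    m = r.shape[0]
    eps = 1e-9
    # end anywhere on the reference (free trailing skip); 3'-most on ties
    best = _NEG
    end_j = 0
    end_state = 0
    for j in range(m + 1):
        for state, mat in ((0, M), (1, Y), (2, X)):  # prefer M, then del, then ins
            v = mat[n, j]
            if v > best + eps or (v > best - eps and j > end_j):
                best, end_j, end_state = v, j, state
    i, j, state = n, end_j, end_state
    aq: list[str] = []
    ar: list[str] = []
    while i > 0:
        if state == 0:  # M: q[i-1] aligned to r[j-1]
            aq.append("ACGTN"[q[i - 1]])
            ar.append("ACGTN"[r[j - 1]])
            prev = (M[i - 1, j - 1], Y[i - 1, j - 1], X[i - 1, j - 1])
            top = max(prev)
            state = (0, 1, 2)[min(k for k in range(3) if prev[k] >= top - eps)]
            i -= 1
            j -= 1
        elif state == 1:  # Y: reference base absent from query (deletion)
            aq.append("-")
            ar.append("ACGTN"[r[j - 1]])
            # prefer closing the gap (coming from M) on ties
            state = 0 if M[i, j - 1] + gap_open >= Y[i, j] - eps else 1
            j -= 1
        else:  # X: extra query base (insertion)
            aq.append("ACGTN"[q[i - 1]])
            ar.append("-")
            state = 0 if M[i - 1, j] + gap_open >= X[i, j] - eps else 2
            i -= 1
    ref_start = j
    return ref_start, end_j, "".join(reversed(aq)), "".join(reversed(ar))


def align_semi_global(
    query: str, reference: str, params: AlignmentParams | None = None
) -> AlignmentResult:
    """Optimal semi-global alignment of ``query`` into ``reference``.

    Leading/trailing unaligned reference (the amplicon context around the
    read) is free; internal gaps are affine.  ``N`` matches nothing and is
    scored as a mismatch.  Traceback ties prefer match/mismatch over gaps
    and deletions over insertions; indels are then normalized to their
    3'-most equivalent placement.
    """
    params = params or AlignmentParams()
    q = _encode(query, "query")
    r = _encode(reference, "reference")
    M, X, Y = _fill_dp(q, r, params.match, params.mismatch, params.gap_open, params.gap_extend)
    ref_start, ref_end, aq, ar = _traceback(q, r, M, X, Y, params.gap_open)
    raw = max(float(np.max(M[len(q)])), float(np.max(X[len(q)])), float(np.max(Y[len(q)])))
    ops, subs = _alignment_ops(aq, ar, reference, ref_start)
    return AlignmentResult(
        score=raw + params.initial_score,
        query=query,
        reference=reference,
        ref_start=ref_start,
        ref_end=ref_end,
        aligned_query=aq,
        aligned_reference=ar,
        ops=tuple(ops),
        substitutions=tuple(subs),
    )


def _alignment_ops(aq: str, ar: str, reference: str, ref_start: int):
    """Extract indel/substitution operations and right-shift indels 3'-most."""
    ops = []
    subs = []
    rpos = ref_start
    i = 0
    ncol = len(aq)
    while i < ncol:
        if aq[i] != "-" and ar[i] != "-":
            if aq[i] != ar[i]:
                subs.append((rpos, ar[i], aq[i]))
            rpos += 1
            i += 1
        elif ar[i] == "-":  # insertion run
            j = i
            while j < ncol and ar[j] == "-":
                j += 1
            ops.append(["ins", rpos, aq[i:j]])
            i = j
        else:  # deletion run
            j = i
            while j < ncol and aq[j] == "-":
                j += 1
            ops.append(["del", rpos, ar[i:j]])
            rpos += j - i
            i = j
    # 3'-most normalization, bounded by the next event or alignment end
    ref_end = rpos
    for k, op in enumerate(ops):
        bound = ops[k + 1][1] if k + 1 < len(ops) else ref_end
        kind, pos, seq = op
        if kind == "del":
            L = len(seq)
            while pos + L < bound and reference[pos] == reference[pos + L]:
                pos += 1
            op[1], op[2] = pos, reference[pos : pos + L]
        else:
            s = seq
            while pos < bound and pos < len(reference) and s[0] == reference[pos]:
                s = s[1:] + s[0]
                pos += 1
            op[1], op[2] = pos, s
    return [tuple(o) for o in ops], subs


# ---------------------------------------------------------------------------
# Indel equivalence windows
# ---------------------------------------------------------------------------


def deletion_window(reference: str, start: int, length: int) -> tuple[int, ...]:
    """All contiguous placements of an equal-length deletion yielding the
    identical mutated sequence (checked literally)."""
    mutated = reference[:start] + reference[start + length :]
    lo = start
    while lo > 0 and reference[lo - 1] == reference[lo - 1 + length]:
        lo -= 1
    hi = start
    while hi + length < len(reference) and reference[hi] == reference[hi + length]:
        hi += 1
    window = tuple(range(lo, hi + 1))
    for p in window:  # literal soundness
        assert reference[:p] + reference[p + length :] == mutated
    return window


def insertion_window(reference: str, bond: int, seq: str) -> tuple[int, ...]:
    """All contiguous junctions where inserting a (rotated) copy of ``seq``
    yields the identical mutated sequence."""
    mutated = reference[:bond] + seq + reference[bond:]
    L = len(seq)

    def fits(p: int) -> bool:
        return mutated[:p] == reference[:p] and mutated[p + L :] == reference[p:]

    lo = bond
    while lo > 0 and fits(lo - 1):
        lo -= 1
    hi = bond
    while hi < len(reference) and fits(hi + 1):
        hi += 1
    return tuple(range(lo, hi + 1))


# ---------------------------------------------------------------------------
# Mutation calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Indel:
    kind: str  # "del" | "ins"
    position: int  # reference coordinate: deletion start / insertion bond
    sequence: str
    window: tuple  # equivalent placements (starts for del, bonds for ins)

    @property
    def size(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutationCall:
    """One molecule's classified repair outcome."""

    barcode: str
    uid: str
    outcome: str
    indels: tuple = ()
    knockin: bool = False
    score: float = 0.0
    rejected: str | None = None

    @property
    def deletions(self) -> tuple:
        return tuple(i for i in self.indels if i.kind == "del")

    @property
    def insertions(self) -> tuple:
        return tuple(i for i in self.indels if i.kind == "ins")


def call_mutation(
    aln: AlignmentResult,
    frame: TargetFrame,
    ssodn_insert: str | None = None,
    barcode: str = "",
    uid: str = "",
) -> MutationCall:
    """Classify a read's repair outcome from its alignment.

    Zero indels -> wild_type (substitutions alone never change the class);
    exactly one deletion -> deletion; exactly one insertion -> insertion;
    two or more indel events -> complex.  An insertion equal to the ssODN
    insert placed within 10 bp of the cut site sets ``knockin``.
    """
    span = frame.protospacer_ref_span()
    if aln.ref_start > span[0] or aln.ref_end < span[1]:
        return MutationCall(
            barcode=barcode, uid=uid, outcome="wild_type", score=aln.score,
            rejected="off_target_fragment",
        )
    indels = []
    for kind, pos, seq in aln.ops:
        if kind == "del":
            window = deletion_window(aln.reference, pos, len(seq))
        else:
            window = insertion_window(aln.reference, pos, seq)
        indels.append(Indel(kind=kind, position=pos, sequence=seq, window=window))
    if not indels:
        outcome = "wild_type"
    elif len(indels) == 1:
        outcome = "deletion" if indels[0].kind == "del" else "insertion"
    else:
        outcome = "complex"
    knockin = False
    if ssodn_insert and outcome == "insertion":
        ins = indels[0]
        cut_ref = frame.ref_bond_to_nt(frame.cut_bond) if frame.guide.orientation == "antisense" else frame.cut_bond
        rotations = {ins.sequence[k:] + ins.sequence[:k] for k in range(len(ins.sequence))}
        near_cut = any(abs(b - cut_ref) <= 10 for b in ins.window)
        if ssodn_insert in rotations and near_cut:
            knockin = True
    return MutationCall(
        barcode=barcode, uid=uid, outcome=outcome, indels=tuple(indels),
        knockin=knockin, score=aln.score,
    )


# ---------------------------------------------------------------------------
# Read layout parsing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadLayout:
    """Positional layout of a synthetic reporter amplicon read."""

    uid_length: int = 16
    anchor1: str = "CGTCAGTC"
    anchor2: str = "GATCGGAA"
    promoter_index_length: int = 5


DEFAULT_LAYOUT = ReadLayout()

ParsedRead = collections.namedtuple(
    "ParsedRead", ["barcode", "uid", "target", "promoter_index"]
)


def parse_amplicon(
    read: str,
    library: dict,
    layout: ReadLayout = DEFAULT_LAYOUT,
    barcode_mismatch_tolerance: int = 0,
):
    """Split a read into (barcode, uid, target, promoter_index).

    ``library`` maps barcode -> anything; barcodes must share one length.
    Returns ``(ParsedRead, None)`` on success or ``(None, reason)`` with
    reason in {"truncated", "anchor_mismatch", "aberrant_barcode"}.
    """
    if not library:
        raise ValueError("library barcode index is empty")
    bc_len = len(next(iter(library)))
    lay = layout
    min_len = lay.uid_length + len(lay.anchor1) + bc_len + len(lay.anchor2) + lay.promoter_index_length + 1
    if len(read) < min_len:
        return None, "truncated"
    p = 0
    uid = read[p : p + lay.uid_length]
    p += lay.uid_length
    if read[p : p + len(lay.anchor1)] != lay.anchor1:
        return None, "anchor_mismatch"
    p += len(lay.anchor1)
    barcode = read[p : p + bc_len]
    p += bc_len
    if read[p : p + len(lay.anchor2)] != lay.anchor2:
        return None, "anchor_mismatch"
    p += len(lay.anchor2)
    promoter_index = read[p : p + lay.promoter_index_length]
    p += lay.promoter_index_length
    target = read[p:]
    if barcode not in library:
        if barcode_mismatch_tolerance > 0:
            hits = [
                b
                for b in library
                if sum(x != y for x, y in zip(b, barcode)) <= barcode_mismatch_tolerance
            ]
            if len(hits) == 1:
                barcode = hits[0]
            else:
                return None, "aberrant_barcode"
        else:
            return None, "aberrant_barcode"
    return ParsedRead(barcode, uid, target, promoter_index), None


def parse_batch(reads, library, layout=DEFAULT_LAYOUT, barcode_mismatch_tolerance=0):
    """Parse many reads; returns (parsed list, summary dict with parse_rate)."""
    parsed = []
    reasons: collections.Counter = collections.Counter()
    for read in reads:
        rec, reason = parse_amplicon(read, library, layout, barcode_mismatch_tolerance)
        if rec is None:
            reasons[reason] += 1
        else:
            parsed.append(rec)
    total = len(parsed) + sum(reasons.values())
    summary = {
        "total": total,
        "parsed": len(parsed),
        "parse_rate": (len(parsed) / total) if total else 0.0,
        "rejections": dict(reasons),
    }
    return parsed, summary


def call_reads(
    reads,
    library,
    guide: GuideTarget,
    params: AlignmentParams | None = None,
    ssodn_insert: str | None = None,
    layout: ReadLayout = DEFAULT_LAYOUT,
    barcode_mismatch_tolerance: int = 0,
):
    """Parse, align and classify a batch of raw read sequences.

    ``library`` maps barcode -> wild-type target-region sequence.  Reads
    whose target equals the reference verbatim are called wild-type without
    dynamic programming (the alignment would be the identity).
    Returns (calls, summary).
    """
    params = params or AlignmentParams()
    parsed, summary = parse_batch(reads, library, layout, barcode_mismatch_tolerance)
    frames = {bc: guide.frame(ref) for bc, ref in library.items()}
    calls = []
    rejected = 0
    for rec in parsed:
        reference = library[rec.barcode]
        frame = frames[rec.barcode]
        if rec.target == reference:
            calls.append(
                MutationCall(
                    barcode=rec.barcode, uid=rec.uid, outcome="wild_type",
                    score=params.initial_score + params.match * len(reference),
                )
            )
            continue
        aln = align_semi_global(rec.target, reference, params)
        call = call_mutation(aln, frame, ssodn_insert, rec.barcode, rec.uid)
        if call.rejected:
            rejected += 1
        else:
            calls.append(call)
    summary["off_target_fragments"] = rejected
    summary["called"] = len(calls)
    return calls, summary


# ---------------------------------------------------------------------------
# UID collapsing
# ---------------------------------------------------------------------------

_OUTCOME_PRIORITY = {o: i for i, o in enumerate(OUTCOMES)}


def collapse_uids(calls):
    """Collapse reads sharing (barcode, UID) to one molecule.

    The molecule outcome is the majority read outcome; ties are broken
    toward wild_type, then by the fixed order deletion < insertion < complex.
    Returns (molecule calls, stats).
    """
    groups: dict = collections.defaultdict(list)
    for c in calls:
        groups[(c.barcode, c.uid)].append(c)
    molecules = []
    ties = 0
    for key in groups:
        members = groups[key]
        counts = collections.Counter(c.outcome for c in members)
        top = max(counts.values())
        winners = sorted(
            (o for o, n in counts.items() if n == top), key=_OUTCOME_PRIORITY.get
        )
        if len(winners) > 1:
            ties += 1
        winner = winners[0]
        rep = next(c for c in members if c.outcome == winner)
        molecules.append(rep)
    stats = {
        "reads": len(calls),
        "molecules": len(molecules),
        "ties": ties,
        "max_family_size": max((len(v) for v in groups.values()), default=0),
    }
    return molecules, stats
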