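"""Enumeration and matching of Cas9 DNA-end conformations from hairpin reads.

Hairpin capture of DNA end structures ligates the two strands of one
double-strand-break end into a hairpin, so a single sequencing read reports
the end conformation.  This module models the PAM-proximal fragment: with
``W`` the ntDNA-oriented duplex (PAM at index ``P``) and termini ``t``
(tDNA junction) and ``nt`` (ntDNA junction), both counted upstream of the
PAM, the expected hairpin read is::

    revcomp(W[P - t:]) + W[P - nt:]

Relative to a blunt end at the same tDNA terminus, a k-nt 5' overhang
(``nt - t = k > 0``) shows as a k-base apex duplication of ntDNA bases and a
k-nt 3' overhang (``nt - t = -k``) as a k-base apex loss.  Distinct
conformations can produce literally identical expected reads; those are
merged into degeneracy groups (e.g. a blunt end at 3|4 cannot be discerned
from certain 2-nt 5'/3' overhangs when base 4 complements base 3).

Observed reads are aligned against the blunt-at-3|4 reference with the
package's semi-global aligner, filtered (alignment >= 50 bp, <= 5 gap
columns, spanning >= 50 bp around the target), reduced to the pattern of
changes within a 30-bp window around the apex, optionally stripped of
substitutions (bisulfite-conversion noise is substitution-like), and
matched exactly against the enumerated group patterns.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass

import pandas as pd

from .readcall import AlignmentParams, align_semi_global, revcomp

__all__ = [
    "EndStructure",
    "EndPattern",
    "StructureCatalog",
    "enumerate_structures",
    "expected_hairpin_read",
    "blunt_reference",
    "extract_end_pattern",
    "mask_substitutions",
    "match_and_rank",
]

BLUNT_JUNCTION = 3


@dataclass(frozen=True)
class EndStructure:
    """A DSB end conformation given by its strand termini.

    ``t_terminus`` / ``nt_terminus`` are junctions upstream of the PAM on
    the target / non-target strand.  The offset ``nt - t`` classifies the
    end: 0 blunt, positive k a k-nt 5' overhang, negative k a k-nt 3'
    overhang.
    """

    t_terminus: int
    nt_terminus: int

    @property
    def offset(self) -> int:
        return self.nt_terminus - self.t_terminus

    @property
    def classification(self) -> str:
        if self.offset == 0:
            return "blunt"
        kind = "5p" if self.offset > 0 else "3p"
        return f"{kind}_{abs(self.offset)}nt_overhang"

    @property
    def label(self) -> str:
        def _j(j: int) -> str:
            return f"{j}|{j + 1}"

        return f"({_j(self.t_terminus)}t, {_j(self.nt_terminus)}nt)"


def expected_hairpin_read(
    duplex: str, pam_index: int, structure: EndStructure
) -> str:
    """Expected hairpin read of the PAM-proximal fragment for a structure."""
    t = pam_index - structure.t_terminus
    nt = pam_index - structure.nt_terminus
    if not (0 <= t <= len(duplex) and 0 <= nt <= len(duplex)):
        raise ValueError(f"structure {structure.label} outside the duplex")
    return revcomp(duplex[t:]) + duplex[nt:]


def blunt_reference(duplex: str, pam_index: int) -> str:
    """The blunt-at-3|4 hairpin read (the matching reference)."""
    return expected_hairpin_read(
        duplex, pam_index, EndStructure(BLUNT_JUNCTION, BLUNT_JUNCTION)
    )


def apex_position(duplex: str, pam_index: int) -> int:
    """Index of the hairpin apex in the blunt reference."""
    return len(duplex) - (pam_index - BLUNT_JUNCTION)


# ---------------------------------------------------------------------------
# Pattern extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndPattern:
    """Indel/substitution signature of a hairpin read relative to the blunt
    reference, restricted to the window around the apex.

    ``ops`` are ("del", ref_start, seq) / ("ins", ref_bond, seq) tuples and
    ``substitutions`` (ref_pos, ref_base, read_base), both 3'-normalized by
    the aligner.
    """

    ops: tuple
    substitutions: tuple

    @property
    def is_reference(self) -> bool:
        return not self.ops and not self.substitutions

    def masked(self) -> "EndPattern":
        return EndPattern(ops=self.ops, substitutions=())

    def key(self, masked: bool = False) -> tuple:
        return self.ops if masked else (self.ops, self.substitutions)


def mask_substitutions(pattern: EndPattern):
    """Drop substitution records (indels untouched); idempotent.

    Returns ``(masked pattern, per-substitution-type counts)`` so bisulfite
    noise (primarily T->C on the converted strand) can be reported.
    """
    stats = collections.Counter(f"{r}>{q}" for _, r, q in pattern.substitutions)
    return pattern.masked(), dict(stats)


def extract_end_pattern(
    read: str,
    reference: str,
    apex: int,
    window: int = 30,
    min_alignment_length: int = 50,
    max_gaps: int = 5,
    min_span: int = 50,
    params: AlignmentParams | None = None,
):
    """Align a hairpin read to the blunt reference and isolate its pattern.

    Returns ``(EndPattern, None)`` or ``(None, reason)`` with reason in
    {"short_alignment", "too_many_gaps", "short_span"}.  The pattern keeps
    only operations within the ``window`` bp centered on the apex.
    """
    if read == reference:
        return EndPattern(ops=(), substitutions=()), None
    aln = align_semi_global(read, reference, params)
    if aln.n_columns < min_alignment_length:
        return None, "short_alignment"
    if aln.n_gap_columns > max_gaps:
        return None, "too_many_gaps"
    half_span = min_span // 2
    if aln.ref_start > apex - half_span or aln.ref_end < apex + half_span:
        return None, "short_span"
    half = window // 2
    lo, hi = apex - half, apex + half
    ops = tuple(op for op in aln.ops if lo <= op[1] < hi)
    subs = tuple(s for s in aln.substitutions if lo <= s[0] < hi)
    return EndPattern(ops=ops, substitutions=subs), None


# ---------------------------------------------------------------------------
# Enumeration and degeneracy grouping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureGroup:
    """Structures whose expected hairpin reads are literally identical."""

    members: tuple  # EndStructure, deterministic order
    sequence: str
    pattern: EndPattern

    @property
    def label(self) -> str:
        return " = ".join(m.label for m in self.members)


@dataclass
class StructureCatalog:
    duplex: str
    pam_index: int
    window: int
    groups: list

    def group_of(self, structure: EndStructure):
        for g in self.groups:
            if structure in g.members:
                return g
        return None

    def pattern_index(self, masked: bool = False) -> dict:
        """Map pattern key -> group label.  Under masking, groups whose
        patterns collapse onto the same indel-only key are merged."""
        index: dict = {}
        for g in self.groups:
            key = g.pattern.key(masked=masked)
            index.setdefault(key, []).append(g.label)
        return {k: " = ".join(sorted(v)) for k, v in index.items()}


def enumerate_structures(
    duplex: str,
    pam_index: int,
    window: int = 30,
    max_overhang: int = 14,
    params: AlignmentParams | None = None,
) -> StructureCatalog:
    """Enumerate all end conformations within the window and group them.

    Termini range over junctions within ``window // 2`` of the canonical
    blunt junction 3|4, restricted to |offset| <= ``max_overhang`` and to
    termini representable in the duplex.  Each structure's expected read is
    built, and structures with identical expected sequences are merged into
    one degeneracy group whose pattern is extracted with the same aligner
    used for observed reads.
    """
    half = window // 2
    if max_overhang > window:
        raise ValueError("max_overhang may not exceed the enumeration window")
    reference = blunt_reference(duplex, pam_index)
    apex = apex_position(duplex, pam_index)
    by_sequence: dict[str, list[EndStructure]] = {}
    for t in range(BLUNT_JUNCTION - half, BLUNT_JUNCTION + half + 1):
        for nt in range(BLUNT_JUNCTION - half, BLUNT_JUNCTION + half + 1):
            if abs(nt - t) > max_overhang:
                continue
            if not (0 <= pam_index - t <= len(duplex)):
                continue
            if not (0 <= pam_index - nt <= len(duplex)):
                continue
            s = EndStructure(t, nt)
            by_sequence.setdefault(expected_hairpin_read(duplex, pam_index, s), []).append(s)
    groups = []
    for seq, members in by_sequence.items():
        pattern, reason = extract_end_pattern(
            seq, reference, apex, window=window, params=params,
            # enumeration reads are clean; keep the span filters permissive
            min_alignment_length=0, max_gaps=10**9, min_span=0,
        )
        assert pattern is not None, reason
        members = tuple(sorted(members, key=lambda m: (m.t_terminus, m.nt_terminus)))
        groups.append(StructureGroup(members=members, sequence=seq, pattern=pattern))
    groups.sort(key=lambda g: (g.members[0].t_terminus, g.members[0].nt_terminus))
    return StructureCatalog(duplex=duplex, pam_index=pam_index, window=window, groups=groups)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def match_and_rank(
    patterns,
    catalog: StructureCatalog,
    masked: bool = True,
) -> pd.DataFrame:
    """Match observed patterns against enumerated degeneracy groups.

    ``patterns`` is an iterable of :class:`EndPattern`.  With ``masked``
    (the default) substitutions are ignored on both sides, as bisulfite
    noise would otherwise split valid matches; with ``masked=False`` the
    raw patterns are matched as-is.  Returns a frequency table over groups
    plus an ``"other"`` bin; frequencies sum to 1 over all rows.
    """
    index = catalog.pattern_index(masked=masked)
    counts: collections.Counter = collections.Counter()
    total = 0
    for p in patterns:
        total += 1
        key = p.key(masked=masked)
        counts[index.get(key, "other")] += 1
    rows = []
    for label, n in counts.most_common():
        rows.append({"group": label, "count": n, "frequency": n / total if total else 0.0})
    df = pd.DataFrame(rows, columns=["group", "count", "frequency"])
    return df
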