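"""Resolution of 1-bp insertion-site ambiguity under Cas9 cleavage models.

A 1-bp insertion next to an identical wild-type base cannot be placed
uniquely: inserting A before or after a wild-type A yields the same mutated
sequence.  Deterministic callers pile such events onto one junction of the
run (here the 3'-most).  This module groups junctions into maximal ambiguity
windows per inserted base, accumulates observed counts into an
:class:`InsertionCountTable`, and redistributes the ambiguous window counts
under three cleavage/repair models:

* **blunt** — template-independent insertion at a blunt end (canonically at
  junction 3|4): window counts follow the relative proportions of
  unambiguous insertions (all four bases) at each junction.
* **staggered** — template-dependent fill-in of a 1-nt 5' overhang with
  termini 3|4 (tDNA) / 4|5 (ntDNA): junctions whose downstream (PAM-ward)
  ntDNA base equals the inserted base are *likely*; each *unlikely* junction
  is assigned the mean of the unambiguous counts of the other three bases at
  that junction, and the remaining window count goes to likely junctions in
  proportion to unambiguous counts.  A negative remainder is clamped to 0
  and reported.
* **combined** — blunt at 3|4 plus staggered at 4|5: a window containing a
  likely junction 4|5 follows the staggered rule; every other window follows
  the blunt proportional rule.

Junction ``j|j+1`` counts bonds upstream of the PAM on the ntDNA; the
analyzed range is 0|1 .. 8|9 (PAM plus 8 bp upstream).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AmbiguityWindow",
    "InsertionCountTable",
    "CleavageModel",
    "find_ambiguity_windows",
    "string_insertion_groups",
    "redistribute_counts",
    "expected_profile",
    "model_concordance",
]

BASES = "ACGT"
JUNCTIONS = tuple(range(0, 9))  # junction j|j+1 for j in 0..8


def junction_label(j: int) -> str:
    return f"{j}|{j + 1}"


# ---------------------------------------------------------------------------
# Ambiguity windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmbiguityWindow:
    """Maximal set of consecutive junctions at which inserting ``base``
    yields literally identical mutated sequences."""

    base: str
    junctions: tuple  # PAM-relative junction indices, ascending

    def __post_init__(self) -> None:
        js = self.junctions
        if not js or any(b - a != 1 for a, b in zip(js, js[1:])):
            raise ValueError("window junctions must be non-empty and consecutive")


def string_insertion_groups(seq: str):
    """Brute-force oracle-style grouping of insertion junctions by result.

    For every base, every string insertion index 0..len(seq) is grouped by
    the resulting mutated string.  Returns {base: [sorted index groups]}.
    """
    out = {}
    for b in BASES:
        results: dict[str, list[int]] = {}
        for i in range(len(seq) + 1):
            results.setdefault(seq[:i] + b + seq[i:], []).append(i)
        out[b] = sorted(tuple(sorted(v)) for v in results.values())
    return out


def find_ambiguity_windows(ntref: str, pam_index: int, junctions=JUNCTIONS):
    """Ambiguity windows per base over the analyzed junction range.

    ``ntref`` is the ntDNA-oriented sequence; ``pam_index`` the index of the
    first PAM base.  Insertion at junction ``j|j+1`` corresponds to string
    index ``pam_index - j``.  A run of ``k`` identical bases induces a
    window of ``k+1`` junctions; windows are clipped to the analyzed range.

    Returns ``(windows, unambiguous)`` where ``windows`` is a list of
    :class:`AmbiguityWindow` (multi-junction only, after clipping) and
    ``unambiguous`` maps base -> tuple of junctions where inserting that
    base is unambiguous.
    """
    return _find_ambiguity_windows_cached(ntref, pam_index, tuple(junctions))


@functools.lru_cache(maxsize=512)
def _find_ambiguity_windows_cached(ntref: str, pam_index: int, junctions):
    jmin, jmax = min(junctions), max(junctions)
    windows = []
    unambiguous = {b: [] for b in BASES}
    for b in BASES:
        # group string indices by identical mutated sequence, then map to
        # junction space and clip
        claimed = set()
        for group in string_insertion_groups(ntref)[b]:
            js = sorted(pam_index - i for i in group)
            js = [j for j in js if jmin <= j <= jmax]
            if not js:
                continue
            if len(js) == 1:
                unambiguous[b].append(js[0])
            else:
                windows.append(AmbiguityWindow(base=b, junctions=tuple(js)))
            claimed.update(js)
    unambiguous = {b: tuple(sorted(v)) for b, v in unambiguous.items()}
    windows.sort(key=lambda w: (w.base, w.junctions))
    return windows, unambiguous


def window_for(ntref: str, pam_index: int, base: str, junction: int, junctions=JUNCTIONS):
    """The (possibly singleton) clipped window containing ``junction`` for
    ``base``; None if the junction is outside the analyzed range."""
    jmin, jmax = min(junctions), max(junctions)
    if not jmin <= junction <= jmax:
        return None
    windows, unamb = find_ambiguity_windows(ntref, pam_index, junctions)
    for w in windows:
        if w.base == base and junction in w.junctions:
            return w
    if junction in unamb[base]:
        return AmbiguityWindow(base=base, junctions=(junction,))
    return None


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------


@dataclass
class InsertionCountTable:
    """Per-junction, per-base 1-bp insertion counts for one guide/assay.

    ``unambiguous[(j, base)]`` holds counts placed uniquely; ``windows``
    maps each multi-junction :class:`AmbiguityWindow` to its accumulated
    ambiguous count.
    """

    guide: str
    ntref: str
    pam_index: int
    unambiguous: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    outside: int = 0

    @property
    def total(self) -> float:
        return sum(self.unambiguous.values()) + sum(self.windows.values())

    def add(self, base: str, junction: int) -> None:
        """Record one 1-bp insertion of ``base`` reported at ``junction``.

        The reported junction may be either edge of its ambiguity window
        (caller convention independent): counts enter as window totals.
        """
        w = window_for(self.ntref, self.pam_index, base, junction)
        if w is None:
            self.outside += 1
            return
        if len(w.junctions) == 1:
            key = (w.junctions[0], base)
            self.unambiguous[key] = self.unambiguous.get(key, 0) + 1
        else:
            self.windows[w] = self.windows.get(w, 0) + 1

    @classmethod
    def from_events(cls, guide: str, ntref: str, pam_index: int, events):
        """Build from an iterable of (base, reported junction) events."""
        table = cls(guide=guide, ntref=ntref, pam_index=pam_index)
        for base, junction in events:
            table.add(base, junction)
        return table

    def unambiguous_matrix(self) -> pd.DataFrame:
        mat = pd.DataFrame(0.0, index=list(JUNCTIONS), columns=list(BASES))
        for (j, b), c in self.unambiguous.items():
            mat.loc[j, b] += c
        return mat

    def to_frame(self) -> pd.DataFrame:
        """Tidy TSV-ready view: junction label, base, count, window id."""
        rows = []
        for (j, b), c in sorted(self.unambiguous.items()):
            rows.append({"junction": junction_label(j), "base": b, "count": c, "window": ""})
        for i, (w, c) in enumerate(sorted(self.windows.items(), key=lambda x: (x[0].base, x[0].junctions))):
            wid = f"{w.base}:{junction_label(w.junctions[0])}-{junction_label(w.junctions[-1])}"
            rows.append({"junction": wid, "base": w.base, "count": c, "window": wid})
        return pd.DataFrame(rows, columns=["junction", "base", "count", "window"])


# ---------------------------------------------------------------------------
# Models and redistribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CleavageModel:
    """A Cas9 cleavage/repair model.

    blunt: blunt ends at junction 3|4, template-independent insertions.
    staggered: 1-nt 5' overhang with termini 3|4 (tDNA) / 4|5 (ntDNA);
    fill-in duplicates ntDNA nucleotide 4.  combined: both.
    """

    kind: str
    blunt_junction: int = 3
    staggered_junction: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("blunt", "staggered", "combined"):
            raise ValueError(f"unknown cleavage model {self.kind!r}")


def _downstream_base(table: InsertionCountTable, junction: int) -> str:
    """ntDNA base immediately downstream (toward the PAM) of a junction:
    the base at PAM-relative position ``junction``."""
    return table.ntref[table.pam_index - junction]


def _proportional(count: float, weights: np.ndarray) -> np.ndarray:
    total = weights.sum()
    if total <= 0:
        return np.full(len(weights), count / len(weights))
    return count * weights / total


def redistribute_counts(table: InsertionCountTable, model: CleavageModel):
    """Redistribute ambiguous window counts under a cleavage model.

    Returns ``(counts, diagnostics)`` where ``counts`` is a junction x base
    DataFrame of redistributed counts and ``diagnostics`` records clamped
    staggered remainders.  Totals are conserved exactly except where a
    negative staggered remainder was clamped to zero (reported).
    """
    if not isinstance(model, CleavageModel):
        model = CleavageModel(kind=str(model))
    counts = table.unambiguous_matrix()
    unamb_totals = counts.sum(axis=1)  # per-junction totals over all bases
    clamped = []
    for w, c in table.windows.items():
        js = np.array(w.junctions)
        weights = unamb_totals.loc[js].to_numpy(dtype=float)
        if model.kind == "blunt":
            shares = _proportional(float(c), weights)
        else:
            likely = np.array([_downstream_base(table, j) == w.base for j in js])
            staggered_window = likely.any() and (
                model.kind == "staggered"
                or (model.staggered_junction in w.junctions
                    and _downstream_base(table, model.staggered_junction) == w.base)
            )
            if not staggered_window:
                shares = _proportional(float(c), weights)
            else:
                shares = np.zeros(len(js))
                other = [b for b in BASES if b != w.base]
                for idx, j in enumerate(js):
                    if not likely[idx]:
                        shares[idx] = counts.loc[j, other].mean()
                remainder = float(c) - shares[~likely].sum()
                if remainder < 0:
                    clamped.append(
                        {"base": w.base,
                         "junctions": [junction_label(j) for j in w.junctions],
                         "count": c, "deficit": -remainder}
                    )
                    remainder = 0.0
                if likely.any():
                    shares[likely] = _proportional(remainder, weights[likely])
        for idx, j in enumerate(js):
            counts.loc[j, w.base] += shares[idx]
    diagnostics = {
        "model": model.kind,
        "clamped_windows": clamped,
        "input_total": table.total,
        "output_total": float(counts.to_numpy().sum()),
        "outside_range": table.outside,
    }
    return counts, diagnostics


def expected_profile(model: CleavageModel, ntref: str, pam_index: int) -> pd.DataFrame:
    """Qualitative model-expected per-junction base distribution.

    blunt: uniform base mass at 3|4; staggered: all mass on the ntDNA
    position-4 base at 4|5; combined: both signatures.  Values are relative
    weights per junction (each targeted junction sums to 1).
    """
    if not isinstance(model, CleavageModel):
        model = CleavageModel(kind=str(model))
    prof = pd.DataFrame(0.0, index=list(JUNCTIONS), columns=list(BASES))
    base4 = ntref[pam_index - 4]
    if model.kind in ("blunt", "combined"):
        prof.loc[model.blunt_junction, :] = 0.25
    if model.kind in ("staggered", "combined"):
        prof.loc[model.staggered_junction, base4] = 1.0
    return prof


def model_concordance(
    counts: pd.DataFrame,
    model: CleavageModel,
    ntref: str,
    pam_index: int,
    uniform_alpha: float = 0.05,
    modal_share_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-junction fit summary against a model's qualitative signature.

    For each junction with counts: the modal base and its share, a chi-square
    uniformity p-value over the four bases, and concordance flags — a blunt
    signature is a uniform distribution at the blunt junction, a staggered
    signature a dominant position-4 base at the staggered junction.  This
    statistic describes fit only; it does not estimate blunt:staggered
    mixture fractions.
    """
    if not isinstance(model, CleavageModel):
        model = CleavageModel(kind=str(model))
    base4 = ntref[pam_index - 4]
    rows = []
    for j in counts.index:
        vec = counts.loc[j].to_numpy(dtype=float)
        total = vec.sum()
        if total <= 0:
            continue
        modal = counts.columns[int(np.argmax(vec))]
        share = float(vec.max() / total)
        p_uniform = float(stats.chisquare(vec).pvalue) if total > 0 else np.nan
        row = {
            "junction": junction_label(int(j)),
            "total": total,
            "modal_base": modal,
            "modal_share": share,
            "uniformity_p": p_uniform,
        }
        if model.kind in ("blunt", "combined") and j == model.blunt_junction:
            row["concordant_blunt"] = bool(p_uniform > uniform_alpha)
        if model.kind in ("staggered", "combined") and j == model.staggered_junction:
            row["concordant_staggered"] = bool(
                modal == base4 and share > modal_share_threshold
            )
        rows.append(row)
    return pd.DataFrame(rows)
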