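"""Aggregation of molecule-level calls into per-IR outcome statistics.

Frequencies are computed per integrated reporter (IR) as the fraction of
molecules in each outcome class among all molecules for that IR, after
excluding IRs below the coverage threshold in any assay of the comparison
set.  Also provided: indel size spectra, deletion-boundary frequencies
around the expected (3|4) and alternative (4|5) break sites with
ambiguity-weighted placement, per-IR 1-bp inserted-base distributions, and
barcode-count expression normalization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .readcall import MutationCall, TargetFrame

__all__ = [
    "compute_profiles",
    "size_spectra",
    "deletion_boundary_frequencies",
    "insertion_base_distribution",
    "compute_ir_expression",
    "one_bp_insertion_events",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("wild_type", "deletion", "insertion", "complex")
MIN_COVERAGE = 30
BASES = "ACGT"


def _flatten_replicates(calls):
    """Accept a flat call list or a list of replicate call lists; replicates
    are merged by pooling counts (never by averaging frequencies)."""
    if not calls:
        return []
    if isinstance(calls[0], MutationCall):
        return list(calls)
    pooled = []
    for replicate in calls:
        pooled.extend(replicate)
    return pooled


def compute_profiles(calls_by_assay: dict, min_coverage: int = MIN_COVERAGE) -> pd.DataFrame:
    """Per-IR, per-assay outcome frequencies over UID-collapsed molecules.

    IRs whose molecule count falls below ``min_coverage`` in *any* assay are
    excluded from every assay, so all comparisons run over one IR set.
    Returns a tidy DataFrame with one row per (assay, barcode).
    """
    if not calls_by_assay or all(not v for v in calls_by_assay.values()):
        logger.warning("empty call set; returning empty profile table")
        return pd.DataFrame(
            columns=["assay", "barcode", "coverage", *OUTCOMES,
                     "knockin_freq", "error_insertion_freq", "total_mut_freq"]
        )
    counts: dict = {}
    for assay, calls in calls_by_assay.items():
        for call in _flatten_replicates(calls):
            key = (assay, call.barcode)
            bucket = counts.setdefault(key, {o: 0 for o in OUTCOMES} | {"knockin": 0})
            bucket[call.outcome] += 1
            if call.knockin:
                bucket["knockin"] += 1
    barcodes_per_assay = {}
    for (assay, bc), bucket in counts.items():
        cov = sum(bucket[o] for o in OUTCOMES)
        barcodes_per_assay.setdefault(assay, {})[bc] = cov
    kept = None
    for assay, covs in barcodes_per_assay.items():
        ok = {bc for bc, c in covs.items() if c >= min_coverage}
        kept = ok if kept is None else kept & ok
    kept = kept or set()
    rows = []
    for (assay, bc), bucket in sorted(counts.items()):
        if bc not in kept:
            continue
        cov = sum(bucket[o] for o in OUTCOMES)
        row = {"assay": assay, "barcode": bc, "coverage": cov}
        for o in OUTCOMES:
            row[o] = bucket[o] / cov
        row["knockin_freq"] = bucket["knockin"] / cov
        row["error_insertion_freq"] = row["insertion"] - row["knockin_freq"]
        row["total_mut_freq"] = 1.0 - row["wild_type"]
        rows.append(row)
    return pd.DataFrame(rows)


def size_spectra(calls) -> dict:
    """Deletion/insertion size frequency tables over single-indel calls.

    Returns {"deletion": DataFrame, "insertion": DataFrame,
    "fraction_deletions_lt10": float, "fraction_insertions_1bp": float};
    each table's frequencies sum to 1 over observed sizes.
    """
    del_sizes = [c.deletions[0].size for c in calls if c.outcome == "deletion"]
    ins_sizes = [c.insertions[0].size for c in calls if c.outcome == "insertion"]

    def _table(sizes):
        if not sizes:
            return pd.DataFrame(columns=["size", "count", "frequency"])
        vc = pd.Series(sizes).value_counts().sort_index()
        return pd.DataFrame(
            {"size": vc.index, "count": vc.values, "frequency": vc.values / len(sizes)}
        )

    return {
        "deletion": _table(del_sizes),
        "insertion": _table(ins_sizes),
        "fraction_deletions_lt10": (
            float(np.mean([s < 10 for s in del_sizes])) if del_sizes else float("nan")
        ),
        "fraction_insertions_1bp": (
            float(np.mean([s == 1 for s in ins_sizes])) if ins_sizes else float("nan")
        ),
    }


def _boundary_junctions(frame: TargetFrame, start: int, size: int):
    """PAM-relative junctions at the two boundaries of a deletion placement
    given in reference coordinates."""
    left = frame.bond_to_junction(frame.ref_bond_to_nt(start))
    right = frame.bond_to_junction(frame.ref_bond_to_nt(start + size))
    return left, right


def deletion_boundary_frequencies(
    calls,
    frame: TargetFrame,
    junctions=(3, 4),
) -> tuple[pd.DataFrame, dict]:
    """Frequency of deletions neighboring the expected/alternative cut sites.

    A deletion placement neighbors junction ``j|j+1`` when one of its two
    boundaries coincides with that junction.  A deletion with ``k``
    equivalent placements of which ``m`` neighbor the junction contributes
    weight ``m/k`` — ambiguous deletions are weighted down by the ratio of
    placements meeting the criterion.  Returns (per-pattern table, overall
    summary); frequencies are relative to all deletion calls.
    """
    for j in junctions:
        if not 0 <= j <= 19:
            raise ValueError(f"junction {j}|{j + 1} outside the protospacer")
    dels = [c.deletions[0] for c in calls if c.outcome == "deletion"]
    if not dels:
        return pd.DataFrame(columns=["pattern", "count", "frequency",
                                     *(f"freq_neighbor_{j}|{j+1}" for j in junctions)]), {
            "total": 0}
    patterns: dict = {}
    for d in dels:
        window = d.window
        key = (d.sequence, window)
        rec = patterns.setdefault(key, {"count": 0, **{j: 0.0 for j in junctions}})
        rec["count"] += 1
        k = len(window)
        for j in junctions:
            m = sum(
                1 for p in window if j in _boundary_junctions(frame, p, d.size)
            )
            rec[j] += m / k
    n = len(dels)
    rows = []
    for (seq, window), rec in sorted(patterns.items(), key=lambda kv: -kv[1]["count"]):
        row = {
            "pattern": seq,
            "placements": len(window),
            "count": rec["count"],
            "frequency": rec["count"] / n,
        }
        for j in junctions:
            row[f"freq_neighbor_{j}|{j+1}"] = rec[j] / n
        rows.append(row)
    table = pd.DataFrame(rows)
    overall = {"total": n, "frequency": 1.0}
    for j in junctions:
        overall[f"freq_neighbor_{j}|{j+1}"] = float(
            sum(rec[j] for rec in patterns.values()) / n
        )
    return table, overall


def one_bp_insertion_events(calls, frame: TargetFrame):
    """(base, PAM-relative junction) pairs for all 1-bp insertion calls.

    The reported junction is the caller's normalized placement converted
    into the ntDNA frame; downstream model code re-derives the full
    ambiguity window, so either caller convention yields identical tables.
    """
    events = []
    for c in calls:
        if c.outcome != "insertion" or c.knockin:
            continue
        ins = c.insertions[0]
        if ins.size != 1:
            continue
        junction = frame.bond_to_junction(frame.ref_bond_to_nt(ins.position))
        base = ins.sequence if frame.guide.orientation == "sense" else ins.sequence.translate(
            str.maketrans("ACGT", "TGCA")
        )
        events.append((base, junction))
    return events


def insertion_base_distribution(calls_by_barcode: dict) -> tuple[pd.DataFrame, pd.Series]:
    """Per-IR inserted-base fractions among 1-bp (non-knock-in) insertions.

    ``calls_by_barcode`` maps barcode -> call list.  IRs without 1-bp
    insertions are omitted.  Returns (per-IR table, pooled assay-level
    distribution).
    """
    rows = {}
    pooled = {b: 0 for b in BASES}
    for bc, calls in calls_by_barcode.items():
        counts = {b: 0 for b in BASES}
        for c in calls:
            if c.outcome != "insertion" or c.knockin:
                continue
            ins = c.insertions[0]
            if ins.size != 1:
                continue
            counts[ins.sequence] += 1
            pooled[ins.sequence] += 1
        total = sum(counts.values())
        if total:
            rows[bc] = {b: counts[b] / total for b in BASES}
    per_ir = pd.DataFrame.from_dict(rows, orient="index", columns=list(BASES))
    total = sum(pooled.values())
    summary = pd.Series(
        {b: (pooled[b] / total if total else float("nan")) for b in BASES}
    )
    return per_ir, summary


def compute_ir_expression(cdna_counts, gdna_counts) -> pd.Series:
    """log2((cDNA + 1) / (gDNA + 1)) per barcode.

    IRs with zero gDNA count are excluded; barcodes present in cDNA but
    absent from the gDNA table are excluded with a warning.  Barcodes with
    zero cDNA stay finite through the pseudocount.
    """
    cdna = pd.Series(cdna_counts, dtype=float)
    gdna = pd.Series(gdna_counts, dtype=float)
    missing = cdna.index.difference(gdna.index)
    if len(missing):
        logger.warning("%d cDNA barcodes absent from gDNA table; excluded", len(missing))
    kept = gdna.index[gdna > 0]
    c = cdna.reindex(kept).fillna(0.0)
    g = gdna.loc[kept]
    return np.log2((c + 1.0) / (g + 1.0))
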