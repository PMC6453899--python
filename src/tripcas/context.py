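"""Association of per-IR responses with genomic/epigenomic feature tracks.

Each feature track scores genomic intervals (bedGraph-like: chromosome,
start, end, score; 0-based half-open).  For every reporter integration the
track is aggregated as the base-weighted mean score over a 2 kb window
centered on the integration site; the aggregated feature matrix is then
correlated (Pearson) with per-IR responses such as deletion frequency,
insertion frequency or expression, with Benjamini-Hochberg adjustment
across the full association table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTrack",
    "read_track",
    "aggregate_feature_window",
    "feature_matrix",
    "correlate_features",
]

logger = logging.getLogger(__name__)

WINDOW = 2000  # bp centered on the integration site


@dataclass
class FeatureTrack:
    """A named genome-wide score track over non-overlapping intervals."""

    name: str
    data: pd.DataFrame  # columns: chromosome, start, end, score
    category: str = "unspecified"
    normalization: str = ""

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end", "score"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"track {self.name} missing columns {required - set(self.data.columns)}")
        if not np.isfinite(self.data["score"].to_numpy(dtype=float)).all():
            raise ValueError(f"track {self.name} has non-finite scores")
        for chrom, sub in self.data.groupby("chromosome"):
            s = sub.sort_values("start")
            if (s["end"].to_numpy()[:-1] > s["start"].to_numpy()[1:]).any():
                raise ValueError(f"track {self.name} has overlapping intervals on {chrom}")


def read_track(path, name=None, category="unspecified") -> FeatureTrack:
    """Read a bedGraph / 4-column TSV track (chrom, start, end, score)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chromosome", "start", "end", "score"], header=None,
    )
    if df.iloc[0]["chromosome"] == "chromosome":  # tolerate a header line
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["score"] = df["score"].astype(float)
    return FeatureTrack(name=name or str(path), data=df, category=category)


def aggregate_feature_window(track: FeatureTrack, locus, window: int = WINDOW) -> float:
    """Base-weighted mean track score over the window around a locus.

    The window is ``[pos - window/2, pos + window/2)``; positions without
    track data are ignored and an all-missing window yields NaN.
    """
    chrom, pos = locus[0], locus[1]
    lo, hi = pos - window // 2, pos + window // 2
    sub = track.data[track.data["chromosome"] == chrom]
    if sub.empty:
        logger.warning("locus chromosome %s absent from track %s", chrom, track.name)
        return float("nan")
    sel = sub[(sub["end"] > lo) & (sub["start"] < hi)]
    if sel.empty:
        return float("nan")
    lengths = np.minimum(sel["end"].to_numpy(), hi) - np.maximum(sel["start"].to_numpy(), lo)
    scores = sel["score"].to_numpy(dtype=float)
    return float(np.sum(scores * lengths) / np.sum(lengths))


def feature_matrix(tracks, loci, window: int = WINDOW) -> pd.DataFrame:
    """Aggregate many tracks over many loci: one row per locus, one column
    per track.  ``tracks`` maps name -> FeatureTrack; ``loci`` maps IR id
    -> (chromosome, position, strand)."""
    data = {}
    for name, track in tracks.items():
        data[name] = [aggregate_feature_window(track, locus, window) for locus in loci.values()]
    return pd.DataFrame(data, index=list(loci.keys()))


def correlate_features(
    responses: pd.DataFrame,
    features: pd.DataFrame,
    min_irs: int = 10,
) -> pd.DataFrame:
    """Pearson correlation of every (response, feature) pair with BH control.

    Both inputs are indexed by IR; rows are matched on the shared index.
    Zero-variance features are skipped (logged).  Returns a table with
    columns (response, feature, n, r, p, q); q-values come from one
    Benjamini-Hochberg family over all tested pairs.
    """
    shared = responses.index.intersection(features.index)
    if len(shared) < min_irs:
        raise ValueError(f"need at least {min_irs} shared IRs, got {len(shared)}")
    resp = responses.loc[shared]
    feat = features.loc[shared]
    rows = []
    for rname in resp.columns:
        y = resp[rname].to_numpy(dtype=float)
        for fname in feat.columns:
            x = feat[fname].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_irs:
                continue
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                logger.info("skipping zero-variance pair (%s, %s)", rname, fname)
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append(
                {"response": rname, "feature": fname, "n": int(ok.sum()),
                 "r": float(r), "p": float(p)}
            )
    table = pd.DataFrame(rows, columns=["response", "feature", "n", "r", "p"])
    if not table.empty:
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q"] = pd.Series(dtype=float)
    return table
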