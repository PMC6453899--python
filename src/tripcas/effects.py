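"""Determinants of per-IR mutation frequency.

Quantifies cross-assay reproducibility (pairwise OLS), factor effect sizes
(eta-squared from a multi-way ANOVA on IR locus, guide RNA, ssODN,
promoter and the locus x guide interaction), nonparametric location shifts
(Hodges-Lehmann estimate with Wilcoxon tests), and the knock-in vs
error-insertion ratio binned by total mutation frequency with bootstrap
confidence intervals.

In the reporter design every locus carries exactly one promoter, so the
promoter factor is nested in (aliased with) locus.  The decomposition fits
promoter on the between-locus contrast first and attributes the remaining
locus variation to locus, reporting the aliasing explicitly.  With the
balanced complete design required here (every IR observed in every assay)
the remaining factors are orthogonal, so these sums of squares coincide
with type-II partial sums of squares and are invariant to term order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "EffectSizes",
    "pairwise_assay_regression",
    "fit_effect_model",
    "wilcoxon_shift",
    "knockin_ratio_binned",
]


# ---------------------------------------------------------------------------
# Pairwise assay regression
# ---------------------------------------------------------------------------


def pairwise_assay_regression(freq_x, freq_y) -> dict:
    """OLS of one assay's per-IR frequencies on another's.

    Inputs are aligned per-IR vectors (or barcode-indexed Series, matched
    on the shared index).  Returns slope, intercept, R^2 and the regression
    F-test p-value (for simple regression the slope t-test is the F test).
    """
    if isinstance(freq_x, pd.Series) and isinstance(freq_y, pd.Series):
        shared = freq_x.index.intersection(freq_y.index)
        freq_x, freq_y = freq_x.loc[shared], freq_y.loc[shared]
    x = np.asarray(freq_x, dtype=float)
    y = np.asarray(freq_y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 shared IRs")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "n": len(x),
    }


# ---------------------------------------------------------------------------
# Effect-size decomposition
# ---------------------------------------------------------------------------


@dataclass
class EffectSizes:
    """eta-squared decomposition of per-IR mutation frequency."""

    r_squared: float
    eta_squared: dict
    residual_share: float
    anova: pd.DataFrame
    aliasing: str = ""

    def __post_init__(self) -> None:
        for k, v in self.eta_squared.items():
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"eta^2 out of range for {k}: {v}")
        total = sum(self.eta_squared.values()) + self.residual_share
        if total > 1 + 1e-6:
            raise ValueError(f"eta^2 shares plus residual exceed 1: {total}")


def _ssr(df: pd.DataFrame, formula: str) -> float:
    return float(smf.ols(formula, data=df).fit().ssr)


def fit_effect_model(profiles: pd.DataFrame, response: str = "total_mut_freq") -> EffectSizes:
    """Multi-way ANOVA of mutation frequency on locus, guide, ssODN,
    promoter and locus x guide.

    ``profiles`` needs columns barcode (the locus), promoter, guide, ssodn
    and the response; every IR must appear in every (guide, ssodn) assay
    cell present in the design (balanced complete factorial), which makes
    the non-nested factors orthogonal.  eta^2(factor) = SS(factor) /
    SS(total).
    """
    df = profiles.copy()
    required = {"barcode", "promoter", "guide", "ssodn", response}
    if not required.issubset(df.columns):
        raise ValueError(f"profiles missing columns {required - set(df.columns)}")
    df["ssodn"] = df["ssodn"].astype(str)
    cells = df.groupby(["guide", "ssodn"])["barcode"].agg(lambda s: frozenset(s))
    if len(set(cells)) != 1:
        raise ValueError("design is not complete: IR sets differ across assays")
    sizes = df.groupby(["guide", "ssodn", "barcode"]).size()
    if sizes.nunique() != 1:
        raise ValueError("design is not balanced: unequal replication per cell")
    levels = {f: df[f].nunique() for f in ("barcode", "promoter", "guide", "ssodn")}
    for f in ("barcode", "guide"):
        if levels[f] < 2:
            raise ValueError(f"factor {f} has a single level; model is rank-deficient")
    # nesting check: promoter constant within locus means promoter||locus
    per_locus = df.groupby("barcode")["promoter"].nunique()
    if (per_locus > 1).any():
        bad = per_locus[per_locus > 1].index.tolist()[:3]
        raise ValueError(f"promoter varies within locus (e.g. {bad}); confounding unresolvable")
    aliasing = (
        "promoter is nested in locus; promoter fitted on the between-locus "
        "contrast first, remainder attributed to locus"
    )
    y = df[response].to_numpy(dtype=float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    n = len(df)
    drop_ssodn = levels["ssodn"] < 2
    f1 = f"{response} ~ C(promoter)"
    # promoter is nested in locus, so span(promoter + locus) = span(locus);
    # using C(barcode) alone keeps every design matrix full rank
    f2 = f"{response} ~ C(barcode)"
    f3 = f2 + " + C(guide)"
    f4 = f3 if drop_ssodn else f3 + " + C(ssodn)"
    f5 = f4 + " + C(barcode):C(guide)"
    ssr1 = _ssr(df, f1)
    ssr2 = _ssr(df, f2)
    ssr3 = _ssr(df, f3)
    ssr4 = ssr3 if drop_ssodn else _ssr(df, f4)
    ssr5 = _ssr(df, f5)
    ss = {
        "promoter": ss_total - ssr1,
        "locus": ssr1 - ssr2,
        "guide": ssr2 - ssr3,
        "ssodn": ssr3 - ssr4,
        "locus:guide": ssr4 - ssr5,
    }
    dfs = {
        "promoter": levels["promoter"] - 1,
        "locus": levels["barcode"] - levels["promoter"],
        "guide": levels["guide"] - 1,
        "ssodn": 0 if drop_ssodn else levels["ssodn"] - 1,
        "locus:guide": (levels["barcode"] - 1) * (levels["guide"] - 1),
    }
    df_model = sum(dfs.values())
    df_resid = n - 1 - df_model
    ss_resid = ssr5
    rows = []
    for factor in ss:
        d = dfs[factor]
        if d <= 0:
            f_stat, p = np.nan, np.nan
        else:
            ms = ss[factor] / d
            ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
            f_stat = ms / ms_resid if ms_resid and np.isfinite(ms_resid) else np.nan
            p = float(stats.f.sf(f_stat, d, df_resid)) if np.isfinite(f_stat) else np.nan
        rows.append({"factor": factor, "ss": max(ss[factor], 0.0), "df": d,
                     "F": f_stat, "p": p})
    rows.append({"factor": "residual", "ss": ss_resid, "df": df_resid,
                 "F": np.nan, "p": np.nan})
    anova = pd.DataFrame(rows)
    eta = {f: max(ss[f], 0.0) / ss_total for f in ss}
    return EffectSizes(
        r_squared=1.0 - ss_resid / ss_total,
        eta_squared=eta,
        residual_share=ss_resid / ss_total,
        anova=anova,
        aliasing=aliasing,
    )


# ---------------------------------------------------------------------------
# Wilcoxon shifts
# ---------------------------------------------------------------------------


def _hodges_lehmann_paired(d: np.ndarray) -> float:
    i, j = np.triu_indices(len(d))
    return float(np.median((d[i] + d[j]) / 2.0))


def _hodges_lehmann_unpaired(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.median(np.subtract.outer(b, a)))


def wilcoxon_shift(
    freqs_a,
    freqs_b,
    paired: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Nonparametric shift of b relative to a with a two-tailed Wilcoxon p.

    Paired mode uses the signed-rank test and the Hodges-Lehmann estimate
    (median of Walsh averages of the differences); unpaired mode uses the
    rank-sum test and the median of pairwise differences.  The CI is a
    seeded percentile bootstrap at ``ci_level``.  All-zero paired
    differences yield shift 0 with p = 1.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    alpha = (1.0 - ci_level) / 2.0
    if paired:
        if len(a) != len(b):
            raise ValueError("paired mode requires equal-length matched vectors")
        d = b - a
        if np.all(d == 0):
            return {"shift": 0.0, "ci": (0.0, 0.0), "p": 1.0, "n": len(d),
                    "method": "wilcoxon_signed_rank"}
        shift = _hodges_lehmann_paired(d)
        p = float(stats.wilcoxon(b, a, alternative="two-sided").pvalue)
        boots = np.empty(n_boot)
        for k in range(n_boot):
            boots[k] = _hodges_lehmann_paired(d[rng.integers(0, len(d), len(d))])
        ci = (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))
        return {"shift": shift, "ci": ci, "p": p, "n": len(d),
                "method": "wilcoxon_signed_rank"}
    shift = _hodges_lehmann_unpaired(a, b)
    p = float(stats.mannwhitneyu(b, a, alternative="two-sided").pvalue)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        ra = a[rng.integers(0, len(a), len(a))]
        rb = b[rng.integers(0, len(b), len(b))]
        boots[k] = _hodges_lehmann_unpaired(ra, rb)
    ci = (float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha)))
    return {"shift": shift, "ci": ci, "p": p, "n": (len(a), len(b)),
            "method": "wilcoxon_rank_sum"}


# ---------------------------------------------------------------------------
# Knock-in vs error-insertion ratio
# ---------------------------------------------------------------------------


def knockin_ratio_binned(
    profiles: pd.DataFrame,
    bin_width: float = 0.10,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Knock-in / error-insertion ratio per IR, binned by total mutation
    frequency, with bootstrap CIs.

    IRs with zero error-insertion frequency are dropped (counted in the
    ``n_dropped`` attribute of the returned frame).  Bins are equal-width
    over [0, 1]; empty bins are reported with NaN means, never zero.
    """
    needed = {"knockin_freq", "error_insertion_freq", "total_mut_freq"}
    if not needed.issubset(profiles.columns):
        raise ValueError(f"profiles missing columns {needed - set(profiles.columns)}")
    df = profiles.copy()
    dropped = int((df["error_insertion_freq"] <= 0).sum())
    df = df[df["error_insertion_freq"] > 0]
    df["ratio"] = df["knockin_freq"] / df["error_insertion_freq"]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x81B5]))
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = df[(df["total_mut_freq"] >= lo) & (df["total_mut_freq"] < hi)]
        if sel.empty:
            rows.append({"bin_low": lo, "bin_high": hi, "n": 0,
                         "mean_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan})
            continue
        vals = sel["ratio"].to_numpy()
        boots = np.array(
            [vals[rng.integers(0, len(vals), len(vals))].mean() for _ in range(n_boot)]
        )
        rows.append(
            {"bin_low": lo, "bin_high": hi, "n": len(vals),
             "mean_ratio": float(vals.mean()),
             "ci_low": float(np.quantile(boots, alpha)),
             "ci_high": float(np.quantile(boots, 1 - alpha))}
        )
    out = pd.DataFrame(rows)
    out.attrs["n_dropped_zero_denominator"] = dropped
    return out
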