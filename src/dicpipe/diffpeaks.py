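"""MA-based quantitative comparison of peak intensity between two conditions.

For each peak matched across conditions the M value is the log2 fold change
of normalized read densities and the A value the average log2 signal
strength.  A robust linear trend M = a + b*A fitted on the common peaks
captures the condition-wide efficiency imbalance; subtracting the fitted
trend gives the normalized M value used for change classification
(increased: M > tau, decreased: M < -tau; default tau = 0.5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_TAU = 0.5
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class NormalizationFit:
    """Linear trend of raw M on A over the matched common peaks."""

    a: float                 # intercept
    b: float                 # slope
    n_common: int
    method: str = "theilsen"

    def predict(self, A: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.asarray(A, dtype=float)


# ---------------------------------------------------------------------------
# Peak matching
# ---------------------------------------------------------------------------

def _overlap_len(s1, e1, s2, e2) -> int:
    return max(0, min(e1, e2) - max(s1, s2))


def match_common_peaks(set1: pd.DataFrame, set2: pd.DataFrame,
                       min_overlap: int = 1) -> pd.DataFrame:
    """Match peaks across two condition-specific site tables.

    Each peak pairs with at most one partner: the greatest-overlap partner
    wins, ties broken by the leftmost partner.  The returned union table has
    one row per matched pair plus one per condition-unique peak, carrying
    both conditions' counts (missing side imputed as 0; the pseudocount is
    added downstream).

    Columns: chrom, start, end (of the condition-1 peak when matched, else
    the unique peak), name, count_a, count_b, matched (bool).
    """
    for tag, df in (("set1", set1), ("set2", set2)):
        if len(df) == 0:
            raise ValueError(f"{tag} is empty")

    s1 = set1.reset_index(drop=True)
    s2 = set2.reset_index(drop=True)
    c1 = "count_a" if "count_a" in s1.columns else "count"
    c2 = "count_b" if "count_b" in s2.columns else "count"

    # candidate pairs per chromosome by sorted sweep
    pairs = []  # (i1, i2, overlap)
    for chrom in sorted(set(s1["chrom"]) | set(s2["chrom"])):
        a = s1[s1["chrom"] == chrom]
        b = s2[s2["chrom"] == chrom].sort_values("start")
        if a.empty or b.empty:
            continue
        b_starts = b["start"].to_numpy()
        b_ends = b["end"].to_numpy()
        b_idx = b.index.to_numpy()
        for i1, row in a.iterrows():
            hit = np.nonzero((b_starts < row["end"]) & (b_ends > row["start"]))[0]
            for k in hit.tolist():
                ov = _overlap_len(row["start"], row["end"],
                                  b_starts[k], b_ends[k])
                if ov >= min_overlap:
                    pairs.append((i1, b_idx[k], ov))

    # greedy greatest-overlap matching; ties -> leftmost partner
    start2 = s2["start"].to_dict()
    pairs.sort(key=lambda t: (-t[2], start2[t[1]], t[0]))
    used1: set[int] = set()
    used2: set[int] = set()
    matched: list[tuple[int, int]] = []
    for i1, i2, _ in pairs:
        if i1 in used1 or i2 in used2:
            continue
        used1.add(i1)
        used2.add(i2)
        matched.append((i1, i2))

    rows = []
    for i1, i2 in matched:
        r1, r2 = s1.loc[i1], s2.loc[i2]
        rows.append((r1["chrom"], int(r1["start"]), int(r1["end"]),
                     str(r1.get("name", f"peak1_{i1}")),
                     float(r1[c1]), float(r2[c2]), True))
    for i1 in s1.index.difference(list(used1)):
        r1 = s1.loc[i1]
        rows.append((r1["chrom"], int(r1["start"]), int(r1["end"]),
                     str(r1.get("name", f"peak1_{i1}")),
                     float(r1[c1]), 0.0, False))
    for i2 in s2.index.difference(list(used2)):
        r2 = s2.loc[i2]
        rows.append((r2["chrom"], int(r2["start"]), int(r2["end"]),
                     str(r2.get("name", f"peak2_{i2}")),
                     0.0, float(r2[c2]), False))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                      "count_a", "count_b", "matched"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# MA computation and normalization
# ---------------------------------------------------------------------------

def compute_ma(counts_a: np.ndarray, counts_b: np.ndarray,
               pseudocount: float = DEFAULT_PSEUDOCOUNT,
               library_sizes: tuple[float, float] = (1e6, 1e6),
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-peak (A, M_raw) from read counts.

    Counts are scaled to reads-per-million of the given library sizes, a
    pseudocount is added, then A = 0.5*(log2 da + log2 db) and
    M_raw = log2(db / da).
    """
    la, lb = library_sizes
    if la <= 0 or lb <= 0:
        raise ValueError("library sizes must be positive")
    da = np.asarray(counts_a, float) * 1e6 / la + pseudocount
    db = np.asarray(counts_b, float) * 1e6 / lb + pseudocount
    A = 0.5 * (np.log2(da) + np.log2(db))
    M = np.log2(db) - np.log2(da)
    return A, M


def fit_ma_normalization(A_common: np.ndarray, M_common: np.ndarray,
                         method: str = "theilsen", min_common: int = 10,
                         max_fit_points: int = 2000, seed: int = 0,
                         ) -> NormalizationFit:
    """Fit the M-on-A trend over common peaks.

    Default fit is Theil–Sen (median of pairwise slopes, robust to the
    genuinely changed minority); ordinary least squares is available as
    ``method="ols"``.  Degenerate A (all equal) fixes the slope at 0 with
    intercept = median M.
    """
    A = np.asarray(A_common, float)
    M = np.asarray(M_common, float)
    if len(A) < min_common:
        raise ValueError(
            f"need >= {min_common} common peaks to fit, got {len(A)}")
    if len(A) > max_fit_points:
        idx = np.random.default_rng(seed).choice(
            len(A), size=max_fit_points, replace=False)
        A, M = A[idx], M[idx]

    if np.ptp(A) == 0:
        warnings.warn("degenerate A values: slope fixed at 0")
        return NormalizationFit(a=float(np.median(M)), b=0.0,
                                n_common=len(A_common), method="degenerate")
    if method == "theilsen":
        slope, intercept, *_ = stats.theilslopes(M, A)
    elif method == "ols":
        slope, intercept, *_ = stats.linregress(A, M)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return NormalizationFit(a=float(intercept), b=float(slope),
                            n_common=len(A_common), method=method)


def normalize_m(fit: NormalizationFit, A: np.ndarray,
                M_raw: np.ndarray) -> np.ndarray:
    """Normalized M = M_raw minus the fitted condition-wide trend."""
    return np.asarray(M_raw, float) - fit.predict(A)


def classify_change(M: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """'increased' iff M > tau, 'decreased' iff M < -tau, else 'unchanged'."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    M = np.asarray(M, float)
    if not np.isfinite(M).all():
        raise ValueError("M values must be finite")
    out = np.full(M.shape, "unchanged", dtype=object)
    out[M > tau] = "increased"
    out[M < -tau] = "decreased"
    return out


def diff_peak_table(union: pd.DataFrame, tau: float = DEFAULT_TAU,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    library_sizes: tuple[float, float] = (1e6, 1e6),
                    method: str = "theilsen", seed: int = 0) -> pd.DataFrame:
    """Full MA pipeline on a union peak table (from match_common_peaks).

    Adds columns A, M_raw, M, change; the normalization is fitted on the
    matched common peaks only and applied to every peak.
    """
    A, M_raw = compute_ma(union["count_a"].to_numpy(),
                          union["count_b"].to_numpy(),
                          pseudocount=pseudocount, library_sizes=library_sizes)
    common = union["matched"].to_numpy() if "matched" in union.columns else (
        np.ones(len(union), dtype=bool))
    fit = fit_ma_normalization(A[common], M_raw[common], method=method,
                               seed=seed)
    M = normalize_m(fit, A, M_raw)
    out = union.copy()
    out["A"] = A
    out["M_raw"] = M_raw
    out["M"] = M
    out["change"] = classify_change(M, tau=tau)
    out.attrs["normalization"] = {"a": fit.a, "b": fit.b,
                                  "n_common": fit.n_common,
                                  "method": fit.method, "tau": tau}
    log.info("MA normalization: a=%.4f b=%.4f on %d common peaks (tau=%.2f)",
             fit.a, fit.b, fit.n_common, tau)
    return out
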