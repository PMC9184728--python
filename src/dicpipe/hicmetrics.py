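"""Contact-matrix analytics: balancing, DLR/ICF, insulation score, APA.

All metrics are ratio or log-ratio constructions, hence invariant to a
uniform rescaling of the whole matrix:

* DLR (distal-to-local ratio): per-bin log2 of cis contacts beyond a local
  cutoff over cis contacts within it; the inter-condition difference
  (ΔDLR = B − A) is positive where a locus de-compacts.
* ICF (inter-chromosomal fraction): per-bin inter / (inter + intra).
* Insulation score: log2 of the mean contact in the off-diagonal square
  crossing a bin over the chromosome-wide expectation at matched distances;
  local minima mark domain boundaries.
* APA (aggregate peak analysis): submatrices centered on a list of anchor
  pairs are summed; score = center over the mean of the lower-left corner
  block (the short-distance background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ContactMapStore, LoopRecord

log = logging.getLogger(__name__)

DEFAULT_LOCAL_CUTOFF = 3_000_000


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

@dataclass
class BalancedMap:
    store: ContactMapStore
    weights: dict[str, np.ndarray]      # per-bin balancing weights (per chrom)
    covered: dict[str, np.ndarray]      # bins that entered balancing
    n_iter: dict[str, int]


def balance_map(store: ContactMapStore, max_iter: int = 200,
                tol: float = 1e-3) -> BalancedMap:
    """Iterative proportional scaling of each intra-chromosomal matrix.

    Row sums of covered bins (nonzero marginal) are equalized within
    ``tol`` relative deviation; zero-marginal bins are excluded and
    flagged.  Non-convergence raises with the last residual.
    """
    out = store.copy()
    weights, covered, iters = {}, {}, {}
    for (c1, c2), m in list(out.matrices.items()):
        if c1 != c2:
            continue
        n = m.shape[0]
        marg = m.sum(axis=1)
        cov = marg > 0
        w = np.ones(n)
        mm = m.copy()
        it = 0
        resid = np.inf
        for it in range(1, max_iter + 1):
            s = mm[np.ix_(cov, cov)].sum(axis=1)
            target = s.mean()
            resid = float(np.max(np.abs(s / target - 1.0))) if len(s) else 0.0
            if resid < tol:
                break
            f = np.sqrt(s / target)
            wf = np.ones(n)
            wf[cov] = f
            mm = mm / wf[:, None] / wf[None, :]
            w = w * wf
        else:
            raise RuntimeError(
                f"balancing did not converge on {c1} in {max_iter} "
                f"iterations (residual {resid:.3e})")
        out.matrices[(c1, c2)] = mm
        weights[c1] = w
        covered[c1] = cov
        iters[c1] = it
    return BalancedMap(store=out, weights=weights, covered=covered,
                       n_iter=iters)


# ---------------------------------------------------------------------------
# DLR / ICF
# ---------------------------------------------------------------------------

@dataclass
class CompactionProfile:
    """Per-bin compaction metrics for one or two conditions."""

    resolution: int
    window: int
    local_cutoff: int
    table: pd.DataFrame   # chrom, bin, + metric columns (NaN = undefined)


def _window_sum(x: np.ndarray, hw: int) -> np.ndarray:
    """Centered rolling sum with half-width hw bins (edges truncated)."""
    if hw == 0:
        return x.copy()
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    lo = np.maximum(np.arange(n) - hw, 0)
    hi = np.minimum(np.arange(n) + hw + 1, n)
    return c[hi] - c[lo]


def _per_bin_local_distal(m: np.ndarray, cut_bins: int) -> tuple[np.ndarray, np.ndarray]:
    n = m.shape[0]
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    local = np.where(d <= cut_bins, m, 0.0).sum(axis=1)
    distal = np.where(d > cut_bins, m, 0.0).sum(axis=1)
    return local, distal


def compute_dlr(map_a: ContactMapStore, map_b: ContactMapStore | None,
                window: int, local_cutoff: int = DEFAULT_LOCAL_CUTOFF,
                ) -> CompactionProfile:
    """Per-bin DLR = log2(distal cis / local cis), aggregated over a window.

    With two maps the profile carries dlr_a, dlr_b and delta_dlr = B - A
    (positive = de-compaction).  DLR is NaN where either sum is zero.
    """
    res = map_a.resolution
    if local_cutoff <= window:
        raise ValueError("local_cutoff must exceed the aggregation window")
    if map_b is not None:
        if map_b.resolution != res or map_b.chrom_sizes != map_a.chrom_sizes:
            raise ValueError("maps must share resolution and chromosomes")
    hw = max(0, window // (2 * res))
    cut_bins = local_cutoff // res

    rows = []
    for chrom in map_a.chrom_sizes:
        n = map_a.nbins(chrom)
        rec: dict[str, np.ndarray] = {}
        for tag, store in (("a", map_a), ("b", map_b)):
            if store is None:
                continue
            m = store.matrix(chrom, chrom)
            local, distal = _per_bin_local_distal(m, cut_bins)
            local = _window_sum(local, hw)
            distal = _window_sum(distal, hw)
            with np.errstate(divide="ignore", invalid="ignore"):
                dlr = np.where((local > 0) & (distal > 0),
                               np.log2(distal / local), np.nan)
            rec[tag] = dlr
        for i in range(n):
            row = {"chrom": chrom, "bin": i, "dlr_a": rec["a"][i]}
            if "b" in rec:
                row["dlr_b"] = rec["b"][i]
                row["delta_dlr"] = rec["b"][i] - rec["a"][i]
            rows.append(row)
    return CompactionProfile(res, window, local_cutoff, pd.DataFrame(rows))


def compute_icf(map_a: ContactMapStore, map_b: ContactMapStore | None,
                window: int = 0) -> CompactionProfile:
    """Per-bin ICF = inter / (inter + intra); delta_icf = B - A if given."""
    res = map_a.resolution
    hw = max(0, window // (2 * res)) if window else 0

    def _icf(store: ContactMapStore) -> dict[str, np.ndarray]:
        out = {}
        chroms = list(store.chrom_sizes)
        for chrom in chroms:
            intra = store.matrix(chrom, chrom).sum(axis=1)
            inter = np.zeros(store.nbins(chrom))
            for other in chroms:
                if other == chrom:
                    continue
                inter += store.matrix(chrom, other).sum(axis=1)
            intra = _window_sum(intra, hw)
            inter = _window_sum(inter, hw)
            tot = intra + inter
            with np.errstate(divide="ignore", invalid="ignore"):
                out[chrom] = np.where(tot > 0, inter / tot, np.nan)
        return out

    icf_a = _icf(map_a)
    icf_b = _icf(map_b) if map_b is not None else None
    rows = []
    for chrom, vals in icf_a.items():
        for i, v in enumerate(vals):
            row = {"chrom": chrom, "bin": i, "icf_a": v}
            if icf_b is not None:
                row["icf_b"] = icf_b[chrom][i]
                row["delta_icf"] = icf_b[chrom][i] - v
            rows.append(row)
    return CompactionProfile(res, window, 0, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Insulation
# ---------------------------------------------------------------------------

@dataclass
class InsulationProfile:
    resolution: int
    square_width: int     # bins
    table: pd.DataFrame   # chrom, bin, score (NaN near chromosome ends)

    def boundaries(self, depth: float = -0.5, radius: int = 2) -> list[tuple[str, int]]:
        """Local minima of the score below ``depth`` within +/- radius bins."""
        out = []
        for chrom, grp in self.table.groupby("chrom", sort=False):
            s = grp["score"].to_numpy()
            for i in range(len(s)):
                v = s[i]
                if not np.isfinite(v) or v >= depth:
                    continue
                lo, hi = max(0, i - radius), min(len(s), i + radius + 1)
                neigh = s[lo:hi]
                if v == np.nanmin(neigh):
                    out.append((chrom, i))
        # collapse plateau runs to their first bin
        collapsed = []
        for chrom, i in out:
            if collapsed and collapsed[-1][0] == chrom and i - collapsed[-1][1] <= 1:
                continue
            collapsed.append((chrom, i))
        return collapsed


def _expected_by_distance(m: np.ndarray) -> np.ndarray:
    """Mean contact per |i-j| distance band over the chromosome."""
    n = m.shape[0]
    exp = np.zeros(n)
    for d in range(n):
        exp[d] = np.mean(np.diagonal(m, offset=d))
    return exp


def compute_insulation(store: ContactMapStore, square_width: int,
                       ) -> InsulationProfile:
    """IS(i) = log2(mean of rows [i-w, i) x cols (i, i+w] / expected mean).

    Expected is the chromosome-wide mean at the matched distance band; the
    score is NaN within ``square_width`` of chromosome ends.  A chromosome
    shorter than 2w + 1 bins yields an empty (all-NaN) profile.
    """
    if square_width < 2:
        raise ValueError("square_width must be >= 2 bins")
    w = square_width
    rows = []
    for chrom in store.chrom_sizes:
        n = store.nbins(chrom)
        score = np.full(n, np.nan)
        if n >= 2 * w + 1:
            m = store.matrix(chrom, chrom)
            exp = _expected_by_distance(m)
            # rows i-w..i-1 x cols i+1..i+w span distances 2..2w; the
            # expected square mean averages exp over the same multiset
            dists = np.add.outer(np.arange(w, 0, -1), np.arange(1, w + 1))
            exp_sq = exp[dists].mean()
            for i in range(w, n - w):
                sub = m[i - w:i, i + 1:i + w + 1]
                obs = sub.mean()
                if obs > 0 and exp_sq > 0:
                    score[i] = np.log2(obs / exp_sq)
        for i in range(n):
            rows.append({"chrom": chrom, "bin": i, "score": score[i]})
    return InsulationProfile(store.resolution, w, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# APA
# ---------------------------------------------------------------------------

@dataclass
class APAResult:
    radius: int
    aggregate: np.ndarray            # (2r+1) x (2r+1)
    per_pair: np.ndarray             # central enrichment per usable pair
    score: float
    n_pairs: int
    n_dropped: int


def _pair_bins(pairs: list[LoopRecord], res: int) -> list[tuple[str, int, int]]:
    out = []
    for lp in pairs:
        if not lp.is_intra:
            continue
        b1 = (lp.anchor1.start + lp.anchor1.end) // 2 // res
        b2 = (lp.anchor2.start + lp.anchor2.end) // 2 // res
        out.append((lp.anchor1.chrom, int(min(b1, b2)), int(max(b1, b2))))
    return out


def run_apa(store: ContactMapStore, pairs: list[LoopRecord], radius: int = 5,
            norm: str = "expected") -> APAResult:
    """Aggregate (2r+1)^2 submatrices centered on each anchor-pair pixel.

    With ``norm="expected"`` each submatrix entry is divided by the
    chromosome's distance-expected value; ``norm="none"`` uses raw counts.
    Score = center / mean of the r x r lower-left corner block (rows below
    center, columns left of center — the shorter-distance background).
    Pairs closer than 2 * radius bins are dropped (count reported).
    """
    res = store.resolution
    r = radius
    size = 2 * r + 1
    agg = np.zeros((size, size))
    per_pair = []
    dropped = 0
    exp_cache: dict[str, np.ndarray] = {}
    for chrom, b1, b2 in _pair_bins(pairs, res):
        n = store.nbins(chrom)
        if b2 - b1 <= 2 * r or b1 - r < 0 or b2 + r >= n:
            dropped += 1
            continue
        m = store.matrix(chrom, chrom)
        sub = m[b1 - r:b1 + r + 1, b2 - r:b2 + r + 1].astype(float).copy()
        if norm == "expected":
            if chrom not in exp_cache:
                exp_cache[chrom] = _expected_by_distance(m)
            exp = exp_cache[chrom]
            di = np.arange(b1 - r, b1 + r + 1)
            dj = np.arange(b2 - r, b2 + r + 1)
            dist = np.abs(np.subtract.outer(di, dj))
            e = exp[dist]
            with np.errstate(divide="ignore", invalid="ignore"):
                sub = np.where(e > 0, sub / e, 0.0)
        elif norm != "none":
            raise ValueError(f"unknown norm {norm!r}")
        agg += sub
        per_pair.append(sub[r, r])
    if not per_pair:
        raise ValueError("no usable pairs for APA")
    corner = agg[r + 1:, :r]          # rows below center, cols left of center
    corner_mean = corner.mean()
    score = float(agg[r, r] / corner_mean) if corner_mean > 0 else np.inf
    return APAResult(radius=r, aggregate=agg, per_pair=np.array(per_pair),
                     score=score, n_pairs=len(per_pair), n_dropped=dropped)


def compare_apa(map_a: ContactMapStore, map_b: ContactMapStore,
                pairs: list[LoopRecord], radius: int = 5,
                norm: str = "expected") -> tuple[float, float, APAResult, APAResult]:
    """Paired two-sided t test on per-pair central enrichment, A vs B.

    Returns (statistic, p, apa_a, apa_b); the sign of the statistic follows
    the mean difference A - B.
    """
    apa_a = run_apa(map_a, pairs, radius=radius, norm=norm)
    apa_b = run_apa(map_b, pairs, radius=radius, norm=norm)
    if apa_a.n_pairs != apa_b.n_pairs:
        raise ValueError("pair lists diverged between conditions")
    if apa_a.n_pairs < 3:
        raise ValueError("need at least 3 usable pairs")
    diff = apa_a.per_pair - apa_b.per_pair
    if np.allclose(diff, 0.0):
        return 0.0, 1.0, apa_a, apa_b
    t, p = stats.ttest_rel(apa_a.per_pair, apa_b.per_pair)
    return float(t), float(p), apa_a, apa_b
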