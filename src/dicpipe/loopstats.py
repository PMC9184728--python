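"""Loop-occurrence and anchor-annotation statistics, plus the generic tests.

A site "has a loop" when its interval overlaps either anchor of any loop by
at least one base pair; occurrence probabilities per site category are
compared pairwise with the two-sided Fisher exact test.  For loops anchored
on a DIC, the distal ("other") anchor is classified against promoter /
enhancer / exon / intron annotations with a fixed priority order.

The statistical helpers wrap the standard tests used throughout the
analysis: Fisher exact (probability-mass two-sided rule), Mann–Whitney U
(exact enumeration for small samples, tie-corrected normal otherwise),
paired t, upper-tail hypergeometric overlap, and Benjamini–Hochberg
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import Gene, GenomicInterval, LoopRecord

PROMOTER_WINDOW = 2_000
ANNOTATION_PRIORITY = ("promoter", "enhancer", "exon", "intron", "intergenic")


@dataclass
class StatResult:
    test: str
    statistic: float
    p: float
    sidedness: str
    n: tuple[int, ...]
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# Loop occurrence
# ---------------------------------------------------------------------------

def _overlaps_any(row_chrom: str, row_start: int, row_end: int,
                  anchors_by_chrom: dict[str, np.ndarray]) -> bool:
    arr = anchors_by_chrom.get(row_chrom)
    if arr is None or not len(arr):
        return False
    return bool(((arr[:, 0] < row_end) & (arr[:, 1] > row_start)).any())


def loop_occurrence(site_sets: dict[str, pd.DataFrame],
                    loops: list[LoopRecord]) -> pd.DataFrame:
    """Per-category loop-occurrence probabilities and pairwise Fisher tests.

    Returns a category table (hits, total, probability) with pairwise
    two-sided Fisher p-values stored in ``.attrs["pairwise"]``.  Empty
    categories are excluded with a warning.
    """
    anchors: dict[str, list] = {}
    for lp in loops:
        for a in (lp.anchor1, lp.anchor2):
            anchors.setdefault(a.chrom, []).append((a.start, a.end))
    anchors_np = {c: np.array(v) for c, v in anchors.items()}

    rows = []
    hits_by_cat = {}
    for cat, sites in site_sets.items():
        if len(sites) == 0:
            warnings.warn(f"category {cat!r} is empty; excluded")
            continue
        hits = sum(
            _overlaps_any(r["chrom"], int(r["start"]), int(r["end"]), anchors_np)
            for _, r in sites.iterrows())
        hits_by_cat[cat] = (hits, len(sites))
        rows.append({"category": cat, "hits": hits, "total": len(sites),
                     "probability": hits / len(sites)})
    out = pd.DataFrame(rows)
    pairwise = {}
    for c1, c2 in combinations(hits_by_cat, 2):
        h1, t1 = hits_by_cat[c1]
        h2, t2 = hits_by_cat[c2]
        res = fisher_exact([[h1, t1 - h1], [h2, t2 - h2]])
        pairwise[(c1, c2)] = res.p
    out.attrs["pairwise"] = pairwise
    return out


# ---------------------------------------------------------------------------
# Other-anchor annotation
# ---------------------------------------------------------------------------

def _interval_hits(iv: GenomicInterval, table: pd.DataFrame) -> bool:
    if table is None or len(table) == 0:
        return False
    sub = table[table["chrom"] == iv.chrom]
    return bool(((sub["start"].to_numpy() < iv.end)
                 & (sub["end"].to_numpy() > iv.start)).any())


def annotate_other_anchor(loops: list[LoopRecord], dics: pd.DataFrame,
                          promoters: pd.DataFrame, enhancers: pd.DataFrame,
                          genes: list[Gene],
                          host_of_dic: dict[str, str] | None = None,
                          ) -> pd.DataFrame:
    """Classify the non-DIC anchor of each DIC-anchored loop.

    Priority: promoter > enhancer > exon > intron > intergenic (the gene
    model here carries no exon structure, so any within-gene-body hit not
    in a promoter/enhancer counts as intron).  Loops with neither anchor on
    a DIC are skipped; the skip count is in ``.attrs["n_skipped"]``.  A
    ``host_promoter`` flag marks contacts with the DIC's host-gene promoter.
    """
    dic_by_chrom = {c: df for c, df in dics.groupby("chrom")}
    bodies = [(g.chrom, g.start, g.end, g.gene_id) for g in genes]
    prom_of_gene = {g.gene_id: (g.chrom, g.tss - PROMOTER_WINDOW,
                                g.tss + PROMOTER_WINDOW) for g in genes}

    def dic_hit(iv: GenomicInterval) -> str | None:
        sub = dic_by_chrom.get(iv.chrom)
        if sub is None:
            return None
        ov = (sub["start"].to_numpy() < iv.end) & (sub["end"].to_numpy() > iv.start)
        if ov.any():
            return str(sub.loc[ov, "name"].iloc[0]) if "name" in sub else "dic"
        return None

    rows = []
    skipped = 0
    for k, lp in enumerate(loops):
        sides = []
        for a, other in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
            name = dic_hit(a)
            if name is not None:
                sides.append((name, other))
        if not sides:
            skipped += 1
            continue
        for dic_name, other in sides:
            if _interval_hits(other, promoters):
                cls = "promoter"
            elif _interval_hits(other, enhancers):
                cls = "enhancer"
            elif any(c == other.chrom and s < other.end and e > other.start
                     for c, s, e, _ in bodies):
                cls = "intron"
            else:
                cls = "intergenic"
            host_prom = False
            if host_of_dic and dic_name in host_of_dic:
                hp = prom_of_gene.get(host_of_dic[dic_name])
                if hp and hp[0] == other.chrom and hp[1] < other.end and hp[2] > other.start:
                    host_prom = True
            rows.append({"loop": k, "dic": dic_name, "class": cls,
                         "host_promoter": host_prom})
    out = pd.DataFrame(rows, columns=["loop", "dic", "class", "host_promoter"])
    out.attrs["n_skipped"] = skipped
    if len(out):
        out.attrs["proportions"] = (
            out["class"].value_counts(normalize=True).to_dict())
    return out


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def fisher_exact(table, sidedness: str = "two-sided") -> StatResult:
    """Fisher exact test on a 2x2 table.

    Two-sided p sums the probabilities of all tables (fixed margins) whose
    probability does not exceed the observed one.  A zero margin gives
    p = 1 by convention (with a warning).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin: p = 1 by convention")
        return StatResult("fisher_exact", np.nan, 1.0, sidedness,
                          tuple(t.sum(axis=1)))
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sidedness]
    odds, p = stats.fisher_exact(t, alternative=alt)
    return StatResult("fisher_exact", float(odds), float(p), sidedness,
                      tuple(int(x) for x in t.sum(axis=1)))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y with ties counted half (midrank convention)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(x, y, sidedness: str = "two-sided",
                   exact_max_n: int = 16) -> StatResult:
    """Mann–Whitney U test.

    For combined samples up to ``exact_max_n`` the p-value is computed by
    exact enumeration over all group assignments (ties handled naturally);
    larger samples use the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    u_obs = _u_statistic(x, y)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = np.arange(n1 + n2)
        count = {"greater": 0, "less": 0, "two": 0}
        total = 0
        for comb in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u >= u_obs - 1e-12:
                count["greater"] += 1
            if u <= u_obs + 1e-12:
                count["less"] += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count["two"] += 1
        p = {"greater": count["greater"] / total,
             "less": count["less"] / total,
             "two-sided": count["two"] / total}[sidedness]
        return StatResult("mann_whitney_u_exact", u_obs, float(p),
                          sidedness, (n1, n2))

    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sidedness]
    res = stats.mannwhitneyu(x, y, alternative=alt, method="asymptotic")
    return StatResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      sidedness, (n1, n2))


def paired_t(x, y, sidedness: str = "two-sided") -> StatResult:
    """Paired t test on the differences x - y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    d = x - y
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return StatResult("paired_t", 0.0, 1.0, sidedness, (len(x),))
        raise ValueError("zero variance of differences")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sidedness]
    t, p = stats.ttest_rel(x, y, alternative=alt)
    return StatResult("paired_t", float(t), float(p), sidedness, (len(x),))


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> StatResult:
    """Upper-tail hypergeometric P(X >= k) for overlap enrichment.

    Drawing n items from a universe of N containing K marked items, the
    probability of observing k or more marked among the drawn.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError("invalid hypergeometric parameters")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return StatResult("hypergeom_overlap", float(k), p, "greater", (n,))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
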