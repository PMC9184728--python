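"""The DIC-extraction cascade.

A decreased intragenic cohesin site (DIC) is a cohesin peak that (1) is no
wider than 3 kb, (2) lost intensity on stimulation (normalized M < -0.5),
(3) sits inside the intragenic region of a gene — the gene body minus 10-kb
flanks around TSS and TES, considering only genes longer than 20 kb — and
(4) whose host gene is stimulus-responsive (elongation-signal ratio > 1.2,
validated by an expression increase).  DICs are then split into low-CTCF
(LC) and high-CTCF (HC) subtypes by two-component clustering of log CTCF
density, after dropping sites with very low cohesin (Rad21) signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats import Gene, GenomicInterval

log = logging.getLogger(__name__)

FLANK_BP = 10_000
MIN_GENE_LENGTH = 20_000
WIDTH_CAP = 3_000
RATIO_THRESHOLD = 1.2
TSS_WINDOW = 10_000


# ---------------------------------------------------------------------------
# Intragenic regions
# ---------------------------------------------------------------------------

@dataclass
class IntragenicRegionSet:
    """Per-gene intragenic intervals with the parameters that produced them."""

    regions: dict[str, GenomicInterval]       # gene_id -> interval
    flank: int
    min_length: int
    extra_exclusions: list[GenomicInterval] = field(default_factory=list)

    def __iter__(self):
        return iter(self.regions.items())


def derive_intragenic_regions(genes: list[Gene], flank: int = FLANK_BP,
                              min_length: int = MIN_GENE_LENGTH,
                              extra_exclusions: list[GenomicInterval] | None = None,
                              ) -> IntragenicRegionSet:
    """Gene body minus [TSS +/- flank] and [TES +/- flank], clipped to the body.

    Genes with length <= ``min_length`` (strict) yield nothing.  Optional
    extra exclusion intervals (e.g. alternative promoters) are subtracted;
    a gene whose region is fully excluded yields nothing.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    extra = extra_exclusions or []
    out: dict[str, GenomicInterval] = {}
    for g in genes:
        if g.length <= min_length:
            continue
        lo, hi = g.start + flank, g.end - flank
        if hi <= lo:
            continue
        # subtract extra exclusions; keep the largest remaining piece
        pieces = [(lo, hi)]
        for ex in extra:
            if ex.chrom != g.chrom:
                continue
            nxt = []
            for (a, b) in pieces:
                if ex.end <= a or ex.start >= b:
                    nxt.append((a, b))
                else:
                    if ex.start > a:
                        nxt.append((a, ex.start))
                    if ex.end < b:
                        nxt.append((ex.end, b))
            pieces = nxt
        if not pieces:
            continue
        a, b = max(pieces, key=lambda p: p[1] - p[0])
        out[g.gene_id] = GenomicInterval(g.chrom, a, b, name=g.gene_id)
    return IntragenicRegionSet(out, flank=flank, min_length=min_length,
                               extra_exclusions=extra)


# ---------------------------------------------------------------------------
# Site location classes
# ---------------------------------------------------------------------------

def classify_site_location(sites: pd.DataFrame, genes: list[Gene],
                           regions: IntragenicRegionSet,
                           tss_window: int = TSS_WINDOW) -> pd.DataFrame:
    """Assign aroundTSS / intragenic / intergenic per site summit.

    aroundTSS wins when the summit is within ``tss_window`` of any TSS;
    otherwise intragenic when the summit lies inside a derived intragenic
    region; otherwise intergenic.  Host gene is the nearest-TSS gene among
    candidates.
    """
    summits = ((sites["start"] + sites["end"]) // 2).to_numpy()
    chroms = sites["chrom"].to_numpy()

    tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for c in sorted({g.chrom for g in genes}):
        gs = sorted((g.tss, g.gene_id) for g in genes if g.chrom == c)
        tss_by_chrom[c] = (np.array([t for t, _ in gs]), [i for _, i in gs])

    reg_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, iv in regions:
        reg_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gid))
    gene_tss = {g.gene_id: g.tss for g in genes}

    classes, hosts = [], []
    for summit, chrom in zip(summits.tolist(), chroms.tolist()):
        tss_arr, tss_ids = tss_by_chrom.get(chrom, (np.array([]), []))
        host = ""
        if len(tss_arr):
            j = int(np.argmin(np.abs(tss_arr - summit)))
            if abs(int(tss_arr[j]) - summit) <= tss_window:
                classes.append("aroundTSS")
                hosts.append(tss_ids[j])
                continue
        hits = [gid for a, b, gid in reg_by_chrom.get(chrom, [])
                if a <= summit < b]
        if hits:
            # nearest-TSS tie-break for overlapping genes
            host = min(hits, key=lambda gid: abs(gene_tss[gid] - summit))
            classes.append("intragenic")
            hosts.append(host)
        else:
            classes.append("intergenic")
            hosts.append("")
    out = sites.copy()
    out["location"] = classes
    out["host_gene"] = hosts
    return out


# ---------------------------------------------------------------------------
# Responsive genes
# ---------------------------------------------------------------------------

def call_responsive_genes(elongation: pd.DataFrame, expression: pd.DataFrame,
                          ratio_threshold: float = RATIO_THRESHOLD,
                          lfc_threshold: float = 0.0) -> pd.DataFrame:
    """Responsive iff elongation ratio > threshold (strict) AND log2FC > lfc.

    Genes present in only one table are excluded with a warning.  Returns
    gene_id, ratio, log2fc, expression_validated, responsive.
    """
    expr = expression.frame if hasattr(expression, "frame") else expression
    merged = elongation.merge(expr[["gene_id", "log2fc"]], on="gene_id",
                              how="outer", indicator=True)
    dropped = merged[merged["_merge"] != "both"]
    if len(dropped):
        warnings.warn(f"{len(dropped)} genes present in only one table; excluded")
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    merged["expression_validated"] = merged["log2fc"] > lfc_threshold
    merged["responsive"] = ((merged["ratio"] > ratio_threshold)
                            & merged["expression_validated"])
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# DIC extraction
# ---------------------------------------------------------------------------

def extract_dics(diff_peaks: pd.DataFrame, locations: pd.DataFrame,
                 responsive: pd.DataFrame, width_cap: int = WIDTH_CAP,
                 tau: float = 0.5) -> pd.DataFrame:
    """Call DICs: the conjunction of the four defining predicates.

    ``diff_peaks`` must carry name + M; ``locations`` name + location +
    host_gene.  Returns the site table with is_dic and the individual
    predicate columns (useful for monotonicity checks).
    """
    if "M" not in diff_peaks.columns:
        raise ValueError("diff peak table lacks normalized M values")
    dp = diff_peaks.set_index("name")
    loc = locations.set_index("name")
    missing = loc.index.difference(dp.index)
    if len(missing):
        raise ValueError(f"missing M value for {len(missing)} sites "
                         f"(e.g. {missing[0]})")
    resp_set = set(responsive.loc[responsive["responsive"], "gene_id"])

    out = locations.copy()
    M = dp.loc[out["name"], "M"].to_numpy(float)
    if not np.isfinite(M).all():
        raise ValueError("non-finite M value encountered")
    out["M"] = M
    width = (out["end"] - out["start"]).to_numpy()
    out["pred_width"] = width <= width_cap
    out["pred_decreased"] = M < -tau
    out["pred_intragenic"] = (out["location"] == "intragenic").to_numpy()
    out["pred_responsive"] = out["host_gene"].isin(resp_set).to_numpy()
    out["is_dic"] = (out["pred_width"] & out["pred_decreased"]
                     & out["pred_intragenic"] & out["pred_responsive"])
    log.info("extracted %d DICs from %d sites", int(out["is_dic"].sum()), len(out))
    return out


# ---------------------------------------------------------------------------
# Densities, LC/HC split
# ---------------------------------------------------------------------------

def quantify_density(read_positions: dict[str, np.ndarray], sites: pd.DataFrame,
                     window: int, library_size: float) -> np.ndarray:
    """Per-million read density in [summit - window, summit + window) per site."""
    if window <= 0:
        raise ValueError("window must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    out = np.zeros(len(sites))
    for k, (_, row) in enumerate(sites.iterrows()):
        pos = read_positions.get(row["chrom"])
        if pos is None or len(pos) == 0:
            continue
        pos = np.sort(np.asarray(pos))
        summit = (int(row["start"]) + int(row["end"])) // 2
        lo = np.searchsorted(pos, summit - window, side="left")
        hi = np.searchsorted(pos, summit + window, side="left")
        out[k] = (hi - lo) * 1e6 / library_size
    return out


def split_lc_hc(dics: pd.DataFrame, ctcf_density: np.ndarray,
                rad21_density: np.ndarray, min_rad21: float = 1.0,
                cutoff: float | None = None, seed: int = 0) -> pd.DataFrame:
    """Split DICs into LC (low CTCF) and HC (high CTCF) subtypes.

    Sites with rad21_density < min_rad21 are dropped.  The split is a
    two-component 1-D k-means on log(ctcf_density + 1) — invariant to
    monotone rescaling of the densities up to the log — with the
    higher-mean component labelled HC.  An explicit numeric ``cutoff`` on
    the raw density overrides clustering.
    """
    ctcf = np.asarray(ctcf_density, float)
    rad21 = np.asarray(rad21_density, float)
    keep = rad21 >= min_rad21
    if keep.sum() < 2:
        raise ValueError("fewer than 2 DICs remain after the Rad21 filter")
    out = dics.loc[keep].copy()
    out["ctcf_density"] = ctcf[keep]
    out["rad21_density"] = rad21[keep]

    if cutoff is not None:
        out["subtype"] = np.where(ctcf[keep] >= cutoff, "HC", "LC")
        return out

    x = np.log(ctcf[keep] + 1.0)
    if np.ptp(x) == 0:
        raise ValueError("all CTCF densities identical: no split possible")
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assign = km.fit_predict(x.reshape(-1, 1))
    hi = int(np.argmax(km.cluster_centers_.ravel()))
    out["subtype"] = np.where(assign == hi, "HC", "LC")
    n_hc = int((out["subtype"] == "HC").sum())
    log.info("LC/HC split: %d HC, %d LC", n_hc, len(out) - n_hc)
    return out


# ---------------------------------------------------------------------------
# Aggregate profiles
# ---------------------------------------------------------------------------

@dataclass
class Metaprofile:
    """Mean signal around site summits with a 95% confidence band."""

    offsets: np.ndarray          # bp relative to summit (bin left edges)
    mean: np.ndarray
    ci_halfwidth: np.ndarray
    n_sites: int


def aggregate_profile(track: dict[str, np.ndarray], track_bin: int,
                      sites: pd.DataFrame, flank: int, bin_size: int,
                      library_size: float = 1e6) -> Metaprofile:
    """Strand-oriented mean signal profile around site summits.

    ``track`` maps chromosome to a binned signal array at ``track_bin`` bp;
    values are scaled to per-million of ``library_size``.  Minus-strand
    sites are mirrored.  The 95% CI is mean +/- 1.96 * SE across sites;
    with a single site the band is reported zero-width with a warning.
    """
    if len(sites) == 0:
        raise ValueError("empty site set")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    nbin = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size)
    per_site = np.full((len(sites), nbin), np.nan)
    scale = 1e6 / library_size
    for k, (_, row) in enumerate(sites.iterrows()):
        arr = track.get(row["chrom"])
        if arr is None:
            continue
        summit = (int(row["start"]) + int(row["end"])) // 2
        vals = np.empty(nbin)
        for j in range(nbin):
            pos = summit - flank + j * bin_size
            t = pos // track_bin
            vals[j] = arr[t] * scale if 0 <= t < len(arr) else np.nan
        strand = row["strand"] if "strand" in sites.columns else "."
        if strand == "-":
            vals = vals[::-1]
        per_site[k] = vals
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_site, axis=0)
        if len(sites) == 1:
            warnings.warn("single site: confidence band undefined, set to 0",
                          stacklevel=2)
            ci = np.zeros(nbin)
        else:
            se = np.nanstd(per_site, axis=0, ddof=1) / np.sqrt(
                np.sum(~np.isnan(per_site), axis=0))
            ci = 1.96 * se
    return Metaprofile(offsets=offsets, mean=mean, ci_halfwidth=ci,
                       n_sites=len(sites))


# ---------------------------------------------------------------------------
# Cross-sample presence and density-expression correlation
# ---------------------------------------------------------------------------

def compare_presence(reference: pd.DataFrame,
                     samples: dict[str, pd.DataFrame],
                     case_samples: list[str] | None = None,
                     min_overlap: int = 1) -> tuple[pd.DataFrame, pd.Index]:
    """Presence/absence of reference sites across sample peak sets.

    A reference site is present in sample S iff it overlaps an S peak by at
    least ``min_overlap`` bp.  Returns the boolean presence matrix (rows =
    reference sites) and the index of sites absent in every listed case
    sample.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    case_samples = case_samples if case_samples is not None else list(samples)
    pres = pd.DataFrame(index=reference.index, columns=list(samples),
                        dtype=bool)
    for sname, peaks in samples.items():
        by_chrom = {c: df for c, df in peaks.groupby("chrom")}
        col = np.zeros(len(reference), dtype=bool)
        for k, (_, row) in enumerate(reference.iterrows()):
            df = by_chrom.get(row["chrom"])
            if df is None:
                continue
            ov = (np.minimum(df["end"].to_numpy(), row["end"])
                  - np.maximum(df["start"].to_numpy(), row["start"]))
            col[k] = bool((ov >= min_overlap).any())
        pres[sname] = col
    absent = pres.index[~pres[case_samples].any(axis=1)]
    return pres, absent


def correlate_site_expression(densities: np.ndarray, expression: np.ndarray,
                              ) -> tuple[float, float]:
    """Spearman rank correlation between site density and host-gene expression."""
    x = np.asarray(densities, float)
    y = np.asarray(expression, float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
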