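"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the structure of a two-condition cohesin ChIP-seq +
Hi-C study on a desk-scale genome: non-overlapping genes on a couple of
chromosomes, cohesin sites placed around TSSs / inside gene bodies /
in intergenic space, negative-binomially dispersed peak intensities with a
planted subset of decreased intragenic sites (DICs) inside
stimulus-responsive genes, a bimodal CTCF co-binding signal that splits the
planted DICs into low-CTCF and high-CTCF subtypes, elongation-signal ratios
and expression fold changes for the responsive genes, and a pair of
distance-decay contact maps carrying planted loops, domain boundaries and
locus-specific de-compaction.

Every generator is a pure function of its parameters and seed.  The emitted
:class:`GroundTruth` is consistent by construction and is the oracle for all
recovery tests downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import (ContactMapStore, ExpressionTable, Gene, GenomicInterval,
                      LoopRecord)

SITE_CLASSES = ("aroundTSS", "intragenic", "intergenic")


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Stable per-stage generator derived from the scene seed."""
    return np.random.default_rng(
        (int(seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2 ** 31))


# ---------------------------------------------------------------------------
# Parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Study conditions for the default synthetic scene.

    The defaults describe a desk-scale scene (2 chromosomes x 20 Mb, 300
    genes, ~3,000 cohesin sites, 100 planted DICs) on which the whole
    pipeline runs in minutes.
    """

    seed: int = 1
    # genome
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 300
    frac_long_genes: float = 0.7          # genes > 20 kb (classification cutoff)
    long_gene_range: tuple[int, int] = (30_000, 80_000)
    short_gene_range: tuple[int, int] = (5_000, 18_000)
    # sites
    n_sites_tss: int = 1000
    n_sites_intragenic: int = 1200
    n_sites_intergenic: int = 800
    wide_site_fraction: float = 0.02      # non-DIC sites wider than the 3-kb cap
    # responsiveness and planted DICs
    fraction_responsive_genes: float = 0.3
    planted_dic_fraction: float = 1.0 / 12.0   # of intragenic sites -> 100
    dic_fold_change: float = 0.5
    hc_fraction: float = 0.25             # high-CTCF share of planted DICs
    # peak intensities
    baseline_mean: float = 200.0
    baseline_log_sd: float = 0.4
    nb_dispersion: float = 0.1            # variance = mu * (1 + dispersion)
    global_factor_b: float = 1.0          # ChIP-efficiency factor on condition B
    library_size: float = 1_000_000.0
    # CTCF mixture (log-normal components; 16-fold mean separation)
    ctcf_mixture: tuple[float, float, float, float, float] = (
        2.0, 32.0, 0.5, 0.5, 0.5)  # mean_lo, mean_hi, sdlog_lo, sdlog_hi, w_hi
    rad21_density_mean: float = 20.0
    rad21_low_fraction: float = 0.02      # sites with near-zero Rad21 signal
    # binary TF co-binding probabilities per truth group
    tf_cobind_probs: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "enhancer_mark": {"LC": 0.85, "HC": 0.15, "other": 0.30},
        "pol2":          {"LC": 0.70, "HC": 0.20, "other": 0.30},
        "er":            {"LC": 0.60, "HC": 0.10, "other": 0.15},
        "boundary_mark": {"LC": 0.10, "HC": 0.80, "other": 0.25},
    })
    # expression / elongation
    responsive_ratio_mean: float = 1.5
    responsive_ratio_sd: float = 0.05
    nonresponsive_ratio_sd: float = 0.05
    responsive_lfc_mean: float = 1.5
    responsive_lfc_sd: float = 0.5
    # contact maps
    resolution: int = 25_000
    hic_base_count: float = 300.0
    decay_exponent: float = 1.0
    inter_mean: float = 0.05
    loop_count: int = 100                 # loops lost at DIC anchors in B
    stable_loop_count: int = 100
    loop_enrichment_fold: float = 5.0
    loop_distance_bins: tuple[int, int] = (10, 40)
    n_boundaries: int = 100
    boundary_attenuation: float = 0.1
    compaction_shift_fraction: float = 0.2
    n_compaction_regions: int = 10
    compaction_region_bins: int = 5
    compaction_local_bins: int = 20

    def __post_init__(self) -> None:
        probs = [self.frac_long_genes, self.fraction_responsive_genes,
                 self.planted_dic_fraction, self.hc_fraction,
                 self.wide_site_fraction, self.rad21_low_fraction,
                 self.ctcf_mixture[4], self.compaction_shift_fraction,
                 self.boundary_attenuation]
        for d in self.tf_cobind_probs.values():
            probs.extend(d.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 0.0 < self.dic_fold_change < 1.0:
            raise ValueError("dic_fold_change must lie in (0, 1)")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class GroundTruth:
    """Planted labels emitted by the simulator; the oracle for recovery tests."""

    site_labels: pd.DataFrame            # name, class, host_gene, is_planted_dic, is_LC, is_HC
    responsive_genes: list[str]
    planted_loops: list[LoopRecord]      # loops lost in condition B (DIC anchors)
    stable_loops: list[LoopRecord]
    boundary_bins: list[tuple[str, int]]
    compaction_bins: list[tuple[str, int]]
    informative_features: list[int] = field(default_factory=list)
    planted_coefficients: np.ndarray | None = None

    def validate(self) -> None:
        lab = self.site_labels
        bad = lab[(lab["is_LC"] | lab["is_HC"]) & ~lab["is_planted_dic"]]
        if len(bad):
            raise AssertionError("LC/HC labels on non-DIC sites")
        dics = lab[lab["is_planted_dic"]]
        if (dics["site_class"] != "intragenic").any():
            raise AssertionError("planted DIC outside intragenic class")
        resp = set(self.responsive_genes)
        if not set(dics["host_gene"]).issubset(resp):
            raise AssertionError("planted DIC in a non-responsive gene")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(params: SimulationParams) -> tuple[list[Gene], dict[str, int]]:
    """Place non-overlapping genes on the synthetic chromosomes.

    Genes are packed left-to-right with random gaps drawn from a Dirichlet
    split of the leftover space, which guarantees non-overlap by
    construction.  Both strands are represented; ``frac_long_genes`` of the
    genes exceed the 20-kb classification cutoff.
    """
    rng = _rng(params.seed, "genome")
    chrom_sizes = params.chrom_sizes
    chroms = list(chrom_sizes)

    n_long = int(round(params.n_genes * params.frac_long_genes))
    lengths = np.concatenate([
        rng.integers(*params.long_gene_range, size=n_long),
        rng.integers(*params.short_gene_range, size=params.n_genes - n_long),
    ])
    rng.shuffle(lengths)
    chrom_of = rng.integers(0, params.n_chroms, size=params.n_genes)

    genes: list[Gene] = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        lens = lengths[chrom_of == ci]
        margin = 50_000  # keep genes away from chromosome ends
        free = chrom_sizes[chrom] - 2 * margin - int(lens.sum())
        if free < len(lens):
            raise ValueError(
                "infeasible gene packing: reduce n_genes or gene lengths")
        gaps = rng.dirichlet(np.ones(len(lens) + 1)) * free
        pos = margin
        for k, L in enumerate(lens):
            pos += int(gaps[k])
            start, end = pos, pos + int(L)
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(Gene(f"gene_{gid:04d}", chrom, strand, tss, tes))
            gid += 1
            pos = end
    return genes, chrom_sizes


def _gene_body_regions(genes: Sequence[Gene], flank: int = 10_000,
                       min_length: int = 20_000) -> dict[str, tuple[int, int]]:
    """Intragenic interval per qualifying gene (body minus TSS/TES flanks)."""
    out = {}
    for g in genes:
        if g.length <= min_length:
            continue
        lo, hi = g.start + flank, g.end - flank
        if hi > lo:
            out[g.gene_id] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# Cohesin peaks
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial with variance = mean * (1 + dispersion).

    Parametrized with a constant overdispersion factor (size r = mean /
    dispersion), i.e. gamma-mixed Poisson; dispersion -> 0 recovers Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    r = mean / dispersion
    lam = rng.gamma(shape=r, scale=dispersion)
    return rng.poisson(lam).astype(float)


def simulate_cohesin_peaks(params: SimulationParams, genes: Sequence[Gene],
                           ) -> tuple[pd.DataFrame, GroundTruth]:
    """Place cohesin sites and draw two-condition peak counts.

    Planted DICs sit inside the intragenic regions of responsive genes and
    have condition-B mean = baseline x ``dic_fold_change``; the global
    factor ``global_factor_b`` multiplies every condition-B mean (a
    condition-wide efficiency imbalance that MA normalization must remove).
    """
    rng = _rng(params.seed, "peaks")
    regions = _gene_body_regions(genes)
    region_genes = [g for g in genes if g.gene_id in regions]
    if not region_genes:
        raise ValueError("no genes long enough to host intragenic sites")

    n_resp = int(round(params.fraction_responsive_genes * len(genes)))
    n_resp = min(n_resp, len(region_genes))
    resp_ids = list(rng.choice([g.gene_id for g in region_genes],
                               size=n_resp, replace=False))
    resp_set = set(resp_ids)

    genes_by_id = {g.gene_id: g for g in genes}
    rows = []

    # aroundTSS sites: summits within 2 kb of a random TSS
    for k in range(params.n_sites_tss):
        g = genes_by_id[rng.choice([x.gene_id for x in genes])]
        width = int(rng.integers(300, 800))
        summit = g.tss + int(rng.integers(-2000, 2001))
        start = max(0, summit - width // 2)
        rows.append((g.chrom, start, start + width, "aroundTSS", g.gene_id))

    # intragenic sites: fully inside a qualifying gene's intragenic region
    region_ids = list(regions)
    region_lens = np.array([regions[i][1] - regions[i][0] for i in region_ids],
                           dtype=float)
    pick_p = region_lens / region_lens.sum()
    for k in range(params.n_sites_intragenic):
        wide = rng.random() < params.wide_site_fraction
        width = int(rng.integers(3500, 5000)) if wide else int(rng.integers(300, 1500))
        for _ in range(50):
            gid = region_ids[rng.choice(len(region_ids), p=pick_p)]
            lo, hi = regions[gid]
            if hi - lo > width + 200:
                break
        else:
            raise ValueError("could not place intragenic site; widen genes")
        start = int(rng.integers(lo + 100, hi - width - 100))
        g = genes_by_id[gid]
        rows.append((g.chrom, start, start + width, "intragenic", gid))

    # intergenic sites: > 10 kb from every TSS and outside every gene body
    chroms = list(params.chrom_sizes)
    tss_by_chrom = {c: np.array(sorted(g.tss for g in genes if g.chrom == c))
                    for c in chroms}
    bodies = {c: sorted((g.start, g.end) for g in genes if g.chrom == c)
              for c in chroms}
    placed = 0
    while placed < params.n_sites_intergenic:
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(300, 1200))
        start = int(rng.integers(10_000, params.chrom_sizes[chrom] - width - 10_000))
        summit = start + width // 2
        tsss = tss_by_chrom[chrom]
        if len(tsss) and np.min(np.abs(tsss - summit)) <= 11_000:
            continue
        if any(lo - 500 <= summit < hi + 500 for lo, hi in bodies[chrom]):
            continue
        rows.append((chrom, start, start + width, "intergenic", ""))
        placed += 1

    sites = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                        "site_class", "host_gene"])
    sites.insert(3, "name", [f"site_{i:05d}" for i in range(len(sites))])
    sites["strand"] = "."
    sites = sites[["chrom", "start", "end", "name", "strand",
                   "site_class", "host_gene"]]

    # plant the DICs among intragenic sites of responsive genes (width <= 3 kb)
    n_dic = int(round(params.planted_dic_fraction * params.n_sites_intragenic))
    widths = sites["end"] - sites["start"]
    eligible = sites.index[(sites["site_class"] == "intragenic")
                           & sites["host_gene"].isin(resp_set)
                           & (widths <= 3000)]
    if n_dic > len(eligible):
        raise ValueError(
            f"planted_dic_fraction asks for {n_dic} DICs but only "
            f"{len(eligible)} eligible intragenic sites exist")
    dic_idx = rng.choice(eligible, size=n_dic, replace=False)
    is_dic = np.zeros(len(sites), dtype=bool)
    is_dic[dic_idx] = True

    is_hc = np.zeros(len(sites), dtype=bool)
    n_hc = int(round(params.hc_fraction * n_dic))
    hc_idx = rng.choice(dic_idx, size=n_hc, replace=False)
    is_hc[hc_idx] = True
    is_lc = is_dic & ~is_hc

    # two-condition counts
    baseline = params.baseline_mean * np.exp(
        rng.normal(0.0, params.baseline_log_sd, size=len(sites)))
    mean_a = baseline
    mean_b = baseline * params.global_factor_b
    mean_b = np.where(is_dic, mean_b * params.dic_fold_change, mean_b)
    sites["count_a"] = _nb_counts(rng, mean_a, params.nb_dispersion)
    sites["count_b"] = _nb_counts(rng, mean_b, params.nb_dispersion)

    labels = pd.DataFrame({
        "name": sites["name"],
        "site_class": sites["site_class"],
        "host_gene": sites["host_gene"],
        "is_planted_dic": is_dic,
        "is_LC": is_lc,
        "is_HC": is_hc,
    })
    truth = GroundTruth(site_labels=labels, responsive_genes=resp_ids,
                        planted_loops=[], stable_loops=[],
                        boundary_bins=[], compaction_bins=[])
    return sites, truth


# ---------------------------------------------------------------------------
# Co-factor signals
# ---------------------------------------------------------------------------

def simulate_cofactor_signals(params: SimulationParams, sites: pd.DataFrame,
                              truth: GroundTruth) -> pd.DataFrame:
    """CTCF / Rad21 densities and binary TF co-binding columns per site.

    CTCF density is a two-component log-normal mixture; planted DICs take
    the component dictated by their LC/HC label, other sites mix with weight
    ``w_hi``.  Binary columns are Bernoulli with class-dependent
    probabilities.
    """
    rng = _rng(params.seed, "cofactors")
    m_lo, m_hi, sd_lo, sd_hi, w_hi = params.ctcf_mixture
    if not 0.0 <= w_hi <= 1.0:
        raise ValueError("mixture weight must lie in [0, 1]")
    n = len(sites)
    lab = truth.site_labels

    hi_component = np.where(
        lab["is_planted_dic"], lab["is_HC"], rng.random(n) < w_hi)
    mu = np.where(hi_component, np.log(m_hi), np.log(m_lo))
    sd = np.where(hi_component, sd_hi, sd_lo)
    ctcf = np.exp(rng.normal(mu, sd))

    rad21 = params.rad21_density_mean * np.exp(rng.normal(0.0, 0.3, size=n))
    low = rng.random(n) < params.rad21_low_fraction
    # near-zero Rad21 only on non-DIC sites so the planted truth stays intact
    low &= ~lab["is_planted_dic"].to_numpy()
    rad21 = np.where(low, rng.uniform(0.0, 0.2, size=n), rad21)

    group = np.where(lab["is_LC"], "LC", np.where(lab["is_HC"], "HC", "other"))
    out = pd.DataFrame({"name": sites["name"].to_numpy(),
                        "ctcf_density": ctcf, "rad21_density": rad21})
    for col, probs in params.tf_cobind_probs.items():
        p = np.array([probs[g] for g in group])
        out[col] = (rng.random(n) < p).astype(int)
    return out


# ---------------------------------------------------------------------------
# Expression / elongation
# ---------------------------------------------------------------------------

def simulate_expression_elongation(params: SimulationParams,
                                   genes: Sequence[Gene], truth: GroundTruth,
                                   ) -> tuple[ExpressionTable, pd.DataFrame]:
    """Elongation-signal ratios and expression summaries per gene.

    Responsive genes draw their stimulated/control elongation ratio from
    N(1.5, 0.05) — essentially all above the 1.2 calling threshold — and a
    positive expression log2 fold change; other genes center at ratio 1 and
    fold change 0.
    """
    rng = _rng(params.seed, "expression")
    resp = set(truth.responsive_genes)
    gene_ids = [g.gene_id for g in genes]
    is_resp = np.array([g in resp for g in gene_ids])

    ratio = np.where(
        is_resp,
        rng.normal(params.responsive_ratio_mean, params.responsive_ratio_sd,
                   size=len(gene_ids)),
        rng.normal(1.0, params.nonresponsive_ratio_sd, size=len(gene_ids)))
    lfc = np.where(
        is_resp,
        np.maximum(rng.normal(params.responsive_lfc_mean,
                              params.responsive_lfc_sd, size=len(gene_ids)),
                   0.1),
        rng.normal(0.0, 0.3, size=len(gene_ids)))
    mean_a = np.exp(rng.normal(np.log(50.0), 1.0, size=len(gene_ids)))
    mean_b = mean_a * np.exp2(lfc)
    expr = ExpressionTable(pd.DataFrame({
        "gene_id": gene_ids, "mean_a": mean_a, "mean_b": mean_b,
        "log2fc": lfc, "significant": is_resp}))
    elong = pd.DataFrame({"gene_id": gene_ids, "ratio": ratio})
    return expr, elong


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def _decay_matrix(nbins: int, base: float, exponent: float) -> np.ndarray:
    d = np.abs(np.subtract.outer(np.arange(nbins), np.arange(nbins)))
    return base / (1.0 + d) ** exponent


def simulate_contact_maps(params: SimulationParams, sites: pd.DataFrame,
                          truth: GroundTruth, sample: bool = True,
                          ) -> tuple[ContactMapStore, ContactMapStore, GroundTruth]:
    """Two-condition contact maps with planted loops, boundaries, compaction.

    Background follows a power-law distance decay; boundaries attenuate
    every contact crossing them; planted loops multiply their anchor pixel
    by ``loop_enrichment_fold`` (DIC-anchored loops only in condition A,
    stable loops in both); de-compaction moves ``compaction_shift_fraction``
    of each planted bin's local contacts to distal positions in condition B.
    With ``sample=False`` the noiseless mean matrices are returned (useful
    for exactness checks).
    """
    rng = _rng(params.seed, "hic")
    res = params.resolution
    chrom_sizes = params.chrom_sizes
    chroms = list(chrom_sizes)
    nbins = {c: -(-chrom_sizes[c] // res) for c in chroms}

    # ---- plant positions -------------------------------------------------
    boundaries: list[tuple[str, int]] = []
    per_chrom = params.n_boundaries // len(chroms)
    if params.n_boundaries > 0:
        per_chrom = max(1, per_chrom)
    for c in chroms:
        if per_chrom == 0:
            break
        spacing = nbins[c] // (per_chrom + 1)
        for k in range(per_chrom):
            pos = (k + 1) * spacing + int(rng.integers(-3, 4))
            if 8 <= pos < nbins[c] - 8:
                boundaries.append((c, pos))

    lab = truth.site_labels
    dic_sites = sites.loc[lab["is_planted_dic"].to_numpy()]
    summits = ((dic_sites["start"] + dic_sites["end"]) // 2) // res

    def _mk_loops(anchor_rows, n, tag):
        rng_l = _rng(params.seed, tag)
        loops = []
        take = anchor_rows.sample(n=min(n, len(anchor_rows)), replace=False,
                                  random_state=int(rng_l.integers(2 ** 31)))
        for _, row in take.iterrows():
            c = row["chrom"]
            b1 = int(((row["start"] + row["end"]) // 2) // res)
            dist = int(rng_l.integers(*params.loop_distance_bins))
            b2 = b1 + dist
            if b2 >= nbins[c] - 1:
                b2 = b1 - dist
                b1, b2 = b2, b1
            if b1 < 0:
                continue
            loops.append(LoopRecord(
                GenomicInterval(c, b1 * res, (b1 + 1) * res),
                GenomicInterval(c, b2 * res, (b2 + 1) * res), source="hic"))
        return loops

    planted_loops = _mk_loops(dic_sites, params.loop_count, "loops_dic")
    non_dic = sites.loc[~lab["is_planted_dic"].to_numpy()]
    stable_loops = _mk_loops(non_dic, params.stable_loop_count, "loops_stable")

    # de-compaction regions: runs of bins clear of boundaries and loop anchors
    compaction_bins: list[tuple[str, int]] = []
    per_chrom_reg = params.n_compaction_regions // len(chroms)
    if params.n_compaction_regions > 0:
        per_chrom_reg = max(1, per_chrom_reg)
    bset = {(c, b) for c, b in boundaries}
    for c in chroms:
        placed, attempts = 0, 0
        while placed < per_chrom_reg and attempts < 1000:
            attempts += 1
            start = int(rng.integers(30, nbins[c] - 30 - params.compaction_region_bins))
            run = [(c, start + k) for k in range(params.compaction_region_bins)]
            near_boundary = any((c, b + off) in bset
                                for _, b in run for off in range(-6, 7))
            taken = set(compaction_bins)
            overlaps = any((c, b + off) in taken
                           for _, b in run for off in range(-2, 3))
            if near_boundary or overlaps:
                continue
            compaction_bins.extend(run)
            placed += 1

    # ---- mean matrices ---------------------------------------------------
    store_a = ContactMapStore(res, dict(chrom_sizes))
    store_b = ContactMapStore(res, dict(chrom_sizes))
    bnd_by_chrom = {c: sorted(b for cc, b in boundaries if cc == c)
                    for c in chroms}

    for c in chroms:
        n = nbins[c]
        mu = _decay_matrix(n, params.hic_base_count, params.decay_exponent)
        # boundary attenuation: one factor per crossing
        if bnd_by_chrom[c]:
            block = np.searchsorted(bnd_by_chrom[c], np.arange(n), side="right")
            k = np.abs(np.subtract.outer(block, block))
            mu = mu * params.boundary_attenuation ** k
        mu_a = mu.copy()
        mu_b = mu.copy()

        for lp in planted_loops + stable_loops:
            if lp.anchor1.chrom != c:
                continue
            b1 = lp.anchor1.start // res
            b2 = lp.anchor2.start // res
            mu_a[b1, b2] *= params.loop_enrichment_fold
            mu_a[b2, b1] = mu_a[b1, b2]
            if lp in stable_loops:
                mu_b[b1, b2] *= params.loop_enrichment_fold
                mu_b[b2, b1] = mu_b[b1, b2]

        # de-compaction in B: local contacts of planted bins damp by (1 - f)
        # and distal contacts swell by (1 + f).  Complementary scaling keeps
        # the planted signal confined to the planted rows instead of
        # flooding the (attenuated) distal background of every other bin.
        L = params.compaction_local_bins
        f = params.compaction_shift_fraction
        rows = [b for cc, b in compaction_bins if cc == c]
        if rows and f > 0:
            base = mu_b.copy()
            idx = np.arange(n)
            for i in rows:
                local = np.abs(idx - i) <= L
                newrow = base[i].copy()
                newrow[local] *= (1.0 - f)
                newrow[~local] *= (1.0 + f)
                mu_b[i, :] = newrow
                mu_b[:, i] = newrow
        mu_b = (mu_b + mu_b.T) / 2.0

        if sample:
            # one seed stream per chromosome, restarted for each condition:
            # identical mean matrices then yield identical draws, and the
            # background noise of the two conditions is paired
            iu = np.triu_indices(n)
            for mu_x, store in ((mu_a, store_a), (mu_b, store_b)):
                rng_s = _rng(params.seed, f"hic_sample:{c}")
                draws = rng_s.poisson(mu_x[iu]).astype(float)
                full = np.zeros((n, n))
                full[iu] = draws
                full = full + np.triu(full, 1).T
                store.matrices[(c, c)] = full
        else:
            store_a.matrices[(c, c)] = mu_a
            store_b.matrices[(c, c)] = mu_b

    # small inter-chromosomal background
    for i, c1 in enumerate(chroms):
        for c2 in chroms[i + 1:]:
            shape = (nbins[c1], nbins[c2])
            if sample:
                for store in (store_a, store_b):
                    rng_i = _rng(params.seed, f"hic_inter:{c1}:{c2}")
                    store.matrices[(c1, c2)] = rng_i.poisson(
                        params.inter_mean, size=shape).astype(float)
            else:
                store_a.matrices[(c1, c2)] = np.full(shape, params.inter_mean)
                store_b.matrices[(c1, c2)] = np.full(shape, params.inter_mean)

    truth.planted_loops = planted_loops
    truth.stable_loops = stable_loops
    truth.boundary_bins = boundaries
    truth.compaction_bins = compaction_bins
    return store_a, store_b, truth


# ---------------------------------------------------------------------------
# Feature matrices for the ML stack
# ---------------------------------------------------------------------------

def simulate_feature_matrix(n_sites: int = 2000, n_features: int = 50,
                            n_informative: int = 10, effect_size: float = 2.0,
                            minority_fraction: float = 0.1,
                            n_binary: int | None = None,
                            n_chroms: int = 22, seed: int = 1,
                            ) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Classification feature matrix with planted informative features.

    Informative continuous features are shifted by ``effect_size`` (in
    within-class SD units) in the minority class; binary features flip their
    Bernoulli rate.  Rows carry a chromosome assignment for held-out splits.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    rng = _rng(seed, "featmat")
    if n_binary is None:
        n_binary = n_features // 3
    y = (rng.random(n_sites) < minority_fraction).astype(int)
    info = rng.choice(n_features, size=n_informative, replace=False)
    info_set = set(info.tolist())

    cols = {}
    for j in range(n_features):
        if j < n_binary:
            p = np.where(
                (y == 1) & (j in info_set), 0.8,
                np.where(j in info_set, 0.2, 0.4))
            cols[f"f{j:03d}"] = (rng.random(n_sites) < p).astype(float)
        else:
            shift = effect_size if j in info_set else 0.0
            cols[f"f{j:03d}"] = rng.normal(0.0, 1.0, size=n_sites) + shift * y
    X = pd.DataFrame(cols)
    X.insert(0, "chrom", [f"chr{(i % n_chroms) + 1}" for i in range(n_sites)])
    X.index = [f"site_{i:05d}" for i in range(n_sites)]

    labels = pd.DataFrame({"name": X.index, "site_class": "intragenic",
                           "host_gene": "", "is_planted_dic": y.astype(bool),
                           "is_LC": False, "is_HC": False})
    truth = GroundTruth(site_labels=labels, responsive_genes=[],
                        planted_loops=[], stable_loops=[], boundary_bins=[],
                        compaction_bins=[],
                        informative_features=sorted(info.tolist()))
    return X, y, truth


def simulate_regression_matrix(n: int = 2000, p: int = 100, k: int = 5,
                               snr: float = 3.0, coef_scale: float = 1.0,
                               seed: int = 1,
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse linear response for elastic-net recovery tests.

    Returns (X, y, beta) with k nonzero coefficients; Gaussian noise is
    scaled so that sd(X beta) / sd(noise) = snr.  snr = inf gives a
    noiseless response.
    """
    if k > p:
        raise ValueError("k cannot exceed p")
    rng = _rng(seed, "regmat")
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    nz = rng.choice(p, size=k, replace=False)
    signs = rng.choice([-1.0, 1.0], size=k)
    beta[nz] = signs * coef_scale * rng.uniform(0.5, 1.5, size=k)
    signal = X @ beta
    if np.isfinite(snr) and snr > 0:
        noise_sd = signal.std() / snr
        y = signal + rng.normal(0.0, noise_sd, size=n)
    else:
        y = signal
    return X, y, beta


# ---------------------------------------------------------------------------
# Whole scene
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScene:
    """Everything one simulated study emits, plus its planted truth."""

    params: SimulationParams
    genes: list[Gene]
    chrom_sizes: dict[str, int]
    sites: pd.DataFrame                  # chrom start end name strand + counts
    cofactors: pd.DataFrame              # ctcf/rad21 densities + binary columns
    expression: ExpressionTable
    elongation: pd.DataFrame
    map_a: ContactMapStore
    map_b: ContactMapStore
    truth: GroundTruth

    @property
    def library_sizes(self) -> tuple[float, float]:
        return (self.params.library_size, self.params.library_size)


def simulate_scene(params: SimulationParams | None = None,
                   with_hic: bool = True) -> SyntheticScene:
    """Run every generator in dependency order and return the full scene."""
    params = params or SimulationParams()
    genes, chrom_sizes = simulate_genome(params)
    sites, truth = simulate_cohesin_peaks(params, genes)
    cof = simulate_cofactor_signals(params, sites, truth)
    expr, elong = simulate_expression_elongation(params, genes, truth)
    if with_hic:
        map_a, map_b, truth = simulate_contact_maps(params, sites, truth)
    else:
        map_a = ContactMapStore(params.resolution, dict(chrom_sizes))
        map_b = ContactMapStore(params.resolution, dict(chrom_sizes))
    truth.validate()
    return SyntheticScene(params, genes, chrom_sizes, sites, cof, expr,
                          elong, map_a, map_b, truth)
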