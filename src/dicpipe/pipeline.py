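"""Pipeline orchestration: config validation, staged execution, manifest.

A single YAML config houses every threshold of the analysis (M-value cutoff
tau = 0.5, elongation ratio 1.2, 10-kb flanks, 20-kb minimum gene length,
3-kb width cap, Hi-C windows) plus the simulation parameters and one seed.
The seed fans out to per-stage derived seeds via stable hashing so stages
can be rerun independently; deterministic stages are bit-reproducible under
a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffpeaks, hicmetrics, loopstats, mlfeat, sitecalls, synthio
from .formats import write_bed, write_bedpe, write_contact_map, write_expression, write_gene_table

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

CONFIG_DEFAULTS: dict = {
    "seed": 1,
    "tau": 0.5,
    "pseudocount": 1.0,
    "fit_method": "theilsen",
    "ratio_threshold": 1.2,
    "lfc_threshold": 0.0,
    "flank": 10_000,
    "min_gene_length": 20_000,
    "width_cap": 3_000,
    "tss_window": 10_000,
    "min_rad21": 1.0,
    "dlr_window": 75_000,
    "dlr_local_cutoff": 500_000,
    "is_square_width": 4,
    "apa_radius": 5,
    "kmeans_k": 10,
    "test_chroms": ["chr2"],
    "cv_folds": 5,
    "smote_k": 5,
    "elastic_alpha": 0.5,
    "simulation": {},
}

_SIM_KEYS = {f.name for f in dataclasses.fields(synthio.SimulationParams)}


class ConfigError(ValueError):
    pass


def validate_config(source) -> dict:
    """Validate a YAML config (path, text or dict); fill defaults.

    Unknown keys are rejected by name; thresholds must be positive; an
    empty file yields the all-defaults config.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = {**CONFIG_DEFAULTS, **raw}
    sim_unknown = set(cfg["simulation"]) - _SIM_KEYS
    if sim_unknown:
        raise ConfigError(f"unknown simulation key(s): {sorted(sim_unknown)}")
    for key in ("tau", "ratio_threshold", "flank", "min_gene_length",
                "width_cap", "tss_window", "dlr_window", "dlr_local_cutoff",
                "is_square_width", "apa_radius", "kmeans_k", "cv_folds",
                "smote_k"):
        if cfg[key] <= 0:
            raise ConfigError(f"config key {key!r} must be positive, "
                              f"got {cfg[key]}")
    if not 0.0 <= cfg["elastic_alpha"] <= 1.0:
        raise ConfigError("elastic_alpha must lie in [0, 1]")
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Derived per-stage seed (stable across runs and platforms)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Scene I/O
# ---------------------------------------------------------------------------

def write_scene(scene: synthio.SyntheticScene, outdir: Path) -> dict[str, Path]:
    """Write a self-contained scene directory in the pipeline's formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    sites = scene.sites[["chrom", "start", "end", "name", "strand",
                         "count_a", "count_b"]].copy()
    sites.insert(4, "score", 0)
    paths["sites"] = outdir / "sites.bed"
    write_bed(sites, paths["sites"])

    paths["genes"] = outdir / "genes.tsv"
    write_gene_table(scene.genes, paths["genes"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression(scene.expression, paths["expression"])
    paths["elongation"] = outdir / "elongation.tsv"
    scene.elongation.to_csv(paths["elongation"], sep="\t", index=False)
    paths["cofactors"] = outdir / "cofactors.tsv"
    scene.cofactors.to_csv(paths["cofactors"], sep="\t", index=False)

    paths["loops"] = outdir / "loops.bedpe"
    write_bedpe(scene.truth.planted_loops + scene.truth.stable_loops,
                paths["loops"])
    paths["map_a"] = outdir / "map_a.tsv"
    paths["map_b"] = outdir / "map_b.tsv"
    write_contact_map(scene.map_a, paths["map_a"])
    write_contact_map(scene.map_b, paths["map_b"])

    paths["truth"] = outdir / "truth.tsv"
    scene.truth.site_labels.to_csv(paths["truth"], sep="\t", index=False)
    chrom_sizes = pd.DataFrame(list(scene.chrom_sizes.items()),
                               columns=["chrom", "length"])
    paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
    chrom_sizes.to_csv(paths["chrom_sizes"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Staged pipeline
# ---------------------------------------------------------------------------

def run_diffpeaks(scene: synthio.SyntheticScene, cfg: dict) -> pd.DataFrame:
    union = scene.sites[["chrom", "start", "end", "name",
                         "count_a", "count_b"]].copy()
    union["matched"] = True
    return diffpeaks.diff_peak_table(
        union, tau=cfg["tau"], pseudocount=cfg["pseudocount"],
        library_sizes=scene.library_sizes, method=cfg["fit_method"],
        seed=stage_seed(cfg["seed"], "manorm"))


def run_dic_extraction(scene: synthio.SyntheticScene, diff: pd.DataFrame,
                       cfg: dict) -> pd.DataFrame:
    regions = sitecalls.derive_intragenic_regions(
        scene.genes, flank=cfg["flank"], min_length=cfg["min_gene_length"])
    located = sitecalls.classify_site_location(
        scene.sites, scene.genes, regions, tss_window=cfg["tss_window"])
    responsive = sitecalls.call_responsive_genes(
        scene.elongation, scene.expression,
        ratio_threshold=cfg["ratio_threshold"],
        lfc_threshold=cfg["lfc_threshold"])
    calls = sitecalls.extract_dics(
        diff, located, responsive, width_cap=cfg["width_cap"], tau=cfg["tau"])

    # LC/HC split on the called DICs
    calls["subtype"] = "none"
    dic_mask = calls["is_dic"].to_numpy()
    if dic_mask.sum() >= 2:
        cof = scene.cofactors.set_index("name")
        dics = calls.loc[dic_mask]
        split = sitecalls.split_lc_hc(
            dics, cof.loc[dics["name"], "ctcf_density"].to_numpy(),
            cof.loc[dics["name"], "rad21_density"].to_numpy(),
            min_rad21=cfg["min_rad21"],
            seed=stage_seed(cfg["seed"], "lchc"))
        calls.loc[split.index, "subtype"] = split["subtype"].to_numpy()
    return calls


def scene_feature_table(scene: synthio.SyntheticScene,
                        diff: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix for the scene: binary co-binding + z-scored continuous."""
    cof = scene.cofactors.set_index("name").loc[scene.sites["name"]]
    binary_cols = [c for c in cof.columns
                   if c not in ("ctcf_density", "rad21_density")]
    X = pd.DataFrame(index=pd.Index(scene.sites["name"], name="name"))
    X["chrom"] = scene.sites["chrom"].to_numpy()
    for c in binary_cols:
        X[c] = cof[c].to_numpy(float)
    m = diff.set_index("name").loc[scene.sites["name"], "M"].to_numpy(float)
    for name, vals in (("ctcf_density", np.log1p(cof["ctcf_density"].to_numpy())),
                       ("rad21_density", np.log1p(cof["rad21_density"].to_numpy())),
                       ("m_value", m)):
        X[name] = (vals - vals.mean()) / vals.std(ddof=0)
    return X


def run_pipeline(cfg: dict, outdir) -> dict:
    """Execute every stage in dependency order; write outputs + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "dicpipe 0.1.0", "stages": {}, "warnings": []}
    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    (outdir / "config.yaml").write_text(cfg_text)
    manifest["config_hash"] = hashlib.sha256(cfg_text.encode()).hexdigest()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (outdir / "manifest.json").write_text(
                    json.dumps(manifest, indent=2, default=str))
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.time() - t0, 3)}
            return result
        return deco

    sim_params = synthio.SimulationParams(
        seed=cfg["seed"], **cfg["simulation"])
    scene = stage("simulate")(lambda: synthio.simulate_scene(sim_params))
    stage("write_scene")(lambda: write_scene(scene, outdir / "scene"))

    diff = stage("diffpeaks")(lambda: run_diffpeaks(scene, cfg))
    diff_out = outdir / "diffpeaks.tsv"
    diff.drop(columns=["matched"]).to_csv(diff_out, sep="\t", index=False,
                                          float_format="%.6g")

    calls = stage("extract_dics")(lambda: run_dic_extraction(scene, diff, cfg))
    dics = calls[calls["is_dic"]]
    dic_bed = outdir / "dics.bed"
    with open(dic_bed, "w") as fh:
        for _, r in dics.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                     f"{r['name']}|{r['subtype']}\t0\t.\n")
    calls.to_csv(outdir / "site_calls.tsv", sep="\t", index=False,
                 float_format="%.6g")

    def _hic():
        dlr = hicmetrics.compute_dlr(
            scene.map_a, scene.map_b, window=cfg["dlr_window"],
            local_cutoff=cfg["dlr_local_cutoff"])
        ins = hicmetrics.compute_insulation(
            scene.map_a, square_width=cfg["is_square_width"])
        pairs = scene.truth.planted_loops
        t, p, apa_a, apa_b = hicmetrics.compare_apa(
            scene.map_a, scene.map_b, pairs, radius=cfg["apa_radius"])
        return dlr, ins, (t, p, apa_a, apa_b)

    dlr, ins, (apa_t, apa_p, apa_a, apa_b) = stage("hic_metrics")(_hic)
    dlr.table.to_csv(outdir / "delta_dlr.tsv", sep="\t", index=False,
                     float_format="%.6g")
    ins.table.to_csv(outdir / "insulation.tsv", sep="\t", index=False,
                     float_format="%.6g")

    def _loops():
        lab = calls.set_index("name")
        cat = {
            "DIC": scene.sites[lab.loc[scene.sites["name"], "is_dic"].to_numpy()],
            "other": scene.sites[~lab.loc[scene.sites["name"], "is_dic"].to_numpy()],
        }
        all_loops = scene.truth.planted_loops + scene.truth.stable_loops
        return loopstats.loop_occurrence(cat, all_loops)

    occurrence = stage("loop_occurrence")(_loops)
    occurrence.to_csv(outdir / "loop_occurrence.tsv", sep="\t", index=False)

    features = stage("features")(lambda: scene_feature_table(scene, diff))
    feat_out = outdir / "features.tsv"
    features.to_csv(feat_out, sep="\t", float_format="%.6g")

    def _train():
        y = calls.set_index("name").loc[features.index, "is_dic"].to_numpy(int)
        # supervised variant excludes M value and CTCF signal
        X = features.drop(columns=["m_value", "ctcf_density"])
        split = mlfeat.make_split(X, cfg["test_chroms"], folds=cfg["cv_folds"],
                                  seed=stage_seed(cfg["seed"], "split"))
        model, metrics = mlfeat.train_dic_classifier(
            X, y, split, smote_k=cfg["smote_k"],
            seed=stage_seed(cfg["seed"], "train"))
        return model, metrics

    model, metrics = stage("train")(_train)

    summary = {
        "n_sites": int(len(scene.sites)),
        "n_dics": int(calls["is_dic"].sum()),
        "n_hc": int((calls["subtype"] == "HC").sum()),
        "n_lc": int((calls["subtype"] == "LC").sum()),
        "ma_intercept": diff.attrs["normalization"]["a"],
        "apa_t": apa_t, "apa_p": apa_p,
        "apa_score_a": apa_a.score, "apa_score_b": apa_b.score,
        "test_auroc": metrics["auroc"],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.setdefault("checksums", {})[
                str(f.relative_to(outdir))] = _sha256(f)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    manifest["summary"] = summary
    return manifest
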