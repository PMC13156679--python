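"""End-to-end orchestration: simulate -> preprocess -> segment -> quantify
-> batch-correct -> cluster -> markers, from a single config with derived
seeds, structured logging and a JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import quant, segment, stats
from . import preprocess as pp
from .synthetic import SimConfig, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "compare_groups_report"]


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name for the audit log."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage={stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters with the analysis defaults.

    Exactly one input source: ``sim`` (a synthetic-experiment template;
    one CTR/EGF pair per ``pair`` with derived seeds) or ``imzml_paths``
    (+ ``brightfield_paths`` and ``metadata``, a per-sample table).
    """

    sim: SimConfig | None = None
    n_pairs: int = 2
    imzml_paths: list | None = None
    brightfield_paths: list | None = None
    metadata: pd.DataFrame | None = None

    # preprocessing
    tol_da: float = 0.1
    snr_min: float = 6.0
    kmeans_k: int = 2
    ratio_min: float = 5.0
    # segmentation
    sigma_px: float = 5.0
    area_range: tuple[float, float] = (100.0, 2500.0)
    aspect_range: tuple[float, float] = (0.75, 1.25)
    # clustering
    k_neighbors: tuple[int, ...] = cl.DEFAULT_K_NEIGHBORS
    resolutions: tuple[float, ...] = cl.DEFAULT_RESOLUTIONS
    n_iter: int = 500
    subsample: float = 0.8
    k_override: int | None = None
    n_pcs: int = 10
    # markers
    fc_high: float = 1.5
    fc_low: float = 0.667
    marker_alpha: float = 0.01
    seed: int = 0
    out_dir: Path | None = None

    def validate(self) -> None:
        if (self.sim is None) == (self.imzml_paths is None):
            raise ValueError("exactly one of sim / imzml_paths must be set")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")
        for name, val in (("snr_min", self.snr_min), ("ratio_min", self.ratio_min)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.fc_low < 1 < self.fc_high:
            raise ValueError("need fc_low < 1 < fc_high")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a pipeline config (optionally with a nested sim block) from YAML."""
        import yaml

        from .synthetic import SimConfig

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("sim"), dict):
            sim_raw = raw["sim"]
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown sim keys: {sorted(bad)}")
            for key in ("grid_shape", "mz_range", "colony_radius_px"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            raw["sim"] = SimConfig(**sim_raw)
        for key in ("area_range", "aspect_range", "k_neighbors", "resolutions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def defaults_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for drop in ("sim", "metadata", "imzml_paths", "brightfield_paths", "out_dir"):
            d.pop(drop, None)
        return d


def _match_features(tables: dict[str, pp.PeakTable], tol_da: float):
    """Match per-sample feature m/z centers into shared features.

    Greedy 1-D clustering of the pooled centers (same rule as peak
    alignment); only features observed in every sample are kept.  Returns
    (consensus m/z, {sample: column indices}).
    """
    recs = []
    for sid, pt in tables.items():
        for j, mz in enumerate(pt.features):
            recs.append((float(mz), sid, j))
    recs.sort()
    groups, current = [], [recs[0]]
    for r in recs[1:]:
        if r[0] - current[-1][0] > tol_da:
            groups.append(current)
            current = [r]
        else:
            current.append(r)
    groups.append(current)
    centers, maps = [], {sid: [] for sid in tables}
    for grp in groups:
        sids = {r[1] for r in grp}
        if sids != set(tables):
            continue
        by_sample = {}
        for mz, sid, j in grp:
            by_sample.setdefault(sid, j)  # first (lowest-m/z) hit per sample
        centers.append(float(np.mean([mz for mz, _, _ in grp])))
        for sid, j in by_sample.items():
            maps[sid].append(j)
    return np.asarray(centers), {sid: np.asarray(js, dtype=int) for sid, js in maps.items()}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and optionally writes) the report."""
    cfg.validate()
    report: dict = {"parameters": cfg.defaults_dict(), "samples": {}}
    rng = np.random.default_rng(cfg.seed)

    # --- stage: inputs -------------------------------------------------
    samples: dict[str, dict] = {}
    truths: dict[str, object] = {}
    if cfg.sim is not None:
        base = cfg.sim
        for pair in range(1, cfg.n_pairs + 1):
            batch_scale = float(1.2 ** rng.normal())
            for treatment in ("CTR", "EGF"):
                sid = f"{treatment}{pair}"
                conf = base.with_(
                    treatment=treatment,
                    pair_id=f"P{pair}",
                    sample_id=sid,
                    batch_scale=batch_scale,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    n_singletons=base.n_singletons if treatment == "EGF" else max(base.n_singletons // 2, 4),
                    n_colonies=base.n_colonies if treatment == "CTR" else max(base.n_colonies // 2, 1),
                )
                ds, bf, truth = simulate_experiment(conf)
                samples[sid] = {"ds": ds, "bf": bf, "treatment": treatment, "pair_id": f"P{pair}"}
                truths[sid] = truth
    else:
        for i, path in enumerate(cfg.imzml_paths):
            meta = cfg.metadata.iloc[i] if cfg.metadata is not None else {}
            sid = str(meta.get("sample_id", f"S{i + 1}"))
            ds = pp.read_imzml(
                path,
                sample_id=sid,
                treatment=str(meta.get("treatment", "CTR")),
                pair_id=str(meta.get("pair_id", "P1")),
            )
            bf = None
            if cfg.brightfield_paths:
                import tifffile

                bf = segment.BrightfieldImage(
                    pixels=tifffile.imread(cfg.brightfield_paths[i]),
                    um_per_px=float(meta.get("bf_um_per_px", 1.0)),
                )
            samples[sid] = {
                "ds": ds,
                "bf": bf,
                "treatment": ds.treatment,
                "pair_id": ds.pair_id,
            }

    # --- stage: preprocess --------------------------------------------
    tables, parts = {}, {}
    for sid, s in samples.items():
        logger.info("preprocess: %s", sid)
        ds = pp.tic_normalize(s["ds"])
        pt = pp.peak_table_from_dataset(ds, tol_da=cfg.tol_da)
        part = pp.spatial_kmeans(pt, k=cfg.kmeans_k, seed=cfg.seed)
        tables[sid], parts[sid] = pt, part

    centers, col_maps = _match_features(tables, cfg.tol_da)
    votes = np.zeros(len(centers))
    for sid in samples:
        spec_idx = pp.cell_specific_peaks(tables[sid], parts[sid], ratio_min=cfg.ratio_min)
        votes += np.isin(col_maps[sid], spec_idx)
    shared_specific = np.where(votes >= len(samples) / 2.0)[0]
    report["n_shared_features"] = int(len(centers))
    report["n_cell_specific_features"] = int(len(shared_specific))

    # --- stage: segment ------------------------------------------------
    for sid, s in samples.items():
        if s["bf"] is None:
            raise PipelineError(
                "segment", f"sample {sid}: no brightfield image supplied; cannot continue past preprocess"
            )
    assignments = {}
    for sid, s in samples.items():
        logger.info("segment: %s", sid)
        mask = segment.blur_and_threshold(s["bf"], sigma_px=cfg.sigma_px)
        cs = segment.find_contours(mask, um_per_px=s["bf"].um_per_px)
        cs = segment.filter_single_cell_contours(cs, cfg.area_range, cfg.aspect_range)
        ca = segment.assign_pixels(cs, parts[sid], s["bf"])
        ca.sample_id = sid
        assignments[sid] = ca

    meta = pd.DataFrame(
        {"treatment": [s["treatment"] for s in samples.values()]},
        index=list(samples),
    )
    pop = segment.population_summary(assignments, meta)
    report["population_summary"] = pop.to_dict(orient="index")
    for col, key in (("pct_cell_pixels", "cell_pixel_pct_test"), ("pct_dispersed", "dispersed_pct_test")):
        groups = [pop.loc[pop["treatment"] == t, col].dropna().to_numpy() for t in ("CTR", "EGF")]
        if all(len(g) >= 2 for g in groups):
            t, df, p = stats.two_sample_t_test(*groups)
            report[key] = {"t": t, "df": df, "p": p}

    # --- stage: extract ------------------------------------------------
    mats = []
    for sid, s in samples.items():
        cols = col_maps[sid][shared_specific]
        cfm = quant.extract_units(
            tables[sid],
            assignments[sid],
            cols,
            mode="single_cell",
            sample_id=sid,
            treatment=s["treatment"],
            pair_id=s["pair_id"],
        )
        cfm.values.columns = [f"mz_{centers[j]:.4f}" for j in shared_specific]
        mats.append(cfm)
    values = pd.concat([m.values for m in mats])
    obs = pd.concat([m.obs for m in mats])
    cells = quant.CellFeatureMatrix(values=values, obs=obs)
    report["n_cells"] = int(cells.n_units)
    report["cells_per_group"] = obs["treatment"].value_counts().to_dict()
    report["group_shares_pct"] = segment.group_cell_shares(
        obs["treatment"].value_counts().to_dict()
    )

    # --- stage: batch correction, scaling, embedding -------------------
    corrected, _model = quant.combat_correct(cells)
    scaled = quant.zscore_scale(corrected)
    n_pcs = min(cfg.n_pcs, scaled.n_units - 1, scaled.values.shape[1])
    scores, evr, _ = quant.pca_embed(scaled, n_components=n_pcs)
    report["pca_explained_variance_ratio"] = [float(v) for v in evr]

    # --- stage: consensus clustering -----------------------------------
    cc = cl.consensus_cluster(
        scaled.values.to_numpy(),
        k_values=tuple(k for k in cfg.k_neighbors if k < scaled.n_units),
        resolutions=cfg.resolutions,
        n_iter=cfg.n_iter,
        subsample=cfg.subsample,
        seed=cfg.seed,
    )
    if not cc.consensus:
        raise PipelineError("cluster", "no candidate cluster count retained")
    cc = cl.select_k(cc, scores, override=cfg.k_override)
    labels = cc.labels
    report["k_ranking"] = [
        {"K": int(K), "mean_silhouette": cc.silhouettes[K], "n_partitions": cc.n_partitions[K]}
        for K in cc.ranking
    ]
    report["selected_k"] = int(cc.selected_k)
    comp = (
        pd.crosstab(labels, obs["treatment"], normalize="index")
        .rename_axis(index="cluster")
    )
    report["cluster_composition"] = comp.to_dict(orient="index")

    # --- stage: markers ------------------------------------------------
    marker_tables = {}
    for K in np.unique(labels):
        in_c = labels == K
        if in_c.sum() < 4 or (~in_c).sum() < 4:
            continue
        spec = stats.ComparisonSpec(
            group_a=in_c,
            group_b=~in_c,
            alpha=cfg.marker_alpha,
            fc_high=cfg.fc_high,
            fc_low=cfg.fc_low,
            name=f"cluster{K}_vs_rest",
        )
        marker_tables[int(K)] = stats.find_markers(corrected.values, spec)
    report["n_markers_per_cluster"] = {
        k: int(t["is_marker"].sum()) for k, t in marker_tables.items()
    }

    result = {
        "report": report,
        "cells": cells,
        "corrected": corrected,
        "scaled": scaled,
        "scores": scores,
        "consensus": cc,
        "labels": labels,
        "markers": marker_tables,
        "assignments": assignments,
        "population": pop,
        "truths": truths,
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
        cells.to_tsv(out / "cells.tsv", out / "cells_annotations.tsv")
        pd.DataFrame({"cell": cells.values.index, "cluster": labels}).to_csv(
            out / "labels.tsv", sep="\t", index=False
        )
        pop.to_csv(out / "population_summary.tsv", sep="\t")
        for k, t in marker_tables.items():
            t.to_csv(out / f"markers_cluster{k}.tsv", sep="\t")
    return result


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, Path):
        return str(x)
    return str(x)


def compare_groups_report(result: dict, out_dir=None) -> dict[str, pd.DataFrame]:
    """The numeric tables behind the standard figures.

    Returns the CSV-ready frames: cell-pixel and dispersed percentage
    box-plot data, paired dot-plot data (one row per pair x feature),
    PCA scores, the cluster x feature heatmap matrix of scaled means,
    t-SNE coordinates, and cluster composition fractions.
    """
    pop = result["population"]
    scaled = result["scaled"]
    labels = result["labels"]
    obs = scaled.obs

    boxes = pop.reset_index()[["sample_id", "treatment", "pct_cell_pixels", "pct_dispersed"]]

    sample_means = result["corrected"].values.groupby(obs["sample_id"]).mean()
    pair_map = obs.drop_duplicates("sample_id").set_index("sample_id")[["pair_id", "treatment"]]
    long = sample_means.join(pair_map).melt(
        id_vars=["pair_id", "treatment"], var_name="feature", value_name="intensity", ignore_index=False
    )
    dots = (
        long.pivot_table(
            index=["pair_id", "feature"], columns="treatment", values="intensity", aggfunc="mean"
        )
        .add_prefix("intensity_")
        .reset_index()
    )

    scores = pd.DataFrame(
        result["scores"][:, :2], columns=["PC1", "PC2"], index=scaled.values.index
    ).join(obs[["treatment", "pair_id"]])
    scores["cluster"] = labels

    heat = scaled.values.groupby(pd.Series(labels, index=scaled.values.index)).mean()
    heat.index.name = "cluster"

    tsne = pd.DataFrame(
        cl.tsne_embed(scaled.values.to_numpy(), seed=result["consensus"].seed),
        columns=["tSNE1", "tSNE2"],
        index=scaled.values.index,
    )
    tsne["cluster"] = labels
    tsne["treatment"] = obs["treatment"].to_numpy()

    comp = pd.crosstab(labels, obs["treatment"], normalize="index")
    comp.index.name = "cluster"

    frames = {
        "population_boxes": boxes,
        "paired_dots": dots,
        "pca_scores": scores,
        "heatmap_matrix": heat,
        "tsne_coords": tsne,
        "cluster_composition": comp,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(out / f"{name}.csv")
    return frames
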