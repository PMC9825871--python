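"""End-to-end pipeline: config, stage orchestration, result bundle.

One config object (loadable from YAML) drives every stage; every effective
parameter and every per-stage seed is echoed to a manifest so that the
manifest alone is sufficient to re-run the pipeline identically.  Stage
random streams are independent substreams of the master seed, so individual
stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, diversity, drivers, network, niche
from .matrix import (
    CommunityMatrix,
    align,
    read_community_table,
    read_metadata,
    write_community_table,
    write_metadata,
)
from .synthetic import StudyConfig, make_study_like

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "generate_fixtures"]

log = logging.getLogger("microassembly")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; no hidden defaults.

    Either ``tables`` + ``metadata`` point at TSV inputs, or ``synthetic``
    holds keyword arguments for :class:`~microassembly.synthetic.StudyConfig`
    and the pipeline generates its own inputs.
    """

    out_dir: str = "results"
    seed: int = 0
    tables: dict = field(default_factory=dict)     # marker name -> TSV path
    metadata: str | None = None                    # metadata TSV path
    synthetic: dict | None = None                  # StudyConfig kwargs
    rarefy: bool = False
    rho_threshold: float = 0.6
    q_threshold: float = 0.01
    prevalence_min: float = network.DEFAULT_PREVALENCE_MIN
    overlap_percentile: float = niche.DEFAULT_OVERLAP_PERCENTILE
    occupancy_min: int = niche.DEFAULT_OCCUPANCY_MIN
    nst_metric: str = "jaccard"
    nst_n_null: int = 1000
    null_algorithm: str = "PF"
    robustness_fraction: float = 0.5
    robustness_reps: int = 100
    n_permutations: int = 999
    rf_trees: int = 500
    drivers_response: str = "multiaxis"  # or "axis1"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.rho_threshold < 1):
            raise ValueError("rho_threshold must be in (0, 1)")
        if not (0 < self.q_threshold <= 1):
            raise ValueError("q_threshold must be in (0, 1]")
        if not (0 <= self.prevalence_min <= 1):
            raise ValueError("prevalence_min must be in [0, 1]")
        if not (0 < self.robustness_fraction < 1):
            raise ValueError("robustness_fraction must be in (0, 1)")
        if self.nst_metric not in ("bray_curtis", "jaccard"):
            raise ValueError(f"unknown nst_metric {self.nst_metric!r}")
        if self.drivers_response not in ("multiaxis", "axis1"):
            raise ValueError(f"unknown drivers_response {self.drivers_response!r}")
        if self.synthetic is None and not (self.tables and self.metadata):
            raise ValueError("config needs either input paths or a synthetic spec")


@dataclass
class ResultBundle:
    """Artifacts of one run: tables, networks, scalar summaries, manifest."""

    out_dir: Path
    tables: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def write_summary(self) -> None:
        with open(self.out_dir / "summary.json", "w") as fh:
            json.dump(self.summaries, fh, indent=2, default=_jsonable)
        with open(self.out_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage_seed(master: int, stage: str) -> int:
    """Stable per-stage substream of the master seed (below 2**31)."""
    import zlib

    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_fixtures(config: RunConfig, force: bool = False) -> dict:
    """Write synthetic study-like inputs (tables, metadata, truth) to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bacteria": out / "bacteria_counts.tsv",
        "fungi": out / "fungi_counts.tsv",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.json",
    }
    existing = [p for p in paths.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(f"refusing to overwrite {existing[0]} (use force)")
    study = StudyConfig(**(config.synthetic or {}))
    bact, fungi, meta, truth = make_study_like(study, seed=config.seed)
    write_community_table(bact, paths["bacteria"])
    write_community_table(fungi, paths["fungi"])
    write_metadata(meta, paths["metadata"])
    paths["truth"].write_text(truth.to_json())
    return {k: str(v) for k, v in paths.items()}


def _load_inputs(config: RunConfig):
    """Tables + metadata, from files or the synthetic generator."""
    if config.tables and config.metadata:
        tables = {
            name: read_community_table(path) for name, path in config.tables.items()
        }
        meta = read_metadata(config.metadata)
    else:
        study = StudyConfig(**(config.synthetic or {}))
        bact, fungi, meta, _ = make_study_like(study, seed=config.seed)
        tables = {"bacteria": bact, "fungi": fungi}
    return tables, meta


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute every stage in order and write all artifacts.

    Stages: load/align -> diversity + ordination + PERMANOVA -> distance
    decay -> niche -> NCM + NST per region -> per-region networks ->
    topology + robustness + negative links -> drivers.  A stage failure
    aborts with the stage name; artifacts written so far stay on disk next
    to a FAILED marker.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(out_dir=out)
    bundle.manifest = {"config": asdict(config), "stage_seeds": {}, "stages": []}

    stage = "load"
    try:
        t0 = time.time()
        tables, meta = _load_inputs(config)
        aligned = {}
        for name, mat in tables.items():
            m, meta_m = align(mat, meta)
            if config.rarefy:
                from .matrix import rarefy as _rarefy

                m = _rarefy(m, seed=_stage_seed(config.seed, f"rarefy/{name}"))
            aligned[name] = (m, meta_m)
        _log_stage(bundle, stage, t0)

        for name, (mat, meta_m) in aligned.items():
            region = meta_m["region"]

            stage = f"diversity/{name}"
            t0 = time.time()
            alpha = diversity.alpha_diversity(mat)
            alpha["region"] = region
            alpha.to_csv(out / f"{name}_alpha.tsv", sep="\t")
            dist = diversity.bray_curtis(mat)
            dist.to_csv(out / f"{name}_braycurtis.tsv", sep="\t")
            ordi = diversity.pcoa(dist, n_axes=2)
            ordi.coordinates.to_csv(out / f"{name}_pcoa.tsv", sep="\t")
            perm = diversity.permanova(
                dist, region, n_permutations=config.n_permutations,
                seed=_stage_seed(config.seed, stage),
            )
            evenness_p = diversity.group_compare(
                alpha["pielou"].to_numpy(), region.to_numpy()
            )
            bundle.summaries[f"{name}/permanova"] = asdict(perm)
            bundle.summaries[f"{name}/pielou_region_p"] = evenness_p
            _log_stage(bundle, stage, t0)

            stage = f"distance_decay/{name}"
            t0 = time.time()
            decay = diversity.distance_decay(dist, meta_m)
            bundle.summaries[stage] = asdict(decay)
            _log_stage(bundle, stage, t0)

            stage = f"niche/{name}"
            t0 = time.time()
            breadth = niche.levins_breadth(mat)
            breadth.rename("levins_breadth").to_csv(out / f"{name}_breadth.tsv", sep="\t")
            overlap = niche.levins_overlap(mat)
            thr = niche.default_overlap_threshold(overlap, config.overlap_percentile)
            bundle.summaries[stage] = {
                "Bcom": niche.community_breadth(mat, config.occupancy_min),
                "overlap_threshold": thr,
                "overlap_network_degree": niche.overlap_degree(overlap, thr),
            }
            _log_stage(bundle, stage, t0)

            stage = f"assembly/{name}"
            t0 = time.time()
            ncm = assembly.fit_ncm(mat)
            ncm.taxa.to_csv(out / f"{name}_ncm_taxa.tsv", sep="\t")
            nst_res = assembly.nst(
                mat, region, metric=config.nst_metric, n_null=config.nst_n_null,
                algorithm=config.null_algorithm, seed=_stage_seed(config.seed, stage),
            )
            nst_res.pairs.to_csv(out / f"{name}_nst_pairs.tsv", sep="\t", index=False)
            bundle.summaries[stage] = {
                "ncm": {"m": ncm.m, "Nm": ncm.Nm, "N": ncm.N, "R2": ncm.R2},
                "nst_percent": nst_res.group_nst,
                "nst_class": nst_res.classification(),
            }
            _log_stage(bundle, stage, t0)

            stage = f"network/{name}"
            t0 = time.time()
            rob_by_region = {}
            for reg in pd.unique(region):
                ids = region.index[region == reg]
                sub = mat.select_samples(ids).drop_empty_taxa()
                net = network.build_network(
                    sub,
                    rho_threshold=config.rho_threshold,
                    q_threshold=config.q_threshold,
                    prevalence_min=config.prevalence_min,
                )
                key = f"{name}/{reg}"
                bundle.networks[key] = net
                net.write_edgelist(out / f"{name}_{reg}_edges.tsv")
                net.write_graphml(out / f"{name}_{reg}_network.graphml")
                summary = {"n_nodes": net.n_nodes, "n_edges": net.n_edges,
                           **net.construction_params}
                if net.n_edges:
                    topo = network.topology(net)
                    rob = network.robustness(
                        net, config.robustness_fraction, config.robustness_reps,
                        seed=_stage_seed(config.seed, f"{stage}/{reg}"),
                    )
                    rob_by_region[reg] = rob
                    pd.Series(rob.per_rep, name="remaining_proportion").to_csv(
                        out / f"{name}_{reg}_robustness.tsv", sep="\t", index=False
                    )
                    summary.update({
                        "mean_degree": topo["mean_degree"],
                        "modularity": topo["modularity"],
                        "negative_link_proportion":
                            network.negative_link_proportion(net),
                        "robustness_mean": rob.mean,
                        "robustness_sd": rob.sd,
                    })
                bundle.summaries[f"network/{key}"] = summary
            if len(rob_by_region) == 2:
                a, b = rob_by_region.values()
                bundle.summaries[f"network/{name}/robustness_region_p"] = (
                    network.compare_robustness(a, b)
                )
            _log_stage(bundle, stage, t0)

            stage = f"drivers/{name}"
            t0 = time.time()
            predictor_cols = [
                c for c in ("aridity_index", "MAT", "MAP", "pH", "TC", "TN",
                            "DOC", "DON", "NO3", "NH4")
                if c in meta_m.columns and meta_m[c].notna().all()
            ]
            if config.drivers_response == "multiaxis":
                imp = drivers.rf_importance_multiaxis(
                    mat, meta_m[predictor_cols], n_trees=config.rf_trees,
                    seed=_stage_seed(config.seed, stage),
                )
            else:
                response = drivers.composition_response(
                    mat, orient_by=meta_m.get("aridity_index")
                )
                imp = drivers.rf_importance(
                    response, meta_m[predictor_cols], n_trees=config.rf_trees,
                    seed=_stage_seed(config.seed, stage),
                )
            imp.table.to_csv(out / f"{name}_importance.tsv", sep="\t", index=False)
            bundle.summaries[stage] = {
                "top_predictor": imp.top_predictor(),
                "model_r2": imp.model_r2,
            }
            _log_stage(bundle, stage, t0)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle.write_summary()
    return bundle


def _log_stage(bundle: ResultBundle, stage: str, t0: float) -> None:
    elapsed = time.time() - t0
    log.info("stage %-28s %.2fs", stage, elapsed)
    bundle.manifest["stages"].append({"stage": stage, "seconds": round(elapsed, 3)})
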