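"""End-to-end orchestration with config, logging, and JSON reports.

Stage order: align -> reduce/log/size-correct -> jaccard -> pcoa ->
BIC/k-select -> k-means -> affiliation -> phylo-PLS -> eco-projection ->
MANOVA -> pairwise -> phylogenetic signal per trait.  Every intermediate
table is written as CSV; the report JSON is byte-reproducible for a
fixed config and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

import ecomorph
from ecomorph import io_formats, measurements, ecospace, phylo_stats

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("ecomorph")


@dataclass
class PipelineConfig:
    traits: str
    habitat: str
    tree: str
    out_dir: str
    schema: str | None = None
    traits_stage: str = "raw"
    grafen_rho: float = 1.0
    kmax: int = 9
    plateau_eps: float = 0.05
    force_k: int | None = None
    kmeans_restarts: int = 100
    gmm_input: str = "pcoa"  # or "distmatrix-rows"
    eco_projection: str = "axes"  # or "scores"
    correlation_method: str = "pearson"
    n_perm: int = 10000
    seed: int = 20220214

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.gmm_input not in ("pcoa", "distmatrix-rows"):
            raise ValueError(f"unknown gmm_input {self.gmm_input!r}")
        if self.eco_projection not in ("axes", "scores"):
            raise ValueError(f"unknown eco_projection {self.eco_projection!r}")

    @classmethod
    def from_json(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**d)

    def canonical(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


class _StageRunner:
    def __init__(self):
        self.timings: dict[str, float] = {}

    def __call__(self, stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc
        dt = time.perf_counter() - t0
        self.timings[stage] = dt
        log.info("stage %s: done in %.2fs", stage, dt)
        return result


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return None if np.isnan(x) else x
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to
    ``report.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = _StageRunner()
    rng = np.random.default_rng(cfg.seed)
    seeds = {
        name: int(s)
        for name, s in zip(
            ("gmm", "kmeans", "pls", "manova", "signal"),
            rng.integers(0, 2**31 - 1, 5),
        )
    }

    # --- load & align -----------------------------------------------------
    def _load():
        traits = io_formats.read_trait_table(cfg.traits, stage=cfg.traits_stage)
        habitat = io_formats.read_microhabitat_table(cfg.habitat)
        tree = io_formats.read_newick(cfg.tree)
        return io_formats.align_species(trait=traits, habitat=habitat, tree=tree)

    traits, habitat, tree = run("align", _load)
    if not tree.has_branch_lengths():
        tree = run("grafen", io_formats.grafen_branch_lengths, tree, cfg.grafen_rho)
    cov = run("vcv", io_formats.phylo_vcv, tree)
    cov = cov.reorder(traits.species_ids)

    # --- measurements -----------------------------------------------------
    def _measure(t):
        if t.stage == "raw":
            schema = (
                measurements.ReductionSchema.from_json(cfg.schema)
                if cfg.schema
                else measurements.default_reduction_schema()
            )
            t = measurements.reduce_variables(t, schema)
        if t.stage == "reduced":
            t = measurements.log_transform(t)
        if t.stage == "log":
            s = measurements.iso_size(t)
            t = measurements.size_correct(t, s)
            return t, s
        return t, None

    corrected, isosize = run("size_correct", _measure, traits)
    corrected.to_csv(out / "corrected_traits.csv")

    # --- ecospace ---------------------------------------------------------
    D = run("jaccard", ecospace.jaccard_distance, habitat)
    D.to_csv(out / "distances.csv")
    ordination = run("pcoa", ecospace.pcoa, D)
    ordination.to_csv(out / "pcoa_scores.csv")

    gmm_X = ordination.scores if cfg.gmm_input == "pcoa" else D.values
    curve = run(
        "bic", ecospace.gmm_bic_curve, gmm_X, cfg.kmax, seed=seeds["gmm"]
    )
    curve.to_csv(out / "bic_curve.csv")
    k = cfg.force_k or run("select_k", ecospace.select_k_plateau, curve, cfg.plateau_eps)
    clusters = run(
        "kmeans",
        ecospace.kmeans_cluster,
        ordination.scores,
        k,
        cfg.kmeans_restarts,
        seeds["kmeans"],
        habitat.species_ids,
    )
    clusters.to_csv(out / "clusters.csv")
    TA = run(
        "trait_axis_corr",
        ecospace.trait_axis_correlation,
        habitat,
        ordination,
        cfg.correlation_method,
    )
    affiliation = run(
        "affiliation",
        ecospace.cluster_trait_affiliation,
        TA,
        clusters,
        cfg.correlation_method,
        habitat.descriptor_names,
    )
    affiliation.to_csv(out / "affiliation.csv")
    ranked = ecospace.name_clusters(affiliation)

    # --- phylogenetic statistics ------------------------------------------
    pls = run(
        "pls",
        phylo_stats.phylo_pls,
        ordination.scores,
        corrected.values,
        cov.C,
        cfg.n_perm,
        seeds["pls"],
    )
    _write_loadings(out / "pls_loadings.csv", ordination, corrected, pls)
    Y_eco = run(
        "eco_projection",
        phylo_stats.eco_project,
        corrected.values,
        cov.C,
        pls,
        cfg.eco_projection,
    )
    manova = run(
        "manova",
        phylo_stats.rrpp_manova,
        Y_eco,
        clusters.assignments,
        cov.C,
        cfg.n_perm,
        seeds["manova"],
    )
    pairwise = run("pairwise", phylo_stats.pairwise_group_tests, manova)

    def _signal():
        rows = []
        for j, name in enumerate(corrected.variable_names):
            kr = phylo_stats.physignal(
                corrected.values[:, j], cov.C, cfg.n_perm, seeds["signal"] + j
            )
            rows.append({"trait": name, "K": kr.K, "p": kr.p})
        kmult = phylo_stats.physignal(
            corrected.values, cov.C, cfg.n_perm, seeds["signal"]
        )
        return rows, {"K": kmult.K, "p": kmult.p}

    k_table, k_mult = run("physignal", _signal)

    report = _jsonify(
        {
            "selected_k": k,
            "bic_curve": {"k": curve.ks, "bic": list(curve.bic), "model": curve.model_names},
            "cluster_assignments": dict(
                zip(clusters.species_ids, clusters.assignments)
            ),
            "cluster_descriptor_ranking": ranked,
            "affiliation": {
                "descriptors": affiliation.descriptor_names,
                "clusters": affiliation.cluster_ids,
                "values": affiliation.values,
                "method": affiliation.method,
            },
            "pcoa": {
                "n_axes": ordination.n_axes,
                "proportion_explained": ordination.proportion_explained,
            },
            "pls": {"r": pls.r, "z": pls.z, "p": pls.p, "n_perm": pls.n_perm},
            "manova": manova.table(),
            "pairwise": pairwise.rows(),
            "phylo_signal": {"per_trait": k_table, "multivariate": k_mult},
            "provenance": {
                "config_sha256": cfg.sha256(),
                "seed": cfg.seed,
                "stage_seeds": seeds,
                "version": ecomorph.__version__,
            },
        }
    )
    payload = json.dumps(report, sort_keys=True, indent=1)
    (out / "report.json").write_text(payload + "\n", encoding="utf-8")
    log.info("report written to %s", out / "report.json")
    return report


def _write_loadings(path, ordination, corrected, pls) -> None:
    import pandas as pd

    x = pd.DataFrame(
        {
            "block": "ecology",
            "variable": [f"axis_{i + 1}" for i in range(len(pls.x_loadings))],
            "loading": pls.x_loadings,
        }
    )
    y = pd.DataFrame(
        {
            "block": "morphology",
            "variable": corrected.variable_names,
            "loading": pls.y_loadings,
        }
    )
    pd.concat([x, y], ignore_index=True).to_csv(path, index=False)
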