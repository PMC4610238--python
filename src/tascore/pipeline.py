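"""End-to-end pipeline: screen -> fit -> network -> TAS -> clustering/stats.

A :class:`RunConfig` carries every stage parameter plus the seed; the same
config always produces byte-identical numeric outputs.  Outputs are stamped
with the config hash, seed and package version so a result file can be
traced back to the exact run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import (
    binary_label_distance,
    bootstrap_support,
    cut_clusters,
    profile_distance,
    ward_cluster,
)
from .cohort import coaddiction, compare_groups
from .congruence import cadm_permutation_test, mantel_test
from .dose_response import DSSConfig, build_response_matrix
from .errors import InvalidConfigError, TascoreError
from .io import (
    read_dose_response,
    read_edges,
    write_dose_response,
    write_edges,
    write_json,
    write_matrix,
    write_network_summary,
)
from .network import TargetNetwork, assemble_network
from .synthetic import SimulationConfig, simulate_screen
from .tas import compute_tas

logger = logging.getLogger(__name__)

VALID_METRICS = ("DSS", "AUC", "pIC50")
VALID_DISTANCES = ("cosangle", "euclidean", "manhattan", "pearson", "spearman", "kendall")


@dataclass
class RunConfig:
    """Parameters of one pipeline run; round-trips losslessly through YAML."""

    seed: int = 0
    metric: str = "DSS"
    amin: float = 10.0
    dss_variant: str = "DSS1"
    distance: str = "cosangle"
    linkage: str = "ward"
    n_boot: int = 500
    n_perm: int = 1000
    k: int = 3
    rho_threshold: float = 0.94
    alpha: float = 1e-5
    max_nM: float = 35.0
    # inputs: either paths to measured data, or a simulation block
    dose_response_path: str | None = None
    network_path: str | None = None
    simulate: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        metric = self.metric if self.metric == "pIC50" else self.metric.upper()
        if metric.lower() == "pic50":
            metric = "pIC50"
        if metric not in VALID_METRICS:
            raise InvalidConfigError(f"unknown metric {self.metric!r}")
        self.metric = metric
        if self.distance not in VALID_DISTANCES:
            raise InvalidConfigError(f"unknown distance {self.distance!r}")
        if self.linkage != "ward":
            raise InvalidConfigError("only ward linkage is supported")
        # no dose_response_path means a synthetic run; an empty simulate
        # block then uses the generator defaults

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stamp(self) -> dict[str, str]:
        return {
            "config_hash": self.digest(),
            "seed": str(self.seed),
            "tascore_version": __version__,
        }


def _timed(name: str, start: float) -> None:
    logger.info("stage %-12s %6.2f s", name, time.perf_counter() - start)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute the configured stages, writing artifacts under ``out_dir``.

    Stages: acquire screen (simulate or read) -> fit and score responses ->
    assemble/accept network -> TAS -> clustering with bootstrap support ->
    congruence between response-space and target-space distances -> cohort
    statistics (when ground-truth labels exist).  Any stage failure raises a
    stage-named error; artifacts written so far remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = config.stamp()
    artifacts: dict[str, Path] = {}

    def _fail(stage: str, exc: Exception) -> None:
        raise TascoreError(f"stage {stage!r} failed: {exc}") from exc

    # --- acquire ---------------------------------------------------------
    t0 = time.perf_counter()
    truth = None
    try:
        if config.simulate or config.dose_response_path is None:
            sim = SimulationConfig(seed=config.seed, **config.simulate)
            series, truth, network = simulate_screen(sim)
            write_dose_response(out / "dose_response.tsv", series)
            artifacts["dose_response"] = out / "dose_response.tsv"
            write_matrix(out / "ground_truth_addiction.tsv", truth.addiction, stamp)
            truth.cluster_labels.to_frame().assign(
                biomarker=truth.biomarker_labels
            ).to_csv(out / "ground_truth_labels.tsv", sep="\t")
        else:
            series = read_dose_response(config.dose_response_path)
            if config.network_path is None:
                raise InvalidConfigError("network_path required with measured data")
            network = assemble_network(read_edges(config.network_path), max_nM=config.max_nM)
    except TascoreError as exc:
        _fail("acquire", exc)
    write_edges(out / "network_edges.tsv", network)
    write_network_summary(out / "network_summary.tsv", network)
    artifacts["network"] = out / "network_edges.tsv"
    _timed("acquire", t0)

    # --- fit -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        dss_cfg = DSSConfig(amin=config.amin, variant=config.dss_variant)
        responses = build_response_matrix(series, config.metric, dss_cfg)
    except TascoreError as exc:
        _fail("fit", exc)
    meta = dict(stamp, metric=responses.metric, amin=str(config.amin), variant=config.dss_variant)
    write_matrix(out / "responses.tsv", responses.data, meta)
    artifacts["responses"] = out / "responses.tsv"
    _timed("fit", t0)

    # --- tas -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        tas = compute_tas(responses, network)
    except TascoreError as exc:
        _fail("tas", exc)
    write_matrix(
        out / "tas.tsv",
        tas.data,
        dict(stamp, metric=tas.metric, n_t=";".join(f"{t}={n}" for t, n in tas.n_t.items())),
    )
    artifacts["tas"] = out / "tas.tsv"
    _timed("tas", t0)

    # --- cluster ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        tas_dist = profile_distance(tas.data, config.distance)
        tree = ward_cluster(tas_dist)
        labels = cut_clusters(tree, config.k)
        support = bootstrap_support(
            tas.data, config.distance, n_boot=config.n_boot, seed=config.seed
        )
    except TascoreError as exc:
        _fail("cluster", exc)
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    support.table.to_csv(out / "support.tsv", sep="\t", index=False)
    artifacts["dendrogram"] = out / "dendrogram.nwk"
    artifacts["support"] = out / "support.tsv"
    _timed("cluster", t0)

    # --- congruence ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        resp_dist = profile_distance(responses.data, config.distance)
        cadm = cadm_permutation_test(
            [resp_dist, tas_dist], n_perm=config.n_perm, seed=config.seed
        )
        mantel = mantel_test(resp_dist, tas_dist, n_perm=config.n_perm, seed=config.seed)
        congruence_payload = {
            "response_vs_tas": {
                "W": cadm.w, "p": cadm.p_value, "N": cadm.n_pairs,
                "m": cadm.n_matrices, "n_perm": cadm.n_perm, "seed": cadm.seed,
                "mantel_r": mantel.r, "mantel_p": mantel.p_value,
            }
        }
        if truth is not None:
            planted = binary_label_distance(truth.cluster_labels.astype(str))
            cadm_t = cadm_permutation_test(
                [tas_dist, planted], n_perm=config.n_perm, seed=config.seed
            )
            congruence_payload["tas_vs_planted_clusters"] = {
                "W": cadm_t.w, "p": cadm_t.p_value, "N": cadm_t.n_pairs,
                "m": cadm_t.n_matrices, "n_perm": cadm_t.n_perm, "seed": cadm_t.seed,
            }
    except TascoreError as exc:
        _fail("congruence", exc)
    write_json(out / "congruence.json", dict(congruence_payload, **stamp))
    artifacts["congruence"] = out / "congruence.json"
    _timed("congruence", t0)

    # --- cohort (only with ground-truth labels) --------------------------
    if truth is not None:
        t0 = time.perf_counter()
        try:
            sim = SimulationConfig(seed=config.seed, **config.simulate)
            biomarker = sim.resolved_biomarker_target
            cohort_payload: dict = {}
            if biomarker in tas.data.columns:
                comp = compare_groups(tas.data[biomarker], truth.biomarker_labels)
                cohort_payload["biomarker"] = {
                    "target": biomarker, "p": comp.p_value, "method": comp.method,
                    "n_positive": comp.n_positive, "n_negative": comp.n_negative,
                }
                co = coaddiction(
                    tas, biomarker, config.rho_threshold, config.alpha, network=network
                )
                co.to_csv(out / "coaddiction.tsv", sep="\t", index=False)
                artifacts["coaddiction"] = out / "coaddiction.tsv"
        except TascoreError as exc:
            _fail("cohort", exc)
        write_json(out / "cohort.json", dict(cohort_payload, **stamp))
        artifacts["cohort"] = out / "cohort.json"
        _timed("cohort", t0)

    return artifacts
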