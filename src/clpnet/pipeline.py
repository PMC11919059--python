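"""End-to-end orchestration: read or simulate a panel, screen missingness,
impute, score, estimate the network, centrality, bootstraps and global
metrics, with every artifact written to disk and one master seed driving all
stochastic stages."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dass, missing, netmetrics, stability
from .centrality import expected_influence
from .estimate import EstimationConfig, SymptomNetwork, build_network
from .panel import PanelDataset
from .simulate import SimulationConfig, generate_true_network, simulate_panel

logger = logging.getLogger(__name__)


@dataclass
class StabilitySettings:
    n_boot: int = 1000
    drop_grid: tuple = stability.DEFAULT_DROP_GRID
    n_boot_per_level: int = 250
    run_edge_bootstrap: bool = True
    run_casedrop: bool = True


@dataclass
class SimulationBlock:
    n_cross_edges: int = 20
    effect_range: tuple = (0.3, 0.6)
    config: SimulationConfig = field(default_factory=SimulationConfig)


@dataclass
class RunConfig:
    """Exactly one of ``input_path`` / ``simulation`` must be set."""

    output_dir: str = "clpn_run"
    master_seed: int = 0
    input_path: str | None = None
    schema: dict | None = None
    simulation: SimulationBlock | None = None
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    stability: StabilitySettings = field(default_factory=StabilitySettings)
    n_random: int = 1000

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "config" in sim:
                sim["config"] = SimulationConfig(**sim["config"])
            if "effect_range" in sim:
                sim["effect_range"] = tuple(sim["effect_range"])
            raw["simulation"] = SimulationBlock(**sim)
        if "estimation" in raw and raw["estimation"] is not None:
            raw["estimation"] = EstimationConfig(**raw["estimation"])
        if "stability" in raw and raw["stability"] is not None:
            st = dict(raw["stability"])
            if "drop_grid" in st:
                st["drop_grid"] = tuple(st["drop_grid"])
            raw["stability"] = StabilitySettings(**st)
        return cls(**raw)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _write_json(path: Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(_to_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _seed_for(master_seed: int, stage: int) -> int:
    return int(np.random.SeedSequence(master_seed).generate_state(16)[stage] % (2**31))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order, writing a report bundle to the output
    directory.  Returns the manifest (also written as manifest.json).

    Stage order follows the analysis chain: acquire data, test missingness,
    impute, score, estimate the network, centrality, bootstraps, global
    metrics.  Any stage error aborts with the stage name and a
    partial-results manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": config.master_seed, "stages": [], "artifacts": {}}
    timings: dict = {}

    def _stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - report stage and re-raise
                manifest["failed_stage"] = name
                _write_json(out / "manifest.json", manifest)
                raise StageError(name, exc, manifest) from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            manifest["stages"].append(name)
            return result
        return wrap

    # -- acquire ----------------------------------------------------------
    def _acquire() -> PanelDataset:
        if config.input_path is not None:
            return dass.read_panel(config.input_path, config.schema)
        block = config.simulation
        sim_cfg = dataclasses.replace(block.config, seed=_seed_for(config.master_seed, 0))
        spec = generate_true_network(block.n_cross_edges, block.effect_range,
                                     seed=_seed_for(config.master_seed, 1))
        panel = simulate_panel(spec, sim_cfg)
        panel.to_csv(out / "panel.csv")
        spec.edge_list().to_csv(out / "true_edges.csv", index=False)
        spec.to_json(out / "true_network.json")
        manifest["artifacts"]["panel"] = "panel.csv"
        return panel

    panel = _stage("acquire")(_acquire)

    # -- missingness screen ------------------------------------------------
    def _screen():
        if panel.non_deceased().has_missing():
            report = missing.little_mcar_test(panel)
        else:
            report = missing.MissingnessReport(0.0, 0, 1.0, 1, "consistent_with_MCAR")
        _write_json(out / "missingness.json", report)
        manifest["artifacts"]["missingness"] = "missingness.json"
        try:
            attrition = dass.attrition_ttest(panel)
            _write_json(out / "attrition.json", attrition)
            manifest["artifacts"]["attrition"] = "attrition.json"
        except ValueError:
            logger.info("attrition comparison skipped (no dropout group)")
        return report

    _stage("missingness")(_screen)

    # -- impute ------------------------------------------------------------
    imputed = _stage("impute")(lambda: missing.em_impute(panel))

    # -- score / prevalence -------------------------------------------------
    def _score():
        table = dass.descriptives(imputed)
        table.to_csv(out / "descriptives.csv", index=False)
        manifest["artifacts"]["descriptives"] = "descriptives.csv"
        return table

    _stage("score")(_score)

    # -- estimate ------------------------------------------------------------
    def _estimate() -> SymptomNetwork:
        est = dataclasses.replace(config.estimation, seed=_seed_for(config.master_seed, 2))
        net = build_network(imputed, est)
        net.edges().to_csv(out / "network_edges.csv", index=False)
        net.to_graphml(out / "network.graphml")
        _write_json(out / "network.json", net.to_json())
        manifest["artifacts"]["network"] = "network_edges.csv"
        return net

    network = _stage("estimate")(_estimate)

    # -- centrality ----------------------------------------------------------
    def _centrality():
        table = expected_influence(network)
        table.to_csv(out / "centrality.csv", index=False)
        _write_json(out / "centrality.json", table.to_dict(orient="records"))
        manifest["artifacts"]["centrality"] = "centrality.csv"
        return table

    _stage("centrality")(_centrality)

    # -- bootstraps ----------------------------------------------------------
    est = dataclasses.replace(config.estimation, seed=_seed_for(config.master_seed, 2))
    if config.stability.run_edge_bootstrap:
        def _boot():
            boot = stability.edge_bootstrap(imputed, est,
                                            n_boot=config.stability.n_boot,
                                            seed=_seed_for(config.master_seed, 3))
            boot.edge_table().to_csv(out / "edge_bootstrap.csv", index=False)
            manifest["artifacts"]["edge_bootstrap"] = "edge_bootstrap.csv"
            manifest["edge_bootstrap_skipped"] = boot.n_skipped
            return boot
        _stage("edge_bootstrap")(_boot)

    if config.stability.run_casedrop:
        def _casedrop():
            rep = stability.casedrop_bootstrap(
                imputed, est, drop_grid=config.stability.drop_grid,
                n_boot_per_level=config.stability.n_boot_per_level,
                seed=_seed_for(config.master_seed, 4))
            _write_json(out / "cs_report.json", rep.to_json())
            stability.plot_stability_curve(rep, out / "stability_curve.png")
            manifest["artifacts"]["cs_report"] = "cs_report.json"
            return rep
        _stage("casedrop_bootstrap")(_casedrop)

    # -- global metrics --------------------------------------------------------
    def _metrics():
        gm = netmetrics.global_metrics(network, n_random=config.n_random,
                                       seed=_seed_for(config.master_seed, 5))
        _write_json(out / "global_metrics.json", gm.to_json())
        manifest["artifacts"]["global_metrics"] = "global_metrics.json"
        return gm

    _stage("global_metrics")(_metrics)

    manifest["config"] = _to_jsonable(config)
    _write_json(out / "manifest.json", manifest)
    logger.info("stage wall times (s): %s", timings)
    return manifest


def compare_groups(networks: list[SymptomNetwork], labels: list[str] | None = None,
                   n_random: int = 1000, seed: int = 0) -> dict:
    """Pairwise signed-edge Jaccard indices plus a per-group global-metrics
    table for two or more networks on the same nodes."""
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    labels = labels or [f"group{k}" for k in range(len(networks))]
    for net in networks[1:]:
        if net.nodes != networks[0].nodes:
            raise ValueError("networks must share an identical node label set")
    pairwise = []
    for a in range(len(networks)):
        for b in range(a + 1, len(networks)):
            cmp = netmetrics.jaccard_index(networks[a], networks[b])
            pairwise.append({"group_a": labels[a], "group_b": labels[b],
                             "jaccard": cmp.jaccard,
                             "n_shared_same_sign": cmp.n_shared_same_sign,
                             "n_union": cmp.n_union})
    metrics = {}
    for label, net in zip(labels, networks):
        gm = netmetrics.global_metrics(net, n_random=n_random, seed=seed)
        metrics[label] = gm.to_json()
    return {"pairwise": pairwise, "global_metrics": metrics}
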