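"""Configuration, file I/O, and the end-to-end analysis pipeline.

The pipeline reproduces the full analysis workflow: impute missing construct
scores, standardize, estimate the overall network (covariates age + group),
estimate the two group-specific networks (covariate age only), compute
expected-influence centralities, run case-drop bootstrap stability per
network, and compare the two group networks. Every stochastic stage draws
its seed deterministically from the single run seed, so a run is exactly
reproducible from its config: the same config and seed produce a
byte-identical JSON report.

Exchange formats are deliberately plain: wide CSV panels (``<node>_t1`` /
``<node>_t2`` columns), long CSV edge lists, GraphML networks, JSON reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .centrality import centrality_table, standardize_centrality
from .comparison import compare_networks
from .estimation import CLPNetwork, EstimationOptions, estimate_network
from .panel import InputError, PanelDataset, node_column
from .preprocess import descriptive_table, impute_random_forest, standardize
from .stability import case_drop_bootstrap, cs_coefficient
from .synthetic import (
    SimulationConfig,
    default_paper_like_config,
    ground_truth_edge_frame,
    simulate_panel,
)

logger = logging.getLogger("clpnet")

GROUP_CODE_COL = "group_code"


def configure_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler()  # stderr
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))


def derive_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (< 2**31) from the run seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(stage,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def infer_node_names(columns: Sequence[str]) -> list[str]:
    """Nodes present with both ``_t1`` and ``_t2`` columns, in column order."""
    t1 = [c[:-3] for c in columns if c.endswith("_t1")]
    t2 = {c[:-3] for c in columns if c.endswith("_t2")}
    return [n for n in t1 if n in t2]


def read_panel_csv(
    path: str | Path,
    node_names: Optional[Sequence[str]] = None,
    covariates: Sequence[str] = ("age",),
    group_col: Optional[str] = "group",
) -> PanelDataset:
    """Load a wide-format panel; NA/empty cells populate the missingness mask."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    frame = pd.read_csv(path)
    if node_names is None:
        node_names = infer_node_names(frame.columns)
        if not node_names:
            raise InputError(f"{path}: no '<node>_t1'/'<node>_t2' column pairs found")
    missing = [
        c
        for c in [node_column(n, w) for n in node_names for w in ("t1", "t2")]
        + list(covariates)
        if c not in frame.columns
    ]
    if missing:
        raise InputError(f"{path}: required column(s) missing: {missing}")
    if group_col is not None and group_col not in frame.columns:
        group_col = None
    numeric_cols = [node_column(n, w) for n in node_names for w in ("t1", "t2")] + list(covariates)
    for c in numeric_cols:
        try:
            frame[c] = pd.to_numeric(frame[c])
        except (ValueError, TypeError) as exc:
            raise InputError(f"{path}: column {c!r} is not numeric: {exc}") from exc
    data = PanelDataset(
        frame=frame,
        node_names=list(node_names),
        covariates=list(covariates),
        group_col=group_col,
    )
    logger.info(
        "read %s: n=%d, %d nodes, %d missing construct cells",
        path,
        data.n,
        data.p,
        int(data.mask[data.node_columns()].to_numpy().sum()),
    )
    return data


def write_panel_csv(data: PanelDataset, path: str | Path) -> None:
    data.frame.to_csv(path, index=False)


def network_to_graphml(net: CLPNetwork, path: str | Path) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(net.node_names)
    for i, src in enumerate(net.node_names):
        for j, dst in enumerate(net.node_names):
            if net.B[i, j] != 0.0:
                g.add_edge(src, dst, weight=float(net.B[i, j]))
    nx.write_graphml(g, path)


def network_from_edge_frame(edges: pd.DataFrame) -> CLPNetwork:
    """Rebuild a network from a long edge list (from,to,weight[,type])."""
    for col in ("from", "to", "weight"):
        if col not in edges.columns:
            raise InputError(f"edge list missing column {col!r}")
    nodes: list[str] = []
    for n in pd.concat([edges["from"], edges["to"]]):
        if n not in nodes:
            nodes.append(n)
    idx = {n: i for i, n in enumerate(nodes)}
    B = np.zeros((len(nodes), len(nodes)))
    for _, row in edges.iterrows():
        B[idx[row["from"]], idx[row["to"]]] = float(row["weight"])
    return CLPNetwork(node_names=nodes, B=B, n=0)


def read_network_csv(path: str | Path) -> CLPNetwork:
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge list not found: {path}")
    return network_from_edge_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative description of one full analysis run."""

    input: Optional[str] = None  # CSV path; mutually exclusive with simulation
    simulation: Optional[dict] = None  # {"preset": "paper_like", ...overrides}
    nodes: Optional[list[str]] = None
    covariates: list[str] = field(default_factory=lambda: ["age"])
    group_col: str = "group"
    estimation: dict = field(default_factory=dict)  # EstimationOptions kwargs
    imputation: dict = field(default_factory=lambda: {"n_trees": 100, "max_iter": 10})
    stability: dict = field(
        default_factory=lambda: {"enabled": True, "n_boot": 200, "drop_grid": None}
    )
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulation is None):
            raise InputError("exactly one of 'input' or 'simulation' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def build_simulation_config(spec: dict | str, seed: int) -> SimulationConfig:
    """Simulation config from a preset name or a full field dictionary."""
    if isinstance(spec, str):
        spec = {"preset": spec}
    spec = dict(spec)
    preset = spec.pop("preset", None)
    if preset is not None:
        if preset != "paper_like":
            raise InputError(f"unknown simulation preset {preset!r}")
        cfg = default_paper_like_config(seed=spec.pop("seed", seed))
        for key, value in spec.items():
            if not hasattr(cfg, key):
                raise InputError(f"unknown simulation override {key!r}")
            setattr(cfg, key, value)
        cfg.__post_init__()
        return cfg
    spec.setdefault("seed", seed)
    try:
        return SimulationConfig(**spec)
    except TypeError as exc:
        raise InputError(f"invalid simulation config: {exc}") from exc


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _network_report(net: CLPNetwork) -> dict:
    tab = centrality_table(net)
    try:
        std = standardize_centrality(tab)
        z = {"out_ei_z": std.out_ei_z.tolist(), "in_ei_z": std.in_ei_z.tolist()}
    except InputError:
        z = {"out_ei_z": None, "in_ei_z": None}
    return {
        "nodes": list(net.node_names),
        "n": net.n,
        "B": net.B.tolist(),
        "lambdas": net.lambdas.tolist() if net.lambdas is not None else None,
        "covariates": list(net.covariate_names),
        "out_ei": tab.out_ei.tolist(),
        "in_ei": tab.in_ei.tolist(),
        **z,
    }


def _min_group_size(p: int, n_cov: int, n_folds: int) -> int:
    return max(p + n_cov + 2, n_folds)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-wave network analysis; returns the JSON report.

    Stages: load/simulate -> impute -> descriptives -> standardize ->
    networks (overall + per group) -> centralities -> stability -> group
    comparison -> artifact writing. Any stage failure aborts with the stage
    name attached.
    """
    configure_logging(config.log_level)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": config.seed}
    stage = "load"
    try:
        truth = None
        if config.simulation is not None:
            sim_cfg = build_simulation_config(config.simulation, config.seed)
            data, truth = simulate_panel(sim_cfg)
            report["source"] = {"kind": "simulation", "config": sim_cfg.to_dict()}
        else:
            data = read_panel_csv(
                config.input, config.nodes, config.covariates, config.group_col
            )
            report["source"] = {"kind": "file", "path": str(config.input)}
        if config.nodes:
            data.node_names = list(config.nodes)
        report["n"] = data.n

        stage = "impute"
        if data.has_missing():
            n_missing = int(data.mask[data.node_columns()].to_numpy().sum())
            logger.info("imputing %d missing construct cells", n_missing)
            data = impute_random_forest(
                data, seed=derive_seed(config.seed, 1), **config.imputation
            )
            report["imputation"] = {"n_missing_cells": n_missing, **config.imputation}
        else:
            report["imputation"] = {"n_missing_cells": 0}

        stage = "descriptives"
        groups = data.groups()
        if len(groups) == 2:
            desc = descriptive_table(data)
            report["descriptives"] = desc.to_dict(orient="records")
        else:
            desc = None

        stage = "estimate"
        est_kwargs = dict(config.estimation)
        n_folds = est_kwargs.get("n_folds", 10)
        min_n = _min_group_size(data.p, len(config.covariates) + 1, n_folds)
        for g in groups:
            n_g = int((data.frame[data.group_col] == g).sum())
            if n_g < min_n:
                raise InputError(f"group {g!r} has n={n_g} below minimum {min_n}")

        networks: dict[str, CLPNetwork] = {}
        panels: dict[str, PanelDataset] = {}
        # overall network: all covariates plus 0/1 group code (two groups)
        overall = data.copy()
        overall_covs = list(config.covariates)
        if len(groups) == 2:
            codes = {g: i for i, g in enumerate(groups)}
            overall.frame[GROUP_CODE_COL] = overall.frame[data.group_col].map(codes).astype(float)
            overall.mask[GROUP_CODE_COL] = False
            overall.covariates = overall_covs + [GROUP_CODE_COL]
            overall_covs = overall.covariates
        overall_std, _ = standardize(overall)
        opts = EstimationOptions(seed=derive_seed(config.seed, 2), **est_kwargs)
        networks["overall"] = estimate_network(overall_std, overall_covs, opts)
        panels["overall"] = overall_std
        for gi, g in enumerate(groups):
            sub = data.group_subset(g)
            sub_std, _ = standardize(sub)
            opts_g = EstimationOptions(seed=derive_seed(config.seed, 3 + gi), **est_kwargs)
            networks[str(g)] = estimate_network(sub_std, config.covariates, opts_g)
            panels[str(g)] = sub_std

        report["networks"] = {label: _network_report(net) for label, net in networks.items()}

        stage = "stability"
        stab_cfg = dict(config.stability)
        if stab_cfg.pop("enabled", True):
            n_boot = stab_cfg.pop("n_boot", 200)
            drop_grid = stab_cfg.pop("drop_grid", None)
            from .stability import DEFAULT_DROP_GRID

            drop_grid = DEFAULT_DROP_GRID if drop_grid is None else drop_grid
            report["stability"] = {}
            for si, (label, panel) in enumerate(panels.items()):
                covs = networks[label].covariate_names
                res = case_drop_bootstrap(
                    panel,
                    options=EstimationOptions(
                        seed=derive_seed(config.seed, 10 + si), **est_kwargs
                    ),
                    drop_grid=drop_grid,
                    n_boot=n_boot,
                    seed=derive_seed(config.seed, 20 + si),
                    covariate_names=covs,
                )
                cs = cs_coefficient(res)
                report["stability"][label] = {
                    "cs": cs,
                    "n_boot": n_boot,
                    "drop_grid": list(np.asarray(drop_grid, dtype=float)),
                    "median_out_ei": res.median_curve("out_ei").tolist(),
                    "median_in_ei": res.median_curve("in_ei").tolist(),
                    "warnings": res.warnings,
                }
                if outdir:
                    res.long_frame().to_csv(outdir / f"stability_{label}.csv", index=False)

        stage = "compare"
        if len(groups) == 2:
            a, b = str(groups[0]), str(groups[1])
            cmp = compare_networks(
                networks[a],
                networks[b],
                centrality_table(networks[a]),
                centrality_table(networks[b]),
            )
            report["comparison"] = {"groups": [a, b], **cmp.to_dict()}

        stage = "write"
        if outdir:
            write_panel_csv(data, outdir / "panel.csv")
            if desc is not None:
                desc.to_csv(outdir / "descriptives.csv", index=False)
            for label, net in networks.items():
                net.edge_frame().to_csv(outdir / f"edges_{label}.csv", index=False)
                network_to_graphml(net, outdir / f"network_{label}.graphml")
                std_tab = None
                tab = centrality_table(net)
                try:
                    std_tab = standardize_centrality(tab)
                except InputError:
                    std_tab = tab
                std_tab.frame().to_csv(outdir / f"centrality_{label}.csv", index=False)
            if truth is not None:
                ground_truth_edge_frame(truth, data.node_names).to_csv(
                    outdir / "ground_truth_edges.csv", index=False
                )
            with open(outdir / "report.json", "w") as fh:
                fh.write(report_json(report))
    except InputError as exc:
        raise InputError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def report_json(report: dict) -> str:
    """Canonical serialization: key-sorted, so identical runs are byte-identical."""
    return json.dumps(report, indent=2, sort_keys=True)
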