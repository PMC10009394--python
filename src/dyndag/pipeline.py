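"""End-to-end pipeline: panel -> scores -> structure sample -> effects -> report.

A single config (YAML or JSON, or an equivalent dict) drives every stage;
the seed is mandatory and feeds every source of randomness, so re-running
the same config reproduces all non-figure outputs byte-identically.  Each
stage writes its machine-readable export into the output directory, and a
manifest records the config echo, package version and content hashes of
all tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .effects import effect_distribution
from .panel_io import (ConfigurationError, DEFAULT_ITEMS, ItemSpec,
                       build_transition_table, dichotomize, read_panel,
                       write_panel, BinaryPanel, TransitionTable)
from .reporting import build_consensus, plot_consensus_dag, plot_effect_grid
from .sampler import DagSample, edge_posteriors, sample_dags
from .scoring import build_score_table
from .synthetic import (AttritionSchedule, DEFAULT_ATTRITION, GroundTruth,
                        generate_true_dbn, simulate_cohort)

log = logging.getLogger("dyndag")

DEFAULTS = {
    "dichotomize": {"PANSS": 4, "CDSS": 2},
    "scoring": {"ess": 1.0, "max_parents": 4, "prior": "uniform",
                "score_first_slice": True},
    "sampler": {"method": "partition", "chain_length": 1_000_000,
                "burn_in": None, "n_samples": 10_000},
    "effects": {"level": 0.95},
    "report": {"include_threshold": 0.5, "direction_ratio": 0.8,
               "display_range": [-0.1, 0.5]},
}


def load_config(config) -> dict:
    """Accept a dict, or a path to a YAML/JSON config file."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    for k, v in config.items():
        if k in cfg and isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    if "seed" not in cfg or cfg["seed"] is None:
        raise ConfigurationError(
            "config must set an integer 'seed'; refusing to run unseeded")
    cfg["seed"] = int(cfg["seed"])
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(cfg: dict, out: Path) -> BinaryPanel:
    sim = cfg.get("simulate") or {}
    seed = cfg["seed"]
    truth = generate_true_dbn(
        n_vars=sim.get("n_vars", 12),
        within_density=sim.get("within_density", 0.15),
        between_density=sim.get("between_density", 0.05),
        self_edge_prob=sim.get("self_edge_prob", 0.9),
        effect_floor=sim.get("effect_floor", 0.3),
        seed=seed,
    )
    attr = sim.get("retention")
    schedule = AttritionSchedule(tuple(attr)) if attr else DEFAULT_ATTRITION
    panel = simulate_cohort(
        truth,
        n_participants=sim.get("n_participants", 1208),
        n_waves=sim.get("n_waves", 5),
        attrition=schedule,
        seed=seed + 1,
    )
    truth.to_json(out / "ground_truth.json")
    write_panel(panel, out / "panel.csv", fmt="wide")
    log.info("simulated cohort: %d participants x %d waves x %d items",
             sim.get("n_participants", 1208), sim.get("n_waves", 5),
             truth.structure.n)
    return panel


def _stage_panel(cfg: dict, out: Path):
    """Load or simulate the panel and build the transition table."""
    if "input" in cfg and cfg.get("input"):
        inp = cfg["input"]
        items = DEFAULT_ITEMS
        if "items" in inp:
            items = tuple(ItemSpec(**d) for d in inp["items"])
        panel = read_panel(inp["panel_csv"], items=items,
                           fmt=inp.get("format"))
        binary = dichotomize(panel, cfg["dichotomize"])
    elif "simulate" in cfg:
        binary = _stage_simulate(cfg, out)  # already binary
    else:
        raise ConfigurationError("config needs an 'input' or 'simulate' section")
    table = build_transition_table(binary)
    table.to_csv(out / "transition.csv")
    log.info("transition table: %d rows x %d variables", table.n_rows, table.n)
    return table


def _stage_fit(cfg: dict, table: TransitionTable, out: Path) -> DagSample:
    sc = cfg["scoring"]
    scores = build_score_table(table, ess=sc["ess"],
                               max_parents=sc["max_parents"],
                               prior=sc["prior"],
                               score_first_slice=sc["score_first_slice"])
    sa = cfg["sampler"]
    sample = sample_dags(scores, n_samples=sa["n_samples"],
                         chain_length=sa["chain_length"],
                         burn_in=sa["burn_in"], seed=cfg["seed"] + 2,
                         method=sa["method"])
    sample.save(out / "dag_sample.tsv")
    post = edge_posteriors(sample)
    _edges_csv(post, table.var_names, out / "edges.csv")
    log.info("sampled %d structures (acceptance %.3f)", len(sample),
             sample.meta.get("acceptance_rate", float("nan")))
    return sample


def _edges_csv(post, names, path):
    import pandas as pd
    rows = []
    n = len(names)
    for i in range(n):
        for j in range(n):
            if i != j and post.within[i, j] > 0:
                rows.append({"source": names[i], "target": names[j],
                             "slice": "within", "posterior": post.within[i, j]})
    for i in range(n):
        for j in range(n):
            if post.between[i, j] > 0:
                rows.append({"source": names[i], "target": names[j],
                             "slice": "between", "posterior": post.between[i, j]})
    pd.DataFrame(rows, columns=["source", "target", "slice", "posterior"]) \
        .to_csv(path, index=False, float_format="%.6f")


def _stage_effects(cfg: dict, sample: DagSample, table: TransitionTable,
                   out: Path):
    dist = effect_distribution(sample, table, ess=cfg["scoring"]["ess"],
                               seed=cfg["seed"] + 3,
                               level=cfg["effects"]["level"])
    dist.save(out / "effects.csv", out / "effect_draws.npy")
    log.info("effects: %d of %d pairs significant at level %.2f",
             int(dist.significant.sum()), dist.significant.size,
             cfg["effects"]["level"])
    return dist


def _stage_report(cfg: dict, sample: DagSample, dist, table, out: Path):
    rep = cfg["report"]
    post = edge_posteriors(sample)
    graph = build_consensus(post, names=table.var_names,
                            include_threshold=rep["include_threshold"],
                            direction_ratio=rep["direction_ratio"])
    graph.to_frame().to_csv(out / "consensus.csv", index=False,
                            float_format="%.6f")
    graph.to_dot(out / "consensus.dot")
    graph.to_graphml(out / "consensus.graphml")
    plot_consensus_dag(graph, out / "consensus.svg")
    plot_effect_grid(dist, out / "effect_grid.svg",
                     display_range=tuple(rep["display_range"]))
    return graph


def run_pipeline(config, output_dir=None) -> Path:
    """Execute every stage and return the output directory."""
    cfg = load_config(config)
    out = Path(output_dir or cfg.get("output_dir", "dyndag_out"))
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        table = _stage_panel(cfg, out)
        sample = _stage_fit(cfg, table, out)
        dist = _stage_effects(cfg, sample, table, out)
        _stage_report(cfg, sample, dist, table, out)
    except Exception as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    tables = sorted(p for p in out.iterdir()
                    if p.suffix in {".csv", ".tsv", ".json", ".dot", ".graphml"}
                    and p.name != "manifest.json")
    manifest = {
        "dyndag_version": __version__,
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items()},
        "hashes": {p.name: _sha256(p) for p in tables},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
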