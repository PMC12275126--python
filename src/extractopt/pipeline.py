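"""End-to-end study pipeline: quadratic RSM fit and ANOVA, BP and
GA-ACO-BP surrogates, model comparison, and surrogate maximization.

The pipeline is a pure function of (design table, configuration, seeds):
every stochastic stage draws from a named stream derived from the global
seed, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .ann import MLPSurrogate, Normalization, TrainConfig, init_weights, predict_mlp, train_bp
from .data_io import DesignTable, load_design_csv, paper_fixture, write_report
from .evaluate import SplitSpec, compare_models, split
from .gaaco import GAACOConfig, train_gaaco_bp
from .optimize import maximize
from .rsm import anova, fit_quadratic

logger = logging.getLogger("extractopt")

__all__ = ["PipelineConfig", "run_paper_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline."""

    seed: Optional[int] = None
    out_dir: str = "extractopt_out"
    design_csv: Optional[str] = None  # None -> packaged 29-run table
    n_hidden: int = 4
    n_train: int = 21
    n_valid: int = 8
    resolution: int = 101
    train: TrainConfig = field(default_factory=TrainConfig)
    gaaco: GAACOConfig = field(default_factory=GAACOConfig)
    box: Optional[list] = None  # per-factor [low, high]; None -> design box

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        train = TrainConfig(**raw.pop("train", {}))
        gaaco = GAACOConfig(**raw.pop("gaaco", {}))
        return cls(train=train, gaaco=gaaco, **raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a global seed is mandatory when stochastic stages run")
        if self.design_csv is not None and not Path(self.design_csv).exists():
            raise FileNotFoundError(self.design_csv)


def _seed_stream(global_seed: int, name: str) -> int:
    """A named 31-bit child seed derived deterministically from the global one."""
    ss = np.random.SeedSequence([global_seed, abs(hash(name)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_paper_pipeline(config: PipelineConfig) -> dict:
    """Execute the full study pipeline and write all artifacts.

    Stages: load table → quadratic fit + ANOVA → random-init BP →
    GA-ACO-BP → model comparison → maximization of both surrogates.
    Returns the bundle of in-memory results.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings, t0 = {}, time.perf_counter()

    def tick(stage):
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done at %.2fs", stage, timings[stage])

    table = load_design_csv(config.design_csv) if config.design_csv else paper_fixture()
    tick("load")

    model = fit_quadratic(table, coding="coded")
    report = anova(model, table)
    write_report(report, out / "anova.json")
    write_report(model, out / "rsm_model.json")
    tick("rsm")

    split_seed = _seed_stream(config.seed, "split")
    spec = SplitSpec(config.n_train, config.n_valid, seed=split_seed)
    train_table, _ = split(table, spec)
    norm = Normalization.fit(table.factors, table.yields)
    bp_seed = _seed_stream(config.seed, "bp-init")
    bp_net = MLPSurrogate(config.n_hidden,
                          init_weights(config.n_hidden, seed=bp_seed), norm)
    bp_net, _ = train_bp(bp_net, train_table, config.train)
    write_report(bp_net, out / "bp_model.json")
    tick("bp")

    gcfg = GAACOConfig(**{**config.gaaco.__dict__,
                          "seed": _seed_stream(config.seed, "gaaco")})
    ga_net, ga_fit, trace = train_gaaco_bp(table, spec, gcfg, config.train,
                                           n_hidden=config.n_hidden)
    write_report(ga_net, out / "gaaco_bp_model.json")
    with open(out / "gaaco_trace.csv", "w") as fh:
        fh.write("iteration,best_fitness,mean_fitness\n")
        for i, (b, m) in enumerate(zip(trace.best, trace.mean)):
            fh.write(f"{i},{b!r},{m!r}\n")
    tick("gaaco")

    comparison = compare_models(table, {
        "Box-Behnken": model, "BP": bp_net, "GA-ACO-BP": ga_net,
    })
    write_report(comparison, out / "comparison.json")
    write_report(comparison, out / "comparison.txt", format="text")
    tick("compare")

    box = config.box or [(d.low, d.high) for d in table.domains]
    opt_rsm = maximize(model, box, resolution=config.resolution)
    opt_ga = maximize(ga_net, box, resolution=config.resolution)
    write_report(opt_rsm, out / "optimum_rsm.json")
    write_report(opt_ga, out / "optimum_gaaco_bp.json")
    tick("optimize")

    with open(out / "run_log.json", "w") as fh:
        json.dump({"seed": config.seed, "timings_s": timings,
                   "seeds": {"split": split_seed, "bp-init": bp_seed,
                             "gaaco": gcfg.seed}}, fh, indent=2)
    return {"table": table, "rsm": model, "anova": report, "bp": bp_net,
            "gaaco_bp": ga_net, "gaaco_fit": ga_fit, "trace": trace,
            "comparison": comparison, "optimum_rsm": opt_rsm,
            "optimum_gaaco_bp": opt_ga}
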