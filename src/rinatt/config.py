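"""Run configuration, master-seed fan-out, and the end-to-end demo pipeline.

A single master seed is fanned out deterministically to every stochastic
stage via ``numpy.random.SeedSequence.spawn``, so a pipeline run is fully
reproducible and each stage's stream is independent. Configurations
round-trip through YAML unchanged; missing keys raise a schema error naming
the key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "save_config", "derive_seeds", "run_pipeline"]

_STAGES = ("simulate", "fit", "optimize", "rl", "mds")


@dataclass
class RunConfig:
    """Settings for the demo pipeline (desk-scale by default)."""

    master_seed: int = 0
    out_dir: str = "runs/demo"
    env_id: str = "constant"
    n_trials: int = 2000
    prior_concentration: float = 0.5
    grid_step: float = 2.0
    equal_angle_fraction: float = 0.02
    # observer ground truth / optimizer settings
    k_max: float = 20.0
    q: float = 2.0
    c50: float = 0.4
    sigma_late: float = 8.0
    eta: float = 0.02
    optimizer_starts: int = 8
    fit_starts: int = 10
    fit_models: tuple = ("DM1", "DM3")
    rl_trials: int = 600
    rl_alpha_plus: float = 0.3
    rl_alpha_minus: float = 0.6
    rl_k_tilde: float = 5.0

    REQUIRED = ("master_seed", "out_dir", "env_id", "n_trials")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit_models"] = list(self.fit_models)
        return d


def load_config(path) -> RunConfig:
    """Read a YAML config; raise ``KeyError`` naming any missing required key."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    for key in RunConfig.REQUIRED:
        if key not in raw:
            raise KeyError(f"config missing required key {key!r}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    if "fit_models" in raw:
        raw["fit_models"] = tuple(raw["fit_models"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def derive_seeds(master_seed: int, stages=_STAGES) -> dict:
    """Deterministic per-stage integer seeds below 2^31 from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(stages))
    return {
        stage: int(np.random.default_rng(child).integers(2**31 - 1))
        for stage, child in zip(stages, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> fit -> optimize -> rl -> mds, writing CSV/JSON artifacts.

    Returns the manifest (also written as ``manifest.json``), which records
    the config, per-stage seeds, and a content hash of every artifact, and
    is byte-identical across runs with the same master seed.
    """
    from . import __version__
    from .fitting import compare, fit
    from .observer import ObserverParams, ResourceGain
    from .resource import CostModel, optimize
    from .psychometrics import build_dissimilarity, classical_mds
    from .rl import RewardBelief, RLParams, run_session
    from .stimulus import ContrastResponse, OrientationPrior, reward_environment
    from .synthetic import SessionSpec, simulate_session, write_trials

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.master_seed)
    manifest = {"version": __version__, "config": config.to_dict(), "seeds": seeds, "artifacts": {}}
    prior = OrientationPrior.horizontal_biased(config.grid_step, config.prior_concentration)
    cr = ContrastResponse(k_max=config.k_max, q=config.q, c50=config.c50)
    truth = ObserverParams(
        gain=ResourceGain.uniform(config.grid_step), cr=cr, sigma_late=config.sigma_late
    )
    env = reward_environment(config.env_id)

    def _record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = hashlib.sha1(path.read_bytes()).hexdigest()

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - tag the failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def _simulate():
        spec = SessionSpec(
            n_trials=config.n_trials,
            env_id=config.env_id,
            equal_angle_fraction=config.equal_angle_fraction,
            prior_step=config.grid_step,
            prior_concentration=config.prior_concentration,
            observer=truth,
            seed=seeds["simulate"],
        )
        trials = simulate_session(spec)
        write_trials(trials, out / "trials.csv")
        _record("trials.csv", out / "trials.csv")
        return trials

    trials = _stage("simulate", _simulate)

    def _fit():
        import pandas as pd

        fits = [
            fit(m, trials, starts=config.fit_starts, seed=seeds["fit"], prior=prior)
            for m in config.fit_models
        ]
        if len(fits) >= 2:
            table = compare(fits)
        else:
            f = fits[0]
            table = pd.DataFrame(
                [
                    {
                        "model_id": f.model_id,
                        "n_params": f.n_params,
                        "log_likelihood": f.log_likelihood,
                        "aic": f.aic,
                        "bic": f.bic,
                        "delta_aic": 0.0,
                        "delta_bic": 0.0,
                    }
                ]
            )
        table.to_csv(out / "model_comparison.csv", index=False)
        _record("model_comparison.csv", out / "model_comparison.csv")
        return fits

    _stage("fit", _fit)

    def _optimize():
        res = optimize(
            env,
            CostModel(eta=config.eta),
            config.sigma_late,
            prior,
            starts=config.optimizer_starts,
            seed=seeds["optimize"],
            cr_template=cr,
        )
        payload = {
            "coeffs": list(res.coeffs),
            "k_max": res.k_max,
            "objective": res.objective,
            "expected_reward": res.expected_reward,
            "expected_loss": res.expected_loss,
            "cost": res.cost,
            "gain": res.gain.values.tolist(),
        }
        (out / "optimal_gain.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        _record("optimal_gain.json", out / "optimal_gain.json")
        return res

    opt = _stage("optimize", _optimize)

    def _rl():
        from .synthetic import generate_trials

        spec = SessionSpec(
            n_trials=config.rl_trials,
            env_id=config.env_id,
            prior_step=config.grid_step,
            prior_concentration=config.prior_concentration,
            seed=seeds["rl"],
        )
        stream = generate_trials(spec)
        traj = run_session(
            stream,
            RewardBelief.flat(prior.grid),
            truth,
            RLParams(config.rl_alpha_plus, config.rl_alpha_minus, config.rl_k_tilde),
            env,
            prior,
            seed=seeds["rl"],
        )
        gdf = np.c_[prior.grid, traj.mean_gain(last=min(500, config.rl_trials))]
        np.savetxt(
            out / "rl_mean_gain.csv", gdf, delimiter=",", header="theta,gain", comments=""
        )
        _record("rl_mean_gain.csv", out / "rl_mean_gain.csv")
        return traj

    _stage("rl", _rl)

    def _mds():
        params = ObserverParams(
            gain=opt.gain,
            cr=ContrastResponse(k_max=opt.k_max, q=config.q, c50=config.c50),
            sigma_late=config.sigma_late,
        )
        mat = build_dissimilarity(params, prior)
        coords = classical_mds(mat, dims=2)
        arr = np.c_[mat.angles, coords]
        np.savetxt(out / "mds.csv", arr, delimiter=",", header="theta,x,y", comments="")
        _record("mds.csv", out / "mds.csv")

    _stage("mds", _mds)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
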