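"""On-disk layout for fitted runs: a directory with a JSON manifest and the
retained summaries (npz).  Stores the MAP draw and the per-draw series; full
draw lists are an in-memory feature only."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .core import Hyperparams, LatentState, ModelParams
from .gibbs import MCMCTrace

__all__ = ["save_trace", "load_trace"]

_PARAM_FIELDS = ("omega", "xi", "mu_cluster", "sigma2_cluster",
                 "mu_feature", "sigma2_feature", "sigma2_irrelevant")


def save_trace(trace: MCMCTrace, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hp = trace.config["hp"]
    manifest = {
        "hyperparams": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in asdict(hp).items()},
        "iters": trace.config["iters"],
        "burn_in": trace.config["burn_in"],
        "seed": trace.config["seed"],
        "thin": trace.config["thin"],
        "S": trace.S,
        "map_index": trace.map_index,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    arrays = {
        "map_z": trace.map_state.z,
        "map_rho": trace.map_state.rho,
        "loglik": trace.loglik,
        "obs_loglik": trace.obs_loglik,
        "log_prior": trace.log_prior,
        "mu_cluster_draws": trace.mu_cluster_draws,
        "n_empty_per_draw": trace.n_empty_per_draw,
    }
    for f in _PARAM_FIELDS:
        arrays[f"map_{f}"] = getattr(trace.map_params, f)
    np.savez_compressed(outdir / "trace.npz", **arrays)


def load_trace(outdir: str | Path) -> MCMCTrace:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    with np.load(outdir / "trace.npz") as data:
        arrays = {k: data[k] for k in data.files}
    hp_dict = manifest["hyperparams"]
    hp = Hyperparams(**{k: (np.asarray(v) if isinstance(v, list) else v)
                        for k, v in hp_dict.items()})
    params = ModelParams(*(arrays[f"map_{f}"] for f in _PARAM_FIELDS))
    return MCMCTrace(
        loglik=arrays["loglik"], obs_loglik=arrays["obs_loglik"],
        log_prior=arrays["log_prior"],
        mu_cluster_draws=arrays["mu_cluster_draws"],
        n_empty_per_draw=arrays["n_empty_per_draw"],
        map_index=int(manifest["map_index"]),
        map_state=LatentState(arrays["map_z"], arrays["map_rho"]),
        map_params=params,
        config={"hp": hp, "iters": manifest["iters"],
                "burn_in": manifest["burn_in"], "seed": manifest["seed"],
                "thin": manifest["thin"]},
        draws=None,
    )
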