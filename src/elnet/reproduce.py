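"""Scripted reproduction of the headline experiments at full or reduced scale.

Each named experiment runs a seeded ensemble of trials, aggregates the
statistics of one table or figure of the study design (mean ± SD over
trials), and returns a machine-readable report carrying every configuration
flag needed to regenerate it exactly.

Measurement conventions
-----------------------
The library's per-network statistics offer two standard conventions each for
clustering (average-local vs transitivity) and mean degree (undirected 2E/|V|
vs directed E/|V|), and two directions for the control's μ.  The reproduction
paths fix one combination — transitivity, directed, μ-degrades-1-bits —
calibrated once against the published control-model network values (see
docs/methods.md); the choice is recorded in every report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bitstate import to_string
from .netmetrics import (
    ccdf_r2,
    clustering_coefficient,
    compare_groups,
    degree_distributions,
    edge_weight_variance,
    fit_exponential_discrete,
    fit_power_law,
    hamming_weight_profile,
    mean_degree,
    mu_sweep,
    recurrence_times,
    trajectory,
    window_series,
)
from .simulate import SimulationConfig, run_simulation
from .transition_network import build_network

__all__ = ["ExperimentSpec", "REPRODUCTION_CONVENTIONS", "EXPERIMENTS",
           "reproduce", "write_report", "generate_fixtures", "trial_seeds"]

#: Conventions used by all reproduction paths (calibrated; see module docs).
REPRODUCTION_CONVENTIONS = {
    "clustering": "transitivity",
    "degree": "directed",
    "control_flip": "mu",
}

WINDOW_LEN = 200          # steps per headline network window
SHORT_WINDOW_LEN = 20     # the short-interval comparison window


@dataclass(frozen=True)
class ExperimentSpec:
    """A named, repeatable experiment: ensemble size plus a base trial config."""

    name: str
    trials: int
    scale: str                      # "full" | "reduced"
    base: SimulationConfig

    def __post_init__(self) -> None:
        if self.trials < 2:
            raise ValueError("an ensemble needs at least 2 trials")
        if self.scale not in ("full", "reduced"):
            raise ValueError("scale must be 'full' or 'reduced'")


def trial_seeds(master_seed: int, trials: int) -> list[int]:
    """Independent per-trial seeds derived from one master seed."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2 ** 31, size=trials)]


def _base(n: int, steps: int, seed: int, **kw) -> SimulationConfig:
    return SimulationConfig(n=n, steps=steps, seed=seed, **kw)


def _ensemble_stats(spec_cfg: SimulationConfig, trials: int, master_seed: int,
                    window_len: int = WINDOW_LEN) -> tuple[pd.DataFrame, dict]:
    """Per-trial network statistics of one measured window, plus pooled samples."""
    conv = REPRODUCTION_CONVENTIONS
    rows, pooled_w, pooled_w20 = [], [], []
    for seed in trial_seeds(master_seed, trials):
        cfg = SimulationConfig(**{**spec_cfg.to_dict(), "seed": seed})
        log = run_simulation(cfg)
        t1 = cfg.burn_in
        net = build_network(log, t1, t1 + window_len)
        in_deg, out_deg = degree_distributions(net)
        prof = hamming_weight_profile(net, log.target)
        rows.append({
            "C": clustering_coefficient(net, conv["clustering"]),
            "MD": mean_degree(net, conv["degree"]),
            "var_w": edge_weight_variance(net),
            "max_k_in": int(in_deg.max(initial=0)),
            "max_k_out": int(out_deg.max(initial=0)),
            "lambda_in": fit_exponential_discrete(in_deg[in_deg >= 1]).param,
            "lambda_out": fit_exponential_discrete(out_deg[out_deg >= 1]).param,
            "n_nodes": net.n_nodes,
            "weight_within_3": float(prof[:4].sum()),
        })
        pooled_w.append(net.weight)
        pooled_w20.append(np.concatenate([
            build_network(log, s, s + SHORT_WINDOW_LEN).weight
            for s in range(t1, t1 + window_len, SHORT_WINDOW_LEN)]))
    pooled = {
        "edge_weights": np.concatenate(pooled_w),
        "edge_weights_short": np.concatenate(pooled_w20),
        "edge_weights_per_trial": pooled_w,
        "edge_weights_short_per_trial": pooled_w20,
    }
    return pd.DataFrame(rows), pooled


def _mean_sd(series) -> dict:
    arr = np.asarray(series, dtype=float)
    return {"mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0}


# ---------------------------------------------------------------------------
# named experiments


def _exp_network_stats(spec: ExperimentSpec, seed: int) -> dict:
    """Fig-2-style comparison: C and MD of the EL model vs the μ=0.005 control."""
    el, _ = _ensemble_stats(spec.base, spec.trials, seed)
    ctrl_cfg = SimulationConfig(**{**spec.base.to_dict(), "model": "control",
                                   "mu": 0.005,
                                   "control_flip":
                                   REPRODUCTION_CONVENTIONS["control_flip"]})
    ctrl, _ = _ensemble_stats(ctrl_cfg, spec.trials, seed + 1)
    return {
        "el": {k: _mean_sd(el[k]) for k in ("C", "MD", "n_nodes",
                                            "weight_within_3")},
        "control": {k: _mean_sd(ctrl[k]) for k in ("C", "MD", "n_nodes")},
    }


def _exp_table1(spec: ExperimentSpec, seed: int) -> dict:
    """Degree-law rates λ_in/λ_out and the max-degree asymmetry, with tests."""
    df, _ = _ensemble_stats(spec.base, spec.trials, seed)
    t_stat, t_p = compare_groups(df.lambda_in, df.lambda_out, "t")
    u_stat, u_p = compare_groups(df.max_k_in, df.max_k_out, "u")
    return {
        "lambda_in": _mean_sd(df.lambda_in),
        "lambda_out": _mean_sd(df.lambda_out),
        "lambda_welch_t": {"t": t_stat, "p": t_p},
        "max_k_in": _mean_sd(df.max_k_in),
        "max_k_out": _mean_sd(df.max_k_out),
        "max_k_mann_whitney": {"U": u_stat, "p": u_p},
    }


def _exp_table2(spec: ExperimentSpec, seed: int) -> dict:
    """Edge-weight power-law exponents with AIC weights, long and short windows."""
    _, pooled = _ensemble_stats(spec.base, spec.trials, seed)
    out = {}
    for key, label in (("edge_weights", f"{WINDOW_LEN}_step"),
                       ("edge_weights_short", f"{SHORT_WINDOW_LEN}_step")):
        fit = fit_power_law(pooled[key])
        out[label] = fit.to_dict()
    return out


def _recurrence_series(spec: ExperimentSpec, seed: int) -> tuple[np.ndarray,
                                                                 np.ndarray,
                                                                 list]:
    md_times, var_times, frames = [], [], []
    for s in trial_seeds(seed, spec.trials):
        cfg = SimulationConfig(**{**spec.base.to_dict(), "seed": s})
        log = run_simulation(cfg)
        df = window_series(log, WINDOW_LEN, stride=1,
                           degree_convention=REPRODUCTION_CONVENTIONS["degree"])
        md_times.append(recurrence_times(df.MD.values).times)
        var_times.append(recurrence_times(df.var_w.values).times)
        frames.append(df)
    return np.concatenate(md_times), np.concatenate(var_times), frames


def _exp_table3(spec: ExperimentSpec, seed: int) -> dict:
    """Recurrence-time laws of the windowed mean degree and weight variance."""
    md_times, var_times, _ = _recurrence_series(spec, seed)
    return {
        "mean_degree_recurrence": fit_power_law(md_times).to_dict(),
        "weight_variance_recurrence":
            fit_exponential_discrete(var_times).to_dict(),
    }


def _exp_fig5(spec: ExperimentSpec, seed: int) -> dict:
    """Trade-off: μ sweep of the control plus the EL (MD, var_w) correlation."""
    sweep = mu_sweep(spec.base, np.round(np.arange(0.005, 0.1001, 0.005), 3),
                     trials=max(2, spec.trials // 4), seed=seed)
    _, _, frames = _recurrence_series(
        dataclasses.replace(spec, trials=max(2, spec.trials // 4)), seed + 1)
    thinned = pd.concat([f.iloc[::8] for f in frames])
    r, p = compare_groups(thinned.MD, thinned.var_w, "pearson")
    return {"mu_sweep": sweep.to_dict(orient="records"),
            "el_tradeoff": {"pearson_r": r, "p": p, "n_pairs": len(thinned)}}


def _exp_fig6(spec: ExperimentSpec, seed: int) -> dict:
    """Phase-plane trajectory closure of one long trial."""
    cfg = SimulationConfig(**{**spec.base.to_dict(),
                              "seed": trial_seeds(seed, 1)[0]})
    log = run_simulation(cfg)
    df = window_series(log, WINDOW_LEN, stride=1,
                       degree_convention=REPRODUCTION_CONVENTIONS["degree"])
    traj = trajectory(df.MD.values[:600], df.var_w.values[:600])
    return {"signed_area": traj.signed_area,
            "path_length": traj.path_length,
            "closure_distance": traj.closure_distance}


def _exp_mu_sweep(spec: ExperimentSpec, seed: int) -> dict:
    """Power-law goodness (CCDF R²) of control edge weights across μ."""
    sweep = mu_sweep(spec.base, np.round(np.arange(0.005, 0.1001, 0.005), 3),
                     trials=spec.trials, seed=seed)
    return {"rows": sweep.to_dict(orient="records")}


_RUNNERS = {
    "fig2": _exp_network_stats,
    "table1": _exp_table1,
    "table2": _exp_table2,
    "table3": _exp_table3,
    "fig5": _exp_fig5,
    "fig6": _exp_fig6,
    "mu_sweep": _exp_mu_sweep,
}


def _default_spec(name: str, scale: str, seed: int) -> ExperimentSpec:
    trials = 100 if scale == "full" else 10
    n = 8 if scale == "full" else 7
    steps = 1600 if name in ("table3", "fig5", "fig6") else 400
    if name in ("table3", "fig5", "fig6"):
        trials = 20 if scale == "full" else 4
    return ExperimentSpec(name=name, trials=trials, scale=scale,
                          base=_base(n, steps, seed))


EXPERIMENTS = tuple(_RUNNERS)


def reproduce(spec: ExperimentSpec | str, seed: int = 0,
              scale: str = "reduced") -> dict:
    """Run a named experiment and return its machine-readable report.

    ``spec`` may be an :class:`ExperimentSpec` or an experiment name (one of
    ``EXPERIMENTS``); reports are deterministic given ``seed``.
    """
    if isinstance(spec, str):
        if spec not in _RUNNERS:
            raise ValueError(
                f"unknown experiment {spec!r}; choose from {sorted(_RUNNERS)}")
        spec = _default_spec(spec, scale, seed)
    if spec.name not in _RUNNERS:
        raise ValueError(f"unknown experiment {spec.name!r}")
    results = _RUNNERS[spec.name](spec, seed)
    return {
        "experiment": spec.name,
        "scale": spec.scale,
        "trials": spec.trials,
        "seed": seed,
        "base_config": spec.base.to_dict(),
        "conventions": dict(REPRODUCTION_CONVENTIONS),
        "version": __version__,
        "results": results,
    }


def write_report(report: dict, outdir) -> None:
    """Write a report as JSON plus flat CSVs for any tabular sections."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = report["experiment"]
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    for key, val in report["results"].items():
        if isinstance(val, list) and val and isinstance(val[0], dict):
            pd.DataFrame(val).to_csv(outdir / f"{name}_{key}.csv", index=False)
    manifest = {k: report[k] for k in ("experiment", "scale", "trials", "seed",
                                       "base_config", "conventions", "version")}
    with open(outdir / f"{name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# toy fixtures


def generate_fixtures(seed: int, outdir) -> dict:
    """Write the small hand-checkable fixtures used by the test suite.

    * a one-step, 32-individual (n=5) trial with its single-window network,
    * the 2-bit lattice/ideal/congruence worked example,
    * a 3-step n=3 transition log.

    Regenerates byte-identically from the same seed.  Returns the objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict = {}

    cfg5 = SimulationConfig(n=5, steps=1, burn_in=0, seed=seed)
    log5 = run_simulation(cfg5)
    log5.write_tsv(outdir / "one_step_n5.tsv")
    net5 = build_network(log5, 0, 1)
    net5.write_edge_tsv(outdir / "one_step_n5_edges.tsv")
    out["one_step"] = (log5, net5)

    from .bitstate import from_string
    from .lattice import Lattice

    lat = Lattice.boolean(2)
    ideal = lat.principal_ideal(from_string("01"))
    part = lat.congruence(ideal)
    classes = sorted(sorted(to_string(x, 2) for x in blk)
                     for blk in part.classes)
    with open(outdir / "two_bit_congruence.json", "w") as fh:
        json.dump({"lattice": [to_string(x, 2) for x in lat],
                   "ideal_generator": to_string(ideal.generator, 2),
                   "classes": classes}, fh, indent=2)
    out["congruence"] = (lat, ideal, part)

    cfg3 = SimulationConfig(n=3, steps=3, burn_in=0, seed=seed + 1)
    log3 = run_simulation(cfg3)
    log3.write_tsv(outdir / "three_step_n3.tsv")
    out["three_step"] = log3
    return out
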