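"""Experiment configuration, scenario orchestration and provenance.

A scenario is a small YAML/JSON mapping with a ``kind`` selecting the
pipeline and sections describing the model, input protocol, initial
condition and resolution.  Every run writes tidy CSV outputs plus a
provenance JSON (config hash, seed, package version) so results are
reproducible bit-for-bit from the config and seed alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cytometry, mi, models, moments, populations, ssa

__all__ = ["load_experiment_config", "run_scenario", "scenario_path", "list_scenarios"]

_TOP_KEYS = {
    "kind",
    "name",
    "model",
    "protocol",
    "initial",
    "observables",
    "times",
    "seed",
    "n_grid",
    "background",
    "variant",
    "n_cells",
    "dose",
    "time",
    "n_runs",
    "xmax",
    "t_min",
    "candidates",
    "equalize",
    "outputs",
}
_MODEL_KEYS = {"name", "table", "gamma_g", "gbar", "adh1_estradiol_dependence", "parameters"}
_KINDS = ("mi", "synth", "ssa_compare", "choose_n", "moments")


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_experiment_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "config")
    kind = cfg.get("kind")
    if kind not in _KINDS:
        raise ConfigError(f"config.kind must be one of {_KINDS}, got {kind!r}")
    if "model" in cfg:
        _check_keys(cfg["model"], _MODEL_KEYS, "config.model")


def _build_model(section: dict) -> models.ReactionNetwork:
    name = section.get("name", "simple_cascade")
    params = dict(models.load_table(section.get("table", "table1")))
    params.update(section.get("parameters") or {})
    if name == "simple_cascade":
        net = models.build_simple_cascade(params)
        if section.get("gamma_g") is not None:
            gspec = models.GlobalVariableSpec.from_mean(
                section.get("gbar", 50.0), section["gamma_g"], models.CASCADE_COUPLED
            )
            net = models.attach_global_variable(net, gspec)
        return net
    if name == "circuit_global":
        gspec = models.GlobalVariableSpec.from_mean(
            section.get("gbar", 42.0), section.get("gamma_g", 3e-6), models.CIRCUIT_COUPLED
        )
        return models.build_synthetic_circuit(
            params, "global", section.get("adh1_estradiol_dependence", True), gspec
        )
    if name == "circuit_intrinsic":
        return models.build_synthetic_circuit(
            params, "intrinsic", section.get("adh1_estradiol_dependence", True)
        )
    raise ConfigError(f"unknown model name {name!r}")


def _build_protocol(section: dict) -> models.StepInputProtocol:
    ptype = section.get("type", "estradiol_12")
    if ptype == "estradiol_12":
        return models.StepInputProtocol.estradiol_12()
    if ptype == "geometric":
        return models.StepInputProtocol.geometric(
            section["xmax"], section["n"], section.get("ratio", 2.0 / 3.0)
        )
    raise ConfigError(f"unknown protocol type {ptype!r}")


def _background_dict(cfg: dict, variant_hint: str) -> dict | None:
    spec = cfg.get("background")
    if spec in (None, False):
        return None
    if spec == "default":
        bg = cytometry.default_background(variant_hint)
        return {"Y2": (bg.y2_mean, bg.y2_sd), "Y1r": (bg.y1r_mean, bg.y1r_sd)}
    return {k: tuple(v) for k, v in spec.items()}


def run_scenario(cfg: dict, outdir) -> dict:
    """Dispatch a validated scenario config; returns {output name: path}."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kind = cfg["kind"]
    seed = int(cfg.get("seed", 0))
    outputs: dict[str, str] = {}

    if kind == "mi":
        net = _build_model(cfg["model"])
        protocol = _build_protocol(cfg.get("protocol", {}))
        times = [float(t) for t in cfg["times"]]
        observables = list(cfg.get("observables", ["Y2"]))
        init = populations.make_initial(cfg.get("initial", "heterogeneous"), net)
        surf = mi.build_surface(net, protocol.doses, times, init, observables)
        variant_hint = "SGF" if net.model == "circuit_global" else "intrinsic"
        bg = _background_dict(cfg, variant_hint)
        if bg:
            surf = mi.add_measurement_background(
                surf, {k: v for k, v in bg.items() if k in observables}
            )
        rows = []
        n_grid = cfg.get("n_grid", mi.N_DOSE_GRID)
        for obs in observables:
            rows.append(mi.mi_curve(surf, n_grid=n_grid, observable=obs).to_frame())
        if len(observables) > 1:
            joint = [mi.joint_mi(surf, t) for t in times]
            rows.append(
                mi.MIResult(
                    np.array(times), np.array(joint), surf.conditioning, tuple(observables)
                ).to_frame()
            )
            if cfg.get("equalize"):
                eq = mi.equalize_reporter_means(surf)
                joint_eq = [mi.joint_mi(eq, t) for t in times]
                rows.append(
                    mi.MIResult(
                        np.array(times), np.array(joint_eq), eq.conditioning, tuple(observables)
                    ).to_frame()
                )

        frame = pd.concat(rows, ignore_index=True)
        out = outdir / "mi.csv"
        frame.to_csv(out, index=False)
        outputs["mi"] = str(out)

    elif kind == "synth":
        table = cytometry.generate(cfg.get("variant", "SGF"), cfg.get("n_cells", 3000), seed)
        summary = cytometry.summarize(table)
        call = cytometry.classify_variability(summary)
        cells_out = outdir / "cells.csv"
        summary_out = outdir / "summary.csv"
        table.to_csv(cells_out, index=False)
        summary.to_csv(summary_out, index=False)
        outputs |= {"cells": str(cells_out), "summary": str(summary_out)}
        outputs["classification"] = call["call"]

    elif kind == "ssa_compare":
        net = _build_model(cfg["model"])
        dose = float(cfg.get("dose", 8.78))
        t = float(cfg.get("time", 580.0))
        n_runs = int(cfg.get("n_runs", 2000))
        init = populations.make_initial(cfg.get("initial", "S1"), net)
        rng = np.random.default_rng(seed)
        states = init.sample_states(n_runs, rng)
        X = ssa.ensemble_states(net, states, [0.0, t], seed + 1, x=dose)

        obs = cfg.get("observables", ["Y2"])[0]
        k = net.species_index(obs)
        sample = X[:, 1, k]
        mom = moments.integrate_moments(net, init.state, [0.0, t], x=dose).at(t)
        frame = pd.DataFrame({"species": obs, "sample": sample})
        out = outdir / "ssa_samples.csv"
        frame.to_csv(out, index=False)
        outputs["ssa_samples"] = str(out)
        outputs["ssa_mean"] = float(sample.mean())
        outputs["moment_mean"] = float(mom.mean[k])

    elif kind == "choose_n":
        net = _build_model(cfg["model"])
        init = populations.make_initial(cfg.get("initial", "S1"), net)
        res = mi.choose_N(
            net,
            init,
            xmax=float(cfg.get("xmax", 250.0)),
            t_min=float(cfg.get("t_min", 750.0)),
            candidates=range(3, 26) if "candidates" not in cfg else cfg["candidates"],
        )

        frame = pd.DataFrame({"n": res["candidates"], "mi_bits": res["mi"]})
        out = outdir / "mi_vs_n.csv"
        frame.to_csv(out, index=False)
        outputs |= {"mi_vs_n": str(out), "chosen_n": res["n"], "converged": bool(res["converged"])}

    elif kind == "moments":
        net = _build_model(cfg["model"])
        init = populations.make_initial(cfg.get("initial", "heterogeneous"), net)
        times = [float(t) for t in cfg["times"]]
        dose = float(cfg.get("dose", 0.0))
        traj = moments.integrate_moments(net, init.state, times, x=dose)
        out = outdir / "moments.csv"
        traj.to_frame(net).to_csv(out, index=False)
        outputs["moments"] = str(out)

    prov = {
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "version": __version__,
        "outputs": outputs,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    return outputs


def scenario_path(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("stochmi.data").joinpath(f"scenarios/{name}.yaml")))


def list_scenarios() -> list[str]:
    from importlib.resources import files

    d = files("stochmi.data").joinpath("scenarios")
    return sorted(p.name[:-5] for p in d.iterdir() if p.name.endswith(".yaml"))
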