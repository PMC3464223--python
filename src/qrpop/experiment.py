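"""Reproducible experiment runner: one stimulus, a simulated population and
any subset of the theories, with every output derivable from the spec file
and seed alone."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibrate import default_model
from .decoders import auto_a_min, decode_eme1, decode_qr
from .encoders import encode_eme1, encode_eme2, encode_qr, encode_renewal
from .io import write_decode_result, write_raster, write_trace
from .metrics import compare_traces, corrcoef
from .model import NeuronModel, Trace, filtered_input
from .popsim import simulate_population, smooth_trace
from .stimulus import OUParams, ou_process, staircase_ou, step_current

log = logging.getLogger("qrpop")

KNOWN_METHODS = ("sim", "renewal", "qr", "eme1", "eme2", "decode_qr", "decode_eme1")


@dataclass
class ExperimentSpec:
    stimulus: dict
    methods: list
    n_neurons: int = 25_000
    dt_sim: float = 0.5
    dt_theory: float = 0.5
    seed: int = 0
    window: float = 2.0
    outputs: str = "out"
    model_config: str | None = None  # path; None = calibrated default
    eps: float = 1e-4

    @classmethod
    def from_yaml(cls, path) -> "ExperimentSpec":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def validate(self) -> None:
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.model_config is not None and not Path(self.model_config).exists():
            raise FileNotFoundError(self.model_config)


def _build_stimulus(spec: ExperimentSpec) -> Trace:
    s = dict(spec.stimulus)
    kind = s.pop("kind")
    if kind == "step":
        return step_current(dt=spec.dt_sim, **s)
    if kind == "ou":
        return ou_process(OUParams(dt=spec.dt_sim, seed=spec.seed, **s))
    if kind == "staircase_ou":
        return staircase_ou(dt=spec.dt_sim, seed=spec.seed, **s)
    raise ValueError(f"unknown stimulus kind {kind!r}")


def run_experiment(spec: ExperimentSpec) -> dict:
    """Execute all requested methods on one stimulus; write traces, reports
    and a provenance record.  Failures are isolated per method."""
    spec.validate()
    out_dir = Path(spec.outputs)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = (
        default_model() if spec.model_config is None else NeuronModel.load(spec.model_config)
    )
    current = _build_stimulus(spec)
    write_trace(current, out_dir / "stimulus.csv", "current_pa")
    h = filtered_input(current, model.kappa)
    write_trace(h, out_dir / "h.csv", "h")

    report: dict = {
        "provenance": {
            "qrpop_version": __version__,
            "seed": spec.seed,
            "n_neurons": spec.n_neurons,
            "dt_sim": spec.dt_sim,
            "dt_theory": spec.dt_theory,
            "window_ms": spec.window,
            "model": model.to_dict(),
            "stimulus": spec.stimulus,
        },
        "methods": {},
        "errors": {},
    }

    sim = None
    if "sim" in spec.methods:
        sim = simulate_population(
            model, h=h, n_neurons=spec.n_neurons, seed=spec.seed, window=spec.window
        )
        write_raster(sim.raster, out_dir / "raster.csv")
        write_trace(sim.activity, out_dir / "psth.csv", "activity_khz")
        report["methods"]["sim"] = {
            "n_spikes": int(sim.raster.n_spikes),
            "mean_rate_hz": 1000.0 * float(sim.counts.sum())
            / (spec.n_neurons * sim.activity.duration),
        }

    encoders = {
        "renewal": encode_renewal,
        "qr": encode_qr,
        "eme1": encode_eme1,
        "eme2": encode_eme2,
    }
    for name, enc in encoders.items():
        if name not in spec.methods:
            continue
        try:
            if name in ("renewal", "qr"):
                a, info = enc(model, h, eps=spec.eps, full_output=True)
                log.info(
                    "%s: max conservation residual %.3e",
                    name,
                    info["max_conservation_residual"],
                )
            else:
                a = enc(model, h, eps=spec.eps)
            write_trace(a, out_dir / f"activity_{name}.csv", "activity_khz")
            entry = {"mean_rate_hz": 1000.0 * float(a.values.mean())}
            if sim is not None:
                rep = compare_traces(a, sim.activity, window=spec.window)
                entry["vs_sim"] = {
                    "pearson_r": rep.pearson_r,
                    "mse": rep.mean_squared_error,
                    "positive_error_fraction": rep.positive_error_fraction,
                }
            report["methods"][name] = entry
        except Exception as exc:  # isolate per-method failures
            log.exception("method %s failed", name)
            report["errors"][name] = repr(exc)

    decoders = {"decode_qr": decode_qr, "decode_eme1": decode_eme1}
    for name, dec in decoders.items():
        if name not in spec.methods:
            continue
        try:
            if sim is None:
                raise ValueError(f"{name} needs 'sim' among the methods")
            a_min = auto_a_min(spec.n_neurons, spec.window)
            res = dec(model, sim.activity, eps=spec.eps, a_min=a_min)
            write_decode_result(res, out_dir / f"{name}.csv")
            entry = {"decodable_fraction": res.decodable_fraction, "a_min_khz": a_min}
            if res.valid.sum() >= 2:
                entry["pearson_r_vs_true_h"] = corrcoef(
                    res.h_hat.values, h.values, mask=res.valid
                )
            report["methods"][name] = entry
        except Exception as exc:
            log.exception("method %s failed", name)
            report["errors"][name] = repr(exc)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
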