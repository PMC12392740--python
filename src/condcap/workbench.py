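"""Experiment orchestration: configuration, replicates, and sweeps.

An :class:`ExperimentConfig` fixes the physical conditions (model,
``eps_ss``, ``eps_c``, concentration, condensate volume ratio) and the
run parameters; :func:`run_experiment` executes ``n_replicates`` seeded
trajectories, analyzes each, and aggregates every observable as
mean +/- twice the standard error of the mean.  Replicate seeds are
``base_seed + replicate_index``, so a summary is reproducible from its
provenance block alone.
"""

from __future__ import annotations

import hashlib
import json
import math
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

import condcap
from condcap.analysis import (
    AssemblyTimeSeries,
    aggregate_replicates,
    analyze_trajectory,
    max_assembly_rate,
    median_assembly_time,
)
from condcap.condensate import CondensateSpec
from condcap.dynamics import RunConfig, initialize_random, run
from condcap.geometry import (
    build_dodecahedron_subunit,
    build_icosahedron_subunit,
    build_interaction_table,
)

__all__ = ["ExperimentConfig", "run_experiment", "sweep"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Physical and numerical conditions of one experiment.

    Exactly one of ``rho_T``/``L`` must be given (with ``N``), and exactly
    one of ``V_r``/``R_c``.
    """

    model: str = "dodecahedron"
    eps_ss: float = 6.0
    eps_c: float = 0.0
    N: int = 60
    rho_T: float | None = 4.0e-4
    L: float | None = None
    V_r: float | None = 5.03e-3
    R_c: float | None = None
    dt: float = 5.0e-3
    gamma: float = 1.0
    t_F: float = 2.0e4
    snapshot_every: float = 500.0
    n_replicates: int = 1
    base_seed: int = 1
    outdir: str | None = None

    def __post_init__(self):
        if (self.rho_T is None) == (self.L is None):
            raise ValueError("give exactly one of rho_T or L")
        if (self.V_r is None) == (self.R_c is None):
            raise ValueError("give exactly one of V_r or R_c")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")

    @property
    def box_L(self) -> float:
        return self.L if self.L is not None else (self.N / self.rho_T) ** (1.0 / 3.0)

    def condensate(self) -> CondensateSpec | None:
        if self.eps_c == 0.0:
            return None
        if self.R_c is not None:
            return CondensateSpec(R_c=self.R_c, eps_c=self.eps_c)
        # at fixed V_r the condensate radius rescales with the box
        return CondensateSpec.from_volume_ratio(self.V_r, self.box_L, eps_c=self.eps_c)

    def template(self):
        if self.model == "dodecahedron":
            return build_dodecahedron_subunit(1.0)
        if self.model == "icosahedron":
            return build_icosahedron_subunit(1.0)
        raise ValueError(f"unknown model {self.model!r}")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    @staticmethod
    def from_toml(path: str | Path) -> "ExperimentConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return ExperimentConfig(**data)


def _replicate_series(config: ExperimentConfig, replicate: int) -> AssemblyTimeSeries:
    template = config.template()
    table = build_interaction_table(config.model, config.eps_ss)
    spec = config.condensate()
    seed = (config.base_seed + replicate) % (2**31 - 1)
    state = initialize_random(config.N, config.box_L, template, seed=seed)
    rc = RunConfig(
        dt=config.dt,
        gamma=config.gamma,
        t_F=config.t_F,
        snapshot_every=config.snapshot_every,
        seed=seed,
    )
    traj = run(state, rc, table, spec, template)
    R_c = spec.R_c if spec is not None else None
    return analyze_trajectory(traj, template, R_c)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run all replicates, aggregate observables, and return a summary.

    The summary is machine-readable: final-frame observables as
    ``{"mean": m, "two_sem": s}`` plus a provenance block (config, hash,
    seeds, package version).  If ``config.outdir`` is set, the summary and
    per-replicate series CSVs are written there.
    """
    all_series: list[AssemblyTimeSeries] = []
    errors: list[str] = []
    for rep in range(config.n_replicates):
        try:
            all_series.append(_replicate_series(config, rep))
        except Exception as exc:  # propagate per-replicate failures as flags
            errors.append(f"replicate {rep}: {type(exc).__name__}: {exc}")
    if not all_series:
        raise RuntimeError("all replicates failed: " + "; ".join(errors))

    def agg(values):
        mean, two_sem = aggregate_replicates(values)
        return {"mean": mean, "two_sem": two_sem}

    finals = {
        "f_c": [s.f_c[-1] for s in all_series],
        "f_c_c": [s.f_c_c[-1] for s in all_series],
        "f_c_bg": [s.f_c_bg[-1] for s in all_series],
        "off_target_fraction": [s.off_target[-1] for s in all_series],
        "mean_cluster_size": [s.mean_cluster_size[-1] for s in all_series],
        "n_complete": [s.n_complete[-1] for s in all_series],
    }
    kc = [s.K_c_meas[-1] for s in all_series if math.isfinite(s.K_c_meas[-1])]
    summary = {name: agg(vals) for name, vals in finals.items()}
    if kc:
        summary["K_c_meas"] = agg(kc)
    tau = []
    rmax = []
    for s in all_series:
        if s.f_c[-1] > 0:
            tau.append(median_assembly_time(s.times, s.f_c))
            if len(s.times) >= 5:
                rmax.append(max_assembly_rate(s.times, s.f_c))
    if tau:
        summary["tau_half"] = agg(tau)
    if rmax:
        summary["r_max"] = agg(rmax)

    result = {
        "observables": summary,
        "provenance": {
            "config": asdict(config),
            "config_hash": config.hash(),
            "seeds": [
                (config.base_seed + r) % (2**31 - 1) for r in range(config.n_replicates)
            ],
            "condcap_version": condcap.__version__,
        },
        "replicate_errors": errors,
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"summary-{config.hash()}.json", "w") as fh:
            json.dump(result, fh, indent=1, default=float)
        for rep, s in enumerate(all_series):
            s.to_dataframe().to_csv(out / f"series-{config.hash()}-r{rep}.csv", index=False)
    return result


def sweep(config: ExperimentConfig, parameter: str, values) -> pd.DataFrame:
    """One :func:`run_experiment` per parameter value; tidy long table
    with columns (parameter, value, observable, mean, two_sem)."""
    if values is not None and len(values) == 0:
        return pd.DataFrame(columns=[parameter, "observable", "mean", "two_sem"])
    if parameter not in {f.name for f in ExperimentConfig.__dataclass_fields__.values()}:
        raise ValueError(f"unknown config field {parameter!r}")
    rows = []
    for v in values:
        res = run_experiment(replace(config, **{parameter: v}))
        for obs, stat in res["observables"].items():
            rows.append(
                {
                    parameter: v,
                    "observable": obs,
                    "mean": stat["mean"],
                    "two_sem": stat["two_sem"],
                }
            )
    return pd.DataFrame(rows)
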