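"""Run configuration and end-to-end orchestration.

A :class:`RunConfig` carries everything needed to reproduce a simulation:
posture, cardiac output (clinical units at this boundary, L/min; SI
internally), the run mode, geometry source, physical parameters and
iteration controls.  :func:`run_from_config` executes the selected mode and
writes the network, the solution state, a metrics JSON block, and the
coupling iteration log into the output directory.  Every output bundle
records the seed and a hash of the configuration so a run can be re-created
from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .capillary import CapillarySheetParams, LadderAcinus
from .coupling import CouplingConfig, run_coupled
from .flow_solver import (BoundaryConditionSet, ComplianceLaw,
                          FluidProperties, SolverOptions, solve_network)
from .geometry import (RIGHT_LUNG_VOLUME_FRACTION, TreeGrowthParams,
                       build_circulation)
from .macro import default_macro_params, surrogate_solve
from .metrics import PerfusionSummary
from .posture import PostureContext

L_MIN_TO_M3_S = 1.0 / 60000.0


def lmin_to_si(q_l_min: float) -> float:
    return q_l_min * L_MIN_TO_M3_S


@dataclass
class RunConfig:
    """Declarative description of one simulation run."""

    posture: str = "supine"
    cardiac_output_L_min: float = 4.8
    mode: str = "coupled"  # "oneD" | "macro" | "coupled"
    seed: int = 0
    n_acini: int = 10000
    total_lung_volume_m3: float = 4.0e-3
    right_lung_fraction: float = RIGHT_LUNG_VOLUME_FRACTION
    acinar_size_cv: float = 0.30  # CV of acinar capillary surface area
    diameter_scatter_cv: float = 0.15  # within-order vessel caliber CV
    network_dir: str | None = None  # load instead of generate when set
    out_dir: str = "results"
    export_vtk: bool = False
    # physical parameter groups (flat keys for YAML friendliness)
    blood_viscosity_Pa_s: float = 0.0035
    blood_density_kg_m3: float = 1050.0
    compliance_alpha_per_Pa: float = 1.49e-4
    venous_outlet_pressure_Pa: float = 666.0
    alveolar_pressure_Pa: float = 0.0
    recoil_ref_Pa: float = -500.0
    recoil_slope_Pa_per_m: float = -981.0
    capillary: dict = field(default_factory=dict)  # CapillarySheetParams overrides
    coupling_lambda: float = 0.5
    coupling_epsilon: float = 0.1
    coupling_max_iterations: int = 200
    coupling_error_metric: str = "sum_sq"

    def __post_init__(self):
        if self.cardiac_output_L_min <= 0:
            raise ValueError("cardiac output must be positive")
        if self.mode not in ("oneD", "macro", "coupled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for key, val in (("blood_viscosity_Pa_s", self.blood_viscosity_Pa_s),
                         ("blood_density_kg_m3", self.blood_density_kg_m3),
                         ("n_acini", self.n_acini)):
            if val <= 0:
                raise ValueError(f"{key} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise KeyError(f"unknown configuration key(s): {unknown}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location does
        not change what is computed, so it is excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    # -- derived parameter objects ---------------------------------------
    def fluid(self) -> FluidProperties:
        return FluidProperties(mu=self.blood_viscosity_Pa_s,
                               rho_b=self.blood_density_kg_m3)

    def law(self) -> ComplianceLaw:
        return ComplianceLaw(alpha=self.compliance_alpha_per_Pa)

    def sheet_params(self) -> CapillarySheetParams:
        return CapillarySheetParams(**self.capillary)

    def ladder(self) -> LadderAcinus:
        return LadderAcinus(sheet=self.sheet_params(),
                            mu_blood=self.blood_viscosity_Pa_s,
                            alveolar_pressure=self.alveolar_pressure_Pa)

    def base_bcs(self) -> BoundaryConditionSet:
        return BoundaryConditionSet(
            venous_outlet_pressure=self.venous_outlet_pressure_Pa,
            alveolar_pressure=self.alveolar_pressure_Pa,
            recoil_ref=self.recoil_ref_Pa,
            recoil_slope=self.recoil_slope_Pa_per_m)

    def coupling(self) -> CouplingConfig:
        return CouplingConfig(lam=self.coupling_lambda,
                              epsilon=self.coupling_epsilon,
                              max_iterations=self.coupling_max_iterations,
                              error_metric=self.coupling_error_metric)

    def posture_context(self) -> PostureContext:
        return PostureContext.from_name(self.posture)

    def q_cardiac_si(self) -> float:
        return lmin_to_si(self.cardiac_output_L_min)


def get_network(config: RunConfig):
    if config.network_dir is not None:
        return pio.read_network(config.network_dir)
    return build_circulation(
        n_acini=config.n_acini,
        total_volume=config.total_lung_volume_m3,
        right_fraction=config.right_lung_fraction,
        diameter_cv=config.diameter_scatter_cv,
        acinar_size_cv=config.acinar_size_cv,
        rng_seed=config.seed,
    )


def run_from_config(config: RunConfig) -> dict:
    """Execute the configured run end-to-end; returns the metrics block."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    posture = config.posture_context()
    q_si = config.q_cardiac_si()
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}

    if config.mode == "macro":
        params = default_macro_params(mu=config.blood_viscosity_Pa_s,
                                      rho_b=config.blood_density_kg_m3)
        p_ref = config.venous_outlet_pressure_Pa + 1000.0
        P_in, Q_out, sawss = surrogate_solve(
            q_si, {"LPA": p_ref, "RPA": p_ref}, params,
            config.blood_viscosity_Pa_s)
        metrics = {
            **stamp, "mode": "macro", "posture": config.posture,
            "CO_L_min": config.cardiac_output_L_min,
            "inlet_pressure_Pa": P_in,
            "LPA_fraction_percent": 100.0 * Q_out["LPA"] / q_si,
            "RPA_fraction_percent": 100.0 * Q_out["RPA"] / q_si,
            "SAWSS_dyne_cm2": sawss.area_weighted_dyne_cm2,
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        return metrics

    network = get_network(config)
    pio.write_network(network, out / "network")
    ladder = config.ladder()
    bcs = config.base_bcs()

    if config.mode == "oneD":
        bcs.inflows = {network.inlet_node: q_si}
        bcs.include_macro_elements = True
        state = solve_network(network, bcs, posture, config.fluid(),
                              config.law(), ladder=ladder)
        log = pd.DataFrame()
        extra = {}
    else:  # coupled
        params = default_macro_params(mu=config.blood_viscosity_Pa_s,
                                      rho_b=config.blood_density_kg_m3)
        result = run_coupled(params, network, q_si, posture,
                             config=config.coupling(), bcs=bcs,
                             fluid=config.fluid(), law=config.law(),
                             ladder=ladder)
        state = result.state
        log = result.coupling.log()
        extra = {
            "coupling_iterations": result.coupling.iterations,
            "coupling_error": result.coupling.error_trace[-1],
            "inlet_pressure_Pa": result.inlet_pressure,
            "SAWSS_dyne_cm2": result.sawss.area_weighted_dyne_cm2,
        }

    pio.write_state(state, network, out / "state")
    if len(log):
        log.to_csv(out / "coupling_log.csv", index=False)
    if config.export_vtk:
        pio.export_vtk(network, out / "network.vtk", state)

    summary = PerfusionSummary.from_state(network, state, posture)
    metrics = {**stamp, "mode": config.mode,
               **summary.metrics_dict(config.cardiac_output_L_min), **extra}
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    return metrics
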