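"""Delimited-text and config serialization.

Waveforms and sweeps travel as CSV with ``#``-prefixed header comment lines
carrying metadata (amplitude, frequency, units, seed, generating
coefficients); die cases as YAML-style structured text; parameter sets and
reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constitutive import (MaterialProperties, PTTParams,
                           PowerLawTemperatureModel)
from .dieflow import DieCase
from .laos import OscillatoryCycle
from .saos import FrequencySweep
from . import tables


def _write_with_meta(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {json.dumps(val)}\n")
        df.to_csv(fh, index=False)


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = json.loads(val.strip())
    return meta


def write_waveform_csv(path, cycle: OscillatoryCycle) -> None:
    meta = {"gamma0": cycle.gamma0, "omega_rad_s": cycle.omega,
            "strain_unit": cycle.unit, "temperature_degC": cycle.temperature,
            **{k: v for k, v in cycle.meta.items()}}
    df = pd.DataFrame({"time_s": cycle.time, "strain": cycle.strain,
                       "strain_rate": cycle.strain_rate,
                       "stress_Pa": cycle.stress})
    _write_with_meta(path, df, meta)


def read_waveform_csv(path) -> OscillatoryCycle:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    e_coeffs = meta.pop("e_coeffs", None)
    v_coeffs = meta.pop("v_coeffs", None)
    extra = {}
    if e_coeffs is not None:
        extra["e_coeffs"] = {int(k): v for k, v in e_coeffs.items()}
    if v_coeffs is not None:
        extra["v_coeffs"] = {int(k): v for k, v in v_coeffs.items()}
    return OscillatoryCycle(
        time=df["time_s"].to_numpy(),
        strain=df["strain"].to_numpy(),
        strain_rate=df["strain_rate"].to_numpy(),
        stress=df["stress_Pa"].to_numpy(),
        gamma0=meta["gamma0"], omega=meta["omega_rad_s"],
        unit=meta.get("strain_unit", "fraction"),
        temperature=meta.get("temperature_degC", float("nan")),
        meta={**extra,
              **{k: v for k, v in meta.items()
                 if k not in ("gamma0", "omega_rad_s", "strain_unit",
                              "temperature_degC")}},
    )


def read_waveform_generic(path, gamma0: float, omega: float,
                          sample_rate: float | None = None,
                          unit: str = "fraction") -> OscillatoryCycle:
    """Read a generic two-column (strain, stress) rheometer export.

    Sampling metadata comes from the arguments (or a time column if the
    file has one); strain rate is reconstructed as gamma0*omega*cos from
    the fitted phase downstream, here by spectral differentiation.
    """
    df = pd.read_csv(path, comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "time_s" in cols:
        t = df["time_s"].to_numpy()
    else:
        if sample_rate is None:
            raise ValueError("need sample_rate when the file has no time column")
        t = np.arange(len(df)) / sample_rate
    strain = df["strain"].to_numpy()
    stress = df["stress"].to_numpy() if "stress" in cols \
        else df["stress_pa"].to_numpy()
    dt = t[1] - t[0]
    rate = np.gradient(strain, dt)
    return OscillatoryCycle(time=t, strain=strain, strain_rate=rate,
                            stress=stress, gamma0=gamma0, omega=omega,
                            unit=unit)


def write_sweep_csv(path, sweep: FrequencySweep, meta: dict | None = None) -> None:
    md = {"temperature_degC": sweep.temperature,
          "state_label": sweep.state_label, **(meta or {})}
    df = pd.DataFrame({"omega_rad_s": sweep.omega,
                       "G_prime_Pa": sweep.G_prime,
                       "G_dprime_Pa": sweep.G_dprime})
    _write_with_meta(path, df, md)


def read_sweep_csv(path) -> FrequencySweep:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    return FrequencySweep(omega=df["omega_rad_s"].to_numpy(),
                          G_prime=df["G_prime_Pa"].to_numpy(),
                          G_dprime=df["G_dprime_Pa"].to_numpy(),
                          temperature=meta.get("temperature_degC",
                                               float("nan")),
                          state_label=meta.get("state_label"))


def _model_to_dict(model) -> dict:
    if isinstance(model, PowerLawTemperatureModel):
        return {"kind": "A", "K0": model.K0, "Ea_k": model.Ea_k,
                "n0": model.n0, "alpha_n": model.alpha_n, "T_ref": model.T_ref}
    if isinstance(model, PTTParams):
        return {"kind": "B", "eta0_ref": model.eta0_ref,
                "lambda_ref": model.lambda_ref, "epsilon": model.epsilon,
                "E_eta": model.E_eta, "E_lambda": model.E_lambda,
                "T_ref": model.T_ref}
    raise TypeError(type(model).__name__)


def _model_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("kind")
    if kind == "A":
        return PowerLawTemperatureModel(**d)
    if kind == "B":
        return PTTParams(**d)
    raise ValueError(f"unknown model kind {kind!r}")


def material_for_sample(sample: str) -> MaterialProperties:
    """MaterialProperties built from the packaged thermophysical table."""
    row = tables.MATERIAL[sample]
    return MaterialProperties(rho=row["rho_kg_per_m3"],
                              cp_poly=row["cp_poly"], k_poly=row["k_poly"])


def ptt_for_sample(sample: str, T_ref_degC: float = 100.0) -> PTTParams:
    """Reference-state PTT parameters from the packaged table."""
    row = tables.MATERIAL[sample]
    return PTTParams(eta0_ref=row["eta0_Pa_s"], lambda_ref=row["lambda_s"],
                     epsilon=row["epsilon"], T_ref=T_ref_degC + 273.15)


def write_die_case_yaml(path, case: DieCase) -> None:
    doc = {
        "geometry": {"width_m": case.width, "height_m": case.height,
                     "length_m": case.length},
        "zones": {"bounds_m": list(case.zone_bounds),
                  "wall_T_degC": list(case.zone_wall_T)},
        "inlet": {"T_degC": case.inlet_T, "Q_m3_s": case.inlet_Q},
        "outlet_gauge_Pa": case.outlet_gauge_P,
        "material": {"rho_kg_per_m3": case.material.rho,
                     "cp_poly": list(map(float, case.material.cp_poly)),
                     "k_poly": list(map(float, case.material.k_poly))},
        "model": _model_to_dict(case.model),
        "include_dissipation": case.include_dissipation,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_die_case_yaml(path) -> DieCase:
    doc = yaml.safe_load(Path(path).read_text())
    geom = doc["geometry"]
    zones = doc["zones"]
    mat = doc["material"]
    return DieCase(
        width=geom["width_m"], height=geom["height_m"],
        length=geom["length_m"],
        zone_bounds=tuple(zones["bounds_m"]),
        zone_wall_T=tuple(zones["wall_T_degC"]),
        inlet_T=doc["inlet"]["T_degC"], inlet_Q=doc["inlet"]["Q_m3_s"],
        outlet_gauge_P=doc.get("outlet_gauge_Pa", 0.0),
        material=MaterialProperties(rho=mat["rho_kg_per_m3"],
                                    cp_poly=mat["cp_poly"],
                                    k_poly=mat["k_poly"]),
        model=_model_from_dict(doc["model"]),
        include_dissipation=doc.get("include_dissipation", True),
    )
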