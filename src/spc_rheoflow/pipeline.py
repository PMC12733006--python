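"""End-to-end orchestration: rheometry inputs -> fits -> die prediction.

One `run_pipeline` call executes the full modeling chain for a sample:

1. obtain a frequency sweep and a LAOS waveform (from files, or synthesized
   from the packaged per-sample parameters when no files are given),
2. SAOS stage: power-law fits of G' and G'', damping factors, crossover,
3. LAOS stage: harmonic/Chebyshev decomposition and intracycle measures,
4. extraction: single-mode PTT parameters (lambda, eta0, eps),
5. die flow: reduced-order non-isothermal solve with Model A and/or
   Model B, optionally calibrating the inlet flow to the mid-die bulk
   temperature,
6. report: a JSON-serializable RunReport with per-stage tables, flow
   summaries, input hashes and the run seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constitutive, dieflow, io, laos, saos, synthetic, tables


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    sample_label: str = "SPC_0"
    sweep_file: str | None = None       # CSV frequency sweep; None -> synthesize
    waveform_file: str | None = None    # CSV LAOS waveform; None -> synthesize
    models: tuple[str, ...] = ("A", "B")
    gamma0_laos: float = 2.0            # strain fraction for the LAOS stage
    omega_laos: float = 1.0             # rad/s
    solver_ny: int = 16
    solver_nz: int = 150
    calibrate_midzone: bool = False
    target_mid_T: float = 86.0          # degC
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for path in (self.sweep_file, self.waveform_file):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")


@dataclass
class RunReport:
    """Serializable record of every stage of a pipeline run."""

    config: dict
    input_hashes: dict
    saos_stage: dict
    laos_stage: dict
    ptt_params: dict
    flow_summaries: dict
    seed: int
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True,
                          default=_jsonable)

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")


def _hash_text(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full chain for one sample; see module docstring."""
    label = config.sample_label
    hashes: dict[str, str] = {}
    mat_row = tables.MATERIAL.get(label)

    # --- stage: inputs -----------------------------------------------------
    try:
        if config.sweep_file:
            sweep = io.read_sweep_csv(config.sweep_file)
            hashes["sweep"] = _hash_text(config.sweep_file)
        else:
            if mat_row is None:
                raise ValueError(f"no packaged parameters for {label!r}; "
                                 "provide a sweep_file")
            sweep = synthetic.make_saos_sweep(synthetic.SweepSpec(
                model_kind="maxwell",
                omega_grid=synthetic.default_omega_grid(0.01, 100.0, 50),
                eta0=mat_row["eta0_Pa_s"], lam=mat_row["lambda_s"],
                seed=config.seed))
            hashes["sweep"] = "synthetic"
        ptt_truth = None
        if config.waveform_file:
            cycle = io.read_waveform_csv(config.waveform_file)
            hashes["waveform"] = _hash_text(config.waveform_file)
        else:
            if mat_row is None:
                raise ValueError(f"no packaged parameters for {label!r}; "
                                 "provide a waveform_file")
            ptt_truth = io.ptt_for_sample(label)
            cycle = constitutive.ptt_laos_cycle(
                ptt_truth, config.gamma0_laos, config.omega_laos)
            hashes["waveform"] = "synthetic-ptt"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'inputs' failed: {exc}") from exc

    # --- stage: SAOS -------------------------------------------------------
    try:
        fit_p = saos.fit_power_law(sweep, "G_prime")
        fit_pp = saos.fit_power_law(sweep, "G_dprime")
        crossover = saos.find_crossover(sweep)
        saos_stage = {
            "power_law_G_prime": {"K": fit_p.K, "n": fit_p.n,
                                  "r_squared": fit_p.r_squared},
            "power_law_G_dprime": {"K": fit_pp.K, "n": fit_pp.n,
                                   "r_squared": fit_pp.r_squared},
            "damping_factor": {str(w): saos.damping_factor(fit_p, fit_pp, w)
                               for w in (1.0, 4.0, 100.0)},
            "crossover_omega_rad_s": crossover,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'saos' failed: {exc}") from exc

    # --- stage: LAOS -------------------------------------------------------
    try:
        spectrum = laos.decompose(cycle)
        cheb = laos.chebyshev_from_fourier(spectrum)
        measures = laos.nonlinear_measures(cheb)
        loop = laos.lissajous(cycle)
        laos_stage = {
            "orders": spectrum.orders.tolist(),
            "G_prime_n": spectrum.G_prime_n.tolist(),
            "G_dprime_n": spectrum.G_dprime_n.tolist(),
            "e": cheb.e.tolist(), "v": cheb.v.tolist(),
            "measures": dataclasses.asdict(measures),
            "loop_area_elastic_Pa": loop.enclosed_area_elastic,
            "loop_area_viscous_Pa": loop.enclosed_area_viscous,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'laos' failed: {exc}") from exc

    # --- stage: extraction -------------------------------------------------
    try:
        ptt = constitutive.extract_ptt(sweep, measures,
                                       gamma0_ref=config.gamma0_laos,
                                       omega_ref=config.omega_laos)
        ptt_dict = {"eta0_Pa_s": ptt.eta0_ref, "lambda_s": ptt.lambda_ref,
                    "epsilon": ptt.epsilon,
                    "estimator_notes": getattr(ptt, "notes", {})}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'extract' failed: {exc}") from exc

    # --- stage: die flow ---------------------------------------------------
    try:
        material = (io.material_for_sample(label) if mat_row is not None
                    else constitutive.MaterialProperties(
                        rho=1050.0, cp_poly=[3600.0], k_poly=[0.5]))
        flow_summaries: dict[str, dict] = {}
        for kind in config.models:
            if kind == "A":
                model = constitutive.PowerLawTemperatureModel(
                    K0=fit_p.K, Ea_k=0.0, n0=fit_p.n, alpha_n=0.0,
                    T_ref=373.15)
            else:
                model = ptt
            case = dieflow.DieCase(material=material, model=model)
            factor = 1.0
            if config.calibrate_midzone:
                case, factor = dieflow.calibrate_inlet_flow(
                    case, config.target_mid_T,
                    ny=config.solver_ny, nz=config.solver_nz)
            fieldd = dieflow.solve(case, ny=config.solver_ny,
                                   nz=config.solver_nz)
            summary = dieflow.temperature_summary(fieldd)
            flow_summaries[kind] = {
                "delta_p_Pa": fieldd.delta_p,
                "temperature_summary_degC": summary,
                "inlet_Q_m3_s": case.inlet_Q,
                "flow_calibration_factor": factor,
                "wall_heat_W": fieldd.wall_heat_W,
                "dissipation_W": fieldd.dissipation_W,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'die_flow' failed: {exc}") from exc

    report = RunReport(
        config=dataclasses.asdict(config),
        input_hashes=hashes,
        saos_stage=saos_stage,
        laos_stage=laos_stage,
        ptt_params=ptt_dict,
        flow_summaries=flow_summaries,
        seed=config.seed,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"report_{label}.json").write_text(report.to_json())
    return report


def table_fixtures():
    """Packaged, machine-readable copies of the characterization tables."""
    return tables.table_fixtures()
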