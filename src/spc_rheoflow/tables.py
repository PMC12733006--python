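"""Packaged rheological and thermophysical parameter tables.

Machine-readable copies of the published characterization tables for the
soy-protein-concentrate (SPC) / coconut-oil system, used as worked-example
inputs throughout the pipeline:

* ``CRITICAL_STRAIN`` — crossover strain, critical strain, modulus at the
  critical strain and cohesive energy density per sample and structural
  state (paste 25 degC, molten 100 degC, weak gel 70 degC).
* ``POWER_LAW`` — damping factors at 1/4/100 rad/s and the power-law
  consistency/exponent fits of G' and G'' per sample and state.
* ``MATERIAL`` — density, cp(T) and k(T) polynomials (T in degC), and the
  single-mode PTT parameters (eta0, lambda, epsilon) per sample.

Critical strains are stored in the percent convention in which they were
printed; cohesive energy densities follow the same convention (see
``saos.cohesive_energy_density``). "nil" crossover strain means no G'-G''
crossover was observed over the swept range.
"""

from __future__ import annotations

import json
from typing import Any

SAMPLES = ("SPC_0", "SPC_0.5", "SPC_1", "SPC_1.5", "SPC_2")
STATES = ("paste", "molten", "weak_gel")

# state -> sample -> {crossover_strain_pct, gamma_cr_pct, G_cr_Pa, E_c_J_per_m3}
# (mean, sd) pairs as printed; crossover "nil" encoded as None.
CRITICAL_STRAIN: dict[str, dict[str, dict[str, Any]]] = {
    "paste": {
        "SPC_0":   {"crossover_strain_pct": None, "gamma_cr_pct": (0.27, 0.05), "G_cr_Pa": (77.09, 1.14), "E_c_J_per_m3": (2.72, 0.04)},
        "SPC_0.5": {"crossover_strain_pct": None, "gamma_cr_pct": (0.23, 0.03), "G_cr_Pa": (56.53, 2.35), "E_c_J_per_m3": (1.48, 0.03)},
        "SPC_1":   {"crossover_strain_pct": None, "gamma_cr_pct": (0.19, 0.01), "G_cr_Pa": (54.79, 4.11), "E_c_J_per_m3": (1.01, 0.11)},
        "SPC_1.5": {"crossover_strain_pct": None, "gamma_cr_pct": (0.18, 0.02), "G_cr_Pa": (33.52, 2.19), "E_c_J_per_m3": (0.52, 0.08)},
        "SPC_2":   {"crossover_strain_pct": None, "gamma_cr_pct": (0.16, 0.02), "G_cr_Pa": (23.94, 1.96), "E_c_J_per_m3": (0.32, 0.06)},
    },
    "molten": {
        "SPC_0":   {"crossover_strain_pct": (3.17, 0.26), "gamma_cr_pct": (0.16, 0.03), "G_cr_Pa": (8981.64, 276.49), "E_c_J_per_m3": (117.92, 5.39)},
        "SPC_0.5": {"crossover_strain_pct": (1.61, 0.31), "gamma_cr_pct": (0.16, 0.02), "G_cr_Pa": (6014.39, 199.64), "E_c_J_per_m3": (73.94, 9.46)},
        "SPC_1":   {"crossover_strain_pct": (1.53, 0.09), "gamma_cr_pct": (0.15, 0.02), "G_cr_Pa": (3791.64, 105.37), "E_c_J_per_m3": (43.54, 3.14)},
        "SPC_1.5": {"crossover_strain_pct": (0.67, 0.15), "gamma_cr_pct": (0.15, 0.04), "G_cr_Pa": (2923.33, 164.88), "E_c_J_per_m3": (32.78, 5.23)},
        "SPC_2":   {"crossover_strain_pct": (0.67, 0.07), "gamma_cr_pct": (0.15, 0.04), "G_cr_Pa": (1843.51, 98.64),  "E_c_J_per_m3": (20.37, 2.03)},
    },
    "weak_gel": {
        "SPC_0":   {"crossover_strain_pct": (4.85, 0.45), "gamma_cr_pct": (0.18, 0.03), "G_cr_Pa": (9508.49, 328.44),  "E_c_J_per_m3": (147.01, 7.65)},
        "SPC_0.5": {"crossover_strain_pct": (3.17, 0.29), "gamma_cr_pct": (0.19, 0.05), "G_cr_Pa": (14626.74, 561.23), "E_c_J_per_m3": (262.77, 11.65)},
        "SPC_1":   {"crossover_strain_pct": (1.61, 0.07), "gamma_cr_pct": (0.20, 0.04), "G_cr_Pa": (30817.52, 615.18), "E_c_J_per_m3": (626.55, 45.77)},
        "SPC_1.5": {"crossover_strain_pct": (1.60, 0.05), "gamma_cr_pct": (0.31, 0.08), "G_cr_Pa": (36514.65, 594.39), "E_c_J_per_m3": (1715.48, 189.64)},
        "SPC_2":   {"crossover_strain_pct": (1.59, 0.06), "gamma_cr_pct": (0.29, 0.07), "G_cr_Pa": (36499.80, 561.78), "E_c_J_per_m3": (1563.67, 167.28)},
    },
}

# state -> sample -> damping factors at 1/4/100 rad/s and power-law fits
# K', K'' in Pa·s^n, n', n'' dimensionless.
POWER_LAW: dict[str, dict[str, dict[str, Any]]] = {
    "paste": {
        "SPC_0":   {"damping_1": (3.522, 0.05), "damping_4": (4.125, 0.05), "damping_100": (5.023, 0.05), "K_prime": (679.3, 11.1), "n_prime": (0.139, 0.003), "K_dprime": (2534.0, 22.4), "n_dprime": (0.206, 0.005)},
        "SPC_0.5": {"damping_1": (3.740, 0.04), "damping_4": (4.023, 0.06), "damping_100": (4.740, 0.06), "K_prime": (613.5, 16.6), "n_prime": (0.140, 0.004), "K_dprime": (2257.0, 25.1), "n_dprime": (0.194, 0.006)},
        "SPC_1":   {"damping_1": (3.309, 0.03), "damping_4": (3.771, 0.07), "damping_100": (4.406, 0.07), "K_prime": (551.1, 27.2), "n_prime": (0.129, 0.005), "K_dprime": (1850.0, 28.4), "n_dprime": (0.191, 0.006)},
        "SPC_1.5": {"damping_1": (3.447, 0.04), "damping_4": (3.765, 0.08), "damping_100": (4.121, 0.08), "K_prime": (481.9, 18.2), "n_prime": (0.124, 0.006), "K_dprime": (1697.0, 19.7), "n_dprime": (0.173, 0.007)},
        "SPC_2":   {"damping_1": (3.521, 0.06), "damping_4": (4.036, 0.09), "damping_100": (4.491, 0.09), "K_prime": (411.2, 19.3), "n_prime": (0.121, 0.007), "K_dprime": (1436.0, 27.3), "n_dprime": (0.186, 0.005)},
    },
    "molten": {
        "SPC_0":   {"damping_1": (0.309, 0.03), "damping_4": (0.301, 0.03), "damping_100": (0.263, 0.03), "K_prime": (4071.0, 10.3), "n_prime": (0.138, 0.002), "K_dprime": (1254.0, 12.7), "n_dprime": (0.096, 0.005)},
        "SPC_0.5": {"damping_1": (0.315, 0.04), "damping_4": (0.298, 0.04), "damping_100": (0.262, 0.04), "K_prime": (3557.0, 15.7), "n_prime": (0.135, 0.002), "K_dprime": (1111.0, 15.4), "n_dprime": (0.097, 0.006)},
        "SPC_1":   {"damping_1": (0.307, 0.05), "damping_4": (0.276, 0.05), "damping_100": (0.253, 0.05), "K_prime": (3258.0, 10.5), "n_prime": (0.129, 0.003), "K_dprime": (978.7, 18.6),  "n_dprime": (0.085, 0.007)},
        "SPC_1.5": {"damping_1": (0.311, 0.06), "damping_4": (0.310, 0.05), "damping_100": (0.282, 0.06), "K_prime": (2742.0, 15.3), "n_prime": (0.117, 0.001), "K_dprime": (862.9, 22.6),  "n_dprime": (0.087, 0.008)},
        "SPC_2":   {"damping_1": (0.336, 0.07), "damping_4": (0.298, 0.07), "damping_100": (0.285, 0.07), "K_prime": (2334.0, 13.2), "n_prime": (0.117, 0.001), "K_dprime": (745.8, 25.1),  "n_dprime": (0.084, 0.009)},
    },
    "weak_gel": {
        "SPC_0":   {"damping_1": (0.305, 0.03), "damping_4": (0.338, 0.03), "damping_100": (0.371, 0.03), "K_prime": (4962.0, 9.1),   "n_prime": (0.025, 0.002), "K_dprime": (1598.0, 12.7), "n_dprime": (0.050, 0.001)},
        "SPC_0.5": {"damping_1": (0.283, 0.04), "damping_4": (0.290, 0.04), "damping_100": (0.313, 0.04), "K_prime": (6714.0, 13.8),  "n_prime": (0.019, 0.002), "K_dprime": (1851.0, 17.5), "n_dprime": (0.052, 0.001)},
        "SPC_1":   {"damping_1": (0.237, 0.05), "damping_4": (0.240, 0.05), "damping_100": (0.257, 0.05), "K_prime": (8661.0, 9.5),   "n_prime": (0.024, 0.001), "K_dprime": (2007.0, 28.6), "n_dprime": (0.056, 0.001)},
        "SPC_1.5": {"damping_1": (0.215, 0.06), "damping_4": (0.218, 0.06), "damping_100": (0.247, 0.06), "K_prime": (10970.0, 11.8), "n_prime": (0.026, 0.001), "K_dprime": (2373.0, 21.2), "n_dprime": (0.061, 0.001)},
        "SPC_2":   {"damping_1": (0.219, 0.07), "damping_4": (0.220, 0.07), "damping_100": (0.238, 0.07), "K_prime": (12641.0, 11.3), "n_prime": (0.028, 0.001), "K_dprime": (2667.0, 29.9), "n_dprime": (0.062, 0.001)},
    },
}

# sample -> density, cp(T)/k(T) polynomial coefficients (highest order first,
# T in degC), and single-mode PTT reference parameters.
MATERIAL: dict[str, dict[str, Any]] = {
    "SPC_0":   {"rho_kg_per_m3": 1052.0, "cp_poly": [4e-15, 0.362, 3606.0],  "k_poly": [-9e-19, -0.0003, 0.5265], "eta0_Pa_s": 5112.0, "lambda_s": 1.0, "epsilon": 0.05},
    "SPC_0.5": {"rho_kg_per_m3": 1049.0, "cp_poly": [8e-6, 0.3609, 3599.0],  "k_poly": [2e-8, -0.0003, 0.5163],   "eta0_Pa_s": 4257.0, "lambda_s": 0.9, "epsilon": 0.05},
    "SPC_1":   {"rho_kg_per_m3": 1047.0, "cp_poly": [0.0, 0.361, 3591.0],    "k_poly": [0.0, -0.0005, 0.5125],    "eta0_Pa_s": 3625.0, "lambda_s": 0.8, "epsilon": 0.05},
    "SPC_1.5": {"rho_kg_per_m3": 1045.0, "cp_poly": [4e-6, 0.3589, 3581.0],  "k_poly": [-5e-8, -0.0005, 0.5022],  "eta0_Pa_s": 3011.0, "lambda_s": 0.7, "epsilon": 0.05},
    "SPC_2":   {"rho_kg_per_m3": 1041.0, "cp_poly": [4e-6, 0.3586, 3571.0],  "k_poly": [-4e-8, -0.0005, 0.4922],  "eta0_Pa_s": 2707.0, "lambda_s": 0.6, "epsilon": 0.05},
}


def table_fixtures() -> dict[str, Any]:
    """Return all packaged parameter tables as one JSON-serializable dict."""
    return {
        "critical_strain": CRITICAL_STRAIN,
        "power_law": POWER_LAW,
        "material": MATERIAL,
    }


def fixtures_json() -> str:
    """Serialize the fixtures losslessly to JSON (round-trips via json.loads)."""
    return json.dumps(table_fixtures(), indent=1)
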