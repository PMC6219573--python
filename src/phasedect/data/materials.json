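{
  "$schema_note": "Material database. Each entry: 'formula' (stoichiometric counts) OR 'mass_fractions' (summing to 1), plus 'density' in g/cm^3. Optional 'measured' block holds published ROI values (mu [cm^-1] at mu_energy_keV, delta at delta_energy_keV, zeff, rhoe [m^-3]) used e.g. for the blood decomposition basis.",
  "materials": {
    "water": {
      "formula": {"H": 2, "O": 1},
      "density": 1.000
    },
    "pmma": {
      "formula": {"C": 5, "O": 2, "H": 8},
      "density": 1.189
    },
    "pom": {
      "formula": {"C": 1, "H": 2, "O": 1},
      "density": 1.421
    },
    "nylon6": {
      "formula": {"C": 6, "H": 11, "N": 1, "O": 1},
      "density": 1.140
    },
    "ethanol": {
      "formula": {"C": 2, "H": 6, "O": 1},
      "density": 0.789
    },
    "blood": {
      "mass_fractions": {"H": 0.102, "C": 0.110, "N": 0.033, "O": 0.745,
                         "Na": 0.001, "P": 0.001, "S": 0.002, "Cl": 0.003,
                         "K": 0.002, "Fe": 0.001},
      "density": 1.060,
      "measured": {"mu_cm1": 0.568, "mu_energy_keV": 24.6,
                   "delta": 4.31e-7, "delta_energy_keV": 23.8,
                   "zeff": 7.60, "rhoe_m3": 3.54e29}
    },
    "sodium_iodide": {
      "formula": {"Na": 1, "I": 1},
      "density": 3.667
    }
  },
  "nai_solution_anchor": {
    "$note": "Published linear attenuation coefficient of a dilute NaI solution, used to calibrate the effective (sub-K-edge) iodine photo-effect strength of the interaction model.",
    "nai_mg_ml": 5.9,
    "mu_cm1": 0.609,
    "energy_keV": 24.6
  }
}
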