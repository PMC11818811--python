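"""Published thermodynamic and geometric reference values for the
phenanthridine-amide calix[4]arene / alkaline-earth system.

These are measured inputs (stability constants and calorimetric
enthalpies per cation and solvent, DFT-derived distances for the
solvent-adduct geometries, and the Na+ reference constant used in
competitive titrations), not quantities this package computes; derived
columns (dG, dS, selectivities) are always recomputed from them.
"""

from __future__ import annotations

from calixtherm.thermo import ThermoRecord

__all__ = [
    "NA_REFERENCE_LOGK",
    "CALIBRATION_LOGK",
    "CALIBRATION_DELTA_H",
    "thermo_records",
    "GEOMETRY_DISTANCES",
]

# Na+ complex of the ligand in MeCN, the fixed competitive reference.
NA_REFERENCE_LOGK = 10.50

# 18-crown-6 + Ba2+ in water, the ITC instrument-validation system.
CALIBRATION_LOGK = 3.761375  # log10(5772)
CALIBRATION_K = 5772.0  # dm^3 mol^-1
CALIBRATION_DELTA_H = -32.2  # kJ mol^-1

# (cation, solvent, logK, se(logK), dH, se(dH), methods)
# MeCN constants from competitive spectrophotometry, enthalpies from ITC;
# alcohol rows use the calorimetric constant where all three methods were
# applied (the dG column of the published table is tied to that method).
_ROWS = [
    ("Mg", "MeCN", 10.99, 0.03, None, None, ("spectrophotometry",)),
    ("Ca", "MeCN", 11.65, 0.05, -49.4, 0.7, ("spectrophotometry", "calorimetry")),
    ("Sr", "MeCN", 11.17, 0.02, -37.3, 0.5, ("spectrophotometry", "calorimetry")),
    ("Ba", "MeCN", 9.66, 0.02, -28.0, 0.4, ("spectrophotometry", "calorimetry")),
    ("Mg", "MeOH", 2.74, 0.02, None, None, ("spectrophotometry",)),
    ("Ca", "MeOH", 2.82, 0.02, None, None, ("spectrophotometry",)),
    ("Sr", "MeOH", 3.49, 0.02, 12.2, 0.4, ("calorimetry",)),
    ("Ba", "MeOH", 2.99, 0.01, 13.6, 0.5, ("calorimetry",)),
    ("Mg", "EtOH", 4.15, 0.02, None, None, ("spectrophotometry",)),
    ("Ca", "EtOH", 4.30, 0.05, 7.2, 0.5, ("calorimetry",)),
    ("Sr", "EtOH", 5.09, 0.02, 3.5, 0.1, ("calorimetry",)),
    ("Ba", "EtOH", 4.95, 0.01, 5.7, 0.2, ("calorimetry",)),
]

# Published dG (kJ mol^-1) and its parenthetical SE, per cation/solvent.
# These were averaged over replicates before rounding, so recomputation
# from the rounded logK can differ by about one unit in the last digit.
PRINTED_DELTA_G = {
    ("Mg", "MeCN"): (-62.7, 0.2), ("Ca", "MeCN"): (-66.5, 0.3),
    ("Sr", "MeCN"): (-63.7, 0.1), ("Ba", "MeCN"): (-55.2, 0.1),
    ("Mg", "MeOH"): (-15.6, 0.1), ("Ca", "MeOH"): (-16.1, 0.1),
    ("Sr", "MeOH"): (-19.9, 0.1), ("Ba", "MeOH"): (-17.08, 0.01),
    ("Mg", "EtOH"): (-23.7, 0.1), ("Ca", "EtOH"): (-24.6, 0.3),
    ("Sr", "EtOH"): (-29.1, 0.2), ("Ba", "EtOH"): (-28.28, 0.05),
}

# Spectrophotometric constants for alcohol rows where the ranking/selectivity
# discussion uses them (method "a" columns).
SPECTROPHOTOMETRIC_LOGK = {
    ("Mg", "MeOH"): 2.74,
    ("Ca", "MeOH"): 2.82,
    ("Sr", "MeOH"): 3.29,
    ("Ba", "MeOH"): 2.96,
    ("Mg", "EtOH"): 4.15,
    ("Ca", "EtOH"): 4.33,
    ("Sr", "EtOH"): 5.20,
    ("Ba", "EtOH"): 4.85,
}


def thermo_records() -> list[ThermoRecord]:
    """The measured (logK, dH) inputs as ThermoRecords with derived dG/dS."""
    return [
        ThermoRecord(
            cation=c, solvent=s, log_k=lk, log_k_se=lkse,
            delta_h=dh, delta_h_se=dhse, methods=m,
        )
        for c, s, lk, lkse, dh, dhse, m in _ROWS
    ]


# DFT-optimised adduct geometries: unsigned distances (Angstrom) from the
# ether-oxygen least-squares plane and between cation and solvent centre of
# mass, per cation and complex form.  Forms: bare complex (no included
# solvent), tail-in MeCN adduct (methyl towards cation), head-in MeCN
# adduct (nitrile towards cation).
GEOMETRY_DISTANCES = {
    # cation: {form: {"plane_cation": .., "plane_solvent": .., "cation_solvent": ..}}
    "Mg": {
        "bare": {"plane_cation": 0.678},
        "tail_in": {"plane_cation": 0.684, "plane_solvent": 4.757, "cation_solvent": 5.494},
        "head_in": {"plane_cation": 0.451, "plane_solvent": 3.112, "cation_solvent": 3.564},
    },
    "Ca": {
        "bare": {"plane_cation": 0.770},
        "tail_in": {"plane_cation": 0.788, "plane_solvent": 4.821, "cation_solvent": 5.655},
        "head_in": {"plane_cation": 0.566, "plane_solvent": 3.280, "cation_solvent": 3.847},
    },
    "Sr": {
        "bare": {"plane_cation": 1.225},
        "tail_in": {"plane_cation": 1.237, "plane_solvent": 4.839, "cation_solvent": 6.129},
        "head_in": {"plane_cation": 0.948, "plane_solvent": 3.082, "cation_solvent": 4.030},
    },
    "Ba": {
        "bare": {"plane_cation": 1.399},
        "tail_in": {"plane_cation": 1.411, "plane_solvent": 4.808, "cation_solvent": 6.262},
        "head_in": {"plane_cation": 1.207, "plane_solvent": 3.027, "cation_solvent": 4.234},
    },
}
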