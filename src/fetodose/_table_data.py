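"""Packaged monoenergetic coefficient tables and the per-nuclide summary subset.

Values are stored exactly as published (3 significant figures, MeV abscissa);
no rescaling or unit conversion happens anywhere in the package.

Units
-----
ground plane source at 0.5 g cm-2 depth:
    organ coefficients  Sv s-1 Bq-1 m2, air kerma  Gy s-1 Bq-1 m2
air submersion (semi-infinite cloud):
    organ coefficients  Sv s-1 Bq-1 m3, air kerma  Gy s-1 Bq-1 m3
"""

# Energy grid of the ground-plane organ tables (29 nodes, MeV).
GROUND_ENERGIES = (
    0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.1, 0.15,
    0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0, 1.1, 1.3,
    1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0,
)

# Energy grid of the air-submersion organ tables (20 nodes, MeV).  The
# submersion grid has gaps relative to the ground grid (no 0.4, 0.6, 0.8,
# 1.1, 1.3, 4, 5, 7, 8 MeV rows); fixtures store only printed nodes.
SUBMERSION_ENERGIES = (
    0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.1, 0.15,
    0.2, 0.3, 0.5, 0.7, 1.0, 1.5, 2.0, 3.0, 6.0, 10.0,
)

# Fetal organ equivalent dose rate coefficients, ground plane source
# (Sv s-1 Bq-1 m2), on GROUND_ENERGIES.
GROUND_ORGANS = {
    "skin": (
        7.00e-23, 2.98e-20, 1.87e-18, 8.19e-18, 1.58e-17, 2.37e-17, 3.09e-17,
        3.79e-17, 5.11e-17, 8.16e-17, 1.12e-16, 1.72e-16, 2.32e-16, 2.92e-16,
        3.53e-16, 4.11e-16, 4.70e-16, 5.87e-16, 6.36e-16, 7.53e-16, 8.54e-16,
        1.11e-15, 1.60e-15, 2.06e-15, 2.48e-15, 2.90e-15, 3.23e-15, 3.56e-15,
        4.34e-15,
    ),
    "eyes": (
        0.00e+00, 2.76e-21, 1.04e-18, 5.69e-18, 1.26e-17, 1.96e-17, 2.66e-17,
        3.34e-17, 4.63e-17, 7.96e-17, 1.04e-16, 1.62e-16, 2.29e-16, 2.86e-16,
        3.30e-16, 3.89e-16, 4.48e-16, 5.74e-16, 6.05e-16, 7.86e-16, 8.23e-16,
        1.04e-15, 1.59e-15, 2.04e-15, 2.44e-15, 2.88e-15, 3.33e-15, 3.78e-15,
        4.27e-15,
    ),
    "lungs": (
        4.37e-24, 1.17e-20, 1.62e-18, 7.98e-18, 1.58e-17, 2.38e-17, 3.10e-17,
        3.78e-17, 5.11e-17, 8.22e-17, 1.13e-16, 1.72e-16, 2.33e-16, 2.93e-16,
        3.51e-16, 4.08e-16, 4.65e-16, 5.90e-16, 6.29e-16, 7.52e-16, 8.48e-16,
        1.09e-15, 1.61e-15, 2.09e-15, 2.50e-15, 2.89e-15, 3.27e-15, 3.64e-15,
        4.30e-15,
    ),
    "heart": (
        0.00e+00, 3.89e-21, 1.18e-18, 6.82e-18, 1.50e-17, 2.27e-17, 2.92e-17,
        3.62e-17, 4.94e-17, 8.10e-17, 1.08e-16, 1.66e-16, 2.30e-16, 2.84e-16,
        3.47e-16, 4.08e-16, 4.69e-16, 5.73e-16, 6.07e-16, 7.60e-16, 8.26e-16,
        1.09e-15, 1.60e-15, 2.07e-15, 2.48e-15, 2.82e-15, 3.18e-15, 3.54e-15,
        4.17e-15,
    ),
    "kidneys": (
        7.84e-24, 1.58e-20, 1.72e-18, 8.32e-18, 1.66e-17, 2.47e-17, 3.24e-17,
        3.92e-17, 5.33e-17, 8.34e-17, 1.14e-16, 1.73e-16, 2.38e-16, 2.98e-16,
        3.59e-16, 4.17e-16, 4.75e-16, 5.85e-16, 6.30e-16, 7.50e-16, 8.55e-16,
        1.12e-15, 1.61e-15, 2.10e-15, 2.43e-15, 2.83e-15, 3.21e-15, 3.59e-15,
        4.37e-15,
    ),
    "liver": (
        4.48e-24, 1.33e-20, 1.67e-18, 8.22e-18, 1.61e-17, 2.41e-17, 3.17e-17,
        3.85e-17, 5.20e-17, 8.33e-17, 1.13e-16, 1.72e-16, 2.32e-16, 2.95e-16,
        3.54e-16, 4.14e-16, 4.73e-16, 5.79e-16, 6.31e-16, 7.59e-16, 8.46e-16,
        1.13e-15, 1.59e-15, 2.10e-15, 2.48e-15, 2.86e-15, 3.20e-15, 3.54e-15,
        4.32e-15,
    ),
    "stomach": (
        0.00e+00, 1.61e-21, 8.11e-19, 5.56e-18, 1.24e-17, 2.06e-17, 2.78e-17,
        3.22e-17, 4.66e-17, 7.58e-17, 1.09e-16, 1.69e-16, 2.17e-16, 2.80e-16,
        3.42e-16, 4.02e-16, 4.62e-16, 5.60e-16, 6.21e-16, 7.04e-16, 8.49e-16,
        1.09e-15, 1.51e-15, 2.10e-15, 2.44e-15, 2.96e-15, 3.16e-15, 3.36e-15,
        4.40e-15,
    ),
    "brain": (
        2.77e-23, 2.35e-20, 1.73e-18, 7.56e-18, 1.51e-17, 2.31e-17, 3.01e-17,
        3.74e-17, 5.01e-17, 8.15e-17, 1.12e-16, 1.70e-16, 2.27e-16, 2.89e-16,
        3.45e-16, 4.01e-16, 4.58e-16, 5.78e-16, 6.25e-16, 7.40e-16, 8.40e-16,
        1.10e-15, 1.61e-15, 2.05e-15, 2.45e-15, 2.95e-15, 3.29e-15, 3.62e-15,
        4.29e-15,
    ),
    "skeleton": (
        5.12e-23, 3.67e-20, 2.92e-18, 1.31e-17, 2.56e-17, 3.71e-17, 4.69e-17,
        5.61e-17, 7.08e-17, 1.03e-16, 1.31e-16, 1.90e-16, 2.44e-16, 3.03e-16,
        3.62e-16, 4.17e-16, 4.72e-16, 5.96e-16, 6.35e-16, 7.57e-16, 8.42e-16,
        1.09e-15, 1.58e-15, 2.05e-15, 2.44e-15, 2.90e-15, 3.25e-15, 3.60e-15,
        4.23e-15,
    ),
    "total_body": (
        2.61e-23, 1.79e-20, 1.63e-18, 7.77e-18, 1.56e-17, 2.36e-17, 3.09e-17,
        3.79e-17, 5.12e-17, 8.22e-17, 1.12e-16, 1.71e-16, 2.30e-16, 2.91e-16,
        3.49e-16, 4.07e-16, 4.64e-16, 5.83e-16, 6.30e-16, 7.48e-16, 8.47e-16,
        1.11e-15, 1.60e-15, 2.07e-15, 2.47e-15, 2.90e-15, 3.23e-15, 3.57e-15,
        4.32e-15,
    ),
}

# Fetal organ equivalent dose rate coefficients, air submersion
# (Sv s-1 Bq-1 m3), on SUBMERSION_ENERGIES.
SUBMERSION_ORGANS = {
    "skin": (
        8.85e-19, 1.67e-17, 2.09e-16, 5.56e-16, 9.96e-16, 1.48e-15, 1.93e-15,
        2.40e-15, 3.30e-15, 5.41e-15, 7.50e-15, 1.17e-14, 2.03e-14, 2.90e-14,
        4.36e-14, 6.73e-14, 9.40e-14, 1.47e-13, 3.08e-13, 5.14e-13,
    ),
    "eyes": (
        0.00e+00, 1.95e-18, 8.66e-17, 3.22e-16, 6.78e-16, 1.10e-15, 1.52e-15,
        1.98e-15, 2.86e-15, 4.75e-15, 6.58e-15, 1.00e-14, 1.87e-14, 2.69e-14,
        4.08e-14, 5.91e-14, 8.79e-14, 1.51e-13, 3.06e-13, 4.84e-13,
    ),
    "lungs": (
        6.97e-20, 7.59e-18, 1.89e-16, 5.49e-16, 1.01e-15, 1.49e-15, 1.92e-15,
        2.44e-15, 3.35e-15, 5.45e-15, 7.47e-15, 1.19e-14, 2.02e-14, 2.97e-14,
        4.37e-14, 6.62e-14, 9.59e-14, 1.48e-13, 3.02e-13, 5.18e-13,
    ),
    "heart": (
        0.00e+00, 2.88e-18, 1.53e-16, 4.78e-16, 9.49e-16, 1.43e-15, 1.91e-15,
        2.35e-15, 3.24e-15, 5.32e-15, 7.28e-15, 1.17e-14, 1.98e-14, 2.91e-14,
        4.36e-14, 6.61e-14, 9.23e-14, 1.56e-13, 3.21e-13, 5.09e-13,
    ),
    "kidneys": (
        2.63e-19, 1.55e-17, 2.48e-16, 6.62e-16, 1.17e-15, 1.71e-15, 2.11e-15,
        2.64e-15, 3.65e-15, 5.74e-15, 7.96e-15, 1.25e-14, 2.13e-14, 3.10e-14,
        4.45e-14, 6.97e-14, 9.95e-14, 1.54e-13, 3.16e-13, 5.12e-13,
    ),
    "liver": (
        1.75e-19, 1.16e-17, 2.38e-16, 6.37e-16, 1.12e-15, 1.65e-15, 2.10e-15,
        2.62e-15, 3.58e-15, 5.73e-15, 7.83e-15, 1.23e-14, 2.12e-14, 3.06e-14,
        4.51e-14, 6.87e-14, 9.81e-14, 1.52e-13, 3.12e-13, 5.23e-13,
    ),
    "stomach": (
        0.00e+00, 2.10e-18, 1.11e-16, 4.22e-16, 8.13e-16, 1.30e-15, 1.70e-15,
        2.18e-15, 2.93e-15, 5.09e-15, 7.03e-15, 1.17e-14, 2.02e-14, 2.83e-14,
        4.56e-14, 6.57e-14, 8.96e-14, 1.44e-13, 2.93e-13, 4.93e-13,
    ),
    "brain": (
        7.66e-21, 1.52e-18, 8.44e-17, 3.26e-16, 7.03e-16, 1.12e-15, 1.51e-15,
        1.97e-15, 2.78e-15, 4.70e-15, 6.58e-15, 1.05e-14, 1.84e-14, 2.66e-14,
        3.99e-14, 6.15e-14, 8.76e-14, 1.41e-13, 2.99e-13, 5.01e-13,
    ),
    "skeleton": (
        4.77e-20, 5.36e-18, 2.02e-16, 6.79e-16, 1.33e-15, 2.00e-15, 2.64e-15,
        3.25e-15, 4.33e-15, 6.66e-15, 8.75e-15, 1.29e-14, 2.12e-14, 2.95e-14,
        4.28e-14, 6.55e-14, 9.08e-14, 1.44e-13, 3.01e-13, 4.98e-13,
    ),
    "total_body": (
        3.12e-19, 9.39e-18, 1.74e-16, 5.08e-16, 9.49e-16, 1.43e-15, 1.87e-15,
        2.35e-15, 3.25e-15, 5.34e-15, 7.38e-15, 1.16e-14, 2.00e-14, 2.88e-14,
        4.29e-14, 6.66e-14, 9.31e-14, 1.46e-13, 3.07e-13, 5.12e-13,
    ),
}

# Air kerma rate coefficients at 1 m above ground (Gy s-1 Bq-1 m2 for the
# buried plane source, Gy s-1 Bq-1 m3 for submersion).  Each geometry has its
# own printed grid; gaps are not filled.
GROUND_AIR_KERMA = (
    (0.015, 7.29e-19), (0.02, 7.42e-18), (0.03, 2.60e-17), (0.04, 3.51e-17),
    (0.05, 3.94e-17), (0.06, 4.53e-17), (0.07, 5.09e-17), (0.08, 5.78e-17),
    (0.1, 7.41e-17), (0.15, 1.20e-16), (0.2, 1.68e-16), (0.3, 2.62e-16),
    (0.4, 3.51e-16), (0.5, 4.39e-16), (0.6, 5.22e-16), (0.8, 6.78e-16),
    (1.0, 8.26e-16), (1.5, 1.15e-15), (2.0, 1.45e-15), (3.0, 1.98e-15),
    (4.0, 2.47e-15), (5.0, 2.93e-15), (6.0, 3.37e-15), (8.0, 4.19e-15),
    (10.0, 5.07e-15),
)

SUBMERSION_AIR_KERMA = (
    (0.015, 1.47e-15), (0.02, 1.71e-15), (0.03, 2.21e-15), (0.04, 2.40e-15),
    (0.05, 2.81e-15), (0.06, 3.31e-15), (0.07, 3.79e-15), (0.08, 4.36e-15),
    (0.1, 5.55e-15), (0.15, 8.68e-15), (0.2, 1.20e-14), (0.3, 1.87e-14),
    (0.5, 3.21e-14), (0.7, 4.56e-14), (1.0, 6.58e-14), (1.5, 9.80e-14),
    (2.0, 1.32e-13), (3.0, 1.96e-13), (6.0, 3.19e-12), (10.0, 4.81e-12),
)

# Per-nuclide summary coefficients, curated subset of the published nuclide
# table: the fission/activation products discussed in the uterus-surrogate
# comparison plus a few common environmental nuclides.  Columns per geometry:
# (air kerma, detriment-weighted dose of the mother, uterus of the mother,
# fetal total body), ground in Gy|Sv s-1 Bq-1 m2, submersion in m3 units.
NUCLIDE_SUMMARY = {
    #                ground                                           submersion
    "Be-7":    ((4.32e-17, 3.18e-17, 3.05e-17, 2.89e-17), (3.19e-15, 2.20e-15, 2.10e-15, 1.99e-15)),
    "Na-22":   ((1.79e-15, 1.38e-15, 1.33e-15, 1.27e-15), (1.42e-13, 1.02e-13, 9.80e-14, 9.28e-14)),
    "K-40":    ((1.21e-16, 9.68e-17, 9.30e-17, 8.97e-17), (1.03e-14, 7.66e-15, 7.35e-15, 6.99e-15)),
    "Co-60":   ((1.96e-15, 1.55e-15, 1.49e-15, 1.44e-15), (1.64e-13, 1.21e-13, 1.15e-13, 1.10e-13)),
    "Zr-95":   ((6.14e-16, 4.64e-16, 4.45e-16, 4.25e-16), (4.78e-14, 3.38e-14, 3.22e-14, 3.03e-14)),
    "Nb-95":   ((6.37e-16, 4.84e-16, 4.65e-16, 4.44e-16), (5.00e-14, 3.54e-14, 3.38e-14, 3.18e-14)),
    "Ru-103":  ((4.30e-16, 3.16e-16, 3.03e-16, 2.88e-16), (3.19e-14, 2.20e-14, 2.10e-14, 1.98e-14)),
    "Te-132":  ((1.98e-16, 1.31e-16, 1.26e-16, 1.19e-16), (1.45e-14, 8.87e-15, 8.48e-15, 7.93e-15)),
    "I-131":   ((3.31e-16, 2.41e-16, 2.31e-16, 2.19e-16), (2.43e-14, 1.67e-14, 1.59e-14, 1.50e-14)),
    "I-132":   ((1.88e-15, 1.43e-15, 1.37e-15, 1.31e-15), (1.48e-13, 1.05e-13, 1.00e-13, 9.49e-14)),
    "I-133":   ((5.24e-16, 3.90e-16, 3.75e-16, 3.57e-16), (3.96e-14, 2.77e-14, 2.65e-14, 2.50e-14)),
    "Xe-133":  ((3.69e-17, 1.80e-17, 1.75e-17, 1.60e-17), (2.84e-15, 1.20e-15, 1.19e-15, 1.03e-15)),
    "Cs-134":  ((1.31e-15, 9.85e-16, 9.47e-16, 9.03e-16), (1.01e-13, 7.15e-14, 6.82e-14, 6.43e-14)),
    "Cs-136":  ((1.74e-15, 1.33e-15, 1.28e-15, 1.23e-15), (1.39e-13, 9.94e-14, 9.48e-14, 8.98e-14)),
    "Cs-137":  ((2.25e-19, 1.18e-19, 1.15e-19, 1.06e-19), (1.72e-17, 6.32e-18, 6.16e-18, 5.45e-18)),
    "Ba-137m": ((5.11e-16, 3.78e-16, 3.63e-16, 3.46e-16), (3.88e-14, 2.71e-14, 2.59e-14, 2.44e-14)),
    "Ba-140":  ((1.58e-16, 1.13e-16, 1.08e-16, 1.03e-16), (1.16e-14, 7.88e-15, 7.54e-15, 7.07e-15)),
    "La-140":  ((1.78e-15, 1.41e-15, 1.36e-15, 1.31e-15), (1.51e-13, 1.11e-13, 1.07e-13, 1.01e-13)),
}

# Nuclides the uterus-surrogate discussion names for the 1.04-1.06 ground
# range; 95Mo is named there but is stable and has no nuclide-table row, so
# reports simply skip identifiers absent from the input table.
RATIO_DISCUSSION_NUCLIDES = (
    "I-131", "I-132", "I-133", "Cs-134", "Cs-136", "Ba-137m", "Ba-140",
    "Te-132", "La-140", "Zr-95", "Nb-95", "Mo-95", "Ru-103",
)
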