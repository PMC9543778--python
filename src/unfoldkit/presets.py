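"""Published reference values for the titin I27 homopolyprotein study.

These are literature inputs, not package outputs: per-domain contour-length
increment, WLC persistence length, the pulling-speed ladder, and the
Bell-Evans energy-landscape parameters reported for 9x I27 at three bath
temperatures.  They parameterise the synthetic-data generator and serve as
ground truth in parameter-recovery tests.
"""

#: Per-domain contour-length increment of unfolded I27 (nm).
I27_DELTA_LC_NM = 27.7

#: Apparent WLC persistence length used for fitting, the average length of
#: one amino acid (nm).
I27_PERSISTENCE_NM = 0.35

#: Average amino-acid size used for *theoretical* contour-length estimates
#: (kept distinct from the fitting persistence length on purpose).
AMINO_ACID_SIZE_NM = 0.365

#: Number of I27 repeats in the construct.
I27_N_DOMAINS = 9

#: Pulling-speed ladder of the force-extension experiment (nm/s).
PULLING_SPEEDS_NM_S = (400.0, 800.0, 1600.0, 3200.0, 6400.0, 12800.0)

#: Piezo travel per retract curve (nm).
PIEZO_RANGE_NM = 400.0

#: Cantilever spring constant used for analysis (N/m); the cantilevers'
#: nominal value is 0.12 N/m but ~0.06 N/m gives the quoted signal-to-noise.
CANTILEVER_K_NM = 0.06

#: Arrhenius pre-factor assumed for barrier heights (s^-1).
ARRHENIUS_A_S = 1.0e7

#: Reported I27 energy-landscape parameters per bath temperature (K):
#: distance to the transition state Δx (nm), zero-force unfolding rate α0
#: (s^-1), barrier height ΔG (kBT), folded-state spring constant D (N/m),
#: and the mean contour-length increment with its event count.
I27_TEMPERATURE_STUDY = {
    291.15: {
        "delta_x_nm": 0.13,
        "alpha0_s": 1.17,
        "delta_g_kbt": 15.98,
        "spring_d_nm": 7.54,
        "mean_dlc_nm": 27.8,
        "n_events": 1073,
    },
    296.15: {
        "delta_x_nm": 0.15,
        "alpha0_s": 0.34,
        "delta_g_kbt": 17.22,
        "spring_d_nm": 6.08,
        "mean_dlc_nm": 27.8,
        "n_events": 1206,
    },
    310.15: {
        "delta_x_nm": 0.17,
        "alpha0_s": 0.67,
        "delta_g_kbt": 16.55,
        "spring_d_nm": 5.17,
        "mean_dlc_nm": 27.7,
        "n_events": 1615,
    },
}
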