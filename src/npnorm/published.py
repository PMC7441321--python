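"""Published summary statistics of the Cameroonian norming study.

Group-level values transcribed from the study report (subject-level data
are not distributed): per-test case/control T-score means, SDs, Ns and
raw p-values, and impairment counts. These are inputs to the
reproduction analyses — every derived quantity (Cohen's d, odds ratios,
CIs, FDR-adjusted p-values, percentages) is recomputed from them at run
time, never copied.

Keys: 8 test ids plus ``motor_summary`` / ``sip_summary``. Tuples are
(control, case).
"""

# T-score comparisons: n, mean, sd per group and the reported raw p
TSCORE_SUMMARY = {
    "gp_dh":        {"n": (362, 318), "mean": (50.0, 48.1), "sd": (10.0, 10.6), "p": 0.018},
    "gp_ndh":       {"n": (362, 318), "mean": (50.0, 49.0), "sd": (9.99, 10.4), "p": 0.188},
    "motor_summary": {"n": (362, 318), "mean": (50.0, 48.6), "sd": (9.10, 9.74), "p": 0.050},
    "wais_ds":      {"n": (361, 321), "mean": (50.0, 47.6), "sd": (9.98, 9.62), "p": 0.001},
    "wais_ss":      {"n": (355, 319), "mean": (50.0, 49.7), "sd": (9.98, 11.0), "p": 0.745},
    "stroop_color": {"n": (362, 314), "mean": (50.0, 49.0), "sd": (10.0, 11.1), "p": 0.233},
    "stroop_word":  {"n": (361, 311), "mean": (50.0, 48.1), "sd": (9.99, 10.3), "p": 0.014},
    "tmt_a":        {"n": (363, 321), "mean": (50.0, 48.1), "sd": (10.0, 10.6), "p": 0.017},
    "ctt1":         {"n": (364, 321), "mean": (50.0, 48.7), "sd": (10.0, 9.58), "p": 0.084},
    "sip_summary":  {"n": (350, 309), "mean": (50.1, 48.6), "sd": (6.62, 6.95), "p": 0.006},
}

# impairment comparisons: total n and number impaired per group
IMPAIRMENT_SUMMARY = {
    "gp_dh":        {"n": (362, 318), "impaired": (60, 73)},
    "gp_ndh":       {"n": (362, 318), "impaired": (56, 59)},
    "motor_summary": {"n": (362, 318), "impaired": (44, 46)},
    "wais_ds":      {"n": (361, 321), "impaired": (44, 73)},
    "wais_ss":      {"n": (355, 319), "impaired": (45, 52)},
    "stroop_color": {"n": (362, 314), "impaired": (50, 60)},
    "stroop_word":  {"n": (361, 311), "impaired": (49, 58)},
    "tmt_a":        {"n": (363, 321), "impaired": (53, 65)},
    "ctt1":         {"n": (364, 321), "impaired": (56, 56)},
    "sip_summary":  {"n": (350, 309), "impaired": (36, 64)},
}

TEST_ROWS = ("gp_dh", "gp_ndh", "wais_ds", "wais_ss",
             "stroop_color", "stroop_word", "tmt_a", "ctt1")
SUMMARY_ROWS = ("motor_summary", "sip_summary")
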