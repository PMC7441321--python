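"""Canonical test identifiers and domain membership.

Eight timed neuropsychological tests in two domains: complex motor function
(Grooved Pegboard, both hands) and speed of information processing (SIP:
WAIS-III Digit Symbol and Symbol Search, Stroop Color Naming and Word
Reading, Trail Making Test A, Color Trails 1).
"""

# order matches the published tables (motor first, then SIP)
MOTOR_TESTS = ("gp_dh", "gp_ndh")
SIP_TESTS = ("wais_ds", "wais_ss", "stroop_color", "stroop_word", "tmt_a", "ctt1")
TESTS = MOTOR_TESTS + SIP_TESTS

# tests scored as completion time in seconds: lower raw = better performance
TIME_TESTS = frozenset({"gp_dh", "gp_ndh", "tmt_a", "ctt1"})

DOMAINS = {"motor": MOTOR_TESTS, "sip": SIP_TESTS}

TEST_LABELS = {
    "gp_dh": "Grooved Pegboard - dominant hand",
    "gp_ndh": "Grooved Pegboard - non-dominant hand",
    "wais_ds": "WAIS-III Digit Symbol total",
    "wais_ss": "WAIS-III Symbol Search total",
    "stroop_color": "Stroop Color Naming total",
    "stroop_word": "Stroop Word Reading total",
    "tmt_a": "Trail Making Test A time",
    "ctt1": "Color Trails 1 time",
}


def check_test_id(test_id: str) -> str:
    if test_id not in TESTS:
        raise KeyError(
            f"unknown test_id {test_id!r}; expected one of {', '.join(TESTS)}"
        )
    return test_id
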