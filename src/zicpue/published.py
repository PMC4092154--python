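"""Published summary statistics from the Recife longline survey (2004-2011).

The raw survey data were never deposited, but the published study reports
summary statistics that serve two roles here: as worked-example inputs for
the statistical machinery (the correlation screen, the sex-ratio tests)
and as calibration targets for the synthetic survey generator (length and
sex composition, positive-catch rates).

p-values printed as "<0.001" are stored as 5e-4.
"""

from __future__ import annotations

from zicpue.screening import CorrelationResult

__all__ = [
    "CORRELATION_SCREEN_ROWS",
    "SEX_RATIO_REPORTS",
    "LENGTH_SUMMARIES",
    "POSITIVE_CATCH_RATES",
    "N_NEARSHORE_CRUISES",
    "N_SHELF_CRUISES",
]

#: number of cruise-level samples used in the published abundance analysis
N_NEARSHORE_CRUISES = 518  # equally split between the BV and PA sites
N_SHELF_CRUISES = 38  # occasional middle-continental-shelf (CS) sets

_P_LT = 5e-4  # stand-in for "p < 0.001"

# covariate pair, t, df, p, ci_low, ci_high, r, s
_SCREEN = [
    ("temp", "salin", 2.768, 241, 0.006, 0.051, 0.295, 0.176, 0.358),
    ("temp", "visib", 13.333, 332, _P_LT, 0.516, 0.656, 0.591, 0.600),
    ("temp", "tidamp", 0.230, 452, 0.818, -0.081, 0.103, 0.011, 0.016),
    ("temp", "pluvio", -4.104, 408, _P_LT, -0.290, -0.104, -0.199, -0.203),
    ("temp", "windspe", -0.432, 418, 0.666, -0.117, 0.075, -0.022, -0.034),
    ("temp", "winddir", -4.267, 418, _P_LT, -0.294, -0.111, -0.204, -0.191),
    ("temp", "solarrad", 4.038, 349, _P_LT, 0.109, 0.309, 0.211, 0.242),
    ("salin", "visib", 0.162, 223, 0.872, -0.120, 0.141, 0.011, 0.198),
    ("salin", "tidamp", 0.836, 241, 0.403, -0.073, 0.178, 0.054, 0.036),
    ("salin", "pluvio", -2.991, 226, 0.003, -0.317, -0.067, -0.195, -0.211),
    ("salin", "windspe", 2.569, 228, 0.011, 0.039, 0.291, 0.168, 0.206),
    ("salin", "winddir", -0.404, 228, 0.687, -0.156, 0.103, -0.027, -0.078),
    ("salin", "solarrad", 2.812, 202, 0.005, 0.058, 0.323, 0.194, 0.151),
    ("visib", "tidamp", -0.131, 376, 0.896, -0.108, 0.094, -0.007, 0.009),
    ("visib", "pluvio", -3.404, 336, _P_LT, -0.284, -0.077, -0.183, -0.172),
    ("visib", "windspe", -11.54, 342, _P_LT, -0.601, -0.449, -0.529, -0.520),
    ("visib", "winddir", -6.007, 342, _P_LT, -0.402, -0.210, -0.309, -0.319),
    ("visib", "solarrad", 1.984, 279, 0.048, 0.001, 0.232, 0.118, 0.113),
    ("pluvio", "windspe", -0.464, 462, 0.643, -0.112, 0.070, -0.022, -0.154),
    ("pluvio", "winddir", 7.820, 462, _P_LT, 0.259, 0.420, 0.342, 0.353),
    ("windspe", "winddir", 8.698, 472, _P_LT, 0.291, 0.447, 0.372, 0.187),
    ("winddir", "solarrad", -5.321, 397, _P_LT, -0.347, -0.164, -0.258, -0.288),
    ("tidamp", "lunday", -5.711, 516, _P_LT, -0.323, -0.161, -0.244, -0.229),
]

#: the published covariate correlation screen as CorrelationResult inputs
#: (n recovered from df = n - 2)
CORRELATION_SCREEN_ROWS: list[CorrelationResult] = [
    CorrelationResult(
        pair=(a, b),
        n=df + 2,
        r=r,
        t_stat=t,
        df=df,
        p=p,
        ci_low=lo,
        ci_high=hi,
        s=s,
    )
    for (a, b, t, df, p, lo, hi, r, s) in _SCREEN
]

#: reported male:female ratios with the number of sexed individuals;
#: the tiger shark row (0.69:1 of 56) admits no integer split that rounds
#: back to the printed ratio, so it is excluded from worked examples
SEX_RATIO_REPORTS = {
    "carcharhinus acronotus": {"ratio": 0.77, "n_sexed": 122},
    "ginglymostoma cirratum": {"ratio": 0.78, "n_sexed": 116},
}

#: reported total-length composition (cm) of the three abundant species:
#: n caught, min, max, mean, sd
LENGTH_SUMMARIES = {
    "ginglymostoma cirratum": {"n": 149, "min": 92.0, "max": 300.0,
                               "mean": 189.0, "sd": 43.5},
    "carcharhinus acronotus": {"n": 125, "min": 39.0, "max": 180.0,
                               "mean": 111.8, "sd": 16.1},
    "galeocerdo cuvier": {"n": 56, "min": 82.0, "max": 355.0,
                          "mean": 158.2, "sd": 58.4},
}

#: reported fraction of cruises with at least one capture
POSITIVE_CATCH_RATES = {
    "ginglymostoma cirratum": 0.16,
    "carcharhinus acronotus": 0.09,
    "galeocerdo cuvier": 0.06,
}
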