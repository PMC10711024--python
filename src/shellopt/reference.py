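"""Published reference values for the green-coconut-shell UAE study.

These constants are transcribed from the published report of the
ultrasound-assisted extraction (UAE) optimization study this package
reimplements: the factor ranges of the Box-Behnken design, the five fitted
coded-factor quadratic surfaces with their residual standard deviations,
the weight and bias matrices of the selected 3-4-5 feed-forward network,
and the experimental-vs-predicted response values at the reported ANN-PSO
optimum. They are ground truth for synthetic-data generation and fixtures
for contract tests — they are never substituted for a user's own fit.
"""

from __future__ import annotations

import numpy as np

from .design import FactorSpec, RESPONSE_COLUMNS
from .rsm import QuadraticSurface

__all__ = [
    "FACTORS",
    "SURFACE_COEFFICIENTS",
    "RESIDUAL_SD",
    "published_surfaces",
    "published_ann_parameters",
    "OPTIMUM_NATURAL",
    "OPTIMUM_PREDICTED",
    "OPTIMUM_EXPERIMENTAL",
    "OPTIMUM_PERCENT_ERROR",
]

#: The three UAE process factors: sonication time (A), bath temperature (B)
#: and the denominator X of the 1:X g/ml solid-solvent ratio (C).
FACTORS = (
    FactorSpec("time_min", 10.0, 30.0, "min"),
    FactorSpec("temp_C", 30.0, 40.0, "degC"),
    FactorSpec("ratio", 10.0, 30.0, "ml solvent per g solid"),
)

#: Published coded-factor quadratic coefficients per response, in term order
#: Intercept, A, B, C, AB, AC, BC, A^2, B^2, C^2.
SURFACE_COEFFICIENTS: dict[str, tuple[float, ...]] = {
    "yield_pct": (
        26.4683, -3.22, -0.3175, 2.9475,
        1.855, 0.04, 3.995,
        -0.504167, -1.41917, 3.65083,
    ),
    "phenols_gae": (
        18.0467, -4.01575, -1.08575, 2.3025,
        5.399, -0.5325, 6.7475,
        0.786167, -3.94883, 7.70967,
    ),
    "flavonoids_qe": (
        13.0433, -3.9825, -1.0775, 2.365,
        5.39, -0.53, 6.825,
        0.770833, -3.94917, 7.77083,
    ),
    "tannins_tae": (
        122.83, -8.27, -1.47, 3.0325,
        17.175, -1.945, 14.075,
        -6.84, -20.915, 12.86,
    ),
    "antioxidant_pct": (
        56.4683, -3.245, -0.2625, 2.9425,
        1.805, 0.04, 4.005,
        -0.449167, -1.52417, 3.59583,
    ),
}

#: Published residual standard deviations of the five quadratic fits, used
#: as the noise SDs of the synthetic-data generator.
RESIDUAL_SD: dict[str, float] = {
    "yield_pct": 0.33,
    "phenols_gae": 0.54,
    "flavonoids_qe": 0.55,
    "tannins_tae": 1.21,
    "antioxidant_pct": 0.31,
}

assert tuple(SURFACE_COEFFICIENTS) == RESPONSE_COLUMNS
assert tuple(RESIDUAL_SD) == RESPONSE_COLUMNS


def published_surfaces() -> dict[str, QuadraticSurface]:
    """The five published quadratic surfaces, keyed by response column."""
    return {
        name: QuadraticSurface.from_coefficients(name, coef, FACTORS)
        for name, coef in SURFACE_COEFFICIENTS.items()
    }


# --- selected 3-4-5 network parameters --------------------------------------
# Row-major convention: W_IH rows are hidden neurons (columns: the 3 inputs),
# W_HO rows are output neurons (columns: the 4 hidden neurons).

W_IH = np.array(
    [
        [-7.2336, -1.0604, 4.7262],
        [0.43575, 2.5957, -2.4158],
        [20.2502, -9.4265, -2.8229],
        [-3.3886, -4.7606, 4.7377],
    ]
)

T_H = np.array([4.4098, -0.8568, 12.2379, 0.92758])

W_HO = np.array(
    [
        [2.4338, -19.482, -2.9182, -21.2476],
        [6.1667, -42.6406, -5.3154, -48.1334],
        [6.1947, -42.9296, -5.3605, -48.4433],
        [9.3231, -51.6052, -5.0571, -60.2125],
        [2.5763, -20.0191, -2.9495, -21.9176],
    ]
)

T_O = np.array([2.2397, 14.4757, 4.5168, 4.3392, 2.2433])


def published_ann_parameters():
    """The published weight/bias set of the selected 3-4-5 network.

    The original report does not state the input/output normalization used
    at training time, so these parameters support forward-pass contract
    checks, not prediction in natural units.
    """
    from .ann import AnnParameters

    return AnnParameters(
        W_ih=W_IH.copy(), B_h=T_H.copy(), W_ho=W_HO.copy(), B_o=T_O.copy()
    )


# --- reported ANN-PSO optimum and its experimental validation ----------------

#: Reported optimum process point: 15 min, 33 degC, 1:24 solid-solvent ratio.
OPTIMUM_NATURAL = np.array([15.0, 33.0, 24.0])

#: Model-predicted responses at the optimum (yield %, phenols, flavonoids,
#: tannins, antioxidant %), and the confirmatory experimental values.
OPTIMUM_PREDICTED = np.array([38.41, 40.99, 36.13, 176.73, 68.39])
OPTIMUM_EXPERIMENTAL = np.array([39.32, 41.12, 37.00, 177.32, 69.55])

#: Published percent-error row (two-decimal rounding, experimental
#: value in the denominator).
OPTIMUM_PERCENT_ERROR = np.array([2.31, 0.32, 2.35, 0.33, 1.67])
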