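"""Synthetic BBD experiments with the statistical structure the analysis assumes.

The raw 18-run response table of the original extraction study was never
deposited, so synthetic datasets stand in for it: responses are the
published coded quadratic surfaces evaluated at each design point, plus
independent homoscedastic Gaussian noise whose per-response SD equals the
published residual SD of the corresponding fit (yield 0.33, phenols 0.54,
flavonoids 0.55, tannins 1.21, antioxidant 0.31). This is the minimal noise
model consistent with the reported pure-error/lack-of-fit ANOVA;
cross-response noise correlation (plausible, since all assays share the
same extracts) is deliberately omitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace
from typing import Optional

import numpy as np
import pandas as pd

from . import reference
from .design import DesignTable, RESPONSE_COLUMNS, make_bbd
from .rsm import QuadraticSurface

__all__ = [
    "GroundTruth",
    "SyntheticDataset",
    "simulate_bbd_experiment",
    "sample_surface_dataset",
    "fixtures",
]


@dataclass
class GroundTruth:
    """Five reference quadratic surfaces plus per-response noise SDs."""

    surfaces: dict[str, QuadraticSurface]
    noise_sd: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.surfaces) != set(self.noise_sd):
            raise ValueError("surfaces and noise SDs must cover the same responses")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be > 0")

    @classmethod
    def published(cls) -> "GroundTruth":
        return cls(
            surfaces=reference.published_surfaces(),
            noise_sd=dict(reference.RESIDUAL_SD),
        )

    @property
    def response_names(self) -> tuple[str, ...]:
        return tuple(n for n in RESPONSE_COLUMNS if n in self.surfaces)


@dataclass
class SyntheticDataset:
    """A simulated design-plus-responses table with its generation metadata.

    Re-running :func:`simulate_bbd_experiment` with the stored metadata
    reproduces the dataset exactly.
    """

    design: DesignTable
    metadata: dict

    @property
    def frame(self) -> pd.DataFrame:
        return self.design.frame


def simulate_bbd_experiment(
    ground_truth: Optional[GroundTruth] = None,
    center_reps: int = 6,
    noise_scale: float = 1.0,
    seed: Optional[int] = None,
) -> SyntheticDataset:
    """Simulate one BBD extraction experiment from the reference surfaces.

    Each response column is the corresponding surface evaluated at the coded
    design points plus independent N(0, (noise_scale * sd)^2) noise. With
    ``noise_scale=0`` the responses are exact surface values.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    gt = ground_truth or GroundTruth.published()
    design = make_bbd(reference.FACTORS, center_reps=center_reps)
    coded = design.coded()
    rng = np.random.default_rng(seed)
    responses = {}
    for name in gt.response_names:
        mean = gt.surfaces[name].evaluate(coded)
        noise = rng.normal(0.0, gt.noise_sd[name] * noise_scale, size=len(coded))
        responses[name] = mean + noise
    dataset = design.with_responses(responses)
    return SyntheticDataset(
        design=dataset,
        metadata={
            "seed": seed,
            "center_reps": center_reps,
            "noise_scale": noise_scale,
            "noise_sd": dict(gt.noise_sd),
            "responses": list(gt.response_names),
        },
    )


def sample_surface_dataset(
    n: int,
    ground_truth: Optional[GroundTruth] = None,
    noise_scale: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Random off-design factor settings with surface-valued responses.

    Draws ``n`` points uniformly in the natural factor box — useful for
    surrogate-capacity checks that need denser coverage than the 18-run
    design provides.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gt = ground_truth or GroundTruth.published()
    rng = np.random.default_rng(seed)
    lo = np.array([f.low for f in reference.FACTORS])
    hi = np.array([f.high for f in reference.FACTORS])
    X = rng.uniform(lo, hi, size=(n, 3))
    frame = pd.DataFrame(X, columns=[f.name for f in reference.FACTORS])
    for name in gt.response_names:
        mean = gt.surfaces[name].evaluate_natural(X)
        noise = rng.normal(0.0, gt.noise_sd[name] * noise_scale, size=n)
        frame[name] = mean + noise
    return frame


def fixtures() -> SimpleNamespace:
    """Bundle of all transcribed reference constants.

    Returns factor specs, the reference ground-truth surfaces and noise SDs,
    the published 3-4-5 network parameters, and the reported optimum with
    its predicted/experimental response vectors and percent-error row.
    """
    return SimpleNamespace(
        factors=reference.FACTORS,
        ground_truth=GroundTruth.published(),
        ann_params=reference.published_ann_parameters(),
        optimum_natural=reference.OPTIMUM_NATURAL.copy(),
        optimum_predicted=reference.OPTIMUM_PREDICTED.copy(),
        optimum_experimental=reference.OPTIMUM_EXPERIMENTAL.copy(),
        optimum_percent_error=reference.OPTIMUM_PERCENT_ERROR.copy(),
        response_names=RESPONSE_COLUMNS,
    )
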