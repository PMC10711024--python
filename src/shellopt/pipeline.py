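"""Hybrid surrogate-PSO process optimization and validation reporting.

The fitness maximized by the swarm is a weighted sum of min-max-normalized
predicted responses,

    fitness(x) = sum_r  w_r * (yhat_r(x) - lo_r) / (hi_r - lo_r),

evaluated over the natural-unit factor box. The prediction model can be a
trained network surrogate or a set of quadratic surfaces. Validation
against confirmatory experiments uses the percent error
100 * |experimental - predicted| / |experimental|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .ann import SurrogateCommittee, TrainedSurrogate
from .design import FactorSpec
from .pso import PsoConfig, SwarmResult, optimize
from .rsm import QuadraticSurface

__all__ = [
    "FitnessSpec",
    "OptimizationReport",
    "make_fitness",
    "optimize_process",
    "percent_error",
    "validate_report",
]

Model = Union[TrainedSurrogate, SurrogateCommittee, Sequence[QuadraticSurface]]


def _predictor(model: Model):
    """(n, 3) natural inputs -> (n, R) predicted responses, plus names."""
    if hasattr(model, "predict") and hasattr(model, "output_names"):
        return model.predict, tuple(model.output_names)
    surfaces = list(model)
    if not surfaces or not all(isinstance(s, QuadraticSurface) for s in surfaces):
        raise TypeError("model must be a TrainedSurrogate or quadratic surfaces")
    names = tuple(s.response_name for s in surfaces)

    def predict(X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([s.evaluate_natural(X) for s in surfaces])

    return predict, names


@dataclass(frozen=True)
class FitnessSpec:
    """Weights and normalization ranges for the composite fitness.

    ``ranges`` is (R, 2) of per-response (lo, hi) used for min-max
    normalization, typically the observed response ranges of the training
    data. All responses are maximized; weights default to 1 each.
    """

    ranges: tuple
    weights: Optional[tuple] = None

    def __post_init__(self) -> None:
        r = self.ranges_array()
        if r.ndim != 2 or r.shape[1] != 2:
            raise ValueError("ranges must be (R, 2)")
        if not np.all(r[:, 1] > r[:, 0]):
            raise ValueError("degenerate normalization range")
        w = self.weights_array()
        if w.shape != (len(r),):
            raise ValueError("weights length must match ranges")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 and not all zero")

    def ranges_array(self) -> np.ndarray:
        return np.asarray(self.ranges, dtype=float)

    def weights_array(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(len(self.ranges_array()))
        return np.asarray(self.weights, dtype=float)

    @classmethod
    def from_responses(cls, responses: np.ndarray, weights=None) -> "FitnessSpec":
        """Normalization ranges from observed response columns (n, R)."""
        responses = np.asarray(responses, dtype=float)
        ranges = tuple(
            (float(c.min()), float(c.max())) for c in responses.T
        )
        return cls(ranges=ranges, weights=tuple(weights) if weights is not None else None)


def make_fitness(model: Model, spec: FitnessSpec):
    """Compose model predictions into a batched PSO objective."""
    predict, names = _predictor(model)
    ranges = spec.ranges_array()
    weights = spec.weights_array()
    if len(ranges) != len(names):
        raise ValueError(
            f"fitness spec covers {len(ranges)} responses, model predicts {len(names)}"
        )
    lo, span = ranges[:, 0], ranges[:, 1] - ranges[:, 0]

    def objective(X: np.ndarray) -> np.ndarray:
        P = predict(np.atleast_2d(X))
        return ((P - lo) / span) @ weights

    return objective


@dataclass
class OptimizationReport:
    """Natural-unit optimum with predicted (and optionally measured) responses."""

    optimum: np.ndarray
    predicted: np.ndarray
    response_names: tuple[str, ...]
    fitness: float
    experimental: Optional[np.ndarray] = None
    percent_errors: Optional[np.ndarray] = None
    pso_config: dict = field(default_factory=dict)
    fitness_spec: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "optimum": np.asarray(self.optimum, float).tolist(),
            "predicted": np.asarray(self.predicted, float).tolist(),
            "response_names": list(self.response_names),
            "fitness": float(self.fitness),
            "pso_config": self.pso_config,
            "fitness_spec": self.fitness_spec,
        }
        if self.experimental is not None:
            d["experimental"] = np.asarray(self.experimental, float).tolist()
        if self.percent_errors is not None:
            d["percent_errors"] = np.asarray(self.percent_errors, float).tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        """Human-readable table; optimum rounded to whole natural units."""
        lines = [
            "Optimum process conditions (time min, temp degC, ratio): "
            + ", ".join(f"{v:.0f}" for v in self.optimum),
            f"{'response':>16} {'predicted':>10}"
            + (f" {'experimental':>13} {'% error':>8}" if self.experimental is not None else ""),
        ]
        for i, name in enumerate(self.response_names):
            row = f"{name:>16} {self.predicted[i]:>10.2f}"
            if self.experimental is not None:
                row += f" {self.experimental[i]:>13.2f} {self.percent_errors[i]:>8.2f}"
            lines.append(row)
        return "\n".join(lines)


def optimize_process(
    model: Model,
    fitness_spec: FitnessSpec,
    pso_config: Optional[PsoConfig] = None,
    factors: Optional[Sequence[FactorSpec]] = None,
    bounds: Optional[Sequence[tuple[float, float]]] = None,
) -> OptimizationReport:
    """Maximize the composite fitness of a model over the factor box.

    Bounds come from ``pso_config`` if given; otherwise from ``bounds`` or
    ``factors``; otherwise, for a network surrogate, from its input scaler
    range. Fully degenerate point bounds short-circuit the swarm: the
    report is the model evaluated at that point.
    """
    predict, names = _predictor(model)
    if pso_config is None:
        if bounds is not None:
            bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
        elif factors is not None:
            bounds = tuple((f.low, f.high) for f in factors)
        elif isinstance(model, (TrainedSurrogate, SurrogateCommittee)):
            bounds = tuple(zip(model.x_scaler.lo, model.x_scaler.hi))
        elif isinstance(model, Sequence) and model[0].factors is not None:
            bounds = tuple((f.low, f.high) for f in model[0].factors)
        else:
            raise ValueError("no bounds available: pass pso_config or factors")
        b = np.asarray(bounds, dtype=float)
        if np.all(b[:, 0] == b[:, 1]):
            point = b[:, 0]
            objective = make_fitness(model, fitness_spec)
            return OptimizationReport(
                optimum=point,
                predicted=predict(point[None, :])[0],
                response_names=names,
                fitness=float(objective(point[None, :])[0]),
                pso_config={"bounds": b.tolist(), "note": "degenerate point bounds"},
                fitness_spec={
                    "ranges": fitness_spec.ranges_array().tolist(),
                    "weights": fitness_spec.weights_array().tolist(),
                },
            )
        pso_config = PsoConfig(bounds=bounds)

    objective = make_fitness(model, fitness_spec)
    result: SwarmResult = optimize(objective, pso_config)
    predicted = predict(result.best_position[None, :])[0]
    return OptimizationReport(
        optimum=result.best_position,
        predicted=predicted,
        response_names=names,
        fitness=result.best_fitness,
        pso_config=result.config,
        fitness_spec={
            "ranges": fitness_spec.ranges_array().tolist(),
            "weights": fitness_spec.weights_array().tolist(),
        },
    )


def percent_error(experimental: float, predicted: float) -> float:
    """Absolute percent deviation, with the experimental value as denominator."""
    if experimental == 0:
        raise ZeroDivisionError("percent error undefined for experimental value 0")
    return 100.0 * abs(experimental - predicted) / abs(experimental)


def validate_report(
    report: OptimizationReport, experimental: Sequence[float]
) -> OptimizationReport:
    """Attach confirmatory experimental values and per-response % errors."""
    experimental = np.asarray(experimental, dtype=float)
    if experimental.shape != (len(report.response_names),):
        raise ValueError(
            f"expected {len(report.response_names)} experimental values, "
            f"got shape {experimental.shape}"
        )
    errors = np.array(
        [percent_error(e, p) for e, p in zip(experimental, report.predicted)]
    )
    return replace(report, experimental=experimental, percent_errors=errors)
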