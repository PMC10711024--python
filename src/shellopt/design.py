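"""Three-factor Box-Behnken designs and natural/coded factor conversion.

A Box-Behnken design (BBD) for three factors consists of the 12 edge
midpoints of the factor cube — every (+/-1, +/-1) combination over each of
the three factor pairs with the remaining factor held at its center — plus
replicated center points. Replicating the center is what provides the
pure-error degrees of freedom needed to test lack of fit of a second-order
model.

Factors are handled in two unit systems: *natural* units (minutes, degrees
Celsius, the denominator of a 1:X solid-solvent ratio, ...) and *coded*
units, the affine rescaling of each factor to [-1, +1] about the design
center. Second-order response-surface models are always fit on the coded
scale, where the BBD basis is near-orthogonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "RESPONSE_COLUMNS",
    "CODED_COLUMNS",
    "make_bbd",
    "code_point",
    "decode_point",
]

#: Canonical response column names, in fixed order: extraction yield (%),
#: total phenolics (mg GAE/g), total flavonoids (mg QE/g), total tannins
#: (mg TAE/g), DPPH antioxidant activity (%).
RESPONSE_COLUMNS = (
    "yield_pct",
    "phenols_gae",
    "flavonoids_qe",
    "tannins_tae",
    "antioxidant_pct",
)

#: Coded factor columns; A, B, C label the three factors in design order.
CODED_COLUMNS = ("coded_A", "coded_B", "coded_C")


@dataclass(frozen=True)
class FactorSpec:
    """One process factor with its natural-unit range.

    The coded transform maps ``low -> -1``, ``center -> 0``, ``high -> +1``.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError(f"factor {self.name!r}: bounds must be finite")
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, natural):
        """Natural -> coded units (vectorized)."""
        return (np.asarray(natural, dtype=float) - self.center) / self.half_range

    def decode(self, coded):
        """Coded -> natural units (vectorized)."""
        return self.center + np.asarray(coded, dtype=float) * self.half_range


def _check_factors(factors: Sequence[FactorSpec]) -> tuple[FactorSpec, ...]:
    factors = tuple(factors)
    if len(factors) != 3:
        raise ValueError(f"expected exactly 3 factors, got {len(factors)}")
    return factors


def code_point(factors: Sequence[FactorSpec], natural) -> np.ndarray:
    """Convert a natural-unit factor triple (or (n, 3) array) to coded units.

    Values outside the [low, high] box are allowed (extrapolation) but a
    warning is raised when they exceed the box by more than one half-range.
    """
    factors = _check_factors(factors)
    x = np.asarray(natural, dtype=float)
    if x.shape[-1] != 3:
        raise ValueError(f"expected factor triples, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite natural factor value")
    coded = np.stack([f.code(x[..., i]) for i, f in enumerate(factors)], axis=-1)
    if np.any(np.abs(coded) > 2.0):
        warnings.warn(
            "natural point lies more than one half-range outside the design box",
            stacklevel=2,
        )
    elif np.any(np.abs(coded) > 1.0 + 1e-12):
        warnings.warn("natural point lies outside the design box", stacklevel=2)
    return coded


def decode_point(factors: Sequence[FactorSpec], coded) -> np.ndarray:
    """Convert a coded factor triple (or (n, 3) array) back to natural units."""
    factors = _check_factors(factors)
    z = np.asarray(coded, dtype=float)
    if z.shape[-1] != 3:
        raise ValueError(f"expected factor triples, got shape {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite coded factor value")
    return np.stack([f.decode(z[..., i]) for i, f in enumerate(factors)], axis=-1)


@dataclass
class DesignTable:
    """A BBD run matrix with coded and natural columns and optional responses.

    The underlying :class:`pandas.DataFrame` carries ``run_id``, the three
    natural-unit factor columns (named after the factors), ``coded_A/B/C``
    and any response columns present.
    """

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.factors = _check_factors(self.factors)
        for col in ("run_id", *self.natural_columns, *CODED_COLUMNS):
            if col not in self.frame.columns:
                raise ValueError(f"design frame missing column {col!r}")
        coded = self.coded()
        natural = self.natural()
        if not np.allclose(natural, decode_point(self.factors, coded), atol=1e-9):
            raise ValueError("natural and coded columns are inconsistent")

    @property
    def natural_columns(self) -> tuple[str, str, str]:
        return tuple(f.name for f in self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    def coded(self) -> np.ndarray:
        """(n, 3) coded design matrix."""
        return self.frame.loc[:, list(CODED_COLUMNS)].to_numpy(dtype=float)

    def natural(self) -> np.ndarray:
        """(n, 3) natural-unit design matrix."""
        return self.frame.loc[:, list(self.natural_columns)].to_numpy(dtype=float)

    @property
    def response_columns(self) -> tuple[str, ...]:
        return tuple(c for c in RESPONSE_COLUMNS if c in self.frame.columns)

    def response(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise KeyError(f"design has no response column {name!r}")
        y = self.frame[name].to_numpy(dtype=float)
        return y

    def with_responses(self, responses: pd.DataFrame | dict) -> "DesignTable":
        """Return a copy with response columns attached (index-aligned order)."""
        frame = self.frame.copy()
        items = responses.items() if isinstance(responses, dict) else responses.to_dict("series").items()
        for name, values in items:
            values = np.asarray(values, dtype=float)
            if len(values) != len(frame):
                raise ValueError(f"response {name!r}: expected {len(frame)} values")
            frame[name] = values
        return DesignTable(self.factors, frame)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, factors: Sequence[FactorSpec]) -> "DesignTable":
        frame = pd.read_csv(path)
        return cls(tuple(factors), frame)


def make_bbd(
    factors: Sequence[FactorSpec],
    center_reps: int = 6,
    shuffle_seed: int | None = None,
) -> DesignTable:
    """Generate the standard three-factor Box-Behnken design.

    Parameters
    ----------
    factors
        Exactly three :class:`FactorSpec`.
    center_reps
        Number of replicated center runs appended after the 12 edge runs.
        The default of 6 gives the 18-run layout used for this extraction
        study (12 + 6), leaving 8 residual degrees of freedom for a
        10-coefficient quadratic model.
    shuffle_seed
        If given, the run order is randomly permuted with this seed;
        otherwise runs appear in deterministic standard order (edge runs in
        factor-pair order, center replicates last). ``run_id`` always labels
        the standard-order run.
    """
    factors = _check_factors(factors)
    if center_reps < 1:
        raise ValueError("center_reps must be >= 1")

    rows = []
    for i, j in combinations(range(3), 2):
        for si in (-1.0, 1.0):
            for sj in (-1.0, 1.0):
                point = [0.0, 0.0, 0.0]
                point[i] = si
                point[j] = sj
                rows.append(point)
    rows.extend([[0.0, 0.0, 0.0]] * center_reps)
    coded = np.asarray(rows)
    natural = decode_point(factors, coded)

    frame = pd.DataFrame({"run_id": np.arange(1, len(coded) + 1)})
    for k, f in enumerate(factors):
        frame[f.name] = natural[:, k]
    for k, col in enumerate(CODED_COLUMNS):
        frame[col] = coded[:, k]

    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(frame))
        frame = frame.iloc[order].reset_index(drop=True)

    return DesignTable(factors, frame)
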