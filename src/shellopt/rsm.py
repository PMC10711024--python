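"""Second-order response-surface models on coded factors, with ANOVA.

The model for one response is the full 10-term quadratic in the coded
factors A, B, C:

    y = b0 + b1*A + b2*B + b3*C + b12*A*B + b13*A*C + b23*B*C
        + b11*A^2 + b22*B^2 + b33*C^2 + e

fit by ordinary least squares. The accompanying ANOVA decomposes the
corrected total sum of squares into nine single-degree-of-freedom model
terms (sequential sums of squares, which coincide with partial sums of
squares on the near-orthogonal BBD basis), lack of fit, and pure error from
replicated design points. Fit-quality summaries follow the conventional
response-surface definitions: CV% = 100 * residual SD / mean response and
predicted R^2 = 1 - PRESS / SS_total with PRESS the leave-one-out squared
prediction error sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .design import DesignTable, FactorSpec, code_point

__all__ = [
    "TERM_NAMES",
    "QuadraticSurface",
    "AnovaReport",
    "quadratic_basis",
    "fit_quadratic",
    "evaluate_surface",
    "anova",
]

#: Model terms in fixed column order (intercept first).
TERM_NAMES = ("Intercept", "A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2")


def quadratic_basis(coded) -> np.ndarray:
    """Expand coded points (n, 3) into the 10-column quadratic basis."""
    z = np.atleast_2d(np.asarray(coded, dtype=float))
    if z.shape[1] != 3:
        raise ValueError(f"expected coded triples, got shape {z.shape}")
    a, b, c = z[:, 0], z[:, 1], z[:, 2]
    return np.column_stack(
        [np.ones_like(a), a, b, c, a * b, a * c, b * c, a * a, b * b, c * c]
    )


@dataclass
class QuadraticSurface:
    """A fitted (or transcribed) coded-factor quadratic model for one response.

    ``linear`` holds (A, B, C), ``interaction`` holds (AB, AC, BC) and
    ``quadratic`` holds (A^2, B^2, C^2) coefficients. ``factors`` optionally
    records the coding so the surface can be evaluated in natural units.
    """

    response_name: str
    intercept: float
    linear: np.ndarray
    interaction: np.ndarray
    quadratic: np.ndarray
    factors: Optional[tuple[FactorSpec, FactorSpec, FactorSpec]] = None

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.interaction = np.asarray(self.interaction, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        for name, arr in (
            ("linear", self.linear),
            ("interaction", self.interaction),
            ("quadratic", self.quadratic),
        ):
            if arr.shape != (3,):
                raise ValueError(f"{name} coefficients must have shape (3,)")
        if not np.isfinite(self.coefficients()).all():
            raise ValueError("non-finite surface coefficient")

    @classmethod
    def from_coefficients(
        cls,
        response_name: str,
        coef: Sequence[float],
        factors: Optional[Sequence[FactorSpec]] = None,
    ) -> "QuadraticSurface":
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (10,):
            raise ValueError("expected 10 coefficients")
        return cls(
            response_name=response_name,
            intercept=float(coef[0]),
            linear=coef[1:4],
            interaction=coef[4:7],
            quadratic=coef[7:10],
            factors=tuple(factors) if factors is not None else None,
        )

    def coefficients(self) -> np.ndarray:
        """All 10 coefficients in :data:`TERM_NAMES` order."""
        return np.concatenate(
            [[self.intercept], self.linear, self.interaction, self.quadratic]
        )

    def evaluate(self, coded) -> np.ndarray | float:
        """Predicted response at coded point(s); scalar for a single triple."""
        z = np.asarray(coded, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite coded value")
        out = quadratic_basis(z) @ self.coefficients()
        return float(out[0]) if z.ndim == 1 else out

    def evaluate_natural(self, natural) -> np.ndarray | float:
        """Predicted response at natural-unit point(s); requires ``factors``."""
        if self.factors is None:
            raise ValueError("surface carries no factor coding")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # extrapolation is the caller's call
            coded = code_point(self.factors, natural)
        return self.evaluate(coded)

    __call__ = evaluate

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "response_name": self.response_name,
            "coefficients": {
                name: float(v)
                for name, v in zip(TERM_NAMES, self.coefficients())
            },
        }
        if self.factors is not None:
            d["factors"] = [
                {"name": f.name, "low": f.low, "high": f.high, "units": f.units}
                for f in self.factors
            ]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticSurface":
        coef = [d["coefficients"][name] for name in TERM_NAMES]
        factors = None
        if "factors" in d:
            factors = tuple(FactorSpec(**f) for f in d["factors"])
        return cls.from_coefficients(d["response_name"], coef, factors)

    @classmethod
    def from_json(cls, path: str | Path) -> "QuadraticSurface":
        return cls.from_dict(json.loads(Path(path).read_text()))


def evaluate_surface(surface: QuadraticSurface, coded):
    """Functional alias for :meth:`QuadraticSurface.evaluate`."""
    return surface.evaluate(coded)


def fit_quadratic(design: DesignTable, response_name: str) -> QuadraticSurface:
    """Ordinary least squares fit of the full quadratic to one response."""
    y = design.response(response_name)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"response {response_name!r} contains non-finite values")
    X = quadratic_basis(design.coded())
    if len(y) < X.shape[1]:
        raise ValueError(
            f"need >= {X.shape[1]} runs to fit a quadratic, got {len(y)}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design is rank-deficient for the quadratic basis")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return QuadraticSurface.from_coefficients(response_name, coef, design.factors)


@dataclass
class AnovaReport:
    """ANOVA and fit-quality statistics for one quadratic surface fit.

    Lack-of-fit fields are ``None`` when the design has no replicated points
    (pure error is then undefined, not zero).
    """

    response_name: str
    n_runs: int
    df_model: int
    df_residual: int
    df_lack_of_fit: Optional[int]
    df_pure_error: Optional[int]
    ss_model: float
    ss_residual: float
    ss_total: float
    term_ss: dict = field(default_factory=dict)
    term_F: dict = field(default_factory=dict)
    model_F: float = np.nan
    lack_of_fit_F: Optional[float] = None
    pure_error_MS: Optional[float] = None
    residual_SD: float = np.nan
    response_mean: float = np.nan
    CV_percent: float = np.nan
    R2: float = np.nan
    adj_R2: float = np.nan
    pred_R2: float = np.nan
    PRESS: float = np.nan

    def to_dict(self) -> dict:
        def opt(v):
            return None if v is None else float(v)

        return {
            "response_name": self.response_name,
            "n_runs": self.n_runs,
            "df": {
                "model": self.df_model,
                "residual": self.df_residual,
                "lack_of_fit": self.df_lack_of_fit,
                "pure_error": self.df_pure_error,
            },
            "ss": {
                "model": float(self.ss_model),
                "residual": float(self.ss_residual),
                "total": float(self.ss_total),
            },
            "term_ss": {k: float(v) for k, v in self.term_ss.items()},
            "term_F": {k: float(v) for k, v in self.term_F.items()},
            "model_F": float(self.model_F),
            "lack_of_fit_F": opt(self.lack_of_fit_F),
            "pure_error_MS": opt(self.pure_error_MS),
            "residual_SD": float(self.residual_SD),
            "response_mean": float(self.response_mean),
            "CV_percent": float(self.CV_percent),
            "R2": float(self.R2),
            "adj_R2": float(self.adj_R2),
            "pred_R2": float(self.pred_R2),
            "PRESS": float(self.PRESS),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _pure_error(coded: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pure-error SS and df from replicated coded points."""
    ss, df = 0.0, 0
    # group runs by exact coded triple
    keys = [tuple(row) for row in np.round(coded, 12)]
    groups: dict[tuple, list[int]] = {}
    for idx, key in enumerate(keys):
        groups.setdefault(key, []).append(idx)
    for idxs in groups.values():
        if len(idxs) > 1:
            yy = y[idxs]
            ss += float(np.sum((yy - yy.mean()) ** 2))
            df += len(idxs) - 1
    return ss, df


def anova(
    design: DesignTable,
    response_name: str,
    surface: Optional[QuadraticSurface] = None,
) -> AnovaReport:
    """ANOVA for a quadratic surface fit to one response of a design.

    Per-term sums of squares are sequential (type I) in :data:`TERM_NAMES`
    order, computed from the QR decomposition of the design matrix; each
    term's F statistic is its mean square over the residual mean square.
    PRESS uses the closed-form leave-one-out residuals e_i / (1 - h_ii).
    """
    y = design.response(response_name)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"response {response_name!r} contains non-finite values")
    coded = design.coded()
    X = quadratic_basis(coded)
    n, p = X.shape
    if surface is None:
        surface = fit_quadratic(design, response_name)

    fitted = X @ surface.coefficients()
    resid = y - fitted
    ss_residual = float(resid @ resid)
    ybar = float(y.mean())
    ss_total = float(np.sum((y - ybar) ** 2))
    ss_model = ss_total - ss_residual

    df_model, df_residual = p - 1, n - p
    ms_residual = ss_residual / df_residual if df_residual > 0 else np.nan

    # sequential single-df SS: project y on successive orthonormal directions
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ y
    term_ss = {name: float(proj[j] ** 2) for j, name in enumerate(TERM_NAMES) if j > 0}
    term_F = {
        name: (ss / ms_residual if ms_residual > 0 else np.inf)
        for name, ss in term_ss.items()
    }
    model_F = (
        (ss_model / df_model) / ms_residual
        if df_residual > 0 and ms_residual > 0
        else np.inf
    )

    ss_pe, df_pe = _pure_error(coded, y)
    if df_pe >= 1:
        df_lof = df_residual - df_pe
        ss_lof = max(ss_residual - ss_pe, 0.0)
        ms_pe = ss_pe / df_pe
        if df_lof > 0 and ms_pe > 0:
            lof_F = (ss_lof / df_lof) / ms_pe
        elif df_lof > 0:
            lof_F = np.inf if ss_lof > 0 else 0.0
        else:
            lof_F = None
            df_lof = 0
    else:
        df_lof, ms_pe, lof_F = None, None, None
        df_pe = None

    residual_sd = float(np.sqrt(ms_residual)) if df_residual > 0 else np.nan
    cv = 100.0 * residual_sd / abs(ybar) if ybar != 0 else np.nan
    r2 = 1.0 - ss_residual / ss_total if ss_total > 0 else np.nan
    adj_r2 = (
        1.0 - (ss_residual / df_residual) / (ss_total / (n - 1))
        if df_residual > 0 and ss_total > 0
        else np.nan
    )

    # PRESS from hat-matrix diagonal
    h = np.sum(Q * Q, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        loo = resid / (1.0 - h)
    loo = np.where(np.isclose(h, 1.0), np.nan, loo)
    press = float(np.nansum(loo**2))
    pred_r2 = 1.0 - press / ss_total if ss_total > 0 else np.nan

    return AnovaReport(
        response_name=response_name,
        n_runs=n,
        df_model=df_model,
        df_residual=df_residual,
        df_lack_of_fit=df_lof,
        df_pure_error=df_pe,
        ss_model=ss_model,
        ss_residual=ss_residual,
        ss_total=ss_total,
        term_ss=term_ss,
        term_F=term_F,
        model_F=model_F,
        lack_of_fit_F=lof_F,
        pure_error_MS=ms_pe,
        residual_SD=residual_sd,
        response_mean=ybar,
        CV_percent=cv,
        R2=r2,
        adj_R2=adj_r2,
        pred_R2=pred_r2,
        PRESS=press,
    )
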