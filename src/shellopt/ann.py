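"""Feed-forward neural-network surrogate for the extraction responses.

The surrogate is a single-hidden-layer feed-forward network: the hidden
pre-activation is the weighted sum of the inputs plus a hidden bias, passed
through the ``tansig`` (hyperbolic-tangent sigmoid) transfer function; the
output layer is linear,

    h = tansig(W_ih x + b_h),      y = W_ho h + b_o.

Inputs (the three process factors) and outputs (the five responses) are
min-max scaled to [-1, 1] — matching tansig's range — before training, and
the scalers are stored with the model so the convention is explicit.
Training is full-batch gradient-descent back-propagation on the mean squared
error with a fixed learning rate drawn once per run from a configured range;
a step that would increase the training MSE is rejected and the step size
halved, so the accepted-loss trajectory is non-increasing. Architecture
selection trains a fixed number of independently seeded runs per candidate
hidden-layer width and keeps the network with the best validation R^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable, RESPONSE_COLUMNS

__all__ = [
    "tansig",
    "Scaler",
    "AnnParameters",
    "TrainConfig",
    "TrainedSurrogate",
    "TrainingDiverged",
    "SurrogateCommittee",
    "forward",
    "train",
    "train_committee",
    "select_architecture",
    "save_params",
    "load_params",
    "save_surrogate",
    "load_surrogate",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def tansig(x):
    """Tangent-sigmoid transfer function, 2 / (1 + exp(-2x)) - 1.

    Algebraically identical to tanh; strictly increasing, odd, with range
    (-1, 1). Saturates (without overflow) for large |x|.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        out = 2.0 / (1.0 + np.exp(-2.0 * x)) - 1.0
    return out if out.ndim else float(out)


@dataclass
class Scaler:
    """Per-variable min-max map between natural units and [-1, 1]."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.atleast_1d(np.asarray(self.lo, dtype=float))
        self.hi = np.atleast_1d(np.asarray(self.hi, dtype=float))
        if self.lo.shape != self.hi.shape:
            raise ValueError("scaler lo/hi shape mismatch")
        if not np.all(self.hi > self.lo):
            raise ValueError("degenerate scaler: every variable needs hi > lo")

    @classmethod
    def from_data(cls, data: np.ndarray) -> "Scaler":
        data = np.asarray(data, dtype=float)
        return cls(lo=data.min(axis=0), hi=data.max(axis=0))

    def scale(self, x):
        x = np.asarray(x, dtype=float)
        return 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0

    def descale(self, z):
        z = np.asarray(z, dtype=float)
        return self.lo + (z + 1.0) * (self.hi - self.lo) / 2.0


@dataclass
class AnnParameters:
    """Weights and biases of a single-hidden-layer network.

    ``W_ih`` is (hidden, inputs) with one row per hidden neuron; ``W_ho`` is
    (outputs, hidden) with one row per output neuron. ``B_h`` and ``B_o``
    are the hidden and output bias vectors.
    """

    W_ih: np.ndarray
    B_h: np.ndarray
    W_ho: np.ndarray
    B_o: np.ndarray

    def __post_init__(self) -> None:
        self.W_ih = np.asarray(self.W_ih, dtype=float)
        self.B_h = np.asarray(self.B_h, dtype=float)
        self.W_ho = np.asarray(self.W_ho, dtype=float)
        self.B_o = np.asarray(self.B_o, dtype=float)
        h, i = self.W_ih.shape
        o, h2 = self.W_ho.shape
        if h2 != h or self.B_h.shape != (h,) or self.B_o.shape != (o,):
            raise ValueError(
                f"inconsistent shapes: W_ih {self.W_ih.shape}, B_h {self.B_h.shape}, "
                f"W_ho {self.W_ho.shape}, B_o {self.B_o.shape}"
            )
        for arr in (self.W_ih, self.B_h, self.W_ho, self.B_o):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite network parameter")

    @property
    def n_inputs(self) -> int:
        return self.W_ih.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_ih.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W_ho.shape[0]

    @property
    def architecture(self) -> str:
        return f"{self.n_inputs}-{self.n_hidden}-{self.n_outputs}"

    def copy(self) -> "AnnParameters":
        return AnnParameters(
            self.W_ih.copy(), self.B_h.copy(), self.W_ho.copy(), self.B_o.copy()
        )

    def n_values(self) -> int:
        return self.W_ih.size + self.B_h.size + self.W_ho.size + self.B_o.size


def forward(params: AnnParameters, x) -> np.ndarray:
    """Network output for scaled input(s); (n, outputs) for (n, inputs)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns, network expects {params.n_inputs}"
        )
    H = tansig(X @ params.W_ih.T + params.B_h)
    Y = H @ params.W_ho.T + params.B_o
    return Y[0] if single else Y


@dataclass(frozen=True)
class TrainConfig:
    """Training and architecture-search settings.

    Defaults follow the study protocol: 2000 gradient iterations per run,
    ten independently initialized runs per candidate architecture, learning
    rate drawn uniformly from [0.5, 1], and a seeded random 70/15/15
    train/test/validation split.
    """

    hidden_range: tuple[int, int] = (2, 8)
    iterations: int = 2000
    runs_per_architecture: int = 10
    lr_range: tuple[float, float] = (0.5, 1.0)
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.runs_per_architecture < 1:
            raise ValueError("runs_per_architecture must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        lo, hi = self.hidden_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid hidden-size range")


@dataclass
class TrainedSurrogate:
    """A trained network plus its scalers and per-split fit metrics."""

    params: AnnParameters
    x_scaler: Scaler
    y_scaler: Scaler
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    metrics: dict
    seed: Optional[int] = None
    learning_rate: Optional[float] = None
    search_candidates: list = field(default_factory=list)

    @property
    def architecture(self) -> str:
        return self.params.architecture

    def predict(self, natural_x) -> np.ndarray:
        """Predicted responses in natural units for natural-unit inputs."""
        x = np.asarray(natural_x, dtype=float)
        z = self.x_scaler.scale(x)
        out = forward(self.params, z)
        return self.y_scaler.descale(out)

    @property
    def validation_r2(self) -> float:
        return self.metrics["validation"]["r2"]

    @property
    def validation_mse(self) -> float:
        return self.metrics["validation"]["mse"]


def _extract_xy(
    dataset,
    input_names: Optional[Sequence[str]] = None,
    output_names: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], tuple[str, ...]]:
    if isinstance(dataset, DesignTable):
        frame = dataset.frame
        input_names = input_names or dataset.natural_columns
    elif isinstance(dataset, pd.DataFrame):
        frame = dataset
        if input_names is None:
            from .reference import FACTORS

            input_names = tuple(f.name for f in FACTORS)
    else:
        raise TypeError("dataset must be a DesignTable or DataFrame")
    if output_names is None:
        output_names = tuple(c for c in RESPONSE_COLUMNS if c in frame.columns)
    if not output_names:
        raise ValueError("dataset has no response columns")
    X = frame.loc[:, list(input_names)].to_numpy(dtype=float)
    Y = frame.loc[:, list(output_names)].to_numpy(dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("dataset contains non-finite values")
    return X, Y, tuple(input_names), tuple(output_names)


def _split_indices(
    n: int, fractions: tuple[float, float, float], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    n_test = int(round(fractions[1] * n))
    n_val = int(round(fractions[2] * n))
    if n - n_test - n_val < 1:
        raise ValueError("split leaves no training rows")
    perm = rng.permutation(n)
    return {
        "test": np.sort(perm[:n_test]),
        "validation": np.sort(perm[n_test : n_test + n_val]),
        "train": np.sort(perm[n_test + n_val :]),
    }


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def _pooled_r2(pred: np.ndarray, target: np.ndarray) -> float:
    sse = float(np.sum((pred - target) ** 2))
    sst = float(np.sum((target - target.mean(axis=0)) ** 2))
    if sst <= 0:
        return np.nan
    return 1.0 - sse / sst


def _loss_and_grads(params: AnnParameters, X, Y):
    H = tansig(X @ params.W_ih.T + params.B_h)
    out = H @ params.W_ho.T + params.B_o
    E = out - Y
    loss = float(np.mean(E**2))
    dOut = 2.0 * E / E.size
    gW_ho = dOut.T @ H
    gB_o = dOut.sum(axis=0)
    dH = (dOut @ params.W_ho) * (1.0 - H**2)
    gW_ih = dH.T @ X
    gB_h = dH.sum(axis=0)
    return loss, (gW_ih, gB_h, gW_ho, gB_o)


def train(
    dataset,
    config: TrainConfig = TrainConfig(),
    n_hidden: int = 4,
    seed: Optional[int] = None,
    input_names: Optional[Sequence[str]] = None,
    output_names: Optional[Sequence[str]] = None,
) -> TrainedSurrogate:
    """Train one network of the given hidden width on a response dataset.

    ``seed`` overrides ``config.seed`` (used by the architecture search to
    give each run its own stream). The returned surrogate carries per-split
    MSE and pooled R^2 computed on the scaled outputs.
    """
    X, Y, in_names, out_names = _extract_xy(dataset, input_names, output_names)
    if len(X) < 2:
        raise ValueError("need at least 2 rows to train")
    x_scaler = Scaler.from_data(X)
    y_scaler = Scaler.from_data(Y)
    Xs, Ys = x_scaler.scale(X), y_scaler.scale(Y)

    run_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)
    splits = _split_indices(len(X), config.split_fractions, rng)

    lr = float(rng.uniform(*config.lr_range))
    params = AnnParameters(
        W_ih=rng.uniform(-0.5, 0.5, size=(n_hidden, X.shape[1])),
        B_h=rng.uniform(-0.5, 0.5, size=n_hidden),
        W_ho=rng.uniform(-0.5, 0.5, size=(Y.shape[1], n_hidden)),
        B_o=rng.uniform(-0.5, 0.5, size=Y.shape[1]),
    )

    Xt, Yt = Xs[splits["train"]], Ys[splits["train"]]
    loss, grads = _loss_and_grads(params, Xt, Yt)
    if not np.isfinite(loss):
        raise TrainingDiverged(f"initial training loss is non-finite ({loss})")
    step = lr
    for _ in range(config.iterations):
        gW_ih, gB_h, gW_ho, gB_o = grads
        candidate = AnnParameters(
            W_ih=params.W_ih - step * gW_ih,
            B_h=params.B_h - step * gB_h,
            W_ho=params.W_ho - step * gW_ho,
            B_o=params.B_o - step * gB_o,
        )
        new_loss, new_grads = _loss_and_grads(candidate, Xt, Yt)
        if np.isfinite(new_loss) and new_loss <= loss:
            params, loss, grads = candidate, new_loss, new_grads
        else:
            # reject the step; retry from the same point with a smaller one
            step *= 0.5
            if step < 1e-15:
                break

    metrics = {}
    for name, idx in splits.items():
        if len(idx) == 0:
            metrics[name] = {"mse": np.nan, "r2": np.nan, "n": 0}
            continue
        pred = forward(params, Xs[idx])
        metrics[name] = {
            "mse": _mse(pred, Ys[idx]),
            "r2": _pooled_r2(pred, Ys[idx]),
            "n": int(len(idx)),
        }

    return TrainedSurrogate(
        params=params,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        input_names=in_names,
        output_names=out_names,
        metrics=metrics,
        seed=run_seed,
        learning_rate=lr,
    )


@dataclass
class SurrogateCommittee:
    """Equal-weight committee (ensemble mean) over trained networks.

    With an 18-run design the 3-point validation split cannot reliably
    single out one well-generalizing network, and individual small-data
    networks behave erratically in the corners of the factor box where the
    BBD places no runs. Averaging the predictions of every network from the
    architecture search smooths those unsupported regions and is the
    recommended surrogate for process optimization.
    """

    members: list

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("committee needs at least one member")
        names = {m.output_names for m in self.members}
        if len(names) != 1:
            raise ValueError("committee members disagree on output names")

    @property
    def output_names(self) -> tuple[str, ...]:
        return self.members[0].output_names

    @property
    def input_names(self) -> tuple[str, ...]:
        return self.members[0].input_names

    @property
    def x_scaler(self) -> Scaler:
        return self.members[0].x_scaler

    @property
    def best(self) -> TrainedSurrogate:
        """The member with the best validation metrics (spec of the search)."""
        winner = self.members[0]
        for m in self.members[1:]:
            if _better(m, winner):
                winner = m
        return winner

    def predict(self, natural_x) -> np.ndarray:
        return np.mean([m.predict(natural_x) for m in self.members], axis=0)


def train_committee(
    dataset,
    config: TrainConfig = TrainConfig(),
    input_names: Optional[Sequence[str]] = None,
    output_names: Optional[Sequence[str]] = None,
) -> SurrogateCommittee:
    """Train every candidate of the architecture search and keep them all.

    For each hidden width in ``config.hidden_range`` (inclusive),
    ``config.runs_per_architecture`` independently seeded runs are trained;
    the committee holds all of them in search order.
    """
    lo, hi = config.hidden_range
    members = []
    for n_hidden in range(lo, hi + 1):
        for run in range(config.runs_per_architecture):
            run_seed = int(
                np.random.SeedSequence([config.seed, n_hidden, run]).generate_state(1)[0]
                % 2**31
            )
            try:
                members.append(
                    train(
                        dataset,
                        config,
                        n_hidden=n_hidden,
                        seed=run_seed,
                        input_names=input_names,
                        output_names=output_names,
                    )
                )
            except TrainingDiverged as err:
                raise TrainingDiverged(
                    f"architecture with {n_hidden} hidden units, run {run}: {err}"
                ) from err
    return SurrogateCommittee(members)


def select_architecture(
    dataset,
    config: TrainConfig = TrainConfig(),
    input_names: Optional[Sequence[str]] = None,
    output_names: Optional[Sequence[str]] = None,
) -> TrainedSurrogate:
    """Search hidden-layer widths and return the best-validating network.

    The winner has the highest validation R^2; ties break toward lower
    validation MSE, then fewer hidden neurons. The returned surrogate's
    ``search_candidates`` lists (architecture, validation R^2, validation
    MSE) for every run evaluated.
    """
    committee = train_committee(dataset, config, input_names, output_names)
    best = committee.best
    best.search_candidates = [
        (m.architecture, m.validation_r2, m.validation_mse) for m in committee.members
    ]
    return best


def _better(a: TrainedSurrogate, b: TrainedSurrogate) -> bool:
    ka = (-_nan_low(a.validation_r2), _nan_high(a.validation_mse), a.params.n_hidden)
    kb = (-_nan_low(b.validation_r2), _nan_high(b.validation_mse), b.params.n_hidden)
    return ka < kb


def _nan_low(v: float) -> float:
    return -np.inf if not np.isfinite(v) else v


def _nan_high(v: float) -> float:
    return np.inf if not np.isfinite(v) else v


# --- serialization -----------------------------------------------------------

def _params_dict(params: AnnParameters) -> dict:
    return {
        "W_ih": params.W_ih.tolist(),
        "T_h": params.B_h.tolist(),
        "W_ho": params.W_ho.tolist(),
        "T_o": params.B_o.tolist(),
        "architecture": params.architecture,
    }


def _params_from_dict(d: dict) -> AnnParameters:
    try:
        return AnnParameters(
            W_ih=np.asarray(d["W_ih"], dtype=float),
            B_h=np.asarray(d["T_h"], dtype=float),
            W_ho=np.asarray(d["W_ho"], dtype=float),
            B_o=np.asarray(d["T_o"], dtype=float),
        )
    except KeyError as err:
        raise ValueError(f"malformed network file: missing key {err}") from err


def save_params(params: AnnParameters, path: str | Path) -> None:
    """Write weights/biases as JSON (keys W_ih, T_h, W_ho, T_o; row lists)."""
    Path(path).write_text(json.dumps(_params_dict(params), indent=2))


def load_params(path: str | Path) -> AnnParameters:
    return _params_from_dict(json.loads(Path(path).read_text()))


def save_surrogate(model: TrainedSurrogate, path: str | Path) -> None:
    d = _params_dict(model.params)
    d["scalers"] = {
        "x": {"lo": model.x_scaler.lo.tolist(), "hi": model.x_scaler.hi.tolist()},
        "y": {"lo": model.y_scaler.lo.tolist(), "hi": model.y_scaler.hi.tolist()},
    }
    d["input_names"] = list(model.input_names)
    d["output_names"] = list(model.output_names)
    d["metrics"] = json.loads(json.dumps(model.metrics, default=float))
    d["seed"] = model.seed
    d["learning_rate"] = model.learning_rate
    Path(path).write_text(json.dumps(d, indent=2))


def load_surrogate(path: str | Path) -> TrainedSurrogate:
    d = json.loads(Path(path).read_text())
    params = _params_from_dict(d)
    try:
        sx, sy = d["scalers"]["x"], d["scalers"]["y"]
        return TrainedSurrogate(
            params=params,
            x_scaler=Scaler(np.asarray(sx["lo"]), np.asarray(sx["hi"])),
            y_scaler=Scaler(np.asarray(sy["lo"]), np.asarray(sy["hi"])),
            input_names=tuple(d["input_names"]),
            output_names=tuple(d["output_names"]),
            metrics=d.get("metrics", {}),
            seed=d.get("seed"),
            learning_rate=d.get("learning_rate"),
        )
    except KeyError as err:
        raise ValueError(f"malformed surrogate file: missing key {err}") from err
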