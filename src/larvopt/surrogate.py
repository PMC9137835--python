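"""Single-hidden-layer perceptron surrogates of the nutritional responses.

Four surrogates are trained, one per response group (proximate, amino acid,
mineral, fatty acid), mapping the 8 one-hot rearing indicators to the group's
outputs.  Training minimizes the sum of squared errors (SOS) in min-max
normalized space with the BFGS quasi-Newton method and analytic gradients,
restarted from many random initializations; model structure (hidden size,
activation family) is selected by validation error over a held-out subset of
conditions.

The topologies of interest are small — e.g. 8-10-6 for the proximate group
has (8+1)*10 + (10+1)*6 = 156 trainable weights and biases — so full-batch
BFGS over all parameters is fast and deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .catalog import DesignPoint, GROUPS, responses_in_group
from .encoding import (
    ENCODED_INPUT_NAMES,
    MinMaxScaler,
    encode_design_matrix,
    mean_table_points,
)

MODEL_FORMAT_VERSION = 1

# activation families: value = (f, f') evaluated elementwise.
# "exponential" is exp(x); "softlog" is the sign-symmetric logarithmic
# softening sign(x) * ln(1 + |x|).
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
    "logistic": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z: (s := 1.0 / (1.0 + np.exp(-z))) * (1.0 - s),
    ),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "exponential": (np.exp, np.exp),
    "softlog": (
        lambda z: np.sign(z) * np.log1p(np.abs(z)),
        lambda z: 1.0 / (1.0 + np.abs(z)),
    ),
}

DEFAULT_ACTIVATIONS: tuple[str, ...] = ("identity", "logistic", "tanh")


def count_parameters(input_width: int, hidden: int, outputs: int) -> int:
    """Number of trainable weights and biases of a fully connected
    single-hidden-layer perceptron: (input_width+1)*hidden + (hidden+1)*outputs."""
    if input_width < 1 or hidden < 1 or outputs < 1:
        raise ValueError("all layer widths must be >= 1")
    return (input_width + 1) * hidden + (hidden + 1) * outputs


@dataclass
class MLPSurrogate:
    """A trained surrogate for one response group."""

    group: str
    output_names: list[str]
    input_to_hidden_weights: np.ndarray  # (hidden, 8)
    hidden_biases: np.ndarray  # (hidden,)
    hidden_to_output_weights: np.ndarray  # (outputs, hidden)
    output_biases: np.ndarray  # (outputs,)
    hidden_activation: str
    output_activation: str
    input_scaling: MinMaxScaler
    output_scaling: MinMaxScaler

    @property
    def hidden_size(self) -> int:
        return self.input_to_hidden_weights.shape[0]

    @property
    def input_width(self) -> int:
        return self.input_to_hidden_weights.shape[1]

    @property
    def parameter_count(self) -> int:
        return count_parameters(self.input_width, self.hidden_size, len(self.output_names))

    @property
    def topology_label(self) -> str:
        return f"MLP {self.input_width}-{self.hidden_size}-{len(self.output_names)}"

    def forward_normalized(self, x_scaled: np.ndarray) -> np.ndarray:
        f = ACTIVATIONS[self.hidden_activation][0]
        g = ACTIVATIONS[self.output_activation][0]
        h = f(x_scaled @ self.input_to_hidden_weights.T + self.hidden_biases)
        return g(h @ self.hidden_to_output_weights.T + self.output_biases)

    def predict(self, points: DesignPoint | Sequence[DesignPoint]) -> pd.DataFrame:
        """Predict the group's responses in original units for one or many
        rearing conditions."""
        single = isinstance(points, DesignPoint)
        pts = [points] if single else list(points)
        x = self.input_scaling.transform(encode_design_matrix(pts))
        y = self.output_scaling.inverse(self.forward_normalized(x))
        if not np.isfinite(y).all():
            raise FloatingPointError("non-finite surrogate prediction")
        return pd.DataFrame(y, columns=self.output_names, index=[p.label() for p in pts])


@dataclass
class FitReport:
    """Diagnostics of one training run / topology search."""

    sos: float
    r2_per_output: dict[str, float]
    r2_overall: float
    topology_label: str
    restarts_run: int
    selection_score: float
    seed: int
    hidden_activation: str = "tanh"
    candidates: list[dict] = field(default_factory=list)

    def candidates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.candidates)


@dataclass(frozen=True)
class TopologySearchConfig:
    """Search space and budget of the model-structure optimization.

    ``restarts`` random initializations are trained per (hidden size,
    activation) candidate; the published analysis used a far larger restart
    budget, which this implementation supports but does not default to.
    """

    hidden_range: tuple[int, int] = (5, 20)
    activations: tuple[str, ...] = DEFAULT_ACTIVATIONS
    restarts: int = 200
    validation_fraction: float = 0.15
    test_fraction: float = 0.15
    seed: int = 0
    max_bfgs_iterations: int = 500
    #: validation scores within this absolute SOS are treated as tied, so the
    #: parsimony tie-break (fewer parameters) applies among interpolating fits
    selection_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        lo, hi = self.hidden_range
        if not (1 <= lo <= hi <= 64):
            raise ValueError("hidden_range must satisfy 1 <= lo <= hi <= 64")
        if not (0 < self.validation_fraction <= 0.5):
            raise ValueError("validation_fraction must be in (0, 0.5]")
        if not (0 <= self.test_fraction < 0.5):
            raise ValueError("test_fraction must be in [0, 0.5)")
        if self.validation_fraction + self.test_fraction >= 1:
            raise ValueError("fractions must sum below 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.selection_tolerance <= 0:
            raise ValueError("selection_tolerance must be > 0")
        unknown = set(self.activations) - set(ACTIVATIONS)
        if unknown:
            raise ValueError(f"unknown activations: {sorted(unknown)}")


def _unpack(theta: np.ndarray, m: int, h: int, q: int):
    i = 0
    w1 = theta[i : i + h * m].reshape(h, m)
    i += h * m
    b1 = theta[i : i + h]
    i += h
    w2 = theta[i : i + q * h].reshape(q, h)
    i += q * h
    b2 = theta[i : i + q]
    return w1, b1, w2, b2


def _loss_grad(theta, x, t, m, h, q, act_h, act_o):
    w1, b1, w2, b2 = _unpack(theta, m, h, q)
    f, fp = ACTIVATIONS[act_h]
    g, gp = ACTIVATIONS[act_o]
    z = x @ w1.T + b1
    hid = f(z)
    o = hid @ w2.T + b2
    y = g(o)
    e = y - t
    loss = float(np.sum(e * e))
    d_o = 2.0 * e * gp(o)
    g_w2 = d_o.T @ hid
    g_b2 = d_o.sum(axis=0)
    d_h = (d_o @ w2) * fp(z)
    g_w1 = d_h.T @ x
    g_b1 = d_h.sum(axis=0)
    grad = np.concatenate([g_w1.ravel(), g_b1, g_w2.ravel(), g_b2])
    return loss, grad


def _sos(model: MLPSurrogate, x_scaled: np.ndarray, t_scaled: np.ndarray) -> float:
    e = model.forward_normalized(x_scaled) - t_scaled
    return float(np.sum(e * e))


def _r2_report(model: MLPSurrogate, points, targets: pd.DataFrame) -> tuple[dict, float]:
    """Per-output r^2 in original units and pooled r^2 in normalized space."""
    pred = model.predict(points)
    r2 = {}
    for name in model.output_names:
        obs = targets[name].to_numpy(dtype=float)
        sse = float(np.sum((pred[name].to_numpy() - obs) ** 2))
        sst = float(np.sum((obs - obs.mean()) ** 2))
        r2[name] = float("nan") if sst == 0 else 1.0 - sse / sst
    t_scaled = model.output_scaling.transform(targets[model.output_names].to_numpy(float))
    x_scaled = model.input_scaling.transform(encode_design_matrix(points))
    y_scaled = model.forward_normalized(x_scaled)
    sse = float(np.sum((y_scaled - t_scaled) ** 2))
    sst = float(np.sum((t_scaled - t_scaled.mean(axis=0)) ** 2))
    r2_overall = float("nan") if sst == 0 else 1.0 - sse / sst
    return r2, r2_overall


def train(
    mean_table: pd.DataFrame,
    group: str,
    hidden: int = 10,
    activations: tuple[str, str] = ("tanh", "identity"),
    seed: int = 0,
    max_bfgs_iterations: int = 500,
    _scalers_and_arrays=None,
) -> tuple[MLPSurrogate, FitReport]:
    """Train one surrogate with a single seeded BFGS run.

    ``activations`` is the (hidden, output) activation pair.  Weights and
    biases start from a seeded uniform(-0.5, 0.5) draw; BFGS then minimizes
    the SOS of the normalized outputs.  Deterministic given the seed.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    outputs = list(responses_in_group(group))
    act_h, act_o = activations
    for a in (act_h, act_o):
        if a not in ACTIVATIONS:
            raise ValueError(f"unknown activation {a!r}")
    if _scalers_and_arrays is None:
        points = mean_table_points(mean_table)
        if len(points) < 4:
            raise ValueError("need at least 4 conditions to train a surrogate")
        x_raw = encode_design_matrix(points)
        t_raw = mean_table[outputs].to_numpy(dtype=float)
        in_scale = MinMaxScaler.fit(x_raw, list(ENCODED_INPUT_NAMES))
        out_scale = MinMaxScaler.fit(t_raw, outputs)
        x = in_scale.transform(x_raw)
        t = out_scale.transform(t_raw)
    else:
        points, x, t, in_scale, out_scale = _scalers_and_arrays

    m, q = x.shape[1], t.shape[1]
    n_par = count_parameters(m, hidden, q)
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-0.5, 0.5, size=n_par)
    res = minimize(
        _loss_grad,
        theta0,
        args=(x, t, m, hidden, q, act_h, act_o),
        method="BFGS",
        jac=True,
        options={"maxiter": max_bfgs_iterations, "gtol": 1e-8},
    )
    if not np.isfinite(res.fun) or not np.isfinite(res.x).all():
        raise FloatingPointError("non-finite loss after BFGS; retry with another seed")
    w1, b1, w2, b2 = (a.copy() for a in _unpack(res.x, m, hidden, q))
    model = MLPSurrogate(
        group=group,
        output_names=outputs,
        input_to_hidden_weights=w1,
        hidden_biases=b1,
        hidden_to_output_weights=w2,
        output_biases=b2,
        hidden_activation=act_h,
        output_activation=act_o,
        input_scaling=in_scale,
        output_scaling=out_scale,
    )
    targets = pd.DataFrame(out_scale.inverse(t), columns=outputs)
    r2_per_output, r2_overall = _r2_report(model, points, targets)
    report = FitReport(
        sos=float(res.fun),
        r2_per_output=r2_per_output,
        r2_overall=r2_overall,
        topology_label=model.topology_label,
        restarts_run=1,
        selection_score=float(res.fun),
        seed=seed,
        hidden_activation=act_h,
    )
    return model, report


def _split_conditions(n: int, cfg: TopologySearchConfig, rng: np.random.Generator):
    n_val = max(1, int(round(n * cfg.validation_fraction)))
    n_test = int(round(n * cfg.test_fraction))
    if n - n_val - n_test < 2:
        raise ValueError(
            f"split leaves {n - n_val - n_test} training conditions out of {n}; "
            "reduce validation_fraction/test_fraction"
        )
    perm = rng.permutation(n)
    return perm[n_val + n_test :], perm[:n_val], perm[n_val : n_val + n_test]


def topology_search(
    mean_table: pd.DataFrame,
    group: str,
    config: TopologySearchConfig = TopologySearchConfig(),
) -> tuple[MLPSurrogate, FitReport]:
    """Restart-based structure search: train ``restarts`` seeded candidates per
    (hidden size, hidden activation) and keep the one with the lowest
    validation SOS.

    Validation scores within ``selection_tolerance`` of each other count as
    tied; ties are broken by fewer parameters, then lower training SOS, then
    seed order (so among exactly interpolating candidates the smallest
    adequate topology wins).  Scaling is fitted on the training partition only.  The returned
    report's r^2 values refer to the training partition; ``selection_score``
    is the winning validation SOS.
    """
    outputs = list(responses_in_group(group))
    points = mean_table_points(mean_table)
    rng = np.random.default_rng((config.seed, 97))
    tr, va, te = _split_conditions(len(points), config, rng)

    x_raw = encode_design_matrix(points)
    t_raw = mean_table[outputs].to_numpy(dtype=float)
    in_scale = MinMaxScaler.fit(x_raw[tr], list(ENCODED_INPUT_NAMES))
    out_scale = MinMaxScaler.fit(t_raw[tr], outputs)
    x = in_scale.transform(x_raw)
    t = out_scale.transform(t_raw)
    train_pack = ([points[i] for i in tr], x[tr], t[tr], in_scale, out_scale)

    seeds = np.random.SeedSequence(config.seed).generate_state(config.restarts) % (2**31)
    best = None  # (val_sos, n_par, train_sos, order, model, train_report)
    candidates = []
    order = 0
    lo, hi = config.hidden_range
    for hidden in range(lo, hi + 1):
        for act in config.activations:
            for r in range(config.restarts):
                model, rep = train(
                    mean_table,
                    group,
                    hidden=hidden,
                    activations=(act, "identity"),
                    seed=int(seeds[r]),
                    max_bfgs_iterations=config.max_bfgs_iterations,
                    _scalers_and_arrays=train_pack,
                )
                val_sos = _sos(model, x[va], t[va])
                quantized = int(val_sos / config.selection_tolerance)
                key = (quantized, model.parameter_count, rep.sos, order)
                candidates.append(
                    {
                        "hidden": hidden,
                        "activation": act,
                        "restart": r,
                        "seed": int(seeds[r]),
                        "train_sos": rep.sos,
                        "val_sos": val_sos,
                        "r2_overall_train": rep.r2_overall,
                    }
                )
                if best is None or key < best[0]:
                    best = (key, model, rep)
                order += 1
    assert best is not None
    _, model, rep = best
    report = FitReport(
        sos=rep.sos,
        r2_per_output=rep.r2_per_output,
        r2_overall=rep.r2_overall,
        topology_label=model.topology_label,
        restarts_run=order,
        selection_score=best[0][0],
        seed=rep.seed,
        hidden_activation=model.hidden_activation,
        candidates=candidates,
    )
    return model, report


def save_model(model: MLPSurrogate, path: str | Path) -> None:
    doc = {
        "version": MODEL_FORMAT_VERSION,
        "group": model.group,
        "output_names": model.output_names,
        "hidden_activation": model.hidden_activation,
        "output_activation": model.output_activation,
        "weights": {
            "input_to_hidden": model.input_to_hidden_weights.tolist(),
            "hidden_biases": model.hidden_biases.tolist(),
            "hidden_to_output": model.hidden_to_output_weights.tolist(),
            "output_biases": model.output_biases.tolist(),
        },
        "scaling": {
            "input": model.input_scaling.to_dict(),
            "output": model.output_scaling.to_dict(),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> MLPSurrogate:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model file {path}: {exc}") from exc
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {doc.get('version')!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    w = doc["weights"]
    model = MLPSurrogate(
        group=doc["group"],
        output_names=list(doc["output_names"]),
        input_to_hidden_weights=np.asarray(w["input_to_hidden"], dtype=float),
        hidden_biases=np.asarray(w["hidden_biases"], dtype=float),
        hidden_to_output_weights=np.asarray(w["hidden_to_output"], dtype=float),
        output_biases=np.asarray(w["output_biases"], dtype=float),
        hidden_activation=doc["hidden_activation"],
        output_activation=doc["output_activation"],
        input_scaling=MinMaxScaler.from_dict(doc["scaling"]["input"]),
        output_scaling=MinMaxScaler.from_dict(doc["scaling"]["output"]),
    )
    if not (
        np.isfinite(model.input_to_hidden_weights).all()
        and np.isfinite(model.hidden_to_output_weights).all()
        and np.isfinite(model.hidden_biases).all()
        and np.isfinite(model.output_biases).all()
    ):
        raise ValueError(f"corrupt model file {path}: non-finite weights")
    return model
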