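"""Connection-weight (Yoon) relative influence of rearing factors.

For a single-hidden-layer perceptron the global relative influence of input
``i`` on output ``j`` is computed from the products of the input-to-hidden and
hidden-to-output weights:

    RI_ij (%) = ( sum_k w_ik * w_kj ) / ( sum_i | sum_k w_ik * w_kj | ) * 100

summing over hidden neurons ``k``; biases are excluded.  The result is a
signed percentage whose absolute values sum to 100 over the inputs for each
output.  Two numerical choices are made explicit here:

* **Denominator.**  The default uses absolute values of the per-input inner
  sums, the standard formulation, which keeps every percentage bounded by
  +/-100.  A ``verbatim`` variant uses the plain signed sum, which can be
  near zero and yield unbounded percentages.

* **Gauge.**  The 8 encoded inputs are one-hot blocks that each sum to 1 for
  every design point, so adding a constant to all input-to-hidden weights of
  one block (and subtracting it from the hidden bias) never changes the
  network function.  Trained networks exploit this freedom to park intercept
  mass in the indicator columns, which would let connection weights attribute
  influence to a factor with no effect at all.  RI is therefore computed by
  default in the *sum-to-zero gauge* — input-to-hidden weights centered
  within each factor block, the same identification convention as ANOVA
  effect coding.  This is an exact reparameterization of the same network.
  Centering applies only when the model has the 8-input design-block
  structure, and is switched off for the ``verbatim`` denominator (whose
  signed sum would vanish identically in the centered gauge).

Influences are computed on the normalized-space weights, i.e. they describe
the trained network, and are aggregated per factor level (species, substrate,
harvest time) for bar-panel reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import ENCODED_INPUT_NAMES
from .surrogate import MLPSurrogate

_FACTOR_OF_INPUT = ["species"] * 2 + ["substrate"] * 3 + ["harvest"] * 3
_LEVEL_OF_INPUT = [name.split("=", 1)[1] for name in ENCODED_INPUT_NAMES]
_BLOCK_SLICES = (slice(0, 2), slice(2, 5), slice(5, 8))


@dataclass
class RelativeInfluenceMatrix:
    """Signed RI percentages, encoded inputs x outputs."""

    ri: pd.DataFrame
    model_label: str


def _block_centered(w1: np.ndarray) -> np.ndarray:
    """Project input-to-hidden weights onto the sum-to-zero gauge per factor
    block (function-preserving because every block of indicators sums to 1)."""
    w1 = w1.copy()
    for blk in _BLOCK_SLICES:
        w1[:, blk] -= w1[:, blk].mean(axis=1, keepdims=True)
    return w1


def yoon_ri(
    model: MLPSurrogate,
    denominator: str = "abs",
    center_blocks: bool | None = None,
) -> RelativeInfluenceMatrix:
    """Relative influence of each encoded input on each model output.

    Parameters
    ----------
    denominator:
        "abs" (default) or "verbatim"; see the module docstring.
    center_blocks:
        Compute RI in the sum-to-zero gauge.  Default: True for the "abs"
        denominator on 8-input design models, False otherwise.
    """
    if denominator not in ("abs", "verbatim"):
        raise ValueError("denominator must be 'abs' or 'verbatim'")
    w1 = model.input_to_hidden_weights
    is_design_model = model.input_width == 8
    if center_blocks is None:
        center_blocks = denominator == "abs" and is_design_model
    if center_blocks:
        if not is_design_model:
            raise ValueError("block centering requires the 8-input design blocks")
        w1 = _block_centered(w1)
    # numerator[j, i] = sum_k w2[j, k] * w1[k, i]
    num = model.hidden_to_output_weights @ w1
    if denominator == "abs":
        den = np.abs(num).sum(axis=1)
    else:
        den = num.sum(axis=1)
    degenerate = np.isclose(den, 0.0, atol=1e-12)
    if degenerate.any():
        bad = [model.output_names[j] for j in np.flatnonzero(degenerate)]
        raise ZeroDivisionError(
            f"degenerate network: zero RI denominator for outputs {bad}"
        )
    index = (
        list(ENCODED_INPUT_NAMES) if is_design_model else list(model.input_scaling.names)
    )
    frame = pd.DataFrame((num / den[:, None]).T * 100.0, index=index,
                         columns=model.output_names)
    return RelativeInfluenceMatrix(ri=frame, model_label=model.topology_label)


def aggregate_by_factor(ri: RelativeInfluenceMatrix) -> pd.DataFrame:
    """Per-factor-level table of signed influences (long layout: factor,
    level, response, ri_percent), suitable for bar panels.

    Because the encoded inputs partition into the three factors' levels, the
    sum of |ri_percent| over all rows of one response remains 100.
    """
    if ri.ri.shape[0] != 8 or list(ri.ri.index) != list(ENCODED_INPUT_NAMES):
        raise ValueError(
            f"expected the 8 encoded-input rows in documented order, "
            f"got {list(ri.ri.index)}"
        )
    records = []
    for pos, input_name in enumerate(ENCODED_INPUT_NAMES):
        for response in ri.ri.columns:
            records.append(
                {
                    "factor": _FACTOR_OF_INPUT[pos],
                    "level": _LEVEL_OF_INPUT[pos],
                    "response": response,
                    "ri_percent": float(ri.ri.at[input_name, response]),
                }
            )
    return pd.DataFrame(records)


def export_bar_panels(ri: RelativeInfluenceMatrix, path) -> None:
    """Optional matplotlib export: one signed-bar panel per output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(ri.ri.index)
    n = len(ri.ri.columns)
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, response in zip(axes.ravel(), ri.ri.columns):
        ax.bar(range(len(labels)), ri.ri[response], tick_label=labels)
        ax.axhline(0.0, lw=0.5, color="k")
        ax.set_title(response)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        ax.set_ylabel("RI (%)")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.suptitle(ri.model_label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
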