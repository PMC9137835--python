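"""Categorical encoding, replicate aggregation and invertible min-max scaling.

The three rearing factors are purely categorical, so the perceptron inputs are
the 8 one-hot indicators (2 species + 3 substrates + 3 harvest times), each
block summing to 1.  Inputs and outputs are min-max normalized to [0, 1]
before training, with exact inversion for reporting in original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (
    HARVEST_LEVELS,
    RESPONSE_NAMES,
    SPECIES_LEVELS,
    SUBSTRATE_LEVELS,
    DesignPoint,
)

#: column labels of the encoded design matrix, in block order
ENCODED_INPUT_NAMES: tuple[str, ...] = (
    *(f"species={s}" for s in SPECIES_LEVELS),
    *(f"substrate={s}" for s in SUBSTRATE_LEVELS),
    *(f"harvest={t}" for t in HARVEST_LEVELS),
)

_BLOCKS = (slice(0, 2), slice(2, 5), slice(5, 8))


def one_hot_encode(point: DesignPoint) -> np.ndarray:
    """8-dimensional one-hot encoding (species block 2, substrate 3, time 3)."""
    v = np.zeros(8)
    v[SPECIES_LEVELS.index(point.species)] = 1.0
    v[2 + SUBSTRATE_LEVELS.index(point.substrate)] = 1.0
    v[5 + HARVEST_LEVELS.index(point.harvest_days)] = 1.0
    return v


def encode_design_matrix(points) -> np.ndarray:
    """Stack one-hot encodings into an (n, 8) design matrix."""
    return np.vstack([one_hot_encode(p) for p in points])


def decode(encoded) -> DesignPoint:
    """Invert a one-hot encoding; each block must sum to exactly 1."""
    v = np.asarray(encoded, dtype=float)
    if v.shape != (8,):
        raise ValueError(f"encoded design must have 8 entries, got shape {v.shape}")
    idx = []
    for blk in _BLOCKS:
        block = v[blk]
        if not (np.isin(block, (0.0, 1.0)).all() and block.sum() == 1.0):
            raise ValueError(f"block {block.tolist()} is not one-hot")
        idx.append(int(np.argmax(block)))
    return DesignPoint(
        SPECIES_LEVELS[idx[0]], SUBSTRATE_LEVELS[idx[1]], HARVEST_LEVELS[idx[2]]
    )


def aggregate_replicates(dataset: pd.DataFrame) -> pd.DataFrame:
    """Average replicates to condition means (one row per rearing condition).

    Mirrors the study's convention of analysing condition means of the
    triplicate determinations; the replicate count is kept in
    ``n_replicates``.
    """
    keys = ["species", "substrate", "harvest_days"]
    grouped = dataset.groupby(keys, sort=False, observed=True)
    means = grouped[list(RESPONSE_NAMES)].mean().reset_index()
    means["n_replicates"] = grouped.size().to_numpy()
    return means


def mean_table_points(mean_table: pd.DataFrame) -> list[DesignPoint]:
    """Design points of a condition-mean table, in row order."""
    return [
        DesignPoint(r.species, r.substrate, int(r.harvest_days))
        for r in mean_table.itertuples()
    ]


@dataclass
class MinMaxScaler:
    """Per-variable affine map of [min, max] onto [0, 1].

    Degenerate variables (max == min) map to the constant 0.5 and invert back
    to their min.  Out-of-range values extrapolate linearly, so predictions
    are well defined slightly outside the training hull.
    """

    names: list[str] = field(default_factory=list)
    mins: np.ndarray = field(default_factory=lambda: np.empty(0))
    maxs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @classmethod
    def fit(cls, values: np.ndarray, names: list[str] | None = None) -> "MinMaxScaler":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.size == 0:
            raise ValueError("cannot fit scaling on empty input")
        names = list(names) if names is not None else [f"x{i}" for i in range(values.shape[1])]
        return cls(names=names, mins=values.min(axis=0), maxs=values.max(axis=0))

    @property
    def _span(self) -> np.ndarray:
        return self.maxs - self.mins

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        span = self._span
        with np.errstate(invalid="ignore", divide="ignore"):
            y = (x - self.mins) / span
        return np.where(span == 0, 0.5, y)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return np.where(self._span == 0, self.mins, self.mins + y * self._span)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "min": self.mins.tolist(),
            "max": self.maxs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        return cls(
            names=list(d["names"]),
            mins=np.asarray(d["min"], dtype=float),
            maxs=np.asarray(d["max"], dtype=float),
        )
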