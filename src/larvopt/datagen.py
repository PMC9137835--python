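"""Synthetic factorial nutritional datasets for the 2 x 3 x 3 rearing design.

The measured dataset behind the published study (one table of 18 rearing
conditions x 3 replicates x 23 responses) is not distributed with this
package.  This module generates statistically structured stand-ins:

* condition means are drawn inside the species-specific response ranges
  shipped in the packaged fixture (``range_fixture.csv``);
* factor effects are additive by default (species + substrate + harvest-time
  main effects), matching the main-effect character of the reported results;
* the flaxseed diet effect is planted: under the ``mixture`` substrate the
  alpha-linolenic acid (C18:3n3) mean is ~10-fold the non-mixture mean and
  the n6/n3 ratio is pulled toward ~2;
* replicate scatter is additive Gaussian with a configurable relative SD.

A *planted-optimum* mode makes one chosen condition strictly best in all 23
responses (per the optimization directions), giving a known ground truth for
end-to-end parameter-recovery tests.

Real measured data in the same CSV layout is accepted via :func:`read_dataset`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    HARVEST_LEVELS,
    MAXIMIZE,
    PERCENT_RESPONSES,
    RESPONSE_CATALOG,
    RESPONSE_NAMES,
    SPECIES_LEVELS,
    SUBSTRATE_LEVELS,
    DesignPoint,
    design_space,
)

KP_NOTE = (
    "protein was determined with a nitrogen-to-protein conversion factor "
    "kp = 4.76 (whole-larvae laboratory convention; metadata only)"
)

#: CSV header for datasets
DATASET_COLUMNS = ["species", "substrate", "harvest_days", "replicate", *RESPONSE_NAMES]

# relative amplitudes of the additive factor effects, as fractions of the
# narrower species range width (substrate, harvest time); their sum < 0.5 so
# that means stay inside the species range for any base placement
_SUBSTRATE_AMP = 0.20
_TIME_AMP = 0.12


class DatasetValidationError(ValueError):
    """A dataset violates the factorial-design contract."""


@dataclass(frozen=True)
class GenerationConfig:
    """Settings of the synthetic-data generator.

    Parameters
    ----------
    replicates_per_condition:
        Analytical replicates per rearing condition (the study used
        triplicates).
    noise_sd_fraction:
        Relative SD of the additive Gaussian replicate noise, as a fraction
        of the condition mean.  0 gives exactly repeated replicates.
    flaxseed_ala_multiplier:
        Fold-increase of the C18:3n3 mean under the mixture (flaxseed)
        substrate relative to the carrot/cabbage baseline.
    seed:
        Seed of the single random stream; identical seeds give identical
        datasets.
    planted_optimum:
        If set, condition means are constructed so this design point is
        strictly best in every response per its optimization direction.
    interaction_strength:
        Relative amplitude of an optional species x substrate interaction
        (fraction of the additive effect scale); 0 keeps the surface purely
        additive.
    """

    replicates_per_condition: int = 3
    noise_sd_fraction: float = 0.03
    flaxseed_ala_multiplier: float = 10.0
    seed: int = 0
    planted_optimum: DesignPoint | None = None
    interaction_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if self.flaxseed_ala_multiplier <= 1:
            raise ValueError("flaxseed_ala_multiplier must be > 1")
        if self.interaction_strength < 0:
            raise ValueError("interaction_strength must be >= 0")


def load_range_fixture() -> pd.DataFrame:
    """Packaged per-species plausible ranges of the 23 responses.

    Rows flagged ``reported-range`` carry published range endpoints; rows
    flagged ``synthetic-default`` are plausible insect-meal bands chosen for
    responses whose ranges were not printed numerically.
    """
    with resources.files("larvopt.data").joinpath("range_fixture.csv").open() as fh:
        fx = pd.read_csv(fh)
    expected_cols = ["response", "species", "low", "high", "source_section"]
    if list(fx.columns) != expected_cols:
        raise RuntimeError(f"corrupt range fixture: columns {list(fx.columns)}")
    if len(fx) != len(RESPONSE_NAMES) * len(SPECIES_LEVELS):
        raise RuntimeError(f"corrupt range fixture: {len(fx)} rows")
    if set(fx["response"]) != set(RESPONSE_NAMES):
        raise RuntimeError("corrupt range fixture: response names do not match catalog")
    if (fx["low"] > fx["high"]).any():
        bad = fx.loc[fx["low"] > fx["high"], "response"].tolist()
        raise RuntimeError(f"corrupt range fixture: low > high for {bad}")
    return fx


def _fixture_ranges() -> dict[str, dict[str, tuple[float, float]]]:
    fx = load_range_fixture()
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for row in fx.itertuples():
        out.setdefault(row.response, {})[row.species] = (float(row.low), float(row.high))
    return out


def _additive_means(
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]],
    response: str,
    interaction_strength: float,
    flax_mult: float,
) -> dict[DesignPoint, float]:
    """Draw one additive response surface inside the species-specific ranges."""
    (low_tm, high_tm), (low_zm, high_zm) = ranges["TM"], ranges["ZM"]
    width_min = min(high_tm - low_tm, high_zm - low_zm)

    if response == "C18_3n3":
        # flaxseed effect: mixture mean ~ multiplier x non-mixture baseline,
        # capped so the boosted level stays inside the fixture band
        low = max(low_tm, low_zm)
        high = min(high_tm, high_zm)
        mu0_low, mu0_high = low / 0.94, high / (flax_mult * 1.06)
        mult = flax_mult
        if mu0_high < mu0_low:
            mult = high / (mu0_low * 1.06)
            mu0_high = mu0_low
        mu0 = rng.uniform(mu0_low, mu0_high)
        a_sub = {
            "carrot": rng.uniform(-0.02, 0.02) * mu0,
            "cabbage": rng.uniform(-0.02, 0.02) * mu0,
            "mixture": (mult - 1.0) * mu0,
        }
        base = {sp: mu0 + rng.uniform(-0.02, 0.02) * mu0 for sp in SPECIES_LEVELS}
        b_t = {t: rng.uniform(-0.02, 0.02) * mu0 for t in HARVEST_LEVELS}
        return {
            DesignPoint(sp, sub, t): base[sp] + a_sub[sub] + b_t[t]
            for sp in SPECIES_LEVELS
            for sub in SUBSTRATE_LEVELS
            for t in HARVEST_LEVELS
        }

    if response == "n6_n3":
        # without flaxseed the omega-6/omega-3 ratio is high; the mixture diet
        # pulls it toward ~2
        min_high = min(high_tm, high_zm)
        a_sub = {
            "carrot": rng.uniform(6.0, min_high - 1.0),
            "cabbage": rng.uniform(6.0, min_high - 1.0),
            "mixture": rng.uniform(1.95, 2.35),
        }
        base = {sp: rng.uniform(-0.15, 0.15) for sp in SPECIES_LEVELS}
        b_t = {t: rng.uniform(-0.15, 0.15) for t in HARVEST_LEVELS}
        return {
            DesignPoint(sp, sub, t): base[sp] + a_sub[sub] + b_t[t]
            for sp in SPECIES_LEVELS
            for sub in SUBSTRATE_LEVELS
            for t in HARVEST_LEVELS
        }

    amp_sub = _SUBSTRATE_AMP * width_min
    amp_t = _TIME_AMP * width_min
    a_sub = {sub: rng.uniform(-amp_sub, amp_sub) for sub in SUBSTRATE_LEVELS}
    b_t = {t: rng.uniform(-amp_t, amp_t) for t in HARVEST_LEVELS}
    margin = amp_sub + amp_t
    base = {}
    for sp, (low, high) in (("TM", ranges["TM"]), ("ZM", ranges["ZM"])):
        base[sp] = rng.uniform(low + margin, high - margin)
    means = {
        DesignPoint(sp, sub, t): base[sp] + a_sub[sub] + b_t[t]
        for sp in SPECIES_LEVELS
        for sub in SUBSTRATE_LEVELS
        for t in HARVEST_LEVELS
    }
    if interaction_strength > 0:
        # species x substrate wiggle, kept inside the range by shrinking
        # toward the species midpoint afterwards
        wig = {
            (sp, sub): rng.uniform(-1, 1) * interaction_strength * amp_sub
            for sp in SPECIES_LEVELS
            for sub in SUBSTRATE_LEVELS
        }
        for pt in means:
            means[pt] += wig[(pt.species, pt.substrate)]
        for sp, (low, high) in (("TM", ranges["TM"]), ("ZM", ranges["ZM"])):
            for pt in means:
                if pt.species == sp:
                    means[pt] = float(np.clip(means[pt], low, high))
    return means


def _planted_means(
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]],
    direction: str,
    planted: DesignPoint,
) -> dict[DesignPoint, float]:
    """Additive surface over the species-merged range with the planted point
    strictly best per the optimization direction.

    Merged ranges are needed because the two species' published ranges can be
    disjoint (e.g. Ca), which would make all-response dominance impossible
    inside per-species bands.
    """
    low = min(ranges["TM"][0], ranges["ZM"][0])
    high = max(ranges["TM"][1], ranges["ZM"][1])
    width = high - low
    sign = 1.0 if direction == MAXIMIZE else -1.0
    amp, delta = 0.15 * width, 0.04 * width

    def factor_effects(levels, best):
        eff = {}
        for lev in levels:
            if lev == best:
                eff[lev] = sign * amp
            else:
                eff[lev] = sign * rng.uniform(-amp, amp - delta)
        return eff

    e_sp = factor_effects(SPECIES_LEVELS, planted.species)
    e_sub = factor_effects(SUBSTRATE_LEVELS, planted.substrate)
    e_t = factor_effects(HARVEST_LEVELS, planted.harvest_days)
    base = rng.uniform(low + 0.45 * width, high - 0.45 * width)
    return {
        DesignPoint(sp, sub, t): base + e_sp[sp] + e_sub[sub] + e_t[t]
        for sp in SPECIES_LEVELS
        for sub in SUBSTRATE_LEVELS
        for t in HARVEST_LEVELS
    }


def condition_means(config: GenerationConfig) -> pd.DataFrame:
    """The noise-free condition-mean table (18 rows x 23 responses) the
    generator builds replicates around."""
    rng = np.random.default_rng(config.seed)
    ranges = _fixture_ranges()
    points = design_space()
    table = {}
    for entry in RESPONSE_CATALOG:
        if config.planted_optimum is not None:
            means = _planted_means(
                rng, ranges[entry.name], entry.direction_in_moo, config.planted_optimum
            )
        else:
            means = _additive_means(
                rng,
                ranges[entry.name],
                entry.name,
                config.interaction_strength,
                config.flaxseed_ala_multiplier,
            )
        table[entry.name] = [means[pt] for pt in points]
    df = pd.DataFrame(
        {
            "species": [p.species for p in points],
            "substrate": [p.substrate for p in points],
            "harvest_days": [p.harvest_days for p in points],
            **table,
        }
    )
    return df


def generate_dataset(config: GenerationConfig) -> pd.DataFrame:
    """Generate a replicate-level synthetic dataset.

    Returns a tidy table with one row per (condition, replicate) and the 23
    catalog responses as columns; ``df.attrs`` records the seed and the
    nitrogen-to-protein convention note.
    """
    if config.planted_optimum is not None:
        # DesignPoint construction already validates levels; re-validate to
        # surface a clear error for e.g. dict-deserialized configs
        p = config.planted_optimum
        DesignPoint(p.species, p.substrate, p.harvest_days)
    means = condition_means(config)
    rng = np.random.default_rng((config.seed, 1))
    rows = []
    for _, mrow in means.iterrows():
        for rep in range(1, config.replicates_per_condition + 1):
            row = {
                "species": mrow["species"],
                "substrate": mrow["substrate"],
                "harvest_days": int(mrow["harvest_days"]),
                "replicate": rep,
            }
            for name in RESPONSE_NAMES:
                mu = float(mrow[name])
                val = mu + rng.normal(0.0, config.noise_sd_fraction * abs(mu))
                val = max(val, 0.0)
                if name in PERCENT_RESPONSES:
                    val = min(val, 100.0)
                row[name] = val
            rows.append(row)
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    df.attrs["kp_note"] = KP_NOTE
    df.attrs["generation_seed"] = config.seed
    validate_dataset(df)
    return df


def plant_dominant_optimum(config: GenerationConfig, point: DesignPoint) -> GenerationConfig:
    """Return a copy of ``config`` whose datasets make ``point`` the unique
    nondominated condition (strictly best in all 23 responses per direction)."""
    DesignPoint(point.species, point.substrate, point.harvest_days)
    return dataclasses.replace(config, planted_optimum=point)


def validate_dataset(df: pd.DataFrame) -> None:
    """Check the factorial-design contract; raise DatasetValidationError."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing columns: {missing}")
    for col, levels in (
        ("species", set(SPECIES_LEVELS)),
        ("substrate", set(SUBSTRATE_LEVELS)),
        ("harvest_days", set(HARVEST_LEVELS)),
    ):
        bad = df.loc[~df[col].isin(levels)]
        if len(bad):
            raise DatasetValidationError(
                f"unknown {col} level {bad.iloc[0][col]!r} at row {bad.index[0]}"
            )
    for name in RESPONSE_NAMES:
        col = df[name]
        if not np.issubdtype(col.dtype, np.number):
            raise DatasetValidationError(f"non-numeric values in column {name!r}")
        if col.isna().any():
            raise DatasetValidationError(
                f"missing value in column {name!r} at row {int(col.isna().idxmax())}"
            )
        if (col < 0).any():
            raise DatasetValidationError(
                f"negative value in column {name!r} at row {int((col < 0).idxmax())}"
            )
        if name in PERCENT_RESPONSES and (col > 100).any():
            raise DatasetValidationError(
                f"percentage above 100 in column {name!r} at row {int((col > 100).idxmax())}"
            )
    n_cond = df.groupby(["species", "substrate", "harvest_days"], observed=True).ngroups
    if n_cond > 18:
        raise DatasetValidationError(f"{n_cond} distinct conditions; the design has 18")


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset CSV (UTF-8, 6 significant digits)."""
    df.to_csv(path, index=False, float_format="%.6g")


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset CSV (the layout written by write_dataset;
    measured data such as the study's appendix table is supplied this way)."""
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise DatasetValidationError(f"unreadable dataset CSV {path}: {exc}") from exc
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"dataset {path} missing columns: {missing}")
    for name in RESPONSE_NAMES:
        if not np.issubdtype(df[name].dtype, np.number):
            bad = df.loc[pd.to_numeric(df[name], errors="coerce").isna()]
            raise DatasetValidationError(
                f"non-numeric cell in column {name!r} at row "
                f"{bad.index[0] if len(bad) else '?'}"
            )
    df = df[DATASET_COLUMNS]
    validate_dataset(df)
    df.attrs["kp_note"] = KP_NOTE
    return df
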