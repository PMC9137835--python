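"""Response catalog and categorical design space for larval-meal rearing experiments.

The experiment is a 2 x 3 x 3 factorial: insect species (*Tenebrio molitor* TM,
*Zophobas morio* ZM), rearing substrate (carrot, cabbage, or a mixture of
cabbage + carrot + flaxseed) and harvest time (90, 97 or 104 days). Each of the
18 conditions is characterised by 23 nutritional responses grouped into
proximate composition, essential amino acids, minerals and fatty acids.

In the multi-objective optimization all responses are maximized except crude
ash and the n6/n3 fatty-acid ratio, which are minimized (a low omega-6 to
omega-3 ratio is nutritionally preferable).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator

SPECIES_LEVELS: tuple[str, ...] = ("TM", "ZM")
SUBSTRATE_LEVELS: tuple[str, ...] = ("carrot", "cabbage", "mixture")
HARVEST_LEVELS: tuple[int, ...] = (90, 97, 104)

#: groups in catalog order
GROUPS: tuple[str, ...] = ("proximate", "amino_acid", "mineral", "fatty_acid")

MAXIMIZE = "maximize"
MINIMIZE = "minimize"


@dataclass(frozen=True)
class ResponseEntry:
    """One measured nutritional response variable."""

    name: str
    group: str
    unit: str
    direction_in_moo: str


#: The 23 modelled responses: 6 proximate, 9 amino acids (% of protein),
#: 5 minerals (mg/100 g dry matter), 3 fatty-acid variables. Exactly crude
#: ash and n6/n3 are minimized.
RESPONSE_CATALOG: tuple[ResponseEntry, ...] = (
    ResponseEntry("yield", "proximate", "g", MAXIMIZE),
    ResponseEntry("protein", "proximate", "%", MAXIMIZE),
    ResponseEntry("crude_fat", "proximate", "%", MAXIMIZE),
    ResponseEntry("crude_ash", "proximate", "%", MINIMIZE),
    ResponseEntry("crude_fiber", "proximate", "%", MAXIMIZE),
    ResponseEntry("digestibility", "proximate", "%", MAXIMIZE),
    ResponseEntry("Thr", "amino_acid", "% of protein", MAXIMIZE),
    ResponseEntry("Val", "amino_acid", "% of protein", MAXIMIZE),
    ResponseEntry("Met", "amino_acid", "% of protein", MAXIMIZE),
    ResponseEntry("Ile", "amino_acid", "% of protein", MAXIMIZE),
    ResponseEntry("Leu", "amino_acid", "% of protein", MAXIMIZE),
    ResponseEntry("Tyr", "amino_acid", "% of protein", MAXIMIZE),
    ResponseEntry("Phe", "amino_acid", "% of protein", MAXIMIZE),
    ResponseEntry("His", "amino_acid", "% of protein", MAXIMIZE),
    ResponseEntry("Lys", "amino_acid", "% of protein", MAXIMIZE),
    ResponseEntry("Ca", "mineral", "mg/100 g", MAXIMIZE),
    ResponseEntry("K", "mineral", "mg/100 g", MAXIMIZE),
    ResponseEntry("Mg", "mineral", "mg/100 g", MAXIMIZE),
    ResponseEntry("Na", "mineral", "mg/100 g", MAXIMIZE),
    ResponseEntry("P", "mineral", "mg/100 g", MAXIMIZE),
    ResponseEntry("C18_2n6c", "fatty_acid", "% of total FA", MAXIMIZE),
    ResponseEntry("C18_3n3", "fatty_acid", "% of total FA", MAXIMIZE),
    ResponseEntry("n6_n3", "fatty_acid", "ratio", MINIMIZE),
)

RESPONSE_NAMES: tuple[str, ...] = tuple(e.name for e in RESPONSE_CATALOG)

#: responses expressed as percentages, bounded in [0, 100]
PERCENT_RESPONSES: frozenset[str] = frozenset(
    e.name for e in RESPONSE_CATALOG if e.unit.startswith("%")
)


def responses_in_group(group: str) -> tuple[str, ...]:
    """Names of the catalog responses belonging to one output group."""
    if group not in GROUPS:
        raise ValueError(f"unknown response group {group!r}; expected one of {GROUPS}")
    return tuple(e.name for e in RESPONSE_CATALOG if e.group == group)


def direction_of(name: str) -> str:
    for e in RESPONSE_CATALOG:
        if e.name == name:
            return e.direction_in_moo
    raise KeyError(f"unknown response {name!r}")


@dataclass(frozen=True, order=True)
class DesignPoint:
    """One categorical rearing condition (species, substrate, harvest time)."""

    species: str
    substrate: str
    harvest_days: int

    def __post_init__(self) -> None:
        if self.species not in SPECIES_LEVELS:
            raise ValueError(
                f"species must be one of {SPECIES_LEVELS}, got {self.species!r}"
            )
        if self.substrate not in SUBSTRATE_LEVELS:
            raise ValueError(
                f"substrate must be one of {SUBSTRATE_LEVELS}, got {self.substrate!r}"
            )
        if self.harvest_days not in HARVEST_LEVELS:
            raise ValueError(
                f"harvest_days must be one of {HARVEST_LEVELS}, got {self.harvest_days!r}"
            )

    def label(self) -> str:
        return f"{self.species}/{self.substrate}/{self.harvest_days}d"


def design_space() -> tuple[DesignPoint, ...]:
    """All 18 rearing conditions in documented level order."""
    return tuple(
        DesignPoint(sp, sub, t)
        for sp, sub, t in product(SPECIES_LEVELS, SUBSTRATE_LEVELS, HARVEST_LEVELS)
    )


def iter_design_space() -> Iterator[DesignPoint]:
    yield from design_space()
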