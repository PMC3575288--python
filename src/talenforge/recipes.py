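"""Golden Gate assembly recipes for TALEN arms.

An RVD string is turned into a plasmid pick list for a one-pot Golden Gate
reaction: positions 1..n-1 draw the slot-specific array-module plasmid for
that RVD and the final RVD draws the last-half-repeat plasmid.  The kit
layout (naming scheme, slots per sub-array, supported repeat counts) is a
YAML data file so kit revisions need no code change.  Pipetting volumes
come from a local reagent-concentration table: volume = target mass /
stock concentration, rounded to 0.1 uL.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

from .rvd import RVD_TO_BASE

#: Equimolar target mass per module plasmid (ng); configurable per call.
DEFAULT_TARGET_MASS_NG = 75.0


class RecipeError(ValueError):
    pass


@dataclass(frozen=True)
class KitLayout:
    name: str
    min_rvds: int
    max_rvds: int
    slots_per_array: int
    module_plasmid: str  # format with {rvd} and {slot}
    last_repeat_plasmid: str  # format with {rvd}

    @classmethod
    def from_yaml(cls, text: str) -> "KitLayout":
        d = yaml.safe_load(text)
        return cls(
            name=d["name"],
            min_rvds=int(d["min_rvds"]),
            max_rvds=int(d["max_rvds"]),
            slots_per_array=int(d["slots_per_array"]),
            module_plasmid=d["module_plasmid"],
            last_repeat_plasmid=d["last_repeat_plasmid"],
        )


def load_default_layout() -> KitLayout:
    text = resources.files("talenforge.data").joinpath("kit_layout.yaml").read_text()
    return KitLayout.from_yaml(text)


@dataclass(frozen=True)
class ReagentTable:
    """Plasmid -> stock concentration (ng/uL)."""

    concentrations: dict

    def __post_init__(self):
        for plasmid, conc in self.concentrations.items():
            if conc <= 0:
                raise RecipeError(f"reagent table: non-positive concentration for {plasmid!r}")

    @classmethod
    def from_text(cls, text: str) -> "ReagentTable":
        conc = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[\t,]", line)
            if len(parts) != 2:
                raise RecipeError(f"bad reagent line: {line!r}")
            conc[parts[0].strip()] = float(parts[1])
        return cls(conc)


def load_default_reagents() -> ReagentTable:
    return ReagentTable.from_text(resources.files("talenforge.data").joinpath("reagents.tsv").read_text())


@dataclass(frozen=True)
class RecipeRow:
    position: int
    plasmid: str
    volume_uL: float
    mass_ng: float


def pick_modules(rvds, layout: KitLayout | None = None) -> list:
    """Map an RVD string to its ordered plasmid pick list.

    Positions 1..n-1 use the array-module plasmid of their slot (slots
    cycle per sub-array); the final RVD uses the last-half-repeat plasmid.
    """
    layout = layout or load_default_layout()
    rvds = list(rvds)
    n = len(rvds)
    if not layout.min_rvds <= n <= layout.max_rvds:
        raise RecipeError(
            f"{n} RVDs outside the kit-supported range {layout.min_rvds}..{layout.max_rvds}"
        )
    for code in rvds:
        if code not in RVD_TO_BASE:
            raise RecipeError(f"unknown RVD code {code!r}")
    picks = []
    for i, code in enumerate(rvds[:-1], start=1):
        slot = (i - 1) % layout.slots_per_array + 1
        picks.append((i, layout.module_plasmid.format(rvd=code, slot=slot)))
    picks.append((n, layout.last_repeat_plasmid.format(rvd=rvds[-1])))
    return picks


def compute_volumes(picks, table: ReagentTable, target_mass_ng: float = DEFAULT_TARGET_MASS_NG) -> list:
    """Convert a pick list to pipetting volumes from local stock
    concentrations.  Volumes round to 0.1 uL and floor at 0.1 uL (with a
    warning: such stocks should be pre-diluted)."""
    if target_mass_ng <= 0:
        raise RecipeError("target mass must be > 0")
    rows = []
    for position, plasmid in picks:
        if plasmid not in table.concentrations:
            raise RecipeError(f"reagent table has no entry for plasmid {plasmid!r}")
        conc = table.concentrations[plasmid]
        volume = round(target_mass_ng / conc, 1)
        if volume < 0.1:
            warnings.warn(
                f"{plasmid}: {target_mass_ng} ng needs under 0.1 uL at {conc} ng/uL; "
                "volume floored to 0.1 uL (consider diluting the stock)",
                UserWarning,
            )
            volume = 0.1
        rows.append(RecipeRow(position=position, plasmid=plasmid, volume_uL=volume, mass_ng=target_mass_ng))
    return rows


def render_recipe_csv(rows) -> str:
    lines = ["position,plasmid,volume_uL,mass_ng"]
    for r in rows:
        lines.append(f"{r.position},{r.plasmid},{r.volume_uL},{r.mass_ng}")
    return "\n".join(lines) + "\n"
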