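"""Plate layouts emulating the plasma-exposure study design.

The design: three clinical groups — healthy controls (HC), compensated
cirrhosis (CC) and decompensated cirrhosis with hypoalbuminemia (DC) — each
contributing plasma samples that are exposed to endothelial monolayers in
replicate wells of 96-well plates. Albumin supplementation arms follow the
study protocol: DC plasma is additionally supplemented to physiological
albumin levels, HC plasma to supraphysiological levels, and CC plasma is
not supplemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("HC", "CC", "DC")
ARMS = ("none", "physiological", "supraphysiological")

#: Albumin arms run for each clinical group, per the exposure protocol.
GROUP_ARMS = {
    "HC": ("none", "supraphysiological"),
    "CC": ("none",),
    "DC": ("none", "physiological"),
}

_ROWS = "ABCDEFGH"
PLATE_CAPACITY = 96


class PlateCapacityError(ValueError):
    """Raised when a layout does not fit a single 96-well plate."""


@dataclass
class WellAssignment:
    well_id: str
    group: str
    albumin_arm: str
    sample_id: str
    replicate: int


@dataclass
class LayoutConfig:
    """Sizes of the plasma-exposure design.

    Defaults reproduce the study cohort: 20 samples per clinical group,
    three replicate wells per (sample, albumin arm) condition.
    """

    n_hc: int = 20
    n_cc: int = 20
    n_dc: int = 20
    replicates: int = 3
    group_arms: dict = field(default_factory=lambda: dict(GROUP_ARMS))

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_cc, self.n_dc) < 1:
            raise ValueError("each group needs at least one sample")
        if self.replicates < 1:
            raise ValueError("need at least one replicate well")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"HC": self.n_hc, "CC": self.n_cc, "DC": self.n_dc}

    def conditions(self) -> list[tuple[str, str, str]]:
        """All (sample_id, group, arm) conditions in a fixed order."""
        out = []
        for group in GROUPS:
            for i in range(self.group_sizes[group]):
                sample_id = f"{group}{i + 1:03d}"
                for arm in self.group_arms[group]:
                    out.append((sample_id, group, arm))
        return out

    @property
    def n_wells(self) -> int:
        return len(self.conditions()) * self.replicates


@dataclass
class PlateLayout:
    plate_id: str
    wells: list[WellAssignment]

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate well ids on plate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plate_id": self.plate_id,
                    "well_id": w.well_id,
                    "group": w.group,
                    "albumin_arm": w.albumin_arm,
                    "sample_id": w.sample_id,
                    "replicate": w.replicate,
                }
                for w in self.wells
            ]
        )


def well_name(index: int) -> str:
    """Row-major 96-well name for a 0-based index (0 -> 'A01')."""
    if not 0 <= index < PLATE_CAPACITY:
        raise ValueError("index outside the 96-well grid")
    return f"{_ROWS[index // 12]}{index % 12 + 1:02d}"


def _assignments(config: LayoutConfig, rng: np.random.Generator):
    """Condition wells in randomised plate order; replicates stay adjacent."""
    conds = config.conditions()
    order = rng.permutation(len(conds))
    out = []
    for k in order:
        sample_id, group, arm = conds[k]
        for rep in range(1, config.replicates + 1):
            out.append((sample_id, group, arm, rep))
    return out


def generate_plate_layout(
    config: LayoutConfig, seed: int, plate_id: str = "P1"
) -> PlateLayout:
    """Lay out the full design on a single 96-well plate.

    Condition order on the plate is randomised (seeded); the three replicate
    wells of a condition are kept adjacent, as they would be pipetted.
    Raises :class:`PlateCapacityError` if the design needs more than 96
    wells.
    """
    if config.n_wells > PLATE_CAPACITY:
        raise PlateCapacityError(
            f"design needs {config.n_wells} wells; a plate holds {PLATE_CAPACITY}"
        )
    rng = np.random.default_rng(seed)
    wells = [
        WellAssignment(well_name(i), group, arm, sample_id, rep)
        for i, (sample_id, group, arm, rep) in enumerate(_assignments(config, rng))
    ]
    return PlateLayout(plate_id, wells)


def generate_study_layout(config: LayoutConfig, seed: int) -> list[PlateLayout]:
    """Split a design that exceeds one plate across balanced plates.

    Replicate wells of a condition are never split across plates (plasma
    aliquots are exposed together), and all albumin arms of one plasma
    sample are kept on the same plate so that within-sample arm contrasts
    are never confounded with plate effects. Samples are dealt round-robin
    across plates within group strata, giving every plate a near-identical
    group composition — the balanced design that keeps per-plate
    normalisation from aliasing plate composition into condition effects.
    """
    rng = np.random.default_rng(seed)
    conds = config.conditions()
    conds_per_plate = PLATE_CAPACITY // config.replicates
    n_plates = int(np.ceil(len(conds) / conds_per_plate))

    # group conditions into per-sample blocks, shuffle within group strata,
    # then deal sample blocks across plates
    blocks: dict[str, list] = {}
    for cond in conds:
        blocks.setdefault(cond[0], []).append(cond)
    strata: dict[str, list] = {}
    for sample_id, block in blocks.items():
        strata.setdefault(block[0][1], []).append(block)
    plate_conds: list[list] = [[] for _ in range(n_plates)]
    cursor = 0
    for group in sorted(strata):
        sample_blocks = strata[group]
        order = rng.permutation(len(sample_blocks))
        for j in order:
            plate_conds[cursor % n_plates].extend(sample_blocks[j])
            cursor += 1
    if any(len(pc) > conds_per_plate for pc in plate_conds):
        raise PlateCapacityError("sample blocks do not fit the plate capacity")

    plates = []
    for p, chunk in enumerate(plate_conds):
        order = rng.permutation(len(chunk))  # randomise plate position
        wells = []
        i = 0
        for j in order:
            sample_id, group, arm = chunk[j]
            for rep in range(1, config.replicates + 1):
                wells.append(WellAssignment(well_name(i), group, arm, sample_id, rep))
                i += 1
        plates.append(PlateLayout(f"P{p + 1}", wells))
    return plates


def layout_frame(plates) -> pd.DataFrame:
    """Concatenate one or many plate layouts into a plate-map table."""
    if isinstance(plates, PlateLayout):
        plates = [plates]
    return pd.concat([p.to_frame() for p in plates], ignore_index=True)
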