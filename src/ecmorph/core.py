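"""Shared in-memory containers for the imaging pipeline.

The pipeline passes around two lightweight containers: :class:`FieldImage`,
one imaged microscope site with named fluorescence channels, and
:class:`LabelMask`, an integer label image produced by segmentation.
Channel access is always by name, never by storage position, so the order
in which channels were acquired or stored is irrelevant downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Canonical channel names used throughout the package.
CHANNELS = ("nuclei", "ve_cadherin", "f_actin", "mitochondria", "vwf")

#: Compartment tag associated with each fluorescence channel.
CHANNEL_COMPARTMENT = {
    "nuclei": "nucleus",
    "ve_cadherin": "junction",
    "f_actin": "actin",
    "mitochondria": "mitochondria",
    "vwf": "vwf",
}


@dataclass
class FieldImage:
    """One imaged site: named 2D intensity channels plus acquisition metadata.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2D non-negative intensity array
        (16-bit scale, stored as float or integer).
    pixel_size_um
        Lateral pixel size in micrometres; all area/length features are
        reported in physical units through this factor.
    field_id, well_id, site
        Identifiers linking the field to its plate position.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float = 0.33
    field_id: str = "F000"
    well_id: str = "A01"
    site: int = 1

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return np.asarray(first).shape

    def require(self, *names: str) -> None:
        """Raise ``KeyError`` unless all named channels are present."""
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"field {self.field_id} lacks channels {missing}")


@dataclass
class LabelMask:
    """Integer label image: 0 = background, k = object k.

    ``kind`` distinguishes nucleus masks from whole-cell masks; for cell
    masks every label region contains exactly one nucleus seed by
    construction of the seeded watershed.
    """

    labels: np.ndarray
    kind: str = "nuclei"  # {"nuclei", "cells"}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_objects(self) -> int:
        return int(len(np.setdiff1d(np.unique(self.labels), [0])))

    def label_ids(self) -> np.ndarray:
        return np.setdiff1d(np.unique(self.labels), [0])
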