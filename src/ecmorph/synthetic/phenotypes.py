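"""Phenotype parameterisation of the simulated endothelial response.

Each (clinical group, albumin arm) condition maps to a small set of
interpretable image-phenotype parameters. The encoded biology:

* disease raises mitochondrial fragmentation and perinuclear clustering,
  junction irregularity, actin stress-fibre content and vWF granule counts,
  with compensated cirrhosis intermediate between healthy and
  decompensated;
* physiological albumin supplementation of decompensated plasma restores
  the *mitochondrial* parameters to healthy levels but leaves junction and
  cytoskeletal remodelling at disease levels;
* supraphysiological albumin added to healthy plasma changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .layout import ARMS, GROUPS


@dataclass(frozen=True)
class PhenotypeParams:
    """Bounded knobs of the field renderer and latent-effect generator.

    ``mito_fragmentation``: 0 = tubular network, 1 = fully punctate.
    ``mito_perinuclear``: fraction of mitochondrial signal biased into the
    perinuclear annulus. ``junction_irregularity`` and ``actin_stress``
    control VE-cadherin border gaps/roughness and stress-fibre density.
    ``wpb_count_mean``: mean Weibel-Palade-body (vWF puncta) count per
    cell. ``cell_density``: cells per field. ``intensity_snr``: signal to
    noise of the rendered channels (``inf`` = noiseless).
    """

    mito_fragmentation: float
    mito_perinuclear: float
    junction_irregularity: float
    actin_stress: float
    wpb_count_mean: float
    cell_density: float = 45.0
    intensity_snr: float = 12.0

    def __post_init__(self) -> None:
        for name in (
            "mito_fragmentation",
            "mito_perinuclear",
            "junction_irregularity",
            "actin_stress",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.wpb_count_mean < 0:
            raise ValueError("wpb_count_mean must be >= 0")
        if self.cell_density <= 0:
            raise ValueError("cell_density must be positive")
        if not self.intensity_snr > 0:
            raise ValueError("intensity_snr must be positive")


_BASE = {
    "HC": PhenotypeParams(
        mito_fragmentation=0.15,
        mito_perinuclear=0.20,
        junction_irregularity=0.10,
        actin_stress=0.10,
        wpb_count_mean=4.0,
    ),
    "CC": PhenotypeParams(
        mito_fragmentation=0.45,
        mito_perinuclear=0.45,
        junction_irregularity=0.40,
        actin_stress=0.40,
        wpb_count_mean=6.0,
    ),
    "DC": PhenotypeParams(
        mito_fragmentation=0.80,
        mito_perinuclear=0.80,
        junction_irregularity=0.70,
        actin_stress=0.70,
        wpb_count_mean=9.0,
    ),
}


def default_phenotype(group: str, albumin_arm: str = "none") -> PhenotypeParams:
    """Phenotype parameters for a (group, albumin arm) condition.

    DC + physiological albumin returns the mitochondrial parameters to HC
    levels while junction and actin remodelling stay at DC levels; HC +
    supraphysiological albumin is identical to untreated HC.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if albumin_arm not in ARMS:
        raise ValueError(f"unknown albumin arm {albumin_arm!r}")
    base = _BASE[group]
    if albumin_arm == "none":
        return base
    if group == "HC" and albumin_arm == "supraphysiological":
        return base
    if group == "DC" and albumin_arm == "physiological":
        hc = _BASE["HC"]
        return replace(
            base,
            mito_fragmentation=hc.mito_fragmentation,
            mito_perinuclear=hc.mito_perinuclear,
        )
    raise ValueError(f"arm {albumin_arm!r} is not part of the design for {group}")
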