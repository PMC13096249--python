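"""Direct simulation of single-cell feature tables, OCR traces and cohorts.

The feature-table generator is a latent-factor model: each cell's feature
vector is ``loadings @ factor_scores + noise``, with factor scores drawn
around condition-specific means. It is the fast stand-in for the full
render → segment → featurize path: it produces tables with the same
statistical structure the profiling stage consumes (correlated feature
blocks, compartment tags, plate batch offsets, per-sample and per-well
random effects) with known ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import LayoutConfig, PlateLayout, layout_frame
from .phenotypes import default_phenotype

METADATA_COLUMNS = (
    "plate_id",
    "well_id",
    "group",
    "albumin_arm",
    "sample_id",
    "replicate",
    "cell_id",
)

#: Cellular compartment attributed to each leading latent factor. The first
#: factors carry the biology (mitochondria, vWF granules, junctions, actin);
#: later factors are nuisance structure tagged nucleus/cell.
FACTOR_COMPARTMENTS = ("mitochondria", "vwf", "junction", "actin", "nucleus")

#: Latent effect size (in within-condition factor-score SD units) reached by
#: the decompensated group on each biological factor, relative to healthy.
EFFECT_SCALES = {"mitochondria": 4.0, "vwf": 1.0, "junction": 1.6, "actin": 1.6}


@dataclass
class LatentFactorSpec:
    """Generative latent-factor model for single-cell features.

    ``loading_matrix`` is features x factors; ``unique_variances`` the
    per-feature independent noise variances; ``group_factor_means`` maps a
    (group, albumin_arm) condition to a factor-mean vector (``None`` means
    all conditions centred at zero).
    """

    n_factors: int
    n_features: int
    loading_matrix: np.ndarray
    unique_variances: np.ndarray
    group_factor_means: dict | None = None
    feature_names: list = field(default_factory=list)
    feature_tags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        self.unique_variances = np.asarray(self.unique_variances, dtype=float)
        if self.loading_matrix.shape != (self.n_features, self.n_factors):
            raise ValueError("loading_matrix shape mismatch")
        if not np.isfinite(self.loading_matrix).all():
            raise ValueError("non-finite loadings")
        if (self.unique_variances < 0).any():
            raise ValueError("unique variances must be non-negative")
        if not self.feature_names:
            self.feature_names = [f"feat{i:03d}" for i in range(self.n_features)]
        if not self.feature_tags:
            self.feature_tags = ["cell"] * self.n_features

    def tags_map(self) -> dict[str, str]:
        return dict(zip(self.feature_names, self.feature_tags))


def factor_compartment(k: int) -> str:
    return FACTOR_COMPARTMENTS[k] if k < len(FACTOR_COMPARTMENTS) else "cell"


def default_group_factor_means(n_factors: int) -> dict:
    """Condition factor means derived from the default phenotypes.

    The decompensated group sits :data:`EFFECT_SCALES` score units from
    healthy on each biological factor; intermediate phenotypes interpolate
    linearly between the healthy and decompensated parameter values, so the
    albumin-restoration contract of :func:`default_phenotype` (mitochondria
    back to healthy, junction/actin unchanged) carries through to factor
    space automatically.
    """
    hc, dc = default_phenotype("HC"), default_phenotype("DC")

    def axis(p, attr_pairs):
        parts = []
        for attr in attr_pairs:
            lo, hi = getattr(hc, attr), getattr(dc, attr)
            parts.append((getattr(p, attr) - lo) / (hi - lo))
        return float(np.mean(parts))

    conditions = [
        ("HC", "none"),
        ("HC", "supraphysiological"),
        ("CC", "none"),
        ("DC", "none"),
        ("DC", "physiological"),
    ]
    means = {}
    for group, arm in conditions:
        p = default_phenotype(group, arm)
        v = np.zeros(n_factors)
        if n_factors > 0:
            v[0] = EFFECT_SCALES["mitochondria"] * axis(
                p, ("mito_fragmentation", "mito_perinuclear")
            )
        if n_factors > 1:
            v[1] = EFFECT_SCALES["vwf"] * axis(p, ("wpb_count_mean",))
        if n_factors > 2:
            v[2] = EFFECT_SCALES["junction"] * axis(p, ("junction_irregularity",))
        if n_factors > 3:
            v[3] = EFFECT_SCALES["actin"] * axis(p, ("actin_stress",))
        means[(group, arm)] = v
    return means


def default_latent_spec(
    n_factors: int = 11,
    n_features: int = 110,
    common_variance: float = 0.82,
    seed: int = 0,
    group_effects: bool = True,
) -> LatentFactorSpec:
    """Simple-structure latent spec calibrated to a target communality.

    Features are assigned round-robin to factors; each feature loads
    ``sqrt(c_i)`` on its factor with communality ``c_i`` jittered around
    ``common_variance`` and unique variance ``1 - c_i``, so the common
    factors explain about ``common_variance`` of the total (standardised)
    within-condition variance.
    """
    rng = np.random.default_rng(seed)
    comm = np.clip(
        rng.uniform(common_variance - 0.04, common_variance + 0.04, n_features),
        0.0,
        0.99,
    )
    loadings = np.zeros((n_features, n_factors))
    tags, names = [], []
    for i in range(n_features):
        k = i % n_factors
        loadings[i, k] = np.sqrt(comm[i])
        tag = factor_compartment(k)
        tags.append(tag)
        names.append(f"{tag}_feat{i:03d}")
    return LatentFactorSpec(
        n_factors=n_factors,
        n_features=n_features,
        loading_matrix=loadings,
        unique_variances=1.0 - comm,
        group_factor_means=default_group_factor_means(n_factors)
        if group_effects
        else None,
        feature_names=names,
        feature_tags=tags,
    )


def generate_feature_table(
    spec: LatentFactorSpec,
    cells_per_well: int,
    layout,
    seed: int,
    sample_effect_sd: float = 0.35,
    well_effect_sd: float = 0.15,
    plate_offset_sd: float = 0.25,
) -> pd.DataFrame:
    """Draw a single-cell feature table for every well of a layout.

    Factor scores per cell are ``condition mean + sample effect + well
    effect + N(0, 1)``; sample effects are drawn once per plasma sample and
    shared across albumin arms (the same plasma is split across arms), which
    is what makes paired per-factor tests between arms well-posed. Plate
    batch effects are independent per-feature intensity offsets, removed
    downstream by per-plate z-scoring.
    """
    if cells_per_well < 1:
        raise ValueError("cells_per_well must be >= 1")
    if isinstance(layout, (PlateLayout, list)):
        layout = layout_frame(layout)
    rng = np.random.default_rng(seed)
    k, p = spec.n_factors, spec.n_features

    sample_ids = sorted(layout["sample_id"].unique())
    sample_eff = {
        s: rng.normal(0.0, sample_effect_sd, k) for s in sample_ids
    }
    plate_ids = sorted(layout["plate_id"].unique())
    plate_off = {pl: rng.normal(0.0, plate_offset_sd, p) for pl in plate_ids}

    blocks, meta_rows = [], []
    for row in layout.itertuples(index=False):
        cond = (row.group, row.albumin_arm)
        mean = np.zeros(k)
        if spec.group_factor_means is not None:
            mean = np.asarray(spec.group_factor_means[cond], dtype=float)
        well_eff = rng.normal(0.0, well_effect_sd, k)
        scores = mean + sample_eff[row.sample_id] + well_eff + rng.normal(
            0.0, 1.0, (cells_per_well, k)
        )
        noise = rng.normal(0.0, 1.0, (cells_per_well, p)) * np.sqrt(
            spec.unique_variances
        )
        x = scores @ spec.loading_matrix.T + noise + plate_off[row.plate_id]
        blocks.append(x)
        for c in range(cells_per_well):
            meta_rows.append(
                (
                    row.plate_id,
                    row.well_id,
                    row.group,
                    row.albumin_arm,
                    row.sample_id,
                    row.replicate,
                    c + 1,
                )
            )
    meta = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    feats = pd.DataFrame(np.vstack(blocks), columns=spec.feature_names)
    return pd.concat([meta, feats], axis=1)


# ---------------------------------------------------------------------------
# OCR traces

DEFAULT_OCR_LEVELS = {
    "baseline": 90.0,
    "glucose": 100.0,
    "oligomycin": 40.0,
    "fccp": 180.0,
    "rot_aa": 20.0,
}


def generate_ocr_trace(
    phase_levels: dict,
    noise_sd: float = 2.0,
    n_per_phase: int = 3,
    cell_count: int = 6000,
    seed: int = 0,
    well_id: str = "A01",
    interval_min: float = 6.5,
):
    """Piecewise-constant OCR trace with Gaussian measurement noise.

    ``phase_levels`` must contain the four injection phases (glucose,
    oligomycin, fccp, rot_aa); a pre-glucose baseline level defaults to the
    glucose level when omitted. Returns an
    :class:`~ecmorph.mitofunction.OCRTrace`.
    """
    from ..mitofunction import PHASE_ORDER, REQUIRED_PHASES, OCRTrace

    missing = [ph for ph in REQUIRED_PHASES if ph not in phase_levels]
    if missing:
        raise ValueError(f"phase levels missing for {missing}")
    levels = dict(phase_levels)
    levels.setdefault("baseline", levels["glucose"])
    if any(v < 0 for v in levels.values()):
        raise ValueError("OCR levels must be non-negative")
    if n_per_phase < 1:
        raise ValueError("n_per_phase must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    for ph in PHASE_ORDER:
        for _ in range(n_per_phase):
            ocr = levels[ph] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"time_min": t, "phase": ph, "ocr": ocr})
            t += interval_min
    return OCRTrace(pd.DataFrame(rows), well_id=well_id, cell_count=cell_count)


# ---------------------------------------------------------------------------
# Clinical cohort tables


def generate_cohort_table(
    group_sizes: dict,
    categorical_specs: dict,
    continuous_specs: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient cohort table with Bernoulli flags and log-normal labs.

    ``categorical_specs``: variable -> {group: probability of the flag}.
    ``continuous_specs``: variable -> {group: (median, sigma_log)} — values
    are drawn log-normal around the group median.
    """
    for var, probs in categorical_specs.items():
        for g, pr in probs.items():
            if not 0.0 <= pr <= 1.0:
                raise ValueError(f"probability {pr} for {var}/{g} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for group, n in group_sizes.items():
        for _ in range(n):
            pid += 1
            rec = {"patient_id": f"PT{pid:03d}", "group": group}
            for var, probs in categorical_specs.items():
                rec[var] = int(rng.random() < probs[group])
            for var, params in continuous_specs.items():
                median, sigma = params[group]
                rec[var] = float(median * np.exp(rng.normal(0.0, sigma)))
            rows.append(rec)
    return pd.DataFrame(rows)
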