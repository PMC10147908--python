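"""Reference parameters for the four uveal melanocyte archetypes.

Normal choroidal melanocytes and the three classical tumor cell types
(epithelioid, spindle A, spindle B) are described by per-feature Gaussian
moments (mean, SD) of nuclear morphometry and calibrated optical densities,
plus per-compartment mixing proportions. These parameters drive the
synthetic-data generator and the cluster-to-archetype matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ("normal", "epithelioid", "spindleA", "spindleB")
COMPARTMENTS = ("normal_choroid", "nevus", "primary_tumor", "metastasis")
REGIONS = ("base", "center", "apex")

#: features carried by the archetype table (Gaussian mean/SD per type)
ARCHETYPE_FEATURES = (
    "nucleus_area",
    "nucleus_circularity",
    "nbap1_od",
    "cytoplasm_bap1_od",
    "membrane_igf1r_od",
    "cytoplasm_ido_od",
    "cytoplasm_tigit_od",
)

#: the four-feature subset that best separates the cell types
CLUSTER_FEATURES = (
    "nucleus_area",
    "nucleus_circularity",
    "nbap1_od",
    "cytoplasm_bap1_od",
)

#: all ten per-cell morphometric / staining features
ALL_FEATURES = (
    "nucleus_area",
    "nucleus_perimeter",
    "nucleus_circularity",
    "nucleus_max_caliper",
    "nucleus_min_caliper",
    "nucleus_eccentricity",
    "hematoxylin_mean_od",
    "nbap1_od",
    "cytoplasm_bap1_od",
    "nucleus_to_cell_ratio",
)

#: published per-compartment cell counts of the reference cohort
COMPARTMENT_CELL_COUNTS = {
    "normal_choroid": 57_255,
    "nevus": 18_276,
    "primary_tumor": 1_028_086,
    "metastasis": 141_794,
}
TOTAL_CELL_COUNT = 1_245_411

# per-type feature moments: {feature: {type: (mean, sd)}}; NaN = not expressed
_MOMENTS = {
    "nucleus_area": {
        "normal": (21.80, 12.13),
        "epithelioid": (23.10, 10.44),
        "spindleA": (22.38, 9.89),
        "spindleB": (33.07, 15.52),
    },
    "nucleus_circularity": {
        "normal": (0.62, 0.16),
        "epithelioid": (0.84, 0.06),
        "spindleA": (0.68, 0.13),
        "spindleB": (0.61, 0.10),
    },
    "nbap1_od": {
        "normal": (0.22, 0.15),
        "epithelioid": (0.11, 0.15),
        "spindleA": (0.46, 0.19),
        "spindleB": (0.08, 0.14),
    },
    "cytoplasm_bap1_od": {
        "normal": (0.28, 0.17),
        "epithelioid": (0.27, 0.12),
        "spindleA": (0.55, 0.21),
        "spindleB": (0.23, 0.11),
    },
    "membrane_igf1r_od": {
        "normal": (np.nan, np.nan),
        "epithelioid": (0.15, 0.10),
        "spindleA": (0.14, 0.09),
        "spindleB": (0.14, 0.09),
    },
    "cytoplasm_ido_od": {
        "normal": (np.nan, np.nan),
        "epithelioid": (0.19, 0.17),
        "spindleA": (0.17, 0.16),
        "spindleB": (0.14, 0.16),
    },
    "cytoplasm_tigit_od": {
        "normal": (np.nan, np.nan),
        "epithelioid": (0.31, 0.14),
        "spindleA": (0.29, 0.12),
        "spindleB": (0.27, 0.12),
    },
}

# mixing proportions pi(type | compartment)
_PROPORTIONS = {
    "normal_choroid": {"normal": 0.82, "spindleA": 0.18},
    "nevus": {"normal": 0.47, "spindleA": 0.53},
    "primary_tumor": {"epithelioid": 0.45, "spindleA": 0.23, "spindleB": 0.32},
    "metastasis": {"epithelioid": 0.69, "spindleB": 0.31},
}

# region-resolved proportions inside primary tumors: epithelioid and spindle B
# enriched at base/apex, spindle A centrally; equal thirds average back to the
# compartment-level proportions (exact region magnitudes are a design choice).
_REGION_PROPORTIONS = {
    "base": {"epithelioid": 0.50, "spindleA": 0.145, "spindleB": 0.355},
    "center": {"epithelioid": 0.35, "spindleA": 0.40, "spindleB": 0.25},
    "apex": {"epithelioid": 0.50, "spindleA": 0.145, "spindleB": 0.355},
}


@dataclass(frozen=True)
class ArchetypeTable:
    """Gaussian feature moments and compartment mixing for the cell types.

    Attributes
    ----------
    means, sds : pandas.DataFrame
        Indexed by cell type, one column per archetype feature. NaN marks a
        marker the type does not express.
    proportions : dict
        ``{compartment: {cell_type: pi}}``, each inner dict summing to 1.
    region_proportions : dict
        ``{region: {cell_type: pi}}`` for primary tumors.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    proportions: dict[str, dict[str, float]]
    region_proportions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sds = self.sds.to_numpy(dtype=float)
        if np.any(sds[np.isfinite(sds)] <= 0):
            raise ValueError("archetype SDs must be positive")
        for comp, mix in self.proportions.items():
            vals = np.asarray(list(mix.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1) or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"proportions for {comp!r} must lie in [0,1] and sum to 1")
            unknown = set(mix) - set(self.means.index)
            if unknown:
                raise ValueError(f"unknown cell types in {comp!r}: {sorted(unknown)}")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(self.means.index)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.means.columns)

    def mixing(self, compartment: str, region: str | None = None) -> dict[str, float]:
        """Mixing proportions for a compartment (optionally region-resolved)."""
        if compartment not in self.proportions:
            raise KeyError(
                f"unknown compartment {compartment!r}; valid: {sorted(self.proportions)}"
            )
        if region is not None and compartment == "primary_tumor" and self.region_proportions:
            if region not in self.region_proportions:
                raise KeyError(
                    f"unknown region {region!r}; valid: {sorted(self.region_proportions)}"
                )
            return dict(self.region_proportions[region])
        return dict(self.proportions[compartment])


def default_archetypes() -> ArchetypeTable:
    """The reference archetype table used throughout the pipeline."""
    means = pd.DataFrame(
        {f: {t: _MOMENTS[f][t][0] for t in CELL_TYPES} for f in ARCHETYPE_FEATURES}
    ).loc[list(CELL_TYPES)]
    sds = pd.DataFrame(
        {f: {t: _MOMENTS[f][t][1] for t in CELL_TYPES} for f in ARCHETYPE_FEATURES}
    ).loc[list(CELL_TYPES)]
    return ArchetypeTable(
        means=means,
        sds=sds,
        proportions={c: dict(p) for c, p in _PROPORTIONS.items()},
        region_proportions={r: dict(p) for r, p in _REGION_PROPORTIONS.items()},
    )
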