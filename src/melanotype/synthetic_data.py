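"""Synthetic melanocyte cohorts: feature tables and rendered stained scenes.

Each cell type is an independent-Gaussian feature component (means/SDs from
the archetype table), truncated to its physical domain by clipping; cell
types are drawn i.i.d. from per-compartment mixing proportions. Shape
features not carried by the archetype table (perimeter, calipers,
eccentricity, nucleus:cell ratio) are derived from an ellipse with the
sampled area and circularity, plus configurable noise. Scenes are rendered
under a Beer–Lambert stain model so that segmentation and morphometry can be
validated against generating ground truth.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .archetypes import ALL_FEATURES, ArchetypeTable, default_archetypes

__all__ = [
    "CohortConfig",
    "SpecimenConfig",
    "SyntheticScene",
    "sample_feature_table",
    "derive_shape_params",
    "ellipse_axis_ratio_from_circularity",
    "ramanujan_perimeter",
    "render_scene",
    "make_cohort",
    "default_cohort_config",
    "clipped_normal_mean",
]

#: (low, high) physical domain per feature; None = unbounded.
_FEATURE_DOMAINS = {
    "nucleus_area": (1.0, None),  # µm²; floor keeps the ellipse inversion defined
    "nucleus_circularity": (0.05, 1.0),
    "nbap1_od": (0.0, None),
    "cytoplasm_bap1_od": (0.0, None),
    "membrane_igf1r_od": (0.0, None),
    "cytoplasm_ido_od": (0.0, None),
    "cytoplasm_tigit_od": (0.0, None),
}

#: background half-normal scale for markers a type does not express
_ABSENT_MARKER_SCALE = 0.02


# ---------------------------------------------------------------------------
# ellipse geometry: invert (area, circularity) -> semi-axes
# ---------------------------------------------------------------------------

def ramanujan_perimeter(a, b):
    """Ramanujan's second approximation to the perimeter of an ellipse."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def _circularity_of_ratio(t):
    """Circularity 4πA/P² of an ellipse with axis ratio t = b/a ∈ (0, 1]."""
    t = np.asarray(t, dtype=float)
    area = np.pi * t  # a = 1, b = t
    per = ramanujan_perimeter(np.ones_like(t), t)
    return 4.0 * np.pi * area / per**2


# monotone lookup ratio -> circularity, inverted by interpolation
_RATIO_GRID = np.linspace(1e-4, 1.0, 4001)
_CIRC_GRID = _circularity_of_ratio(_RATIO_GRID)


def ellipse_axis_ratio_from_circularity(circularity):
    """Axis ratio b/a of the ellipse whose circularity matches (vectorized)."""
    c = np.asarray(circularity, dtype=float)
    if np.any(c <= 0) or np.any(c > 1):
        raise ValueError("circularity must lie in (0, 1]")
    return np.interp(c, _CIRC_GRID, _RATIO_GRID)


def derive_shape_params(nucleus_area, nucleus_circularity, orientation=0.0):
    """Invert area (µm²) and circularity to ellipse semi-axes (a ≥ b, µm).

    The returned ellipse satisfies πab = area exactly, and its Ramanujan
    perimeter reproduces the requested circularity to better than 1e-3.
    """
    area = np.asarray(nucleus_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("nucleus_area must be positive")
    t = ellipse_axis_ratio_from_circularity(nucleus_circularity)
    ab = area / np.pi
    a = np.sqrt(ab / t)
    b = a * t
    return a, b, np.broadcast_to(np.asarray(orientation, dtype=float), a.shape if a.ndim else ())


def clipped_normal_mean(mu, sd, lo=None, hi=None):
    """Analytic mean of a Normal(mu, sd) clipped (not resampled) to [lo, hi]."""
    from scipy.stats import norm

    mean = mu
    if lo is not None:
        alpha = (lo - mu) / sd
        mean = mean + sd * norm.pdf(alpha) + (lo - mu) * norm.cdf(alpha)
    if hi is not None:
        beta = (hi - mu) / sd
        mean = mean - sd * norm.pdf(beta) + (hi - mu) * norm.sf(beta)
    return mean


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    """Relative/additive noise applied to ellipse-derived features."""

    derived_rel_sd: float = 0.02      # perimeter and calipers, multiplicative
    eccentricity_sd: float = 0.01     # additive
    ratio_rel_sd: float = 0.05        # nucleus:cell ratio, multiplicative
    hematoxylin_mean: float = 0.45
    hematoxylin_sd: float = 0.20
    pixel_noise_sd: float = 2.0       # rendered image, intensity counts


def sample_feature_table(
    archetypes: ArchetypeTable,
    compartment: str,
    n: int,
    seed: int | np.random.Generator | None = None,
    *,
    region: str | None = None,
    specimen_id: str = "S0",
    noise: NoiseParams | None = None,
    cell_expansion_um: float = 3.5,
) -> pd.DataFrame:
    """Draw ``n`` cells from the compartment's mixture of type components.

    Returns one row per cell with the ten morphometric/staining features,
    the three extra marker ODs, identifiers, and the generating cell type in
    a ``true_type`` column (hidden ground truth, not a measured feature).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = noise or NoiseParams()
    mix = archetypes.mixing(compartment, region)  # raises on unknown labels
    types = list(mix)
    probs = np.asarray([mix[t] for t in types], dtype=float)
    draw = rng.choice(len(types), size=n, p=probs)
    type_labels = np.asarray(types, dtype=object)[draw]

    cols: dict[str, np.ndarray] = {}
    for feat in archetypes.features:
        mu = archetypes.means.loc[:, feat].reindex(types).to_numpy()[draw]
        sd = archetypes.sds.loc[:, feat].reindex(types).to_numpy()[draw]
        x = np.where(
            np.isfinite(mu),
            mu + sd * rng.standard_normal(n),
            np.abs(rng.standard_normal(n)) * _ABSENT_MARKER_SCALE,
        )
        lo, hi = _FEATURE_DOMAINS.get(feat, (None, None))
        cols[feat] = np.clip(x, lo, hi)

    # ellipse-derived shape features
    if n:
        a, b, _ = derive_shape_params(cols["nucleus_area"], cols["nucleus_circularity"])
    else:
        a = b = np.empty(0)
    rel = lambda scale: 1.0 + scale * rng.standard_normal(n)
    cols["nucleus_perimeter"] = ramanujan_perimeter(a, b) * rel(noise.derived_rel_sd)
    cols["nucleus_max_caliper"] = 2.0 * a * rel(noise.derived_rel_sd)
    cols["nucleus_min_caliper"] = 2.0 * b * rel(noise.derived_rel_sd)
    cols["nucleus_min_caliper"] = np.minimum(cols["nucleus_min_caliper"], cols["nucleus_max_caliper"])
    ecc = np.sqrt(np.clip(1.0 - (b / np.maximum(a, 1e-12)) ** 2, 0.0, None)) if n else np.empty(0)
    cols["nucleus_eccentricity"] = np.clip(
        ecc + noise.eccentricity_sd * rng.standard_normal(n), 0.0, 0.999
    )
    cols["hematoxylin_mean_od"] = np.clip(
        noise.hematoxylin_mean + noise.hematoxylin_sd * rng.standard_normal(n), 0.0, None
    )
    cell_area = np.pi * (a + cell_expansion_um) * (b + cell_expansion_um)
    ratio = np.where(cell_area > 0, cols["nucleus_area"] / cell_area, 1.0)
    cols["nucleus_to_cell_ratio"] = np.clip(ratio * rel(noise.ratio_rel_sd), 1e-6, 1.0)

    df = pd.DataFrame(
        {
            "specimen_id": np.repeat(specimen_id, n),
            "compartment": np.repeat(compartment, n),
            "region": np.repeat(region if region is not None else "none", n),
            "true_type": type_labels,
        }
    )
    for feat in ALL_FEATURES:
        df[feat] = cols[feat]
    for feat in ("membrane_igf1r_od", "cytoplasm_ido_od", "cytoplasm_tigit_od"):
        df[feat] = cols[feat]
    return df


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SpecimenConfig:
    specimen_id: str
    compartment: str
    n_cells: int
    split_regions: bool = False  # primary tumors: equal thirds base/center/apex

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class CohortConfig:
    specimens: list[SpecimenConfig]
    pixel_size_um: float = 0.25  # µm/px at x400 scanning
    seed: int = 0
    noise: NoiseParams = field(default_factory=NoiseParams)
    cell_expansion_um: float = 3.5
    scene_shape_um: tuple[float, float] = (120.0, 120.0)
    background_rgb: tuple[float, float, float] = (255.0, 255.0, 255.0)
    max_place_attempts: int = 500

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, (SpecimenConfig, NoiseParams)):
                return asdict(o)
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_cohort_config(scale: float = 0.01, seed: int = 0) -> CohortConfig:
    """One pooled specimen per compartment at ``scale`` times the reference counts."""
    from .archetypes import COMPARTMENT_CELL_COUNTS

    specs = [
        SpecimenConfig(
            specimen_id=f"{comp}_pooled",
            compartment=comp,
            n_cells=int(round(count * scale)),
            split_regions=(comp == "primary_tumor"),
        )
        for comp, count in COMPARTMENT_CELL_COUNTS.items()
    ]
    return CohortConfig(specimens=specs, seed=seed)


@dataclass
class Cohort:
    cells: pd.DataFrame
    manifest: dict


def make_cohort(config: CohortConfig, archetypes: ArchetypeTable | None = None) -> Cohort:
    """Generate one feature table per specimen and a reproducibility manifest."""
    archetypes = archetypes or default_archetypes()
    rng = np.random.default_rng(config.seed)
    tables = []
    counts = {}
    for spec in config.specimens:
        if spec.split_regions and spec.compartment == "primary_tumor":
            per = spec.n_cells // 3
            ns = {"base": spec.n_cells - 2 * per, "center": per, "apex": per}
            parts = [
                sample_feature_table(
                    archetypes, spec.compartment, ns[r], rng,
                    region=r, specimen_id=spec.specimen_id, noise=config.noise,
                    cell_expansion_um=config.cell_expansion_um,
                )
                for r in ("base", "center", "apex")
            ]
            table = pd.concat(parts, ignore_index=True)
        else:
            table = sample_feature_table(
                archetypes, spec.compartment, spec.n_cells, rng,
                specimen_id=spec.specimen_id, noise=config.noise,
                cell_expansion_um=config.cell_expansion_um,
            )
        tables.append(table)
        counts[spec.specimen_id] = int(len(table))
    cells = (
        pd.concat(tables, ignore_index=True)
        if tables
        else sample_feature_table(archetypes, "normal_choroid", 0)
    )
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "counts": counts,
        "total_cells": int(sum(counts.values())),
    }
    return Cohort(cells=cells, manifest=manifest)


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScene:
    """Rendered RGB image with ground-truth label maps and generating records."""

    image: np.ndarray          # uint8, (H, W, 3)
    nucleus_labels: np.ndarray  # uint16, 0 = background
    cell_labels: np.ndarray
    records: pd.DataFrame      # row i generated label i+1
    pixel_size_um: float


def _ellipse_mask(shape, center, a_px, b_px, theta):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def render_scene(
    records: pd.DataFrame,
    config: CohortConfig,
    stains=None,
    seed: int | None = 0,
    marker_nucleus: str = "nbap1_od",
    marker_cytoplasm: str = "cytoplasm_bap1_od",
) -> SyntheticScene:
    """Render cells as stained ellipses under a Beer–Lambert absorbance model.

    Nucleus pixels absorb hematoxylin (at the record's hematoxylin mean OD)
    plus chromogen at the nuclear-marker OD; the 3.5 µm cytoplasm ring
    absorbs chromogen at the cytoplasmic-marker OD. Placement is by
    rejection sampling; cells never overlap.
    """
    from .segmentation import StainModel

    stains = stains or StainModel.default()
    rng = np.random.default_rng(seed)
    px = config.pixel_size_um
    shape = (int(round(config.scene_shape_um[0] / px)), int(round(config.scene_shape_um[1] / px)))
    nucleus_labels = np.zeros(shape, dtype=np.uint16)
    cell_labels = np.zeros(shape, dtype=np.uint16)
    hema_od = np.zeros(shape)
    marker_od = np.zeros(shape)
    expansion_px = config.cell_expansion_um / px

    for i, rec in enumerate(records.itertuples(index=False)):
        a_um, b_um, _ = derive_shape_params(rec.nucleus_area, rec.nucleus_circularity)
        a_px, b_px = float(a_um) / px, float(b_um) / px
        r_cell = a_px + expansion_px + 1
        placed = False
        for _ in range(config.max_place_attempts):
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(r_cell, shape[0] - r_cell)
            cx = rng.uniform(r_cell, shape[1] - r_cell)
            # local window around the candidate cell
            y0, y1 = int(cy - r_cell) - 1, int(cy + r_cell) + 2
            x0, x1 = int(cx - r_cell) - 1, int(cx + r_cell) + 2
            win = (slice(max(y0, 0), min(y1, shape[0])), slice(max(x0, 0), min(x1, shape[1])))
            local_shape = (win[0].stop - win[0].start, win[1].stop - win[1].start)
            center = (cy - win[0].start, cx - win[1].start)
            nuc = _ellipse_mask(local_shape, center, a_px, b_px, theta)
            if not nuc.any():
                continue
            dist = ndimage.distance_transform_edt(~nuc)
            cell = dist <= expansion_px
            if (cell_labels[win][cell] != 0).any():
                continue
            label = i + 1
            nucleus_labels[win][nuc] = label
            cell_labels[win][cell] = label
            hema_od[win][nuc] += rec.hematoxylin_mean_od
            marker_od[win][nuc] += getattr(rec, marker_nucleus)
            cyto = cell & ~nuc
            marker_od[win][cyto] += getattr(rec, marker_cytoplasm)
            placed = True
            break
        if not placed:
            n_placed = int((np.unique(nucleus_labels) > 0).sum())
            raise RuntimeError(
                f"could not place cell {i} after {config.max_place_attempts} attempts "
                f"({n_placed}/{len(records)} placed); enlarge the canvas"
            )

    absorbance = (
        hema_od[..., None] * stains.hematoxylin[None, None, :]
        + marker_od[..., None] * stains.chromogen[None, None, :]
    )
    i0 = np.asarray(config.background_rgb, dtype=float)
    image = i0[None, None, :] * 10.0 ** (-absorbance)
    if config.noise.pixel_noise_sd > 0:
        image = image + rng.normal(0.0, config.noise.pixel_noise_sd, size=image.shape)
    image = np.clip(np.round(image), 1, 255).astype(np.uint8)
    return SyntheticScene(
        image=image,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        records=records.reset_index(drop=True),
        pixel_size_um=px,
    )
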