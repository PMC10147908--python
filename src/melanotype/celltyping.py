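"""Mapping clusters to the named cell-type archetypes and BAP-1 status.

Fitted cluster centroids are matched one-to-one to the archetype mean
vectors (normal, epithelioid, spindle A, spindle B) by Hungarian assignment
on a pooled-SD-standardized Euclidean distance. Per-cell nuclear BAP-1
status uses a calibrated-OD cutoff; per-lesion status follows the >= 33%
immunoreactive-cell rule evaluated in the most intensely stained
high-power fields when cell coordinates are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .archetypes import ArchetypeTable, default_archetypes
from .twostep import ClusterModel

__all__ = [
    "assign_archetypes",
    "classify_cell_nbap1",
    "classify_lesion_bap1",
    "distribution_tables",
    "type_cohort",
    "recover_type_proportions",
]

NBAP1_CELL_CUTOFF = 0.5   # calibrated OD; 0 = negative ref, 1 = positive ref
LESION_POSITIVE_FRACTION = 0.33
HPF_AREA_UM2 = 950_000.0  # approx. x200 high-power field


def assign_archetypes(
    model: ClusterModel, archetypes: ArchetypeTable | None = None
) -> dict[int, str]:
    """Optimal one-to-one mapping of cluster ids to archetype names.

    Distance between a cluster centroid (raw units) and an archetype mean
    vector is Euclidean after standardizing each feature by its pooled
    across-type SD; only features shared by the model and the archetype
    table enter. Archetypes left unmatched are simply absent from the
    mapping's values.
    """
    archetypes = archetypes or default_archetypes()
    shared = [f for f in model.features if f in archetypes.features]
    if not shared:
        raise ValueError("model shares no features with the archetype table")
    k = len(model.sizes)
    types = list(archetypes.cell_types)
    if k > len(types):
        raise ValueError(
            f"{k} clusters exceed the {len(types)} archetypes; centroids:\n"
            f"{model.centroids_raw}"
        )
    cols = [model.features.index(f) for f in shared]
    cent = model.centroids_raw[:, cols]
    means = archetypes.means.loc[types, shared].to_numpy()
    sds = archetypes.sds.loc[types, shared].to_numpy()
    pooled = np.sqrt(np.nanmean(sds**2, axis=0))
    cost = np.zeros((k, len(types)))
    for t in range(len(types)):
        diff = (cent - means[t][None, :]) / pooled[None, :]
        cost[:, t] = np.nansum(diff**2, axis=1)
    rows, cols_assign = linear_sum_assignment(cost)
    return {int(r): types[c] for r, c in zip(rows, cols_assign)}


def classify_cell_nbap1(nbap1_od, cutoff: float = NBAP1_CELL_CUTOFF):
    """Per-cell nuclear BAP-1 status: positive iff calibrated OD >= cutoff."""
    od = np.asarray(nbap1_od, dtype=float)
    if np.any(np.isnan(od)):
        raise ValueError("nBAP-1 OD missing for some cells")
    return od >= cutoff


def classify_lesion_bap1(
    cells: pd.DataFrame,
    cell_cutoff: float = NBAP1_CELL_CUTOFF,
    positive_fraction: float = LESION_POSITIVE_FRACTION,
    hpf_area_um2: float = HPF_AREA_UM2,
    n_hpf: int = 3,
) -> str:
    """Lesion-level BAP-1 status by the >= 33% immunoreactive-cell rule.

    When cells carry ``centroid_x_um``/``centroid_y_um`` coordinates, the
    lesion is tiled into high-power-field windows, the ``n_hpf`` windows
    with the most intense mean nuclear BAP-1 staining are pooled, and the
    positive fraction is computed there (emulating field selection under
    the microscope). Without coordinates the whole-lesion fraction is used.
    """
    if len(cells) == 0:
        raise ValueError("lesion has no cells")
    od = cells["nbap1_od"].to_numpy(dtype=float)
    have_xy = {"centroid_x_um", "centroid_y_um"}.issubset(cells.columns)
    if have_xy and len(cells) > 1:
        side = math.sqrt(hpf_area_um2)
        gx = np.floor(cells["centroid_x_um"].to_numpy() / side).astype(int)
        gy = np.floor(cells["centroid_y_um"].to_numpy() / side).astype(int)
        window = pd.Series(list(zip(gx, gy)), index=cells.index)
        mean_od = pd.Series(od, index=cells.index).groupby(window).mean()
        top = mean_od.sort_values(ascending=False).index[:n_hpf]
        sel = window.isin(set(top)).to_numpy()
        od = od[sel]
    frac = float(np.mean(od >= cell_cutoff))
    return "positive" if frac >= positive_fraction else "negative"


def nbap1_cutoff_sweep(cells: pd.DataFrame, cutoffs=None) -> pd.DataFrame:
    """Positive-cell fraction as a function of the per-cell OD cutoff.

    The per-cell threshold has no published numeric value, so conclusions
    should be checked across a range; returns one row per cutoff.
    """
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.1, 0.95, 0.05), 2)
    od = cells["nbap1_od"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "cutoff": cutoffs,
            "positive_fraction": [float(np.mean(od >= c)) for c in cutoffs],
        }
    )


def type_cohort(
    cells: pd.DataFrame,
    model: ClusterModel,
    archetypes: ArchetypeTable | None = None,
    cell_cutoff: float = NBAP1_CELL_CUTOFF,
) -> pd.DataFrame:
    """Append cluster id, archetype label, and nBAP-1 status columns."""
    mapping = assign_archetypes(model, archetypes)
    out = cells.copy()
    out["cluster"] = model.assignments
    out["cell_type"] = [mapping[int(c)] for c in model.assignments]
    if "nbap1_od" in out.columns:
        out["nbap1_status"] = np.where(
            classify_cell_nbap1(out["nbap1_od"], cell_cutoff), "positive", "negative"
        )
    return out


def distribution_tables(typed: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cell-type counts and proportions by compartment and by region.

    Returns ``{"compartment_counts", "compartment_proportions",
    "region_counts", "region_proportions"}``; the count tables are the
    contingency-table inputs for chi-square testing.
    """
    out = {}
    for by in ("compartment", "region"):
        if by not in typed.columns:
            continue
        counts = pd.crosstab(typed[by], typed["cell_type"])
        out[f"{by}_counts"] = counts
        out[f"{by}_proportions"] = counts.div(counts.sum(axis=1), axis=0)
    return out


def recover_type_proportions(
    cells: pd.DataFrame,
    features,
    seed: int | None = 0,
    archetypes: ArchetypeTable | None = None,
    **fit_kwargs,
):
    """Cluster a feature table and report archetype-labelled proportions.

    Convenience end-to-end step: fit the two-step model, match clusters to
    archetypes, and return ``(proportions dict, model, mapping)``.
    """
    from .twostep import fit_twostep

    model = fit_twostep(cells, features, seed=seed, **fit_kwargs)
    mapping = assign_archetypes(model, archetypes)
    props = {}
    total = float(len(cells))
    for cluster, name in mapping.items():
        props[name] = float(np.sum(model.assignments == cluster)) / total
    return props, model, mapping
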