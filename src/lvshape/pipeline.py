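"""End-to-end plumbing: mask -> mesh -> 27-feature row -> feature table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh

from .features_curvature import CURVATURE_FEATURE_NAMES, compute_curvature
from .features_global import GLOBAL_FEATURE_NAMES, compute_global
from .features_local import LOCAL_FEATURE_NAMES, NeighborhoodSpec, compute_local
from .voxmesh import MeshConfig, VoxelMask, extract_mesh

__all__ = ["FEATURE_NAMES", "featurize_mesh", "cohort_features"]

# canonical 27 feature columns: 11 global, 12 local, 4 curvature
FEATURE_NAMES: tuple[str, ...] = (
    GLOBAL_FEATURE_NAMES + LOCAL_FEATURE_NAMES + CURVATURE_FEATURE_NAMES
)


def featurize_mesh(
    mesh: trimesh.Trimesh, spec: NeighborhoodSpec | None = None
) -> dict[str, float]:
    """All 27 features of one standardized mesh, keyed by canonical name."""
    row: dict[str, float] = {}
    row.update(compute_global(mesh).as_dict())
    row.update(compute_local(mesh, spec).as_dict())
    row.update(compute_curvature(mesh).as_dict())
    return {k: row[k] for k in FEATURE_NAMES}


def cohort_features(
    masks,
    labels=None,
    mesh_cfg: MeshConfig | None = None,
    neighborhood: NeighborhoodSpec | None = None,
) -> pd.DataFrame:
    """Run the mesh + feature pipeline over a cohort of masks.

    Parameters
    ----------
    masks : sequence of VoxelMask
    labels : optional sequence of binary responses, appended as a
        ``response`` column.

    Returns a DataFrame with one row per subject and the 27 canonical
    feature columns (plus ``response`` if labels are given).
    """
    rows = []
    for mask in masks:
        mesh = extract_mesh(mask, mesh_cfg)
        rows.append(featurize_mesh(mesh, neighborhood))
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is not None:
        df["response"] = np.asarray(labels, dtype=int)
    return df
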