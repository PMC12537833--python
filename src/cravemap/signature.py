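"""Voxel-space signature: back-projection, display scaling, atlas summary.

For a PCA + linear-regression pipeline the product of the eigenvector
matrix V and the regression coefficient vector B is a voxel-indexed weight
map — each voxel's contribution to the predicted craving level.  Two
variants are kept:

* ``vb``    — V·B in standardized feature space (the literal signature;
              used for figures and regional summaries);
* ``vb_raw``— V·B with the 1/sigma scaling folded in and scattered to the
              full-grid layout, so that a plain dot product with a raw beta
              vector plus the adjusted intercept reproduces the pipeline's
              prediction exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import ParcellationVolume, VolumeStack, write_map
from .models import FittedPipeline

__all__ = [
    "SignatureMap",
    "back_project",
    "normalize_for_display",
    "summarize_by_atlas",
    "write_signature",
]


@dataclass(frozen=True)
class SignatureMap:
    """Per-voxel contribution weights of a fitted linear pipeline.

    Both vectors use the full-grid flat layout (Fortran order) and are zero
    at filtered-out and off-mask voxels.  ``b0_adj`` satisfies
    yhat = <x_raw, vb_raw> + b0_adj for every raw sample x_raw.
    """

    vb: np.ndarray
    vb_raw: np.ndarray
    b0_adj: float
    norm_factor: float = 1.0
    regional_means: pd.DataFrame | None = None


def back_project(pipeline: FittedPipeline) -> SignatureMap:
    """Scatter V·B back to voxel space with the prediction identity intact.

    Requires a PCA reducer and a linear regression family (tree models have
    no voxel-linear form; ANOVA selection has no eigenvector matrix).
    """
    if not pipeline.spec.is_linear:
        raise ValueError("back-projection requires a linear regression family")
    red = pipeline.reducer
    if red.method != "pca":
        raise ValueError("back-projection requires a PCA reducer (no V for ANOVA)")
    V = red.components_  # (n_components, n_kept), rows orthonormal
    B = pipeline.B
    vb_kept = V.T @ B  # weight per kept column, standardized space
    n_full = red.n_features_in_
    vb = np.zeros(n_full)
    vb[red.kept_columns_] = vb_kept
    vb_raw = np.zeros(n_full)
    vb_raw[red.kept_columns_] = vb_kept / red.scale_
    b0_adj = pipeline.b0 - float(np.sum(red.mean_ * vb_kept / red.scale_))
    return SignatureMap(vb=vb, vb_raw=vb_raw, b0_adj=b0_adj)


def normalize_for_display(
    sig: SignatureMap, reference: np.ndarray
) -> SignatureMap:
    """Scale the map so its vb_raw L2 norm matches the reference map's norm.

    The reference is typically the cohort's average beta map; only the
    scale changes — the sign pattern and ranking are untouched.
    """
    reference = np.asarray(reference, dtype=float)
    ref_norm = float(np.linalg.norm(reference))
    if ref_norm == 0:
        raise ValueError("reference map has zero norm")
    own = float(np.linalg.norm(sig.vb_raw))
    if own == 0:
        raise ValueError("cannot normalize an all-zero signature")
    factor = ref_norm / own
    return replace(
        sig,
        vb=sig.vb * factor,
        vb_raw=sig.vb_raw * factor,
        norm_factor=factor,
    )


def summarize_by_atlas(
    sig: SignatureMap,
    parcellation: ParcellationVolume,
    stack: VolumeStack,
    use: str = "vb",
) -> pd.DataFrame:
    """Mean signature value per atlas region, ranked descending.

    Regions with no in-mask voxels are omitted (missing, not zero).  The
    ``vb`` variant is summarized by default — the literal V·B signature.
    """
    if parcellation.labels.shape != tuple(stack.grid_shape):
        raise ValueError("parcellation grid does not match the map grid")
    values = getattr(sig, use)
    vol = stack.unflatten(values)
    labels = parcellation.labels
    in_mask = stack.mask
    if not np.any((labels > 0) & in_mask):
        raise ValueError("no overlap between the parcellation and the mask")
    rows = []
    for rid in parcellation.region_ids:
        sel = (labels == rid) & in_mask
        n_vox = int(sel.sum())
        if n_vox == 0:
            continue
        name = (parcellation.region_names or {}).get(int(rid), "")
        rows.append(
            {
                "region_id": int(rid),
                "region_name": name,
                "mean_vb": float(vol[sel].mean()),
                "n_voxels": n_vox,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "mean_vb", ascending=False, kind="stable"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def write_signature(
    sig: SignatureMap, stack: VolumeStack, out_dir: str | Path
) -> dict[str, Path]:
    """Write both signature variants as 3D NIfTI maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "vb": write_map(sig.vb, stack, out / "signature_vb.nii.gz"),
        "vb_raw": write_map(sig.vb_raw, stack, out / "signature_vb_raw.nii.gz"),
    }
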