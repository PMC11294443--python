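"""Statistics on 3D segmentation masks and nascent-RNA spot coordinates.

Masks live on a common voxel grid with (possibly anisotropic) physical
voxel sizes; spot coordinates are in µm on the same axes.  The central
quantities are territory volumes, the pairwise intermingling index
(squared overlap volume over the product of the two volumes), surface-
to-membrane radial distance, and transcriptional intensity (spots per
µm^3 of mask).  All per-cell statistics can be normalized to nucleus
size to remove cell-size variation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

__all__ = [
    "TerritoryImage",
    "mask_volume",
    "intermingling_index",
    "radial_distance",
    "count_spots",
    "transcriptional_intensity",
    "nucleus_equivalent_diameter",
    "normalize_by_nucleus",
    "territory_stats",
]


@dataclass
class TerritoryImage:
    """Voxel masks for a nucleus and its chromosome territories, plus spots.

    ``spots`` is an (n, 3) array of µm coordinates in array-axis order.
    Territory masks extending outside the nucleus warn and are clipped.
    """

    voxel_size: tuple[float, float, float]
    nucleus_mask: np.ndarray
    territory_masks: dict[str, np.ndarray] = field(default_factory=dict)
    spots: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive per axis")
        for label, m in list(self.territory_masks.items()):
            outside = m & ~self.nucleus_mask
            if outside.any():
                warnings.warn(
                    f"territory {label!r}: {int(outside.sum())} voxels outside "
                    "the nucleus were clipped"
                )
                self.territory_masks[label] = m & self.nucleus_mask

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    # -- plain-text persistence ---------------------------------------
    def save(self, directory) -> None:
        """Write masks (NPZ-equivalent: one .txt per mask), spots TSV, sidecar JSON."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        shape = self.nucleus_mask.shape
        np.savetxt(d / "nucleus.mask.txt", self.nucleus_mask.reshape(-1, shape[-1]), fmt="%d")
        for label, m in self.territory_masks.items():
            np.savetxt(d / f"territory_{label}.mask.txt", m.reshape(-1, shape[-1]), fmt="%d")
        pd.DataFrame(self.spots, columns=["x", "y", "z"]).to_csv(
            d / "spots.tsv", sep="\t", index=False
        )
        meta = {
            "voxel_size": list(self.voxel_size),
            "shape": list(shape),
            "labels": list(self.territory_masks),
        }
        (d / "image.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "TerritoryImage":
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "image.json").read_text())
        shape = tuple(meta["shape"])
        nucleus = np.loadtxt(d / "nucleus.mask.txt").astype(bool).reshape(shape)
        masks = {
            lab: np.loadtxt(d / f"territory_{lab}.mask.txt").astype(bool).reshape(shape)
            for lab in meta["labels"]
        }
        spots = pd.read_csv(d / "spots.tsv", sep="\t").to_numpy()
        return cls(
            voxel_size=tuple(meta["voxel_size"]),
            nucleus_mask=nucleus,
            territory_masks=masks,
            spots=spots,
        )


def mask_volume(mask: np.ndarray, voxel_size) -> float:
    """Physical volume of a boolean mask in µm^3."""
    n = int(np.asarray(mask, bool).sum())
    if n == 0:
        warnings.warn("empty mask: volume 0")
    return n * float(np.prod(voxel_size))


def intermingling_index(mask_a: np.ndarray, mask_b: np.ndarray, voxel_size) -> float:
    """Degree of intermingling of two territories.

    Defined as V_AB^2 / (V_A * V_B), where V_AB is the volume of the
    voxelwise intersection.  Symmetric in its arguments; 1 for identical
    masks, 0 for disjoint ones.  NaN if either mask is empty.
    """
    vv = float(np.prod(voxel_size))
    va = np.asarray(mask_a, bool).sum() * vv
    vb = np.asarray(mask_b, bool).sum() * vv
    if va == 0 or vb == 0:
        warnings.warn("intermingling index undefined for an empty mask")
        return float("nan")
    vab = (np.asarray(mask_a, bool) & np.asarray(mask_b, bool)).sum() * vv
    return float(vab**2 / (va * vb))


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one false 6-neighbor (3D surface)."""
    mask = np.asarray(mask, bool)
    struct = ndi.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndi.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~interior


def radial_distance(mask: np.ndarray, nucleus_mask: np.ndarray, voxel_size) -> float:
    """Minimum distance (µm) from a territory's surface to the nucleus membrane.

    Uses an anisotropy-aware Euclidean distance transform of the nucleus
    mask: each nucleus voxel's distance to the nearest non-nucleus voxel.
    The grid boundary counts as membrane (the mask is padded with
    background), so nuclei clipped by the field of view behave sensibly.
    """
    mask = np.asarray(mask, bool)
    nucleus_mask = np.asarray(nucleus_mask, bool)
    if (mask & ~nucleus_mask).any():
        raise ValueError("territory mask extends outside the nucleus")
    padded = np.pad(nucleus_mask, 1, constant_values=False)
    dt = ndi.distance_transform_edt(padded, sampling=voxel_size)[1:-1, 1:-1, 1:-1]
    surf = surface_voxels(mask)
    if not surf.any():
        return float("nan")
    return float(dt[surf].min())


def count_spots(spots: np.ndarray, mask: np.ndarray, voxel_size) -> int:
    """Number of spots whose containing voxel is true in the mask.

    Spot-to-voxel assignment is floor(coordinate / voxel_size) per axis;
    spots outside the grid warn and are excluded.
    """
    mask = np.asarray(mask, bool)
    spots = np.asarray(spots, float)
    if spots.size == 0:
        return 0
    vox = np.floor(spots / np.asarray(voxel_size)).astype(int)
    inside = np.all((vox >= 0) & (vox < np.asarray(mask.shape)), axis=1)
    if (~inside).any():
        warnings.warn(f"{int((~inside).sum())} spots outside the grid were excluded")
    vox = vox[inside]
    return int(mask[vox[:, 0], vox[:, 1], vox[:, 2]].sum())


def transcriptional_intensity(spots: np.ndarray, mask: np.ndarray, voxel_size) -> float:
    """Spots per µm^3 of mask (nascent-RNA yield density)."""
    vol = mask_volume(mask, voxel_size)
    if vol == 0:
        return float("nan")
    return count_spots(spots, mask, voxel_size) / vol


def nucleus_equivalent_diameter(nucleus_volume: float) -> float:
    """Diameter of the sphere with the nucleus's volume."""
    return 2.0 * (3.0 * nucleus_volume / (4.0 * np.pi)) ** (1.0 / 3.0)


def normalize_by_nucleus(stats: pd.DataFrame, nucleus_volume: float) -> pd.DataFrame:
    """Normalize volume columns by nucleus volume and distance columns by
    the nucleus equivalent-sphere diameter, removing cell-size variation.

    Columns ending in ``_volume`` (other than ``nucleus_volume``) gain a
    ``_norm`` counterpart divided by the nucleus volume; columns ending
    in ``_distance`` gain one divided by the equivalent diameter.
    """
    if nucleus_volume <= 0:
        raise ValueError("nucleus volume must be positive")
    diam = nucleus_equivalent_diameter(nucleus_volume)
    out = stats.copy()
    for col in stats.columns:
        if col.endswith("_volume") and col != "nucleus_volume":
            out[col + "_norm"] = stats[col] / nucleus_volume
        elif col.endswith("_distance"):
            out[col + "_norm"] = stats[col] / diam
    return out


def territory_stats(image: TerritoryImage, normalize: bool = True) -> dict[str, pd.DataFrame]:
    """Full per-territory and per-pair statistics table for one cell.

    Returns ``{"territories": ..., "pairs": ...}``.  The pair table
    reports overlap volume, intermingling index, and transcriptional
    intensity of the intersection (intermingling) and symmetric-
    difference (non-intermingling) regions.
    """
    vs = image.voxel_size
    nuc_vol = mask_volume(image.nucleus_mask, vs)
    rows = []
    for label, m in image.territory_masks.items():
        rows.append(
            {
                "label": label,
                "territory_volume": mask_volume(m, vs),
                "spot_count": count_spots(image.spots, m, vs),
                "intensity": transcriptional_intensity(image.spots, m, vs),
                "radial_distance": radial_distance(m, image.nucleus_mask, vs),
                "nucleus_volume": nuc_vol,
            }
        )
    terr = pd.DataFrame(rows)
    labels = list(image.territory_masks)
    prow = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ma, mb = image.territory_masks[labels[i]], image.territory_masks[labels[j]]
            inter = ma & mb
            symdiff = ma ^ mb
            prow.append(
                {
                    "label_a": labels[i],
                    "label_b": labels[j],
                    "overlap_volume": mask_volume(inter, vs) if inter.any() else 0.0,
                    "intermingling_index": intermingling_index(ma, mb, vs),
                    "intermingle_intensity": transcriptional_intensity(
                        image.spots, inter, vs
                    )
                    if inter.any()
                    else float("nan"),
                    "non_intermingle_intensity": transcriptional_intensity(
                        image.spots, symdiff, vs
                    )
                    if symdiff.any()
                    else float("nan"),
                }
            )
    pairs = pd.DataFrame(prow)
    if normalize:
        terr = normalize_by_nucleus(terr, nuc_vol)
    return {"territories": terr, "pairs": pairs}
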