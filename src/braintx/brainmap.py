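"""Gene-set ("module") spatial mapping over a region-annotated volume.

The spatial expression of a module is the voxel-wise **sum** of the energy
fields of the module genes that are available in the volume's gene panel;
absent genes are counted and reported, never imputed.  Per-region summaries
(voxel count, sum, mean) and an up-vs-down contrast (log2 ratio of region
means) reproduce the region-profile analysis; 2-D sagittal sections can be
extracted for plotting, with the section axis running lateral -> medial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionVolume

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleSpatialMap",
    "module_spatial_score",
    "region_summary",
    "region_contrast",
    "extract_section",
]


@dataclass
class ModuleSpatialMap:
    """Voxel-wise module score: sum of available module genes' energies."""

    name: str
    score: np.ndarray
    genes_used: list[str]
    genes_missing: list[str]

    @property
    def n_genes_available(self) -> int:
        return len(self.genes_used)


def module_spatial_score(
    volume: ExpressionVolume, genes, name: str = "module"
) -> ModuleSpatialMap:
    """Sum the energy fields of the module genes present in the panel."""
    genes = list(dict.fromkeys(genes))
    panel = set(volume.genes)
    used = [g for g in genes if g in panel]
    missing = [g for g in genes if g not in panel]
    if not used:
        raise ValueError(
            f"no gene of module {name!r} is present in the volume panel; "
            f"missing: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    if missing:
        logger.info(
            "module %r: %d of %d genes absent from the volume panel",
            name, len(missing), len(genes),
        )
    idx = [volume.genes.index(g) for g in used]
    score = volume.energy[idx].sum(axis=0)
    return ModuleSpatialMap(name=name, score=score,
                            genes_used=used, genes_missing=missing)


def region_summary(
    spatial_map: ModuleSpatialMap, volume: ExpressionVolume
) -> pd.DataFrame:
    """Per-region voxel count, total and mean score, ranked by mean."""
    if spatial_map.score.shape != volume.grid_shape:
        raise ValueError(
            f"map grid {spatial_map.score.shape} does not match volume grid "
            f"{volume.grid_shape}"
        )
    rows = []
    for r, region in enumerate(volume.region_names):
        mask = volume.region_labels == r
        n = int(mask.sum())
        if n == 0:
            logger.warning("region %r has no voxels; excluded", region)
            continue
        total = float(spatial_map.score[mask].sum())
        rows.append(
            {"region": region, "n_voxels": n, "sum": total, "mean": total / n}
        )
    out = pd.DataFrame(rows).set_index("region")
    return out.sort_values("mean", ascending=False)


def region_contrast(
    map_up: ModuleSpatialMap,
    map_down: ModuleSpatialMap,
    volume: ExpressionVolume,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Per-region log2 ratio of the two modules' mean scores.

    Positive values mark regions dominated by the first (up) module,
    negative by the second (down) module.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    up = region_summary(map_up, volume)["mean"]
    down = region_summary(map_down, volume)["mean"]
    regions = up.index.intersection(down.index)
    out = pd.DataFrame(
        {
            f"mean_{map_up.name}": up.loc[regions],
            f"mean_{map_down.name}": down.loc[regions],
            "log2_ratio": np.log2(
                (up.loc[regions] + pseudocount) / (down.loc[regions] + pseudocount)
            ),
        }
    )
    return out.sort_values("log2_ratio", ascending=False)


def extract_section(
    volume: ExpressionVolume,
    index: int,
    axis: str | None = None,
    spatial_map: ModuleSpatialMap | None = None,
) -> dict[str, np.ndarray]:
    """Extract one 2-D section of region labels (and, optionally, scores).

    ``axis`` defaults to the volume's section axis (z, lateral -> medial,
    so index 0 is the lateral-most sagittal plane).  No interpolation is
    performed.
    """
    axis = volume.section_axis if axis is None else axis
    if axis not in ExpressionVolume.AXES:
        raise ValueError(f"axis must be one of {ExpressionVolume.AXES}")
    dim = ExpressionVolume.AXES.index(axis)
    size = volume.grid_shape[dim]
    if not 0 <= index < size:
        raise ValueError(f"section index {index} out of range [0, {size})")
    slicer = tuple(
        index if d == dim else slice(None) for d in range(3)
    )
    out = {"region": volume.region_labels[slicer]}
    if spatial_map is not None:
        if spatial_map.score.shape != volume.grid_shape:
            raise ValueError("map grid does not match volume grid")
        out["score"] = spatial_map.score[slicer]
    return out
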