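"""Mask perturbation and node-reproducibility analysis.

Region masks typically come from an ICA decomposition, and re-running ICA
on other data (or other iterations) yields somewhat different regions.  To
quantify how robust node identification is to such variation, the original
masks are perturbed — eroded (smaller ICA result), inflated (larger), or
"adjusted" by a small random boundary jitter — node identification is
re-run, and each node's time series is correlated with the series obtained
from the original masks.  High correlations mean the identified nodes are
stable under reasonable mask differences.

Morphology uses standard binary erosion/dilation with a 3D structuring
element of face (6), edge (18) or corner (26) connectivity; face
connectivity is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_model import NodeTable, RegionMask

__all__ = [
    "MaskVariant",
    "erode_mask",
    "dilate_mask",
    "jitter_mask",
    "reproducibility_compare",
]

_STRUCTS = {6: 1, 18: 2, 26: 3}  # connectivity -> ndimage structure rank


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, _STRUCTS[connectivity])


@dataclass
class MaskVariant:
    """A perturbed version of a base region mask."""

    base_region: str
    kind: str  # eroded | adjusted | inflated | external
    level: float  # iteration count or jitter fraction
    mask: RegionMask

    @property
    def n_voxels(self) -> int:
        return self.mask.n_voxels


def erode_mask(mask: RegionMask, iterations: int = 1, connectivity: int = 6) -> MaskVariant:
    """Binary morphological erosion; the result is always a subset of the base.

    Raises ``ValueError`` if erosion empties the mask.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    data = ndimage.binary_erosion(mask.data, structure=_structure(connectivity),
                                  iterations=iterations)
    if not data.any():
        raise ValueError(
            f"eroding {mask.region_name!r} {iterations}x empties the mask"
        )
    new = RegionMask(mask.region_name, mask.network_name, data, mask.affine)
    return MaskVariant(mask.region_name, "eroded", float(iterations), new)


def dilate_mask(mask: RegionMask, iterations: int = 1, connectivity: int = 6) -> MaskVariant:
    """Binary morphological dilation, clipped to the image grid; the result
    is always a superset of the base."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    data = ndimage.binary_dilation(mask.data, structure=_structure(connectivity),
                                   iterations=iterations)
    new = RegionMask(mask.region_name, mask.network_name, data, mask.affine)
    return MaskVariant(mask.region_name, "inflated", float(iterations), new)


def jitter_mask(mask: RegionMask, fraction: float, seed: int) -> MaskVariant:
    """"Adjusted" mask: swap a seeded random sample of boundary voxels for an
    equal-sized sample of outside neighbours.

    ``round(fraction * size)`` boundary voxels are removed and the same
    number of outside-boundary neighbours added, so the total size is
    unchanged while up to ``2 * fraction`` of the membership moves.  The
    same seed always yields the same variant.
    """
    if not (0.0 < fraction <= 0.1):
        raise ValueError("fraction must lie in (0, 0.1]")
    struct = _structure(6)
    boundary = mask.data & ~ndimage.binary_erosion(mask.data, structure=struct)
    outside = ndimage.binary_dilation(mask.data, structure=struct) & ~mask.data
    n_move = int(round(fraction * mask.n_voxels))
    b_idx = np.argwhere(boundary)
    o_idx = np.argwhere(outside)
    if n_move > len(b_idx) or n_move > len(o_idx):
        raise ValueError("fraction too large for the available boundary")
    data = mask.data.copy()
    if n_move > 0:
        rng = np.random.default_rng(seed)
        rem = b_idx[rng.choice(len(b_idx), size=n_move, replace=False)]
        add = o_idx[rng.choice(len(o_idx), size=n_move, replace=False)]
        data[rem[:, 0], rem[:, 1], rem[:, 2]] = False
        data[add[:, 0], add[:, 1], add[:, 2]] = True
    new = RegionMask(mask.region_name, mask.network_name, data, mask.affine)
    return MaskVariant(mask.region_name, "adjusted", fraction, new)


def reproducibility_compare(
    nodes_original: NodeTable | list[NodeTable],
    nodes_variant: NodeTable | list[NodeTable],
) -> pd.DataFrame:
    """Correlate each node's series under variant masks with its series under
    the original masks.

    Tables are matched by subject and (source, target) key; comparison is on
    the series themselves, so a variant that picks a different voxel with an
    identical series still scores 1.  Per-subject correlations are
    aggregated as mean ± sd per source region, plus an ``__all__`` row over
    every node.  The comparison is symmetric in its two arguments.
    """
    orig = [nodes_original] if isinstance(nodes_original, NodeTable) else list(nodes_original)
    var = [nodes_variant] if isinstance(nodes_variant, NodeTable) else list(nodes_variant)
    if len(orig) != len(var):
        raise ValueError("table lists differ in length")
    rows = []
    for to, tv in zip(orig, var):
        if set(to.keys()) != set(tv.keys()):
            raise ValueError(
                f"node keys differ between tables for subject {to.subject_id!r}"
            )
        for n in to.nodes:
            m = tv.node(*n.key)
            a, b = n.series, m.series
            if np.array_equal(a, b):
                r = 1.0  # identical series compare as exactly 1
            elif a.std() == 0 or b.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            rows.append({"subject": to.subject_id, "source_region": n.source_region,
                         "target_region": n.target_region, "r": r})
    df = pd.DataFrame(rows)
    per_region = (
        df.groupby("source_region")["r"].agg(["mean", "std", "count"]).reset_index()
    )
    overall = pd.DataFrame(
        [{"source_region": "__all__", "mean": df["r"].mean(),
          "std": df["r"].std(), "count": len(df)}]
    )
    return pd.concat([per_region, overall], ignore_index=True)
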