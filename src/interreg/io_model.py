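"""Domain types and file I/O shared by every analysis stage.

The method operates on a *network* of named brain regions (binary 3D masks on
a common voxel grid), on per-voxel BOLD time series extracted under those
masks, and on the per-region-pair *nodes* (hub voxels) that the analysis
identifies.  This module defines those containers, validates their
invariants, and provides the NIfTI/TSV/YAML (de)serialisers used by the
command-line tools.

Conventions
-----------
* Voxel indices are 0-based ``(i, j, k)`` in the image's own grid.  World
  coordinates in mm are derivable through the stored affine but are never
  used in any computation — node distances are reported in voxel units.
* Voxel (row) order within a region is the ascending linearised index with
  the last axis fastest (C order).  This makes row order a deterministic
  function of the mask alone and fixes all downstream tie-breaking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NetworkSpec",
    "RegionMask",
    "VoxelSeriesBlock",
    "Node",
    "NodeTable",
    "MeasureSet",
    "GroupComparison",
    "RunConfig",
    "load_region_masks",
    "extract_block",
    "write_node_table",
    "read_node_table",
    "write_matrix",
    "read_matrix",
]


# ---------------------------------------------------------------------------
# network description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """An ordered set of region names forming one resting-state network.

    The connectivity-measure taxonomy (primary / primary-secondary /
    secondary / intra-regional edges) requires at least three regions, so
    ``N >= 3`` is enforced.
    """

    network_name: str
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if len(set(self.regions)) != len(self.regions):
            raise ValueError(f"duplicate region names in network {self.network_name!r}")
        if self.n < 3:
            raise ValueError(
                f"network {self.network_name!r} has {self.n} regions; "
                "the measure taxonomy needs at least 3"
            )

    @property
    def n(self) -> int:
        """Number of regions N."""
        return len(self.regions)

    def ordered_pairs(self) -> list[tuple[str, str]]:
        """All N(N-1) ordered region pairs (a, b), a != b, in spec order."""
        return [(a, b) for a in self.regions for b in self.regions if a != b]

    def unordered_pairs(self) -> list[tuple[str, str]]:
        """All N(N-1)/2 unordered region pairs in spec order."""
        return list(combinations(self.regions, 2))


# ---------------------------------------------------------------------------
# masks and voxel blocks
# ---------------------------------------------------------------------------

@dataclass
class RegionMask:
    """A named binary 3D mask belonging to a named network."""

    region_name: str
    network_name: str
    data: np.ndarray  # boolean, 3D
    affine: np.ndarray  # 4x4 voxel-to-world (mm)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if not self.data.any():
            raise ValueError(f"mask for region {self.region_name!r} is empty")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_indices(self) -> np.ndarray:
        """(n, 3) integer indices in ascending linearised (C) order."""
        return np.argwhere(self.data)  # argwhere scans C-order: last axis fastest

    @classmethod
    def from_indices(
        cls,
        region_name: str,
        network_name: str,
        indices: Iterable[Sequence[int]],
        shape: tuple[int, int, int],
        affine: np.ndarray | None = None,
    ) -> "RegionMask":
        data = np.zeros(shape, dtype=bool)
        idx = np.asarray(list(indices), dtype=int)
        if idx.size and (idx.min() < 0 or (idx >= np.array(shape)).any()):
            raise ValueError("voxel index outside grid bounds")
        data[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        if affine is None:
            affine = np.eye(4)
        return cls(region_name, network_name, data, affine)


@dataclass
class VoxelSeriesBlock:
    """Per-voxel time series extracted under one region mask.

    ``series`` has one row per voxel, in the same ascending linearised order
    as ``voxel_indices``; columns are time points.
    """

    region_name: str
    voxel_indices: np.ndarray  # (n, 3) int
    series: np.ndarray  # (n, T) float

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.voxel_indices.shape != (self.series.shape[0], 3):
            raise ValueError("series must be (n_voxels, T) matching voxel_indices")
        if self.T < 3:
            raise ValueError("need at least 3 time points")
        if not np.isfinite(self.series).all():
            raise ValueError("series contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.series.shape[0]

    @property
    def T(self) -> int:
        return self.series.shape[1]

    def constant_rows(self) -> np.ndarray:
        """Boolean flag per voxel: True where the series is exactly constant.

        Constant (zero-variance) voxels are retained — dropping them would
        change voxel indexing — and their correlations are defined as 0
        downstream.
        """
        return np.ptp(self.series, axis=1) == 0


def extract_block(image4d: np.ndarray, mask: RegionMask) -> VoxelSeriesBlock:
    """Extract the time series of every voxel under ``mask`` from a 4D image.

    Rows are ordered by ascending linearised voxel index, so two extractions
    from the same mask always agree row-for-row.
    """
    img = np.asarray(image4d, dtype=float)
    if img.ndim != 4:
        raise ValueError("image must be 4D (i, j, k, t)")
    if img.shape[:3] != mask.shape:
        raise ValueError(
            f"image grid {img.shape[:3]} does not match mask grid {mask.shape}"
        )
    if img.shape[3] < 3:
        raise ValueError("need at least 3 time points")
    idx = mask.voxel_indices
    series = img[idx[:, 0], idx[:, 1], idx[:, 2], :]
    return VoxelSeriesBlock(mask.region_name, idx, series)


# ---------------------------------------------------------------------------
# nodes
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """The node V_xy: the voxel of region ``x`` selected by its thresholded
    total correlation to region ``y``, together with its time series."""

    source_region: str
    target_region: str
    voxel: tuple[int, int, int]
    score: float
    series: np.ndarray
    suprathreshold: bool = True

    def __post_init__(self) -> None:
        if self.source_region == self.target_region:
            raise ValueError("a node's source and target regions must differ")
        self.voxel = tuple(int(v) for v in self.voxel)
        self.series = np.asarray(self.series, dtype=float)

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_region, self.target_region)


@dataclass
class NodeTable:
    """All N(N-1) identified nodes of one network for one subject."""

    network_name: str
    subject_id: str
    nodes: list[Node] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [n.key for n in self.nodes]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (source, target) node key in table")

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, source: str, target: str) -> Node:
        for n in self.nodes:
            if n.key == (source, target):
                return n
        raise KeyError(f"no node V[{source}->{target}] in table")

    def keys(self) -> list[tuple[str, str]]:
        return [n.key for n in self.nodes]

    def validate_complete(self, spec: NetworkSpec) -> None:
        """Check the table holds exactly one node per ordered region pair."""
        expect = set(spec.ordered_pairs())
        have = set(self.keys())
        if have != expect:
            missing = sorted(expect - have)
            extra = sorted(have - expect)
            raise ValueError(
                f"node table incomplete for {spec.network_name}: "
                f"missing={missing} extra={extra}"
            )

    @property
    def T(self) -> int:
        if not self.nodes:
            raise ValueError("empty node table")
        return len(self.nodes[0].series)


_NODE_COLUMNS = [
    "subject", "network", "source_region", "target_region",
    "i", "j", "k", "score", "suprathreshold",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".series.tsv") if path.suffix == ".tsv" else Path(str(path) + ".series.tsv")


def write_node_table(table: NodeTable, path: str | Path) -> None:
    """Write a node table as TSV plus a ``*.series.tsv`` sidecar of time series."""
    path = Path(path)
    rows = []
    series_rows = []
    for n in table.nodes:
        rows.append(
            {
                "subject": table.subject_id,
                "network": table.network_name,
                "source_region": n.source_region,
                "target_region": n.target_region,
                "i": n.voxel[0],
                "j": n.voxel[1],
                "k": n.voxel[2],
                "score": n.score,
                "suprathreshold": int(n.suprathreshold),
            }
        )
        series_rows.append(
            {"source_region": n.source_region, "target_region": n.target_region}
            | {f"t{t}": v for t, v in enumerate(n.series)}
        )
    pd.DataFrame(rows, columns=_NODE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(series_rows).to_csv(
        _sidecar_path(path), sep="\t", index=False, float_format="%.17g"
    )


def read_node_table(path: str | Path) -> NodeTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(_NODE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"malformed node table {path}: missing columns {sorted(missing)}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing series sidecar {sidecar}")
    sdf = pd.read_csv(sidecar, sep="\t")
    tcols = [c for c in sdf.columns if c.startswith("t") and c[1:].isdigit()]
    series_by_key = {
        (r["source_region"], r["target_region"]): np.array([r[c] for c in tcols], dtype=float)
        for _, r in sdf.iterrows()
    }
    nodes = []
    for _, r in df.iterrows():
        key = (r["source_region"], r["target_region"])
        nodes.append(
            Node(
                source_region=key[0],
                target_region=key[1],
                voxel=(int(r["i"]), int(r["j"]), int(r["k"])),
                score=float(r["score"]),
                series=series_by_key[key],
                suprathreshold=bool(r["suprathreshold"]),
            )
        )
    subjects = df["subject"].unique()
    networks = df["network"].unique()
    if len(subjects) != 1 or len(networks) != 1:
        raise ValueError("node table file must hold one subject and one network")
    return NodeTable(network_name=str(networks[0]), subject_id=str(subjects[0]), nodes=nodes)


# ---------------------------------------------------------------------------
# labelled symmetric matrices (node-by-node correlation / p-value matrices)
# ---------------------------------------------------------------------------

def write_matrix(labels: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    """Write a labelled square symmetric matrix as TSV; diagonal forced to 1."""
    matrix = np.asarray(matrix, dtype=float)
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("matrix labels must be unique")
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match labels")
    if np.abs(matrix - matrix.T).max() > 1e-12:
        raise ValueError("matrix is not symmetric (tolerance 1e-12)")
    out = matrix.copy()
    np.fill_diagonal(out, 1.0)
    pd.DataFrame(out, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix row/column labels disagree")
    return list(df.columns), df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# measure sets and group comparisons
# ---------------------------------------------------------------------------

def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered region pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class MeasureSet:
    """Per-pair and network-averaged connectivity measures for one subject.

    ``r1``, ``r12`` and ``r2`` are keyed by the canonical unordered region
    pair, ``ri`` by region.  All four are symmetric in their pair by
    construction; mean-mode values are bounded by [-1, 1].
    """

    network_name: str
    subject_id: str
    r1: dict[tuple[str, str], float]
    r12: dict[tuple[str, str], float]
    r2: dict[tuple[str, str], float]
    ri: dict[str, float]
    ri_mode: str = "mean"

    @property
    def r1_network(self) -> float:
        return float(np.mean(list(self.r1.values())))

    @property
    def r12_network(self) -> float:
        return float(np.mean(list(self.r12.values())))

    @property
    def r2_network(self) -> float:
        return float(np.mean(list(self.r2.values())))

    @property
    def ri_network(self) -> float:
        return float(np.mean(list(self.ri.values())))

    def network_means(self) -> dict[str, float]:
        return {
            "R1": self.r1_network,
            "R12": self.r12_network,
            "R2": self.r2_network,
            "RI": self.ri_network,
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, d in (("R1", self.r1), ("R12", self.r12), ("R2", self.r2)):
            for (a, b), v in d.items():
                rows.append(
                    {"subject": self.subject_id, "network": self.network_name,
                     "measure": name, "region_a": a, "region_b": b, "value": v}
                )
        for a, v in self.ri.items():
            rows.append(
                {"subject": self.subject_id, "network": self.network_name,
                 "measure": "RI", "region_a": a, "region_b": "", "value": v}
            )
        for name, v in self.network_means().items():
            rows.append(
                {"subject": self.subject_id, "network": self.network_name,
                 "measure": name, "region_a": "*network*", "region_b": "*network*",
                 "value": v}
            )
        return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Outcome of one between-group test, with its FDR-correction family."""

    measure: str
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_value: float
    family: str
    p_adjusted: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable parameters of the analysis.

    tau
        Correlation threshold for node identification; only voxel-to-voxel
        correlations strictly greater than ``tau`` contribute to a voxel's
        total-correlation score.  Default 0.25, the conventional
        global-brain-connectivity cutoff.
    ri_mode
        ``"mean"`` averages intra-regional edges (comparable in scale to the
        other measures); ``"raw_sum"`` reports their plain sum.
    """

    tau: float = 0.25
    ri_mode: str = "mean"
    tie_rule: str = "lowest_index"
    regress_nuisance: bool = True
    p_display: float = 0.001
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau < 1.0):
            raise ValueError("tau must lie in [0, 1)")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.ri_mode not in ("mean", "raw_sum"):
            raise ValueError("ri_mode must be 'mean' or 'raw_sum'")
        if self.tie_rule != "lowest_index":
            raise ValueError("only the 'lowest_index' tie rule is implemented")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "ri_mode": self.ri_mode,
            "tie_rule": self.tie_rule,
            "regress_nuisance": self.regress_nuisance,
            "p_display": self.p_display,
            "fdr_alpha": self.fdr_alpha,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# mask loading
# ---------------------------------------------------------------------------

def _check_grid(shapes: list, affines: list) -> None:
    ref_shape, ref_aff = shapes[0], affines[0]
    for s, a in zip(shapes[1:], affines[1:]):
        if s != ref_shape or not np.allclose(a, ref_aff, atol=1e-6):
            raise ValueError("all masks must share one grid (shape and affine)")


def load_region_masks(
    source: Mapping[str, str | Path] | tuple[str | Path, Mapping[int, str]],
    network_assignment: Mapping[str, Sequence[str]],
) -> tuple[list[RegionMask], list[NetworkSpec]]:
    """Load region masks from NIfTI files or a single integer label image.

    Parameters
    ----------
    source
        Either a mapping ``region_name -> NIfTI path`` of binary masks, or a
        pair ``(label_image_path, {label_value: region_name})`` where the
        label image uses positive integer labels.
    network_assignment
        Mapping ``network_name -> ordered region names``; region order is
        preserved into the returned :class:`NetworkSpec` objects.
    """
    region_to_network: dict[str, str] = {}
    for net, regions in network_assignment.items():
        for r in regions:
            if r in region_to_network:
                raise ValueError(f"region {r!r} assigned to more than one network")
            region_to_network[r] = net

    masks: dict[str, RegionMask] = {}
    if isinstance(source, tuple):
        label_path, label_map = source
        img = nib.load(str(label_path))
        data = np.asanyarray(img.dataobj)
        for label, region in label_map.items():
            if label <= 0:
                raise ValueError("label image labels must be positive integers")
            sel = data == label
            if not sel.any():
                raise ValueError(f"label {label} ({region}) selects no voxels")
            if region in masks:
                raise ValueError(f"duplicate region name {region!r}")
            masks[region] = RegionMask(region, region_to_network[region], sel, img.affine)
    else:
        shapes, affines = [], []
        for region, p in source.items():
            img = nib.load(str(p))
            data = np.asanyarray(img.dataobj) > 0
            shapes.append(data.shape)
            affines.append(img.affine)
            if region in masks:
                raise ValueError(f"duplicate region name {region!r}")
            masks[region] = RegionMask(region, region_to_network[region], data, img.affine)
        _check_grid(shapes, affines)

    ordered = []
    specs = []
    for net, regions in network_assignment.items():
        for r in regions:
            if r not in masks:
                raise ValueError(f"no mask provided for region {r!r}")
            ordered.append(masks[r])
        specs.append(NetworkSpec(net, tuple(regions)))
    return ordered, specs
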