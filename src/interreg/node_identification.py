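"""Identification of per-pair network nodes by maximal inter-regional correlation.

For every ordered pair of regions (a, b) in a network, the node V_ab is the
voxel of region ``a`` whose *thresholded total correlation* to region ``b``
is largest: each voxel's score is the sum of its Pearson correlations to all
voxels of ``b``, counting only correlations strictly greater than the
threshold ``tau`` (default 0.25).  The winning voxel's time series is the
node's series for all downstream connectivity measures.

Conventions
-----------
* Sub-threshold correlations contribute exactly 0 to a voxel's score (the
  global-brain-connectivity convention); with ``tau >= 0`` this also
  excludes all negative correlations.
* If no correlation anywhere passes the threshold, the voxel with the
  largest *unthresholded* correlation sum is selected and flagged
  ``suprathreshold=False``, so the node table always has its full
  N(N-1) shape.
* Score ties are broken by the lowest linearised voxel index, which is the
  first row in block order — deterministic across runs and platforms.
* Exactly constant (zero-variance) series have all their correlations
  defined as 0: a flat voxel carries no connectivity evidence.
* When nuisance regressors are supplied, every voxel series is first
  replaced by its least-squares residual against an intercept plus the
  regressors; Pearson correlations of those residuals equal partial
  correlations controlling for the nuisance signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_model import Node, NodeTable, NetworkSpec, RunConfig, VoxelSeriesBlock

__all__ = [
    "CorrBlockResult",
    "residualize",
    "pairwise_voxel_correlation",
    "thresholded_total_correlation",
    "score_block_pair",
    "select_primary_node",
    "identify_network_nodes",
    "duplicate_voxel_report",
]


@dataclass
class CorrBlockResult:
    """Per-voxel thresholded total-correlation scores of one region pair.

    ``scores[u]`` is the thresholded total correlation of source voxel ``u``
    to the target region when any voxel passed the threshold
    (``suprathreshold=True``); otherwise the unthresholded fallback sums.
    """

    source_region: str
    target_region: str
    scores: np.ndarray
    argmax_row: int
    suprathreshold: bool


def residualize(block: VoxelSeriesBlock, nuisance: np.ndarray | None) -> VoxelSeriesBlock:
    """Regress nuisance time courses out of every voxel series.

    Each row of the block is replaced by its ordinary-least-squares residual
    against ``[intercept | nuisance]``.  With ``nuisance=None`` (or zero
    columns) this reduces to row demeaning, which leaves Pearson
    correlations unchanged.

    Raises ``ValueError`` if the design matrix (including the intercept) is
    rank deficient.
    """
    T = block.T
    if nuisance is None:
        nuisance = np.empty((T, 0))
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if nuisance.shape[0] != T:
        raise ValueError(f"nuisance has {nuisance.shape[0]} rows, expected T={T}")
    if nuisance.shape[1] >= T:
        raise ValueError("more nuisance regressors than time points")
    X = np.column_stack([np.ones(T), nuisance])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("nuisance design matrix is rank deficient")
    # residual = (I - X (X'X)^-1 X') y  via lstsq for numerical stability
    coef, *_ = np.linalg.lstsq(X, block.series.T, rcond=None)
    resid = block.series.T - X @ coef
    return VoxelSeriesBlock(block.region_name, block.voxel_indices, resid.T)


def _standardized_rows(series: np.ndarray) -> np.ndarray:
    """Rows centred and scaled to unit norm; exactly-constant rows become 0."""
    S = np.asarray(series, dtype=float)
    constant = np.ptp(S, axis=1) == 0
    Z = S - S.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1)
    norms[constant] = 1.0  # avoid 0/0; the zeroed rows give correlation 0
    Z /= norms[:, None]
    Z[constant] = 0.0
    return Z


def pairwise_voxel_correlation(
    blockA: VoxelSeriesBlock | np.ndarray, blockB: VoxelSeriesBlock | np.ndarray
) -> np.ndarray:
    """Pearson correlation of every voxel of A with every voxel of B.

    Returns a ``(#voxA, #voxB)`` matrix with entries in [-1, 1].  Rows with
    zero variance yield 0 correlations.
    """
    A = blockA.series if isinstance(blockA, VoxelSeriesBlock) else np.asarray(blockA, float)
    B = blockB.series if isinstance(blockB, VoxelSeriesBlock) else np.asarray(blockB, float)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"time-point mismatch: {A.shape[1]} vs {B.shape[1]}")
    if A.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    C = _standardized_rows(A) @ _standardized_rows(B).T
    return np.clip(C, -1.0, 1.0)


def thresholded_total_correlation(corr_matrix: np.ndarray, tau: float) -> np.ndarray:
    """Per-source-voxel sum of correlations strictly greater than ``tau``.

    Entries at exactly ``tau`` are excluded (strict inequality).  With
    ``tau >= 0`` every score is non-negative.
    """
    if not (0.0 <= tau < 1.0):
        raise ValueError("tau must lie in [0, 1)")
    C = np.asarray(corr_matrix, dtype=float)
    return np.where(C > tau, C, 0.0).sum(axis=1)


def _argmax_lowest_index(
    scores: np.ndarray,
    blockA: VoxelSeriesBlock,
    blockB: VoxelSeriesBlock,
    tau: float | None,
) -> int:
    """Argmax with the lowest linearised index winning exact ties.

    BLAS matrix products can differ in the last ulp between bit-identical
    rows depending on their position, so near-ties (relative 1e-9) are
    re-scored with sequential dot products, under which identical series
    score identically; ``np.argmax`` then returns the first maximum.
    """
    m = scores.max()
    cand = np.flatnonzero(scores >= m - 1e-9 * max(1.0, abs(m)))
    if len(cand) == 1:
        return int(cand[0])
    Zb = _standardized_rows(blockB.series)
    exact = np.empty(len(cand))
    for i, u in enumerate(cand):
        z = _standardized_rows(blockA.series[u][None, :])[0]
        r = np.clip(np.array([np.dot(z, zb) for zb in Zb]), -1.0, 1.0)
        exact[i] = np.where(r > tau, r, 0.0).sum() if tau is not None else r.sum()
    return int(cand[int(np.argmax(exact))])


def score_block_pair(
    blockA: VoxelSeriesBlock,
    blockB: VoxelSeriesBlock,
    tau: float = 0.25,
    target_region: str | None = None,
) -> CorrBlockResult:
    """Score every voxel of ``blockA`` against ``blockB`` and locate the
    maximum.

    When no correlation anywhere exceeds ``tau``, scores fall back to the
    unthresholded sums and the result is flagged.  Exact score ties resolve
    to the lowest linearised voxel index.
    """
    if blockA.n_voxels == 0 or blockB.n_voxels == 0:
        raise ValueError("empty voxel block")
    C = pairwise_voxel_correlation(blockA, blockB)
    scores = thresholded_total_correlation(C, tau)
    supra = bool(scores.max() > 0.0)
    if not supra:
        scores = C.sum(axis=1)  # fallback keeps the table complete
    row = _argmax_lowest_index(scores, blockA, blockB, tau if supra else None)
    return CorrBlockResult(
        source_region=blockA.region_name,
        target_region=target_region or blockB.region_name,
        scores=scores,
        argmax_row=row,
        suprathreshold=supra,
    )


def select_primary_node(
    blockA: VoxelSeriesBlock,
    blockB: VoxelSeriesBlock,
    tau: float = 0.25,
    target_region: str | None = None,
) -> Node:
    """Select V_ab: the voxel of ``blockA`` with maximal thresholded total
    correlation to ``blockB``.

    Falls back to the unthresholded correlation sum (flagging the node) when
    no voxel has any suprathreshold correlation.  Ties go to the lowest
    linearised voxel index, i.e. the first row.
    """
    res = score_block_pair(blockA, blockB, tau=tau, target_region=target_region)
    row = res.argmax_row
    return Node(
        source_region=blockA.region_name,
        target_region=res.target_region,
        voxel=tuple(blockA.voxel_indices[row]),
        score=float(res.scores[row]),
        series=blockA.series[row].copy(),
        suprathreshold=res.suprathreshold,
    )


def identify_network_nodes(
    blocks: Mapping[str, VoxelSeriesBlock],
    spec: NetworkSpec,
    config: RunConfig | None = None,
    nuisance: np.ndarray | None = None,
    subject_id: str = "subject",
) -> NodeTable:
    """Identify all N(N-1) nodes of a network for one subject.

    ``blocks`` maps region name to its extracted voxel block.  If
    ``nuisance`` is given (and enabled in the config), all blocks are
    residualized before any correlation is computed, so node scores and node
    series are both based on partial correlations.
    """
    config = config or RunConfig()
    missing = [r for r in spec.regions if r not in blocks]
    if missing:
        raise ValueError(f"missing voxel blocks for regions {missing}")
    work = dict(blocks)
    if nuisance is not None and config.regress_nuisance:
        work = {r: residualize(b, nuisance) for r, b in work.items()}
    nodes = [
        select_primary_node(work[a], work[b], tau=config.tau, target_region=b)
        for a, b in spec.ordered_pairs()
    ]
    table = NodeTable(network_name=spec.network_name, subject_id=subject_id, nodes=nodes)
    table.validate_complete(spec)
    return table


def duplicate_voxel_report(table: NodeTable) -> list[dict]:
    """List voxels selected as the node to more than one target region.

    The method permits this (a strongly connected voxel can be the hub
    towards several regions), but duplicated voxels make the affected
    intra-regional correlations exactly 1, so they are reported rather than
    silently accepted.
    """
    by_voxel: dict[tuple[str, tuple[int, int, int]], list[str]] = {}
    for n in table.nodes:
        by_voxel.setdefault((n.source_region, n.voxel), []).append(n.target_region)
    return [
        {"region": region, "voxel": voxel, "targets": sorted(targets)}
        for (region, voxel), targets in sorted(by_voxel.items())
        if len(targets) > 1
    ]
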