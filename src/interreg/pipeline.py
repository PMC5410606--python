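"""End-to-end orchestration: subject-level node identification, measures,
group statistics and reports.

``run_pipeline`` drives the whole analysis from a manifest file::

    networks:
      dmn: [PFC, PCC, PLL]
    subjects:
      - id: s01
        group: HC
        image: s01_func.nii.gz
        masks: {PFC: masks/pfc.nii.gz, PCC: masks/pcc.nii.gz, PLL: masks/pll.nii.gz}
        nuisance: s01_nuisance.txt     # optional, whitespace-delimited T x q

For every subject it writes the node table (with time-series sidecar), the
node-by-node correlation matrix and the measure set; for every pair of
groups it writes the edgewise Welch comparison (p-matrix plus uncorrected
and FDR masks) and the measure-level tests; duplicate-node and
sub-threshold-fallback events are summarised in a report, and the run
configuration, seed and package version go to a JSON run log.  Two runs
with identical inputs and configuration produce byte-identical numeric
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity_measures import network_summary, node_edge_matrix
from .group_stats import anova_posthoc, apply_bh_by_family, compare_edge_matrices, measure_group_tests
from .io_model import (
    NetworkSpec,
    NodeTable,
    RegionMask,
    RunConfig,
    extract_block,
    load_region_masks,
    write_matrix,
    write_node_table,
)
from .node_identification import duplicate_voxel_report, identify_network_nodes
from .synthetic_data import SimulatedSubject

__all__ = [
    "SubjectResult",
    "analyze_subject",
    "analyze_simulated_subject",
    "specs_from_masks",
    "run_pipeline",
]


@dataclass
class SubjectResult:
    """Per-network outputs of one subject's analysis."""

    subject_id: str
    table: NodeTable
    labels: list[str]
    matrix: np.ndarray
    measure_set: object  # MeasureSet
    measures: pd.DataFrame
    duplicates: list[dict]

    @property
    def network_name(self) -> str:
        return self.table.network_name


def analyze_subject(
    image4d: np.ndarray,
    masks: dict[str, RegionMask],
    specs: list[NetworkSpec],
    config: RunConfig | None = None,
    nuisance: np.ndarray | None = None,
    subject_id: str = "subject",
) -> dict[str, SubjectResult]:
    """Run node identification and measures for one subject, per network."""
    config = config or RunConfig()
    results: dict[str, SubjectResult] = {}
    for spec in specs:
        blocks = {r: extract_block(image4d, masks[r]) for r in spec.regions}
        table = identify_network_nodes(
            blocks, spec, config=config, nuisance=nuisance, subject_id=subject_id
        )
        labels, matrix = node_edge_matrix(table)
        measures = network_summary(table, spec, config)
        results[spec.network_name] = SubjectResult(
            subject_id=subject_id,
            table=table,
            labels=labels,
            matrix=matrix,
            measure_set=measures,
            measures=measures.to_dataframe(),
            duplicates=duplicate_voxel_report(table),
        )
    return results


def specs_from_masks(masks: dict[str, RegionMask]) -> list[NetworkSpec]:
    """Reconstruct network specs from masks, preserving insertion order."""
    by_net: dict[str, list[str]] = {}
    for region, m in masks.items():
        by_net.setdefault(m.network_name, []).append(region)
    return [NetworkSpec(net, tuple(regions)) for net, regions in by_net.items()]


def analyze_simulated_subject(
    subject: SimulatedSubject, config: RunConfig | None = None
) -> dict[str, SubjectResult]:
    return analyze_subject(
        subject.image,
        subject.masks,
        specs_from_masks(subject.masks),
        config=config,
        subject_id=subject.subject_id,
    )


# ---------------------------------------------------------------------------
# manifest-driven end-to-end run
# ---------------------------------------------------------------------------

def _load_manifest(manifest: str | Path | dict) -> dict:
    if isinstance(manifest, (str, Path)):
        manifest = yaml.safe_load(Path(manifest).read_text())
    if not isinstance(manifest, dict) or "subjects" not in manifest or "networks" not in manifest:
        raise ValueError("manifest must define 'networks' and 'subjects'")
    ids = [s["id"] for s in manifest["subjects"]]
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    return manifest


def _load_subject_inputs(entry: dict, networks: dict, base: Path):
    img = nib.load(str(base / entry["image"]))
    image4d = np.asarray(img.dataobj, dtype=float)
    if "masks" in entry:
        source = {r: base / p for r, p in entry["masks"].items()}
    else:
        source = (base / entry["label_image"], {int(k): v for k, v in entry["labels"].items()})
    mask_list, specs = load_region_masks(source, networks)
    masks = {m.region_name: m for m in mask_list}
    nuisance = None
    if entry.get("nuisance"):
        nuisance = np.loadtxt(base / entry["nuisance"], ndmin=2)
    return image4d, masks, specs, nuisance


def run_pipeline(
    manifest: str | Path | dict,
    outdir: str | Path,
    config: RunConfig | None = None,
    base_dir: str | Path | None = None,
) -> Path:
    """Run the full analysis described by a manifest; returns the output dir.

    Group comparisons are produced for every pair of group labels found in
    the manifest (edgewise matrices and network-level measures); with three
    or more groups a one-way ANOVA omnibus test is added per network and
    measure.
    """
    config = config or RunConfig()
    manifest_dict = _load_manifest(manifest)
    base = Path(base_dir) if base_dir is not None else (
        Path(manifest).parent if isinstance(manifest, (str, Path)) else Path(".")
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    networks = manifest_dict["networks"]
    subj_results: dict[str, dict[str, SubjectResult]] = {}
    groups: dict[str, list[str]] = {}
    report_rows = []
    measure_rows = []

    for entry in manifest_dict["subjects"]:
        sid = str(entry["id"])
        try:
            image4d, masks, specs, nuisance = _load_subject_inputs(entry, networks, base)
            results = analyze_subject(
                image4d, masks, specs, config=config, nuisance=nuisance, subject_id=sid
            )
        except Exception as e:  # noqa: BLE001 - aggregated into a per-subject report
            raise RuntimeError(f"subject {sid!r} failed: {e}") from e
        subj_results[sid] = results
        groups.setdefault(str(entry.get("group", "all")), []).append(sid)
        for net, res in results.items():
            write_node_table(res.table, outdir / f"nodes_{net}_{sid}.tsv")
            write_matrix(res.labels, res.matrix, outdir / f"matrix_{net}_{sid}.tsv")
            measure_rows.append(res.measures)
            for d in res.duplicates:
                report_rows.append(
                    {"subject": sid, "network": net, "kind": "duplicate_voxel",
                     "detail": f"{d['region']} voxel {d['voxel']} -> {d['targets']}"}
                )
            for n in res.table.nodes:
                if not n.suprathreshold:
                    report_rows.append(
                        {"subject": sid, "network": net, "kind": "subthreshold_fallback",
                         "detail": f"V[{n.source_region}->{n.target_region}]"}
                    )

    measures_df = pd.concat(measure_rows, ignore_index=True)
    measures_df.to_csv(outdir / "measures.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(report_rows, columns=["subject", "network", "kind", "detail"]).to_csv(
        outdir / "flags.tsv", sep="\t", index=False
    )

    group_labels = sorted(groups)
    subject_group = {sid: g for g, sids in groups.items() for sid in sids}
    net_names = list(networks)

    # network-level measure values per subject, long format
    net_measures = measures_df[measures_df["region_a"] == "*network*"].copy()
    net_measures["group"] = net_measures["subject"].map(subject_group)

    if len(group_labels) >= 2:
        for ga, gb in combinations(group_labels, 2):
            # edgewise comparison per network
            for net in net_names:
                sa = [sid for sid in groups[ga]]
                sb = [sid for sid in groups[gb]]
                if len(sa) < 2 or len(sb) < 2:
                    continue
                labels = subj_results[sa[0]][net].labels
                stack_a = np.stack([subj_results[s][net].matrix for s in sa])
                stack_b = np.stack([subj_results[s][net].matrix for s in sb])
                cmp = compare_edge_matrices(stack_a, stack_b, labels, config)
                prefix = outdir / f"edges_{net}_{ga}_vs_{gb}"
                write_matrix(labels, cmp.p_matrix, Path(f"{prefix}_p.tsv"))
                write_matrix(labels, cmp.mask_uncorrected.astype(float),
                             Path(f"{prefix}_mask_uncorrected.tsv"))
                write_matrix(labels, cmp.mask_fdr.astype(float),
                             Path(f"{prefix}_mask_fdr.tsv"))
            # measure-level tests
            sub = net_measures[net_measures["group"].isin([ga, gb])]
            tests = measure_group_tests(
                sub[["subject", "group", "network", "measure", "value"]],
                alpha=config.fdr_alpha,
            )
            tests.to_csv(outdir / f"measure_tests_{ga}_vs_{gb}.tsv", sep="\t",
                         index=False, float_format="%.17g")

    if len(group_labels) >= 3:
        rows = []
        for net in net_names:
            for measure in ("R1", "R12", "R2", "RI"):
                cell = net_measures[(net_measures["network"] == net)
                                    & (net_measures["measure"] == measure)]
                samples = {g: cell.loc[cell["group"] == g, "value"].to_numpy()
                           for g in group_labels}
                omnibus, _ = anova_posthoc(samples, measure=measure, family=measure,
                                           alpha=config.fdr_alpha)
                rows.append({"network": net, "measure": measure,
                             "F": omnibus[0], "p": omnibus[1]})
        pd.DataFrame(rows).to_csv(outdir / "anova_omnibus.tsv", sep="\t",
                                  index=False, float_format="%.17g")

    log = {
        "version": __version__,
        "config": config.to_dict(),
        "groups": {g: sorted(s) for g, s in groups.items()},
        "networks": networks,
        "n_subjects": len(subj_results),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return outdir
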