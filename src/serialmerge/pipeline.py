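"""Two-stage orchestration: cell-based clustering to a completeness cutover,
cluster merging, then reflection-correlation clustering of the merged sets.

Stage 1 builds a cell distance matrix (NCDist by default, or the original
PCA/Euclidean cell distance), Ward-clusters it, annotates the dendrogram
with completeness, and selects the lowest non-overlapping nodes whose
merged completeness reaches the cutover (default 10%).  Stage 2 merges
each selected cluster into one reflection set, builds the SFDist matrix
over the merged sets, Ward-clusters again and cuts the tree into flat
clusters (largest height gap by default).  Purity reporting against known
form labels supports both flat assignments and dendrogram-node candidate
clusters; the latter mirrors how the largest 100%-pure clusters of a
hierarchical clustering are counted.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import (
    ClusterSelection,
    Dendrogram,
    annotate_completeness,
    annotate_lcv,
    cluster_report_tsv,
    cut_count,
    cut_height,
    cut_largest_gap,
    dendrogram_to_json,
    dendrogram_to_newick,
    select_nonoverlapping,
    ward_linkage,
)
from .errors import ConfigError, MissingLabelError, SerialMergeError
from .lattice import (
    UnitCell,
    blend_cell_distance_matrix,
    ncdist_matrix,
    read_cells_csv,
    write_distance_tsv,
)
from .reflections import ReflectionSet, merge_sets, read_hkl, sfdist_matrix

logger = logging.getLogger("serialmerge")

__all__ = [
    "RunConfig",
    "PurityReport",
    "RunResult",
    "run_stage1",
    "run_stage2",
    "run_two_stage",
    "purity_report",
    "largest_pure_node_sizes",
    "load_inputs",
]


@dataclass
class RunConfig:
    """All knobs of a two-stage run; (de)serializes to YAML."""

    stage1_metric: str = "ncdist"  # ncdist | blend_pca
    cutover_completeness: float = 0.10
    d_min: float = 2.5
    laue_group: str = "4/mmm"
    sfdist_penalty_weight: float = 1.0
    sfdist_activation: float = 0.90
    sfdist_base: str = "chord"  # chord | sine
    scale_mode: str = "linear"  # linear | none
    comparison: str = "intensity"  # intensity | amplitude
    stage2_cut_mode: str = "gap"  # gap | count | height
    stage2_cut_value: float | None = None
    variance_cutoff: float = 0.01  # blend_pca explained-variance cutoff
    merge_max_lcv_percent: float = 2.0
    sentinel_distance: float = 10.0
    random_seed: int = 0
    cells_csv: str | None = None
    truth_csv: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.stage1_metric not in ("ncdist", "blend_pca"):
            raise ConfigError(f"unknown stage1_metric {self.stage1_metric!r}")
        if not 0 < self.cutover_completeness <= 1:
            raise ConfigError("cutover_completeness must be in (0, 1]")
        if self.d_min <= 0:
            raise ConfigError("d_min must be positive")
        if self.stage2_cut_mode not in ("gap", "count", "height"):
            raise ConfigError(f"unknown stage2_cut_mode {self.stage2_cut_mode!r}")
        if self.stage2_cut_mode in ("count", "height") and self.stage2_cut_value is None:
            raise ConfigError(f"stage2_cut_mode={self.stage2_cut_mode} needs a value")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


def load_inputs(config: RunConfig):
    """Read the cells CSV and every referenced HKL file."""
    if config.cells_csv is None:
        raise ConfigError("config.cells_csv is not set")
    base = Path(config.cells_csv).parent
    ids, cells, paths = read_cells_csv(config.cells_csv)
    sets = {}
    for ds in ids:
        p = Path(paths[ds])
        if not p.is_absolute():
            p = base / p
        sets[ds] = read_hkl(p, cell=cells[ds], laue_group=config.laue_group,
                            dataset_id=ds, merged=True)
    return ids, cells, sets


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage1_matrix(cells_list, ids, config: RunConfig) -> np.ndarray:
    if config.stage1_metric == "ncdist":
        return ncdist_matrix(cells_list, ids=ids)
    return blend_cell_distance_matrix(cells_list, variance_cutoff=config.variance_cutoff)


def run_stage1(cells: dict[str, UnitCell], sets: dict[str, ReflectionSet],
               config: RunConfig, ids=None):
    """Cell-distance Ward clustering and completeness-gated selection.

    Returns (annotated Dendrogram, ClusterSelection).
    """
    ids = list(ids) if ids is not None else sorted(cells)
    missing = [ds for ds in ids if ds not in sets]
    if missing:
        raise MissingLabelError(f"datasets without reflection sets: {missing[:5]}")
    D = _stage1_matrix([cells[ds] for ds in ids], ids, config)
    dend = ward_linkage(D, ids)
    annotate_completeness(dend, sets, config.d_min)
    annotate_lcv(dend, cells)
    selection = select_nonoverlapping(dend, config.cutover_completeness)
    logger.info(
        "stage 1: %d datasets in, %d clusters selected covering %d datasets, "
        "%d unassigned", len(ids), len(selection), selection.n_datasets(),
        len(selection.unassigned),
    )
    return dend, selection


def _cut(dend: Dendrogram, config: RunConfig) -> dict[str, int]:
    if config.stage2_cut_mode == "count":
        return cut_count(dend, int(config.stage2_cut_value))
    if config.stage2_cut_mode == "height":
        return cut_height(dend, float(config.stage2_cut_value))
    return cut_largest_gap(dend)


def run_stage2(selection: ClusterSelection, sets: dict[str, ReflectionSet],
               config: RunConfig):
    """Merge the selected clusters and Ward-cluster them on SFDist.

    Returns (Dendrogram over merged sets, {merged id: flat cluster},
    {merged id: ReflectionSet}, {merged id: [dataset ids]}, failures).
    A single selected cluster degenerates to the identity assignment with a
    warning.
    """
    merged: dict[str, ReflectionSet] = {}
    membership: dict[str, list[str]] = {}
    for node_id, members, _comp in selection.clusters:
        mid = f"c{node_id:05d}"
        merged[mid] = merge_sets([sets[ds] for ds in members],
                                 scale_mode=config.scale_mode,
                                 max_lcv_percent=config.merge_max_lcv_percent,
                                 dataset_id=mid)
        membership[mid] = list(members)
    mids = sorted(merged)
    if len(mids) < 2:
        logger.warning("stage 2: only %d merged cluster(s); identity assignment",
                       len(mids))
        return None, {m: 0 for m in mids}, merged, membership, []
    D, failures = sfdist_matrix(
        [merged[m] for m in mids],
        penalty_weight=config.sfdist_penalty_weight,
        activation_threshold=config.sfdist_activation,
        base=config.sfdist_base,
        quantity=config.comparison,
        sentinel=config.sentinel_distance,
    )
    for a, b, reason in failures:
        logger.warning("stage 2: sentinel distance for %s vs %s (%s)", a, b, reason)
    dend = ward_linkage(D, mids)
    assignment = _cut(dend, config)
    logger.info("stage 2: %d merged sets in, %d flat clusters out",
                len(mids), len(set(assignment.values())))
    return dend, assignment, merged, membership, failures


@dataclass
class RunResult:
    """Artifacts of a two-stage run."""

    config: RunConfig
    stage1_dendrogram: Dendrogram
    selection: ClusterSelection
    stage2_dendrogram: Dendrogram | None
    merged_sets: dict[str, ReflectionSet]
    membership: dict[str, list[str]]  # merged id -> dataset ids
    cluster_of_merged: dict[str, int]
    assignment: pd.DataFrame  # dataset_id, stage1_node, stage2_cluster
    failures: list

    def dataset_cluster(self) -> dict[str, int]:
        """Flat stage-2 cluster per assigned dataset."""
        out = {}
        for mid, members in self.membership.items():
            for ds in members:
                out[ds] = self.cluster_of_merged[mid]
        return out


def _assignment_frame(selection: ClusterSelection, membership, cluster_of_merged,
                      all_ids) -> pd.DataFrame:
    node_of_ds = {}
    for node_id, members, _ in selection.clusters:
        for ds in members:
            node_of_ds[ds] = node_id
    merged_of_ds = {ds: mid for mid, members in membership.items() for ds in members}
    rows = []
    for ds in all_ids:
        if ds in node_of_ds:
            mid = merged_of_ds[ds]
            rows.append((ds, node_of_ds[ds], cluster_of_merged[mid]))
        else:
            rows.append((ds, -1, -1))
    return pd.DataFrame(rows, columns=["dataset_id", "stage1_node", "stage2_cluster"])


def run_two_stage(config: RunConfig, cells=None, sets=None, ids=None,
                  truth=None) -> RunResult:
    """Execute stage 1 then stage 2 and write all artifact files.

    Inputs may be given in memory or loaded from ``config.cells_csv``.  The
    run is fully deterministic given config and inputs.  On an error after
    stage 1, partial artifacts are flushed with a MANIFEST marking the run
    incomplete.
    """
    if cells is None or sets is None:
        ids, cells, sets = load_inputs(config)
    ids = list(ids) if ids is not None else sorted(cells)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    written = []

    def flush(name, text):
        if out:
            (out / name).write_text(text, encoding="utf-8")
            written.append(name)

    try:
        dend1, selection = run_stage1(cells, sets, config, ids=ids)
        if out:
            flush("stage1.nwk", dendrogram_to_newick(dend1))
            flush("stage1.json", dendrogram_to_json(dend1))
            selection.to_tsv(out / "selection.tsv")
            written.append("selection.tsv")
            cluster_report_tsv(dend1, out / "stage1_clusters.tsv")
            written.append("stage1_clusters.tsv")
        dend2, cluster_of_merged, merged, membership, failures = run_stage2(
            selection, sets, config)
    except SerialMergeError as exc:
        flush("MANIFEST", "status: INCOMPLETE\nerror: " + str(exc) + "\n"
              + "files:\n" + "".join(f"- {w}\n" for w in written))
        raise

    assignment = _assignment_frame(selection, membership, cluster_of_merged, ids)
    result = RunResult(
        config=config, stage1_dendrogram=dend1, selection=selection,
        stage2_dendrogram=dend2, merged_sets=merged, membership=membership,
        cluster_of_merged=cluster_of_merged, assignment=assignment,
        failures=failures,
    )
    if out:
        if dend2 is not None:
            flush("stage2.nwk", dendrogram_to_newick(dend2))
            flush("stage2.json", dendrogram_to_json(dend2))
        assignment.to_csv(out / "assignment.tsv", sep="\t", index=False)
        written.append("assignment.tsv")
        if truth is not None:
            rep = purity_report(result.dataset_cluster(), truth)
            rep.to_tsv(out / "purity.tsv")
            written.append("purity.tsv")
        n_assigned = int((assignment["stage1_node"] >= 0).sum())
        log_text = (
            f"datasets_in: {len(ids)}\n"
            f"stage1_selected_clusters: {len(selection)}\n"
            f"datasets_selected: {n_assigned}\n"
            f"datasets_unassigned: {len(selection.unassigned)}\n"
            f"stage2_merged_sets: {len(merged)}\n"
            f"stage2_flat_clusters: {len(set(cluster_of_merged.values()))}\n"
            f"sfdist_sentinel_pairs: {len(failures)}\n"
        )
        flush("run_log.txt", log_text)
        flush("MANIFEST", "status: COMPLETE\nfiles:\n"
              + "".join(f"- {w}\n" for w in sorted(set(written))))
    return result


# ---------------------------------------------------------------------------
# Purity reporting
# ---------------------------------------------------------------------------


@dataclass
class PurityReport:
    """Composition and purity of clusters against true form labels."""

    table: pd.DataFrame  # cluster, size, purity, majority_label, <per-label counts>
    largest_pure: dict[str, int]  # form label -> size of largest 100%-pure cluster

    @property
    def mean_purity(self) -> float:
        return float(self.table["purity"].mean())

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def purity_report(assignment: dict[str, int], truth: dict[str, str]) -> PurityReport:
    """Purity of a flat clustering: per cluster, composition counts and the
    maximum label fraction; per form, the largest cluster that is 100% pure.
    """
    missing = [ds for ds in assignment if ds not in truth]
    if missing:
        raise MissingLabelError(f"datasets without truth label: {missing[:5]}")
    labels = sorted(set(truth[ds] for ds in assignment))
    rows = []
    clusters = sorted(set(assignment.values()))
    largest_pure = {lab: 0 for lab in labels}
    for cl in clusters:
        members = [ds for ds, c in assignment.items() if c == cl]
        counts = {lab: 0 for lab in labels}
        for ds in members:
            counts[truth[ds]] += 1
        size = len(members)
        best_label = max(counts, key=lambda k: (counts[k], k))
        purity = counts[best_label] / size
        if purity == 1.0:
            largest_pure[best_label] = max(largest_pure[best_label], size)
        rows.append({"cluster": cl, "size": size, "purity": purity,
                     "majority_label": best_label, **counts})
    table = pd.DataFrame(rows)
    return PurityReport(table=table, largest_pure=largest_pure)


def largest_pure_node_sizes(dend: Dendrogram, membership: dict[str, list[str]],
                            truth: dict[str, str]) -> dict[str, int]:
    """Largest 100%-pure cluster per form over all dendrogram nodes.

    ``membership`` maps each dendrogram leaf (a merged set) to its original
    dataset ids; node size is counted in datasets.  For a dendrogram whose
    leaves are datasets themselves, pass ``{ds: [ds]}``.
    """
    labels = sorted(set(truth.values()))
    out = {lab: 0 for lab in labels}
    for node_id in dend.all_node_ids():
        datasets = [ds for leaf in dend.member_ids(node_id)
                    for ds in membership[leaf]]
        node_labels = {truth[ds] for ds in datasets}
        if len(node_labels) == 1:
            lab = node_labels.pop()
            out[lab] = max(out[lab], len(datasets))
    return out
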