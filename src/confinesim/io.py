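"""Serialization of runs and datasets.

A run is written as a small file set under one output directory:

``clones.tsv``
    One row per clone ever created (lineage table).
``trajectory.tsv``
    One row per checkpoint (population totals and metrics).
``phylogeny.nwk``
    Newick tree over the *displayed* clones — those whose alive fraction
    reached at least 1% of the population at some checkpoint — with branch
    lengths equal to birth-step differences and an ``x`` suffix marking
    clones that ended with fewer than 1000 alive cells (extinct for display
    purposes).
``fish_populations.tsv`` / ``fish_edges.tsv``
    The two-table layout consumed by common Muller-plot tools, restricted
    to the displayed clones.
``run_log.json``
    Seed, restarts used, termination reason, steps and final totals.

All tables are tab-separated with header rows and round-trip through their
own readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd

from .engine import RunResult
from .fit import Dataset, FitResult
from .metrics import MetricPoint

__all__ = [
    "DISPLAY_CUTOFF",
    "EXTINCT_DISPLAY_THRESHOLD",
    "DatasetFormatError",
    "write_run",
    "read_clone_table",
    "read_dataset",
    "write_dataset",
    "write_grid",
    "build_phylogeny",
]

#: Minimum alive population fraction a clone must ever reach to be displayed.
DISPLAY_CUTOFF = 0.01
#: Clones ending with fewer alive cells than this are flagged extinct.
EXTINCT_DISPLAY_THRESHOLD = 1000

CLONE_COLUMNS = [
    "clone_id",
    "parent_id",
    "birth_step",
    "n_alive",
    "n_necrotic",
    "n_drivers",
    "fitness",
]
TRAJECTORY_COLUMNS = ["step", "pop_alive", "pop_necrotic", "mean_drivers", "diversity"]
DATASET_COLUMNS = ["sample", "mean_drivers", "diversity"]


class DatasetFormatError(ValueError):
    """A dataset file does not conform to the sample/drivers/diversity schema."""


def _displayed_clones(result: RunResult) -> set[int]:
    """Clone ids whose alive fraction ever reached ``DISPLAY_CUTOFF``."""
    pops = result.clone_populations.merge(
        result.checkpoints[["step", "pop_alive"]], on="step", how="left"
    )
    big = pops[pops["pop"] >= DISPLAY_CUTOFF * pops["pop_alive"]]
    displayed = set(big["clone_id"].tolist())
    displayed.add(0)  # the founder is always shown as the root
    return displayed


def _display_parent(cid: int, parents: dict[int, int], displayed: set[int]) -> int:
    """Nearest displayed ancestor (non-displayed intermediates contracted)."""
    pid = parents[cid]
    while pid >= 0 and pid not in displayed:
        pid = parents[pid]
    return pid


def build_phylogeny(result: RunResult) -> dendropy.Tree:
    """Clone phylogeny over displayed clones, branch lengths in steps."""
    displayed = _displayed_clones(result)
    df = result.clones
    parents = dict(zip(df["clone_id"], df["parent_id"]))
    birth = dict(zip(df["clone_id"], df["birth_step"]))
    alive = dict(zip(df["clone_id"], df["n_alive"]))

    tree = dendropy.Tree()
    nodes: dict[int, dendropy.Node] = {}
    for cid in sorted(displayed):
        label = str(cid) + ("x" if alive[cid] < EXTINCT_DISPLAY_THRESHOLD else "")
        node = tree.seed_node if cid == 0 else dendropy.Node()
        node.label = label
        nodes[cid] = node
    for cid in sorted(displayed):
        if cid == 0:
            continue
        pid = _display_parent(cid, parents, displayed)
        nodes[pid].add_child(nodes[cid])
        nodes[cid].edge.length = birth[cid] - birth[pid]
    # attach taxa to leaves so standard Newick readers round-trip the labels
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    for node in tree.leaf_node_iter():
        node.taxon = ns.new_taxon(node.label)
    return tree


def write_run(result: RunResult, out_prefix: str | Path) -> dict[str, Path]:
    """Write the full file set for one run under directory ``out_prefix``."""
    out = Path(out_prefix)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    paths = {}

    clones = result.clones[CLONE_COLUMNS]
    paths["clones"] = out / "clones.tsv"
    clones.to_csv(paths["clones"], sep="\t", index=False)

    paths["trajectory"] = out / "trajectory.tsv"
    result.checkpoints[TRAJECTORY_COLUMNS].to_csv(
        paths["trajectory"], sep="\t", index=False, float_format="%.6g"
    )

    displayed = _displayed_clones(result)
    pops = result.clone_populations
    fish_pops = pops[pops["clone_id"].isin(displayed)][["clone_id", "step", "pop"]]
    paths["fish_populations"] = out / "fish_populations.tsv"
    fish_pops.to_csv(paths["fish_populations"], sep="\t", index=False)

    parents = dict(zip(result.clones["clone_id"], result.clones["parent_id"]))
    edges = [
        {"parent_id": _display_parent(cid, parents, displayed), "child_id": cid}
        for cid in sorted(displayed)
        if cid != 0
    ]
    paths["fish_edges"] = out / "fish_edges.tsv"
    pd.DataFrame(edges, columns=["parent_id", "child_id"]).to_csv(
        paths["fish_edges"], sep="\t", index=False
    )

    tree = build_phylogeny(result)
    paths["phylogeny"] = out / "phylogeny.nwk"
    tree.write(
        path=str(paths["phylogeny"]),
        schema="newick",
        suppress_internal_node_labels=False,
        suppress_rooting=True,
    )

    paths["log"] = out / "run_log.json"
    paths["log"].write_text(json.dumps(result.log, indent=2, sort_keys=True) + "\n")
    return paths


def read_clone_table(path: str | Path) -> pd.DataFrame:
    """Read ``clones.tsv`` back; validates the schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLONE_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")
    return df


def read_dataset(path: str | Path, label: str | None = None) -> Dataset:
    """Read a delimited sample table (``sample,mean_drivers,diversity``).

    The delimiter (comma or tab) is sniffed.  Malformed rows raise
    :class:`DatasetFormatError` naming the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")
    points = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        md, dv = row["mean_drivers"], row["diversity"]
        if pd.isna(md) or pd.isna(dv):
            raise DatasetFormatError(f"{path}: line {line}: missing value")
        try:
            md, dv = float(md), float(dv)
        except (TypeError, ValueError):
            raise DatasetFormatError(f"{path}: line {line}: non-numeric value") from None
        if dv < 1.0:
            raise DatasetFormatError(f"{path}: line {line}: diversity < 1")
        if md < 0.0:
            raise DatasetFormatError(f"{path}: line {line}: negative mean_drivers")
        points.append(MetricPoint(md, dv))
    return Dataset(label=label or path.stem, points=tuple(points))


def write_dataset(dataset: Dataset, path: str | Path) -> Path:
    """Write a dataset as CSV in the schema :func:`read_dataset` consumes."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample": [f"{dataset.label}_{i}" for i in range(len(dataset.points))],
            "mean_drivers": [p.mean_drivers for p in dataset.points],
            "diversity": [p.diversity for p in dataset.points],
        }
    )
    df.to_csv(path, index=False)
    return path


def write_grid(fit_result: FitResult, path: str | Path) -> Path:
    """Write the grid-search scores as a long-format TSV."""
    path = Path(path)
    pd.DataFrame(fit_result.to_records()).to_csv(path, sep="\t", index=False)
    return path
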