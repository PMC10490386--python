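"""Reading, writing and harmonizing the pipeline's external artifacts.

Trees travel as Newick, incidence/distance/assignment tables as delimited
text (tab or comma, auto-detected on read), and run summaries as JSON.
``harmonize`` reconciles the taxon label sets of a tree and an occurrence
matrix, which is needed because tree building is upstream of this package:
the tree typically covers more (or fewer) taxa than the survey matrix.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    DistanceMatrix,
    FloregionError,
    OccurrenceMatrix,
    Phylogeny,
    SiteAdjacency,
)

log = logging.getLogger("floregion")


def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override:
        return override
    sample = Path(path).read_text().splitlines()[0]
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def read_tree(path, default_edge_length: float | None = None) -> Phylogeny:
    """Parse a Newick file into a :class:`Phylogeny`.

    Missing branch lengths are rejected unless ``default_edge_length`` is
    given (branch-length turnover is undefined without lengths); zero-length
    edges are preserved as zero.
    """
    text = Path(path).read_text()
    try:
        return Phylogeny.from_newick(text, default_edge_length=default_edge_length)
    except FloregionError:
        raise
    except Exception as exc:  # dendropy parse errors
        raise FloregionError(f"could not parse Newick file {path}: {exc}") from exc


def write_tree(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_matrix(
    path,
    delimiter: str | None = None,
    transpose: bool = False,
) -> tuple[OccurrenceMatrix, dict]:
    """Read a site x taxon presence-absence table.

    First column holds site ids, header row taxon ids, cells 0/1. All-zero
    rows and columns are dropped and reported. ``transpose=True`` accepts
    taxa-in-rows input.
    """
    delim = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.map(lambda s: str(s).strip())
    df.columns = df.columns.map(lambda s: str(s).strip())
    mat = OccurrenceMatrix(df)
    mat, report = mat.drop_empty()
    if report["dropped_sites"] or report["dropped_taxa"]:
        log.info(
            "read_matrix: dropped %d empty sites %s and %d empty taxa %s",
            len(report["dropped_sites"]), report["dropped_sites"],
            len(report["dropped_taxa"]), report["dropped_taxa"],
        )
    return mat, report


def write_matrix(mat: OccurrenceMatrix, path, delimiter: str = "\t") -> None:
    mat.table.to_csv(path, sep=delimiter, index_label="site")


def read_distance(path, delimiter: str | None = None, metric: str = "") -> DistanceMatrix:
    """Read a labelled square dissimilarity matrix."""
    delim = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, index_col=0)
    ids = [str(s).strip() for s in df.index]
    if [str(c).strip() for c in df.columns] != ids:
        raise FloregionError("distance matrix row and column labels differ")
    return DistanceMatrix(tuple(ids), df.to_numpy(dtype=float), metric)


def write_distance(dist: DistanceMatrix, path, delimiter: str = "\t") -> None:
    dist.to_dataframe().to_csv(path, sep=delimiter, index_label="site")


def read_adjacency(path, known_sites: Iterable[str] | None = None) -> SiteAdjacency:
    """Read adjacency as two-column delimited text (one pair per line)."""
    pairs = []
    with open(path, newline="") as fh:
        sample = fh.read()
    delim = "\t" if sample.count("\t") >= sample.count(",") else ","
    for row in csv.reader(sample.splitlines(), delimiter=delim):
        if not row or row[0].startswith("#"):
            continue
        if len(row) < 2:
            raise FloregionError(f"adjacency line has fewer than 2 fields: {row}")
        pairs.append((row[0], row[1]))
    return SiteAdjacency.from_pairs(pairs, known_sites=known_sites)


def write_regions(assignment, path, delimiter: str = "\t") -> None:
    """Write a (site_id, region, realm) assignment table."""
    rows = [
        {"site": s, "region": assignment.regions[s], "realm": assignment.realms[s]}
        for s in assignment.site_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_summary(summary: dict, path) -> None:
    """Write the structured run summary as deterministic JSON."""
    Path(path).write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _json_default(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def harmonize(
    tree: Phylogeny, mat: OccurrenceMatrix
) -> tuple[Phylogeny, OccurrenceMatrix, dict]:
    """Restrict tree and matrix to their shared taxon labels.

    Pruning suppresses the degree-2 internal nodes it creates, summing their
    incident branch lengths, so root-to-tip distances of retained taxa are
    unchanged. Idempotent: applying it twice equals applying it once.
    """
    tree_taxa = set(tree.tip_labels)
    mat_taxa = set(mat.taxon_ids)
    shared = tree_taxa & mat_taxa
    if not shared:
        raise FloregionError("tree and matrix share no taxon labels")
    if len(shared) < 2:
        raise FloregionError("tree and matrix share fewer than 2 taxon labels")
    report = {
        "dropped_from_tree": sorted(tree_taxa - mat_taxa),
        "dropped_from_matrix": sorted(mat_taxa - tree_taxa),
    }
    out_tree = tree if not report["dropped_from_tree"] else tree.prune_to(shared)
    out_mat = mat if not report["dropped_from_matrix"] else mat.restrict_taxa(shared)
    if report["dropped_from_matrix"]:
        out_mat, drop_report = out_mat.drop_empty()
        report["sites_emptied"] = drop_report["dropped_sites"]
    else:
        report["sites_emptied"] = []
    if report["dropped_from_tree"] or report["dropped_from_matrix"]:
        log.info(
            "harmonize: dropped %d tree-only and %d matrix-only taxa",
            len(report["dropped_from_tree"]), len(report["dropped_from_matrix"]),
        )
    return out_tree, out_mat, report
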