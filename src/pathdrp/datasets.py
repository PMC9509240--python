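"""Shared data types and readers/writers for omics matrices, response labels
and pathway graphs.

Omics matrices are TSV with gene identifiers in the first column and sample
identifiers in the header row.  Labels are a 2-column TSV ``sample_id\tlabel``
where the label is either a raw clinical response category or already 0/1
(auto-detected).  Pathways are a line-oriented TSV: ``pathway_id\tgeneA\tgeneB``
declares an undirected edge, ``pathway_id\tgeneA`` an isolated node, and lines
starting with ``#`` are comments.  Gene identifiers are opaque strings matched
exactly; no ID mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical omics layer order used throughout the package
DEFAULT_OMICS_NAMES = ("mRNA", "Methyl", "CNV")

#: clinical response categories collapsed to the responder class
RESPONDER_CATEGORIES = frozenset({"complete response", "partial response"})
NONRESPONDER_CATEGORIES = frozenset({"stable disease", "progressive disease"})


class DataFormatError(ValueError):
    """Raised when an input file violates the expected text format."""


@dataclass
class OmicsDataset:
    """Multi-omics cohort: gene×sample matrices sharing one sample axis.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers; column ``i`` of every omics matrix refers
        to ``sample_ids[i]``.
    omics
        Mapping from omics name to a gene×sample :class:`pandas.DataFrame`.
        Gene sets may differ between layers.
    labels
        Binary drug response per sample, 1 = responder, 0 = non-responder.
    """

    sample_ids: list[str]
    omics: dict[str, pd.DataFrame]
    labels: np.ndarray
    omics_names: tuple[str, ...] = DEFAULT_OMICS_NAMES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError(
                f"labels length {len(self.labels)} != "
                f"{len(self.sample_ids)} samples"
            )
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        for name, mat in self.omics.items():
            if list(mat.columns) != list(self.sample_ids):
                raise ValueError(
                    f"omics layer {name!r} sample axis differs from dataset "
                    "sample_ids"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def genes(self) -> set[str]:
        """Union of gene identifiers over all layers."""
        out: set[str] = set()
        for mat in self.omics.values():
            out.update(mat.index)
        return out

    def subset(self, idx: Sequence[int]) -> "OmicsDataset":
        """Column-subset every layer (and the labels) to the given positions."""
        idx = list(idx)
        return OmicsDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            omics={k: v.iloc[:, idx] for k, v in self.omics.items()},
            labels=self.labels[idx],
            omics_names=self.omics_names,
        )


@dataclass
class PathwayGraph:
    """Node-weighted undirected pathway graph.

    Edge direction present in source files is discarded: subpathway search
    only needs adjacency.  Unscored genes carry weight 0.
    """

    pathway_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def set_weights(self, weights: Mapping[str, float]) -> None:
        """Attach composite scores as node weights; missing genes get 0."""
        for n in self.graph.nodes:
            w = float(weights.get(n, 0.0))
            if w < 0:
                raise ValueError(f"negative weight for gene {n!r}")
            self.graph.nodes[n]["weight"] = w

    def node_weight(self, gene: str) -> float:
        return float(self.graph.nodes[gene].get("weight", 0.0))

    def weight_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else self.nodes
        return np.array(
            [self.graph.nodes[n].get("weight", 0.0) for n in order], float
        )


def binarize_response(raw: Iterable[str]) -> list[int]:
    """Collapse the four clinical response categories to 0/1.

    Complete and partial response are responders (1); stable and progressive
    disease are non-responders (0).  Matching is case-insensitive.
    """
    out = []
    for cat in raw:
        key = str(cat).strip().lower()
        if key in RESPONDER_CATEGORIES:
            out.append(1)
        elif key in NONRESPONDER_CATEGORIES:
            out.append(0)
        else:
            raise ValueError(
                f"unknown response category {cat!r}; expected one of "
                f"{sorted(RESPONDER_CATEGORIES | NONRESPONDER_CATEGORIES)}"
            )
    return out


def read_omics_matrix(path: str | Path, omics_name: str = "") -> pd.DataFrame:
    """Read a gene×sample TSV into a numeric DataFrame.

    Duplicate gene rows are collapsed by mean; non-numeric cells become NaN.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"empty omics file: {path}") from None
    if df.shape[1] == 0:
        raise DataFormatError(f"omics file has no sample columns: {path}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.index.has_duplicates:
        logger.warning(
            "%s: %d duplicate gene rows collapsed by mean in %s",
            omics_name or path.name,
            int(df.index.duplicated().sum()),
            path,
        )
        df = df.groupby(level=0, sort=False).mean()
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_labels(path: str | Path) -> pd.Series:
    """Read the 2-column labels TSV; raw categories are binarized.

    Returns a Series of 0/1 indexed by sample id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataFormatError(f"labels file needs 2 columns: {path}")
    # tolerate an optional header line
    first = df.iloc[0, 1].strip().lower()
    if first not in {"0", "1"} | RESPONDER_CATEGORIES | NONRESPONDER_CATEGORIES:
        df = df.iloc[1:]
    samples = df.iloc[:, 0].astype(str).tolist()
    vals = [v.strip() for v in df.iloc[:, 1]]
    if all(v in {"0", "1"} for v in vals):
        binary = [int(v) for v in vals]
    else:
        binary = binarize_response(vals)
    return pd.Series(binary, index=samples, name="response")


def assemble_dataset(
    omics_paths: Mapping[str, str | Path],
    labels_path: str | Path,
) -> OmicsDataset:
    """Load omics layers + labels and align everything on shared samples.

    Samples must be common to the labels file and every omics layer; a layer
    with no overlap is a hard error naming the file.
    """
    labels = read_labels(labels_path)
    shared = list(labels.index)
    mats: dict[str, pd.DataFrame] = {}
    for name, path in omics_paths.items():
        mat = read_omics_matrix(path, name)
        keep = [s for s in shared if s in set(mat.columns)]
        if not keep:
            raise DataFormatError(
                f"omics layer {name!r} ({path}) shares no samples with the "
                "previously loaded layers/labels"
            )
        shared = keep
        mats[name] = mat
    omics = {name: mat.loc[:, shared] for name, mat in mats.items()}
    return OmicsDataset(
        sample_ids=shared,
        omics=omics,
        labels=labels.loc[shared].to_numpy(),
        omics_names=tuple(omics_paths),
    )


def read_pathways(path: str | Path) -> list[PathwayGraph]:
    """Parse the pathway edge-list file into one graph per pathway id.

    Self-loop lines are dropped with a warning; malformed lines raise with
    the offending line number.
    """
    path = Path(path)
    graphs: dict[str, nx.Graph] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3) or any(not p.strip() for p in parts):
                raise DataFormatError(
                    f"{path}:{lineno}: malformed pathway line: {line!r}"
                )
            pid = parts[0].strip()
            if pid not in graphs:
                graphs[pid] = nx.Graph()
                order.append(pid)
            g = graphs[pid]
            if len(parts) == 2:
                g.add_node(parts[1].strip())
            else:
                a, b = parts[1].strip(), parts[2].strip()
                if a == b:
                    logger.warning("%s:%d: self-loop on %r dropped", path, lineno, a)
                    g.add_node(a)
                else:
                    g.add_edge(a, b)
    return [PathwayGraph(pid, graphs[pid]) for pid in order]


def write_pathways(pathways: Iterable[PathwayGraph], path: str | Path) -> None:
    """Inverse of :func:`read_pathways` (weights are not serialized)."""
    with open(path, "w") as fh:
        fh.write("# pathway_id\tgeneA[\tgeneB]\n")
        for pw in pathways:
            covered: set[str] = set()
            for a, b in pw.graph.edges:
                fh.write(f"{pw.pathway_id}\t{a}\t{b}\n")
                covered.update((a, b))
            for n in pw.graph.nodes:
                if n not in covered:
                    fh.write(f"{pw.pathway_id}\t{n}\n")


def write_omics_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", header=False)
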