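"""Synthetic multi-omics cohorts with planted signal subpathways.

The generator emulates the statistical structure the pipeline assumes: a
binary drug response, a collection of random connected pathway graphs, and —
inside some pathways — a planted connected "active module" whose member genes
shift in mean between responders and non-responders across all three omics
layers, with a tunable cross-omics correlation.  Labels are assigned first
with fixed class counts and molecular values are drawn conditionally (a
planted mean-shift model), so the effect size ``delta`` is directly the
between-class mean difference in units of ``noise_sd``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import (
    DEFAULT_OMICS_NAMES,
    OmicsDataset,
    PathwayGraph,
    write_labels,
    write_omics_matrix,
    write_pathways,
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the scale of a 130-patient cohort with 17 signal
    subpathways feeding a 17×3 feature matrix downstream.
    """

    n_samples: int = 130
    n_genes: int = 600
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (15, 40)
    n_planted_subpathways: int = 17
    planted_size_range: tuple[int, int] = (3, 8)
    delta: float = 1.0            # between-class mean shift of signal genes
    noise_sd: float = 1.0
    inter_omics_correlation: float = 0.5
    responder_fraction: float = 0.5
    seed: int = 0
    omics_names: tuple[str, ...] = DEFAULT_OMICS_NAMES

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        plo, phi = self.planted_size_range
        if plo < 3:
            raise ValueError("planted subpathways need >= 3 genes")
        if phi > lo:
            raise ValueError(
                f"max planted size {phi} exceeds min pathway size {lo}"
            )
        if not 0 <= self.inter_omics_correlation < 1:
            raise ValueError("inter_omics_correlation must be in [0, 1)")
        if self.n_planted_subpathways > self.n_pathways:
            raise ValueError("more planted subpathways than pathways")
        if self.n_planted_subpathways * phi > self.n_genes:
            raise ValueError("gene pool too small for the planted modules")
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    """What was planted; consumed only by tests and recovery metrics."""

    planted: dict[str, set[str]] = field(default_factory=dict)  # pathway -> genes
    signal_genes: dict[str, set[str]] = field(default_factory=dict)  # omics -> genes

    def all_signal_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.planted.values():
            out |= s
        return out


def _random_connected_graph(
    rng: np.random.Generator, nodes: list[str], planted: list[str]
) -> nx.Graph:
    """Random connected graph in which ``planted`` induces a connected subgraph.

    Built as a random tree whose first |planted| attachment steps stay inside
    the planted set, then densified with extra random edges.
    """
    g = nx.Graph()
    order = planted + [n for n in nodes if n not in planted]
    g.add_node(order[0])
    for i, n in enumerate(order[1:], start=1):
        if n in planted:
            anchor = order[int(rng.integers(0, min(i, len(planted))))]
            while anchor not in planted:  # pragma: no cover - defensive
                anchor = order[int(rng.integers(0, i))]
        else:
            anchor = order[int(rng.integers(0, i))]
        g.add_edge(n, anchor)
    # densify: ~0.5 extra edges per node keeps realistic sparsity
    n_extra = max(1, len(nodes) // 2)
    for _ in range(n_extra):
        a, b = rng.choice(len(order), size=2, replace=False)
        if order[a] != order[b]:
            g.add_edge(order[a], order[b])
    return g


def generate_pathway_collection(
    config: SimulationConfig,
) -> tuple[list[PathwayGraph], GroundTruth]:
    """Random connected pathway graphs with planted connected modules.

    Planted genes are globally unique across pathways; background members may
    be shared between pathways (real pathways overlap).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    pool = list(rng.permutation(genes))

    lo, hi = config.pathway_size_range
    plo, phi = config.planted_size_range
    truth = GroundTruth()
    pathways: list[PathwayGraph] = []
    # reserve all planted genes first so no background slot reuses them
    planted_sets: list[list[str]] = []
    cursor = 0
    for p in range(config.n_planted_subpathways):
        k = int(rng.integers(plo, phi + 1))
        planted_sets.append(pool[cursor : cursor + k])
        cursor += k
    bg_pool = pool[cursor:]
    for p in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        pid = f"path{p:03d}"
        planted = planted_sets[p] if p < config.n_planted_subpathways else []
        n_bg = size - len(planted)
        if n_bg > len(bg_pool):
            raise ValueError("gene pool exhausted; increase n_genes")
        bg = list(rng.choice(bg_pool, size=n_bg, replace=False))
        g = _random_connected_graph(rng, planted + bg, planted)
        pathways.append(PathwayGraph(pid, g))
        if planted:
            truth.planted[pid] = set(planted)
    signal = truth.all_signal_genes()
    truth.signal_genes = {name: set(signal) for name in config.omics_names}
    return pathways, truth


def generate_omics_and_labels(
    pathways: list[PathwayGraph],
    truth: GroundTruth,
    config: SimulationConfig,
) -> OmicsDataset:
    """Draw labels (fixed class counts) and conditional molecular values.

    Signal genes: value = delta·y + sqrt(rho)·L + sqrt(1−rho)·eps, with the
    latent factor L shared across omics layers per gene/sample, so each
    marginal is N(delta·y, noise_sd²) and the cross-omics correlation of the
    noise is rho.  Background genes are independent N(0, noise_sd²).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_samples
    n_resp = int(round(config.responder_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[:n_resp] = 1
    rng.shuffle(labels)
    sample_ids = [f"S{i:03d}" for i in range(n)]

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    signal = truth.all_signal_genes()
    sig_idx = np.array([i for i, g in enumerate(genes) if g in signal], int)

    rho = config.inter_omics_correlation
    sd = config.noise_sd
    latent = rng.standard_normal((len(sig_idx), n))
    omics: dict[str, pd.DataFrame] = {}
    for name in config.omics_names:
        vals = rng.standard_normal((config.n_genes, n)) * sd
        if len(sig_idx):
            eps = rng.standard_normal((len(sig_idx), n))
            noise = np.sqrt(rho) * latent + np.sqrt(1 - rho) * eps
            vals[sig_idx] = config.delta * labels[None, :] + sd * noise
        omics[name] = pd.DataFrame(vals, index=genes, columns=sample_ids)
    return OmicsDataset(
        sample_ids=sample_ids,
        omics=omics,
        labels=labels,
        omics_names=config.omics_names,
    )


def simulate(config: SimulationConfig) -> tuple[OmicsDataset, list[PathwayGraph], GroundTruth]:
    """One-call generator: pathways + omics + labels for a config."""
    pathways, truth = generate_pathway_collection(config)
    dataset = generate_omics_and_labels(pathways, truth, config)
    return dataset, pathways, truth


def write_fixture_set(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full text fixture set (omics TSVs, labels, pathways, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, pathways, truth = simulate(config)
    paths: dict[str, Path] = {}
    for name, mat in dataset.omics.items():
        p = outdir / f"omics_{name}.tsv"
        write_omics_matrix(mat, p)
        paths[name] = p
    labels = pd.Series(dataset.labels, index=dataset.sample_ids)
    paths["labels"] = outdir / "labels.tsv"
    write_labels(labels, paths["labels"])
    paths["pathways"] = outdir / "pathways.tsv"
    write_pathways(pathways, paths["pathways"])
    paths["truth"] = outdir / "ground_truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "planted": {k: sorted(v) for k, v in truth.planted.items()},
                "signal_genes": {k: sorted(v) for k, v in truth.signal_genes.items()},
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(config).items()
                },
            },
            fh,
            indent=1,
        )
    return paths
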