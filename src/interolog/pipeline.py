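"""End-to-end orchestration over emitted fixture files.

Thin glue that wires the modules together in the order the analysis runs:
compile interactions, build the bridge, load domains and known DDIs,
construct the training set, fit (beta, epsilon) by Bethe-free-energy grid
search, select high-confidence DDIs, assemble the tiered target
interactome, and summarize its structure.  Each step is the corresponding
module function; nothing here adds behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import bridge as bridge_mod
from . import netstats
from .bp import (
    FitResult,
    ModelParams,
    SelectionResult,
    build_factor_graph,
    fit_parameters,
    run_bp,
    select_ddis,
)
from .ddi import NegativeSamplingConfig, sample_negatives
from .domains import fuse_known_ddis, load_ddi_table, load_domain_assignments
from .mitab import collapse_duplicates, filter_by_method, parse_mitab
from .predict import PredictionSet, assemble_tiers, domain_predict, transfer_via_bridge
from .simulate import load_coexpr_table, load_go_table

DEFAULT_BETA_GRID = [round(0.1 * i, 2) for i in range(1, 9)]  # 0.1 .. 0.8
DEFAULT_EPSILON_GRID = [round(0.01 * i, 3) for i in range(1, 11)]  # 0.01 .. 0.10
Y2H_TERMS = {"MI:0018", "two hybrid"}


@dataclass
class PipelineResult:
    d1: object
    d1_sub: object
    bridge: object
    source_assignments: dict
    target_assignments: dict
    d4: object
    negatives: list
    positives: list
    graph: object
    fit: FitResult | None
    params: ModelParams
    state: object
    selection: SelectionResult
    p1: dict
    p3: dict
    pall: PredictionSet
    summary: object


def run_from_fixtures(
    fixture_dir,
    seed: int,
    n_negatives: int | None = None,
    beta_grid=None,
    epsilon_grid=None,
    params: ModelParams | None = None,
    cutoff: float = 0.85,
    bp_kwargs: dict | None = None,
) -> PipelineResult:
    """Run the full analysis on a fixture directory (see ``simulate.emit_fixtures``).

    If ``params`` is given the grid search is skipped and BP runs at those
    parameters; otherwise (beta, epsilon) are fitted on the default grids.
    ``n_negatives`` defaults to the number of positive training pairs
    (1:1 positive:negative ratio).
    """
    fx = Path(fixture_dir)
    bp_kwargs = bp_kwargs or {}

    d1 = collapse_duplicates(parse_mitab(fx / "mitab.tsv", "SYNPPI").records, "D1")
    d1_sub, _ = filter_by_method(d1, Y2H_TERMS)

    clusters, _ = load_ortholog_clusters_auto(fx / "clusters.tsv")
    blocks, _ = bridge_mod.load_synteny_blocks(fx / "synteny.tsv")
    hits = bridge_mod.load_blast_hits(fx / "blast.tsv")
    bmap = bridge_mod.build_bridge(clusters, blocks, hits)

    src_asn = load_domain_assignments(fx / "source_domains.tsv").assignments
    tgt_asn = load_domain_assignments(fx / "target_domains.tsv").assignments
    d4 = fuse_known_ddis([(load_ddi_table(fx / "known_ddis.tsv"), "known")])

    go_source = load_go_table(fx / "go_source.tsv")
    go_target = load_go_table(fx / "go_target.tsv")
    coexpr = load_coexpr_table(fx / "coexpr.tsv")

    positives = sorted(d1_sub.pairs)
    if n_negatives is None:
        n_negatives = len(positives)
    negatives, _ = sample_negatives(
        sorted({p for pair in d1.pairs for p in pair} | set(src_asn)),
        d1,
        d4,
        src_asn,
        go_source,
        coexpr,
        NegativeSamplingConfig(n_negatives=n_negatives, seed=seed),
    )

    graph, _ = build_factor_graph(positives, negatives, src_asn)
    fit = None
    if params is None:
        fit = fit_parameters(
            graph,
            beta_grid or DEFAULT_BETA_GRID,
            epsilon_grid or DEFAULT_EPSILON_GRID,
            **bp_kwargs,
        )
        params = fit.best
    state = run_bp(graph, params, **bp_kwargs)
    selection = select_ddis(graph, state, cutoff, d4)

    p1 = transfer_via_bridge(d1, bmap).edges
    ddis_for_p3 = fuse_known_ddis(
        [(sorted(selection.selected), "inferred"), (sorted(d4.pairs), "known")]
    )
    p3 = domain_predict(tgt_asn, ddis_for_p3, go_target, p1, {})
    pall = assemble_tiers(p1, {}, p3)
    summary = netstats.structural_summary(pall.edges)

    return PipelineResult(
        d1=d1,
        d1_sub=d1_sub,
        bridge=bmap,
        source_assignments=src_asn,
        target_assignments=tgt_asn,
        d4=d4,
        negatives=negatives,
        positives=positives,
        graph=graph,
        fit=fit,
        params=params,
        state=state,
        selection=selection,
        p1=p1,
        p3=p3,
        pall=pall,
        summary=summary,
    )


def load_ortholog_clusters_auto(path):
    """Cluster loader that infers the two species labels from the file."""
    import pandas as pd

    species = sorted(pd.read_csv(path, sep="\t", dtype=str)["species"].unique())
    if len(species) != 2:
        raise ValueError(f"expected exactly two species in {path}, found {species}")
    # convention: source species sorts first only by accident; pick by majority
    # of cluster leaders (first row per cluster is the source member)
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.groupby("cluster_id", sort=False).head(1)["species"].mode()
    source = first.iloc[0]
    target = next(s for s in species if s != source)
    return bridge_mod.load_ortholog_clusters(path, source, target)


def derive_seed(base: int, salt: int) -> int:
    """Deterministic sub-seed below 2**31 for independent random streams."""
    return int(np.random.default_rng([base, salt]).integers(0, 2**31 - 1))
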