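"""Target-species interactome assembly: interolog transfer, domain-based
prediction, confidence tiers, and genome-coverage reporting.

Three prediction streams are combined: P1 (experimental source-species
interactions transferred through the bridging map), P2 (externally
predicted source interactions transferred the same way), and P3
(domain-based predictions from target-species domain architectures and the
inferred/known DDI set, gated by restriction rules).  An edge supported by
at least two streams is high-confidence (Phc); one stream is
low-confidence (Plc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

import pandas as pd

from .util import canonical_pair, venn_counts


@dataclass
class TransferResult:
    edges: dict  # canonical target pair -> set of source pairs (provenance)
    n_dropped: int  # source interactions with an unbridged endpoint


def transfer_via_bridge(ppis, bridge) -> TransferResult:
    """Transfer source interactions to the target species through the bridge.

    For a source interaction (a1, a2), every combination of bridged copies
    b1 of a1 and b2 of a2 yields a predicted target edge.  A source
    self-interaction (a, a) yields all unordered pairs *with replacement*
    among the bridged copies: the homomer in each copy plus cross-copy
    dimers.  Source pairs with either endpoint unbridged are dropped and
    tallied; duplicate target edges keep the union of their source
    provenance.
    """
    pairs = ppis.pairs if hasattr(ppis, "pairs") else set(ppis)
    index = bridge.target_index()
    edges: dict = {}
    n_dropped = 0
    for a1, a2 in pairs:
        t1 = index.get(a1, set())
        t2 = index.get(a2, set())
        if not t1 or not t2:
            n_dropped += 1
            continue
        if a1 == a2:
            target_pairs = combinations_with_replacement(sorted(t1), 2)
        else:
            target_pairs = ((b1, b2) for b1 in t1 for b2 in t2)
        for b1, b2 in target_pairs:
            edges.setdefault(canonical_pair(b1, b2), set()).add(canonical_pair(a1, a2))
    return TransferResult(edges, n_dropped)


def domain_predict(
    assignments,
    ddis,
    go_cc,
    p1_edges,
    p2_edges,
    min_domain_pairs: int = 2,
    include_self: bool = True,
) -> dict:
    """Domain-based interaction prediction (P3) with restriction rules.

    Candidate universe: annotated protein pairs sharing >= 1 GO
    cellular-component term (rule i).  A pair is admitted if it has at
    least ``min_domain_pairs`` interacting candidate domain pairs (rule
    ii), or at least one when the pair is already predicted by interolog
    transfer, i.e. in P1 or P2 (rule iii, read as sufficiency).  Returns a
    mapping canonical pair -> tuple of supporting domain pairs.
    """
    ddi_pairs = ddis.pairs if hasattr(ddis, "pairs") else set(ddis)
    transferred = set(p1_edges) | set(p2_edges)

    by_term: dict = {}
    for protein, asn in assignments.items():
        if not asn.domains:
            continue
        for term in go_cc.get(protein, ()):  # unannotated proteins fall out of the universe
            by_term.setdefault(term, []).append(protein)

    out: dict = {}
    seen: set = set()
    for term, members in by_term.items():
        members = sorted(set(members))
        pair_iter = (
            combinations_with_replacement(members, 2) if include_self else combinations(members, 2)
        )
        for p, q in pair_iter:
            pair = (p, q)
            if pair in seen:
                continue
            seen.add(pair)
            dp, dq = assignments[p].domains, assignments[q].domains
            support = sorted(
                {canonical_pair(a, b) for a in dp for b in dq} & ddi_pairs
            )
            if not support:
                continue
            if len(support) >= min_domain_pairs or pair in transferred:
                out[pair] = tuple(support)
    return out


@dataclass
class PredictionSet:
    """Tiered target-species interaction set with per-edge evidence labels."""

    edges: dict  # canonical pair -> set of evidence labels in {P1, P2, P3}
    detail: dict = field(default_factory=dict)  # canonical pair -> supporting info
    overlap: dict = field(default_factory=dict)  # Venn intersection counts

    @property
    def phc(self) -> set:
        """High confidence: >= 2 evidence sources."""
        return {e for e, ev in self.edges.items() if len(ev) >= 2}

    @property
    def plc(self) -> set:
        """Low confidence: exactly one evidence source."""
        return {e for e, ev in self.edges.items() if len(ev) == 1}

    def proteins(self) -> set:
        out = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.edges)


def assemble_tiers(p1, p2, p3, p1_detail=None, p2_detail=None, p3_detail=None) -> PredictionSet:
    """Union P1/P2/P3 into the full prediction set with evidence labels.

    ``p1``/``p2``/``p3`` are collections of canonical target pairs (dicts
    keep their values as supporting detail).  The overlap report carries
    the three-set Venn intersection counts.
    """
    edges: dict = {}
    detail: dict = {}
    for label, stream, extra in (
        ("P1", p1, p1_detail),
        ("P2", p2, p2_detail),
        ("P3", p3, p3_detail),
    ):
        mapping = stream if isinstance(stream, dict) else None
        for edge in stream:
            edges.setdefault(edge, set()).add(label)
            info = None
            if mapping is not None:
                info = mapping[edge]
            elif extra is not None:
                info = extra.get(edge)
            if info is not None:
                detail.setdefault(edge, {})[label] = info
    overlap = venn_counts({"P1": set(p1), "P2": set(p2), "P3": set(p3)})
    return PredictionSet(edges, detail, overlap)


@dataclass
class CoverageReport:
    table: pd.DataFrame  # aspect, category, genome_count, interactome_count, ratio_pct
    overall_interactome_coverage_pct: float  # |interactome proteins| / |genome|
    genome_annotated_pct: float  # genome proteins with >= 1 slim category
    n_unmapped_interactome: int


def annotated_fraction_pct(n_annotated: int, genome_size: int) -> float:
    """Percentage of a genome covered by an annotation (e.g. GO assignment)."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n_annotated > genome_size:
        raise ValueError("annotated count exceeds genome size")
    return 100.0 * n_annotated / genome_size


def coverage_report(pall, genome, go_slim) -> CoverageReport:
    """Per-slim-category genome vs interactome counts and ratios.

    ``go_slim`` is a DataFrame with columns (protein, aspect, category) or a
    mapping protein -> iterable of (aspect, category).  Proteins absent
    from the mapping are counted in an "unmapped" bucket per aspect.
    """
    genome = list(genome)
    genome_set = set(genome)
    inter_proteins = pall.proteins() if hasattr(pall, "proteins") else set(pall)

    if isinstance(go_slim, pd.DataFrame):
        mapping: dict = {}
        for row in go_slim.itertuples(index=False):
            mapping.setdefault(row.protein, []).append((row.aspect, row.category))
    else:
        mapping = {p: list(v) for p, v in go_slim.items()}

    counts: dict = {}
    mapped_genome = 0
    n_unmapped_inter = 0
    aspects = sorted({a for v in mapping.values() for a, _ in v}) or ["C"]
    for protein in genome_set | inter_proteins:
        cats = mapping.get(protein)
        in_genome = protein in genome_set
        in_inter = protein in inter_proteins
        if not cats:
            for aspect in aspects:
                key = (aspect, "unmapped")
                g, i = counts.get(key, (0, 0))
                counts[key] = (g + in_genome, i + in_inter)
            n_unmapped_inter += in_inter
            continue
        mapped_genome += in_genome
        for aspect, category in set(cats):
            g, i = counts.get((aspect, category), (0, 0))
            counts[(aspect, category)] = (g + in_genome, i + in_inter)

    rows = []
    for (aspect, category), (g, i) in sorted(counts.items()):
        rows.append(
            {
                "aspect": aspect,
                "category": category,
                "genome_count": g,
                "interactome_count": i,
                "ratio_pct": 100.0 * i / g if g else float("nan"),
            }
        )
    return CoverageReport(
        table=pd.DataFrame(rows),
        overall_interactome_coverage_pct=annotated_fraction_pct(
            len(inter_proteins & genome_set), len(genome_set)
        ),
        genome_annotated_pct=annotated_fraction_pct(mapped_genome, len(genome_set)),
        n_unmapped_interactome=n_unmapped_inter,
    )


def write_prediction_tsv(pset: PredictionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tevidence\ttier\n")
        for pair in sorted(pset.edges):
            ev = pset.edges[pair]
            tier = "Phc" if len(ev) >= 2 else "Plc"
            fh.write(f"{pair[0]}\t{pair[1]}\t{','.join(sorted(ev))}\t{tier}\n")


def write_sif(edges, path, relation: str = "pp") -> None:
    """Export an edge list in SIF format for graph viewers."""
    with open(path, "w") as fh:
        for a, b in sorted(set(edges)):
            fh.write(f"{a}\t{relation}\t{b}\n")
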