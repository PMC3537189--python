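"""Cross-species "bridging" map: ortholog clusters, synteny blocks, BLAST best hits.

Source-species interactions can only be transferred to the target species
through a protein-to-protein correspondence.  Because the target genome
(here modelled on *B. rapa*, a fractionated paleohexaploid relative of
*A. thaliana*) retains one to three copies of most source genes, this map
is multi-to-multi.  Three complementary evidence streams contribute links:

* ``I`` - InParanoid-style ortholog clusters (all source x target members),
* ``P`` - synteny/collinearity gene pairs (PGDD-style blocks),
* ``B`` - BLAST best hits, used only as a fill-in for target proteins not
  already covered by I or P evidence.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class OrthologCluster:
    cluster_id: str
    source_members: set
    target_members: set


@dataclass
class SyntenyBlock:
    block_id: str
    gene_pairs: list  # ordered (source, target) pairs


@dataclass
class BlastHit:
    query: str
    subject: str
    evalue: float
    bitscore: float


@dataclass
class BridgingMap:
    """Multi-to-multi source<->target links with evidence codes in {I, P, B}."""

    links: dict = field(default_factory=dict)  # (source, target) -> set of codes

    def add(self, source: str, target: str, code: str) -> None:
        self.links.setdefault((source, target), set()).add(code)

    def __len__(self) -> int:
        return len(self.links)

    def __eq__(self, other) -> bool:
        return isinstance(other, BridgingMap) and self.links == other.links

    def targets_of(self, source: str) -> set:
        return {t for (s, t) in self.links if s == source}

    def sources_of(self, target: str) -> set:
        return {s for (s, t) in self.links if t == target}

    @property
    def covered_sources(self) -> set:
        return {s for s, _ in self.links}

    @property
    def covered_targets(self) -> set:
        return {t for _, t in self.links}

    def target_index(self) -> dict:
        """source -> set of targets, precomputed for repeated transfer queries."""
        idx: dict = defaultdict(set)
        for s, t in self.links:
            idx[s].add(t)
        return dict(idx)


def load_ortholog_clusters(path, source_species: str, target_species: str):
    """Load a tabular ortholog-cluster file (cluster_id, species, accession, score).

    Clusters represented in only one of the two species are dropped and
    tallied.  Returns ``(clusters, n_dropped)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    clusters = []
    n_dropped = 0
    for cid, grp in df.groupby("cluster_id", sort=True):
        src = set(grp.loc[grp["species"] == source_species, "accession"])
        tgt = set(grp.loc[grp["species"] == target_species, "accession"])
        if not src or not tgt:
            n_dropped += 1
            logger.warning("cluster %s has members from a single species; dropped", cid)
            continue
        clusters.append(OrthologCluster(str(cid), src, tgt))
    return clusters, n_dropped


def load_synteny_blocks(path):
    """Load a tabular synteny file (block_id, source, target), ordered within block.

    Rows missing either partner are skipped and tallied. Returns
    ``(blocks, n_skipped)``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    blocks: dict = {}
    order: list = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        if not row.source or not row.target or row.source == "-" or row.target == "-":
            n_skipped += 1
            continue
        if row.block_id not in blocks:
            blocks[row.block_id] = []
            order.append(row.block_id)
        blocks[row.block_id].append((row.source, row.target))
    return [SyntenyBlock(bid, blocks[bid]) for bid in order], n_skipped


def load_blast_hits(path, evalue_cutoff: float = 1e-6):
    """Load BLAST tabular (outfmt 6) hits and keep the best hit per query.

    Hits with e-value above ``evalue_cutoff`` are discarded; per query the
    smallest e-value wins, ties broken by higher bit score then
    lexicographic subject id.  Rows with a non-numeric e-value are skipped.
    An e-value of exactly 0 (too small to report) is retained.
    """
    best: dict = {}
    with Path(path).open() as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                continue
            try:
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError:
                continue
            if evalue > evalue_cutoff:
                continue
            hit = BlastHit(cols[0], cols[1], evalue, bitscore)
            cur = best.get(hit.query)
            if cur is None or (hit.evalue, -hit.bitscore, hit.subject) < (
                cur.evalue,
                -cur.bitscore,
                cur.subject,
            ):
                best[hit.query] = hit
    return [best[q] for q in sorted(best)]


def build_bridge(clusters, blocks, blast_hits, blast_only_for=None) -> BridgingMap:
    """Combine the three evidence streams into the final bridging map (D3).

    BLAST links are a fill-in: a ``B`` link is added only when the target
    protein (the BLAST query) is not already covered by I or P evidence.
    ``blast_only_for`` may name that target set explicitly; by default it is
    derived from the I/P coverage.
    """
    bmap = BridgingMap()
    for cl in clusters:
        for s in cl.source_members:
            for t in cl.target_members:
                bmap.add(s, t, "I")
    for bl in blocks:
        for s, t in bl.gene_pairs:
            bmap.add(s, t, "P")
    if blast_only_for is None:
        blast_only_for = {q.query for q in blast_hits} - bmap.covered_targets
    for hit in blast_hits:
        if hit.query in blast_only_for:
            bmap.add(hit.subject, hit.query, "B")
    return bmap


@dataclass
class CoverageReport:
    n_source: int
    n_target: int
    source_covered: int
    target_covered: int

    @property
    def source_uncovered(self) -> int:
        return self.n_source - self.source_covered

    @property
    def target_uncovered(self) -> int:
        return self.n_target - self.target_covered

    @property
    def source_uncovered_pct(self) -> float:
        return 100.0 * self.source_uncovered / self.n_source

    @property
    def target_uncovered_pct(self) -> float:
        return 100.0 * self.target_uncovered / self.n_target


def uncovered_fraction(n_covered: int, genome_size: int):
    """Uncovered count and percentage for a genome of ``genome_size`` proteins."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if n_covered > genome_size:
        raise ValueError(f"covered count {n_covered} exceeds genome size {genome_size}")
    n_unc = genome_size - n_covered
    return n_unc, 100.0 * n_unc / genome_size


def bridge_coverage(bmap: BridgingMap, genome_sizes) -> CoverageReport:
    """Coverage of both genomes by the bridging map.

    Raises if either covered count exceeds its stated genome size
    (inconsistent inputs).
    """
    n_source, n_target = genome_sizes
    sc, tc = len(bmap.covered_sources), len(bmap.covered_targets)
    uncovered_fraction(sc, n_source)
    uncovered_fraction(tc, n_target)
    return CoverageReport(n_source, n_target, sc, tc)


def write_bridge_tsv(bmap: BridgingMap, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tcodes\n")
        for (s, t) in sorted(bmap.links):
            fh.write(f"{s}\t{t}\t{','.join(sorted(bmap.links[(s, t)]))}\n")


def read_bridge_tsv(path) -> BridgingMap:
    bmap = BridgingMap()
    df = pd.read_csv(path, sep="\t", dtype=str)
    for row in df.itertuples(index=False):
        for code in row.codes.split(","):
            bmap.add(row.source, row.target, code)
    return bmap
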