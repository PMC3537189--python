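"""PSI-MI TAB interaction records: parsing, deduplication and multi-source merging.

Interaction databases exported in the MITAB format record one line per
*detection event*, so the same physical pair appears many times (different
methods, different publications) and co-purified complexes are already
spoke-expanded (bait x each prey).  This module canonicalizes those lines
into undirected protein pairs, collapses duplicates while unioning their
provenance, merges several database exports with overlap (Venn) reporting,
and filters a compiled set down to selected detection methods (e.g. the
yeast two-hybrid subset used to train domain-interaction inference).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .util import Pair, canonical_pair, inclusion_exclusion_union, strip_isoform, venn_counts

logger = logging.getLogger(__name__)

#: Identifier namespaces tried in order when extracting an accession from a
#: MITAB identifier column. Unmatched identifiers are kept verbatim.
DEFAULT_ID_PRIORITY = ("tair", "locus", "entrez gene/locuslink", "uniprotkb", "srcdb")

_MI_RE = re.compile(r"MI:\d{4}")
_PAREN_RE = re.compile(r"\(([^)]*)\)")


@dataclass
class InteractionRecord:
    """One undirected protein pair with provenance.

    The pair is stored in canonical order (lexicographically smallest
    first); self-pairs are permitted.
    """

    protein_a: str
    protein_b: str
    sources: set = field(default_factory=set)
    pmids: set = field(default_factory=set)
    methods: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.protein_a, self.protein_b = canonical_pair(self.protein_a, self.protein_b)

    @property
    def pair(self) -> Pair:
        return (self.protein_a, self.protein_b)

    def merged_with(self, other: "InteractionRecord") -> "InteractionRecord":
        if other.pair != self.pair:
            raise ValueError(f"cannot merge records for {self.pair} and {other.pair}")
        return InteractionRecord(
            self.protein_a,
            self.protein_b,
            self.sources | other.sources,
            self.pmids | other.pmids,
            self.methods | other.methods,
        )


@dataclass
class CompiledPPISet:
    """Deduplicated interaction set keyed by canonical pair (e.g. D1, D1-sub, D2)."""

    records: dict
    label: str = "D1"

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pair: Pair) -> bool:
        return canonical_pair(*pair) in self.records

    @property
    def pairs(self) -> set:
        return set(self.records)

    def proteins(self) -> set:
        out = set()
        for a, b in self.records:
            out.add(a)
            out.add(b)
        return out

    def pmids(self) -> set:
        out = set()
        for rec in self.records.values():
            out |= rec.pmids
        return out


@dataclass
class ParseResult:
    records: list
    n_skipped: int


def _tokens(column: str) -> list:
    return [t for t in column.split("|") if t and t != "-"]


def _first_accession(column: str, id_priority, isoform_pattern: str) -> str | None:
    toks = _tokens(column)
    if not toks:
        return None
    parsed = []
    for tok in toks:
        db, _, acc = tok.partition(":")
        acc = acc.strip('"')
        parsed.append((db.lower(), acc if acc else db))
    for ns in id_priority:
        for db, acc in parsed:
            if db == ns:
                return strip_isoform(acc, isoform_pattern)
    # unmapped namespace: keep the first accession verbatim
    return strip_isoform(parsed[0][1], isoform_pattern)


def _method_terms(column: str) -> set:
    """Extract detection-method terms: PSI-MI CV ids plus their readable names."""
    out = set()
    for tok in _tokens(column):
        out.update(_MI_RE.findall(tok))
        for name in _PAREN_RE.findall(tok):
            if name:
                out.add(name.strip('"').lower())
    return out


def _pmid_terms(column: str) -> set:
    out = set()
    for tok in _tokens(column):
        db, _, acc = tok.partition(":")
        if db.lower() == "pubmed" and acc:
            out.add(acc)
    return out


def parse_mitab(
    path,
    source_label: str,
    id_priority=DEFAULT_ID_PRIORITY,
    isoform_pattern: str = r"\.\d+$",
) -> ParseResult:
    """Parse a MITAB 2.5/2.6 file into raw (uncollapsed) interaction records.

    One record is produced per well-formed line; lines with fewer than 15
    columns or with both interactor identifier columns missing are skipped
    and tallied.  Accessions are extracted from the first identifier
    namespace matching ``id_priority``, with splice-variant suffixes
    stripped to gene-level accessions.
    """
    path = Path(path)
    records: list = []
    n_skipped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                n_skipped += 1
                logger.warning("%s:%d: malformed MITAB line (%d columns)", path, lineno, len(cols))
                continue
            acc_a = _first_accession(cols[0], id_priority, isoform_pattern)
            acc_b = _first_accession(cols[1], id_priority, isoform_pattern)
            if acc_a is None and acc_b is None:
                n_skipped += 1
                logger.warning("%s:%d: both interactor columns empty", path, lineno)
                continue
            if acc_a is None or acc_b is None:
                # single missing partner cannot form a binary pair
                n_skipped += 1
                logger.warning("%s:%d: missing one interactor", path, lineno)
                continue
            records.append(
                InteractionRecord(
                    acc_a,
                    acc_b,
                    sources={source_label},
                    pmids=_pmid_terms(cols[8]),
                    methods=_method_terms(cols[6]),
                )
            )
    return ParseResult(records, n_skipped)


def collapse_duplicates(records, label: str = "D1") -> CompiledPPISet:
    """Merge records sharing a canonical pair, unioning sources/pmids/methods."""
    out: dict = {}
    for rec in records:
        if rec.pair in out:
            out[rec.pair] = out[rec.pair].merged_with(rec)
        else:
            out[rec.pair] = InteractionRecord(
                rec.protein_a, rec.protein_b, set(rec.sources), set(rec.pmids), set(rec.methods)
            )
    return CompiledPPISet(out, label)


def expand_complex(bait: str, participants) -> list:
    """Spoke-model expansion: one binary pair per non-bait participant.

    A co-purification of n participants yields n-1 bait-prey pairs (never
    the n(n-1)/2 prey-prey pairs of the matrix model).
    """
    participants = list(participants)
    if not participants:
        raise ValueError("participants must be nonempty")
    return [canonical_pair(bait, p) for p in participants if p != bait]


@dataclass
class OverlapReport:
    """Per-source counts and all intersection counts for pairs/proteins/PMIDs."""

    pair_counts: dict
    protein_counts: dict
    pmid_counts: dict

    def union_size(self, what: str = "pair") -> int:
        counts = getattr(self, f"{what}_counts")
        return inclusion_exclusion_union(counts)


def merge_sources(sets, label: str = "D1"):
    """Union several compiled sets into one, with a Venn overlap report.

    Returns ``(merged CompiledPPISet, OverlapReport)``.  The report gives,
    for every combination of input sets, the intersection count in terms of
    interaction pairs, proteins and publications.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("at least one input set required")
    merged: dict = {}
    for cset in sets:
        for rec in cset.records.values():
            if rec.pair in merged:
                merged[rec.pair] = merged[rec.pair].merged_with(rec)
            else:
                merged[rec.pair] = InteractionRecord(
                    rec.protein_a, rec.protein_b, set(rec.sources), set(rec.pmids), set(rec.methods)
                )
    report = OverlapReport(
        pair_counts=venn_counts({s.label: s.pairs for s in sets}),
        protein_counts=venn_counts({s.label: s.proteins() for s in sets}),
        pmid_counts=venn_counts({s.label: s.pmids() for s in sets}),
    )
    return CompiledPPISet(merged, label), report


def filter_by_method(cset: CompiledPPISet, allowed_methods, label: str = "D1-sub"):
    """Keep records having >= 1 allowed detection-method term.

    Returns ``(filtered CompiledPPISet, tallies)`` where tallies counts
    records excluded for having no method annotation at all versus records
    whose methods simply did not match.
    """
    allowed = set(allowed_methods)
    kept: dict = {}
    tallies = {"no_method": 0, "method_mismatch": 0}
    for pair, rec in cset.records.items():
        if not rec.methods:
            tallies["no_method"] += 1
        elif rec.methods & allowed:
            kept[pair] = rec
        else:
            tallies["method_mismatch"] += 1
    return CompiledPPISet(kept, label), tallies


def write_compiled_tsv(cset: CompiledPPISet, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein_a\tprotein_b\tsources\tpmids\tmethods\n")
        for pair in sorted(cset.records):
            rec = cset.records[pair]
            fh.write(
                "\t".join(
                    [
                        rec.protein_a,
                        rec.protein_b,
                        "|".join(sorted(rec.sources)),
                        "|".join(sorted(rec.pmids)),
                        "|".join(sorted(rec.methods)),
                    ]
                )
                + "\n"
            )


def read_compiled_tsv(path, label: str = "D1") -> CompiledPPISet:
    records = []
    with Path(path).open() as fh:
        header = fh.readline()
        assert header.startswith("protein_a")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            a, b = cols[0], cols[1]
            split = lambda c: set(c.split("|")) - {""}  # noqa: E731
            records.append(InteractionRecord(a, b, split(cols[2]), split(cols[3]), split(cols[4])))
    return collapse_duplicates(records, label)
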