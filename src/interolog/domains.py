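"""Protein domain assignments and the fused known-DDI catalogue.

Holds per-protein Pfam-style domain sets (filtered at a stringent e-value
cutoff), the union of known/high-confidence domain-pair tables (the D4
analogue, DOMINE-style), and the enumeration of candidate domain pairs
underlying a set of protein pairs — the variables on which the
belief-propagation inference operates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .util import canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class DomainAssignment:
    protein: str
    domains: set = field(default_factory=set)
    best_evalues: dict = field(default_factory=dict)


@dataclass
class AssignmentResult:
    assignments: dict  # protein -> DomainAssignment
    n_skipped: int
    mean_domains_per_protein: float


@dataclass
class KnownDDISet:
    """Canonical union of known/high-confidence interacting domain pairs (D4)."""

    pairs: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)  # pair -> set of origin labels

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return canonical_pair(*pair) in self.pairs


def load_domain_assignments(path, evalue_cutoff: float = 1e-10) -> AssignmentResult:
    """Load a per-domain tabular file (protein, domain, evalue; extra columns ignored).

    Rows above the e-value cutoff are dropped; per protein, each domain is
    kept once with its best (smallest) e-value.  Malformed rows are skipped
    and tallied.
    """
    assignments: dict = {}
    n_skipped = 0
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            try:
                protein = cols[idx.get("protein", 0)]
                domain = cols[idx.get("domain", 1)]
                evalue = float(cols[idx.get("evalue", 2)])
            except (IndexError, ValueError):
                n_skipped += 1
                logger.warning("malformed domain-assignment row skipped: %r", line.rstrip())
                continue
            if not protein or not domain:
                n_skipped += 1
                continue
            if evalue > evalue_cutoff:
                continue
            asn = assignments.setdefault(protein, DomainAssignment(protein))
            asn.domains.add(domain)
            if evalue < asn.best_evalues.get(domain, float("inf")):
                asn.best_evalues[domain] = evalue
    mean = (
        sum(len(a.domains) for a in assignments.values()) / len(assignments)
        if assignments
        else 0.0
    )
    return AssignmentResult(assignments, n_skipped, mean)


def load_ddi_table(path) -> list:
    """Load a DDI TSV (domain_a, domain_b[, origin]) into canonical pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [canonical_pair(r.domain_a, r.domain_b) for r in df.itertuples(index=False)]


def fuse_known_ddis(tables) -> KnownDDISet:
    """Union DDI tables into one canonical set with per-pair provenance.

    ``tables`` is an iterable of ``(pairs, origin_label)``; fusion is
    idempotent and symmetric in pair orientation.
    """
    out = KnownDDISet()
    for pairs, origin in tables:
        for d1, d2 in pairs:
            pair = canonical_pair(d1, d2)
            out.pairs.add(pair)
            out.provenance.setdefault(pair, set()).add(origin)
    return out


@dataclass
class CandidateResult:
    candidates: set  # global set of canonical domain pairs
    incidence: dict  # canonical protein pair -> sorted tuple of domain pairs
    n_excluded: int  # protein pairs with an unannotated partner


def candidate_domain_pairs(pairs, assignments) -> CandidateResult:
    """Enumerate candidate domain pairs for each protein pair.

    For a protein pair (p, q) the candidates are all canonical pairs
    {a, b} with a in domains(p), b in domains(q); duplicates arising from
    canonicalization are collapsed.  Protein pairs with an unannotated
    partner are excluded and tallied.
    """
    candidates: set = set()
    incidence: dict = {}
    n_excluded = 0
    for p, q in pairs:
        key = canonical_pair(p, q)
        ap, aq = assignments.get(p), assignments.get(q)
        if ap is None or aq is None or not ap.domains or not aq.domains:
            n_excluded += 1
            continue
        local = {canonical_pair(a, b) for a in ap.domains for b in aq.domains}
        candidates |= local
        incidence[key] = tuple(sorted(local))
    return CandidateResult(candidates, incidence, n_excluded)


def write_assignments_tsv(result: AssignmentResult, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein\tdomain\tevalue\n")
        for protein in sorted(result.assignments):
            asn = result.assignments[protein]
            for dom in sorted(asn.domains):
                fh.write(f"{protein}\t{dom}\t{asn.best_evalues.get(dom, 0.0):.3g}\n")


def write_ddi_tsv(ddis: KnownDDISet, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("domain_a\tdomain_b\torigin\n")
        for d1, d2 in sorted(ddis.pairs):
            origins = ",".join(sorted(ddis.provenance.get((d1, d2), set())))
            fh.write(f"{d1}\t{d2}\t{origins}\n")
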