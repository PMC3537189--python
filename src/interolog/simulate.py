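"""Seeded synthetic two-species world with planted ground truth.

The generator mirrors the generative assumptions of the inference model:
proteins carry Pfam-like domain sets; a planted set of true domain-domain
interactions (DDIs) induces protein-protein interactions by a noisy-OR
rule (a pair interacts iff at least one of its candidate domain pairs is a
true DDI); the observed interaction map drops true pairs with probability
``epsilon_true`` and is contaminated with false positives; the target
proteome descends from the source by whole-genome duplication with
fractionation (1-3 retained copies per source gene), inheriting domains
and GO terms.  Bridging evidence (ortholog clusters, synteny pairs, BLAST
best hits), GO cellular-component tables and pairwise co-expression values
are generated consistently with the planted truth and emitted in every
tabular format the pipeline consumes, so the full pipeline can be
exercised end-to-end against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from .bridge import BridgingMap
from .domains import DomainAssignment
from .predict import transfer_via_bridge
from .util import canonical_pair


@dataclass
class WorldConfig:
    n_source_proteins: int = 300
    n_domains: int = 120
    domains_per_protein_mean: float = 1.4
    ddi_density: float = 0.007
    epsilon_true: float = 0.05
    false_positive_rate: float = 0.05
    copy_number_probs: dict = field(default_factory=lambda: {1: 0.4, 2: 0.35, 3: 0.25})
    coexpr_interacting_mean: float = 0.7
    coexpr_interacting_sd: float = 0.15
    coexpr_noninteracting_bound: float = 0.35
    n_go_cc_terms: int = 15
    go_share_prob: float = 0.9
    y2h_fraction: float = 0.8
    p_ortholog: float = 0.7
    p_synteny: float = 0.5
    n_articles: int = 40
    source_species: str = "Ath"
    target_species: str = "Bra"
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("ddi_density", "epsilon_true", "false_positive_rate", "y2h_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        total = sum(self.copy_number_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("copy_number_probs must sum to 1")
        if self.domains_per_protein_mean < 1.0:
            raise ValueError("domains_per_protein_mean must be >= 1")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    source_proteins: list
    target_proteins: list
    domain_names: list
    source_assignments: dict  # protein -> DomainAssignment
    target_assignments: dict
    true_ddis: set  # canonical domain pairs
    true_source_ppis: set  # canonical protein pairs (self-pairs possible)
    observed_source_ppis: set
    dropped_ppis: set
    false_positive_ppis: set
    copy_map: dict  # source -> list of target copies
    bridge_truth: BridgingMap
    go_cc_source: dict  # protein -> set of CC terms
    go_cc_target: dict
    coexpr: dict  # canonical source pair -> correlation
    target_true_interactome: set
    pair_methods: dict  # observed pair -> method kind ("y2h" | "coip")


def _canonical_domain_pairs(domains_p, domains_q):
    return {canonical_pair(a, b) for a in domains_p for b in domains_q}


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Generate a seeded world; all randomness flows from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_source_proteins
    source = [f"{cfg.source_species}{i:04d}" for i in range(n)]
    domain_names = [f"PF{i:05d}" for i in range(cfg.n_domains)]

    # domain architectures: 1 + Poisson(mean - 1) distinct domains per protein
    source_assignments: dict = {}
    for p in source:
        k = 1 + rng.poisson(cfg.domains_per_protein_mean - 1.0)
        k = min(k, cfg.n_domains)
        doms = rng.choice(cfg.n_domains, size=k, replace=False)
        asn = DomainAssignment(p)
        for d in doms:
            name = domain_names[int(d)]
            asn.domains.add(name)
            asn.best_evalues[name] = 10.0 ** rng.uniform(-30, -11)
        source_assignments[p] = asn

    # planted DDIs over all unordered domain pairs (self-pairs allowed)
    all_domain_pairs = [
        canonical_pair(a, b)
        for i, a in enumerate(domain_names)
        for b in domain_names[i:]
    ]
    mask = rng.random(len(all_domain_pairs)) < cfg.ddi_density
    true_ddis = {pair for pair, m in zip(all_domain_pairs, mask) if m}

    # noisy-OR truth: a pair interacts iff >= 1 candidate domain pair is a true DDI
    true_ppis: set = set()
    dom_lists = {p: sorted(source_assignments[p].domains) for p in source}
    for i, p in enumerate(source):
        for q in source[i:]:
            if _canonical_domain_pairs(dom_lists[p], dom_lists[q]) & true_ddis:
                true_ppis.add(canonical_pair(p, q))
    if not true_ppis:
        raise ValueError(
            "infeasible config: planted DDI density produced no true interactions"
        )

    # observation noise: epsilon_true dropouts plus false positives
    kept, dropped = set(), set()
    for pair in sorted(true_ppis):
        (dropped if rng.random() < cfg.epsilon_true else kept).add(pair)
    n_fp = int(round(cfg.false_positive_rate * len(kept) / max(1e-12, 1.0 - cfg.false_positive_rate)))
    false_positives: set = set()
    while len(false_positives) < n_fp:
        i, j = rng.choice(n, size=2, replace=False)
        pair = canonical_pair(source[int(i)], source[int(j)])
        if pair not in true_ppis and pair not in false_positives:
            false_positives.add(pair)
    observed = kept | false_positives

    # detection method per observed pair (two-hybrid subset feeds training)
    pair_methods = {
        pair: ("y2h" if rng.random() < cfg.y2h_fraction else "coip")
        for pair in sorted(observed)
    }

    # duplicated / fractionated target proteome
    copy_numbers = sorted(cfg.copy_number_probs)
    copy_p = [cfg.copy_number_probs[c] for c in copy_numbers]
    copy_map: dict = {}
    target: list = []
    target_assignments: dict = {}
    for i, p in enumerate(source):
        k = int(rng.choice(copy_numbers, p=copy_p))
        copies = [f"{cfg.target_species}{i:04d}_{c}" for c in range(1, k + 1)]
        copy_map[p] = copies
        target.extend(copies)
        for t in copies:
            asn = DomainAssignment(t)
            asn.domains = set(source_assignments[p].domains)
            asn.best_evalues = dict(source_assignments[p].best_evalues)
            target_assignments[t] = asn

    # bridging evidence codes: I and/or P, BLAST as fill-in for the rest
    bridge = BridgingMap()
    for p in source:
        for t in copy_map[p]:
            codes = set()
            if rng.random() < cfg.p_ortholog:
                codes.add("I")
            if rng.random() < cfg.p_synteny:
                codes.add("P")
            if not codes:
                codes.add("B")
            for code in codes:
                bridge.add(p, t, code)

    # GO cellular component: primary term per protein; interacting partners share
    terms = [f"CC{i:03d}" for i in range(cfg.n_go_cc_terms)]
    go_source: dict = {}
    for p in source:
        go_source[p] = {terms[int(rng.integers(cfg.n_go_cc_terms))]}
        if rng.random() < 0.3:
            go_source[p].add(terms[int(rng.integers(cfg.n_go_cc_terms))])
    primary = {p: min(go_source[p]) for p in source}
    for p, q in sorted(true_ppis):
        if p != q and rng.random() < cfg.go_share_prob:
            go_source[p].add(primary[q])
    go_target = {t: set(go_source[p]) for p in source for t in copy_map[p]}

    # pairwise co-expression: interacting pairs mostly above the 0.4 screen,
    # non-interacting pairs bounded strictly below it
    coexpr: dict = {}
    for p, q in combinations(source, 2):
        pair = canonical_pair(p, q)
        if pair in true_ppis:
            r = rng.normal(cfg.coexpr_interacting_mean, cfg.coexpr_interacting_sd)
            coexpr[pair] = float(np.clip(r, -0.99, 0.99))
        else:
            b = cfg.coexpr_noninteracting_bound
            coexpr[pair] = float(rng.uniform(-b, b))

    target_truth = set(transfer_via_bridge(true_ppis, bridge).edges)

    return SyntheticWorld(
        config=cfg,
        source_proteins=source,
        target_proteins=target,
        domain_names=domain_names,
        source_assignments=source_assignments,
        target_assignments=target_assignments,
        true_ddis=true_ddis,
        true_source_ppis=true_ppis,
        observed_source_ppis=observed,
        dropped_ppis=dropped,
        false_positive_ppis=false_positives,
        copy_map=copy_map,
        bridge_truth=bridge,
        go_cc_source=go_source,
        go_cc_target=go_target,
        coexpr=coexpr,
        target_true_interactome=target_truth,
        pair_methods=pair_methods,
    )


_METHOD_COLUMN = {
    "y2h": 'psi-mi:"MI:0018"(two hybrid)',
    "coip": 'psi-mi:"MI:0019"(coimmunoprecipitation)',
}


def emit_fixtures(world: SyntheticWorld, out_dir) -> dict:
    """Write the world as the tabular fixture files the pipeline reads.

    Returns a manifest mapping file path -> number of data rows.  A fresh
    generator seeded from the world seed drives cosmetic randomness
    (publication ids, decoy BLAST rows), so emission is reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    rng = np.random.default_rng(cfg.seed + 1)
    manifest: dict = {}

    def _record(path: Path, n_rows: int) -> None:
        manifest[str(path)] = n_rows

    # --- MITAB (observed source-species interactions, spoke model) ---
    mitab = out / "mitab.tsv"
    n_rows = 0
    pmids = [f"{1000000 + i}" for i in range(cfg.n_articles)]
    with mitab.open("w") as fh:
        for pair in sorted(world.observed_source_ppis):
            a, b = pair
            method = _METHOD_COLUMN[world.pair_methods[pair]]
            pmid = pmids[int(rng.integers(len(pmids)))]
            cols = [
                f"srcdb:{a}",
                f"srcdb:{b}",
                "-",
                "-",
                "-",
                "-",
                method,
                "-",
                f"pubmed:{pmid}",
                "taxid:3702",
                "taxid:3702",
                'psi-mi:"MI:0915"(physical association)',
                'psi-mi:"MI:0000"(SYNPPI)',
                "-",
                "-",
            ]
            fh.write("\t".join(cols) + "\n")
            n_rows += 1
            if rng.random() < 0.2:  # duplicate entry with another detection method
                cols[6] = 'psi-mi:"MI:0018"(two hybrid)'
                cols[8] = f"pubmed:{pmids[int(rng.integers(len(pmids)))]}"
                fh.write("\t".join(cols) + "\n")
                n_rows += 1
    _record(mitab, n_rows)

    # --- ortholog clusters (I evidence) ---
    clusters = out / "clusters.tsv"
    n_rows = 0
    with clusters.open("w") as fh:
        fh.write("cluster_id\tspecies\taccession\tscore\n")
        cid = 0
        for p in world.source_proteins:
            itargets = sorted(
                t for t in world.copy_map[p] if "I" in world.bridge_truth.links.get((p, t), set())
            )
            if not itargets:
                continue
            cid += 1
            fh.write(f"C{cid:04d}\t{cfg.source_species}\t{p}\t1.000\n")
            n_rows += 1
            for t in itargets:
                fh.write(f"C{cid:04d}\t{cfg.target_species}\t{t}\t{rng.uniform(0.5, 1.0):.3f}\n")
                n_rows += 1
    _record(clusters, n_rows)

    # --- synteny blocks (P evidence), consecutive runs of aligned pairs ---
    synteny = out / "synteny.tsv"
    p_links = sorted(
        (s, t) for (s, t), codes in world.bridge_truth.links.items() if "P" in codes
    )
    n_rows = 0
    with synteny.open("w") as fh:
        fh.write("block_id\tsource\ttarget\n")
        for start in range(0, len(p_links), 8):
            bid = f"B{start // 8 + 1:04d}"
            for s, t in p_links[start : start + 8]:
                fh.write(f"{bid}\t{s}\t{t}\n")
                n_rows += 1
    _record(synteny, n_rows)

    # --- BLAST tabular (B evidence: fill-in best hits, plus decoys) ---
    blast = out / "blast.tsv"
    n_rows = 0
    source_list = world.source_proteins
    with blast.open("w") as fh:

        def _row(query, subject, evalue, bitscore):
            nonlocal n_rows
            fh.write(
                f"{query}\t{subject}\t{rng.uniform(60, 99):.2f}\t"
                f"{int(rng.integers(100, 900))}\t{int(rng.integers(0, 40))}\t"
                f"{int(rng.integers(0, 5))}\t1\t100\t1\t100\t{evalue:.3g}\t{bitscore:.1f}\n"
            )
            n_rows += 1

        for (s, t), codes in sorted(world.bridge_truth.links.items()):
            if codes == {"B"}:
                evalue = 10.0 ** rng.uniform(-50, -10)
                _row(t, s, evalue, rng.uniform(200, 600))
                if rng.random() < 0.3:  # worse secondary hit, must lose best-hit selection
                    other = source_list[int(rng.integers(len(source_list)))]
                    _row(t, other, evalue * 1e5, rng.uniform(50, 150))
            else:
                if rng.random() < 0.1:  # above-cutoff decoy for a covered target
                    _row(t, s, 10.0 ** rng.uniform(-5, -1), rng.uniform(30, 60))
                if rng.random() < 0.05:  # below-cutoff hit that the fill-in rule must ignore
                    _row(t, s, 10.0 ** rng.uniform(-30, -10), rng.uniform(100, 300))
    _record(blast, n_rows)

    # --- domain assignments (source and target) ---
    for name, assignments in (
        ("source_domains.tsv", world.source_assignments),
        ("target_domains.tsv", world.target_assignments),
    ):
        path = out / name
        n_rows = 0
        with path.open("w") as fh:
            fh.write("protein\tdomain\tevalue\n")
            for protein in sorted(assignments):
                asn = assignments[protein]
                for dom in sorted(asn.domains):
                    fh.write(f"{protein}\t{dom}\t{asn.best_evalues[dom]:.3g}\n")
                    n_rows += 1
                if rng.random() < 0.1:  # weak spurious hit above the loader cutoff
                    dom = world.domain_names[int(rng.integers(len(world.domain_names)))]
                    fh.write(f"{protein}\t{dom}\t{10.0 ** rng.uniform(-8, -3):.3g}\n")
                    n_rows += 1
        _record(path, n_rows)

    # --- known-DDI table: partial/corrupted copy of the truth (D4 analogue) ---
    ddi_path = out / "known_ddis.tsv"
    true_list = sorted(world.true_ddis)
    keep_mask = rng.random(len(true_list)) < 0.5
    known = [pair for pair, m in zip(true_list, keep_mask) if m]
    n_decoys = int(round(0.1 * len(true_list)))
    decoys: set = set()
    while len(decoys) < n_decoys:
        a, b = rng.choice(len(world.domain_names), size=2, replace=True)
        pair = canonical_pair(world.domain_names[int(a)], world.domain_names[int(b)])
        if pair not in world.true_ddis:
            decoys.add(pair)
    n_rows = 0
    with ddi_path.open("w") as fh:
        fh.write("domain_a\tdomain_b\torigin\n")
        for d1, d2 in sorted(set(known) | decoys):
            fh.write(f"{d1}\t{d2}\tsynthetic-known\n")
            n_rows += 1
    _record(ddi_path, n_rows)

    # --- GO cellular-component tables ---
    for name, table in (("go_source.tsv", world.go_cc_source), ("go_target.tsv", world.go_cc_target)):
        path = out / name
        n_rows = 0
        with path.open("w") as fh:
            fh.write("protein\tgo_id\taspect\n")
            for protein in sorted(table):
                for term in sorted(table[protein]):
                    fh.write(f"{protein}\t{term}\tC\n")
                    n_rows += 1
        _record(path, n_rows)

    # --- co-expression correlations ---
    coexpr_path = out / "coexpr.tsv"
    n_rows = 0
    with coexpr_path.open("w") as fh:
        fh.write("protein_a\tprotein_b\tr\n")
        for (a, b) in sorted(world.coexpr):
            fh.write(f"{a}\t{b}\t{world.coexpr[(a, b)]:.4f}\n")
            n_rows += 1
    _record(coexpr_path, n_rows)

    # --- target genome protein list ---
    genome_path = out / "target_genome.txt"
    with genome_path.open("w") as fh:
        for t in sorted(world.target_proteins):
            fh.write(t + "\n")
    _record(genome_path, len(world.target_proteins))

    return manifest


def load_go_table(path) -> dict:
    """Read a (protein, go_id, aspect) TSV into protein -> set of CC terms."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict = {}
    for row in df.itertuples(index=False):
        if row.aspect == "C":
            out.setdefault(row.protein, set()).add(row.go_id)
    return out


def load_coexpr_table(path) -> dict:
    """Read a (protein_a, protein_b, r) TSV into canonical pair -> r."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str, "r": float})
    return {
        canonical_pair(row.protein_a, row.protein_b): float(row.r)
        for row in df.itertuples(index=False)
    }


def config_from_yaml(path) -> WorldConfig:
    """Load a WorldConfig from a flat key: value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "copy_number_probs" in raw:
        raw["copy_number_probs"] = {int(k): float(v) for k, v in raw["copy_number_probs"].items()}
    return WorldConfig(**raw)
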