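"""Training-set construction for domain-interaction inference.

Positives come from the two-hybrid subset of the compiled interaction set
(D1-sub).  Negatives (D5) are hypothetical non-interacting pairs: true
negatives cannot be observed, so random pairs are screened through four
conservative rules — (i) not in the compiled PPI set, (ii) no candidate
domain pair in the known-DDI catalogue, (iii) sharing a cellular-component
GO term, and (iv) absolute co-expression below a threshold.  Rules iii/iv
ensure the pair is co-localized yet shows no expression signature of
interaction, making "non-interacting" the parsimonious label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .util import canonical_pair


@dataclass
class NegativeSamplingConfig:
    n_negatives: int
    seed: int
    coexpr_threshold: float = 0.4
    max_attempts: int | None = None  # default: 200 draws per requested negative

    def __post_init__(self) -> None:
        if self.coexpr_threshold < 0:
            raise ValueError("coexpr_threshold must be >= 0")


def sample_negatives(
    proteins,
    d1,
    d4,
    assignments,
    go_cc,
    coexpr,
    cfg: NegativeSamplingConfig,
):
    """Draw hypothetical non-interacting protein pairs (D5).

    ``go_cc`` maps protein -> set of cellular-component terms; ``coexpr``
    maps canonical protein pair -> correlation.  Returns ``(pairs,
    tallies)`` where tallies counts rejections by rule; pairs with missing
    annotation or correlation data are rejected and tallied separately.
    Emits a warning and returns fewer pairs if the attempt budget is
    exhausted first.
    """
    proteins = sorted(proteins)
    if len(proteins) < 2:
        raise ValueError("need at least two proteins to sample pairs")
    rng = np.random.default_rng(cfg.seed)
    budget = cfg.max_attempts if cfg.max_attempts is not None else 200 * cfg.n_negatives
    d4_pairs = d4.pairs if hasattr(d4, "pairs") else set(d4)

    accepted: list = []
    seen: set = set()
    tallies = {
        "in_d1": 0,
        "domain_pair_in_d4": 0,
        "no_shared_cc": 0,
        "coexpressed": 0,
        "unannotated": 0,
        "no_go": 0,
        "no_coexpr": 0,
        "duplicate": 0,
    }
    attempts = 0
    while len(accepted) < cfg.n_negatives and attempts < budget:
        attempts += 1
        i, j = rng.choice(len(proteins), size=2, replace=False)
        pair = canonical_pair(proteins[i], proteins[j])
        if pair in seen:
            tallies["duplicate"] += 1
            continue
        p, q = pair
        # rule i: must not appear in the compiled PPI set
        if pair in d1:
            tallies["in_d1"] += 1
            continue
        # rule ii: no candidate domain pair present in D4
        ap, aq = assignments.get(p), assignments.get(q)
        if ap is None or aq is None or not ap.domains or not aq.domains:
            tallies["unannotated"] += 1
            continue
        if any(canonical_pair(a, b) in d4_pairs for a in ap.domains for b in aq.domains):
            tallies["domain_pair_in_d4"] += 1
            continue
        # rule iii: same GO cellular-component term
        gp, gq = go_cc.get(p), go_cc.get(q)
        if not gp or not gq:
            tallies["no_go"] += 1
            continue
        if not (set(gp) & set(gq)):
            tallies["no_shared_cc"] += 1
            continue
        # rule iv: |co-expression| below threshold
        r = coexpr.get(pair)
        if r is None:
            tallies["no_coexpr"] += 1
            continue
        if abs(r) >= cfg.coexpr_threshold:
            tallies["coexpressed"] += 1
            continue
        seen.add(pair)
        accepted.append(pair)

    if len(accepted) < cfg.n_negatives:
        warnings.warn(
            f"negative sampler exhausted budget ({budget} draws): "
            f"returning {len(accepted)} of {cfg.n_negatives} requested pairs",
            stacklevel=2,
        )
    return accepted, tallies
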