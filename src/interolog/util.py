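"""Small shared helpers."""

from __future__ import annotations

import re
from typing import Hashable, Tuple

Pair = Tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical (lexicographic) order.

    Self-pairs (a == b) are permitted and returned as-is.
    """
    return (a, b) if a <= b else (b, a)


def strip_isoform(accession: str, pattern: str = r"\.\d+$") -> str:
    """Strip a splice-variant suffix (e.g. ``At1g07140.1`` -> ``At1g07140``)."""
    return re.sub(pattern, "", accession)


def venn_counts(named_sets: dict[str, set]) -> dict[frozenset, int]:
    """Intersection sizes for every combination of >= 1 input sets.

    Returns a mapping ``frozenset(labels) -> |intersection of those sets|``
    (plain intersection counts, not exclusive Venn regions; the union size
    follows by inclusion-exclusion).
    """
    from itertools import combinations

    labels = sorted(named_sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inter = set(named_sets[combo[0]])
            for lab in combo[1:]:
                inter &= named_sets[lab]
            out[frozenset(combo)] = len(inter)
    return out


def inclusion_exclusion_union(counts: dict[frozenset, int]) -> int:
    """Union size implied by intersection counts from :func:`venn_counts`."""
    total = 0
    for combo, n in counts.items():
        total += n if len(combo) % 2 == 1 else -n
    return total
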