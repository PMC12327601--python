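"""Reaction-rule space preparation: transition indexing, Pfam pruning, and
database-coverage statistics.

Every reaction rule carries a signed monoisotopic mass transition
(product - substrate). The transition index is a sorted multimap from
transition value to rule ids, with bidirectional rules indexed under both
+t and -t, supporting windowed lookups in Da or ppm.

Pfam pruning drops rule-enzyme associations whose protein family is linked
to many distinct rules: such generic domains (e.g., broad transferase
families) explain almost any mass difference and mostly add noise.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core_data import ReactionRule, ValidationError


@dataclass
class TransitionIndex:
    """Sorted multimap: signed mass transition -> rule ids.

    ``entries`` is a list of (transition, rule_id, direction) sorted by
    transition, where direction is "forward" if the rule is traversed
    substrate->product at +transition and "reverse" for the mirrored entry
    of a bidirectional rule.
    """

    entries: list[tuple[float, str, str]]
    rules: dict[str, ReactionRule]

    def __post_init__(self):
        self.entries = sorted(self.entries)
        self._keys = [e[0] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, value: float, tol_da: float) -> list[tuple[str, str]]:
        """All (rule_id, direction) whose indexed transition lies within
        ``value`` +/- ``tol_da``."""
        lo = bisect.bisect_left(self._keys, value - tol_da)
        hi = bisect.bisect_right(self._keys, value + tol_da)
        return sorted((rid, direction) for _, rid, direction in self.entries[lo:hi])

    def lookup_ppm(self, value: float, reference_mass: float, ppm: float) -> list[tuple[str, str]]:
        """Windowed lookup with a ppm tolerance applied to a reference
        neutral mass (the implied substrate/product scale)."""
        return self.lookup(value, abs(reference_mass) * ppm * 1e-6)


def build_transition_index(rules: list[ReactionRule]) -> TransitionIndex:
    """Index rules by signed transition; direction "both" gets entries at
    +t (forward) and -t (reverse)."""
    entries: list[tuple[float, str, str]] = []
    by_id: dict[str, ReactionRule] = {}
    for rule in rules:
        by_id[rule.rule_id] = rule
        t = rule.mass_transition
        if rule.direction in ("forward", "both"):
            entries.append((t, rule.rule_id, "forward"))
        if rule.direction in ("retro", "both"):
            entries.append((-t, rule.rule_id, "reverse"))
    return TransitionIndex(entries=entries, rules=by_id)


def pfam_filter(rules: list[ReactionRule], max_reactions_per_pfam: int) -> list[ReactionRule]:
    """Drop associations whose Pfam is linked to more than
    ``max_reactions_per_pfam`` distinct rules; rules left with no
    association are removed. Idempotent."""
    counts: dict[str, set[str]] = {}
    for rule in rules:
        for assoc in rule.enzyme_associations:
            counts.setdefault(assoc.pfam_id, set()).add(rule.rule_id)
    generic = {p for p, rids in counts.items() if len(rids) > max_reactions_per_pfam}
    out = []
    for rule in rules:
        kept = tuple(a for a in rule.enzyme_associations if a.pfam_id not in generic)
        if kept:
            out.append(replace(rule, enzyme_associations=kept))
    return out


def coverage_chisq(found: int, total: int) -> tuple[float, float]:
    """Goodness-of-fit of a found/missing split against the equal-probability
    null (expected total/2 in each cell), DF = 1.

    Returns (chi2, p). Symmetric: coverage_chisq(k, n) == coverage_chisq(n-k, n).
    """
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= found <= total:
        raise ValidationError(f"found must lie in [0, {total}], got {found}")
    expected = total / 2.0
    chi2 = (found - expected) ** 2 / expected + ((total - found) - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
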