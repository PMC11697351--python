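"""Protein-level FDR from search-engine probabilities.

The protein table of a search carries a per-group identification
probability.  Its complement, PEP = 1 − probability, is the posterior error
probability of that single identification; sorting by PEP and taking the
running mean converts local error into the expected false-discovery rate of
the list accepted up to that row — the q-value.  Groups with q ≤ α (default
1%) are retained; contaminants are removed before any further analysis.
Records that tie on PEP share the q of the last tied row (the conservative
choice).

Also houses the accession harmonization used when the same protein group is
reported with different member lists by different searches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

DEFAULT_FDR_ALPHA = 0.01


@dataclass
class ProteinScoreRecord:
    """Protein group with probability, PEP, q-value and filter state."""

    group_ids: tuple[str, ...]
    probability: float
    pep: float = field(default=float("nan"))
    q_value: float = field(default=float("nan"))
    contaminant: bool = False
    retained: bool = False

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(
                f"probability {self.probability} outside [0, 1] for "
                f"{';'.join(self.group_ids)}"
            )


def qvalues_from_probabilities(probabilities: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """PEPs and q-values for an array of protein probabilities.

    q_i is the mean PEP of all records with PEP ≤ PEP_i: sort ascending by
    PEP, take the cumulative mean, and let ties share the value of the last
    tied row.  Returned in the original input order.
    """
    prob = np.asarray(probabilities, dtype=float)
    if prob.size == 0:
        return np.array([]), np.array([])
    if np.any((prob < 0) | (prob > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    pep = 1.0 - prob
    order = np.argsort(pep, kind="stable")
    sorted_pep = pep[order]
    q_sorted = np.cumsum(sorted_pep) / np.arange(1, pep.size + 1)
    # ties share the q of the last tied row
    i = pep.size - 1
    while i > 0:
        if sorted_pep[i - 1] == sorted_pep[i]:
            q_sorted[i - 1] = q_sorted[i]
        i -= 1
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return pep, q


def compute_qvalues(records: Sequence[ProteinScoreRecord]) -> list[ProteinScoreRecord]:
    """Fill ``pep`` and ``q_value`` on each record; input order preserved."""
    if not records:
        return []
    pep, q = qvalues_from_probabilities([r.probability for r in records])
    return [
        replace(r, pep=float(p), q_value=float(qv))
        for r, p, qv in zip(records, pep, q)
    ]


def filter_fdr(
    records: Sequence[ProteinScoreRecord], alpha: float = DEFAULT_FDR_ALPHA
) -> list[ProteinScoreRecord]:
    """Retain records with q ≤ alpha that are not contaminants."""
    out = []
    for r in records:
        if np.isnan(r.q_value):
            raise ValidationError("q-values must be computed before filtering")
        retained = (r.q_value <= alpha) and not r.contaminant
        out.append(replace(r, retained=retained))
    return [r for r in out if r.retained]


def remove_contaminants(
    records: Sequence[ProteinScoreRecord], contaminant_accessions: Iterable[str]
) -> list[ProteinScoreRecord]:
    """Drop any record whose group shares an accession with the contaminant set."""
    contaminants = set(contaminant_accessions)
    return [r for r in records if not (set(r.group_ids) & contaminants)]


def harmonize_group_ids(
    groups_per_search: Mapping[str, Sequence[Sequence[str]]],
) -> dict[str, dict[tuple[str, ...], str]]:
    """Pick one representative accession per multi-ID protein group.

    For each search and each of its groups with multiple accessions, the
    member that occurs most frequently across all *other* searches is kept;
    ties break to the lexicographically smaller accession.  Single-ID groups
    map to their sole member.
    """
    if len(groups_per_search) < 2:
        raise ValidationError("harmonization needs at least two searches")
    counts_per_search: dict[str, Counter] = {}
    for search, groups in groups_per_search.items():
        c: Counter = Counter()
        for group in groups:
            c.update(group)
        counts_per_search[search] = c

    result: dict[str, dict[tuple[str, ...], str]] = {}
    for search, groups in groups_per_search.items():
        other = Counter()
        for s, c in counts_per_search.items():
            if s != search:
                other.update(c)
        mapping: dict[tuple[str, ...], str] = {}
        for group in groups:
            group = tuple(group)
            if len(group) == 1:
                mapping[group] = group[0]
            else:
                # max count, lexicographic tie-break
                mapping[group] = min(group, key=lambda a: (-other[a], a))
        result[search] = mapping
    return result
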