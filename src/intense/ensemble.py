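"""Majority-vote aggregation of factor clusterings into consensus
interactions — the ensemble decision rule.

Each clustering method contributes one vote per factor pair: 1 if it placed
the two factors in the same cluster, 0 otherwise. Summing the co-membership
matrices across methods gives the vote matrix; pairs reaching the quorum are
consensus interactions, with the unanimous tier (all methods agree) as the
headline. Maximal consensus groups are the connected components of the
unanimous-pair graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clustering import FactorClustering, GroupRecommendation
from .exceptions import ConfigError

Recommendation = FactorClustering | GroupRecommendation


def _groups_of(item: Recommendation) -> list[list[str]]:
    if isinstance(item, FactorClustering):
        return list(item.clusters().values())
    return [list(g) for g in item.groups]


def comembership(item: Recommendation, factor_names: Sequence[str]) -> np.ndarray:
    """Binary F x F matrix: 1 iff two factors share a cluster/group
    (diagonal 1).

    Accepts a strict partition or a :class:`GroupRecommendation` whose
    groups may overlap (two factors co-member iff they share *any* group).
    Factors in ``factor_names`` outside every group count as singletons;
    factors in the item but absent from ``factor_names`` are an error.
    """
    known = set(factor_names)
    covered = (
        set(item.assignment) if isinstance(item, FactorClustering) else set(item.factor_names)
    )
    unknown = sorted(covered - known)
    if unknown:
        raise ConfigError(f"clustering contains unknown factor label(s): {unknown}")
    f = len(factor_names)
    index = {n: i for i, n in enumerate(factor_names)}
    out = np.eye(f, dtype=int)
    for group in _groups_of(item):
        for a in group:
            for b in group:
                out[index[a], index[b]] = 1
    return out


@dataclass
class VoteMatrix:
    """Summed co-membership over methods; entry (i, j) in [0, M]."""

    values: np.ndarray
    factor_names: list[str]
    methods: list[str]

    @property
    def n_methods(self) -> int:
        return len(self.methods)

    def pair_votes(self, a: str, b: str) -> int:
        i, j = self.factor_names.index(a), self.factor_names.index(b)
        return int(self.values[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.factor_names, columns=self.factor_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def vote(
    clusterings: Sequence[Recommendation],
    factor_names: Sequence[str] | None = None,
) -> VoteMatrix:
    """Elementwise sum of the methods' co-membership matrices.

    If ``factor_names`` is given, it is the voting universe and each
    clustering may cover a subset of it (uncovered factors vote as
    singletons). Otherwise all clusterings must cover the same factor set; a
    mismatch is an error listing the difference.
    """
    if len(clusterings) < 2:
        raise ConfigError("voting needs at least 2 clusterings")
    if factor_names is None:
        sets = [
            frozenset(c.assignment) if isinstance(c, FactorClustering) else frozenset(c.factor_names)
            for c in clusterings
        ]
        if len(set(sets)) != 1:
            union = frozenset().union(*sets)
            diffs = {
                c.method: sorted(union - s) for c, s in zip(clusterings, sets) if union - s
            }
            raise ConfigError(f"clusterings cover different factor sets; missing: {diffs}")
        factor_names = list(clusterings[0].factor_names)
    total = sum(comembership(c, factor_names) for c in clusterings)
    return VoteMatrix(
        values=np.asarray(total),
        factor_names=list(factor_names),
        methods=[c.method for c in clusterings],
    )


@dataclass
class ConsensusReport:
    """Tiered consensus interactions.

    ``unanimous_pairs``: pairs every method grouped together.
    ``majority_pairs``: pairs reaching the quorum but short of unanimity.
    ``groups``: connected components of the unanimous-pair graph (size >= 2).
    ``ranked_pairs``: all pairs at or above quorum, by descending vote count.
    ``directions``: per-factor sign annotations where a signed method (IPCA)
    provided them.
    """

    unanimous_pairs: list[tuple[str, str]]
    majority_pairs: list[tuple[str, str]]
    groups: list[list[str]]
    ranked_pairs: list[tuple[str, str, int]]
    quorum: int
    n_methods: int
    directions: dict[str, int] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def pair_direction(self, a: str, b: str) -> str | None:
        """'same' / 'opposite' when both factors carry a sign, else None."""
        if a in self.directions and b in self.directions:
            return "same" if self.directions[a] == self.directions[b] else "opposite"
        return None

    def to_dict(self) -> dict:
        return {
            "quorum": self.quorum,
            "n_methods": self.n_methods,
            "unanimous_pairs": [list(p) for p in self.unanimous_pairs],
            "majority_pairs": [list(p) for p in self.majority_pairs],
            "groups": [list(g) for g in self.groups],
            "ranked_pairs": [
                {
                    "pair": [a, b],
                    "votes": v,
                    **(
                        {"direction": self.pair_direction(a, b)}
                        if self.pair_direction(a, b)
                        else {}
                    ),
                }
                for a, b, v in self.ranked_pairs
            ],
            "directions": dict(self.directions),
            "provenance": list(self.provenance),
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def to_markdown(self) -> str:
        lines = ["# Consensus interaction report", ""]
        lines.append(f"Methods voting: {self.n_methods}; quorum: {self.quorum}.")
        lines.append("")
        lines.append("## Unanimous consensus groups")
        if self.groups:
            for g in self.groups:
                lines.append("- " + ", ".join(g))
        else:
            lines.append("- (none)")
        lines.append("")
        lines.append("## Ranked consensus pairs")
        if self.ranked_pairs:
            lines.append("| factor A | factor B | votes | direction |")
            lines.append("|---|---|---|---|")
            for a, b, v in self.ranked_pairs:
                d = self.pair_direction(a, b) or ""
                lines.append(f"| {a} | {b} | {v} | {d} |")
        else:
            lines.append("(no pair reached the quorum)")
        lines.append("")
        if self.provenance:
            lines.append("## Method provenance")
            for entry in self.provenance:
                lines.append(f"- **{entry.get('method')}**: {json.dumps(entry.get('params', {}))}")
            lines.append("")
        return "\n".join(lines)


def _connected_components(nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> list[list[str]]:
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps: dict[str, list[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    return [c for c in comps.values() if len(c) >= 2]


def consensus(
    votes: VoteMatrix,
    quorum: int = 2,
    directions: Mapping[str, int] | None = None,
    provenance: Sequence[Mapping] | None = None,
) -> ConsensusReport:
    """Extract tiered consensus interactions from a vote matrix.

    Raising the quorum can only remove pairs. Pairs are ranked by descending
    vote count, ties broken by factor order.
    """
    m = votes.n_methods
    if not 1 <= quorum <= m:
        raise ConfigError(f"quorum must be in [1, {m}], got {quorum}")
    names = votes.factor_names
    unanimous, majority, ranked = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            v = int(votes.values[i, j])
            if v >= quorum:
                ranked.append((names[i], names[j], v))
            if v == m:
                unanimous.append((names[i], names[j]))
            elif quorum <= v < m:
                majority.append((names[i], names[j]))
    ranked.sort(key=lambda t: -t[2])
    groups = _connected_components(names, unanimous)
    return ConsensusReport(
        unanimous_pairs=unanimous,
        majority_pairs=majority,
        groups=groups,
        ranked_pairs=ranked,
        quorum=quorum,
        n_methods=m,
        directions=dict(directions or {}),
        provenance=[dict(p) for p in (provenance or [])],
    )
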