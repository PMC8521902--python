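"""The partition type exchanged between the three clustering views and the
ensemble voter."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .exceptions import ConfigError


@dataclass(frozen=True)
class FactorClustering:
    """A partition of factor labels into clusters, tagged with the method
    that produced it.

    ``assignment`` maps every factor name to a cluster id; ids are contiguous
    integers starting at 0. ``params`` records the parameters the method ran
    with, for provenance.
    """

    method: str
    assignment: Mapping[str, int]
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids and ids != list(range(len(ids))):
            raise ConfigError(f"cluster ids must be contiguous from 0, got {ids}")

    @property
    def factor_names(self) -> list[str]:
        return list(self.assignment)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for name, cid in self.assignment.items():
            out.setdefault(cid, []).append(name)
        return dict(sorted(out.items()))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "clusters": {str(k): v for k, v in self.clusters().items()},
            "params": dict(self.params),
        }


@dataclass(frozen=True)
class GroupRecommendation:
    """A method's raw interaction groups, which — unlike a partition — may
    overlap (a factor can appear in several recommended groups). Factors
    outside every group are implicit singletons."""

    method: str
    groups: tuple[tuple[str, ...], ...]
    params: Mapping[str, object] = field(default_factory=dict)

    @property
    def factor_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for group in self.groups:
            for name in group:
                seen.setdefault(name)
        return list(seen)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "groups": [list(g) for g in self.groups],
            "params": dict(self.params),
        }


def clustering_from_labels(
    method: str,
    factor_names: Iterable[str],
    labels: Iterable[int],
    params: Mapping[str, object] | None = None,
) -> FactorClustering:
    """Build a clustering from parallel name/label sequences, relabeling
    cluster ids to contiguous integers in order of first appearance."""
    factor_names = list(factor_names)
    labels = list(labels)
    if len(factor_names) != len(labels):
        raise ConfigError("factor_names and labels differ in length")
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for name, lab in zip(factor_names, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[name] = remap[lab]
    return FactorClustering(method=method, assignment=assignment, params=dict(params or {}))


def clustering_from_groups(
    method: str,
    groups: Iterable[Iterable[str]],
    all_factors: Iterable[str] | None = None,
    params: Mapping[str, object] | None = None,
) -> FactorClustering:
    """Build a clustering from explicit factor groups.

    Factors in ``all_factors`` not covered by any group become singletons —
    the convention used when a method genuinely produced no grouping for a
    factor.
    """
    assignment: dict[str, int] = {}
    for cid, group in enumerate(groups):
        for name in group:
            if name in assignment:
                raise ConfigError(f"factor {name!r} appears in more than one group")
            assignment[name] = cid
    next_id = len(set(assignment.values()))
    for name in all_factors or ():
        if name not in assignment:
            assignment[name] = next_id
            next_id += 1
    return FactorClustering(method=method, assignment=assignment, params=dict(params or {}))
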