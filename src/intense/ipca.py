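"""Interaction principal component analysis (IPCA).

IPCA looks for *interacting* factors by correlating each factor with the
principal components of the standardized cohort. A principal component on
which two or more factors load strongly (|r| >= tau) defines part of the
*interaction zone*; factors never reaching the threshold on any such
component are non-interacting. The procedure is two-pass: the interaction
zone of the full data selects the interacting factors, then PCA is recomputed
on the selected factors alone and each one is assigned to the interaction
component on which it loads most strongly, together with the sign of that
loading. The signed per-component groups are IPCA's interaction
recommendation and enter the ensemble vote as a factor partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import FactorClustering, clustering_from_groups
from .cohort_io import NormalizedMatrix
from .exceptions import ConfigError, DegenerateDataError

DEFAULT_TAU = 0.40
DEFAULT_CUTOFF = 0.70


@dataclass
class PCADecomposition:
    """Full PCA of a standardized matrix.

    ``scores`` is N x F (component score vectors in columns), ``loadings`` is
    F x F (unit eigenvectors of the correlation matrix in columns),
    ``explained_fraction`` the per-component variance fractions (sum to 1,
    non-increasing). Sign convention: each component is oriented so that its
    largest-|loading| factor loads positively.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray
    factor_names: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def compute_pcs(matrix: NormalizedMatrix) -> PCADecomposition:
    """PCA via singular-value decomposition of the Z-scored data.

    Because columns are standardized, the squared singular values are
    proportional to the eigenvalues of the factor correlation matrix;
    ``explained_fraction`` equals those eigenvalues divided by their sum (= F
    for full-rank standardized data). Rank-deficient input is allowed —
    trailing fractions are 0.
    """
    X = matrix.values
    n, f = X.shape
    if n < 2 or f < 2:
        raise DegenerateDataError(f"PCA needs at least 2 subjects and 2 factors, got {n}x{f}")
    # economy SVD unless N < F, where the full F x F right basis is needed
    _, s, vt = np.linalg.svd(X, full_matrices=(n < f))
    s_full = np.zeros(f)
    s_full[: s.shape[0]] = s
    V = vt.T  # F x F, columns are components
    # deterministic orientation: largest-|loading| entry of each component positive
    for j in range(f):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    scores = X @ V
    ev = s_full**2
    explained = ev / ev.sum()
    return PCADecomposition(
        scores=scores,
        loadings=V,
        explained_fraction=explained,
        factor_names=list(matrix.factor_names),
    )


def cumulative_dims(pca: PCADecomposition, cutoff: float = DEFAULT_CUTOFF) -> int:
    """Smallest number of leading components whose cumulative explained
    variance reaches ``cutoff`` (a fraction in (0, 1])."""
    if not 0 < cutoff <= 1:
        raise ConfigError(f"cutoff must be in (0, 1], got {cutoff}")
    csum = np.cumsum(pca.explained_fraction)
    # tolerate float round-off at the boundary
    reached = np.nonzero(csum >= cutoff - 1e-12)[0]
    if reached.size == 0:
        return pca.n_components
    return int(reached[0]) + 1


@dataclass
class JointCorrelationMap:
    """Pearson correlations over the concatenation [factors | PC scores].

    A (2F) x (2F) symmetric matrix in four F x F blocks: factor-factor
    (top-left), factor-PC (top-right), PC-factor, and PC-PC (identity, since
    components are orthogonal). Components with zero score variance (beyond
    the data's rank) correlate as 0 by convention and are listed in
    ``zero_variance_pcs``.
    """

    values: np.ndarray
    factor_names: list[str]
    zero_variance_pcs: tuple[int, ...] = ()

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    @property
    def factor_factor(self) -> np.ndarray:
        f = self.n_factors
        return self.values[:f, :f]

    @property
    def factor_pc(self) -> np.ndarray:
        f = self.n_factors
        return self.values[:f, f:]

    @property
    def pc_pc(self) -> np.ndarray:
        f = self.n_factors
        return self.values[f:, f:]

    def to_frame(self):
        import pandas as pd

        f = self.n_factors
        labels = list(self.factor_names) + [f"PC{j + 1}" for j in range(self.values.shape[0] - f)]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def joint_correlation_map(matrix: NormalizedMatrix, pca: PCADecomposition) -> JointCorrelationMap:
    if matrix.values.shape[0] != pca.scores.shape[0]:
        raise ConfigError("matrix and PCA decomposition have different subject counts")
    joint = np.hstack([matrix.values, pca.scores])
    sds = joint.std(axis=0, ddof=1)
    # relative floor: score columns beyond the data's rank carry only
    # round-off noise, not signal
    ok = sds > 1e-9 * max(sds.max(), 1.0)
    corr = np.zeros((joint.shape[1], joint.shape[1]))
    if ok.any():
        corr_ok = np.corrcoef(joint[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = np.atleast_2d(corr_ok)
    np.fill_diagonal(corr, 1.0)
    f = matrix.values.shape[1]
    zero_pcs = tuple(int(j - f) for j in np.nonzero(~ok)[0] if j >= f)
    return JointCorrelationMap(
        values=corr, factor_names=list(matrix.factor_names), zero_variance_pcs=zero_pcs
    )


@dataclass
class InteractionZone:
    """Components carrying >= 2 strongly-loading factors, and those factors.

    ``interaction_pcs`` are 0-based component indices (ordered); a factor is
    selected iff it attains |r| >= tau on at least one interaction component.
    """

    interaction_pcs: tuple[int, ...]
    selected_factors: tuple[str, ...]
    tau: float
    max_pcs: int

    @property
    def is_empty(self) -> bool:
        return not self.interaction_pcs


def detect_interaction_zone(
    jmap: JointCorrelationMap, tau: float = DEFAULT_TAU, max_pcs: int | None = None
) -> InteractionZone:
    """Scan the first ``max_pcs`` components for those where two or more
    factors have |correlation| >= ``tau``; return them with the union of
    suprathreshold factors. An empty zone is a valid result."""
    if not 0 < tau < 1:
        raise ConfigError(f"tau must be in (0, 1), got {tau}")
    f = jmap.n_factors
    n_pcs = jmap.values.shape[0] - f
    max_pcs = n_pcs if max_pcs is None else min(max_pcs, n_pcs)
    block = jmap.factor_pc
    pcs: list[int] = []
    selected: set[str] = set()
    for j in range(max_pcs):
        hits = np.nonzero(np.abs(block[:, j]) >= tau)[0]
        if hits.size >= 2:
            pcs.append(j)
            selected.update(jmap.factor_names[i] for i in hits)
    ordered = tuple(n for n in jmap.factor_names if n in selected)
    return InteractionZone(
        interaction_pcs=tuple(pcs), selected_factors=ordered, tau=tau, max_pcs=max_pcs
    )


@dataclass
class IPCAResult:
    """Two-pass IPCA output.

    ``interaction_groups`` maps each second-pass interaction component to its
    ``(factor, sign)`` members, where sign is the sign of the factor's
    correlation with that component (+1: moves with the component's positive
    direction, -1: against it). ``clustering`` is the partition formed by
    those groups with all remaining factors as singletons.
    """

    first_zone: InteractionZone
    second_pass: PCADecomposition | None
    second_zone: InteractionZone | None
    interaction_groups: dict[int, list[tuple[str, int]]]
    clustering: FactorClustering
    tau: float
    cutoff: float
    first_pass: PCADecomposition = field(repr=False, default=None)
    joint_map: JointCorrelationMap = field(repr=False, default=None)
    second_joint_map: JointCorrelationMap = field(repr=False, default=None)

    @property
    def factor_signs(self) -> dict[str, int]:
        """Flat factor -> sign map over all interaction groups."""
        return {name: sign for grp in self.interaction_groups.values() for name, sign in grp}

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "cutoff": self.cutoff,
            "first_zone": {
                "interaction_pcs": [int(j) for j in self.first_zone.interaction_pcs],
                "selected_factors": list(self.first_zone.selected_factors),
                "max_pcs": self.first_zone.max_pcs,
            },
            "interaction_groups": {
                f"PC{j + 1}": [{"factor": n, "sign": s} for n, s in grp]
                for j, grp in self.interaction_groups.items()
            },
            "clustering": self.clustering.to_dict(),
        }


def _assign_groups(
    zone: InteractionZone, jmap: JointCorrelationMap
) -> dict[int, list[tuple[str, int]]]:
    """Assign each zone factor to its max-|r| interaction component (ties ->
    lower component index) with the sign of that correlation."""
    groups: dict[int, list[tuple[str, int]]] = {}
    block = jmap.factor_pc
    for name in zone.selected_factors:
        i = jmap.factor_names.index(name)
        best_j, best_r = None, 0.0
        for j in zone.interaction_pcs:
            r = block[i, j]
            if abs(r) > abs(best_r) + 1e-15:
                best_j, best_r = j, r
        assert best_j is not None  # zone guarantees a suprathreshold component
        groups.setdefault(best_j, []).append((name, 1 if best_r >= 0 else -1))
    return dict(sorted(groups.items()))


def run_ipca(
    matrix: NormalizedMatrix,
    tau: float = DEFAULT_TAU,
    cutoff: float = DEFAULT_CUTOFF,
    max_pcs: int | None = None,
) -> IPCAResult:
    """The full two-pass IPCA procedure.

    Pass 1: PCA on all factors; the number of components scanned defaults to
    the cumulative-variance rule (smallest m reaching ``cutoff``); the
    interaction zone selects the interacting factors. Pass 2: PCA and zone
    detection are recomputed on the selected factors only, and signed
    interaction groups are read off the second-pass factor-component
    correlations. Fewer than two selected factors yields empty groups and an
    all-singleton clustering.
    """
    pca1 = compute_pcs(matrix)
    m = cumulative_dims(pca1, cutoff) if max_pcs is None else max_pcs
    jmap1 = joint_correlation_map(matrix, pca1)
    zone1 = detect_interaction_zone(jmap1, tau, m)

    empty = IPCAResult(
        first_zone=zone1,
        second_pass=None,
        second_zone=None,
        interaction_groups={},
        clustering=clustering_from_groups(
            "IPCA", [], matrix.factor_names, {"tau": tau, "cutoff": cutoff}
        ),
        tau=tau,
        cutoff=cutoff,
        first_pass=pca1,
        joint_map=jmap1,
    )
    if len(zone1.selected_factors) < 2:
        return empty

    sub = matrix.subset(zone1.selected_factors)
    pca2 = compute_pcs(sub)
    m2 = cumulative_dims(pca2, cutoff)
    jmap2 = joint_correlation_map(sub, pca2)
    zone2 = detect_interaction_zone(jmap2, tau, m2)
    groups = _assign_groups(zone2, jmap2)
    clustering = clustering_from_groups(
        "IPCA",
        [[n for n, _ in grp] for _, grp in sorted(groups.items())],
        matrix.factor_names,
        {"tau": tau, "cutoff": cutoff},
    )
    return IPCAResult(
        first_zone=zone1,
        second_pass=pca2,
        second_zone=zone2,
        interaction_groups=groups,
        clustering=clustering,
        tau=tau,
        cutoff=cutoff,
        first_pass=pca1,
        joint_map=jmap1,
        second_joint_map=jmap2,
    )
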