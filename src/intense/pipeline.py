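"""End-to-end orchestration: normalize -> three clustering views -> vote ->
consensus, with artifact export.

All randomness flows from one root seed, split per stage with
``numpy.random.SeedSequence`` so each stage is individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._version import __version__ as _version
from .cbc import DEFAULT_RESTARTS, embed_factors, kmeans_factors, select_k
from .cohort_io import CohortTable, FactorSchema, default_schema, load_cohort, normalize_cohort
from .ensemble import consensus, vote
from .exceptions import ConfigError
from .hca import average_linkage_tree, cut_tree, factor_distances, to_newick
from .ipca import DEFAULT_CUTOFF, DEFAULT_TAU, run_ipca
from .synthetic import CohortConfig, default_config, generate_cohort

# k-means runs on the 2-D factor embedding: the leading two principal
# directions carry the planted/real block structure while higher directions
# mostly add the diffuse spread of unclustered factors, which drowns the
# inertia elbow
DEFAULT_EMBED_DIM = 2


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    Exactly one of ``input_path`` (a cohort CSV) or ``synthetic`` (a
    generator configuration; None + ``use_default_synthetic`` selects the
    packaged default) provides the cohort.
    """

    input_path: str | Path | None = None
    synthetic: CohortConfig | None = None
    use_default_synthetic: bool = False
    schema: FactorSchema | None = None
    tau: float = DEFAULT_TAU
    cutoff: float = DEFAULT_CUTOFF
    k: int | None = None  # None -> inertia-elbow selection
    k_range: tuple[int, int] = (2, 10)
    quorum: int = 2
    seed: int = 1
    restarts: int = DEFAULT_RESTARTS
    embed_dim: int | None = None  # None -> min(F, N, DEFAULT_EMBED_DIM)
    impute_missing: bool = False

    def resolve_cohort(self) -> CohortTable:
        sources = sum(
            [self.input_path is not None, self.synthetic is not None, self.use_default_synthetic]
        )
        if sources != 1:
            raise ConfigError(
                "exactly one cohort source required: input_path, synthetic, "
                "or use_default_synthetic"
            )
        if self.input_path is not None:
            return load_cohort(self.input_path, self.schema or default_schema())
        config = self.synthetic if self.synthetic is not None else default_config()
        return generate_cohort(config, seed=_stage_seed(self.seed, 0))


def _stage_seed(root_seed: int, stage: int) -> int:
    """Deterministic per-stage child seed below 2**31."""
    child = np.random.SeedSequence(root_seed).spawn(stage + 1)[stage]
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class RunResult:
    """All artifacts of one pipeline run."""

    report: "ConsensusReport"
    cohort: CohortTable
    normalized: "NormalizedMatrix"
    ipca: "IPCAResult"
    tree: "Dendrogram"
    hca_clustering: "FactorClustering"
    embedding: "FactorEmbedding"
    kmeans: "KMeansResult"
    k_selection: "KSelection | None"
    votes: "VoteMatrix"
    config: RunConfig
    resolved_params: dict = field(default_factory=dict)

    def write_artifacts(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the machine-readable artifact set; returns name -> path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "report": out / "consensus_report.json",
            "report_md": out / "consensus_report.md",
            "votes": out / "vote_matrix.csv",
            "dendrogram": out / "dendrogram.nwk",
            "inertia": out / "inertia_curve.csv",
            "run_log": out / "run_log.json",
        }
        self.report.to_json(paths["report"])
        paths["report_md"].write_text(self.report.to_markdown(), encoding="utf-8")
        self.votes.to_csv(paths["votes"])
        paths["dendrogram"].write_text(to_newick(self.tree) + "\n", encoding="utf-8")
        if self.k_selection is not None:
            curve = self.k_selection.inertia_curve
            lines = ["k,inertia"] + [f"{k},{v!r}" for k, v in sorted(curve.items())]
        else:
            lines = ["k,inertia", f"{self.kmeans.k},{self.kmeans.inertia!r}"]
        paths["inertia"].write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths["run_log"].write_text(
            json.dumps(self.resolved_params, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return paths


def run_intense(config: RunConfig) -> RunResult:
    """Run the full consensus pipeline; deterministic given ``config``."""
    cohort = config.resolve_cohort()
    normalized = normalize_cohort(cohort, impute_missing=config.impute_missing)
    f = normalized.n_factors

    ipca_result = run_ipca(normalized, tau=config.tau, cutoff=config.cutoff)

    dist = factor_distances(normalized)
    tree = average_linkage_tree(dist)

    embed_dim = config.embed_dim or min(f, DEFAULT_EMBED_DIM, normalized.n_subjects)
    embedding = embed_factors(normalized, d=embed_dim)
    km_seed = _stage_seed(config.seed, 1)
    k_selection = None
    if config.k is None:
        k_hi = min(config.k_range[1], f - 1)
        k_selection = select_k(
            embedding, (config.k_range[0], k_hi), seed=km_seed, restarts=config.restarts
        )
        k = k_selection.k
    else:
        k = config.k
    kmeans = kmeans_factors(embedding, k, seed=km_seed, restarts=config.restarts)
    cbc_clustering = kmeans.to_clustering()

    hca_clustering = cut_tree(tree, k)  # same k as CBC for cross-method comparability

    clusterings = [ipca_result.clustering, hca_clustering, cbc_clustering]
    votes = vote(clusterings, normalized.factor_names)
    report = consensus(
        votes,
        quorum=config.quorum,
        directions=ipca_result.factor_signs,
        provenance=[c.to_dict() for c in clusterings],
    )

    resolved = {
        "version": _version,
        "seed": config.seed,
        "stage_seeds": {"synthetic": _stage_seed(config.seed, 0), "kmeans": km_seed},
        "tau": config.tau,
        "cutoff": config.cutoff,
        "k": k,
        "k_selected": config.k is None,
        "k_range": list(config.k_range),
        "quorum": config.quorum,
        "restarts": config.restarts,
        "embed_dim": embed_dim,
        "n_subjects": cohort.n_subjects,
        "n_factors": f,
        "impute_missing": config.impute_missing,
    }
    return RunResult(
        report=report,
        cohort=cohort,
        normalized=normalized,
        ipca=ipca_result,
        tree=tree,
        hca_clustering=hca_clustering,
        embedding=embedding,
        kmeans=kmeans,
        k_selection=k_selection,
        votes=votes,
        config=config,
        resolved_params=resolved,
    )
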