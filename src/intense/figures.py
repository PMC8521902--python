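"""Presentational figure export for a completed pipeline run.

Four figures mirror the standard way each view is inspected: the joint
factor/component correlation heat map with the interaction zone, the
second-pass heat map over the selected factors, the factor dendrogram, and
the 2-D embedding scatter colored by k-means cluster. No numbers originate
here; failures warn and are skipped rather than aborting a run.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless-safe; figures are file exports only

import matplotlib.pyplot as plt
from scipy.cluster import hierarchy

from .pipeline import RunResult


def _heatmap(ax, jmap, title: str, interaction_pcs=()):
    values = jmap.values
    f = jmap.n_factors
    im = ax.imshow(values, cmap="RdBu_r", vmin=-1, vmax=1)
    labels = list(jmap.factor_names) + [f"PC{j + 1}" for j in range(values.shape[0] - f)]
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=5)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=5)
    ax.axhline(f - 0.5, color="k", lw=0.8)
    ax.axvline(f - 0.5, color="k", lw=0.8)
    for j in interaction_pcs:
        ax.add_patch(
            plt.Rectangle((f + j - 0.5, -0.5), 1, f, fill=False, edgecolor="green", lw=1.0)
        )
    ax.set_title(title, fontsize=9)
    return im


def render_figures(result: RunResult, out_dir: str | Path, fmt: str = "png") -> dict[str, Path]:
    """Write the four run figures; returns name -> path for those written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _try(name: str, fn) -> None:
        path = out / f"{name}.{fmt}"
        try:
            fn(path)
            written[name] = path
        except Exception as exc:  # presentational only — never fatal
            warnings.warn(f"figure {name!r} failed: {exc}")

    def joint_heatmap(path):
        fig, ax = plt.subplots(figsize=(10, 10))
        im = _heatmap(
            ax,
            result.ipca.joint_map,
            "Factor / principal-component correlations (pass 1)",
            result.ipca.first_zone.interaction_pcs,
        )
        fig.colorbar(im, ax=ax, shrink=0.6)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def selected_heatmap(path):
        fig, ax = plt.subplots(figsize=(8, 8))
        if result.ipca.second_joint_map is not None:
            im = _heatmap(
                ax,
                result.ipca.second_joint_map,
                "Selected-factor correlations (pass 2)",
                result.ipca.second_zone.interaction_pcs if result.ipca.second_zone else (),
            )
            fig.colorbar(im, ax=ax, shrink=0.6)
        else:
            ax.text(0.5, 0.5, "no interacting factors selected", ha="center", va="center")
            ax.set_axis_off()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def dendrogram(path):
        fig, ax = plt.subplots(figsize=(10, 5))
        hierarchy.dendrogram(
            result.tree.merges, labels=result.tree.leaf_names, ax=ax, leaf_rotation=90
        )
        ax.set_ylabel("average-linkage merge height")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def cluster_scatter(path):
        fig, ax = plt.subplots(figsize=(7, 6))
        coords = result.embedding.coords[:, :2]
        labels = result.kmeans.labels
        for cid in sorted(set(labels)):
            sel = labels == cid
            ax.scatter(coords[sel, 0], coords[sel, 1], label=f"cluster {cid}", s=30)
        for name, (x, y) in zip(result.embedding.factor_names, coords):
            ax.annotate(name, (x, y), fontsize=6, alpha=0.8)
        ax.set_xlabel("factor PC1")
        ax.set_ylabel("factor PC2")
        ax.legend(fontsize=7)
        ax.set_title(f"Centroid-based clustering (k = {result.kmeans.k})", fontsize=9)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    _try("joint_heatmap", joint_heatmap)
    _try("selected_heatmap", selected_heatmap)
    _try("dendrogram", dendrogram)
    _try("cluster_scatter", cluster_scatter)
    return written
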