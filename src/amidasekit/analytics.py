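"""Substrate-specificity analytics on the binary activity matrix.

Four views of the screen results:

* a dendrogram of enzymes clustered by Jaccard distance between their
  substrate-acceptance profiles (substrates hit by no enzyme excluded),
* a Pearson correlation matrix of substrates accepted by at least one
  enzyme,
* a centered PCA biplot of the activity matrix (enzyme scores, substrate
  loadings, explained variance),
* promiscuity classes — promiscuous (>= 8 substrates), narrow (<= 2),
  intermediate otherwise — with per-class residue-frequency logos at
  alignment positions of interest (reported in 1-based original
  alignment numbering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .hitcalling import ActivityMatrix

PROMISCUOUS_MIN = 8
NARROW_MAX = 2


class AnalyticsError(ValueError):
    """Raised on contract violations in the analytics stage."""


# ---------------------------------------------------------------------------
# Jaccard dendrogram
# ---------------------------------------------------------------------------

def jaccard_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distances ``1 - |A&B| / |A|B|`` between binary
    rows; two empty profiles are at distance 0 by convention."""
    x = np.asarray(profiles, dtype=bool)
    inter = (x[:, None, :] & x[None, :, :]).sum(axis=2).astype(float)
    union = (x[:, None, :] | x[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore"):
        dist = 1.0 - np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
    return dist


def jaccard_dendrogram(
    matrix: ActivityMatrix, min_substrates: int = 0
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of enzymes on Jaccard profile distance.

    Substrate columns with no hits are dropped first; enzymes with fewer
    than ``min_substrates`` accepted substrates can optionally be
    excluded before clustering.  Returns the scipy linkage matrix and
    the enzyme labels in input order.
    """
    values = matrix.values
    values = values.loc[:, values.sum(axis=0) > 0]
    if min_substrates:
        values = values.loc[values.sum(axis=1) >= min_substrates]
    if len(values) < 2:
        raise AnalyticsError("need at least two enzymes to build a dendrogram")
    dist = jaccard_distance_matrix(values.to_numpy())
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return linkage, list(values.index)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as a rooted newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return render(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Substrate correlation and PCA
# ---------------------------------------------------------------------------

def substrate_correlation(matrix: ActivityMatrix) -> pd.DataFrame:
    """Pearson correlations between substrates accepted by >= 1 enzyme.

    Constant columns (accepted by every enzyme) have undefined
    correlations, reported as missing values rather than zeros.
    """
    values = matrix.values
    eligible = values.loc[:, values.sum(axis=0) > 0]
    if eligible.shape[1] < 2:
        raise AnalyticsError("need at least two substrates with hits for a correlation matrix")
    return eligible.astype(float).corr(method="pearson")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # enzymes x components
    loadings: pd.DataFrame  # substrates x components
    explained_variance_ratio: np.ndarray
    substrate_counts: pd.Series  # per-enzyme accepted-substrate counts


def pca_biplot(matrix: ActivityMatrix, n_components: int | None = None) -> PCAResult:
    """Column-centered PCA of the binary activity matrix.

    No scaling beyond centering: binary columns share a common range.
    Enzyme scores, substrate loadings and explained-variance ratios are
    returned together with per-enzyme substrate counts (used to colour
    biplots).
    """
    values = matrix.values.astype(float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise AnalyticsError("PCA needs at least two enzymes and two substrates")
    centered = values - values.mean(axis=0)
    if not np.any(centered):
        raise AnalyticsError("activity matrix has rank 0 after centering")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(values)
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=values.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        substrate_counts=matrix.values.sum(axis=1),
    )


# ---------------------------------------------------------------------------
# Promiscuity classes and logos
# ---------------------------------------------------------------------------

@dataclass
class PromiscuityClass:
    enzyme_id: str
    n_substrates: int
    promiscuity: str  # promiscuous | narrow | intermediate


@dataclass
class PositionLogo:
    """Residue frequencies of one class at one alignment column
    (1-based original numbering)."""

    position: int
    promiscuity: str
    frequencies: dict[str, float]


def classify_promiscuity(matrix: ActivityMatrix) -> list[PromiscuityClass]:
    """Assign each enzyme exactly one promiscuity class."""
    counts = matrix.values.sum(axis=1)
    out = []
    for enzyme_id, n in counts.items():
        if n >= PROMISCUOUS_MIN:
            label = "promiscuous"
        elif n <= NARROW_MAX:
            label = "narrow"
        else:
            label = "intermediate"
        out.append(PromiscuityClass(enzyme_id=enzyme_id, n_substrates=int(n), promiscuity=label))
    return out


def promiscuity_logos(
    matrix: ActivityMatrix,
    alignment: dict[str, str],
    positions: list[int],
    classes: tuple[str, ...] = ("promiscuous", "narrow"),
) -> tuple[list[PromiscuityClass], list[PositionLogo]]:
    """Per-class residue frequency vectors at the requested columns.

    ``positions`` are 1-based original alignment columns.  Intermediate
    enzymes are excluded from the class contrast by default.
    """
    ncol = len(next(iter(alignment.values())))
    for pos in positions:
        if not 1 <= pos <= ncol:
            raise AnalyticsError(f"position {pos} outside the {ncol}-column alignment")
    assignments = classify_promiscuity(matrix)
    logos = []
    for label in classes:
        members = [a.enzyme_id for a in assignments if a.promiscuity == label]
        if not members:
            continue
        for pos in positions:
            residues = [alignment[e][pos - 1] for e in members if e in alignment]
            if not residues:
                continue
            counts = pd.Series(residues).value_counts()
            freqs = (counts / counts.sum()).to_dict()
            logos.append(PositionLogo(position=pos, promiscuity=label, frequencies=freqs))
    return assignments, logos


def logo_frequency_table(logos: list[PositionLogo]) -> pd.DataFrame:
    """Long-format frequency table (class, position, residue, frequency)."""
    rows = [
        {"promiscuity": lg.promiscuity, "position": lg.position, "residue": r, "frequency": f}
        for lg in logos
        for r, f in sorted(lg.frequencies.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plotting (optional outputs)
# ---------------------------------------------------------------------------

def plot_analytics(matrix: ActivityMatrix, out_dir, positions=None, alignment=None) -> list[str]:
    """Write dendrogram, correlation heatmap, PCA biplot and logo bar
    charts as PNGs under ``out_dir``; returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    linkage, labels = jaccard_dendrogram(matrix)
    fig, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(linkage, labels=labels, ax=ax, color_threshold=0)
    ax.set_ylabel("Jaccard distance")
    fig.tight_layout()
    p = out / "jaccard_dendrogram.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(str(p))

    corr = substrate_correlation(matrix)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    p = out / "substrate_correlation.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(str(p))

    res = pca_biplot(matrix)
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(
        res.scores["PC1"],
        res.scores["PC2"],
        c=res.substrate_counts.loc[res.scores.index],
        cmap="viridis",
    )
    for sid in res.loadings.index:
        ax.annotate(
            sid,
            xy=(0, 0),
            xytext=(res.loadings.at[sid, "PC1"] * 2, res.loadings.at[sid, "PC2"] * 2),
            fontsize=6,
            color="crimson",
        )
    fig.colorbar(sc, ax=ax, label="substrates accepted")
    ax.set_xlabel(f"PC1 ({res.explained_variance_ratio[0]:.0%})")
    ax.set_ylabel(f"PC2 ({res.explained_variance_ratio[1]:.0%})")
    fig.tight_layout()
    p = out / "pca_biplot.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(str(p))

    if positions and alignment:
        _, logos = promiscuity_logos(matrix, alignment, positions)
        table = logo_frequency_table(logos)
        if len(table):
            fig, axes = plt.subplots(
                1, len(positions), figsize=(2.2 * len(positions), 3), squeeze=False
            )
            for ax, pos in zip(axes[0], positions):
                sub = table[table["position"] == pos]
                pivot = sub.pivot_table(
                    index="residue", columns="promiscuity", values="frequency", fill_value=0
                )
                pivot.plot.bar(ax=ax, legend=False, fontsize=6)
                ax.set_title(f"position {pos}", fontsize=8)
            axes[0][-1].legend(fontsize=6)
            fig.tight_layout()
            p = out / "promiscuity_logos.png"
            fig.savefig(p, dpi=150)
            plt.close(fig)
            written.append(str(p))
    return written
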