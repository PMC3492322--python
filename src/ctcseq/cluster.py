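"""Unsupervised clustering of expression profiles.

Samples are clustered on the Euclidean distance between their FPKM vectors
over a pooled gene set: the union, over samples, of each sample's top-k
genes by FPKM (k = 100 by default).  Agglomerative linkage is complete by
default, matching the R ``heatmap``/``hclust`` default that this stage
reproduces.  Distances are computed on raw FPKM — in the R function,
row/column scaling affects colors, not the dissimilarity — with an optional
log transform.

Cluster-vs-patient concordance is summarized by the adjusted Rand index and
a per-cluster majority-patient purity table.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio import TreeNode
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "top_k_union",
    "hierarchical_cluster",
    "patient_concordance",
    "to_newick",
    "from_newick",
]


@dataclass
class ClusterResult:
    """Result of hierarchical clustering of samples.

    Attributes
    ----------
    gene_pool : list of str
        The pooled gene set the distances were computed on.
    linkage : numpy.ndarray
        scipy linkage matrix (merge tree with non-decreasing heights).
    sample_ids : list of str
        Samples in input order (the leaves, each exactly once).
    leaf_order : list of str
        Samples in dendrogram leaf order.
    method : str
        Linkage method used.
    """

    gene_pool: list[str]
    linkage: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]
    method: str

    def flat_labels(self, k: int) -> pd.Series:
        """Cut the tree into ``k`` flat clusters (labels 1..k)."""
        if k > len(self.sample_ids):
            raise ValueError(f"k={k} exceeds {len(self.sample_ids)} samples")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def to_newick(self) -> str:
        return to_newick(self.linkage, self.sample_ids)


def top_k_union(fpkm: pd.DataFrame, k: int = 100) -> list[str]:
    """Union of each sample's top-k genes by FPKM.

    Ties are broken by descending FPKM then lexicographic gene name, so the
    pool is deterministic across platforms.  A sample with fewer than ``k``
    genes contributes all of them (logged).  The pool is returned sorted by
    gene name; its size is logged.
    """
    pool: set[str] = set()
    genes = fpkm.index.to_numpy()
    for sample in fpkm.columns:
        col = fpkm[sample].to_numpy()
        # sort by (-fpkm, gene name): lexsort's last key is primary
        order = np.lexsort((genes, -col))
        take = min(k, len(genes))
        if take < k:
            logger.info("sample %s has only %d genes (< k=%d)", sample, take, k)
        pool.update(genes[order[:take]])
    result = sorted(pool)
    logger.info("top-%d union pool: %d genes over %d samples", k, len(result), fpkm.shape[1])
    return result


def hierarchical_cluster(
    fpkm_pool: pd.DataFrame,
    linkage: str = "complete",
    log_transform: bool = False,
) -> ClusterResult:
    """Agglomerative clustering of samples (columns) on Euclidean distance.

    ``fpkm_pool`` is the pooled-genes x samples FPKM submatrix.  With
    ``log_transform`` the distances are computed on log2(FPKM + 1).
    """
    if fpkm_pool.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if fpkm_pool.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    data = fpkm_pool.to_numpy().T  # samples as observations
    if log_transform:
        data = np.log2(data + 1.0)
    dist = pdist(data, metric="euclidean")
    Z = hierarchy.linkage(dist, method=linkage)
    sample_ids = list(fpkm_pool.columns)
    leaf_order = [sample_ids[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        gene_pool=list(fpkm_pool.index),
        linkage=Z,
        sample_ids=sample_ids,
        leaf_order=leaf_order,
        method=linkage,
    )


def patient_concordance(
    result: ClusterResult, patient_labels: pd.Series, k: int
) -> tuple[float, pd.DataFrame]:
    """Concordance between a flat cut of the tree and patient-of-origin labels.

    Returns the adjusted Rand index (chance-corrected, in [-1, 1]) and a
    per-cluster table with the majority patient and its purity (fraction of
    the cluster's samples from that patient).
    """
    missing = [s for s in result.sample_ids if s not in patient_labels.index]
    if missing:
        raise KeyError(f"patient labels missing for samples: {missing}")
    flat = result.flat_labels(k)
    patients = patient_labels.reindex(flat.index)
    ari = float(adjusted_rand_score(patients.to_numpy(), flat.to_numpy()))
    rows = []
    for cluster_id, members in flat.groupby(flat):
        counts = patients.loc[members.index].value_counts()
        rows.append(
            {
                "cluster": cluster_id,
                "n_samples": len(members),
                "majority_patient": counts.index[0],
                "purity": counts.iloc[0] / len(members),
            }
        )
    return ari, pd.DataFrame(rows).set_index("cluster")


# ----------------------------------------------------------------- newick


def to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix to a Newick string with branch
    lengths (parent height minus child height)."""
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{parent_height:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.10g}"

    root = tree
    left = build(root.left, root.dist)
    right = build(root.right, root.dist)
    return f"({left},{right}):0;"


def from_newick(newick: str) -> TreeNode:
    """Parse a Newick string into a tree object (leaves carry sample ids)."""
    return TreeNode.read(io.StringIO(newick))
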