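"""Two-mode transcriptomic workflow on time-course DE tables.

Starting from per-contrast differential-expression tables (gene id, log2
fold change, adjusted p-value), the workflow identifies genes regulated in
the mutant but not the wild type at each timepoint, partitions them by
timepoint, assembles their mutant-vs-wild-type fold-change trajectories,
clusters the trajectories hierarchically, and classifies each cluster into
one of two regulatory modes:

* **gradual** — fold change rises monotonically to a moderate level
  (~1 log2 unit by the last timepoint): genes whose activation is merely
  accelerated in the mutant;
* **ectopic** — fold change is already large (~4 log2 units) at the first
  post-baseline timepoint: genes normally never expressed in this tissue.

Cluster membership can then be tested for enrichment of externally defined
bound-target gene lists with a one-sided Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene_id", "log2fc", "padj")


@dataclass
class DEGPartition:
    """Exclusive/shared partition of two DEG sets (Venn-diagram counts)."""

    only_a: frozenset
    only_b: frozenset
    both: frozenset

    @property
    def union(self) -> frozenset:
        return self.only_a | self.only_b | self.both

    def sizes(self) -> dict[str, int]:
        return {
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
            "both": len(self.both),
            "union": len(self.union),
        }


@dataclass
class ClusterAssignment:
    """Gene-to-cluster labels from fold-change trajectory clustering."""

    labels: pd.Series            # index: gene_id, values 1..k
    k: int
    linkage_method: str
    metric: str
    linkage_matrix: np.ndarray
    mean_trajectories: pd.DataFrame  # index: cluster, columns: timepoints


@dataclass
class EnrichmentResult:
    """One-sided Fisher's exact test of bound-target enrichment in a DEG set."""

    deg_bound: int
    deg_unbound: int
    nondeg_bound: int
    nondeg_unbound: int
    odds_ratio: float
    p_value: float
    continuity_corrected: bool = False

    def table(self) -> np.ndarray:
        return np.array(
            [[self.deg_bound, self.deg_unbound],
             [self.nondeg_bound, self.nondeg_unbound]]
        )


def log_transform(fpkm):
    """log2(FPKM + 1); accepts scalars, arrays or DataFrames."""
    arr = np.asarray(fpkm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("FPKM values must be non-negative")
    out = np.log2(arr + 1.0)
    if isinstance(fpkm, (pd.DataFrame, pd.Series)):
        return type(fpkm)(out, index=fpkm.index,
                          **({"columns": fpkm.columns} if isinstance(fpkm, pd.DataFrame) else {}))
    return out if arr.ndim else float(out)


def call_degs(table: pd.DataFrame, padj_threshold: float = 0.05) -> frozenset:
    """Genes with adjusted p below the threshold."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"contrast table missing columns: {missing}")
    return frozenset(table.loc[table["padj"] < padj_threshold, "gene_id"])


def genotype_specific_degs(mutant: frozenset, wildtype: frozenset) -> frozenset:
    """Genes differentially expressed in the mutant but not the wild type."""
    return frozenset(mutant) - frozenset(wildtype)


def partition_timepoints(set_a, set_b) -> DEGPartition:
    """Partition two DEG sets into exclusive and shared parts."""
    a, b = frozenset(set_a), frozenset(set_b)
    return DEGPartition(only_a=a - b, only_b=b - a, both=a & b)


def build_fc_matrix(
    tables: dict[str, pd.DataFrame], genes, timepoint_order: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Genes x timepoints matrix of cross-genotype log2 fold changes.

    ``tables`` maps contrast names (ordered by time unless
    ``timepoint_order`` is given) to per-contrast DataFrames.  Genes absent
    from any table are dropped and returned in the exclusion report.
    """
    names = timepoint_order if timepoint_order is not None else list(tables)
    genes = sorted(set(genes))
    columns = {}
    present = pd.Series(True, index=pd.Index(genes, name="gene_id"))
    for name in names:
        tbl = tables[name].set_index("gene_id")["log2fc"]
        columns[name] = tbl.reindex(genes)
        present &= columns[name].notna()
    dropped = sorted(present.index[~present])
    if dropped:
        logger.warning("dropping %d genes absent from at least one contrast",
                       len(dropped))
    matrix = pd.DataFrame(columns).loc[present]
    matrix.index.name = "gene_id"
    return matrix, dropped


def cluster_trajectories(
    matrix: pd.DataFrame,
    k: int = 5,
    linkage_method: str = "complete",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Agglomerative clustering of fold-change trajectories cut to k clusters.

    Rows are sorted lexicographically by gene id before linkage so that
    equal-distance merge ties resolve identically regardless of input
    order.  Cluster labels are renumbered 1..k in order of first appearance
    along the sorted gene list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of genes ({len(matrix)})")
    matrix = matrix.sort_index()
    values = matrix.to_numpy(dtype=float)
    if len(matrix) == 1:
        labels = pd.Series([1], index=matrix.index)
        Z = np.empty((0, 4))
    else:
        Z = linkage(values, method=linkage_method, metric=metric)
        raw = fcluster(Z, t=k, criterion="maxclust")
        # renumber deterministically by first appearance
        mapping: dict[int, int] = {}
        labels_list = []
        for lab in raw:
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            labels_list.append(mapping[lab])
        labels = pd.Series(labels_list, index=matrix.index)
    means = matrix.groupby(labels).mean()
    means.index.name = "cluster"
    return ClusterAssignment(
        labels=labels,
        k=int(labels.max()),
        linkage_method=linkage_method,
        metric=metric,
        linkage_matrix=Z,
        mean_trajectories=means,
    )


def summarize_clusters(
    assignment: ClusterAssignment, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Mean +/- sd trajectory and size per cluster."""
    matrix = matrix.loc[assignment.labels.index]
    grouped = matrix.groupby(assignment.labels)
    if any(size == 0 for size in grouped.size()):
        raise ValueError("empty cluster encountered")
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).fillna(0.0).add_suffix("_sd")
    out = pd.concat([grouped.size().rename("n"), mean, sd], axis=1)
    out.index.name = "cluster"
    return out


def fisher_greater_p(deg_bound: int, deg_unbound: int,
                     nondeg_bound: int, nondeg_unbound: int) -> float:
    """One-sided (greater) Fisher p: upper hypergeometric tail of the table."""
    N = deg_bound + deg_unbound + nondeg_bound + nondeg_unbound
    K = deg_bound + nondeg_bound          # bound genes overall
    n = deg_bound + deg_unbound           # DEG set size
    return float(sps.hypergeom.sf(deg_bound - 1, N, K, n))


def enrichment_test(deg_set, background_set, bound_set) -> EnrichmentResult:
    """Bound-target enrichment of a DEG set against its background.

    Compares the ratio of bound to non-bound genes in the DEG set with the
    same ratio in the non-DEG remainder of the background using Fisher's
    exact test with the alternative hypothesis 'greater'.  The odds ratio
    uses a 0.5 continuity correction (flagged) when any cell is zero.
    """
    deg = frozenset(deg_set)
    background = frozenset(background_set)
    bound = frozenset(bound_set)
    if not deg <= background:
        raise ValueError("DEG set must be a subset of the background")
    nondeg = background - deg
    a = len(deg & bound)
    b = len(deg - bound)
    c = len(nondeg & bound)
    d = len(nondeg - bound)
    p = fisher_greater_p(a, b, c, d)
    corrected = 0 in (a, b, c, d)
    if corrected:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        deg_bound=a, deg_unbound=b, nondeg_bound=c, nondeg_unbound=d,
        odds_ratio=float(odds), p_value=p, continuity_corrected=corrected,
    )


def classify_modes(
    assignment: ClusterAssignment,
    ectopic_threshold: float = 2.0,
    gradual_final_range: tuple[float, float] = (0.5, 2.0),
    min_size: int = 5,
) -> pd.DataFrame:
    """Label each cluster's mean trajectory as gradual, ectopic or other.

    A cluster is **ectopic** when its mean log2FC at the first
    post-baseline timepoint reaches ``ectopic_threshold``; **gradual** when
    the mean trajectory is monotonically non-decreasing with a final value
    inside ``gradual_final_range``; otherwise **other**.  Clusters smaller
    than ``min_size`` are flagged and left unclassified (the tree cut can
    produce singleton clusters that carry no trend information).
    """
    sizes = assignment.labels.value_counts()
    rows = []
    for cluster, traj in assignment.mean_trajectories.iterrows():
        vals = traj.to_numpy(dtype=float)
        n = int(sizes.get(cluster, 0))
        if n < min_size:
            rows.append({"cluster": cluster, "n": n, "mode": "not_classified",
                         "small": True})
            continue
        first_post = vals[1] if len(vals) > 1 else vals[0]
        if first_post >= ectopic_threshold:
            mode = "ectopic"
        elif (np.all(np.diff(vals) >= 0)
              and gradual_final_range[0] <= vals[-1] < gradual_final_range[1]):
            mode = "gradual"
        else:
            mode = "other"
        rows.append({"cluster": cluster, "n": n, "mode": mode, "small": False})
    return pd.DataFrame(rows).set_index("cluster")
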