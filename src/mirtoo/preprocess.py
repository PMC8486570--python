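"""Raw copies-per-microlitre matrices to classifier-ready features.

Pipeline order (each step enforces its ordering contract via the matrix
state flags):

1. :func:`average_replicates` — same-patient reference primaries collapse to
   their per-miRNA arithmetic mean, *before* normalization.
2. :func:`normalize_median` — each sample is divided by its own 50th
   percentile over the full miRNA panel (control assays never participate;
   candidate reference RNAs are more variable than the median and are not
   used as normalizers).
3. :func:`exclude_mirnas` — drop miR-122-5p (liver-microenvironment signal in
   liver-site biopsies) and miR-21-5p (ubiquitous, non-specific), leaving the
   87 prediction features.
4. :func:`log_transform` — log2(x + 0.01) feature stabilization.

Also here: class-label merging (19 histological labels -> 17 prediction
classes), the two-step detectability filter for externally sourced matrices,
per-class mean/SD profiles and descriptive complete-linkage clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError, aligned_meta
from .panel import DEFAULT_CLASS_MAP, DEFAULT_EXCLUSIONS


def average_replicates(
    matrix: ExpressionMatrix, meta: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse same-patient reference-primary replicates to their mean row.

    Only reference primaries are averaged (a patient's multiple *metastases*
    are distinct biological samples and stay separate). The averaged row
    keeps the first replicate's sample_id and metadata. Raises if a patient's
    replicates carry different class labels.
    """
    if matrix.normalized:
        raise MatrixError("replicates must be averaged before normalization")
    meta = aligned_meta(meta, matrix)
    ref = meta[meta["role"] == "reference_primary"]
    keep_rows: list[str] = []
    drop_rows: set[str] = set()
    new_data = matrix.data.copy()
    for patient, grp in ref.groupby("patient_id"):
        if len(grp) < 2:
            continue
        labels = set(grp["class_label"])
        if len(labels) > 1:
            raise MatrixError(
                f"patient {patient}: replicates with different class labels "
                f"{sorted(labels)} cannot be averaged"
            )
        ids = grp["sample_id"].tolist()
        new_data.loc[ids[0]] = matrix.data.loc[ids].mean(axis=0)
        drop_rows.update(ids[1:])
        keep_rows.append(ids[0])
    if not drop_rows:
        return matrix, meta
    new_data = new_data.drop(index=list(drop_rows))
    new_meta = meta[~meta["sample_id"].isin(drop_rows)].reset_index(drop=True)
    return matrix.with_data(new_data), new_meta


def normalize_median(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its 50th percentile over the panel miRNAs.

    Uses the inclusive linear-interpolation percentile convention (numpy
    default). After this step every sample's median over the panel is 1.
    """
    if matrix.normalized:
        raise MatrixError("matrix is already normalized")
    vals = matrix.data.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise MatrixError("normalize_median requires a complete matrix "
                          "(run detectability_filter first)")
    medians = np.median(vals, axis=1)
    bad = np.nonzero(medians <= 0)[0]
    if bad.size:
        names = [matrix.sample_ids[i] for i in bad]
        raise MatrixError(f"zero or undefined median for samples: {names}")
    out = matrix.data.div(pd.Series(medians, index=matrix.data.index), axis=0)
    return matrix.with_data(out, normalized=True)


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 0.01) -> ExpressionMatrix:
    """log2(x + pseudocount) transform of a normalized matrix.

    The pseudocount (default 0.01, well below one copy per microlitre on the
    normalized scale) keeps zeros finite while preserving the ordering of
    low values.
    """
    if matrix.log_transformed:
        raise MatrixError("matrix is already log-transformed")
    if not matrix.normalized:
        raise MatrixError("log transform applies to the normalized matrix")
    out = np.log2(matrix.data + pseudocount)
    return matrix.with_data(out, log_transformed=True)


def exclude_mirnas(
    matrix: ExpressionMatrix,
    exclusion_list: tuple[str, ...] | list[str] = DEFAULT_EXCLUSIONS,
) -> ExpressionMatrix:
    """Drop the listed assays (default: miR-122-5p and miR-21-5p).

    A name absent from the matrix raises (guards typos and double exclusion).
    """
    missing = [m for m in exclusion_list if m not in matrix.data.columns]
    if missing:
        raise MatrixError(f"assays not in panel: {missing}")
    if not exclusion_list:
        return matrix
    return matrix.with_data(matrix.data.drop(columns=list(exclusion_list)))


def merge_classes(
    labels, class_map: dict[str, str] | None = None
):
    """Map histological labels onto prediction classes (19 -> 17 by default)."""
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    labels = pd.Series(labels)
    unknown = sorted(set(labels.dropna()) - set(class_map))
    if unknown:
        raise MatrixError(f"labels outside the class map: {unknown}")
    return labels.map(lambda x: class_map[x] if pd.notna(x) else x)


def detectability_filter(
    matrix: ExpressionMatrix, sample_frac: float = 0.8
) -> ExpressionMatrix:
    """Two-step missingness filter for externally sourced matrices.

    Step 1 keeps samples with non-missing values for at least ``sample_frac``
    of the miRNAs; step 2 keeps miRNAs with no missing values among the
    retained samples. The step order is part of the contract. The output
    contains no missing values.
    """
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must be in (0, 1]")
    df = matrix.data
    ok_frac = df.notna().mean(axis=1)
    kept_samples = df.loc[ok_frac >= sample_frac]
    if kept_samples.empty:
        raise MatrixError("detectability filter removed every sample")
    kept = kept_samples.dropna(axis=1)
    return matrix.with_data(kept)


def class_mean_profiles(
    matrix: ExpressionMatrix, labels
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class arithmetic mean and sample SD (n-1) of each miRNA.

    Returns ``(means, sds)`` indexed by class. SD is NaN for singleton
    classes (undefined with the n-1 denominator).
    """
    labels = pd.Series(list(labels), index=matrix.data.index)
    if labels.isna().any():
        raise MatrixError("every sample needs a class label")
    grouped = matrix.data.groupby(labels)
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    return means, sds


# ------------------------------------------------------------- clustering
@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history.

    ``merges[i] = (a, b, height, size)`` in scipy linkage convention: leaves
    are 0..n-1, the cluster formed at step i gets id n+i; ``a < b``;
    ``height`` is the complete-linkage distance at the merge.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    def to_linkage(self) -> np.ndarray:
        """scipy-style (n-1, 4) linkage array for plotting/cutting."""
        return np.array([list(m) for m in self.merges], dtype=float)


def _pairwise(profiles: np.ndarray, metric: str) -> np.ndarray:
    if metric == "manhattan":
        return np.abs(profiles[:, None, :] - profiles[None, :, :]).sum(axis=2)
    if metric == "correlation":
        c = np.corrcoef(profiles)
        return 1.0 - c
    raise ValueError(f"unknown metric {metric!r}")


def hierarchical_cluster(
    profiles: pd.DataFrame, metric: str = "manhattan"
) -> Dendrogram:
    """Complete-linkage agglomerative clustering of class profiles.

    Default distance is Manhattan (L1); ``metric="correlation"`` gives
    1 - Pearson correlation. Deterministic: when two merges tie on height,
    the lexicographically lowest cluster-id pair merges first.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise MatrixError("need at least two profiles of equal length")
    n = X.shape[0]
    D = _pairwise(X, metric)
    # active cluster id -> member leaf indices
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(members) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new_members = members.pop(a) + members.pop(b)
        merges.append((a, b, h, len(new_members)))
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c, mem in members.items():
            # complete linkage: max pairwise leaf distance
            dcn = float(max(D[i, j] for i in mem for j in new_members))
            dist[(min(c, next_id), max(c, next_id))] = dcn
        members[next_id] = new_members
        next_id += 1
    return Dendrogram(labels=tuple(map(str, profiles.index)), merges=tuple(merges))
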