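"""Profile similarity, RMSD-based P-values, and clustering of profiles.

Normalized peak-volume vectors make the root-mean-square deviation (RMSD) a
natural distance between profiles.  To make an RMSD interpretable it is
referred to a null distribution fitted (as a normal) to all pairwise RMSDs
within a collection of known-good datasets; the P-value of an observed RMSD
is its upper-tail probability under that null — small P means the pair is
more dissimilar than known-good replicates ever are.  Collections of
profiles are grouped by complete-linkage hierarchical clustering with the
number of clusters chosen by the Davies-Bouldin validity score.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm
from sklearn.metrics import davies_bouldin_score

from .errors import DegenerateNullError, InsufficientDataError, InvalidInputError
from .volumes import PeakVolumes, align

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class RmsdNull:
    """Normal null for pairwise RMSDs within a known-good collection."""

    mu: float
    sd: float
    n_pairs: int

    def __post_init__(self):
        if not self.sd > 0:
            raise DegenerateNullError(f"null sd must be > 0, got {self.sd}")
        if self.n_pairs < 3:
            raise InsufficientDataError("null needs >= 3 pairwise RMSDs")


@dataclass(frozen=True)
class ClusterResult:
    """Chosen flat clustering plus the evidence behind the choice."""

    labels: np.ndarray           # 1..k per profile
    k: int
    linkage_record: np.ndarray   # scipy condensed merge history
    db_scores: dict[int, float]  # Davies-Bouldin score per candidate k


def _check_normalized(vec: PeakVolumes, name: str) -> None:
    if not vec.is_normalized(_NORM_TOL):
        raise InvalidInputError(
            f"{name} is not normalized (sums to {vec.total():.6g}); "
            "normalize volume vectors before comparison")


def rmsd(a: PeakVolumes, b: PeakVolumes) -> float:
    """RMSD between two normalized volume vectors over the union of peaks.

    Peaks absent from one vector read as zero.  Symmetric, non-negative,
    zero iff the vectors are identical.
    """
    _check_normalized(a, "first vector")
    _check_normalized(b, "second vector")
    _, matrix = align([a, b])
    return float(np.sqrt(np.mean((matrix[0] - matrix[1]) ** 2)))


def pairwise_rmsd(vectors: list[PeakVolumes]) -> np.ndarray:
    """All C(n, 2) pairwise RMSDs, in ``itertools.combinations`` order."""
    for i, v in enumerate(vectors):
        _check_normalized(v, f"vector {i}")
    _, matrix = align(vectors)
    return np.array([
        np.sqrt(np.mean((matrix[i] - matrix[j]) ** 2))
        for i, j in combinations(range(len(vectors)), 2)
    ])


def fit_null(vectors: list[PeakVolumes]) -> RmsdNull:
    """Fit the RMSD null from a known-good collection.

    Computes all pairwise RMSDs and fits a normal by maximum likelihood
    (sample mean and standard deviation).
    """
    if len(vectors) < 3:
        raise InsufficientDataError(f"need >= 3 vectors to fit a null, got {len(vectors)}")
    values = pairwise_rmsd(vectors)
    mu, sd = norm.fit(values)
    if sd <= 0:
        raise DegenerateNullError("pairwise RMSDs have zero variance")
    return RmsdNull(mu=float(mu), sd=float(sd), n_pairs=values.size)


def rmsd_pvalue(value: float, null: RmsdNull) -> float:
    """Upper-tail probability P(X >= value) under the fitted normal null.

    Large RMSD (dissimilar profiles) gives small P.  Values below the null
    mean give P > 0.5; they are reported as-is, being plain tail
    probabilities.
    """
    return float(norm.sf(value, loc=null.mu, scale=null.sd))


def cluster_profiles(
    vectors: list[PeakVolumes],
    k_range=None,
    select: str = "min-db",
) -> ClusterResult:
    """Complete-linkage hierarchical clustering of aligned volume vectors.

    Euclidean distances on the union-aligned vectors, complete linkage
    (cluster distance = farthest pair).  For each candidate k the flat
    cutting is scored with the Davies-Bouldin index; ``select="min-db"``
    (default) picks the k minimizing the standard index (lower = better
    separated), ``select="max-inverse-db"`` maximizes the inverted
    between/within ratio instead.
    """
    n = len(vectors)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 profiles to cluster, got {n}")
    if k_range is None:
        k_range = range(2, min(n, 7))
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
        raise InvalidInputError(f"k_range must lie within [2, {n - 1}]")
    if select not in ("min-db", "max-inverse-db"):
        raise InvalidInputError(f"unknown selection rule {select!r}")

    _, matrix = align(vectors)
    record = linkage(matrix, method="complete", metric="euclidean")

    db_scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        labels = fcluster(record, t=k, criterion="maxclust")
        labelings[k] = labels
        if np.unique(labels).size < 2:
            db_scores[k] = np.inf
        else:
            db_scores[k] = float(davies_bouldin_score(matrix, labels))

    finite = {k: s for k, s in db_scores.items() if np.isfinite(s)}
    if not finite:
        raise InvalidInputError("no candidate k produced a scorable clustering")
    if select == "min-db":
        best_k = min(finite, key=lambda k: (finite[k], k))
    else:
        best_k = max(finite, key=lambda k: (1.0 / finite[k] if finite[k] > 0 else np.inf, -k))
    return ClusterResult(labels=labelings[best_k], k=int(best_k),
                         linkage_record=record, db_scores=db_scores)


def meta_profile(vectors: list[PeakVolumes], labels) -> dict[int, PeakVolumes]:
    """Per-cluster meta-profile: mean of aligned vectors, renormalized."""
    labels = np.asarray(labels)
    if labels.size != len(vectors):
        raise InvalidInputError("one label per vector required")
    indices, matrix = align(vectors)
    out: dict[int, PeakVolumes] = {}
    for lab in np.unique(labels):
        members = matrix[labels == lab]
        if members.size == 0:
            raise InvalidInputError(f"cluster {lab} is empty")
        mean = members.mean(axis=0)
        out[int(lab)] = PeakVolumes(dict(zip(indices, mean))).normalized()
    return out
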