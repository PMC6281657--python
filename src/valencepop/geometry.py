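"""Population-level geometry: noise correlations, population vectors, PCA
reduction and Mahalanobis-distance analyses.

The population vector (PV) at a time point (or trial) stacks the z-scored
responses of all neurons; ensemble separation is measured with the
Mahalanobis distance MD(a, b) = sqrt((a - b)^T S^-1 (a - b)) where S is a
sample covariance of the reference (or pooled) vectors — the covariance-
aware generalisation of Euclidean distance, so MD = Euclid under identity
covariance and MD is invariant to joint invertible affine maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .preprocessing import ZScoreTensor, extract_response_window

__all__ = [
    "NoiseCorrelationResult",
    "PopulationVectorSet",
    "ReducedSpace",
    "MDTrajectory",
    "noise_correlations",
    "build_population_vectors",
    "pca_reduce",
    "mahalanobis_distance",
    "ensemble_md",
    "trial_md_trajectory",
]


@dataclass
class NoiseCorrelationResult:
    pairs: np.ndarray  # (n_pairs, 2) neuron indices, within-mouse
    coefficients: np.ndarray  # Pearson r per pair
    per_mouse_mean: dict[int, float]
    stage: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.coefficients))


@dataclass
class PopulationVectorSet:
    """Vectors indexed by time point or trial; dimension = n neurons (or k
    components after reduction)."""

    vectors: np.ndarray  # (n_vectors, dim)
    labels: np.ndarray  # condition / trial label per vector
    per: str  # "timepoint" | "trial"
    reduced: "ReducedSpace | None" = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.vectors.ndim != 2 or len(self.labels) != len(self.vectors):
            raise ValueError("vectors must be 2-d with one label per vector")


@dataclass
class ReducedSpace:
    components: np.ndarray  # (k, dim) orthonormal loadings
    explained_variance_ratio: np.ndarray
    mean: np.ndarray  # centering used at fit time

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        """Project out-of-sample vectors using the stored fit mean."""
        return (np.asarray(vectors) - self.mean) @ self.components.T


@dataclass
class MDTrajectory:
    distances: np.ndarray  # per-trial MD >= 0
    reference: str


def noise_correlations(
    trial_responses: np.ndarray,
    mouse_ids: np.ndarray,
    stage: str = "",
) -> NoiseCorrelationResult:
    """Pairwise noise correlations of single-stimulus trial responses.

    `trial_responses` is neurons x trials of per-trial response values
    (mean z in the 1-s post-CS window). The across-trial mean is removed
    per neuron and the Pearson correlation of the residual fluctuations is
    computed for every pair of simultaneously recorded (same-mouse)
    neurons; zero-variance neurons are skipped with a warning.
    """
    resp = np.asarray(trial_responses, dtype=float)
    mouse_ids = np.asarray(mouse_ids)
    if resp.ndim != 2 or resp.shape[1] < 3:
        raise ValueError("need neurons x trials with >= 3 trials")
    if mouse_ids.shape[0] != resp.shape[0]:
        raise ValueError("one mouse id per neuron required")
    fluct = resp - resp.mean(axis=1, keepdims=True)
    sd = fluct.std(axis=1)
    if np.any(sd == 0):
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance neuron(s) skipped in "
            "noise correlations", stacklevel=2)
    pairs, coeffs = [], []
    per_mouse: dict[int, float] = {}
    for m in np.unique(mouse_ids):
        idx = np.flatnonzero((mouse_ids == m) & (sd > 0))
        if idx.size < 2:
            continue
        c = np.corrcoef(fluct[idx])
        iu, ju = np.triu_indices(idx.size, k=1)
        pairs.append(np.column_stack([idx[iu], idx[ju]]))
        coeffs.append(c[iu, ju])
        per_mouse[int(m)] = float(c[iu, ju].mean())
    if not pairs:
        raise ValueError("no mouse contributes >= 2 usable neurons")
    return NoiseCorrelationResult(
        np.concatenate(pairs), np.concatenate(coeffs), per_mouse, stage)


def build_population_vectors(
    z: ZScoreTensor,
    per: str = "timepoint",
    window_s: float = 1.0,
) -> PopulationVectorSet:
    """Across-neuron activity vectors in the 1-s post-onset window.

    per="timepoint": one n-neuron vector per frame of the window (expects
    trial-averaged z traces, neurons x frames). per="trial": one vector
    per trial of mean window z (expects per-trial z, neurons x trials x
    frames). Excluded (degenerate) neurons contribute zeros so dimensions
    stay comparable across conditions.
    """
    w = int(round(window_s * z.frame_rate))
    if w < 1:
        raise ValueError("empty window")
    values = np.where(np.isnan(z.values), 0.0, z.values)
    if per == "timepoint":
        if values.ndim != 2:
            raise ValueError("timepoint vectors need trial-averaged z traces")
        seg = values[:, z.onset_frame:z.onset_frame + w]
        vectors = seg.T  # one vector per frame
        labels = np.arange(w)
    elif per == "trial":
        if values.ndim != 3:
            raise ValueError("trial vectors need per-trial z traces")
        means = extract_response_window(values, z.onset_frame, z.frame_rate,
                                        "post", window_s)
        vectors = means.T  # one vector per trial
        labels = (z.stimuli if z.stimuli is not None
                  else np.arange(vectors.shape[0]))
    else:
        raise ValueError("per must be 'timepoint' or 'trial'")
    return PopulationVectorSet(vectors, labels, per)


def pca_reduce(
    pvs: PopulationVectorSet, k: int
) -> tuple[PopulationVectorSet, ReducedSpace]:
    """Mean-centred PCA fit on the vector set; scores + reusable basis."""
    n, dim = pvs.vectors.shape
    if not 1 <= k <= min(dim, n):
        raise ValueError(f"k={k} invalid for {n} vectors of dim {dim}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(pvs.vectors)
    space = ReducedSpace(pca.components_, pca.explained_variance_ratio_,
                         pca.mean_)
    return PopulationVectorSet(scores, pvs.labels, pvs.per, reduced=space), space


def _regularised_cov(ref: np.ndarray, ridge: float) -> np.ndarray:
    """Unbiased sample covariance with trace-scaled ridge when needed."""
    dim = ref.shape[1]
    cov = np.cov(ref, rowvar=False, ddof=1).reshape(dim, dim)
    cond = np.linalg.cond(cov)
    needs_ridge = ref.shape[0] < dim + 1 or not np.isfinite(cond) or cond > 1e8
    if needs_ridge:
        if ridge <= 0:
            raise np.linalg.LinAlgError(
                "singular covariance and ridge disabled")
        tr = np.trace(cov)
        scale = tr / dim if tr > 0 else 1.0
        cov = cov + ridge * scale * np.eye(dim)
    return cov


def mahalanobis_distance(
    query: np.ndarray,
    reference: np.ndarray,
    ridge: float = 1e-6,
) -> float:
    """MD of `query` from the mean of a reference vector distribution.

    S is the unbiased (n-1) sample covariance of the reference set,
    ridge-regularised by ridge * trace(S)/dim * I when ill-conditioned or
    when the reference has fewer than dim + 1 vectors.
    """
    query = np.asarray(query, dtype=float).ravel()
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if ref.shape[1] != query.size:
        raise ValueError("query and reference dimensions differ")
    cov = _regularised_cov(ref, ridge)
    d = query - ref.mean(axis=0)
    md2 = float(d @ np.linalg.solve(cov, d))
    return float(np.sqrt(max(md2, 0.0)))


def ensemble_md(
    set_a: PopulationVectorSet,
    set_b: PopulationVectorSet,
    ridge: float = 1e-6,
) -> float:
    """Separation of two condition ensembles over the response window.

    Computes the MD between the paired vectors PV(a, t) and PV(b, t) at
    each time point under the pooled sample covariance of both sets'
    vectors (the symmetric choice of S) and averages over the window.
    """
    a, b = set_a.vectors, set_b.vectors
    if a.shape != b.shape:
        raise ValueError("vector sets must have matching shape")
    pooled = np.concatenate(
        [a - a.mean(axis=0), b - b.mean(axis=0)], axis=0)
    cov = _regularised_cov(pooled, ridge)
    inv = np.linalg.inv(cov)
    diffs = a - b
    md = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", diffs, inv, diffs), 0.0))
    return float(md.mean())


def trial_md_trajectory(
    trial_pvs: PopulationVectorSet,
    reference_trials: np.ndarray,
    n_components: int = 3,
    ridge: float = 1e-6,
) -> MDTrajectory:
    """Per-trial MD of population CS responses from a reference block.

    PCA is fit on all trials' vectors, the first `n_components` scores
    represent each trial, and every trial's MD (including the reference
    trials') is taken from the distribution of the reference-trial scores.
    """
    reference_trials = np.asarray(reference_trials, dtype=int)
    if reference_trials.size < 2:
        raise ValueError("need at least 2 reference trials")
    reduced, _ = pca_reduce(trial_pvs, n_components)
    scores = reduced.vectors
    ref = scores[reference_trials]
    cov = _regularised_cov(ref, ridge)
    inv = np.linalg.inv(cov)
    d = scores - ref.mean(axis=0)
    md = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", d, inv, d), 0.0))
    return MDTrajectory(md, f"trials {reference_trials.min()}-"
                            f"{reference_trials.max()} (n={reference_trials.size})")
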