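"""Trial-wise valence decoding and functional-type clustering.

The decoder asks whether single-trial population CS responses identify
the predicted valence: PCA to 2 components on the stage's trials, then a
linear max-margin classifier (SVM, C = 1) evaluated with stratified
10-fold cross-validation (each fold holds out one trial per class, as in
a 10-reward / 10-punishment stage window). Clustering groups neurons into
k functional types from their stimulus x stage mean-response features:
PCA to 3 components, agglomerative clustering with correlation distance
and complete linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "DecoderReport",
    "ClusterAssignment",
    "train_eval_cs_decoder",
    "cluster_response_types",
]


@dataclass
class DecoderReport:
    stage: str
    fold_accuracies: np.ndarray
    mean_accuracy: float


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # cluster id (1..k) per retained neuron
    kept: np.ndarray  # indices of neurons that entered the clustering
    linkage_description: str
    feature_description: str

    @property
    def k(self) -> int:
        return int(np.unique(self.labels).size)


def train_eval_cs_decoder(
    trial_pvs: np.ndarray,
    labels: np.ndarray,
    stage: str = "",
    n_components: int = 2,
    n_folds: int = 10,
    c: float = 1.0,
    seed: int = 0,
) -> DecoderReport:
    """Cross-validated linear-SVM decoding of CS valence from trial PVs.

    `trial_pvs` is trials x neurons; `labels` the two CS classes with
    equal counts. PCA (fit on this stage's trials) reduces to
    `n_components`, then stratified `n_folds`-fold CV with a linear SVM;
    the report carries per-fold and mean accuracy.
    """
    pvs = np.asarray(trial_pvs, dtype=float)
    labels = np.asarray(labels)
    if pvs.ndim != 2 or labels.shape[0] != pvs.shape[0]:
        raise ValueError("need trials x neurons with one label per trial")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2 or counts[0] != counts[1]:
        raise ValueError("exactly two balanced classes required")
    k = min(n_components, pvs.shape[0], pvs.shape[1])
    scores = PCA(n_components=k, svd_solver="full").fit_transform(pvs)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(scores, labels):
        clf = SVC(kernel="linear", C=c)
        clf.fit(scores[train], labels[train])
        accs.append(float(np.mean(clf.predict(scores[test]) == labels[test])))
    accs = np.asarray(accs)
    return DecoderReport(stage, accs, float(accs.mean()))


def cluster_response_types(
    features: np.ndarray,
    k: int = 4,
    n_components: int = 3,
) -> ClusterAssignment:
    """Group neurons into k functional response types.

    `features` is neurons x (stimulus x stage mean-response windows).
    PCA reduces the features to `n_components` scores; agglomerative
    clustering with correlation distance and complete linkage is cut at k
    clusters. Zero-variance rows (correlation distance undefined) are
    dropped with a warning and do not receive a label.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim != 2:
        raise ValueError("features must be neurons x features")
    if not np.all(np.isfinite(feats)):
        raise ValueError("features must be finite")
    if feats.shape[0] < k:
        raise ValueError(f"need at least k={k} neurons")
    ncomp = min(n_components, feats.shape[0], feats.shape[1])
    scores = PCA(n_components=ncomp, svd_solver="full").fit_transform(feats)
    sd = scores.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < feats.shape[0]:
        warnings.warn(
            f"{feats.shape[0] - kept.size} zero-variance neuron(s) dropped "
            "from clustering", stacklevel=2)
    if kept.size < k:
        raise ValueError("too few usable neurons after dropping "
                         "zero-variance rows")
    if k == 1:
        labels = np.ones(kept.size, dtype=int)
    else:
        z = linkage(scores[kept], method="complete", metric="correlation")
        labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=np.asarray(labels, dtype=int), kept=kept,
        linkage_description="complete linkage, correlation distance, "
                            f"cut at k={k}",
        feature_description=f"PCA({ncomp}) scores of "
                            f"{feats.shape[1]} response features")
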