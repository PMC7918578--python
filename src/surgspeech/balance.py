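"""SVM-based SMOTE oversampling of training features.

Class imbalance in the study corpus is severe (the extra pseudo-phase
holds a third of all segments while suturing/port removal holds under
4%).  Balancing generates synthetic minority samples near the decision
boundary: seed points are the class's support vectors of a multi-class
soft-margin SVM fitted on the full training set, and each synthetic
point is an interpolation x_i + u * (x_nn - x_i), u ~ Uniform(0, 1),
toward one of the seed's k nearest same-class neighbours (Euclidean).

Only interpolation is used (no extrapolation branch), so synthetic
points always lie on a segment between two original same-class points.
Oversampling is applied to training features only, never to test data,
because the test videos must keep their real temporal composition.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.svm import SVC

__all__ = ["svm_smote"]


def svm_smote(
    X: np.ndarray,
    y: np.ndarray,
    target_per_class: int,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every class up to exactly ``target_per_class`` samples.

    Original rows are preserved unmodified (and come first, in input
    order); synthetic rows are appended per class.  Deterministic under
    ``seed``.

    Raises ``ValueError`` if the target is below the current largest
    class.  A class with a single sample cannot be interpolated and is
    duplicated, with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if target_per_class < counts.max():
        raise ValueError(
            f"target_per_class={target_per_class} is below the current "
            f"majority class size {counts.max()}"
        )
    rng = np.random.default_rng(seed)

    needed = {c: target_per_class - n for c, n in zip(classes, counts)}
    if all(n == 0 for n in needed.values()):
        return X.copy(), y.copy()

    # Support vectors of a multi-class soft-margin SVM define the
    # boundary-adjacent seed points for each class.
    svm = SVC(kernel="rbf", C=1.0, gamma="scale")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        svm.fit(X, y)
    support_by_class: dict = {}
    start = 0
    for c, n_sv in zip(svm.classes_, svm.n_support_):
        support_by_class[c] = svm.support_[start : start + n_sv]
        start += n_sv

    new_rows: list[np.ndarray] = []
    new_labels: list = []
    for c in classes:
        n_new = needed[c]
        if n_new == 0:
            continue
        members = np.flatnonzero(y == c)
        if len(members) == 1:
            warnings.warn(
                f"class {c!r} has a single sample; duplicating instead of "
                "interpolating",
                stacklevel=2,
            )
            new_rows.extend([X[members[0]].copy() for _ in range(n_new)])
            new_labels.extend([c] * n_new)
            continue

        seeds = support_by_class.get(c, np.array([], dtype=int))
        if len(seeds) == 0:
            seeds = members  # degenerate fit: fall back to all class points
        k_eff = min(k, len(members) - 1)

        # k nearest same-class neighbours of each seed (excluding itself)
        Xc = X[members]
        for t in range(n_new):
            i = seeds[t % len(seeds)]
            dists = np.linalg.norm(Xc - X[i], axis=1)
            self_pos = np.flatnonzero(members == i)
            if len(self_pos):
                dists[self_pos[0]] = np.inf
            nn_local = np.argsort(dists, kind="stable")[:k_eff]
            pick = members[nn_local[rng.integers(0, k_eff)]]
            u = rng.random()
            new_rows.append(X[i] + u * (X[pick] - X[i]))
            new_labels.append(c)

    X_out = np.vstack([X] + [np.asarray(new_rows)]) if new_rows else X.copy()
    y_out = np.concatenate([y, np.asarray(new_labels, dtype=y.dtype)])
    return X_out, y_out
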