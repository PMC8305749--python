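"""Resampling methods for imbalanced binary classification.

Thirteen options behind one interface: no sampling; random under/over
sampling; the neighbour-based cleaners (Tomek links, ENN, RENN, AllKNN); the
SMOTE family of interpolating oversamplers (SMOTE, Borderline-SMOTE,
SVM-SMOTE, ADASYN); and the hybrids SMOTEENN / SMOTETomek that oversample
first and clean afterwards.

Where a method supports a target class balance it is parameterised by the
*sampling fraction*: the minority/majority count ratio after resampling, in
(f0, 1] with f0 the dataset's original fraction.  Fraction 1 means exact
balance; fraction f0 leaves the data untouched.  The cleaners (Tomek, ENN,
RENN, AllKNN) have fixed removal rules and take no fraction.

All samplers preserve the original minority rows: oversamplers only add
points, and the cleaners delete majority-class rows only.  SMOTE-family
synthetic points lie on segments between a minority point and one of its
minority-class nearest neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .errors import ConfigError, DomainError

SAMPLER_NAMES = (
    "none",
    "rus",
    "tomek",
    "enn",
    "renn",
    "allknn",
    "ros",
    "smote",
    "svmsmote",
    "borderline_smote",
    "adasyn",
    "smoteenn",
    "smotetomek",
)

#: Cleaners with fixed removal rules: the sampling fraction does not apply.
RATIO_FREE = frozenset({"tomek", "enn", "renn", "allknn"})

_OVERSAMPLERS = frozenset(
    {"ros", "smote", "svmsmote", "borderline_smote", "adasyn", "smoteenn", "smotetomek"}
)


@dataclass
class SamplerSpec:
    """One point in the sampling dimension of the search space.

    method : one of :data:`SAMPLER_NAMES`.
    sampling_fraction : minority/majority ratio after resampling; ignored
        (and meaningless) for the fixed-rule cleaners.
    k_neighbors : neighbourhood size for the SMOTE family.
    cleaner_k : neighbourhood size for the ENN-family cleaners.
    """

    method: str
    sampling_fraction: float | None = None
    k_neighbors: int = 5
    cleaner_k: int = 3

    def __post_init__(self) -> None:
        if self.method not in SAMPLER_NAMES:
            raise ConfigError(f"unknown sampling method {self.method!r}")

    @property
    def applicable(self) -> bool:
        """Whether the sampling fraction applies to this method."""
        return self.method not in RATIO_FREE and self.method != "none"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sampling_fraction": self.sampling_fraction,
            "k_neighbors": self.k_neighbors,
            "cleaner_k": self.cleaner_k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SamplerSpec":
        return cls(**d)


def _classes(y: np.ndarray) -> tuple[int, int]:
    """(minority_class, majority_class); ties break toward 1 as minority."""
    vals, counts = np.unique(y), np.bincount(y.astype(int), minlength=2)
    if len(vals) < 2:
        raise DomainError("both classes must be present")
    if set(vals) != {0, 1}:
        raise DomainError("labels must be binary 0/1")
    return (1, 0) if counts[1] <= counts[0] else (0, 1)


def effective_fraction(y) -> float:
    """Minority/majority count ratio of a binary label vector."""
    y = np.asarray(y).astype(int)
    mino, majo = _classes(y)
    return float(np.sum(y == mino) / np.sum(y == majo))


def _interpolate(X_seed, X_pool, nn_idx, n_new, rng):
    """Synthetic points on segments seed -> one of its pool neighbours."""
    base = rng.integers(0, len(X_seed), size=n_new)
    pick = rng.integers(0, nn_idx.shape[1], size=n_new)
    neigh = X_pool[nn_idx[base, pick]]
    u = rng.random((n_new, 1))
    return X_seed[base] + u * (neigh - X_seed[base])


def _minority_nn(X_min, k):
    k = min(k, len(X_min) - 1)
    if k < 1:
        raise DomainError("minority class too small for neighbour interpolation")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    return nn.kneighbors(X_min, return_distance=False)[:, 1:]


def _smote_points(X, y, mino, n_new, k, rng, seeds_mask=None, weights=None):
    X_min = X[y == mino]
    nn_idx = _minority_nn(X_min, k)
    if seeds_mask is None and weights is None:
        return _interpolate(X_min, X_min, nn_idx, n_new, rng)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            w = np.ones(len(X_min))
        w = w / w.sum()
        base = rng.choice(len(X_min), size=n_new, p=w)
    else:
        seed_ids = np.nonzero(seeds_mask)[0]
        base = seed_ids[rng.integers(0, len(seed_ids), size=n_new)]
    pick = rng.integers(0, nn_idx.shape[1], size=n_new)
    neigh = X_min[nn_idx[base, pick]]
    u = rng.random((n_new, 1))
    return X_min[base] + u * (neigh - X_min[base])


def _oversample_target(y, mino, majo, frac) -> int:
    """Number of synthetic minority points needed to reach the fraction."""
    n_min, n_maj = int(np.sum(y == mino)), int(np.sum(y == majo))
    f0 = n_min / n_maj
    if frac is None:
        raise ConfigError("oversampler requires a sampling_fraction")
    if frac < f0 - 1e-12:
        raise ConfigError(
            f"sampling_fraction {frac:.4f} below the original fraction {f0:.4f}"
        )
    return max(0, int(round(frac * n_maj)) - n_min)


def _majority_neighbour_counts(X, y, majo, subjects, m):
    """For each subject row, how many of its m nearest neighbours are majority."""
    nn = NearestNeighbors(n_neighbors=m + 1).fit(X)
    idx = nn.kneighbors(X[subjects], return_distance=False)
    subject_ids = np.nonzero(subjects)[0]
    counts = np.zeros(len(subject_ids), dtype=int)
    for r, row in enumerate(idx):
        own = subject_ids[r]
        neigh = [j for j in row if j != own][:m]
        counts[r] = int(np.sum(y[np.array(neigh)] == majo))
    return counts


def _tomek_pass(X, y, majo) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    idx = nn.kneighbors(X, return_distance=False)
    nearest = idx[:, 1]
    keep = np.ones(len(y), dtype=bool)
    for i, j in enumerate(nearest):
        if nearest[j] == i and y[i] != y[j]:
            drop = i if y[i] == majo else j
            keep[drop] = False
    return keep


def _tomek_mask(X, y, majo) -> np.ndarray:
    """Boolean mask of rows to KEEP after Tomek-link cleaning.

    A Tomek link is a pair of mutual nearest neighbours with opposite
    labels; the majority member of each link is removed.  Removing a link
    can expose a new one, so passes repeat until no links remain.
    """
    keep = np.ones(len(y), dtype=bool)
    for _ in range(100):
        mask = _tomek_pass(X[keep], y[keep], majo)
        if mask.all():
            break
        live = np.nonzero(keep)[0]
        keep[live[~mask]] = False
    return keep


def _enn_mask(X, y, majo, k) -> np.ndarray:
    """Keep mask after one edited-nearest-neighbours pass.

    A majority row is kept only if all of its k nearest neighbours share its
    class; minority rows are never removed.
    """
    if len(X) <= k:
        return np.ones(len(y), dtype=bool)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(X, return_distance=False)[:, 1:]
    keep = np.ones(len(y), dtype=bool)
    majority_rows = np.nonzero(y == majo)[0]
    bad = np.any(y[idx[majority_rows]] != majo, axis=1)
    keep[majority_rows[bad]] = False
    return keep


def apply_sampling(X, y, spec: SamplerSpec, seed: int = 0):
    """Resample a binary dataset according to ``spec``.

    Deterministic given ``seed``.  Returns ``(X_res, y_res)``; the input is
    returned unchanged (copied) for method ``none`` or when the requested
    fraction equals the original one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    mino, majo = _classes(y)
    rng = np.random.default_rng(seed)
    frac = spec.sampling_fraction

    if spec.method == "none":
        return X.copy(), y.copy()

    if spec.method == "rus":
        n_min, n_maj = int(np.sum(y == mino)), int(np.sum(y == majo))
        if frac is None:
            raise ConfigError("rus requires a sampling_fraction")
        f0 = n_min / n_maj
        if frac < f0 - 1e-12:
            raise ConfigError(
                f"sampling_fraction {frac:.4f} below the original fraction {f0:.4f}"
            )
        target_maj = min(n_maj, int(round(n_min / frac)))
        maj_rows = np.nonzero(y == majo)[0]
        kept = rng.choice(maj_rows, size=target_maj, replace=False)
        keep = np.concatenate([np.nonzero(y == mino)[0], kept])
        keep.sort()
        return X[keep], y[keep]

    if spec.method == "ros":
        n_new = _oversample_target(y, mino, majo, frac)
        min_rows = np.nonzero(y == mino)[0]
        extra = rng.choice(min_rows, size=n_new, replace=True)
        return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])

    if spec.method in ("smote", "smoteenn", "smotetomek"):
        n_new = _oversample_target(y, mino, majo, frac)
        if n_new:
            X_new = _smote_points(X, y, mino, n_new, spec.k_neighbors, rng)
            X_res = np.vstack([X, X_new])
            y_res = np.concatenate([y, np.full(n_new, mino)])
        else:
            X_res, y_res = X.copy(), y.copy()
        if spec.method == "smoteenn":
            keep = _enn_mask(X_res, y_res, majo, spec.cleaner_k)
            return X_res[keep], y_res[keep]
        if spec.method == "smotetomek":
            keep = _tomek_mask(X_res, y_res, majo)
            return X_res[keep], y_res[keep]
        return X_res, y_res

    if spec.method == "borderline_smote":
        n_new = _oversample_target(y, mino, majo, frac)
        if not n_new:
            return X.copy(), y.copy()
        m = min(10, len(X) - 1)
        min_rows = y == mino
        counts = _majority_neighbour_counts(X, y, majo, min_rows, m)
        danger = (counts >= m / 2) & (counts < m)
        if not danger.any():
            danger = None  # no borderline points: degrade to plain SMOTE
        X_new = _smote_points(X, y, mino, n_new, spec.k_neighbors, rng, seeds_mask=danger)
        return np.vstack([X, X_new]), np.concatenate([y, np.full(n_new, mino)])

    if spec.method == "svmsmote":
        n_new = _oversample_target(y, mino, majo, frac)
        if not n_new:
            return X.copy(), y.copy()
        svc = SVC(kernel="rbf", gamma="scale", C=1.0, random_state=seed)
        svc.fit(X, y)
        sv = svc.support_[y[svc.support_] == mino]
        min_rows_idx = np.nonzero(y == mino)[0]
        pos_in_min = {g: i for i, g in enumerate(min_rows_idx)}
        seeds = np.zeros(int(np.sum(y == mino)), dtype=bool)
        m = min(10, len(X) - 1)
        if len(sv):
            subj = np.zeros(len(y), dtype=bool)
            subj[sv] = True
            counts = _majority_neighbour_counts(X, y, majo, subj, m)
            for g, c in zip(sv, counts):
                if c < m:  # not surrounded entirely by majority (noise)
                    seeds[pos_in_min[g]] = True
        if not seeds.any():
            seeds = None  # no usable support vectors: degrade to plain SMOTE
        X_new = _smote_points(X, y, mino, n_new, spec.k_neighbors, rng, seeds_mask=seeds)
        return np.vstack([X, X_new]), np.concatenate([y, np.full(n_new, mino)])

    if spec.method == "adasyn":
        n_new = _oversample_target(y, mino, majo, frac)
        if not n_new:
            return X.copy(), y.copy()
        min_rows = y == mino
        k = min(spec.k_neighbors, len(X) - 1)
        counts = _majority_neighbour_counts(X, y, majo, min_rows, k)
        weights = counts.astype(float)  # harder-to-learn points get more
        X_new = _smote_points(X, y, mino, n_new, spec.k_neighbors, rng, weights=weights)
        return np.vstack([X, X_new]), np.concatenate([y, np.full(n_new, mino)])

    if spec.method == "tomek":
        keep = _tomek_mask(X, y, majo)
        return X[keep], y[keep]

    if spec.method == "enn":
        keep = _enn_mask(X, y, majo, spec.cleaner_k)
        return X[keep], y[keep]

    if spec.method == "renn":
        keep = np.ones(len(y), dtype=bool)
        for _ in range(100):
            mask = _enn_mask(X[keep], y[keep], majo, spec.cleaner_k)
            if mask.all():
                break
            live = np.nonzero(keep)[0]
            keep[live[~mask]] = False
        return X[keep], y[keep]

    if spec.method == "allknn":
        keep = np.ones(len(y), dtype=bool)
        for k in range(1, spec.cleaner_k + 1):
            mask = _enn_mask(X[keep], y[keep], majo, k)
            live = np.nonzero(keep)[0]
            keep[live[~mask]] = False
        return X[keep], y[keep]

    raise ConfigError(f"unknown sampling method {spec.method!r}")
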