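"""Similarity kernels for semicontinuous metabolite abundance profiles.

Mass-spectrometry metabolomics measurements are zero-inflated: an entry of
0 means the metabolite was not detected in that sample, while a positive
entry is its abundance.  Two layers of information therefore coexist —
presence/absence and, when present, a quantitative level.  Ordinary
similarity measures (e.g. the Gaussian kernel) treat 0 as just another
number and ignore the discrete layer.  The two families implemented here
use both layers:

``distance``
    Squared Euclidean distance augmented by a unit penalty for every
    coordinate whose presence status disagrees between the two samples;
    the kernel is ``exp(-d^2 / rho)``.

``stratified``
    The sample space is partitioned into the ``2**p`` strata defined by
    the presence pattern of the ``p`` metabolites in the set.  Samples in
    different strata have kernel value exactly 0; within a stratum a
    Gaussian kernel is applied.

``gaussian``
    The plain Gaussian (RBF) kernel, provided as the reference point the
    two bespoke families reduce to when there are no zeros.

All three are bounded in [0, 1], symmetric and positive semidefinite, so
their Gram matrices are valid inputs to a kernel score test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FAMILIES",
    "KernelSpec",
    "presence_pattern",
    "metabolite_distance",
    "distance_kernel_value",
    "stratified_kernel_value",
    "gaussian_kernel_value",
    "gram_matrix",
    "pairwise_components",
    "scale_nonzero",
]

FAMILIES = ("distance", "stratified", "gaussian")


def _as_vector(x, *, require_nonnegative: bool = True) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.ndim != 1:
        raise ValueError("expected a 1-d measurement vector")
    if x.size < 1:
        raise ValueError("measurement vector must have at least one entry")
    if require_nonnegative and np.any(x < 0):
        raise ValueError("abundance measurements must be nonnegative")
    return x


def _check_rho(rho: float) -> float:
    rho = float(rho)
    if not rho > 0:
        raise ValueError(f"bandwidth rho must be positive, got {rho}")
    return rho


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its bandwidth (shape) parameter ``rho``."""

    family: str
    bandwidth: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {FAMILIES}")
        _check_rho(self.bandwidth)


def presence_pattern(x) -> np.ndarray:
    """Boolean presence indicator per metabolite (True where the value is nonzero).

    The ``2**p`` distinct patterns index the strata of the stratified
    kernel, from the all-absent stratum up to the all-present one.
    """
    return _as_vector(x) != 0


def metabolite_distance(x, y) -> float:
    """Presence-penalized distance between two metabolite-set measurements.

    ``sqrt(#{i: presence differs} + sum_i (x_i - y_i)^2)``.  The count term
    penalizes coordinates where one sample has the metabolite and the
    other does not; the Euclidean term compares quantitative levels.  This
    is a proper metric on the space of nonnegative vectors.
    """
    x = _as_vector(x)
    y = _as_vector(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    mismatch = np.count_nonzero((x != 0) != (y != 0))
    return float(np.sqrt(mismatch + np.sum((x - y) ** 2)))


def distance_kernel_value(x, y, rho: float) -> float:
    """Distance-based kernel ``exp(-d^2(x, y) / rho)`` in (0, 1]."""
    rho = _check_rho(rho)
    return float(np.exp(-metabolite_distance(x, y) ** 2 / rho))


def gaussian_kernel_value(x, y, rho: float) -> float:
    """Plain Gaussian kernel ``exp(-||x - y||^2 / rho)``; accepts any reals."""
    rho = _check_rho(rho)
    x = _as_vector(x, require_nonnegative=False)
    y = _as_vector(y, require_nonnegative=False)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return float(np.exp(-np.sum((x - y) ** 2) / rho))


def stratified_kernel_value(x, y, rho: float) -> float:
    """Stratified kernel: 0 across presence strata, Gaussian within.

    Two measurements from different strata (unequal presence patterns) get
    similarity 0.  Within a stratum the Gaussian kernel is evaluated on
    the full vectors; the coordinates that are zero in both contribute
    nothing to the sum, so this equals the Gaussian on the present
    coordinates.
    """
    rho = _check_rho(rho)
    x = _as_vector(x)
    y = _as_vector(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if np.any((x != 0) != (y != 0)):
        return 0.0
    return float(np.exp(-np.sum((x - y) ** 2) / rho))


def scale_nonzero(values: np.ndarray) -> np.ndarray:
    """Per-feature scaling of the nonzero entries by their standard deviation.

    Each row (feature) has its nonzero entries divided by the standard
    deviation of those nonzero entries, leaving zeros untouched.  Useful
    when abundances are large, in which case the quantitative term of the
    presence-penalized distance would swamp the presence penalty.  Rows
    with fewer than two nonzero entries, or with zero spread, are left
    unchanged.
    """
    values = np.asarray(values, dtype=float)
    out = values.copy()
    for i in range(out.shape[0]):
        nz = out[i] != 0
        if np.count_nonzero(nz) < 2:
            continue
        sd = out[i, nz].std(ddof=1)
        if sd > 0:
            out[i, nz] /= sd
    return out


def pairwise_components(X: np.ndarray, family: str):
    """Pairwise building blocks of a Gram matrix for ``n`` samples.

    Parameters
    ----------
    X : (n, p) array
        One measurement vector per row (samples by metabolites).
    family : str
        One of ``FAMILIES``.

    Returns
    -------
    d2 : (n, n) array
        Squared distances entering the exponential: presence-penalized for
        the ``distance`` family, plain squared Euclidean otherwise.
    mask : (n, n) bool array or None
        For the ``stratified`` family, True where the two samples share a
        presence pattern; None for the other families.

    The Gram matrix at bandwidth ``rho`` is ``exp(-d2 / rho)`` times the
    mask (where present).  Separating the bandwidth-independent parts lets
    a whole bandwidth grid be evaluated from one distance computation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-d (samples x metabolites) array")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    if family not in FAMILIES:
        raise ValueError(f"unknown kernel family {family!r}; choose from {FAMILIES}")
    if family != "gaussian" and np.any(X < 0):
        raise ValueError("abundance measurements must be nonnegative")

    d2 = cdist(X, X, metric="sqeuclidean")
    if family == "distance":
        pres = (X != 0).astype(float)
        # number of coordinates with mismatched presence status
        mismatch = cdist(pres, pres, metric="hamming") * X.shape[1]
        return d2 + np.round(mismatch), None
    if family == "stratified":
        pres = (X != 0).astype(float)
        mismatch = cdist(pres, pres, metric="hamming") * X.shape[1]
        return d2, np.round(mismatch) == 0
    return d2, None


def gram_matrix(X: np.ndarray, family: str, rho: float) -> np.ndarray:
    """The ``n x n`` Gram matrix ``K_ij = k_rho(x_i, x_j)`` for a sample set.

    Symmetric with unit diagonal; positive semidefinite for all three
    families.
    """
    rho = _check_rho(rho)
    d2, mask = pairwise_components(X, family)
    K = np.exp(-d2 / rho)
    if mask is not None:
        K = np.where(mask, K, 0.0)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K
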