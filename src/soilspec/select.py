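"""Exploratory PCA and Kennard-Stone calibration/test partitioning.

Sample selection follows chemometric practice: a PCA of the
continuum-removed reflectance matrix captures the absorption-feature
variation; the Euclidean metric on the *normalized* score space (each
retained component scaled to unit variance) drives the deterministic
Kennard-Stone maximin algorithm, which picks a space-filling calibration
subset — two thirds of the samples by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial import distance
from sklearn.base import BaseEstimator

from .containers import PROPERTY_COLUMNS, SpectraMatrix, SpectralLibrary
from .errors import SoilSpecError
from .preprocess import average_scans_qc, continuum_remove


@dataclass
class PcaModel:
    """Fitted PCA retaining the minimal prefix of components whose
    cumulative explained variance exceeds the threshold."""

    loadings: np.ndarray            # (k, n_bands) orthonormal rows
    eigenvalues: np.ndarray         # (k,) variances along components
    explained_variance_ratio: np.ndarray
    scores: np.ndarray              # (n, k), normalized to unit variance
    score_scale: np.ndarray         # (k,) SDs used for normalization
    mean: np.ndarray                # (n_bands,) centering vector
    var_threshold: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def project(self, X: np.ndarray | SpectraMatrix) -> np.ndarray:
        """Normalized scores of new samples."""
        if isinstance(X, SpectraMatrix):
            X = X.values
        return (np.asarray(X, float) - self.mean) @ self.loadings.T / self.score_scale


def pca_fit(m: SpectraMatrix | np.ndarray, var_threshold: float = 0.99
            ) -> PcaModel:
    """PCA of the column-centred matrix, retaining the minimal prefix of
    components whose cumulative explained variance exceeds ``var_threshold``.

    Exact eigendecomposition of the covariance; when n_samples < n_bands
    the Gram matrix (n x n) is decomposed instead, which is algebraically
    equivalent and much cheaper for wide spectral matrices.
    """
    X = m.values if isinstance(m, SpectraMatrix) else np.atleast_2d(np.asarray(m, float))
    n, p = X.shape
    if not 0 < var_threshold <= 1:
        raise SoilSpecError("var_threshold must lie in (0, 1]")
    mean = X.mean(axis=0)
    Xc = X - mean
    if np.allclose(Xc.var(axis=0), 0):
        raise SoilSpecError("zero-variance matrix: PCA undefined")

    if p > n:
        # eigh of the Gram matrix: eigenvalues match X'X, loadings recovered
        # as X' u / sqrt(l)
        gram = Xc @ Xc.T
        lam, U = linalg.eigh(gram)
        lam, U = lam[::-1], U[:, ::-1]
        pos = lam > max(lam[0], 0) * 1e-12
        lam, U = lam[pos], U[:, pos]
        loadings_full = (Xc.T @ U) / np.sqrt(lam)
        loadings_full = loadings_full.T            # (r, p) orthonormal rows
    else:
        cov = Xc.T @ Xc
        lam, V = linalg.eigh(cov)
        lam, V = lam[::-1], V[:, ::-1]
        pos = lam > max(lam[0], 0) * 1e-12
        lam, V = lam[pos], V[:, pos]
        loadings_full = V.T

    eigenvalues = lam / (n - 1)                    # variances along components
    evr = lam / lam.sum()
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, var_threshold) + 1)
    k = min(k, lam.size)

    loadings = loadings_full[:k]
    raw_scores = Xc @ loadings.T
    scale = raw_scores.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    return PcaModel(
        loadings=loadings,
        eigenvalues=eigenvalues[:k],
        explained_variance_ratio=evr[:k],
        scores=raw_scores / scale,
        score_scale=scale,
        mean=mean,
        var_threshold=var_threshold,
    )


def property_correlations(model: PcaModel, props: pd.DataFrame,
                          k: int = 3) -> pd.DataFrame:
    """Pearson correlation of the first ``k`` component scores with each
    numeric soil property; constant properties yield NaN (undefined)."""
    k = min(k, model.n_components)
    out = {}
    for col in PROPERTY_COLUMNS:
        if col not in props.columns:
            continue
        x = pd.to_numeric(props[col], errors="coerce").to_numpy(float)
        row = []
        for j in range(k):
            s = model.scores[:, j]
            ok = np.isfinite(x)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(s[ok]) == 0:
                row.append(np.nan)
            else:
                row.append(float(np.corrcoef(x[ok], s[ok])[0, 1]))
        out[col] = row
    return pd.DataFrame(out, index=[f"PC{j + 1}" for j in range(k)]).T


@dataclass
class SelectionResult:
    """A Kennard-Stone train/test partition with its audit trail.

    ``order`` lists training indices in selection order; ``distance_trace``
    holds, per accepted point, the maximin distance d(i0) (for the initial
    pair, the maximal pairwise distance, recorded twice).  The trace is
    non-increasing after the initial pair.  ``ties`` records any step where
    the maximin argmax was not unique (broken by lowest index).
    """

    train: np.ndarray
    test: np.ndarray
    order: np.ndarray
    distance_trace: np.ndarray
    ties: list[int] = field(default_factory=list)

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        n = self.train.size + self.test.size
        ids = np.arange(n) if sample_ids is None else np.asarray(sample_ids)
        role = np.full(n, "test", dtype=object)
        role[self.train] = "train"
        rank = np.full(n, -1)
        rank[self.order] = np.arange(self.order.size)
        dist = np.full(n, np.nan)
        dist[self.order] = self.distance_trace
        return pd.DataFrame({
            "sample_id": ids, "role": role,
            "selection_rank": rank, "maximin_distance": dist,
        })


class KennardStoneSplitter(BaseEstimator):
    """Deterministic maximin selection of a space-filling training set.

    The first pair is the two mutually farthest points; thereafter the
    unassigned point farthest from its nearest assigned neighbour is added
    until ``n_train`` points are selected.  Ties break to the lowest index.
    """

    def __init__(self, n_train: int = 2):
        self.n_train = n_train

    def fit(self, X, y=None) -> "KennardStoneSplitter":
        X = np.atleast_2d(np.asarray(X, float))
        n = X.shape[0]
        if not 2 <= self.n_train <= n:
            raise SoilSpecError(f"n_train must lie in [2, {n}]")

        d2 = distance.cdist(X, X, "sqeuclidean")
        # initial pair: global farthest, lowest indices on ties
        flat = np.argmax(d2)
        best = d2.flat[flat]
        ii, jj = np.divmod(flat, n)  # argmax returns first occurrence: lowest i, then j
        i0, j0 = (ii, jj) if ii < jj else (jj, ii)
        d_init = float(np.sqrt(best))

        order = [int(i0), int(j0)]
        trace = [d_init, d_init]
        ties: list[int] = []
        assigned = np.zeros(n, dtype=bool)
        assigned[[i0, j0]] = True
        min_d2 = np.minimum(d2[i0], d2[j0])

        while len(order) < self.n_train:
            cand = np.where(~assigned, min_d2, -np.inf)
            pick = int(np.argmax(cand))
            if np.count_nonzero(cand == cand[pick]) > 1:
                ties.append(len(order))
            order.append(pick)
            trace.append(float(np.sqrt(cand[pick])))
            assigned[pick] = True
            np.minimum(min_d2, d2[pick], out=min_d2)

        train = np.sort(order)
        test = np.flatnonzero(~assigned)
        tr = np.asarray(trace)
        if tr.size > 2 and np.any(np.diff(tr[1:]) > 1e-9 * max(tr[1], 1.0)):
            raise AssertionError("maximin distance trace must be non-increasing")
        self.result_ = SelectionResult(
            train=train, test=test, order=np.asarray(order),
            distance_trace=tr, ties=ties,
        )
        return self


def kennard_stone(scores: np.ndarray, n_train: int) -> SelectionResult:
    """Functional wrapper over :class:`KennardStoneSplitter`."""
    return KennardStoneSplitter(n_train).fit(scores).result_


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def split_library(
    lib: SpectralLibrary | SpectraMatrix,
    fraction: float = 2.0 / 3.0,
    var_threshold: float = 0.99,
) -> tuple[SelectionResult, PcaModel]:
    """Kennard-Stone split of a library: continuum-removed reflectance ->
    PCA (>99 % variance) -> maximin selection of ``round(fraction * n)``."""
    if isinstance(lib, SpectralLibrary):
        matrix, _ = average_scans_qc(lib, threshold=None)
    else:
        matrix = lib
    n = matrix.n_samples
    if n < 3:
        raise SoilSpecError("need at least 3 samples to split")
    cr = continuum_remove(matrix)
    model = pca_fit(cr, var_threshold)
    n_train = _round_half_away(fraction * n)
    n_train = min(max(n_train, 2), n)
    return kennard_stone(model.scores, n_train), model
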