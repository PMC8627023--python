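"""Transfer Component Analysis (TCA) for cross-domain feature alignment.

TCA embeds a labeled source domain (microindels) and an unlabeled target
domain (microexons) into a shared low-dimensional latent space in which
the maximum mean discrepancy (MMD) between the two domains is small
while the variance of the embedded data is preserved.

Given the stacked kernel matrix

    K = [[K_SS, K_ST], [K_TS, K_TT]],

the MMD coefficient matrix L (``1/n1^2`` within source, ``1/n2^2``
within target, ``-1/(n1 n2)`` across) and the centering matrix
``H = I - (1/(n1+n2)) 11^T``, the transfer components are the leading
eigenvectors of

    (K L K + mu I)^(-1) K H K,

equivalently the generalized eigenproblem ``KHK w = nu (KLK + mu I) w``.
The numerator rewards embedded variance (through the centered kernel)
and the denominator penalizes embedded domain discrepancy, with ``mu``
a small ridge keeping the system well posed. Embeddings are rows of
``K W``; new points embed through their kernel row against the training
stack (a Nystroem-style out-of-sample extension).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import joblib
import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import euclidean_distances, linear_kernel, rbf_kernel

logger = logging.getLogger(__name__)

DEFAULT_MU = 0.1
DEFAULT_M = 8
ZERO_EIGVAL_RTOL = 1e-10


@dataclass
class DomainDataset:
    """A feature matrix tagged as source or target, with optional labels.

    ``matrix`` is an ``n x p`` DataFrame (canonically the 25 features);
    ``labels`` is a binary vector (functional=1, neutral=0) required for
    source datasets used in training.
    """

    matrix: pd.DataFrame
    labels: np.ndarray | None = None
    domain_tag: str = "source"

    def __post_init__(self) -> None:
        if self.domain_tag not in ("source", "target"):
            raise ValueError(f"invalid domain_tag {self.domain_tag!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.matrix),):
                raise ValueError("labels must be one per record")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary (functional=1, neutral=0)")

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.matrix)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family used for the stacked Gram matrix.

    ``gamma=None`` for the RBF family means the median pairwise-distance
    heuristic, resolved (and frozen) at fit time.
    """

    name: str = "linear"
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.name!r}")


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF gamma = 1 / (2 sigma^2) with sigma the median pairwise distance."""
    X = np.asarray(X, dtype=float)
    dist = euclidean_distances(X)
    upper = dist[np.triu_indices_from(dist, k=1)]
    upper = upper[upper > 0]
    if upper.size == 0:
        return 1.0
    sigma = float(np.median(upper))
    return 1.0 / (2.0 * sigma**2)


def _as_matrix(data: DomainDataset | pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(data, DomainDataset):
        return data.values
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def kernel_matrix(
    A: np.ndarray, B: np.ndarray | None, spec: KernelSpec
) -> np.ndarray:
    """Pairwise kernel evaluations between rows of A and B."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = A if B is None else np.atleast_2d(np.asarray(B, dtype=float))
    if spec.name == "linear":
        return linear_kernel(A, B)
    gamma = spec.gamma
    if gamma is None:
        raise ValueError("RBF gamma unresolved; fit first or set it explicitly")
    return rbf_kernel(A, B, gamma=gamma)


def mmd_distance(
    A: DomainDataset | np.ndarray,
    B: DomainDataset | np.ndarray,
    spec: KernelSpec = KernelSpec(),
) -> float:
    """Squared kernel distance between the empirical means of two samples.

    ``mean(K_AA) - 2 mean(K_AB) + mean(K_BB)``, clipped at zero against
    negative round-off. With the linear kernel this is exactly
    ``|| mean(A) - mean(B) ||^2``.
    """
    A = _as_matrix(A)
    B = _as_matrix(B)
    if A.size == 0 or B.size == 0:
        raise ValueError("mmd_distance requires non-empty matrices")
    spec = _resolve_spec(spec, np.vstack([A, B]))
    value = (
        kernel_matrix(A, A, spec).mean()
        - 2.0 * kernel_matrix(A, B, spec).mean()
        + kernel_matrix(B, B, spec).mean()
    )
    return max(float(value), 0.0)


def _resolve_spec(spec: KernelSpec, stacked: np.ndarray) -> KernelSpec:
    if spec.name == "rbf" and spec.gamma is None:
        return KernelSpec("rbf", median_heuristic_gamma(stacked))
    return spec


def mmd_coefficient_matrix(n1: int, n2: int) -> np.ndarray:
    """The matrix L with tr(KL) equal to the squared MMD."""
    s = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    return np.outer(s, s)


def centering_matrix(n: int) -> np.ndarray:
    return np.eye(n) - np.full((n, n), 1.0 / n)


def build_kernel_system(
    source: DomainDataset | np.ndarray,
    target: DomainDataset | np.ndarray,
    spec: KernelSpec = KernelSpec(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked kernel matrix K (source rows first), L, and H.

    ``tr(K @ L)`` equals :func:`mmd_distance` of the two domains under
    the same kernel — the identity the eigenproblem optimizes.
    """
    Xs = _as_matrix(source)
    Xt = _as_matrix(target)
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target feature dimensions differ")
    stacked = np.vstack([Xs, Xt])
    if not np.isfinite(stacked).all():
        raise ValueError("non-finite feature values; impute before TCA")
    spec = _resolve_spec(spec, stacked)
    K = kernel_matrix(stacked, stacked, spec)
    L = mmd_coefficient_matrix(len(Xs), len(Xt))
    H = centering_matrix(len(Xs) + len(Xt))
    return K, L, H


@dataclass
class TCAProjection:
    """Fitted TCA state: kernel, training stack, and retained eigenpairs."""

    kernel_spec: KernelSpec
    training_matrix: np.ndarray  # (n1+n2) x p stacked source-then-target
    eigvecs: np.ndarray          # (n1+n2) x m
    eigvals: np.ndarray          # m, non-increasing, all above zero tolerance
    m: int
    mu: float
    n_source: int
    n_target: int
    embedding_: np.ndarray = field(repr=False, default=None)  # fit-time K @ W

    @property
    def source_embedding(self) -> np.ndarray:
        return self.embedding_[: self.n_source]

    @property
    def target_embedding(self) -> np.ndarray:
        return self.embedding_[self.n_source:]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "TCAProjection":
        projection = joblib.load(Path(path))
        if not isinstance(projection, cls):
            raise TypeError(f"{path} does not contain a TCAProjection")
        return projection


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Scale each eigenvector so its largest-magnitude entry is positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_tca(
    source: DomainDataset | np.ndarray,
    target: DomainDataset | np.ndarray,
    spec: KernelSpec = KernelSpec(),
    m: int = DEFAULT_M,
    mu: float = DEFAULT_MU,
) -> TCAProjection:
    """Fit the transfer components from a source/target pair.

    Solves ``KHK w = nu (KLK + mu I) w``, sorts eigenpairs by descending
    eigenvalue, drops eigenvalues below ``1e-10`` of the largest, and
    retains the first ``m`` (all of them, with a warning, if fewer than
    ``m`` are nonzero).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    Xs = _as_matrix(source)
    Xt = _as_matrix(target)
    spec = _resolve_spec(spec, np.vstack([Xs, Xt]))
    K, L, H = build_kernel_system(Xs, Xt, spec)
    n = K.shape[0]
    A = K @ H @ K
    B = K @ L @ K + mu * np.eye(n)
    A = (A + A.T) / 2.0
    B = (B + B.T) / 2.0
    try:
        eigvals, eigvecs = scipy.linalg.eigh(A, B)
    except scipy.linalg.LinAlgError as exc:
        cond = np.linalg.cond(B)
        raise np.linalg.LinAlgError(
            f"TCA eigenproblem is numerically singular (cond(KLK+muI)={cond:.3g})"
        ) from exc
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = ZERO_EIGVAL_RTOL * max(np.abs(eigvals).max(), 1.0)
    nonzero = np.abs(eigvals) > tol
    n_nonzero = int(nonzero.sum())
    if n_nonzero < m:
        warnings.warn(
            f"only {n_nonzero} nonzero transfer components available; "
            f"requested m={m}",
            RuntimeWarning,
            stacklevel=2,
        )
    keep = min(m, n_nonzero)
    W = _fix_signs(eigvecs[:, :keep])
    projection = TCAProjection(
        kernel_spec=spec,
        training_matrix=np.vstack([Xs, Xt]),
        eigvecs=W,
        eigvals=eigvals[:keep],
        m=keep,
        mu=mu,
        n_source=len(Xs),
        n_target=len(Xt),
    )
    projection.embedding_ = K @ W
    if not np.isfinite(projection.embedding_).all():
        raise np.linalg.LinAlgError("non-finite TCA embedding")
    return projection


def transform(
    projection: TCAProjection, data: DomainDataset | np.ndarray
) -> np.ndarray:
    """Embed rows of ``data`` into the fitted latent space.

    Training-stack rows reproduce the fit-time embedding exactly; new
    rows use their kernel against the training stack with the same
    eigenvectors.
    """
    X = np.atleast_2d(_as_matrix(data))
    if X.shape[1] != projection.training_matrix.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {projection.training_matrix.shape[1]}"
        )
    Kx = kernel_matrix(X, projection.training_matrix, projection.kernel_spec)
    return Kx @ projection.eigvecs


def pca_baseline(
    source: DomainDataset | np.ndarray,
    target: DomainDataset | np.ndarray,
    m: int = DEFAULT_M,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Project both domains on the top-m principal components of the stack.

    Serves as the non-adaptive baseline: PCA keeps variance but ignores
    the domain discrepancy. Returns the two component matrices and the
    post-projection linear-kernel MMD.
    """
    Xs = _as_matrix(source)
    Xt = _as_matrix(target)
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source and target feature dimensions differ")
    if m > Xs.shape[1]:
        raise ValueError(f"m={m} exceeds feature count {Xs.shape[1]}")
    stacked = np.vstack([Xs, Xt])
    if not np.isfinite(stacked).all():
        raise ValueError("non-finite feature values; impute before PCA")
    pca = PCA(n_components=m, svd_solver="full")
    components = pca.fit_transform(stacked)
    comp_s = components[: len(Xs)]
    comp_t = components[len(Xs):]
    return comp_s, comp_t, mmd_distance(comp_s, comp_t, KernelSpec("linear"))
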