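"""Square-root transform and covariance-matrix principal components.

All color statistics run on square-rooted channel intensities (the raw
RGB distributions are right-skewed).  PCA is always on the sample
covariance matrix — the 18 channels share one physical scale — with the
sign of each component fixed so its mean loading is positive, making
larger PC1 scores read as lighter/redder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class TransformError(ValueError):
    """Degenerate input to a transform (negative channel, zero variance)."""


def sqrt_transform(values):
    """Square root of channel intensities; domain [0, 255] -> [0, √255]."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise TransformError("negative channel intensity")
    out = np.sqrt(arr)
    return float(out) if out.ndim == 0 else out


@dataclass
class PCModel:
    """A fitted principal-component basis.

    ``loadings`` has one column per component (orthonormal);
    ``eigenvalues`` are the sample covariance eigenvalues in
    non-increasing order; ``k`` is the number of retained components.
    """

    variables: list[str]
    means: np.ndarray
    loadings: np.ndarray          # (p, p), columns = components
    eigenvalues: np.ndarray       # (p,), non-increasing
    k: int

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            raise TransformError("zero total variance")
        return self.eigenvalues / total

    def transform(self, X) -> np.ndarray:
        """Scores on the k retained components (unweighted projections)."""
        X = np.asarray(X, dtype=float)
        return (X - self.means) @ self.loadings[:, : self.k]

    def to_text(self) -> str:
        lines = ["variables\t" + "\t".join(self.variables),
                 "k\t" + str(self.k),
                 "means\t" + "\t".join(repr(float(v)) for v in self.means),
                 "eigenvalues\t" + "\t".join(repr(float(v)) for v in
                                             self.eigenvalues)]
        for j in range(self.loadings.shape[1]):
            lines.append(
                f"loading{j + 1}\t"
                + "\t".join(repr(float(v)) for v in self.loadings[:, j])
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PCModel":
        fields = {}
        for line in text.strip().splitlines():
            key, *vals = line.split("\t")
            fields[key] = vals
        variables = fields["variables"]
        p = len(variables)
        loadings = np.column_stack(
            [np.array(fields[f"loading{j + 1}"], dtype=float)
             for j in range(p)]
        )
        return cls(
            variables=variables,
            means=np.array(fields["means"], dtype=float),
            loadings=loadings,
            eigenvalues=np.array(fields["eigenvalues"], dtype=float),
            k=int(fields["k"][0]),
        )


def fit_pca(X, variables: list[str] | None = None, k: int | None = None
            ) -> PCModel:
    """Eigendecomposition of the sample (n−1) covariance of ``X``.

    Components are ordered by decreasing eigenvalue and sign-fixed so the
    mean loading of each is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise TransformError("need at least two rows")
    means = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    if not np.any(cov.diagonal() > 0):
        raise TransformError("zero total variance: PC directions undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    signs = np.where(eigvecs.mean(axis=0) >= 0, 1.0, -1.0)
    eigvecs = eigvecs * signs
    if variables is None:
        variables = [f"x{i + 1}" for i in range(p)]
    return PCModel(
        variables=list(variables),
        means=means,
        loadings=eigvecs,
        eigenvalues=eigvals,
        k=p if k is None else k,
    )


def pc1_scores(X) -> tuple[np.ndarray, float]:
    """PC1 scores and PC1's explained-variance fraction.

    ``X`` is typically (n specimens × 3 sqrt channels) of one body part,
    n ≥ 3.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise TransformError("need at least three specimens")
    model = fit_pca(X, k=1)
    scores = model.transform(X)[:, 0]
    return scores, float(model.explained_variance_ratio[0])


def reduce_cumulative(X, threshold: float = 0.8,
                      variables: list[str] | None = None
                      ) -> tuple[np.ndarray, PCModel]:
    """Scores on the smallest leading-component set whose cumulative
    explained variance reaches ``threshold``.
    """
    if not (0.0 < threshold <= 1.0):
        raise TransformError("threshold must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    model = fit_pca(X, variables=variables)
    cum = np.cumsum(model.explained_variance_ratio)
    model.k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return model.transform(X), model
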