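"""Genetic relationship matrices under three scalings, plus PCs.

The GRM is K = Z Z'/m where Z is a column-transformed dosage matrix.  The
scaling determines what a random-effects variance component on K measures
in a structured population:

* ``standard`` -- z_i = (x_i - 2 f_i)/sqrt(2 f_i (1 - f_i)), the usual
  Hardy-Weinberg scaling.  Assumes V(x_i) = 2 f_i (1 - f_i), which is an
  undercount when ancestry varies (V(z_i) = 1 + 2 V(theta) FST_i).
* ``variance`` -- z_i = (x_i - 2 f_i)/sqrt(V(x_i)) with the sample
  variance, restoring the per-locus structural variance.
* ``ld`` -- Z = (X - 2 P) U^{-1} with Sigma = U'U the Cholesky factor of
  the sample covariance of the centered dosages: whitening by the LD
  matrix, which additionally recovers the cross-locus (directional-LD)
  variance.  Requires Sigma invertible; with the same in-sample Sigma and
  no ridge the mean diagonal of K is exactly 1.

Local-ancestry GRMs use the dosage matrix gamma with gamma-bar in place of
2f; the "standard" analogue divides by sqrt(2 (gbar/2)(1 - gbar/2)),
reading gamma-bar/2 as the ancestry-dosage frequency.

Allele frequencies for centering are always in-sample (column means / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "GRMatrix",
    "build_genotype_grm",
    "build_local_ancestry_grm",
    "principal_components",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_grm_gcta",
    "read_grm_gcta",
]

SCALINGS = ("standard", "variance", "ld")


@dataclass
class GRMatrix:
    """An n x n relationship matrix tagged with its provenance."""

    K: np.ndarray
    scaling: str
    source: str  # "genotype" or "local_ancestry"
    m: int
    ridge: float = 0.0

    @property
    def n(self) -> int:
        return self.K.shape[0]


def _scaled_matrix(
    D: np.ndarray, scaling: str, ridge: float | None, kind: str
) -> tuple[np.ndarray, float]:
    """Column-transform a dosage matrix per the requested scaling."""
    if scaling not in SCALINGS:
        raise ValueError(f"unknown scaling {scaling!r}")
    D = np.asarray(D, dtype=float)
    n, m = D.shape
    colmean = D.mean(axis=0)
    C = D - colmean
    if scaling in ("standard", "variance"):
        if scaling == "standard":
            freq = colmean / 2.0  # dosage-scale frequency in [0, 1]
            denom2 = 2.0 * freq * (1.0 - freq)
        else:
            denom2 = C.var(axis=0)  # population convention
        if np.any(denom2 <= 0):
            bad = np.flatnonzero(denom2 <= 0)
            raise ValueError(
                f"monomorphic {kind} column(s) {bad[:5].tolist()}...: cannot scale"
            )
        return C / np.sqrt(denom2), 0.0
    # LD scaling
    Sigma = C.T @ C / n
    if ridge is None:
        if m > n:
            ridge = 1e-3 * float(np.mean(np.diag(Sigma)))
        else:
            ridge = 0.0
    if ridge > 0:
        Sigma = Sigma + ridge * np.eye(m)
    try:
        U = scipy.linalg.cholesky(Sigma, lower=False)
    except scipy.linalg.LinAlgError as err:
        raise ValueError(
            "singular column covariance: LD scaling needs m <= n and "
            "non-degenerate columns, or a positive ridge"
        ) from err
    Z = scipy.linalg.solve_triangular(U, C.T, lower=False, trans="T").T
    return Z, ridge


def build_genotype_grm(
    X: np.ndarray, scaling: str = "standard", ridge: float | None = None
) -> GRMatrix:
    """GRM from genotype dosages; see module docstring for the scalings."""
    Z, used_ridge = _scaled_matrix(X, scaling, ridge, kind="genotype")
    m = Z.shape[1]
    return GRMatrix(K=Z @ Z.T / m, scaling=scaling, source="genotype", m=m, ridge=used_ridge)


def build_local_ancestry_grm(
    gamma: np.ndarray, scaling: str = "standard", ridge: float | None = None
) -> GRMatrix:
    """GRM from local-ancestry dosages (same scalings, gamma-bar centering)."""
    gamma = np.asarray(gamma, dtype=float)
    if scaling == "standard":
        gbar = gamma.mean(axis=0)
        freq = gbar / 2.0
        denom2 = 2.0 * freq * (1.0 - freq)
        if np.any(denom2 <= 0):
            raise ValueError("constant local-ancestry column: cannot scale")
        Z = (gamma - gbar) / np.sqrt(denom2)
        used_ridge = 0.0
    else:
        Z, used_ridge = _scaled_matrix(gamma, scaling, ridge, kind="local ancestry")
    m = Z.shape[1]
    return GRMatrix(
        K=Z @ Z.T / m, scaling=scaling, source="local_ancestry", m=m, ridge=used_ridge
    )


def principal_components(K: GRMatrix | np.ndarray, n_pcs: int) -> np.ndarray:
    """Top eigenvectors of the GRM, unit norm, deterministic sign.

    The sign convention makes the largest-magnitude entry of each
    component positive.
    """
    A = K.K if isinstance(K, GRMatrix) else np.asarray(K, dtype=float)
    n = A.shape[0]
    if n_pcs >= n:
        raise ValueError("n_pcs must be smaller than the matrix dimension")
    vals, vecs = scipy.linalg.eigh(A, subset_by_index=(n - n_pcs, n - 1))
    vecs = vecs[:, ::-1]  # descending eigenvalue order
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs


# ---------------------------------------------------------------------------
# round-trips

def write_grm_tsv(grm: GRMatrix, path) -> None:
    """Plain-TSV GRM: header comment with metadata, then the dense matrix."""
    with open(path, "w") as fh:
        fh.write(
            f"# scaling={grm.scaling} source={grm.source} m={grm.m} ridge={grm.ridge:.17g}\n"
        )
        np.savetxt(fh, grm.K, delimiter="\t", fmt="%.17g")


def read_grm_tsv(path) -> GRMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("GRM TSV must start with a metadata comment line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        K = np.loadtxt(fh, delimiter="\t")
    return GRMatrix(
        K=np.atleast_2d(K),
        scaling=meta["scaling"],
        source=meta["source"],
        m=int(meta["m"]),
        ridge=float(meta["ridge"]),
    )


def write_grm_gcta(grm: GRMatrix, prefix, ids=None) -> None:
    """GCTA binary triad: <prefix>.grm.bin/.grm.N.bin (float32 lower
    triangle, row-major) and <prefix>.grm.id (FID IID)."""
    n = grm.n
    iu = np.tril_indices(n)
    vals = grm.K[iu].astype("<f4")
    vals.tofile(f"{prefix}.grm.bin")
    np.full(vals.size, grm.m, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    if ids is None:
        ids = [f"id{i}" for i in range(n)]
    pd.DataFrame({"fid": ids, "iid": ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_gcta(prefix, scaling: str = "standard", source: str = "genotype") -> GRMatrix:
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    K = np.zeros((n, n))
    iu = np.tril_indices(n)
    K[iu] = vals
    K = K + K.T - np.diag(np.diag(K))
    return GRMatrix(K=K, scaling=scaling, source=source, m=int(counts[0]))
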