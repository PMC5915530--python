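"""Essential dynamics: positional-covariance PCA and subspace overlap metrics.

After least-squares superposition of every frame onto the ensemble mean,
the 3n x 3n positional covariance matrix is diagonalized. Its leading
eigenvectors (the "essential" modes) span the dominant conformational
subspace; two ensembles sample similar conformational spaces when these
subspaces overlap.

Two standard similarity metrics are provided:

* RMSIP — root-mean-square inner product of the k leading eigenvectors,
  ``sqrt( (1/k) * sum_{i<=k} sum_{j<=k} (v_i^A . v_j^B)^2 )``;
* covariance overlap — a full-spectrum similarity,
  ``1 - sqrt( (sum_i lam_i^A + sum_i lam_i^B
  - 2 sum_ij sqrt(lam_i^A lam_j^B) (v_i^A . v_j^B)^2)
  / (sum_i lam_i^A + sum_i lam_i^B) )``.

Both lie in [0, 1] and equal 1 for identical subspaces / covariances.
For a parent/retro-D pair the retro ensemble's coordinates must first be
re-ordered by the :class:`~retromimic.mimicry.RetroAtomMap` so mode
vectors live in a common index space (see
:func:`retromimic.mimicry.mapped_coordinates`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensembles import ConformerEnsemble
from .errors import InputError, NumericalError
from .mimicry import kabsch_superpose


@dataclass(frozen=True)
class EDModes:
    """Essential-dynamics decomposition of one ensemble."""

    mean_structure: np.ndarray  # (n_atoms, 3), Å
    eigenvalues: np.ndarray  # Å², descending
    eigenvectors: np.ndarray  # (3 n_atoms, n_modes), orthonormal columns
    atom_selection: np.ndarray  # indices of atoms used
    converged: bool  # iterative superposition reached tolerance

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


def _superpose_all(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = np.empty_like(frames)
    for i, f in enumerate(frames):
        fit = kabsch_superpose(reference, f)
        out[i] = f @ fit.rotation.T + fit.translation
    return out


def covariance_modes(
    ens: ConformerEnsemble | np.ndarray,
    atom_selection: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> EDModes:
    """Diagonalize the positional covariance of a superposed ensemble.

    Frames are iteratively superposed onto the running mean structure
    (proper rotations only) until the mean moves by less than ``tol`` Å
    RMS — using the converged mean as reference removes the bias a fixed
    reference frame would introduce into the covariance. Non-convergence
    within ``max_iter`` iterations is flagged on the result, not raised.

    Accepts either an ensemble (with optional atom selection) or a bare
    ``(n_frames, n_atoms, 3)`` coordinate array.
    """
    if isinstance(ens, ConformerEnsemble):
        sel = (
            np.arange(ens.n_atoms)
            if atom_selection is None
            else np.asarray(atom_selection, dtype=int)
        )
        frames = ens.frames[:, sel, :]
    else:
        frames = np.asarray(ens, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise InputError("coordinate array must be (n_frames, n_atoms, 3)")
        sel = np.arange(frames.shape[1])
    if frames.shape[0] < 2:
        raise InputError("covariance analysis needs at least 2 frames")
    if sel.size == 0:
        raise InputError("empty atom selection")

    mean = frames[0].copy()
    converged = False
    fitted = frames
    for _ in range(max_iter):
        fitted = _superpose_all(frames, mean)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if shift < tol:
            converged = True
            break

    disp = (fitted - mean).reshape(frames.shape[0], -1)  # (n_frames, 3n)
    cov = disp.T @ disp / frames.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return EDModes(
        mean_structure=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        atom_selection=sel,
        converged=converged,
    )


def _check_dims(a: EDModes, b: EDModes) -> None:
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise InputError(
            f"mode spaces have different dimension: "
            f"{a.eigenvectors.shape[0]} vs {b.eigenvectors.shape[0]}"
        )


def rmsip(a: EDModes, b: EDModes, k: int = 10) -> float:
    """Root-mean-square inner product of the k leading modes of each side.

    1 when the two k-dimensional essential subspaces coincide, 0 when
    they are orthogonal. Invariant to sign flips and to rotations within
    degenerate eigenspaces, and symmetric in its arguments.
    """
    _check_dims(a, b)
    if k < 1:
        raise InputError("k must be >= 1")
    if k > a.n_modes or k > b.n_modes:
        raise InputError(
            f"k={k} exceeds available modes ({a.n_modes}, {b.n_modes})"
        )
    va = a.eigenvectors[:, :k]
    vb = b.eigenvectors[:, :k]
    dots = va.T @ vb
    return float(np.sqrt((dots**2).sum() / k))


def covariance_overlap(a: EDModes, b: EDModes) -> float:
    """Normalized similarity of the two full positional covariances.

    Uses every mode, weighted by eigenvalue, so it measures both the
    directions and the amplitudes of the sampled fluctuations. Equals 1
    iff the covariances are identical; rejected when both covariances
    vanish (no fluctuations to compare).
    """
    _check_dims(a, b)
    tr_a = float(a.eigenvalues.sum())
    tr_b = float(b.eigenvalues.sum())
    if tr_a + tr_b <= 0:
        raise NumericalError(
            "covariance overlap undefined: both covariances are zero"
        )
    dots = a.eigenvectors.T @ b.eigenvectors  # (ma, mb)
    dim = a.eigenvectors.shape[0]
    if a.n_modes == dim and b.n_modes == dim:
        # complete orthonormal bases: use the cancellation-free identity
        # sum_ij (v_i.v_j)^2 (sqrt(l_i) - sqrt(l_j))^2 for the numerator
        diff = (
            np.sqrt(a.eigenvalues)[:, None] - np.sqrt(b.eigenvalues)[None, :]
        ) ** 2
        num = float((dots**2 * diff).sum())
    else:
        cross = (
            np.sqrt(np.outer(a.eigenvalues, b.eigenvalues)) * dots**2
        ).sum()
        num = tr_a + tr_b - 2.0 * cross
    arg = num / (tr_a + tr_b)
    return float(1.0 - np.sqrt(max(arg, 0.0)))
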