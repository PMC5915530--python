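"""Cross-ensemble topological comparison of a peptide and its retro-D version.

The central object is the non-symmetric cross-RMSD matrix: every frame of
the parent ensemble is superposed on every frame of the retro-D ensemble
over an explicit atom correspondence in which residue ``i`` of the parent
maps to residue ``N+1-i`` of the retro-D peptide (the N-terminal residue
of one corresponds to the C-terminal residue of the other). Low matrix
minima mean the two stereochemically distinct molecules can adopt the
same three-dimensional arrangement.

Superposition uses proper rotations only (determinant +1): chirality is a
physical property of these molecules and must never be absorbed by a
reflection. A mirrored comparison is available as an explicitly flagged
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

import biotite.structure.info as struc_info

from .ensembles import Atom, ConformerEnsemble
from .errors import InputError, NumericalError
from .peptides import THREE_LETTER, PeptideSequence, check_retro_pair

#: Backbone heavy atoms in standard PDB nomenclature. The carbonyl O is
#: listed here so it is excluded from every mapping policy: the amide
#: direction reverses in a retro peptide, so carbonyl positions have no
#: analog under the residue correspondence.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

POLICIES = ("ca", "ca-sidechain", "all-heavy-swap")


# ---------------------------------------------------------------------------
# Atom correspondence


@dataclass(frozen=True)
class RetroAtomMap:
    """Explicit atom-pair correspondence under residue-index reversal.

    ``pairs[k] = (i_A, i_B)`` are flat atom indices into the parent (A)
    and retro-D (B) atom lists; ``weights`` are per-pair superposition
    weights (uniform or parent-atom mass).
    """

    pairs: tuple[tuple[int, int], ...]
    policy: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise InputError("empty atom map")
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise InputError("each atom may appear at most once in the map")
        object.__setattr__(
            self, "weights", np.asarray(self.weights, dtype=float)
        )
        if self.weights.shape != (len(self.pairs),):
            raise InputError("one weight per pair required")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise InputError("weights must be >= 0 and not all zero")

    @property
    def indices_a(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def indices_b(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)

    def inverted(self) -> "RetroAtomMap":
        """The same correspondence viewed from the retro-D side."""
        return RetroAtomMap(
            tuple((b, a) for a, b in self.pairs), self.policy, self.weights
        )


@lru_cache(maxsize=32)
def sidechain_heavy_atoms(residue_code: str) -> tuple[str, ...]:
    """Heavy side-chain atom names of a canonical residue (template lookup)."""
    res = struc_info.residue(THREE_LETTER[residue_code])
    names = []
    for name, elem in zip(res.atom_name, res.element):
        if elem == "H" or name in BACKBONE_ATOMS:
            continue
        names.append(str(name))
    return tuple(names)


def template_inventory(seq: PeptideSequence) -> tuple[Atom, ...]:
    """Full heavy-atom inventory for a sequence, from residue templates.

    Used to build small all-atom fixtures; coordinates are not assigned.
    """
    atoms: list[Atom] = []
    for i, res in enumerate(seq, start=1):
        res3 = THREE_LETTER[res.code]
        tmpl = struc_info.residue(res3)
        for name, elem in zip(tmpl.atom_name, tmpl.element):
            if elem == "H" or name == "OXT":
                continue
            atoms.append(
                Atom(
                    atom_name=str(name),
                    element=str(elem).capitalize(),
                    mass=float(struc_info.mass(str(elem).capitalize())),
                    residue_index=i,
                    residue_code=res.code,
                    chirality=res.chirality,
                )
            )
    return tuple(atoms)


def _inventory(atoms: Iterable[Atom] | ConformerEnsemble) -> dict[int, dict[str, tuple[int, Atom]]]:
    if isinstance(atoms, ConformerEnsemble):
        atoms = atoms.atoms
    inv: dict[int, dict[str, tuple[int, Atom]]] = {}
    for flat, a in enumerate(atoms):
        inv.setdefault(a.residue_index, {})[a.atom_name] = (flat, a)
    return inv


def build_retro_atom_map(
    parent_seq: PeptideSequence,
    retro_seq: PeptideSequence,
    parent_atoms: Iterable[Atom] | ConformerEnsemble,
    retro_atoms: Iterable[Atom] | ConformerEnsemble,
    policy: str = "ca-sidechain",
    weights: str = "uniform",
) -> RetroAtomMap:
    """Pair atoms of a parent peptide with its retro-D counterpart.

    Residue ``i`` of the parent is paired with residue ``N+1-i`` of the
    retro-D peptide (which carries the same side chain). Within a residue
    pair, Cα is always mapped; side-chain heavy atoms are matched by
    identical atom name; under ``all-heavy-swap`` the backbone N of one
    residue additionally maps to the backbone C of its analog (and vice
    versa), reflecting the reversed amide direction. Carbonyl O and amide
    H are never mapped.

    Parameters
    ----------
    policy : {"ca", "ca-sidechain", "all-heavy-swap"}
    weights : {"uniform", "mass"}
        Mass weights are taken from the parent-side atom.
    """
    if policy not in POLICIES:
        raise InputError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if weights not in ("uniform", "mass"):
        raise InputError("weights must be 'uniform' or 'mass'")
    check_retro_pair(parent_seq, retro_seq)
    inv_a = _inventory(parent_atoms)
    inv_b = _inventory(retro_atoms)
    n = len(parent_seq)
    pairs: list[tuple[int, int]] = []
    w: list[float] = []

    def add(entry_a, entry_b):
        pairs.append((entry_a[0], entry_b[0]))
        w.append(1.0 if weights == "uniform" else entry_a[1].mass)

    for i in range(1, n + 1):
        j = n + 1 - i
        res_a = inv_a.get(i, {})
        res_b = inv_b.get(j, {})
        if "CA" not in res_a or "CA" not in res_b:
            raise InputError(
                f"CA missing for parent residue {i} or retro residue {j}"
            )
        add(res_a["CA"], res_b["CA"])
        if policy in ("ca-sidechain", "all-heavy-swap"):
            code = parent_seq.residues[i - 1].code
            for name in sidechain_heavy_atoms(code):
                if name in res_a and name in res_b:
                    add(res_a[name], res_b[name])
            # coarse models carry a single side-chain centroid named CB
            if (
                "CB" in res_a
                and "CB" in res_b
                and not any(p == (res_a["CB"][0], res_b["CB"][0]) for p in pairs)
            ):
                add(res_a["CB"], res_b["CB"])
        if policy == "all-heavy-swap":
            if "N" in res_a and "C" in res_b:
                add(res_a["N"], res_b["C"])
            if "C" in res_a and "N" in res_b:
                add(res_a["C"], res_b["N"])
    return RetroAtomMap(tuple(pairs), policy, np.array(w))


def mapped_coordinates(
    ens: ConformerEnsemble, amap: RetroAtomMap, side: str
) -> np.ndarray:
    """Coordinates of the mapped atoms, in map pair order.

    ``side="A"`` (parent) or ``"B"`` (retro-D). Pair order puts both
    molecules' mapped atoms in a common index space, which is what the
    essential-dynamics comparison operates in.
    """
    if side == "A":
        idx = amap.indices_a
    elif side == "B":
        idx = amap.indices_b
    else:
        raise InputError("side must be 'A' or 'B'")
    if idx.max() >= ens.n_atoms:
        raise InputError("map refers to atoms beyond this ensemble")
    return ens.frames[:, idx, :]


# ---------------------------------------------------------------------------
# Superposition


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper-rotation fit of Y onto X."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector
    rmsd: float  # Å
    degenerate: bool  # collinear/coincident point set; rotation not unique


def kabsch_superpose(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Weighted least-squares superposition restricted to proper rotations.

    Finds the rotation ``R`` (det = +1) and translation ``t`` minimizing
    the weighted RMSD between ``x`` and ``R y + t``. Restricting to
    proper rotations means a structure and its mirror image do not
    superpose to zero: chirality is preserved, which is essential when
    comparing L- and D-peptides.

    Degenerate (collinear or coincident) point sets are flagged, not
    silently accepted: the optimal rotation is then not unique.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise InputError("x and y must both have shape (n, 3)")
    n = x.shape[0]
    if n < 3:
        raise InputError("superposition requires at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise InputError("one weight per point required")
        if np.any(w < 0) or not np.any(w > 0):
            raise InputError("weights must be >= 0 and not all zero")
    wsum = w.sum()
    xc = x - (w[:, None] * x).sum(0) / wsum
    yc = y - (w[:, None] * y).sum(0) / wsum
    h = (w[:, None] * yc).T @ xc  # maps y-space into x-space
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    if d == 0:
        d = 1.0
    corr = np.array([1.0, 1.0, d])
    rotation = (vt.T * corr) @ u.T
    # two vanishing singular values => points (near-)collinear
    scale = max(s[0], 1e-12)
    degenerate = bool(s[1] / scale < 1e-8)
    resid = xc - yc @ rotation.T
    msd = (w[:, None] * resid**2).sum() / wsum
    x_mean = (w[:, None] * x).sum(0) / wsum
    y_mean = (w[:, None] * y).sum(0) / wsum
    translation = x_mean - rotation @ y_mean
    return SuperpositionResult(rotation, translation, float(np.sqrt(msd)), degenerate)


def _pairwise_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    weights: np.ndarray,
    allow_reflection: bool = False,
    chunk: int = 64,
) -> np.ndarray:
    """All-against-all Kabsch RMSD between two frame sets sharing an atom
    correspondence (both already ordered pair-wise). Vectorized over frame
    pairs with batched 3x3 SVDs."""
    w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    a = coords_a - (w[None, :, None] * coords_a).sum(1, keepdims=True) / wsum
    b = coords_b - (w[None, :, None] * coords_b).sum(1, keepdims=True) / wsum
    wa = w[None, :, None] * a
    sq_a = (wa * a).sum(axis=(1, 2))
    sq_b = (w[None, :, None] * b * b).sum(axis=(1, 2))
    n_a, n_b = a.shape[0], b.shape[0]
    out = np.empty((n_a, n_b))
    for start in range(0, n_a, chunk):
        stop = min(start + chunk, n_a)
        h = np.einsum("ank,bnl->abkl", wa[start:stop], b)
        s = np.linalg.svd(h, compute_uv=False)
        if allow_reflection:
            tr = s.sum(-1)
        else:
            sign = np.where(np.linalg.det(h) < 0, -1.0, 1.0)
            tr = s[..., 0] + s[..., 1] + sign * s[..., 2]
        msd = (sq_a[start:stop, None] + sq_b[None, :] - 2.0 * tr) / wsum
        out[start:stop] = np.sqrt(np.maximum(msd, 0.0))
    return out


# ---------------------------------------------------------------------------
# Cross-RMSD


@dataclass(frozen=True)
class CrossRMSDResult:
    """Non-symmetric cross-RMSD matrix with its histogram and best pairing."""

    matrix: np.ndarray  # (n_A, n_B), Å
    frame_ids_a: np.ndarray
    frame_ids_b: np.ndarray
    bin_edges: np.ndarray  # Å
    counts: np.ndarray
    best_pair: tuple[int, int, float]  # (frame_A, frame_B, rmsd)

    @property
    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        return self.bin_edges, self.counts


def rmsd_histogram(
    matrix: np.ndarray, bin_width: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of all matrix entries in right-open bins ``[k·w, (k+1)·w)``.

    Bins start at zero and extend to ``ceil(max/w)·w``; counts always sum
    to the number of matrix entries.
    """
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    values = np.asarray(matrix, dtype=float).ravel()
    n_bins = max(int(np.ceil(values.max() / bin_width)), 1)
    if values.max() >= n_bins * bin_width:  # value exactly on the top edge
        n_bins += 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((values / bin_width).astype(int), n_bins - 1)
    # floor(v/w) can land one bin high for v just under an edge; correct it
    idx = np.where(values < idx * bin_width, idx - 1, idx)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts


def _best_pair(matrix: np.ndarray) -> tuple[int, int, float]:
    # lexicographically first among ties: C-order argmin already is
    flat = int(np.argmin(matrix))
    i, j = np.unravel_index(flat, matrix.shape)
    return int(i), int(j), float(matrix[i, j])


def cross_rmsd_matrix(
    ens_a: ConformerEnsemble,
    ens_b: ConformerEnsemble,
    amap: RetroAtomMap,
    bin_width: float = 0.25,
) -> CrossRMSDResult:
    """The non-symmetric frame-by-frame RMSD matrix between two ensembles.

    Entry ``(i, j)`` is the proper-rotation Kabsch RMSD between frame
    ``i`` of the parent ensemble and frame ``j`` of the retro-D ensemble
    over the mapped atoms with the map's weights. The best pairing is the
    matrix argmin (lowest ``(i, j)`` on ties).
    """
    ca = mapped_coordinates(ens_a, amap, "A")
    cb = mapped_coordinates(ens_b, amap, "B")
    matrix = _pairwise_rmsd(ca, cb, amap.weights)
    edges, counts = rmsd_histogram(matrix, bin_width)
    return CrossRMSDResult(
        matrix=matrix,
        frame_ids_a=np.arange(ens_a.n_frames),
        frame_ids_b=np.arange(ens_b.n_frames),
        bin_edges=edges,
        counts=counts,
        best_pair=_best_pair(matrix),
    )


def ranked_pairings(
    result: CrossRMSDResult, n: int = 10
) -> list[tuple[int, int, float]]:
    """The ``n`` lowest-RMSD frame pairings, ascending (ties by index)."""
    flat = result.matrix.ravel()
    order = np.lexsort((np.arange(flat.size), flat))[:n]
    out = []
    for k in order:
        i, j = np.unravel_index(int(k), result.matrix.shape)
        out.append((int(i), int(j), float(result.matrix[i, j])))
    return out


def mirror_cross_rmsd_matrix(
    ens_a: ConformerEnsemble, ens_b: ConformerEnsemble, amap: RetroAtomMap
) -> np.ndarray:
    """DIAGNOSTIC ONLY: cross-RMSD allowing improper (mirror) superposition.

    Reports how similar the ensembles would look if reflection were
    permitted. Never used in the mimicry verdict — a mirror fit has no
    physical realization for chiral molecules.
    """
    ca = mapped_coordinates(ens_a, amap, "A")
    cb = mapped_coordinates(ens_b, amap, "B")
    return _pairwise_rmsd(ca, cb, amap.weights, allow_reflection=True)


def self_rmsd_matrix(
    ens: ConformerEnsemble, mass_weighted: bool = True
) -> np.ndarray:
    """Symmetric 2D RMSD matrix of an ensemble against itself.

    Mass weighting (the default) uses atomic masses as superposition
    weights, matching the usual trajectory 2D-RMSD convention.
    """
    if ens.n_frames < 2:
        raise InputError("self-RMSD needs at least 2 frames")
    w = ens.masses if mass_weighted else np.ones(ens.n_atoms)
    m = _pairwise_rmsd(ens.frames, ens.frames, w)
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


def count_clusters(
    matrix: np.ndarray, cutoff: float = 2.0
) -> tuple[int, np.ndarray]:
    """Single-linkage cluster count of a symmetric self-RMSD matrix.

    Frames ``i`` and ``j`` join one cluster whenever ``M[i, j] <= cutoff``
    (transitively). This replaces a by-eye reading of the 2D RMSD plot
    with a deterministic criterion; labels are ordered by each cluster's
    first frame.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise InputError("matrix must be symmetric")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    adj = csr_matrix(m <= cutoff)
    n, raw = connected_components(adj, directed=False)
    # relabel so cluster ids follow first-frame order
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return int(n), labels
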