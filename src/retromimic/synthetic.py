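"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this kind of study are cluster-scale replica-exchange
simulations and animal sera — neither is reproducible at a desk. This
module generates structurally plausible stand-ins whose ground truth is
known exactly:

* a coarse peptide model (backbone N, CA, C plus one side-chain centroid
  per residue) built from canonical internal coordinates, with Cα
  chirality realized by the sign of the side-chain improper dihedral;
* a replica-exchange Metropolis sampler in (φ, ψ) torsion space under a
  chirality-aware multi-basin potential with a soft-sphere clash term —
  it emulates the *shape* of a replica-exchange run (temperature ladder,
  swap bookkeeping, multi-basin heterogeneity), not molecular physics;
  its energy scale is arbitrary;
* parent/retro-D ensemble pairs with controllable topological overlap
  (``mimic`` mode retro-constructs each parent frame geometrically, so
  the pair is superposable by construction up to added noise;
  ``independent`` mode samples the retro-D peptide in its own right);
* NMR shift tables (random-coil baseline + imposed deviations, amide
  temperature series, cis/trans species intensities);
* ELISA titration plates (logistic titration curves with per-animal
  amplitude variation and read noise).

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .ensembles import Atom, ConformerEnsemble
from .errors import InputError
from .nmr import load_random_coil
from .peptides import PeptideSequence, retro_d_transform
from .sero import TitrationSeries

#: Boltzmann constant in kcal/(mol·K), the sampler's energy unit system.
KB_KCAL_PER_MOL_K = 0.0019872041

# canonical backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_CA_CB = 1.53
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_C_CA_CB = 110.6
#: improper-like dihedral N(i)-C(i)-CA(i)-CB(i) realizing Calpha chirality;
#: sign flips between L and D.
CB_DIHEDRAL_L = -122.6
OMEGA = 180.0

ELEMENT_MASS = {"N": 14.007, "C": 12.011}

#: Side-chain masses (Da, heavy atoms + side-chain hydrogens) used for the
#: single-centroid pseudo-atom of each residue type.
SIDECHAIN_MASS = {
    "A": 15.03, "R": 100.14, "N": 58.06, "D": 59.04, "C": 47.10,
    "Q": 72.09, "E": 73.07, "G": 1.008, "H": 81.10, "I": 57.11,
    "L": 57.11, "K": 72.13, "M": 75.15, "F": 91.13, "P": 41.07,
    "S": 31.03, "T": 45.06, "W": 130.17, "Y": 107.13, "V": 43.09,
}

# (phi, psi) basin centers and mixture weights for an L-residue; a
# D-residue uses the mirrored centers. Alpha-helical, polyproline-II and
# extended-beta regions — enough multi-basin structure for the analysis
# stages to see heterogeneous ensembles.
L_BASINS = ((-63.0, -43.0, 0.40), (-75.0, 150.0, 0.35), (-120.0, 135.0, 0.25))
L_PRO_BASINS = ((-75.0, 150.0, 0.60), (-75.0, -30.0, 0.40))


def residue_basins(code: str, chirality: str) -> tuple[tuple[float, float, float], ...]:
    """Torsion basin centers/weights for one residue, chirality-aware."""
    base = L_PRO_BASINS if code == "P" else L_BASINS
    if chirality == "L":
        return base
    if chirality == "D":
        return tuple((-p, -q, w) for p, q, w in base)
    # glycine: achiral, both mirror halves accessible
    half = tuple((p, q, w / 2) for p, q, w in base)
    mirror = tuple((-p, -q, w / 2) for p, q, w in base)
    return half + mirror


# ---------------------------------------------------------------------------
# Geometry


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
          angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension reference frame: place atom D given A-B-C."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees) of four points about the p1-p2 axis."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone_and_centroids(
    seq: PeptideSequence, torsions: np.ndarray
) -> np.ndarray:
    """Coordinates for the coarse atom list of ``coarse_atoms(seq)``."""
    n_res = len(seq)
    # backbone trace with virtual C0 and N_{n+1} so every (phi, psi) is
    # realized, including phi_1 and psi_n
    c_prev = np.array([0.0, 0.0, 0.0])  # virtual C of residue 0
    n_cur = np.array([BOND_C_N, 0.0, 0.0])
    ca_cur = _nerf(
        np.array([0.0, 1.0, 0.0]), c_prev, n_cur, BOND_N_CA, ANGLE_C_N_CA, 0.0
    )
    coords: list[np.ndarray] = []
    bb_n, bb_ca, bb_c = [], [], []
    for i in range(n_res):
        phi, psi = torsions[i]
        c_cur = _nerf(c_prev, n_cur, ca_cur, BOND_CA_C, ANGLE_N_CA_C, phi)
        bb_n.append(n_cur)
        bb_ca.append(ca_cur)
        bb_c.append(c_cur)
        n_next = _nerf(n_cur, ca_cur, c_cur, BOND_C_N, ANGLE_CA_C_N, psi)
        if i < n_res - 1:
            ca_next = _nerf(ca_cur, c_cur, n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c_prev, n_cur, ca_cur = c_cur, n_next, ca_next
    for i, res in enumerate(seq):
        coords.append(bb_n[i])
        coords.append(bb_ca[i])
        coords.append(bb_c[i])
        if res.code != "G":
            sign = -1.0 if res.chirality == "D" else 1.0
            cb = _nerf(
                bb_n[i], bb_c[i], bb_ca[i], BOND_CA_CB, ANGLE_C_CA_CB,
                sign * abs(CB_DIHEDRAL_L),
            )
            coords.append(cb)
    return np.asarray(coords)


def coarse_atoms(seq: PeptideSequence) -> tuple[Atom, ...]:
    """Atom metadata of the coarse model: N, CA, C (+ CB centroid)."""
    atoms: list[Atom] = []
    for i, res in enumerate(seq, start=1):
        atoms.append(Atom("N", "N", ELEMENT_MASS["N"], i, res.code, res.chirality))
        atoms.append(Atom("CA", "C", ELEMENT_MASS["C"], i, res.code, res.chirality))
        atoms.append(Atom("C", "C", ELEMENT_MASS["C"], i, res.code, res.chirality))
        if res.code != "G":
            atoms.append(
                Atom("CB", "C", SIDECHAIN_MASS[res.code], i, res.code, res.chirality)
            )
    return tuple(atoms)


def build_peptide_coords(
    seq: PeptideSequence, torsions: np.ndarray
) -> ConformerEnsemble:
    """Build a single-frame coarse ensemble from per-residue (φ, ψ).

    Bond lengths and angles take canonical values; ω is fixed trans.
    Side chains are single pseudo-atom centroids ("CB") whose placement
    sign realizes the per-residue L/D annotation: the improper dihedral
    N-CA-C-CB flips sign between enantiomeric residues.
    """
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape != (len(seq), 2):
        raise InputError(
            f"torsions must have shape ({len(seq)}, 2), got {torsions.shape}"
        )
    coords = _backbone_and_centroids(seq, torsions)
    return ConformerEnsemble(coarse_atoms(seq), coords[None, :, :])


def build_ensemble(seq: PeptideSequence, torsion_sets: np.ndarray) -> ConformerEnsemble:
    """Build a multi-frame coarse ensemble from (n_frames, n_res, 2) torsions."""
    torsion_sets = np.asarray(torsion_sets, dtype=float)
    frames = np.stack(
        [_backbone_and_centroids(seq, t) for t in torsion_sets]
    )
    return ConformerEnsemble(coarse_atoms(seq), frames)


def measure_torsions(ens: ConformerEnsemble) -> np.ndarray:
    """Measure (φ, ψ) from coarse-model coordinates of a single frame.

    φ of the first residue and ψ of the last need atoms outside the
    chain and are returned as NaN.
    """
    if ens.n_frames != 1:
        raise InputError("measure_torsions expects a single-frame ensemble")
    f = ens.frames[0]
    idx = {(a.residue_index, a.atom_name): k for k, a in enumerate(ens.atoms)}
    n_res = max(a.residue_index for a in ens.atoms)
    out = np.full((n_res, 2), np.nan)
    for i in range(1, n_res + 1):
        n_i, ca_i, c_i = (idx[(i, x)] for x in ("N", "CA", "C"))
        if (i - 1, "C") in idx:
            out[i - 1, 0] = dihedral_angle(
                f[idx[(i - 1, "C")]], f[n_i], f[ca_i], f[c_i]
            )
        if (i + 1, "N") in idx:
            out[i - 1, 1] = dihedral_angle(
                f[n_i], f[ca_i], f[c_i], f[idx[(i + 1, "N")]]
            )
    return out


def improper_sign(ens: ConformerEnsemble, residue_index: int, frame: int = 0) -> float:
    """Sign of the N-CA-C-CB improper dihedral (Cα handedness probe)."""
    f = ens.frames[frame]
    pts = [
        f[ens.atom_index(residue_index, name)] for name in ("N", "CA", "C", "CB")
    ]
    return float(np.sign(dihedral_angle(*pts)))


# ---------------------------------------------------------------------------
# Replica-exchange torsion sampler


@dataclass
class ToySamplerConfig:
    """Configuration of the toy replica-exchange sampler.

    Defaults mirror the shape of a published replica-exchange setup at
    desk scale: a geometric 300-500 K ladder (8 replicas instead of 16),
    periodic swap attempts, tens of thousands of Metropolis steps. The
    energy scale is arbitrary — this sampler provides realistically
    heterogeneous multi-basin ensembles for the analysis stages, not
    physics.
    """

    sequence: PeptideSequence
    n_replicas: int = 8
    t_min: float = 300.0
    t_max: float = 500.0
    swap_interval: int = 50
    n_steps: int = 20_000
    sample_interval: int = 50
    seed: int = 0
    basin_width_deg: float = 20.0
    basin_depth_kcal: float = 1.5
    clash_scale_kcal: float = 0.5
    clash_r0: float = 4.0
    step_deg: float = 25.0
    #: optional override: E(torsions_deg flat array) in kcal/mol; when set,
    #: the basin + clash terms are not used (handy for exact checks such as
    #: a single harmonic torsion).
    potential: Callable[[np.ndarray], float] | None = None

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise InputError("need at least one replica")
        if self.t_min > self.t_max:
            raise InputError("t_min must be <= t_max")
        if self.n_steps < 1 or self.swap_interval < 1 or self.sample_interval < 1:
            raise InputError("step counts must be positive")

    @property
    def temperatures(self) -> np.ndarray:
        """Strictly increasing geometric ladder from t_min to t_max."""
        if self.n_replicas == 1:
            return np.array([self.t_min])
        return self.t_min * (self.t_max / self.t_min) ** (
            np.arange(self.n_replicas) / (self.n_replicas - 1)
        )


@dataclass(frozen=True)
class SwapStats:
    """Replica-swap bookkeeping for one adjacent temperature pair."""

    pair: tuple[int, int]
    attempts: int
    accepted: int
    mean_analytic_prob: float

    @property
    def empirical_rate(self) -> float:
        return self.accepted / self.attempts if self.attempts else float("nan")


@dataclass(frozen=True)
class RemdResult:
    """Sampler output: per-temperature ensembles plus swap statistics."""

    ensembles: dict[float, ConformerEnsemble]
    torsion_traces: dict[float, np.ndarray]  # (n_samples, n_res, 2) deg
    swap_stats: tuple[SwapStats, ...]
    acceptance_overall: float


def _wrap(deg: np.ndarray | float) -> np.ndarray | float:
    return (deg + 180.0) % 360.0 - 180.0


class _TorsionPotential:
    """Chirality-aware multi-basin torsion energy + CA soft-sphere clash."""

    def __init__(self, cfg: ToySamplerConfig):
        self.cfg = cfg
        seq = cfg.sequence
        self.centers: list[np.ndarray] = []
        self.logw: list[np.ndarray] = []
        for res in seq:
            basins = residue_basins(res.code, res.chirality)
            self.centers.append(np.array([(p, q) for p, q, _ in basins]))
            self.logw.append(np.log(np.array([w for _, _, w in basins])))
        self.two_w2 = 2.0 * cfg.basin_width_deg**2
        self.use_clash = cfg.clash_scale_kcal > 0 and len(seq) >= 4
        self.seq = seq

    def torsion_energy(self, torsions: np.ndarray) -> float:
        e = 0.0
        for i, (centers, logw) in enumerate(zip(self.centers, self.logw)):
            d = _wrap(torsions[i][None, :] - centers)
            arg = logw - (d**2).sum(axis=1) / self.two_w2
            e -= self.cfg.basin_depth_kcal * float(
                np.logaddexp.reduce(np.append(arg, -12.0))
            )
        return e

    def clash_energy(self, torsions: np.ndarray) -> float:
        coords = _backbone_and_centroids(self.seq, torsions)
        # CA atoms sit at positions 1, 5, 9, ... only if every residue has
        # a CB; recover their indices from the atom list layout instead
        ca_idx = []
        k = 0
        for res in self.seq:
            ca_idx.append(k + 1)
            k += 3 if res.code == "G" else 4
        ca = coords[ca_idx]
        diff = ca[:, None, :] - ca[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        n = len(ca_idx)
        ii, jj = np.triu_indices(n, k=3)
        overlap = np.clip(self.cfg.clash_r0 - dist[ii, jj], 0.0, None)
        return self.cfg.clash_scale_kcal * float((overlap**2).sum())

    def __call__(self, torsions: np.ndarray) -> float:
        if self.cfg.potential is not None:
            return float(self.cfg.potential(np.asarray(torsions).ravel()))
        e = self.torsion_energy(torsions)
        if self.use_clash:
            e += self.clash_energy(torsions)
        return e


def remd_sample(cfg: ToySamplerConfig) -> RemdResult:
    """Replica-exchange Metropolis sampling in torsion space.

    Each replica performs single-torsion Gaussian moves accepted by the
    Metropolis criterion at its own temperature; every ``swap_interval``
    steps, adjacent temperature pairs (alternating even/odd pairings)
    attempt a configuration exchange accepted with probability
    ``min(1, exp[(β_i - β_j)(E_i - E_j)])``. Alongside the empirical
    acceptance count, the analytic acceptance probability of every
    attempt is accumulated, so the Metropolis bookkeeping can be checked
    against its own trajectory average. Fully deterministic given the
    seed.
    """
    rng = np.random.default_rng(cfg.seed)
    temps = cfg.temperatures
    betas = 1.0 / (KB_KCAL_PER_MOL_K * temps)
    n_rep = cfg.n_replicas
    n_res = len(cfg.sequence)
    energy = _TorsionPotential(cfg)

    # initialize each replica at a random basin center per residue
    states = np.empty((n_rep, n_res, 2))
    for r in range(n_rep):
        for i, res in enumerate(cfg.sequence):
            basins = residue_basins(res.code, res.chirality)
            p, q, _ = basins[rng.integers(len(basins))]
            states[r, i] = (p, q)
    energies = np.array([energy(states[r]) for r in range(n_rep)])

    traces: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    attempts = np.zeros(max(n_rep - 1, 1), dtype=int)
    accepted = np.zeros(max(n_rep - 1, 1), dtype=int)
    analytic = np.zeros(max(n_rep - 1, 1))
    move_acc = 0
    move_tot = 0
    swap_phase = 0

    for step in range(1, cfg.n_steps + 1):
        for r in range(n_rep):
            i = int(rng.integers(n_res))
            j = int(rng.integers(2))
            proposal = states[r].copy()
            proposal[i, j] = _wrap(proposal[i, j] + rng.normal(0.0, cfg.step_deg))
            e_new = energy(proposal)
            move_tot += 1
            if e_new <= energies[r] or rng.random() < np.exp(
                -betas[r] * (e_new - energies[r])
            ):
                states[r] = proposal
                energies[r] = e_new
                move_acc += 1
        if n_rep > 1 and step % cfg.swap_interval == 0:
            for lo in range(swap_phase % 2, n_rep - 1, 2):
                hi = lo + 1
                delta = (betas[lo] - betas[hi]) * (energies[lo] - energies[hi])
                prob = min(1.0, float(np.exp(min(delta, 50.0))))
                attempts[lo] += 1
                analytic[lo] += prob
                if rng.random() < prob:
                    accepted[lo] += 1
                    states[[lo, hi]] = states[[hi, lo]]
                    energies[[lo, hi]] = energies[[hi, lo]]
            swap_phase += 1
        if step % cfg.sample_interval == 0:
            for r in range(n_rep):
                traces[r].append(states[r].copy())

    stats = tuple(
        SwapStats(
            pair=(k, k + 1),
            attempts=int(attempts[k]),
            accepted=int(accepted[k]),
            mean_analytic_prob=float(analytic[k] / attempts[k])
            if attempts[k]
            else float("nan"),
        )
        for k in range(n_rep - 1)
    )
    trace_arrays = {
        float(temps[r]): np.array(traces[r]) for r in range(n_rep)
    }
    ensembles = {
        t: build_ensemble(cfg.sequence, arr)
        for t, arr in trace_arrays.items()
        if len(arr)
    }
    return RemdResult(
        ensembles=ensembles,
        torsion_traces=trace_arrays,
        swap_stats=stats,
        acceptance_overall=move_acc / move_tot if move_tot else float("nan"),
    )


# ---------------------------------------------------------------------------
# Mimic-pair generator


def retro_relabel(parent: ConformerEnsemble, parent_seq: PeptideSequence) -> ConformerEnsemble:
    """Exact geometric retro-construction of every parent frame.

    The retro-D molecule is built on the *same* point set read in the
    opposite chain direction: retro residue ``j`` takes its CA and
    side-chain centroid from parent residue ``N+1-j``, and its backbone N
    and C from the parent's C and N respectively. Reversing the chain
    direction on fixed coordinates inverts every Cα configuration, so
    the result is a genuine retro-D conformer superposable on the parent
    by construction.
    """
    retro_seq = retro_d_transform(parent_seq)
    n = len(parent_seq)
    order: list[int] = []
    for j in range(1, n + 1):
        i = n + 1 - j
        order.append(parent.atom_index(i, "C"))  # retro N
        order.append(parent.atom_index(i, "CA"))
        order.append(parent.atom_index(i, "N"))  # retro C
        if parent_seq.residues[i - 1].code != "G":
            order.append(parent.atom_index(i, "CB"))
    atoms = []
    k = 0
    for j, res in enumerate(retro_seq, start=1):
        atoms.append(Atom("N", "N", ELEMENT_MASS["N"], j, res.code, res.chirality))
        atoms.append(Atom("CA", "C", ELEMENT_MASS["C"], j, res.code, res.chirality))
        atoms.append(Atom("C", "C", ELEMENT_MASS["C"], j, res.code, res.chirality))
        if res.code != "G":
            atoms.append(
                Atom("CB", "C", SIDECHAIN_MASS[res.code], j, res.code, res.chirality)
            )
    return ConformerEnsemble(tuple(atoms), parent.frames[:, order, :].copy())


def _sample_basin_torsions(
    seq: PeptideSequence, n_frames: int, rng: np.random.Generator,
    jitter_deg: float = 12.0, dirichlet_alpha: float = 0.5,
) -> np.ndarray:
    """Draw per-frame torsions from per-residue basin mixtures whose
    weights are themselves drawn once per ensemble (so different seeds
    yield genuinely different conformational distributions)."""
    torsions = np.empty((n_frames, len(seq), 2))
    for i, res in enumerate(seq):
        basins = residue_basins(res.code, res.chirality)
        weights = rng.dirichlet(np.full(len(basins), dirichlet_alpha))
        choice = rng.choice(len(basins), size=n_frames, p=weights)
        centers = np.array([(p, q) for p, q, _ in basins])[choice]
        torsions[:, i, :] = _wrap(
            centers + rng.normal(0.0, jitter_deg, size=(n_frames, 2))
        )
    return torsions


def make_mimic_pair(
    seq: PeptideSequence,
    overlap_mode: str = "mimic",
    noise_sigma: float = 0.5,
    n_frames: int = 100,
    seed: int = 0,
) -> tuple[ConformerEnsemble, ConformerEnsemble, dict]:
    """A parent/retro-D ensemble pair with known topological overlap.

    ``mimic`` mode retro-constructs every parent frame geometrically and
    adds isotropic Gaussian coordinate noise of ``noise_sigma`` Å — the
    pair is then superposable by construction up to that noise.
    ``independent`` mode samples the retro-D peptide as a molecule in its
    own right from a fresh seed (its D-residues prefer the mirrored
    torsion basins), so the two ensembles share no construction.

    Returns (parent ensemble, retro-D ensemble, ground-truth record).
    """
    if overlap_mode not in ("mimic", "independent"):
        raise InputError(f"unknown overlap_mode {overlap_mode!r}")
    if any(r.chirality == "D" for r in seq):
        raise InputError("make_mimic_pair expects an all-L (or Gly) parent")
    rng = np.random.default_rng(seed)
    parent_torsions = _sample_basin_torsions(seq, n_frames, rng)
    parent = build_ensemble(seq, parent_torsions)
    if overlap_mode == "mimic":
        retro = retro_relabel(parent, seq)
        if noise_sigma > 0:
            retro = ConformerEnsemble(
                retro.atoms,
                retro.frames
                + rng.normal(0.0, noise_sigma, size=retro.frames.shape),
            )
    else:
        retro_seq = retro_d_transform(seq)
        rng_b = np.random.default_rng(np.random.default_rng(seed + 1).integers(2**31))
        retro_torsions = _sample_basin_torsions(retro_seq, n_frames, rng_b)
        retro = build_ensemble(retro_seq, retro_torsions)
    truth = {
        "mode": overlap_mode,
        "noise_sigma": noise_sigma,
        "seed": seed,
        "n_frames": n_frames,
    }
    return parent, retro, truth


# ---------------------------------------------------------------------------
# NMR and ELISA generators


def gen_shift_table(
    seq: PeptideSequence,
    true_csd: dict[tuple[int, str], float] | None = None,
    cis_fraction: float = 0.0,
    noise_sigma: float = 0.0,
    temperatures: tuple[float, ...] = (278.0, 283.0, 288.0, 293.0, 298.0, 303.0, 308.0),
    hn_slopes_ppb_per_k: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Synthetic shift table: random-coil baseline plus imposed structure.

    ``true_csd`` maps (residue_index, nucleus) to the deviation (ppm) to
    impose; unlisted entries are random coil. HA/CA/CB shifts are emitted
    at 298 K; HN shifts across ``temperatures`` with per-residue true
    slopes (default -7 ppb/K) anchored so the 298 K value equals
    RC + CSD. With ``cis_fraction > 0`` a minor species is emitted with a
    fixed +0.10 ppm offset, and the returned intensity record integrates
    to the stated cis/trans ratio. At ``noise_sigma = 0`` every analysis
    stage recovers the imposed ground truth exactly.
    """
    if not 0.0 <= cis_fraction < 1.0:
        raise InputError("cis_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rc = load_random_coil()
    rc_lookup = {(r.residue_code, r.nucleus): r.shift_ppm for r in rc.itertuples()}
    true_csd = true_csd or {}
    slopes = hn_slopes_ppb_per_k or {}
    rows = []
    species_list = ["major"] + (["minor"] if cis_fraction > 0 else [])
    for i, res in enumerate(seq, start=1):
        for nucleus in ("HA", "CA", "CB"):
            key = (res.code, nucleus)
            if key not in rc_lookup:
                continue  # Gly has no CB
            base = rc_lookup[key] + true_csd.get((i, nucleus), 0.0)
            for species in species_list:
                offset = 0.10 if species == "minor" else 0.0
                rows.append(
                    {
                        "residue_index": i,
                        "residue_code": res.code,
                        "nucleus": nucleus,
                        "species": species,
                        "temperature_K": 298.0,
                        "shift_ppm": base
                        + offset
                        + rng.normal(0.0, noise_sigma),
                    }
                )
        if (res.code, "HN") in rc_lookup:
            slope = slopes.get(i, -7.0) / 1000.0  # ppm/K
            anchor = rc_lookup[(res.code, "HN")] + true_csd.get((i, "HN"), 0.0)
            for temp in temperatures:
                rows.append(
                    {
                        "residue_index": i,
                        "residue_code": res.code,
                        "nucleus": "HN",
                        "species": "major",
                        "temperature_K": float(temp),
                        "shift_ppm": anchor
                        + slope * (temp - 298.0)
                        + rng.normal(0.0, noise_sigma),
                    }
                )
    intensities = {"trans": 1.0 - cis_fraction, "cis": cis_fraction}
    return pd.DataFrame(rows), intensities


def gen_titration(
    group_params: dict[tuple[str, str], dict],
    n_animals: int = 4,
    n_dilutions: int = 10,
    start_dilution: float = 100.0,
    animal_sd: float = 0.2,
    read_noise: float = 0.02,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], TitrationSeries], dict]:
    """Synthetic ELISA plates on a two-fold dilution grid from 1:100.

    Each (group, bleed) gets parameters ``amplitude``, ``ec50`` (dilution
    at half-maximal OD), ``hill`` and ``background``; the titration curve
    is ``OD(d) = background + A_a / (1 + (d/ec50)^hill)`` with per-animal
    amplitude ``A_a`` log-normally scattered (σ = ``animal_sd`` in log
    space) and additive Gaussian read noise. Defaults emulate a four-
    mouse-per-group study read over ten doubling dilutions. Ground truth
    (including realized per-animal amplitudes) is returned alongside.
    """
    rng = np.random.default_rng(seed)
    grid = start_dilution * 2.0 ** np.arange(n_dilutions)
    series = {}
    truth: dict = {"grid": grid.tolist(), "groups": {}}
    for (group, bleed), params in sorted(group_params.items()):
        amp = float(params.get("amplitude", 1.0))
        ec50 = float(params.get("ec50", 800.0))
        hill = float(params.get("hill", 1.5))
        background = float(params.get("background", 0.05))
        rows = []
        animal_amps = {}
        for a in range(1, n_animals + 1):
            a_amp = amp * float(np.exp(rng.normal(0.0, animal_sd))) if amp > 0 else 0.0
            animal_amps[f"m{a}"] = a_amp
            mean_od = background + a_amp / (1.0 + (grid / ec50) ** hill)
            noise = rng.normal(0.0, read_noise, size=grid.size) if read_noise > 0 else 0.0
            od = np.clip(mean_od + noise, 0.0, None)
            for d, v in zip(grid, od):
                rows.append(
                    {"animal_id": f"m{a}", "dilution_factor": d, "od450": v}
                )
        series[(group, bleed)] = TitrationSeries(
            group, bleed, pd.DataFrame(rows)
        )
        truth["groups"][f"{group}/{bleed}"] = {
            "amplitude": amp,
            "ec50": ec50,
            "hill": hill,
            "background": background,
            "animal_amplitudes": animal_amps,
        }
    return series, truth


def gen_stability_curve(
    rate_per_h: float,
    plateau: float = 0.0,
    n_points: int = 8,
    t_max_h: float = 24.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic serum-stability time course (% intact vs hours).

    ``rate_per_h = 0`` gives the flat curve of a protease-resistant
    D-peptide; positive rates give one-phase decay from 100%.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max_h, n_points)
    span = 100.0 - plateau
    y = plateau + span * np.exp(-rate_per_h * t)
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=t.size)
    return t, y
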