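"""Cα Gō-type Hamiltonian and Metropolis Monte-Carlo sampler.

The synthetic-data engine of the pipeline: a structure-based
(Gō) model in which only native contacts attract, giving cooperative
two-state folding with a melting temperature controlled by the contact
well depth ε.  Energies are in kJ/mol, distances in Å, temperatures
in K (kB = 0.0083145 kJ/mol/K).

The Hamiltonian has three terms:

* native contacts — the classic 12-10 Gō well, per pair
  ``w·ε·[5(r0/r)^12 − 6(r0/r)^10]``, minimum exactly −w·ε at r = r0;
* chain connectivity — harmonic bonds ``½·k·(r − b0)²`` between
  sequence neighbours, with per-bond reference lengths taken from the
  native structure when available (scalar default 3.8 Å otherwise),
  plus a bending term ``½·k_a·(cosθ − cosθ0)²`` restraining each
  virtual bond angle to its native value (β-strands are stiff; the
  bending term is what makes unfolding cooperative rather than a
  gradual per-residue fraying).  Both are reported together as the
  bonded energy; the angle term is active only when a native reference
  is supplied;
* excluded volume — truncated-and-shifted soft repulsion
  ``ε·[(σ/r)^12 − 1]`` for non-native, non-bonded pairs closer than σ.

Sampling is single-bead Metropolis Monte Carlo (Gaussian displacement
or crankshaft rotation about the axis through the two flanking beads,
picked at random with equal probability); one sweep is N attempted
moves.  Time is measured in sweeps.  A ``hamiltonian_scale`` factor λ
multiplies the whole (solute) energy in the acceptance rule, which is
how replica exchange with solute scaling reuses this sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .structure_io import ContactMap

KB = 0.0083145  # kJ/mol/K

__all__ = [
    "KB",
    "GoParameters",
    "Conformation",
    "EnergyBreakdown",
    "GoSystem",
    "compute_energy",
    "propagate_mc",
]


@dataclass(frozen=True)
class GoParameters:
    """Parameters of the Cα Gō Hamiltonian and the MC move set.

    ``epsilon`` sets the energy scale and hence the melting temperature
    of a given topology; the default was calibrated once so that the
    bundled 85-residue barrel fixture melts inside the default
    300–698 K ladder.
    """

    epsilon: float = 4.5          # kJ/mol, contact well depth
    bond_k: float = 40.0          # kJ/mol/Å²
    bond_r0: float = 3.8          # Å, fallback when no native bond lengths
    excluded_sigma: float = 3.0   # Å
    angle_k: float = 15.0         # kJ/mol, harmonic in cos(angle) vs native
    kB: float = KB                # kJ/mol/K
    step_sigma: float = 0.35      # Å, Gaussian displacement SD
    crank_max_angle: float = 1.5  # rad, crankshaft angle ~ U(−a, a)

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.bond_k <= 0 or self.excluded_sigma <= 0:
            raise ValueError("epsilon, bond_k, excluded_sigma must be positive")


@dataclass(frozen=True)
class Conformation:
    """One chain conformation with an MC time stamp (in sweeps)."""

    coordinates: np.ndarray   # (n, 3) Å
    step_index: int = 0

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", xyz)
        if xyz.ndim != 2 or xyz.shape[1] != 3 or not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be a finite (n, 3) array")


@dataclass(frozen=True)
class EnergyBreakdown:
    e_native: float
    e_bond: float
    e_excluded: float

    @property
    def e_total(self) -> float:
        return self.e_native + self.e_bond + self.e_excluded


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True, inline="always")
def _cos3(ax, ay, az, bx, by, bz, cx, cy, cz):
    # cosine of the angle at the middle point b
    ux, uy, uz = ax - bx, ay - by, az - bz
    vx, vy, vz = cx - bx, cy - by, cz - bz
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    if nu < 1e-12 or nv < 1e-12:
        return 1.0
    return (ux * vx + uy * vy + uz * vz) / (nu * nv)


@njit(cache=True, fastmath=True)
def _cos_angle(coords, j):
    return _cos3(
        coords[j - 1, 0], coords[j - 1, 1], coords[j - 1, 2],
        coords[j, 0], coords[j, 1], coords[j, 2],
        coords[j + 1, 0], coords[j + 1, 1], coords[j + 1, 2],
    )


@njit(cache=True, fastmath=True)
def _full_energy(coords, nat_mask, nat_r0, nat_w, b0, eps, bond_k, sigma,
                 angle_k, cos_theta0):
    n = coords.shape[0]
    e_nat = 0.0
    e_bond = 0.0
    e_exc = 0.0
    sigma2 = sigma * sigma
    if angle_k > 0.0:
        for j in range(1, n - 1):
            d = _cos_angle(coords, j) - cos_theta0[j - 1]
            e_bond += 0.5 * angle_k * d * d
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if j == i + 1:
                r = math.sqrt(r2)
                d = r - b0[i]
                e_bond += 0.5 * bond_k * d * d
            elif nat_mask[i, j]:
                if r2 < 1e-18:
                    return 1e30, 1e30, 1e30
                x2 = nat_r0[i, j] * nat_r0[i, j] / r2
                x10 = x2 * x2 * x2 * x2 * x2
                e_nat += nat_w[i, j] * eps * (5.0 * x10 * x2 - 6.0 * x10)
            elif r2 < sigma2:
                if r2 < 1e-18:
                    return 1e30, 1e30, 1e30
                s2 = sigma2 / r2
                e_exc += eps * (s2 * s2 * s2 * s2 * s2 * s2 - 1.0)
    return e_nat, e_bond, e_exc


@njit(cache=True, fastmath=True)
def _bead_energy(coords, i, pos, nat_mask, nat_r0, nat_w, b0, eps, bond_k, sigma,
                 angle_k, cos_theta0):
    """Interaction energy of bead i placed at ``pos`` with all others,
    including the bending terms that involve bead i."""
    n = coords.shape[0]
    e = 0.0
    sigma2 = sigma * sigma
    if angle_k > 0.0:
        px, py, pz = pos[0], pos[1], pos[2]
        if i >= 2:      # angle centred at i-1: beads i-2, i-1, i
            c = _cos3(coords[i - 2, 0], coords[i - 2, 1], coords[i - 2, 2],
                      coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2],
                      px, py, pz)
            d = c - cos_theta0[i - 2]
            e += 0.5 * angle_k * d * d
        if 1 <= i <= n - 2:  # angle centred at i
            c = _cos3(coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2],
                      px, py, pz,
                      coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2])
            d = c - cos_theta0[i - 1]
            e += 0.5 * angle_k * d * d
        if i <= n - 3:  # angle centred at i+1: beads i, i+1, i+2
            c = _cos3(px, py, pz,
                      coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2],
                      coords[i + 2, 0], coords[i + 2, 1], coords[i + 2, 2])
            d = c - cos_theta0[i]
            e += 0.5 * angle_k * d * d
    for j in range(n):
        if j == i:
            continue
        dx = pos[0] - coords[j, 0]
        dy = pos[1] - coords[j, 1]
        dz = pos[2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if j == i - 1 or j == i + 1:
            r = math.sqrt(r2)
            d = r - b0[min(i, j)]
            e += 0.5 * bond_k * d * d
        else:
            a, b = (i, j) if i < j else (j, i)
            if nat_mask[a, b]:
                if r2 < 1e-18:
                    return 1e30
                x2 = nat_r0[a, b] * nat_r0[a, b] / r2
                x10 = x2 * x2 * x2 * x2 * x2
                e += nat_w[a, b] * eps * (5.0 * x10 * x2 - 6.0 * x10)
            elif r2 < sigma2:
                if r2 < 1e-18:
                    return 1e30
                s2 = sigma2 / r2
                e += eps * (s2 * s2 * s2 * s2 * s2 * s2 - 1.0)
    return e


@njit(cache=True, fastmath=True)
def _move_delta(coords, i, px, py, pz, nat_mask, nat_r0, nat_w, b0, eps,
                bond_k, sigma, angle_k, cos_theta0):
    """Energy change of moving bead i to (px, py, pz), one fused pass."""
    n = coords.shape[0]
    de = 0.0
    sigma2 = sigma * sigma
    ox, oy, oz = coords[i, 0], coords[i, 1], coords[i, 2]
    if angle_k > 0.0:
        for j in range(max(1, i - 1), min(n - 1, i + 2)):
            ax, ay, az = coords[j - 1, 0], coords[j - 1, 1], coords[j - 1, 2]
            bx, by, bz = coords[j, 0], coords[j, 1], coords[j, 2]
            cx, cy, cz = coords[j + 1, 0], coords[j + 1, 1], coords[j + 1, 2]
            d_old = _cos3(ax, ay, az, bx, by, bz, cx, cy, cz) - cos_theta0[j - 1]
            if j - 1 == i:
                ax, ay, az = px, py, pz
            elif j == i:
                bx, by, bz = px, py, pz
            else:
                cx, cy, cz = px, py, pz
            d_new = _cos3(ax, ay, az, bx, by, bz, cx, cy, cz) - cos_theta0[j - 1]
            de += 0.5 * angle_k * (d_new * d_new - d_old * d_old)
    for j in range(n):
        if j == i:
            continue
        qx, qy, qz = coords[j, 0], coords[j, 1], coords[j, 2]
        dxn = px - qx
        dyn = py - qy
        dzn = pz - qz
        r2n = dxn * dxn + dyn * dyn + dzn * dzn
        dxo = ox - qx
        dyo = oy - qy
        dzo = oz - qz
        r2o = dxo * dxo + dyo * dyo + dzo * dzo
        if j == i - 1 or j == i + 1:
            ref = b0[min(i, j)]
            dn = math.sqrt(r2n) - ref
            do = math.sqrt(r2o) - ref
            de += 0.5 * bond_k * (dn * dn - do * do)
        elif nat_mask[i, j]:
            if r2n < 1e-18 or r2o < 1e-18:
                return 1e30
            rr = nat_r0[i, j] * nat_r0[i, j]
            x2 = rr / r2n
            x10 = x2 * x2 * x2 * x2 * x2
            y2 = rr / r2o
            y10 = y2 * y2 * y2 * y2 * y2
            de += nat_w[i, j] * eps * (5.0 * (x10 * x2 - y10 * y2) - 6.0 * (x10 - y10))
        else:
            if r2n < sigma2:
                if r2n < 1e-18:
                    return 1e30
                s2 = sigma2 / r2n
                de += eps * (s2 * s2 * s2 * s2 * s2 * s2 - 1.0)
            if r2o < sigma2:
                if r2o < 1e-18:
                    return 1e30
                s2 = sigma2 / r2o
                de -= eps * (s2 * s2 * s2 * s2 * s2 * s2 - 1.0)
    return de


@njit(cache=True, fastmath=True)
def _run_mc(coords, n_sweeps, record_every, beta_eff, step_sigma, crank_max,
            nat_mask, nat_r0, nat_w, b0, eps, bond_k, sigma, angle_k,
            cos_theta0, seed):
    np.random.seed(seed)
    n = coords.shape[0]
    n_rec = n_sweeps // record_every + 1
    rec = np.empty((n_rec, n, 3))
    rec_steps = np.empty(n_rec, dtype=np.int64)
    rec[0] = coords
    rec_steps[0] = 0
    k_rec = 1
    n_acc = 0
    pos_new = np.empty(3)
    for sweep in range(1, n_sweeps + 1):
        for _ in range(n):
            i = np.random.randint(0, n)
            use_crank = np.random.random() < 0.5 and 0 < i < n - 1
            if use_crank:
                ax = coords[i + 1] - coords[i - 1]
                an = math.sqrt(ax[0] ** 2 + ax[1] ** 2 + ax[2] ** 2)
                if an < 1e-9:
                    use_crank = False
            if use_crank:
                ux, uy, uz = ax[0] / an, ax[1] / an, ax[2] / an
                vx = coords[i, 0] - coords[i - 1, 0]
                vy = coords[i, 1] - coords[i - 1, 1]
                vz = coords[i, 2] - coords[i - 1, 2]
                phi = (2.0 * np.random.random() - 1.0) * crank_max
                c, s = math.cos(phi), math.sin(phi)
                dot = ux * vx + uy * vy + uz * vz
                cx = uy * vz - uz * vy
                cy = uz * vx - ux * vz
                cz = ux * vy - uy * vx
                pos_new[0] = coords[i - 1, 0] + vx * c + cx * s + ux * dot * (1.0 - c)
                pos_new[1] = coords[i - 1, 1] + vy * c + cy * s + uy * dot * (1.0 - c)
                pos_new[2] = coords[i - 1, 2] + vz * c + cz * s + uz * dot * (1.0 - c)
            else:
                pos_new[0] = coords[i, 0] + np.random.normal(0.0, step_sigma)
                pos_new[1] = coords[i, 1] + np.random.normal(0.0, step_sigma)
                pos_new[2] = coords[i, 2] + np.random.normal(0.0, step_sigma)
            de = _move_delta(coords, i, pos_new[0], pos_new[1], pos_new[2],
                             nat_mask, nat_r0, nat_w, b0, eps, bond_k, sigma,
                             angle_k, cos_theta0)
            if de <= 0.0 or np.random.random() < math.exp(-beta_eff * de):
                coords[i, 0] = pos_new[0]
                coords[i, 1] = pos_new[1]
                coords[i, 2] = pos_new[2]
                n_acc += 1
        if sweep % record_every == 0:
            rec[k_rec] = coords
            rec_steps[k_rec] = sweep
            k_rec += 1
    return rec[:k_rec], rec_steps[:k_rec], n_acc


# ---------------------------------------------------------------------------
# python surface
# ---------------------------------------------------------------------------


@dataclass
class GoSystem:
    """Dense pairwise tables for the kernel, built once per contact map.

    The bending term needs a native reference; without one
    (``native_coordinates`` omitted) it is disabled and the chain is
    freely jointed apart from the bonds.
    """

    nat_mask: np.ndarray     # (n, n) bool, upper triangle
    nat_r0: np.ndarray       # (n, n) float
    nat_w: np.ndarray        # (n, n) float
    b0: np.ndarray           # (n-1,) bond reference lengths
    cos_theta0: np.ndarray   # (n-2,) native cos of virtual bond angles
    angle_k: float           # effective bending constant (0 = disabled)
    params: GoParameters = field(default_factory=GoParameters)

    @classmethod
    def from_contact_map(
        cls,
        cmap: ContactMap,
        params: GoParameters | None = None,
        native_coordinates: np.ndarray | None = None,
    ) -> "GoSystem":
        """Bond reference lengths and native angles come from
        ``native_coordinates`` when given (structure-based convention),
        else scalar-default bonds and no bending term."""
        params = params or GoParameters()
        n = cmap.n_residues
        mask = np.zeros((n, n), dtype=bool)
        r0 = np.zeros((n, n))
        w = np.zeros((n, n))
        i0 = cmap.pairs[:, 0] - 1
        j0 = cmap.pairs[:, 1] - 1
        # symmetric tables: the kernel reads row i of the moved bead
        mask[i0, j0] = mask[j0, i0] = True
        r0[i0, j0] = r0[j0, i0] = cmap.r0
        w[i0, j0] = w[j0, i0] = cmap.weight
        cos_theta0 = np.zeros(max(n - 2, 0))
        if native_coordinates is not None:
            xyz = np.asarray(native_coordinates, dtype=float)
            b0 = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
            u = xyz[:-2] - xyz[1:-1]
            v = xyz[2:] - xyz[1:-1]
            cos_theta0 = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            angle_k = params.angle_k
        else:
            b0 = np.full(max(n - 1, 0), params.bond_r0)
            angle_k = 0.0
        return cls(nat_mask=mask, nat_r0=r0, nat_w=w, b0=b0,
                   cos_theta0=cos_theta0, angle_k=angle_k, params=params)


def compute_energy(
    conf: Conformation,
    cmap: ContactMap,
    params: GoParameters | None = None,
    system: GoSystem | None = None,
) -> EnergyBreakdown:
    """Energy breakdown of one conformation under the Gō Hamiltonian."""
    sys_ = system or GoSystem.from_contact_map(cmap, params)
    xyz = np.ascontiguousarray(conf.coordinates)
    if xyz.shape[0] != cmap.n_residues:
        raise ValueError("conformation length does not match contact map")
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(xyz), k=1)
    if np.any(d[iu, ju] < 1e-9):
        raise ValueError("zero interparticle distance")
    e_nat, e_bond, e_exc = _full_energy(
        xyz, sys_.nat_mask, sys_.nat_r0, sys_.nat_w, sys_.b0,
        sys_.params.epsilon, sys_.params.bond_k, sys_.params.excluded_sigma,
        sys_.angle_k, sys_.cos_theta0,
    )
    return EnergyBreakdown(e_native=float(e_nat), e_bond=float(e_bond), e_excluded=float(e_exc))


def propagate_mc(
    conf: Conformation,
    cmap: ContactMap,
    params: GoParameters,
    temperature: float,
    n_sweeps: int,
    seed: int,
    record_every: int = 10,
    hamiltonian_scale: float = 1.0,
    system: GoSystem | None = None,
    native_coordinates: np.ndarray | None = None,
) -> list[Conformation]:
    """Metropolis MC trajectory of the Gō model.

    Returns conformations recorded at sweeps 0, ``record_every``,
    2·``record_every``, ...; deterministic for a fixed seed.
    ``hamiltonian_scale`` multiplies the energy in the acceptance rule
    (λ < 1 selectively heats the solute at fixed bath temperature).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n_sweeps < 0:
        raise ValueError("n_sweeps must be non-negative")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    sys_ = system or GoSystem.from_contact_map(cmap, params, native_coordinates)
    coords = np.ascontiguousarray(conf.coordinates, dtype=float).copy()
    if n_sweeps == 0:
        return [Conformation(coords, step_index=conf.step_index)]
    beta_eff = hamiltonian_scale / (params.kB * temperature)
    rec, steps, _ = _run_mc(
        coords, n_sweeps, record_every, beta_eff, params.step_sigma,
        params.crank_max_angle, sys_.nat_mask, sys_.nat_r0, sys_.nat_w,
        sys_.b0, params.epsilon, params.bond_k, params.excluded_sigma,
        sys_.angle_k, sys_.cos_theta0, np.uint32(seed),
    )
    base = conf.step_index
    return [Conformation(rec[k].copy(), step_index=int(base + steps[k])) for k in range(len(steps))]


def acceptance_ratio(
    conf: Conformation,
    cmap: ContactMap,
    params: GoParameters,
    temperature: float,
    n_sweeps: int,
    seed: int,
) -> float:
    """Fraction of accepted moves over a short run (diagnostic)."""
    sys_ = GoSystem.from_contact_map(cmap, params)
    coords = np.ascontiguousarray(conf.coordinates, dtype=float).copy()
    _, _, n_acc = _run_mc(
        coords, n_sweeps, max(n_sweeps, 1), 1.0 / (params.kB * temperature),
        params.step_sigma, params.crank_max_angle, sys_.nat_mask, sys_.nat_r0,
        sys_.nat_w, sys_.b0, params.epsilon, params.bond_k,
        params.excluded_sigma, sys_.angle_k, sys_.cos_theta0, np.uint32(seed),
    )
    return n_acc / max(n_sweeps * coords.shape[0], 1)
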