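"""Hybrid MD/Monte-Carlo engine.

Langevin dynamics (BAOAB splitting) of free beads and rigid bodies in a
periodic cubic box, interleaved with two Metropolis-type chemistry moves:

* a *phosphorylation swap* Ser <-> pSer, attempted when a phosphosite is in
  contact with the enzyme active site, driven by the ATP/ADP chemical
  potential difference ``dmu_p``;
* a *reservoir exchange*, a detailed-balance-obeying identity swap attempted
  when the phosphosite is far from the enzyme, which mimics exchanging the
  substrate with an equilibrated reservoir (as a phosphatase would) and
  closes the reaction cycle in validation runs.

Every ``mc_interval`` MD steps the engine performs a contact check; at most
one swap is attempted per check, on the closest eligible site.  All
randomness flows from a single seed.  Units: nm, ps, amu, kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import (ParameterSet, SequenceModel, PSER_CODE, R_GAS,
                     COULOMB_K, is_cation_pi_pair, load_parameter_set,
                     ResidueParams)

RT_300 = R_GAS * 300.0

# named chemical-driving presets, kJ/mol; -48 is the physiological ATP/ADP ratio
DMU_PRESETS = {"equilibrium": 0.0, "weak": -5.0, "moderate": -10.0,
               "physiological": -48.0}


@dataclass
class SimConfig:
    """Run parameters for the hybrid engine."""

    dt: float = 0.01                 # ps
    temperature: float = 300.0       # K
    friction: float = 0.001          # ps^-1 (per unit mass)
    rotational_drag: float = 4.0     # ps^-1, per principal axis
    box_side: float = 50.0           # nm
    mc_interval: int = 200           # MD steps between contact checks
    contact_cutoff: float = 1.0      # nm, all-three-distances criterion
    reservoir_distance: float | None = None   # nm; default box_side/2
    dmu_p: float = 0.0               # kJ/mol
    reservoir_enabled: bool = False
    n_steps: int = 10_000
    traj_stride: int = 200           # MD steps between saved frames
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mc_interval < 1:
            raise ValueError("mc_interval must be >= 1")
        if self.reservoir_distance is None:
            self.reservoir_distance = self.box_side / 2.0
        if self.reservoir_distance > self.box_side / 2.0 + 1e-12:
            raise ValueError("reservoir_distance cannot exceed box_side/2")

    @property
    def kT(self) -> float:
        return R_GAS * self.temperature


@dataclass
class SystemTopology:
    """Chains, bonds, rigid groups and reaction annotations for one system."""

    codes: list[str]                      # residue code per bead
    chain_id: np.ndarray                  # int per bead
    resids: np.ndarray                    # author numbering per bead
    bonds: np.ndarray                     # (nb, 2) bead indices
    rigid_bodies: list[np.ndarray] = field(default_factory=list)
    phosphosites: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    active_site: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self):
        self.chain_id = np.asarray(self.chain_id, dtype=int)
        self.resids = np.asarray(self.resids, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.rigid_bodies = [np.asarray(b, dtype=int) for b in self.rigid_bodies]
        self.phosphosites = np.asarray(self.phosphosites, dtype=int)
        self.active_site = np.asarray(self.active_site, dtype=int)
        seen: set[int] = set()
        for body in self.rigid_bodies:
            if seen.intersection(body.tolist()):
                raise ValueError("rigid bodies overlap")
            seen.update(body.tolist())
        for s in self.phosphosites:
            if self.codes[s] not in ("S", PSER_CODE):
                raise ValueError(f"bead {s} is not a serine phosphosite")

    @property
    def n_beads(self) -> int:
        return len(self.codes)

    def rigid_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_beads, dtype=bool)
        for body in self.rigid_bodies:
            mask[body] = True
        return mask


@dataclass
class EventLog:
    """Time-stamped MC bookkeeping (attempts are supersets of accepts)."""

    records: list[dict] = field(default_factory=list)

    def add(self, time_ns, kind, chain, site, delta_u=np.nan, acc=np.nan):
        self.records.append(dict(time_ns=float(time_ns), kind=kind,
                                 chain=int(chain), site=int(site),
                                 delta_u=float(delta_u), acceptance=float(acc)))

    def to_frame(self):
        import pandas as pd
        cols = ["time_ns", "kind", "chain", "site", "delta_u", "acceptance"]
        return pd.DataFrame(self.records, columns=cols)


@dataclass
class Trajectory:
    """In-memory frame store (positions wrapped to the box)."""

    times: np.ndarray            # ns
    positions: np.ndarray        # (nframe, n, 3)
    chem: np.ndarray             # (nframe, n_sites) True = pSer
    box: float
    seed: int = 0

    def __len__(self):
        return len(self.times)

    def site_active_distances(self, topology: SystemTopology,
                              site_index: int = 0) -> np.ndarray:
        """Min-image distances (nframe, 3) from one phosphosite to the triad."""
        s = topology.phosphosites[site_index]
        d = self.positions[:, topology.active_site, :] - self.positions[:, [s], :]
        d -= self.box * np.rint(d / self.box)
        return np.linalg.norm(d, axis=2)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True, fastmath=False)
def _forces(pos, box, sigma, lam, cpi, qq, eps_ah, cut_ah, debye, cut_yk,
            excl, bonds, bond_k, bond_r0, F):
    """Pair + bond forces; returns total potential energy."""
    n = pos.shape[0]
    U = 0.0
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r <= 1e-12:
                continue
            fmag = 0.0                      # magnitude of -dU/dr
            if r < cut_ah:
                sr6 = (sigma[i, j] / r) ** 6
                lj = 4.0 * eps_ah * (sr6 * sr6 - sr6)
                dlj = 24.0 * eps_ah * (2.0 * sr6 * sr6 - sr6) / r
                rmin = 1.1224620483093730 * sigma[i, j]
                if r <= rmin:
                    U += lj + (1.0 - lam[i, j]) * eps_ah
                    fmag += dlj
                else:
                    U += lam[i, j] * lj
                    fmag += lam[i, j] * dlj
                if cpi[i, j] > 0.0:
                    U += 4.0 * cpi[i, j] * (sr6 * sr6 - sr6)
                    fmag += 24.0 * cpi[i, j] * (2.0 * sr6 * sr6 - sr6) / r
            if cut_yk > 0.0 and r < cut_yk and qq[i, j] != 0.0:
                uy = qq[i, j] * np.exp(-r / debye) / r
                U += uy
                fmag += uy * (1.0 / debye + 1.0 / r)
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.rint(dx / box)
        dy -= box * np.rint(dy / box)
        dz -= box * np.rint(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-9:
            r = 1e-9
        U += 0.5 * bond_k * (r - bond_r0) ** 2
        fmag = -bond_k * (r - bond_r0)
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[j, 0] -= fx
        F[j, 1] -= fy
        F[j, 2] -= fz
    return U


@njit(cache=True)
def _bead_energy(pos, box, k, sigma_row, lam_row, cpi_row, qq_row,
                 eps_ah, cut_ah, debye, cut_yk, excl_row):
    """Non-bonded energy of bead k against all others, for candidate rows."""
    n = pos.shape[0]
    U = 0.0
    for j in range(n):
        if j == k or excl_row[j]:
            continue
        dx = pos[k, 0] - pos[j, 0]
        dy = pos[k, 1] - pos[j, 1]
        dz = pos[k, 2] - pos[j, 2]
        dx -= box * np.rint(dx / box)
        dy -= box * np.rint(dy / box)
        dz -= box * np.rint(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < cut_ah:
            sr6 = (sigma_row[j] / r) ** 6
            lj = 4.0 * eps_ah * (sr6 * sr6 - sr6)
            rmin = 1.1224620483093730 * sigma_row[j]
            if r <= rmin:
                U += lj + (1.0 - lam_row[j]) * eps_ah
            else:
                U += lam_row[j] * lj
            if cpi_row[j] > 0.0:
                U += 4.0 * cpi_row[j] * (sr6 * sr6 - sr6)
        if cut_yk > 0.0 and r < cut_yk and qq_row[j] != 0.0:
            U += qq_row[j] * np.exp(-r / debye) / r
    return U


@njit(cache=True)
def _quat_mul(a, b, out):
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]


@njit(cache=True)
def _quat_rotate(q, v, out):
    # out = R(q) v
    t0 = 2.0 * (q[2] * v[2] - q[3] * v[1])
    t1 = 2.0 * (q[3] * v[0] - q[1] * v[2])
    t2 = 2.0 * (q[1] * v[1] - q[2] * v[0])
    out[0] = v[0] + q[0] * t0 + (q[2] * t2 - q[3] * t1)
    out[1] = v[1] + q[0] * t1 + (q[3] * t0 - q[1] * t2)
    out[2] = v[2] + q[0] * t2 + (q[1] * t1 - q[2] * t0)


@njit(cache=True)
def _quat_rotate_inv(q, v, out):
    t0 = 2.0 * (-q[2] * v[2] + q[3] * v[1])
    t1 = 2.0 * (-q[3] * v[0] + q[1] * v[2])
    t2 = 2.0 * (-q[1] * v[1] + q[2] * v[0])
    out[0] = v[0] + q[0] * t0 + (q[2] * t2 - q[3] * t1)
    out[1] = v[1] + q[0] * t1 + (q[3] * t0 - q[1] * t2)
    out[2] = v[2] + q[0] * t2 + (q[1] * t1 - q[2] * t0)


@njit(cache=True)
def _quat_step(q, omega_body, dt):
    """Rotate quaternion by body-frame angular velocity over dt."""
    wx, wy, wz = omega_body[0], omega_body[1], omega_body[2]
    wnorm = np.sqrt(wx * wx + wy * wy + wz * wz)
    dq = np.empty(4)
    if wnorm < 1e-14:
        return
    half = 0.5 * wnorm * dt
    s = np.sin(half) / wnorm
    dq[0] = np.cos(half)
    dq[1] = s * wx
    dq[2] = s * wy
    dq[3] = s * wz
    out = np.empty(4)
    _quat_mul(q, dq, out)
    norm = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2 + out[3] ** 2)
    for i in range(4):
        q[i] = out[i] / norm


@njit(cache=True)
def _sync_body_beads(pos, bead_body, bead_ref, centers, quats):
    n = pos.shape[0]
    tmp = np.empty(3)
    for i in range(n):
        b = bead_body[i]
        if b >= 0:
            _quat_rotate(quats[b], bead_ref[i], tmp)
            pos[i, 0] = centers[b, 0] + tmp[0]
            pos[i, 1] = centers[b, 1] + tmp[1]
            pos[i, 2] = centers[b, 2] + tmp[2]


@njit(cache=True)
def _body_force_torque(F, pos, bead_body, centers, quats, box, nbody,
                       Fnet, Tq_body):
    Fnet[:] = 0.0
    Tq_body[:] = 0.0
    n = pos.shape[0]
    lab = np.empty(3)
    body = np.empty(3)
    for i in range(n):
        b = bead_body[i]
        if b < 0:
            continue
        Fnet[b, 0] += F[i, 0]
        Fnet[b, 1] += F[i, 1]
        Fnet[b, 2] += F[i, 2]
        rx = pos[i, 0] - centers[b, 0]
        ry = pos[i, 1] - centers[b, 1]
        rz = pos[i, 2] - centers[b, 2]
        lab[0] = ry * F[i, 2] - rz * F[i, 1]
        lab[1] = rz * F[i, 0] - rx * F[i, 2]
        lab[2] = rx * F[i, 1] - ry * F[i, 0]
        _quat_rotate_inv(quats[b], lab, body)
        Tq_body[b, 0] += body[0]
        Tq_body[b, 1] += body[1]
        Tq_body[b, 2] += body[2]


@njit(cache=True)
def _md_block(pos, vel, mass, box, dt, kT, c1_free, c1_rot,
              bead_body, bead_ref, centers, quats, omegas, body_vel,
              body_mass, body_inertia, c1_body,
              sigma, lam, cpi, qq, eps_ah, cut_ah, debye, cut_yk,
              excl, bonds, bond_k, bond_r0,
              F, noise_free, noise_bt, noise_br, free_idx):
    """Advance ``nsteps`` BAOAB Langevin steps; returns final potential energy.

    Free beads follow standard BAOAB; rigid bodies translate with their total
    mass and rotate about their principal axes with an Ornstein-Uhlenbeck
    thermostat on the body-frame angular velocity.
    """
    nsteps = noise_free.shape[0]
    nbody = centers.shape[0]
    Fnet = np.zeros((nbody, 3))
    Tq = np.zeros((nbody, 3))
    U = _forces(pos, box, sigma, lam, cpi, qq, eps_ah, cut_ah, debye, cut_yk,
                excl, bonds, bond_k, bond_r0, F)
    if nbody > 0:
        _body_force_torque(F, pos, bead_body, centers, quats, box, nbody,
                           Fnet, Tq)
    for step in range(nsteps):
        # B half-kick
        for ii in range(free_idx.shape[0]):
            i = free_idx[ii]
            for a in range(3):
                vel[i, a] += 0.5 * dt * F[i, a] / mass[i]
        for b in range(nbody):
            for a in range(3):
                body_vel[b, a] += 0.5 * dt * Fnet[b, a] / body_mass[b]
                omegas[b, a] += 0.5 * dt * Tq[b, a] / body_inertia[b, a]
        # A half-drift
        for ii in range(free_idx.shape[0]):
            i = free_idx[ii]
            for a in range(3):
                pos[i, a] += 0.5 * dt * vel[i, a]
        for b in range(nbody):
            for a in range(3):
                centers[b, a] += 0.5 * dt * body_vel[b, a]
            _quat_step(quats[b], omegas[b], 0.5 * dt)
        # O full step
        for ii in range(free_idx.shape[0]):
            i = free_idx[ii]
            sd = np.sqrt((1.0 - c1_free * c1_free) * kT / mass[i])
            for a in range(3):
                vel[i, a] = c1_free * vel[i, a] + sd * noise_free[step, ii, a]
        for b in range(nbody):
            sd = np.sqrt((1.0 - c1_body * c1_body) * kT / body_mass[b])
            for a in range(3):
                body_vel[b, a] = (c1_body * body_vel[b, a]
                                  + sd * noise_bt[step, b, a])
                sr = np.sqrt((1.0 - c1_rot * c1_rot) * kT / body_inertia[b, a])
                omegas[b, a] = c1_rot * omegas[b, a] + sr * noise_br[step, b, a]
        # A half-drift
        for ii in range(free_idx.shape[0]):
            i = free_idx[ii]
            for a in range(3):
                pos[i, a] += 0.5 * dt * vel[i, a]
        for b in range(nbody):
            for a in range(3):
                centers[b, a] += 0.5 * dt * body_vel[b, a]
            _quat_step(quats[b], omegas[b], 0.5 * dt)
        if nbody > 0:
            _sync_body_beads(pos, bead_body, bead_ref, centers, quats)
        # forces at new positions, B half-kick
        U = _forces(pos, box, sigma, lam, cpi, qq, eps_ah, cut_ah, debye,
                    cut_yk, excl, bonds, bond_k, bond_r0, F)
        if nbody > 0:
            _body_force_torque(F, pos, bead_body, centers, quats, box, nbody,
                               Fnet, Tq)
        for ii in range(free_idx.shape[0]):
            i = free_idx[ii]
            for a in range(3):
                vel[i, a] += 0.5 * dt * F[i, a] / mass[i]
        for b in range(nbody):
            for a in range(3):
                body_vel[b, a] += 0.5 * dt * Fnet[b, a] / body_mass[b]
                omegas[b, a] += 0.5 * dt * Tq[b, a] / body_inertia[b, a]
    return U


# ---------------------------------------------------------------------------
# system assembly


class HybridSimulation:
    """Orchestrates MD blocks and MC chemistry for one topology + force field.

    Builds dense per-pair parameter tables from the residue table once, then
    updates only the affected row/column when a phosphosite changes identity.
    """

    def __init__(self, topology: SystemTopology, params: ParameterSet,
                 config: SimConfig, positions: np.ndarray | None = None):
        self.top = topology
        self.params = params
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        n = topology.n_beads
        if config.reservoir_enabled and len(topology.phosphosites) != 1:
            raise ValueError("reservoir exchange is restricted to "
                             "single-phosphosite validation systems")
        if len(topology.active_site) not in (0, 3):
            raise ValueError("active site must be a triad of beads")

        self.codes = list(topology.codes)          # mutable chemical identity
        self.chem = np.array([c == PSER_CODE for c in
                              (topology.codes[s] for s in topology.phosphosites)])
        self._rigid = topology.rigid_mask()
        self._build_tables()
        self._build_bodies()

        if positions is None:
            positions = self._random_placement()
        self.pos = np.array(positions, dtype=float)
        kT = config.kT
        self.vel = (self.rng.standard_normal((n, 3))
                    * np.sqrt(kT / self.masses[:, None]))
        # zero net drift for free beads only; bodies start at rest
        self.time_ps = 0.0
        self.n_thermal_resets = 0
        self.max_thermal_resets = 50
        self._F = np.zeros((n, 3))
        self._sync_bodies_from_positions()

    # -- tables -------------------------------------------------------------

    def _residue_of(self, i: int) -> ResidueParams:
        return self.params.residue(self.codes[i])

    def _build_tables(self):
        p, top = self.params, self.top
        n = top.n_beads
        sig = np.array([self._residue_of(i).sigma for i in range(n)])
        lam = np.array([self._residue_of(i).lambda_h for i in range(n)])
        q = np.array([self._residue_of(i).charge for i in range(n)])
        self.masses = np.array([self._residue_of(i).mass for i in range(n)])
        scale = np.where(self._rigid[:, None] | self._rigid[None, :],
                         p.folded_scale, 1.0)
        self.sigma_ij = 0.5 * (sig[:, None] + sig[None, :])
        self.lam_ij = scale * 0.5 * (lam[:, None] + lam[None, :])
        self.qq_ij = COULOMB_K * np.outer(q, q) / p.dielectric
        cpi = np.zeros((n, n))
        if p.variant == "modified_hps":
            for i in range(n):
                for j in range(n):
                    if is_cation_pi_pair(self.codes[i], self.codes[j]):
                        cpi[i, j] = p.cation_pi_epsilon * scale[i, j]
        self.cpi_ij = cpi
        excl = np.zeros((n, n), dtype=np.bool_)
        for i, j in top.bonds:
            excl[i, j] = excl[j, i] = True
        for body in top.rigid_bodies:
            excl[np.ix_(body, body)] = True
        np.fill_diagonal(excl, True)
        self.excl = excl

    def _refresh_bead_tables(self, bead: int):
        """Recompute row/column of the pair tables for one bead."""
        p = self.params
        rp = self._residue_of(bead)
        n = self.top.n_beads
        sig = np.array([self._residue_of(j).sigma for j in range(n)])
        lam = np.array([self._residue_of(j).lambda_h for j in range(n)])
        q = np.array([self._residue_of(j).charge for j in range(n)])
        scale_row = np.where(self._rigid[bead] | self._rigid,
                             p.folded_scale, 1.0)
        srow = 0.5 * (rp.sigma + sig)
        lrow = scale_row * 0.5 * (rp.lambda_h + lam)
        qrow = COULOMB_K * rp.charge * q / p.dielectric
        self.sigma_ij[bead, :] = srow
        self.sigma_ij[:, bead] = srow
        self.lam_ij[bead, :] = lrow
        self.lam_ij[:, bead] = lrow
        self.qq_ij[bead, :] = qrow
        self.qq_ij[:, bead] = qrow
        self.masses[bead] = rp.mass

    def _candidate_rows(self, bead: int, code: str):
        """Pair-table rows bead would have if it carried ``code``."""
        p = self.params
        rp = p.residue(code)
        n = self.top.n_beads
        sig = np.array([self._residue_of(j).sigma for j in range(n)])
        lam = np.array([self._residue_of(j).lambda_h for j in range(n)])
        q = np.array([self._residue_of(j).charge for j in range(n)])
        scale_row = np.where(self._rigid[bead] | self._rigid,
                             p.folded_scale, 1.0)
        srow = 0.5 * (rp.sigma + sig)
        lrow = scale_row * 0.5 * (rp.lambda_h + lam)
        qrow = COULOMB_K * rp.charge * q / p.dielectric
        cpirow = self.cpi_ij[bead, :].copy()    # Ser/pSer: no cation-pi
        return srow, lrow, cpirow, qrow

    # -- rigid bodies ---------------------------------------------------------

    def _build_bodies(self):
        top = self.top
        n = top.n_beads
        self.bead_body = np.full(n, -1, dtype=np.int64)
        nb = len(top.rigid_bodies)
        self.body_mass = np.ones(nb)
        self.body_inertia = np.ones((nb, 3))
        self.bead_ref = np.zeros((n, 3))
        self.body_center = np.zeros((nb, 3))
        self.body_quat = np.zeros((nb, 4))
        if nb:
            self.body_quat[:, 0] = 1.0
        self.body_vel = np.zeros((nb, 3))
        self.body_omega = np.zeros((nb, 3))
        self._body_rot = [np.eye(3) for _ in range(nb)]
        for b, body in enumerate(top.rigid_bodies):
            self.bead_body[body] = b
        free = np.where(self.bead_body < 0)[0]
        self.free_idx = free.astype(np.int64)
        self.n_bodies = nb

    def set_reference_frames(self, positions: np.ndarray):
        """Fix each body's principal frame from reference coordinates."""
        for b, body in enumerate(self.top.rigid_bodies):
            m = self.masses[body]
            com = np.average(positions[body], axis=0, weights=m)
            rel = positions[body] - com
            if len(body) < 3 or np.linalg.matrix_rank(rel) < 2:
                raise ValueError("degenerate (collinear) rigid body")
            inertia = np.zeros((3, 3))
            for mi, ri in zip(m, rel):
                inertia += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
            evals, evecs = np.linalg.eigh(inertia)
            if np.linalg.det(evecs) < 0:
                evecs[:, -1] *= -1
            self.body_mass[b] = m.sum()
            self.body_inertia[b] = np.maximum(evals, 1e-12)
            self.bead_ref[body] = rel @ evecs      # body-frame coordinates
            self._body_rot[b] = evecs

    def _sync_bodies_from_positions(self):
        """Initialize body pose (center, quaternion) from current positions."""
        if self.n_bodies == 0:
            return
        self.set_reference_frames(self.pos)
        from scipy.spatial.transform import Rotation
        for b, body in enumerate(self.top.rigid_bodies):
            m = self.masses[body]
            self.body_center[b] = np.average(self.pos[body], axis=0, weights=m)
            quat = Rotation.from_matrix(self._body_rot[b]).as_quat()  # x,y,z,w
            self.body_quat[b] = np.array([quat[3], quat[0], quat[1], quat[2]])
        _sync_body_beads(self.pos, self.bead_body, self.bead_ref,
                         self.body_center, self.body_quat)

    def _random_placement(self) -> np.ndarray:
        """Random initial placement: self-avoiding chain walks and rigid
        tetrahedra, rejected until no inter-bead distance falls below 0.5 nm."""
        top, cfg = self.top, self.config
        n = top.n_beads
        pos = np.full((n, 3), np.nan)
        bond_of = {}
        for i, j in top.bonds:
            bond_of.setdefault(max(i, j), min(i, j))
        in_body = top.rigid_mask()

        def min_dist(candidate, placed):
            if not placed:
                return np.inf
            arr = pos[placed] - candidate
            arr -= cfg.box_side * np.rint(arr / cfg.box_side)
            return float(np.min(np.linalg.norm(arr, axis=1)))

        def clash(candidate, placed):
            return min_dist(candidate, placed) < 0.5

        placed: list[int] = []
        for i in range(n):
            if in_body[i]:
                continue
            best, best_d = None, -1.0
            for _ in range(200):
                if i in bond_of and bond_of[i] in placed:
                    step = self.rng.standard_normal(3)
                    step *= self.params.bond_r0 / np.linalg.norm(step)
                    cand = pos[bond_of[i]] + step
                else:
                    cand = self.rng.uniform(0, cfg.box_side, 3)
                d = min_dist(cand, placed)
                if d > best_d:
                    best, best_d = cand, d
                if d >= 0.5:
                    break
            pos[i] = best
            placed.append(i)
        base = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                        dtype=float)
        base *= 0.8 / np.linalg.norm(base[0] - base[1])
        for body in top.rigid_bodies:
            k = len(body)
            pts = base[:k] if k <= 4 else np.vstack(
                [base, self.rng.standard_normal((k - 4, 3)) * 0.4])
            for _ in range(500):
                origin = self.rng.uniform(0, cfg.box_side, 3)
                cand_all = pts + origin
                if not any(clash(c, placed) for c in cand_all):
                    break
            pos[body] = cand_all
            placed.extend(body.tolist())
        return pos

    # -- energies -------------------------------------------------------------

    def total_energy(self) -> float:
        p = self.params
        return float(_forces(self.pos, self.config.box_side, self.sigma_ij,
                             self.lam_ij, self.cpi_ij, self.qq_ij,
                             p.epsilon_ah, p.cutoff_ah, p.debye_length,
                             p.cutoff_yukawa, self.excl, self.top.bonds,
                             p.bond_k, p.bond_r0, self._F.copy()))

    def bead_energy(self, bead: int, code: str | None = None) -> float:
        """Non-bonded energy of one bead, optionally with a candidate identity."""
        p = self.params
        if code is None:
            code = self.codes[bead]
        srow, lrow, cpirow, qrow = self._candidate_rows(bead, code)
        return float(_bead_energy(self.pos, self.config.box_side, bead,
                                  srow, lrow, cpirow, qrow, p.epsilon_ah,
                                  p.cutoff_ah, p.debye_length,
                                  p.cutoff_yukawa, self.excl[bead]))

    # -- contact and MC moves -------------------------------------------------

    def site_distances(self, site_index: int) -> np.ndarray:
        s = self.top.phosphosites[site_index]
        d = self.pos[self.top.active_site] - self.pos[s]
        L = self.config.box_side
        d -= L * np.rint(d / L)
        return np.linalg.norm(d, axis=1)

    def detect_contact(self) -> int | None:
        """Closest phosphosite with all three active-site distances < cutoff.

        Ties in mean distance break toward the lower residue index.
        """
        if len(self.top.active_site) != 3:
            raise ValueError("topology lacks an active-site triad annotation")
        best, best_mean = None, np.inf
        for si in range(len(self.top.phosphosites)):
            d = self.site_distances(si)
            if np.all(d < self.config.contact_cutoff):
                mean = d.mean()
                if mean < best_mean - 1e-15:
                    best, best_mean = si, mean
        return best

    def _swap_site(self, site_index: int, new_code: str):
        bead = self.top.phosphosites[site_index]
        self.codes[bead] = new_code
        self.chem[site_index] = (new_code == PSER_CODE)
        self._refresh_bead_tables(bead)
        # redraw velocity at the new mass so the ensemble stays canonical
        self.vel[bead] = (self.rng.standard_normal(3)
                          * np.sqrt(self.config.kT / self.masses[bead]))

    def attempt_phospho_swap(self, site_index: int,
                             log: EventLog | None = None):
        """Metropolis Ser<->pSer swap at the active site, driven by dmu_p.

        ``delta_u`` is always U(pSer) - U(Ser); the forward (Ser->pSer) move
        accepts with min(1, exp(-beta(dU + dmu))), the reverse with the
        sign-flipped exponent.
        """
        if not 0 <= site_index < len(self.top.phosphosites):
            raise ValueError(f"no phosphosite with index {site_index}")
        bead = self.top.phosphosites[site_index]
        if self.codes[bead] not in ("S", PSER_CODE):
            raise ValueError(f"bead {bead} is not a phosphosite")
        beta = 1.0 / self.config.kT
        du = (self.bead_energy(bead, PSER_CODE)
              - self.bead_energy(bead, "S"))
        forward = self.codes[bead] == "S"
        expo = -beta * (du + self.config.dmu_p)
        if not forward:
            expo = -expo
        acc = min(1.0, np.exp(expo))
        t_ns = self.time_ps * 1e-3
        chain = self.top.chain_id[bead]
        resid = self.top.resids[bead]
        if log is not None:
            log.add(t_ns, "phospho_attempt", chain, resid, du, acc)
        accepted = self.rng.random() < acc
        if accepted:
            self._swap_site(site_index, PSER_CODE if forward else "S")
            if log is not None:
                kind = "phospho_accept" if forward else "dephospho_accept"
                log.add(t_ns, kind, chain, resid, du, acc)
        return accepted, du

    def reservoir_eligible(self, site_index: int) -> bool:
        return bool(np.all(self.site_distances(site_index)
                           > self.config.reservoir_distance))

    def attempt_reservoir_exchange(self, site_index: int,
                                   log: EventLog | None = None):
        """Detailed-balance identity swap with an implicit substrate reservoir."""
        if not self.config.reservoir_enabled:
            raise ValueError("reservoir exchange is disabled in this config")
        bead = self.top.phosphosites[site_index]
        beta = 1.0 / self.config.kT
        cur = self.codes[bead]
        new = PSER_CODE if cur == "S" else "S"
        du = self.bead_energy(bead, new) - self.bead_energy(bead, cur)
        acc = min(1.0, np.exp(-beta * du))
        t_ns = self.time_ps * 1e-3
        chain = self.top.chain_id[bead]
        resid = self.top.resids[bead]
        if log is not None:
            log.add(t_ns, "reservoir_attempt", chain, resid, du, acc)
        accepted = self.rng.random() < acc
        if accepted:
            self._swap_site(site_index, new)
            if log is not None:
                log.add(t_ns, "reservoir_accept", chain, resid, du, acc)
        return accepted, du

    # -- dynamics -------------------------------------------------------------

    def advance(self, n_steps: int):
        """Run ``n_steps`` MD steps (no MC)."""
        cfg, p = self.config, self.params
        nfree = len(self.free_idx)
        nb = self.n_bodies
        c1 = np.exp(-cfg.friction * cfg.dt)
        c1r = np.exp(-cfg.rotational_drag * cfg.dt)
        noise_free = self.rng.standard_normal((n_steps, nfree, 3))
        noise_bt = self.rng.standard_normal((n_steps, nb, 3))
        noise_br = self.rng.standard_normal((n_steps, nb, 3))
        _md_block(self.pos, self.vel, self.masses, cfg.box_side, cfg.dt,
                  cfg.kT, c1, c1r, self.bead_body, self.bead_ref,
                  self.body_center, self.body_quat, self.body_omega,
                  self.body_vel, self.body_mass, self.body_inertia, c1,
                  self.sigma_ij, self.lam_ij, self.cpi_ij, self.qq_ij,
                  p.epsilon_ah, p.cutoff_ah, p.debye_length, p.cutoff_yukawa,
                  self.excl, self.top.bonds, p.bond_k, p.bond_r0, self._F,
                  noise_free, noise_bt, noise_br, self.free_idx)
        self.time_ps += n_steps * cfg.dt
        if not np.all(np.isfinite(self.pos)):
            raise FloatingPointError(
                "non-finite coordinates: integrator unstable "
                f"(dt={cfg.dt} ps, t={self.time_ps} ps)")
        # thermal speeds are ~0.1-1 nm/ps; 10 nm/ps is never a thermal
        # fluctuation.  Redrawing all momenta from the Maxwell-Boltzmann
        # distribution is an exact canonical move, so a hot spot is drained
        # without touching the configurational ensemble; if it keeps
        # recurring the timestep is genuinely too large and we abort.
        vmax = (np.max(np.abs(self.vel[self.free_idx]))
                if len(self.free_idx) else 0.0)
        if vmax > 10.0:
            self._rethermalize()
            self.n_thermal_resets += 1
            if self.n_thermal_resets > self.max_thermal_resets:
                raise FloatingPointError(
                    "persistent runaway velocities: integrator unstable "
                    f"(dt={cfg.dt} ps, t={self.time_ps} ps, "
                    f"{self.n_thermal_resets} momentum refreshes)")

    def minimize(self, n_iter: int = 200, max_disp: float = 0.02):
        """Capped steepest-descent relaxation for rough initial configurations.

        Moves free beads and rigid-body centers along the force, at most
        ``max_disp`` nm per iteration; does not rotate bodies.  Velocities
        are re-thermalized afterwards.
        """
        p = self.params
        for _ in range(n_iter):
            U = _forces(self.pos, self.config.box_side, self.sigma_ij,
                        self.lam_ij, self.cpi_ij, self.qq_ij, p.epsilon_ah,
                        p.cutoff_ah, p.debye_length, p.cutoff_yukawa,
                        self.excl, self.top.bonds, p.bond_k, p.bond_r0,
                        self._F)
            F = self._F
            norm = np.linalg.norm(F, axis=1, keepdims=True)
            step = F * (max_disp / np.maximum(norm, 1e-12))
            small = norm[:, 0] < 1.0
            step[small] = 0.0
            for b, body in enumerate(self.top.rigid_bodies):
                net = F[body].sum(axis=0)
                nn = np.linalg.norm(net)
                move = net * (max_disp / max(nn, 1e-12)) if nn > 1.0 else 0.0
                self.body_center[b] += move
                step[body] = 0.0
            self.pos[self.free_idx] += step[self.free_idx]
            if self.n_bodies:
                _sync_body_beads(self.pos, self.bead_body, self.bead_ref,
                                 self.body_center, self.body_quat)
        kT = self.config.kT
        self.vel = (self.rng.standard_normal((self.top.n_beads, 3))
                    * np.sqrt(kT / self.masses[:, None]))

    def _rethermalize(self):
        kT = self.config.kT
        self.vel = (self.rng.standard_normal((self.top.n_beads, 3))
                    * np.sqrt(kT / self.masses[:, None]))
        for b in range(self.n_bodies):
            self.body_vel[b] = (self.rng.standard_normal(3)
                                * np.sqrt(kT / self.body_mass[b]))
            self.body_omega[b] = (self.rng.standard_normal(3)
                                  * np.sqrt(kT / self.body_inertia[b]))

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.pos, self.config.box_side)

    def run(self, log_contacts: bool = True,
            mc_enabled: bool = True) -> tuple[Trajectory, EventLog]:
        """Advance ``config.n_steps`` MD steps with interleaved MC checks."""
        cfg = self.config
        log = EventLog()
        frames_t, frames_x, frames_c = [], [], []

        def snapshot():
            frames_t.append(self.time_ps * 1e-3)
            frames_x.append(self.wrapped_positions())
            frames_c.append(self.chem.copy())

        snapshot()
        n_blocks = cfg.n_steps // cfg.mc_interval
        strides_per_block = max(cfg.traj_stride // cfg.mc_interval, 1)
        for block in range(n_blocks):
            self.advance(cfg.mc_interval)
            if mc_enabled:
                site = self.detect_contact()
                if site is not None:
                    bead = self.top.phosphosites[site]
                    if log_contacts:
                        log.add(self.time_ps * 1e-3, "contact",
                                self.top.chain_id[bead], self.top.resids[bead])
                    self.attempt_phospho_swap(site, log)
                elif cfg.reservoir_enabled:
                    for si in range(len(self.top.phosphosites)):
                        if self.reservoir_eligible(si):
                            self.attempt_reservoir_exchange(si, log)
            if (block + 1) % strides_per_block == 0:
                snapshot()
        traj = Trajectory(times=np.array(frames_t),
                          positions=np.array(frames_x),
                          chem=np.array(frames_c, dtype=bool),
                          box=cfg.box_side, seed=cfg.seed)
        return traj, log


# ---------------------------------------------------------------------------
# single-step wrappers (testing surface)


def langevin_step(sim: HybridSimulation) -> None:
    """One BAOAB Langevin step of the whole system."""
    sim.advance(1)


def rigid_body_step(sim: HybridSimulation) -> None:
    """Alias of :func:`langevin_step`; bodies and free beads share the loop."""
    sim.advance(1)


def detect_contact(sim: HybridSimulation) -> int | None:
    return sim.detect_contact()


# ---------------------------------------------------------------------------
# toy validation system


def toy_parameter_set(epsilon_ah: float = 6.0) -> ParameterSet:
    """Force field for the desk-scale validation system.

    Bead types: L (inert linker), S/p (the reactive site), Z (sticky,
    weakly negative enzyme bead).  The slight negative charge of the
    catalytic triad makes phosphorylation destabilize the bound complex,
    mimicking product release and keeping both reaction directions
    well-sampled.
    """
    base = load_parameter_set("hps")
    res = dict(base.residues)
    res["Z"] = ResidueParams(code="Z", mass=110.0, sigma=0.60,
                             lambda_h=1.0, charge=-0.3)
    res["L"] = ResidueParams(code="L", mass=110.0, sigma=0.45,
                             lambda_h=0.1, charge=0.0)
    pset = ParameterSet(residues=res, variant="hps", epsilon_ah=epsilon_ah,
                        cutoff_ah=2.0, cutoff_yukawa=3.5)
    return pset


def build_toy_validation_system(config: SimConfig | None = None,
                                ) -> tuple[SystemTopology, ParameterSet, SimConfig]:
    """Small enzyme+substrate system that cycles through all four MSM states.

    Substrate: G-S-G tri-bead chain with the middle bead the sole
    phosphosite.  Enzyme: rigid tetrahedron whose three sticky, weakly
    positive beads form the active-site triad (the fourth bead is inert and
    merely completes the body), so the substrate binds the catalytic face.
    The box is small enough that binding, unbinding and reservoir
    excursions all recur within ~1e6 MD steps.
    """
    if config is None:
        config = SimConfig(box_side=8.0, mc_interval=20, n_steps=1_000_000,
                           friction=0.1, traj_stride=20,
                           reservoir_enabled=True)
    codes = ["L", "S", "L", "Z", "Z", "Z", "L"]
    top = SystemTopology(
        codes=codes,
        chain_id=np.array([0, 0, 0, 1, 1, 1, 1]),
        resids=np.array([1, 2, 3, 101, 102, 103, 104]),
        bonds=np.array([[0, 1], [1, 2]]),
        rigid_bodies=[np.array([3, 4, 5, 6])],
        phosphosites=np.array([1]),
        active_site=np.array([3, 4, 5]),
    )
    return top, toy_parameter_set(), config


def run_hybrid_simulation(topology: SystemTopology, params: ParameterSet,
                          config: SimConfig,
                          positions: np.ndarray | None = None,
                          ) -> tuple[Trajectory, EventLog]:
    """Build a :class:`HybridSimulation` and run it to completion."""
    sim = HybridSimulation(topology, params, config, positions=positions)
    return sim.run()
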