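"""Condensate identification and analysis under periodic boundaries.

Clustering follows DBSCAN semantics on minimum-image distances: beads with
at least ``n_min`` neighbors within ``eps`` are core beads; non-core beads
join a cluster only through a core neighbor.  Defaults eps = 1 nm,
n_min = 2, under which every isolated chain is its own cluster and two
chains merge whenever any two of their beads come within 1 nm.  The
condensate is the largest cluster by chain count; a chain belongs to a
cluster if any of its beads does.

Neighbor queries use a periodic k-d tree, so clustering, centering
(per-axis circular means) and radial profiles are all invariant under
translations by lattice vectors.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .params import (ParameterSet, pair_energy, pair_params,
                     yukawa_energy, cation_pi_energy)


@dataclass
class ClusterResult:
    labels: np.ndarray           # per bead; -1 = noise
    chain_id: np.ndarray         # per bead
    eps: float
    n_min: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if (self.labels >= 0).any() else 0

    def chain_clusters(self) -> dict[int, set]:
        """Cluster labels touched by each chain (any-bead membership)."""
        out: dict[int, set] = {}
        for lab, ch in zip(self.labels, self.chain_id):
            out.setdefault(int(ch), set()).add(int(lab))
        return out

    def _membership(self, restrict_chains=None) -> dict[int, set]:
        membership: dict[int, set] = {}
        for lab, ch in zip(self.labels, self.chain_id):
            if lab < 0:
                continue
            if restrict_chains is not None and ch not in restrict_chains:
                continue
            membership.setdefault(int(lab), set()).add(int(ch))
        return membership

    def largest_cluster_label(self, restrict_chains=None) -> int | None:
        """Label of the largest cluster by chain count among
        ``restrict_chains`` (default all); ties break toward the lowest label."""
        membership = self._membership(restrict_chains)
        if not membership:
            return None
        return max(sorted(membership), key=lambda lab: len(membership[lab]))

    def largest_cluster_chains(self, restrict_chains=None) -> set[int]:
        best = self.largest_cluster_label(restrict_chains)
        return set() if best is None else self._membership(restrict_chains)[best]

    def largest_cluster_beads(self, restrict_chains=None) -> np.ndarray:
        best = self.largest_cluster_label(restrict_chains)
        if best is None:
            return np.empty(0, dtype=int)
        return np.flatnonzero(self.labels == best)


@dataclass
class RadialProfile:
    edges: np.ndarray                      # nm, contiguous
    density: dict[str, np.ndarray]         # beads/nm^3 per species
    center: np.ndarray

    @property
    def mids(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def shell_volumes(self) -> np.ndarray:
        return 4.0 * np.pi / 3.0 * (self.edges[1:] ** 3 - self.edges[:-1] ** 3)


# ---------------------------------------------------------------------------
# clustering


def cluster_beads(positions: np.ndarray, box: float, eps: float = 1.0,
                  n_min: int = 2, chain_id: np.ndarray | None = None,
                  ) -> ClusterResult:
    """DBSCAN on minimum-image distances in a periodic cubic box."""
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("empty position array")
    if eps <= 0 or n_min < 1:
        raise ValueError("eps must be positive and n_min >= 1")
    if chain_id is None:
        chain_id = np.zeros(len(pos), dtype=int)
    wrapped = np.mod(pos, box)
    # cKDTree requires points strictly inside [0, box)
    wrapped[wrapped >= box] = 0.0
    tree = cKDTree(wrapped, boxsize=box)
    neighbors = tree.query_ball_tree(tree, r=eps)
    n = len(pos)
    # DBSCAN convention: n_min counts neighbors other than the bead itself
    core = np.array([len(nb) - 1 >= n_min for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for seed_bead in range(n):
        if not core[seed_bead] or labels[seed_bead] >= 0:
            continue
        queue = deque([seed_bead])
        labels[seed_bead] = cluster
        while queue:
            b = queue.popleft()
            if not core[b]:
                continue
            for nb in neighbors[b]:
                if labels[nb] < 0:
                    labels[nb] = cluster
                    if core[nb]:
                        queue.append(nb)
        cluster += 1
    return ClusterResult(labels=labels, chain_id=np.asarray(chain_id, int),
                         eps=eps, n_min=n_min)


def condensate_fraction(result: ClusterResult, n_chains: int,
                        restrict_chains=None) -> float:
    """Fraction of chains belonging to the largest cluster."""
    chains = result.largest_cluster_chains(restrict_chains)
    return len(chains) / n_chains


def enzyme_attachment(result: ClusterResult, enzyme_chain_ids,
                      substrate_chain_ids=None) -> float:
    """Fraction of enzyme chains sharing the substrate condensate cluster.

    The largest cluster is determined among substrate chains only, so a
    detached enzyme pair can never itself count as the condensate.
    """
    enzyme_chain_ids = set(int(c) for c in enzyme_chain_ids)
    if not enzyme_chain_ids:
        raise ValueError("no enzyme chains declared")
    if substrate_chain_ids is None:
        substrate_chain_ids = (set(int(c) for c in np.unique(result.chain_id))
                               - enzyme_chain_ids)
    condensate_chains = result.largest_cluster_chains(substrate_chain_ids)
    condensate_labels = set()
    for lab, ch in zip(result.labels, result.chain_id):
        if lab >= 0 and int(ch) in condensate_chains:
            condensate_labels.add(int(lab))
    attached = 0
    chain_map = result.chain_clusters()
    for e in enzyme_chain_ids:
        if chain_map.get(e, set()) & condensate_labels:
            attached += 1
    return attached / len(enzyme_chain_ids)


# ---------------------------------------------------------------------------
# geometry


def condensate_center(positions: np.ndarray, box: float) -> np.ndarray:
    """Per-axis circular mean of bead coordinates, PBC-safe.

    Mapping each axis onto a circle makes the center invariant (mod lattice
    vectors) under global translation, even when the cluster straddles a
    face of the box.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("empty cluster")
    theta = 2.0 * np.pi * pos / box
    center = (box / (2.0 * np.pi)) * np.arctan2(
        np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return np.mod(center, box)


def radial_density(positions: np.ndarray, species: np.ndarray,
                   center: np.ndarray, box: float,
                   bin_width: float = 0.5) -> RadialProfile:
    """Per-species bead density in spherical shells about ``center``.

    count_s(bin) / shell volume, with shells up to box/2 and min-image
    distances to the center.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    pos = np.asarray(positions, dtype=float)
    species = np.asarray(species)
    d = pos - center
    d -= box * np.rint(d / box)
    r = np.linalg.norm(d, axis=1)
    edges = np.arange(0.0, box / 2.0 + bin_width, bin_width)
    volumes = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    density = {}
    for s in np.unique(species):
        counts, _ = np.histogram(r[species == s], bins=edges)
        density[str(s)] = counts / volumes
    return RadialProfile(edges=edges, density=density,
                         center=np.asarray(center, float))


def pser_fraction_profile(profile: RadialProfile, ser_key: str = "Ser",
                          pser_key: str = "pSer") -> np.ndarray:
    """pSer / (Ser + pSer) per shell; empty shells are NaN."""
    ser = profile.density.get(ser_key, np.zeros(len(profile.mids)))
    pser = profile.density.get(pser_key, np.zeros(len(profile.mids)))
    total = ser + pser
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, pser / total, np.nan)
    return frac


def pser_per_chain_distribution(pser_count_per_chain: np.ndarray,
                                chains_in_condensate: set[int],
                                ) -> dict[str, np.ndarray]:
    """Histograms of pSer per chain, split into dense and dilute phase."""
    counts = np.asarray(pser_count_per_chain, dtype=int)
    n_chains = len(counts)
    dense = np.array([c in chains_in_condensate for c in range(n_chains)])
    nmax = counts.max(initial=0)
    out = {}
    for phase, mask in (("dense", dense), ("dilute", ~dense)):
        out[phase] = np.bincount(counts[mask], minlength=nmax + 1)
    return out


# ---------------------------------------------------------------------------
# energetics


def energy_decomposition(positions: np.ndarray, codes: list[str],
                         box: float, params: ParameterSet,
                         group: np.ndarray, partners: np.ndarray,
                         rigid_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-residue interaction energy of ``group`` with ``partners``,
    split into Ashbaugh-Hatch, Yukawa and cation-pi terms.

    Group-partner pairs contribute fully to the group residue; pairs inside
    the group (if partners overlap it, that is an error) never arise.  The
    component sums over the group equal the total group-partner interaction
    energy exactly.
    """
    group = np.asarray(group, dtype=int)
    partners = np.asarray(partners, dtype=int)
    if np.intersect1d(group, partners).size:
        raise ValueError("group and partner sets overlap")
    if rigid_mask is None:
        rigid_mask = np.zeros(len(codes), dtype=bool)
    pos = np.asarray(positions, dtype=float)
    rows = []
    for g in group:
        d = pos[partners] - pos[g]
        d -= box * np.rint(d / box)
        r = np.linalg.norm(d, axis=1)
        u_ah = u_yk = u_cp = 0.0
        for dist, p in zip(r, partners):
            if dist <= 1e-12:
                continue
            total = pair_energy(dist, codes[g], codes[p], params,
                                rigid_mask[g], rigid_mask[p])
            qi = params.residue(codes[g]).charge
            qj = params.residue(codes[p]).charge
            yk = yukawa_energy(dist, qi, qj, params.debye_length,
                               params.dielectric, params.cutoff_yukawa)
            _, _, scale = pair_params(codes[g], codes[p], params,
                                      rigid_mask[g], rigid_mask[p])
            cp = scale * cation_pi_energy(dist, codes[g], codes[p], params)
            u_yk += yk
            u_cp += cp
            u_ah += total - yk - cp
        rows.append(dict(bead=int(g), code=codes[g], ah=u_ah, yukawa=u_yk,
                         cation_pi=u_cp, total=u_ah + u_yk + u_cp))
    return pd.DataFrame(rows)


def dissolution_onset(times: np.ndarray, fractions: np.ndarray,
                      plateau_frames: int = 5,
                      threshold: float = 0.975) -> float | None:
    """First time the condensate fraction drops below ``threshold`` x its
    initial plateau; None if it never does."""
    f0 = float(np.mean(fractions[:plateau_frames]))
    below = np.flatnonzero(fractions < threshold * f0)
    return float(times[below[0]]) if len(below) else None
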