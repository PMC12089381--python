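"""Coarse-grained force field: residue parameters, pair potentials, sequence variants.

One bead per residue, implicit solvent.  Non-bonded interactions are the
Ashbaugh-Hatch (AH) hydropathy-scaled Lennard-Jones potential plus a
Debye-screened Coulomb (Yukawa) term; the *modified* variant adds an
explicit short-range cation-pi well between Arg/Lys and aromatic residues.
Beads belonging to rigid folded domains interact with a reduced attractive
strength (default 30% reduction) with every partner.

Energies are in kJ/mol, distances in nm, masses in amu, charges in units
of the elementary charge.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

# e^2 / (4 pi eps0), in kJ mol^-1 nm e^-2
COULOMB_K = 138.935458

# molar gas constant, kJ mol^-1 K^-1
R_GAS = 8.31446261815324e-3

VARIANTS = ("hps", "modified_hps", "no_charge", "average_lambda",
            "average_lambda_equi_ser")

CATION_RESIDUES = frozenset("RK")
AROMATIC_RESIDUES = frozenset("FWY")

PSER_CODE = "p"


@dataclass(frozen=True)
class ResidueParams:
    """Per-residue-type bead parameters."""

    code: str
    mass: float      # amu
    sigma: float     # vdW diameter, nm
    lambda_h: float  # hydropathy, dimensionless, in [0, 1]
    charge: float    # elementary charges

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not 0.0 <= self.lambda_h <= 1.0:
            raise ValueError(f"lambda_h must lie in [0, 1], got {self.lambda_h}")


@dataclass
class ParameterSet:
    """A complete force field: residue table plus interaction constants."""

    residues: dict[str, ResidueParams]
    variant: str = "hps"
    epsilon_ah: float = 0.8368          # kJ/mol (0.2 kcal/mol)
    debye_length: float = 1.0           # nm, ~100 mM ionic strength
    dielectric: float = 80.0
    cation_pi_epsilon: float = 3.138    # kJ/mol; active only in modified_hps
    folded_scale: float = 0.7           # attractive scaling for rigid-domain pairs
    cutoff_ah: float = 2.0              # nm
    cutoff_yukawa: float = 3.5          # nm
    bond_k: float = 8033.0              # kJ/(mol nm^2)
    bond_r0: float = 0.38               # nm
    temperature: float = 300.0          # K

    def __post_init__(self):
        if not 0.0 < self.folded_scale <= 1.0:
            raise ValueError("folded_scale must lie in (0, 1]")
        if self.debye_length <= 0:
            raise ValueError("debye_length must be positive")
        if self.cutoff_ah <= 0 or self.cutoff_yukawa <= 0:
            raise ValueError("cutoffs must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"expected one of {VARIANTS}")

    @property
    def kT(self) -> float:
        return R_GAS * self.temperature

    def residue(self, code: str) -> ResidueParams:
        try:
            return self.residues[code]
        except KeyError:
            raise KeyError(f"residue code {code!r} missing from parameter table")

    def with_overrides(self, **overrides) -> "ParameterSet":
        new = copy.deepcopy(self)
        for key, value in overrides.items():
            if not hasattr(new, key):
                raise ValueError(f"unknown parameter field {key!r}")
            setattr(new, key, value)
        new.__post_init__()
        return new


@dataclass
class SequenceModel:
    """A protein chain with author numbering and simulation annotations.

    ``first_resid`` anchors author numbering: bead i carries author residue
    number ``first_resid + i``.  Phosphosites, rigid groups and the active
    site are all recorded in author numbering and preserved end to end.
    """

    codes: list[str]
    first_resid: int = 1
    name: str = ""
    phosphosites: list[int] = field(default_factory=list)     # author numbers
    rigid_groups: dict[str, list[int]] = field(default_factory=dict)
    active_site: list[int] = field(default_factory=list)      # author numbers

    def __post_init__(self):
        for site in self.phosphosites:
            if self.code_at(site) not in ("S", PSER_CODE):
                raise ValueError(
                    f"phosphosite {site} is {self.code_at(site)!r}, not Ser")
        seen: set[int] = set()
        for name, group in self.rigid_groups.items():
            overlap = seen.intersection(group)
            if overlap:
                raise ValueError(f"rigid group {name!r} overlaps another "
                                 f"group at residues {sorted(overlap)}")
            seen.update(group)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def resids(self) -> np.ndarray:
        return np.arange(self.first_resid, self.first_resid + len(self.codes))

    def index_of(self, resid: int) -> int:
        idx = resid - self.first_resid
        if not 0 <= idx < len(self.codes):
            raise IndexError(f"residue {resid} outside chain "
                             f"({self.first_resid}-{self.resids[-1]})")
        return idx

    def code_at(self, resid: int) -> str:
        return self.codes[self.index_of(resid)]

    def serine_positions(self) -> list[int]:
        return [int(r) for r, c in zip(self.resids, self.codes) if c == "S"]


# ---------------------------------------------------------------------------
# parameter-table loading and variants


def _read_residue_table(path=None) -> dict[str, ResidueParams]:
    if path is None:
        source = resources.files("phosdyn.data").joinpath("hps_residues.tsv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    required = {"code", "mass", "sigma", "lambda", "charge"}
    missing = required.difference(table.columns)
    if missing:
        raise ValueError(f"parameter table missing columns {sorted(missing)}")
    table = table.rename(columns={"lambda": "lambda_h"})
    residues = {}
    for row in table.itertuples():
        residues[row.code] = ResidueParams(
            code=row.code, mass=float(row.mass), sigma=float(row.sigma),
            lambda_h=float(row.lambda_h), charge=float(row.charge))
    for code in "ARNDCQEGHILKMFPSTWYV" + PSER_CODE:
        if code not in residues:
            raise ValueError(f"residue table incomplete: {code!r} missing")
    return residues


def load_parameter_set(variant: str = "hps", table_path=None,
                       **overrides) -> ParameterSet:
    """Load a named force-field variant.

    ``hps``            the plain hydropathy-scale model;
    ``modified_hps``   same table, cation-pi well switched on;
    ``no_charge``      all charges zeroed except pSer;
    ``average_lambda`` / ``average_lambda_equi_ser``
                       tags only -- the averaged-bead tables are built per
                       sequence by :func:`build_sequence_variant`.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    residues = _read_residue_table(table_path)
    if variant == "no_charge":
        residues = {
            code: (rp if code == PSER_CODE else replace(rp, charge=0.0))
            for code, rp in residues.items()
        }
    pset = ParameterSet(residues=residues, variant=variant)
    if overrides:
        pset = pset.with_overrides(**overrides)
    return pset


def sequence_average_params(seq: SequenceModel,
                            params: ParameterSet) -> tuple[float, float, float]:
    """Arithmetic mean of per-residue mass, sigma and hydropathy over the chain."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    rps = [params.residue(c) for c in seq.codes]
    mass = float(np.mean([rp.mass for rp in rps]))
    sigma = float(np.mean([rp.sigma for rp in rps]))
    lam = float(np.mean([rp.lambda_h for rp in rps]))
    return mass, sigma, lam


AVERAGED_BEAD_CODE = "X"


def build_sequence_variant(seq: SequenceModel, variant: str,
                           params: ParameterSet | None = None,
                           ) -> tuple[SequenceModel, ParameterSet]:
    """Build an averaged-interaction homopolymer variant of ``seq``.

    Non-Ser residues are replaced by a single neutral bead type carrying the
    chain-averaged mass, size and hydropathy; Ser (and pSer) keep their own
    parameters.  ``average_lambda`` leaves the serines at their original
    positions, ``average_lambda_equi_ser`` spreads the same number of Ser
    evenly along the chain (ties toward the N-terminus).
    """
    if variant not in ("average_lambda", "average_lambda_equi_ser"):
        raise ValueError(f"unknown averaged variant {variant!r}")
    if params is None:
        params = load_parameter_set("hps")
    n_ser = seq.codes.count("S")
    if n_ser == 0:
        raise ValueError("sequence has no Ser to keep as phosphosites")
    mass, sigma, lam = sequence_average_params(seq, params)

    n = len(seq)
    if variant == "average_lambda":
        ser_idx = [i for i, c in enumerate(seq.codes) if c == "S"]
    else:
        # n_ser serines at equal gaps; floor puts ties toward the N-terminus
        ser_idx = [int(np.floor(k * n / n_ser)) for k in range(n_ser)]
    codes = [AVERAGED_BEAD_CODE] * n
    for i in ser_idx:
        codes[i] = "S"

    residues = dict(params.residues)
    residues[AVERAGED_BEAD_CODE] = ResidueParams(
        code=AVERAGED_BEAD_CODE, mass=mass, sigma=sigma,
        lambda_h=lam, charge=0.0)
    new_params = copy.deepcopy(params)
    new_params.residues = residues
    new_params.variant = variant
    new_seq = SequenceModel(
        codes=codes, first_resid=seq.first_resid, name=f"{seq.name}:{variant}",
        phosphosites=[int(seq.first_resid + i) for i in ser_idx],
        rigid_groups={}, active_site=list(seq.active_site))
    return new_seq, new_params


# ---------------------------------------------------------------------------
# pair potentials


def _lj(r, sigma, epsilon):
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def ashbaugh_hatch_energy(r, sigma_ij, lambda_ij, epsilon, cutoff):
    """AH potential: LJ shifted up by (1-lambda)eps inside the minimum,
    LJ scaled by lambda outside, zero beyond the cutoff.

    Continuous at r = 2^(1/6) sigma with value -lambda*eps.  Accepts scalar
    or array ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    rmin = 2.0 ** (1.0 / 6.0) * sigma_ij
    lj = _lj(np.where(r > 0, r, 1.0), sigma_ij, epsilon)
    inner = lj + (1.0 - lambda_ij) * epsilon
    outer = lambda_ij * lj
    u = np.where(r <= rmin, inner, outer)
    u = np.where(r > cutoff, 0.0, u)
    return u if u.ndim else float(u)


def ashbaugh_hatch_force(r, sigma_ij, lambda_ij, epsilon, cutoff):
    """Magnitude of -dU/dr for the AH potential (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma_ij / r) ** 6
    dlj = 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r   # -d(U_LJ)/dr
    rmin = 2.0 ** (1.0 / 6.0) * sigma_ij
    f = np.where(r <= rmin, dlj, lambda_ij * dlj)
    f = np.where(r > cutoff, 0.0, f)
    return f if f.ndim else float(f)


def yukawa_energy(r, qi, qj, debye_length, dielectric, cutoff):
    """Screened Coulomb: (qi qj k_e / eps_r) exp(-r/lambda_D)/r, truncated."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if debye_length <= 0:
        raise ValueError("debye_length must be positive")
    u = COULOMB_K * qi * qj / dielectric * np.exp(-r / debye_length) / r
    u = np.where(r > cutoff, 0.0, u)
    return u if u.ndim else float(u)


def is_cation_pi_pair(code_i: str, code_j: str) -> bool:
    return ((code_i in CATION_RESIDUES and code_j in AROMATIC_RESIDUES)
            or (code_j in CATION_RESIDUES and code_i in AROMATIC_RESIDUES))


def cation_pi_energy(r, code_i, code_j, params: ParameterSet):
    """Extra 12-6 well of depth ``cation_pi_epsilon`` for Arg/Lys vs Phe/Trp/Tyr.

    Zero for every other pair and zero in the plain ``hps`` variant; additive
    with the AH and Yukawa terms.  Uses the same arithmetic-mean sigma as AH.
    """
    r = np.asarray(r, dtype=float)
    zero = np.zeros_like(r) if r.ndim else 0.0
    if params.variant != "modified_hps" or not is_cation_pi_pair(code_i, code_j):
        return zero
    sigma_ij = 0.5 * (params.residue(code_i).sigma + params.residue(code_j).sigma)
    u = _lj(r, sigma_ij, params.cation_pi_epsilon)
    u = np.where(r > params.cutoff_ah, 0.0, u)
    return u if u.ndim else float(u)


def pair_params(code_i: str, code_j: str, params: ParameterSet,
                rigid_i: bool = False, rigid_j: bool = False,
                ) -> tuple[float, float, float]:
    """Combined (sigma_ij, lambda_ij, scale) for a bead pair.

    Arithmetic-mean combination; ``scale`` is the folded-domain reduction
    factor, applied when at least one partner sits in a rigid group.
    """
    rp_i, rp_j = params.residue(code_i), params.residue(code_j)
    sigma_ij = 0.5 * (rp_i.sigma + rp_j.sigma)
    lambda_ij = 0.5 * (rp_i.lambda_h + rp_j.lambda_h)
    scale = params.folded_scale if (rigid_i or rigid_j) else 1.0
    return sigma_ij, lambda_ij, scale


def pair_energy(r, code_i, code_j, params: ParameterSet,
                rigid_i=False, rigid_j=False):
    """Total non-bonded pair energy: scaled-attraction AH + Yukawa + cation-pi.

    The folded-domain reduction multiplies the hydropathy-scaled (attractive)
    part of the AH term and the cation-pi well; electrostatics are unscaled.
    """
    sigma_ij, lambda_ij, scale = pair_params(code_i, code_j, params,
                                             rigid_i, rigid_j)
    u_ah = ashbaugh_hatch_energy(r, sigma_ij, scale * lambda_ij,
                                 params.epsilon_ah, params.cutoff_ah)
    qi, qj = params.residue(code_i).charge, params.residue(code_j).charge
    u_yk = yukawa_energy(r, qi, qj, params.debye_length, params.dielectric,
                         params.cutoff_yukawa)
    u_cp = scale * cation_pi_energy(r, code_i, code_j, params)
    return u_ah + u_yk + u_cp
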