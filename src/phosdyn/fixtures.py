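"""Packaged fixtures: sequences, parameter tables, toy systems.

The TDP-43 low-complexity domain (UniProt Q13148, residues 261-414) is
bundled as FASTA with author numbering carried in the header
(``offset=261``).  The bundled CK1d file is a SYNTHETIC stand-in of the
right length (415) with the Asp149-Phe150-Gly151 active-site triad; supply
the real UniProt P48730 FASTA via ``sequence_path`` for production use.
Folded-domain coordinates (PDB 6RU7, AlphaFold P48730) are user-supplied
inputs and are never downloaded.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from Bio import SeqIO

from .engine import SimConfig, build_toy_validation_system
from .params import SequenceModel, load_parameter_set

FIXTURES = ("tdp43_lcd", "ck1d_truncated", "ck1d_full_open",
            "ck1d_full_closed", "toy_enzyme", "hps_table",
            "modified_hps_table")

CK1D_ACTIVE_SITE = [149, 150, 151]     # Asp, Phe, Gly (author numbering)
TDP43_HELIX_RIGID = list(range(320, 333))   # optional rigid helix group


def _data_path(name: str) -> Path:
    source = resources.files("phosdyn.data").joinpath(name)
    with resources.as_file(source) as p:
        return Path(p)


def read_fasta_sequence(path) -> SequenceModel:
    """Read one chain from FASTA; ``offset=N`` in the header sets author
    numbering of the first residue (default 1)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    first = 1
    for token in record.description.replace("|", " ").split():
        if token.startswith("offset="):
            first = int(token.split("=", 1)[1])
    return SequenceModel(codes=list(str(record.seq)), first_resid=first,
                         name=record.id)


def load_fixture(name: str, sequence_path=None, structure_path=None):
    """Load a named fixture; see ``FIXTURES`` for the catalogue."""
    if name == "tdp43_lcd":
        seq = read_fasta_sequence(sequence_path
                                  or _data_path("tdp43_lcd.fasta"))
        seq.phosphosites = seq.serine_positions()
        return seq
    if name in ("ck1d_truncated", "ck1d_full_open", "ck1d_full_closed"):
        seq = read_fasta_sequence(sequence_path
                                  or _data_path("ck1d_synthetic.fasta"))
        if name == "ck1d_truncated":
            seq = SequenceModel(codes=seq.codes[2:294], first_resid=3,
                                name=seq.name + ":3-294")
        seq.active_site = list(CK1D_ACTIVE_SITE)
        last = seq.first_resid + len(seq) - 1
        rigid_span = list(range(seq.first_resid, min(294, last) + 1))
        seq.rigid_groups = {"folded_domain": rigid_span}
        if structure_path is None:
            accession = ("PDB 6RU7" if name != "ck1d_full_closed"
                         else "AlphaFold P48730")
            raise FileNotFoundError(
                f"fixture {name!r} needs folded-domain coordinates; "
                f"fetch {accession} and pass structure_path=...")
        return seq, Path(structure_path)
    if name == "toy_enzyme":
        return build_toy_validation_system()
    if name == "hps_table":
        return load_parameter_set("hps")
    if name == "modified_hps_table":
        return load_parameter_set("modified_hps")
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")


# ---------------------------------------------------------------------------
# desk-scale study systems


def build_lcd_fragment_system(region: str):
    """TDP-43 LCD fragment plus a generic cationic sticky enzyme.

    ``region``: ``n_terminal`` (residues 261-310) or ``c_terminal``
    (365-414).  The enzyme is a rigid tetrahedron of uniformly sticky,
    positively charged beads, three of which form the active-site triad; it
    stands in for the kinase's aromatic-philic, positively charged catalytic
    cleft.  Comparing pooled Ser phosphorylation rates between the two
    fragments probes the sequence-context effect (aromatic enrichment in
    the C-terminal segment, positive charges in the N-terminal one) at a
    fraction of the full-chain cost.

    Returns (topology, params, site_resids).
    """
    import numpy as np

    from .engine import SystemTopology
    from .params import ParameterSet, ResidueParams

    spans = {"n_terminal": (261, 310), "c_terminal": (365, 414)}
    try:
        lo, hi = spans[region]
    except KeyError:
        raise ValueError(f"region must be one of {sorted(spans)}")
    seq = load_fixture("tdp43_lcd")
    idx = [seq.index_of(r) for r in range(lo, hi + 1)]
    codes = [seq.codes[i] for i in idx]
    n = len(codes)
    sites = [r for r in seq.phosphosites if lo <= r <= hi]
    base = load_parameter_set("hps")
    residues = dict(base.residues)
    residues["Z"] = ResidueParams(code="Z", mass=110.0, sigma=0.60,
                                  lambda_h=1.0, charge=1.0)
    params = ParameterSet(residues=residues, variant="hps")
    top = SystemTopology(
        codes=codes + ["Z"] * 4,
        chain_id=np.array([0] * n + [1] * 4),
        resids=np.concatenate([np.arange(lo, hi + 1),
                               [1001, 1002, 1003, 1004]]),
        bonds=np.array([[i, i + 1] for i in range(n - 1)]),
        rigid_bodies=[np.arange(n, n + 4)],
        phosphosites=np.array([r - lo for r in sites]),
        active_site=np.array([n, n + 1, n + 2]),
    )
    return top, params, sites


DISSOLUTION_CHAIN = "MMSMMMSMMMSM"   # methionine-rich sticker chain, 3 Ser


def build_dissolution_system(pser_level: float, seed: int,
                             n_chains: int = 8, epsilon_ah: float = 2.0,
                             box: float = 10.0):
    """Small methionine-rich condensate with an imposed phosphorylation level.

    ``pser_level`` of the serines (rounded) are converted to pSer before the
    run; the -2e charges plus the reduced hydropathy of pSer weaken the
    droplet cohesion, so the equilibrium fraction of chains in the largest
    cluster decreases as the level rises.  Returns (simulation, topology,
    config) ready to run with MC disabled; the caller should ``minimize()``
    first (the droplet generator packs beads tightly).
    """
    import numpy as np

    from .engine import HybridSimulation, SimConfig, SystemTopology
    from .params import ParameterSet
    from .synthetic import generate_droplet_gas

    base = load_parameter_set("hps")
    params = ParameterSet(residues=dict(base.residues), variant="hps",
                          epsilon_ah=epsilon_ah)
    bpc = len(DISSOLUTION_CHAIN)
    codes, chain_id, bonds = [], [], []
    for c in range(n_chains):
        for b, aa in enumerate(DISSOLUTION_CHAIN):
            codes.append(aa)
            chain_id.append(c)
            if b:
                bonds.append([c * bpc + b - 1, c * bpc + b])
    rng = np.random.default_rng(seed)
    ser = [i for i, cd in enumerate(codes) if cd == "S"]
    k = int(round(pser_level * len(ser)))
    for i in rng.choice(ser, size=k, replace=False):
        codes[i] = "p"
    top = SystemTopology(codes=codes, chain_id=np.array(chain_id),
                         resids=np.arange(len(codes)),
                         bonds=np.array(bonds), phosphosites=np.array(ser))
    pos, _, _, _ = generate_droplet_gas(n_chains, 0, bpc, droplet_radius=3.0,
                                        box=box, seed=seed)
    config = SimConfig(box_side=box, mc_interval=5000, friction=0.05,
                       n_steps=400_000, traj_stride=25_000, seed=seed)
    sim = HybridSimulation(top, params, config, positions=pos)
    return sim, top, config
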