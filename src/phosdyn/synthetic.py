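"""Synthetic data generators with known ground truth.

These stand in for study-scale simulation output so every analysis module
can be exercised (and its estimators validated against the generating
truth) at desk scale: a continuous-time Markov cycle with a prescribed
affinity, telegraph contact signals, censored exponential first-passage
tables, and droplet-plus-gas bead configurations with known cluster
membership.  Every generator takes an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import EventTable
from .msm import DiscreteTrajectory
from .params import R_GAS


def cycle_rate_matrix(forward: list[float], backward: list[float]) -> np.ndarray:
    """Generator matrix of an n-state ring with given edge rates.

    ``forward[i]`` is the rate i -> i+1 (mod n), ``backward[i]`` the rate
    i+1 -> i.  Off-ring entries are zero.
    """
    n = len(forward)
    if len(backward) != n:
        raise ValueError("forward/backward lists differ in length")
    Q = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        Q[i, j] = forward[i]
        Q[j, i] = backward[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def cycle_affinity(forward, backward, temperature: float = 300.0) -> float:
    """Analytic affinity -RT ln prod(k_fwd/k_bwd) of the ring, kJ/mol."""
    ratio = np.prod(np.asarray(forward) / np.asarray(backward))
    return float(-R_GAS * temperature * np.log(ratio))


def generate_markov_cycle(forward: list[float], backward: list[float],
                          n_steps: int, stride: float = 1.0,
                          seed: int = 0, markov_step_ns: float = 0.1,
                          ) -> tuple[DiscreteTrajectory, float]:
    """Exact CTMC ring sampled at a fixed stride, with its analytic affinity.

    Rates are per unit time; ``stride`` is the sampling interval in the
    same unit.  Uses exact jump-chain (Gillespie) simulation, so the strided
    sequence is an exact realization of the discrete-time chain exp(Q*stride).
    """
    if np.any(np.asarray(forward) <= 0) or np.any(np.asarray(backward) <= 0):
        raise ValueError("edge rates must be positive "
                         "(a zero rate implies an absorbing direction)")
    Q = cycle_rate_matrix(forward, backward)
    n = Q.shape[0]
    exit_rates = -np.diag(Q)
    rng = np.random.default_rng(seed)
    t_end = n_steps * stride
    state = 0
    t = 0.0
    samples = np.empty(n_steps + 1, dtype=np.int64)
    next_sample = 0
    while next_sample <= n_steps:
        dwell = rng.exponential(1.0 / exit_rates[state])
        t_next = t + dwell
        while next_sample <= n_steps and next_sample * stride < t_next:
            samples[next_sample] = state + 1
            next_sample += 1
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = rng.choice(n, p=probs)
        t = t_next
    dtraj = DiscreteTrajectory(samples, markov_step_ns, n_states=n)
    return dtraj, cycle_affinity(forward, backward)


def generate_telegraph_contact(rate_on: float, rate_off: float,
                               n_frames: int, frame_time: float = 1.0,
                               seed: int = 0) -> np.ndarray:
    """Boolean contact signal from a two-state telegraph process.

    ``rate_on`` is the off -> on switching rate per unit time.  Sampled on a
    regular frame grid from the exact continuous-time process.
    """
    rng = np.random.default_rng(seed)
    t_end = n_frames * frame_time
    state = False
    t = 0.0
    out = np.empty(n_frames, dtype=bool)
    next_frame = 0
    while next_frame < n_frames:
        rate = rate_off if state else rate_on
        t_next = t + rng.exponential(1.0 / rate)
        while next_frame < n_frames and next_frame * frame_time < t_next:
            out[next_frame] = state
            next_frame += 1
        state = not state
        t = t_next
    return out


def generate_exponential_events(rate: float, n_sim: int, t_tot: float,
                                seed: int = 0, binding_rate: float | None = None,
                                site_name=0) -> EventTable:
    """First-passage table from a (possibly binding-conditioned) exponential.

    With ``binding_rate`` set, event times are the sum of an exponential
    binding wait (rate r_B) and an exponential reaction wait (rate r_P),
    i.e. draws from the conditioned two-step model.  Events beyond ``t_tot``
    are right-censored (NaN).
    """
    rng = np.random.default_rng(seed)
    times = rng.exponential(1.0 / rate, size=n_sim)
    if binding_rate is not None:
        times += rng.exponential(1.0 / binding_rate, size=n_sim)
    censored = times > t_tot
    times[censored] = np.nan
    frame = pd.DataFrame({site_name: times},
                         index=pd.RangeIndex(n_sim, name="replica"))
    return EventTable(t_phospho=frame, t_tot=t_tot)


def generate_multisite_events(rates: dict, n_sim: int, t_tot: float,
                              seed: int = 0) -> EventTable:
    """Independent exponential first-passage times for several sites."""
    rng = np.random.default_rng(seed)
    data = {}
    for site, r in rates.items():
        t = rng.exponential(1.0 / r, size=n_sim)
        t[t > t_tot] = np.nan
        data[site] = t
    frame = pd.DataFrame(data, index=pd.RangeIndex(n_sim, name="replica"))
    return EventTable(t_phospho=frame, t_tot=t_tot)


def generate_droplet_gas(n_dense_chains: int, n_dilute_chains: int,
                         beads_per_chain: int = 24, droplet_radius: float = 8.0,
                         box: float = 50.0, seed: int = 0,
                         bead_spacing: float = 0.38,
                         pser_per_chain: np.ndarray | None = None,
                         straddle: bool = False, gas_margin: float = 4.0):
    """Dense spherical droplet plus dispersed gas chains, with ground truth.

    Returns (positions, chain_id, is_pser, truth) where ``truth`` is a dict
    holding the constructed droplet chain set and center.  Chains are short
    self-avoiding-ish random walks; dense chains start inside the droplet
    sphere, dilute chains at least ``gas_margin`` nm away from it.  With
    ``straddle``
    the droplet center sits on a box corner so the droplet wraps around
    the periodic boundary.
    """
    n_chains = n_dense_chains + n_dilute_chains
    volume_needed = n_chains * beads_per_chain * bead_spacing**3
    if volume_needed > box**3:
        raise ValueError("overfilled box")
    rng = np.random.default_rng(seed)
    center = (np.zeros(3) if straddle
              else np.full(3, box / 2.0))
    positions = []
    chain_id = []
    for c in range(n_chains):
        if c < n_dense_chains:
            # chain origin uniform in the droplet sphere
            while True:
                o = rng.uniform(-1, 1, 3)
                if np.dot(o, o) <= 1:
                    break
            origin = center + o * (droplet_radius - 1.0)
        else:
            while True:
                origin = rng.uniform(0, box, 3)
                d = origin - center
                d -= box * np.rint(d / box)
                if np.linalg.norm(d) > droplet_radius + gas_margin + 1.0:
                    break
        chain = [origin]
        placed = np.array(positions) if positions else np.empty((0, 3))
        for _ in range(beads_per_chain - 1):
            best, best_d = None, -1.0
            for _try in range(60):
                step = rng.standard_normal(3)
                step *= bead_spacing / np.linalg.norm(step)
                nxt = chain[-1] + step
                dc = nxt - center
                dc -= box * np.rint(dc / box)
                if c < n_dense_chains:      # keep dense chains in the droplet
                    if np.linalg.norm(dc) > droplet_radius:
                        nxt = chain[-1] - step
                elif np.linalg.norm(dc) < droplet_radius + gas_margin:
                    nxt = chain[-1] - step   # keep gas out of the droplet shell
                # enforce a ~0.4 nm exclusion against everything placed so far
                d_old = (np.min(np.linalg.norm(placed - nxt, axis=1))
                         if len(placed) else np.inf)
                d_own = min((np.linalg.norm(p - nxt) for p in chain[:-1]),
                            default=np.inf)
                d = min(d_old, d_own)
                if d > best_d:
                    best, best_d = nxt, d
                if d >= 0.4:
                    break
            chain.append(best)
        positions.extend(chain)
        chain_id.extend([c] * beads_per_chain)
    positions = np.mod(np.array(positions), box)
    chain_id = np.array(chain_id)
    if pser_per_chain is None:
        pser_per_chain = np.zeros(n_chains, dtype=int)
    pser_per_chain = np.asarray(pser_per_chain, dtype=int)
    is_pser = np.zeros(len(positions), dtype=bool)
    for c in range(n_chains):
        beads = np.flatnonzero(chain_id == c)
        k = min(pser_per_chain[c], len(beads))
        is_pser[beads[:k]] = True
    truth = dict(droplet_chains=set(range(n_dense_chains)), center=center,
                 droplet_radius=droplet_radius)
    return positions, chain_id, is_pser, truth


GENERATOR_KINDS = ("markov_cycle", "telegraph_contact", "exponential_events",
                   "droplet_gas")


class SyntheticSpec:
    """Declarative generator spec: kind + parameters + mandatory seed.

    ``generate()`` dispatches to the matching module function, so configs
    and manifests can carry a single serializable description of the
    synthetic input.
    """

    def __init__(self, kind: str, seed: int, **parameters):
        if kind not in GENERATOR_KINDS:
            raise ValueError(f"unknown generator kind {kind!r}")
        if seed is None:
            raise ValueError("seed is mandatory")
        for key in ("rate", "rates", "forward", "backward", "rate_on",
                    "rate_off", "binding_rate"):
            val = parameters.get(key)
            if val is None:
                continue
            arr = np.atleast_1d(np.asarray(
                list(val.values()) if isinstance(val, dict) else val,
                dtype=float))
            if np.any(arr <= 0):
                raise ValueError(f"{key} must be positive")
        self.kind = kind
        self.seed = int(seed)
        self.parameters = parameters

    def generate(self):
        fn = {"markov_cycle": generate_markov_cycle,
              "telegraph_contact": generate_telegraph_contact,
              "exponential_events": generate_exponential_events,
              "droplet_gas": generate_droplet_gas}[self.kind]
        return fn(seed=self.seed, **self.parameters)
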