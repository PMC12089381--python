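"""Markov-state-model machinery for the 4-state phosphorylation cycle.

The cycle states are 1: unbound/Ser, 2: bound/Ser, 3: bound/pSer,
4: unbound/pSer.  A non-reversible maximum-likelihood estimator (sliding-
window transition counts, row normalization) gives the transition matrix
T(tau); first-order rates k_ij = T_ij(tau)/tau feed the local-detailed-
balance estimate of the heat dissipated per forward cycle,

    dmu_cycle = -RT ln[(k12 k23 k34 k41) / (k14 k43 k32 k21)],

which must equal the chemical driving dmu_p applied in the phosphorylation
Monte-Carlo step if the simulation is thermodynamically consistent.
Model quality is checked through implied timescales and the
Chapman-Kolmogorov test; uncertainties come from a circular block bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import R_GAS

STATE_LABELS = {1: "unbound/Ser", 2: "bound/Ser", 3: "bound/pSer",
                4: "unbound/pSer"}

# forward cycle 1 -> 2 -> 3 -> 4 -> 1 (0-based edges)
_FORWARD_EDGES = [(0, 1), (1, 2), (2, 3), (3, 0)]


@dataclass
class DiscreteTrajectory:
    """Integer state sequence on the Markov time base."""

    states: np.ndarray            # values in 1..n_states
    markov_step_ns: float = 0.1   # ns per Markov step (1e4 MD steps of 10 fs)
    n_states: int = 4

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise ValueError("state sequence must be one-dimensional")
        if len(self.states) and (self.states.min() < 1
                                 or self.states.max() > self.n_states):
            raise ValueError(f"states must lie in 1..{self.n_states}")

    def __len__(self):
        return len(self.states)

    def discard_burn_in(self, burn_in_ns: float) -> "DiscreteTrajectory":
        k = int(round(burn_in_ns / self.markov_step_ns))
        return DiscreteTrajectory(self.states[k:], self.markov_step_ns,
                                  self.n_states)


@dataclass
class MSMModel:
    """Transition matrix at lag tau with derived spectral quantities."""

    lag: int
    counts: np.ndarray
    transition_matrix: np.ndarray
    markov_step_ns: float = 0.1
    empty_rows: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def eigenvalues(self) -> np.ndarray:
        ev = np.linalg.eigvals(self.transition_matrix)
        return ev[np.argsort(-np.abs(ev))]

    @property
    def stationary_distribution(self) -> np.ndarray:
        evals, evecs = np.linalg.eig(self.transition_matrix.T)
        i = np.argmin(np.abs(evals - 1.0))
        pi = np.real(evecs[:, i])
        return pi / pi.sum()


# ---------------------------------------------------------------------------
# state assignment


def _tbsa(labels: np.ndarray, soft: np.ndarray,
          low: float = 0.30, high: float = 0.70) -> np.ndarray:
    """Transition-based state assignment for low-confidence frames.

    Frames whose soft (bound) probability lies strictly inside (low, high)
    inherit the preceding firmly assigned state until the next firm state;
    the uncertain stretch is split at the transition midpoint.  Leading and
    trailing uncertain stretches take the nearest firm state.
    """
    labels = labels.copy()
    firm = (soft <= low) | (soft >= high)
    if not firm.any():
        return labels
    idx = np.flatnonzero(firm)
    # leading stretch
    labels[: idx[0]] = labels[idx[0]]
    # trailing stretch
    labels[idx[-1] + 1:] = labels[idx[-1]]
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a <= 1:
            continue
        if labels[a] == labels[b]:
            labels[a + 1: b] = labels[a]
        else:
            mid = (a + b + 1) // 2
            labels[a + 1: mid] = labels[a]
            labels[mid: b] = labels[b]
    return labels


def assign_two_states(features: np.ndarray, method: str = "threshold",
                      cutoff: float = 1.0, soft_width: float = 0.15,
                      lag: int = 10, random_state: int = 0) -> np.ndarray:
    """Label frames bound (True) / unbound (False) from distance features.

    ``threshold``    bound if the minimum active-site distance is below
                     ``cutoff`` (nm); soft probability from a logistic of
                     width ``soft_width`` around the cutoff.
    ``vamp_linear``  two-state split along the dominant VAMP-scored linear
                     projection of the (whitened) features at lag ``lag``,
                     soft probabilities from a two-component 1-D Gaussian
                     mixture on the projection.

    Frames with soft probability in (0.30, 0.70) are relabeled by
    transition-based state assignment.  Raises if only one state is visited.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and features.ndim == 1:
        X = X.T
    if method == "threshold":
        d = X.min(axis=1)
        soft = 1.0 / (1.0 + np.exp((d - cutoff) / soft_width))
        labels = soft >= 0.5
    elif method == "vamp_linear":
        proj = _dominant_vamp_projection(X, lag)
        soft, labels = _gmm_soft_labels(proj, random_state)
        # orient: bound = smaller mean feature norm
        if X[labels].mean() > X[~labels].mean():
            labels, soft = ~labels, 1.0 - soft
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = _tbsa(labels, soft)
    if labels.all() or not labels.any():
        raise ValueError("trajectory never leaves one state; "
                         "MSM construction refused")
    return labels


def _dominant_vamp_projection(X: np.ndarray, lag: int) -> np.ndarray:
    """First non-trivial singular function of the whitened time-lagged
    covariance (linear VAMP); returns the per-frame projection."""
    X = X - X.mean(axis=0)
    X0, Xt = X[:-lag], X[lag:]
    c00 = X0.T @ X0 / len(X0)
    ctt = Xt.T @ Xt / len(Xt)
    c0t = X0.T @ Xt / len(X0)
    eps = 1e-10 * np.trace(c00) / len(c00)
    w0 = np.linalg.inv(np.linalg.cholesky(c00 + eps * np.eye(len(c00))))
    wt = np.linalg.inv(np.linalg.cholesky(ctt + eps * np.eye(len(ctt))))
    K = w0 @ c0t @ wt.T
    u, s, vt = np.linalg.svd(K)
    return X @ (w0.T @ u[:, 0])


def _gmm_soft_labels(proj: np.ndarray, random_state: int):
    from sklearn.mixture import GaussianMixture
    gm = GaussianMixture(n_components=2, random_state=random_state,
                         n_init=3).fit(proj.reshape(-1, 1))
    resp = gm.predict_proba(proj.reshape(-1, 1))[:, 0]
    labels = resp >= 0.5
    return resp, labels


def build_cycle_trajectory(bound: np.ndarray, pser: np.ndarray,
                           markov_step_ns: float = 0.1) -> DiscreteTrajectory:
    """Combine bound/unbound labels with chemical identity into states 1-4."""
    bound = np.asarray(bound, dtype=bool)
    pser = np.asarray(pser, dtype=bool)
    if bound.shape != pser.shape:
        raise ValueError("label sequences differ in length")
    states = np.where(pser, np.where(bound, 3, 4), np.where(bound, 2, 1))
    return DiscreteTrajectory(states, markov_step_ns)


# ---------------------------------------------------------------------------
# estimation


def count_transitions(states: np.ndarray, lag: int, n_states: int) -> np.ndarray:
    """Sliding-window transition counts at the given lag."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if len(states) <= lag:
        raise ValueError("trajectory shorter than the lag")
    a = states[:-lag] - 1
    b = states[lag:] - 1
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (a, b), 1.0)
    return counts


def estimate_transition_matrix(dtraj: DiscreteTrajectory,
                               lag: int = 10) -> MSMModel:
    """Non-reversible maximum-likelihood estimate T_ij = C_ij / sum_j C_ij."""
    counts = count_transitions(dtraj.states, lag, dtraj.n_states)
    rowsum = counts.sum(axis=1)
    empty = np.flatnonzero(rowsum == 0)
    if len(empty):
        raise ValueError(
            f"states {(empty + 1).tolist()} have no outgoing transitions "
            f"at lag {lag}; the chain is disconnected at this lag")
    T = counts / rowsum[:, None]
    return MSMModel(lag=lag, counts=counts, transition_matrix=T,
                    markov_step_ns=dtraj.markov_step_ns, empty_rows=empty)


def transition_rates(model: MSMModel) -> np.ndarray:
    """First-order rate estimate k_ij = T_ij(tau)/tau (per Markov step).

    Isolated here so an alternative estimator (e.g. a matrix logarithm)
    can be swapped in without touching the cycle affinity.
    """
    if model.lag == 0:
        raise ValueError("lag must be positive")
    k = model.transition_matrix / model.lag
    np.fill_diagonal(k, 0.0)
    return k


def cycle_affinity_from_rates(k: np.ndarray, temperature: float = 300.0) -> float:
    """-RT ln of the forward/backward rate product around the 4-cycle, kJ/mol."""
    fwd = np.prod([k[i, j] for i, j in _FORWARD_EDGES])
    bwd = np.prod([k[j, i] for i, j in _FORWARD_EDGES])
    if fwd <= 0 or bwd <= 0:
        zero = [(i + 1, j + 1) for i, j in _FORWARD_EDGES
                if k[i, j] <= 0 or k[j, i] <= 0]
        raise ValueError(f"zero rate on cycle edges {zero}; affinity undefined")
    return float(-R_GAS * temperature * np.log(fwd / bwd))


def delta_mu_cycle(dtraj: DiscreteTrajectory, lag: int = 10,
                   temperature: float = 300.0, n_boot: int = 30,
                   block_len: int | None = None, seed: int = 0,
                   ) -> tuple[float, float]:
    """Dissipated heat per forward cycle with a bootstrap SEM (kJ/mol).

    Negative for clockwise driving (dmu_p < 0).  Invariant under uniform
    rescaling of all rates, so the estimate does not depend on the MC
    attempt frequency.
    """
    def estimator(states: np.ndarray) -> float:
        model = estimate_transition_matrix(
            DiscreteTrajectory(states, dtraj.markov_step_ns, dtraj.n_states),
            lag)
        return cycle_affinity_from_rates(transition_rates(model), temperature)

    value = estimator(dtraj.states)
    if block_len is None:
        block_len = 10 * lag
    _, sem = bootstrap_observable(dtraj, estimator, n_boot=n_boot,
                                  block_len=block_len, seed=seed)
    return value, sem


def edge_log_rate_ratios(k: np.ndarray, temperature: float = 300.0) -> dict:
    """RT ln(k_ij/k_ji) per cycle edge; only 2<->3 should move with dmu_p."""
    out = {}
    for i, j in _FORWARD_EDGES:
        if k[i, j] <= 0 or k[j, i] <= 0:
            out[(i + 1, j + 1)] = np.nan
        else:
            out[(i + 1, j + 1)] = float(R_GAS * temperature
                                        * np.log(k[i, j] / k[j, i]))
    return out


def coarse_grain_states(dtraj: DiscreteTrajectory,
                        mapping: dict[int, int]) -> DiscreteTrajectory:
    """Merge states (e.g. {1:1, 2:2, 3:3, 4:1} for the 3-state robustness check)."""
    states = np.vectorize(mapping.__getitem__)(dtraj.states)
    return DiscreteTrajectory(states, dtraj.markov_step_ns,
                              n_states=max(mapping.values()))


def cycle_affinity_3state(k: np.ndarray, temperature: float = 300.0) -> float:
    """Affinity of the merged 3-state cycle 1 -> 2 -> 3 -> 1."""
    edges = [(0, 1), (1, 2), (2, 0)]
    fwd = np.prod([k[i, j] for i, j in edges])
    bwd = np.prod([k[j, i] for i, j in edges])
    if fwd <= 0 or bwd <= 0:
        raise ValueError("zero rate on 3-state cycle edge")
    return float(-R_GAS * temperature * np.log(fwd / bwd))


# ---------------------------------------------------------------------------
# validation diagnostics


def implied_timescales(model: MSMModel, flag_oscillatory: bool = False):
    """t_i = -tau/ln|lambda_i| for each non-unit eigenvalue, in Markov steps.

    Eigenvalues are sorted by magnitude; the leading (unit) one is dropped.
    Zero eigenvalues mean relaxation below the lag resolution and yield 0.
    Negative real eigenvalues are flagged oscillatory when requested.
    """
    ev = model.eigenvalues
    ev = ev[1:]                               # drop the stationary eigenvalue
    mags = np.abs(ev)
    with np.errstate(divide="ignore"):
        ts = np.where(mags > 0, -model.lag / np.log(mags), 0.0)
    ts = np.real(ts)
    if flag_oscillatory:
        return ts, np.real(ev) < 0
    return ts


def implied_timescales_vs_lag(dtraj: DiscreteTrajectory,
                              lags: list[int]) -> np.ndarray:
    return np.array([implied_timescales(estimate_transition_matrix(dtraj, L))
                     for L in lags])


def ck_test(dtraj: DiscreteTrajectory, lag: int, n_values: list[int],
            n_boot: int = 100, block_len: int | None = None,
            seed: int = 0) -> dict:
    """Chapman-Kolmogorov test: T(n tau) vs [T(tau)]^n with bootstrap CIs.

    Returns a dict with arrays ``estimated``/``predicted`` of shape
    (len(n_values), n, n) and matching 95% bootstrap confidence bands.
    """
    n_values = list(n_values)
    if min(n_values) < 1:
        raise ValueError("n must be >= 1")
    if len(dtraj) <= lag * max(n_values):
        raise ValueError("trajectory too short at the largest lag multiple")
    ns = dtraj.n_states
    if block_len is None:
        block_len = 10 * lag

    def both(states):
        T1 = (estimate_transition_matrix(
            DiscreteTrajectory(states, dtraj.markov_step_ns, ns), lag)
            .transition_matrix)
        est = np.empty((len(n_values), ns, ns))
        pred = np.empty((len(n_values), ns, ns))
        for a, nv in enumerate(n_values):
            est[a] = (estimate_transition_matrix(
                DiscreteTrajectory(states, dtraj.markov_step_ns, ns),
                lag * nv).transition_matrix)
            pred[a] = np.linalg.matrix_power(T1, nv)
        return est, pred

    est, pred = both(dtraj.states)
    rng = np.random.default_rng(seed)
    boots_e, boots_p = [], []
    for _ in range(n_boot):
        sample = _circular_block_resample(dtraj.states, block_len, rng)
        try:
            e, p = both(sample)
        except ValueError:          # disconnected resample; skip
            continue
        boots_e.append(e)
        boots_p.append(p)
    boots_e, boots_p = np.array(boots_e), np.array(boots_p)
    ci = lambda b: (np.percentile(b, 2.5, axis=0),
                    np.percentile(b, 97.5, axis=0))
    lo_e, hi_e = ci(boots_e)
    lo_p, hi_p = ci(boots_p)
    # agreement = the two 95% bands overlap
    within = (lo_e <= hi_p + 1e-12) & (hi_e >= lo_p - 1e-12)
    return dict(n_values=n_values, estimated=est, predicted=pred,
                estimated_ci=(lo_e, hi_e), predicted_ci=(lo_p, hi_p),
                within_ci=within)


def ck_max_deviation(result: dict) -> float:
    """Largest |estimated - predicted| over all entries and lag multiples."""
    return float(np.max(np.abs(result["estimated"] - result["predicted"])))


# ---------------------------------------------------------------------------
# bootstrap


def _circular_block_resample(states: np.ndarray, block_len: int,
                             rng: np.random.Generator) -> np.ndarray:
    n = len(states)
    n_blocks = int(np.ceil(n / block_len))
    starts = rng.integers(0, n, size=n_blocks)
    idx = (starts[:, None] + np.arange(block_len)[None, :]) % n
    return states[idx.ravel()][:n]


def bootstrap_observable(dtraj: DiscreteTrajectory, estimator,
                         n_boot: int = 100, block_len: int = 100,
                         seed: int = 0) -> tuple[float, float]:
    """Circular block bootstrap of a scalar estimator over the state sequence.

    Returns the bootstrap mean and SEM (standard deviation of the replicate
    estimates).  Replicates on which the estimator is undefined (e.g. a
    disconnected resample) are dropped and at least 3 must survive.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 for an SEM")
    if block_len >= len(dtraj):
        raise ValueError("block_len must be shorter than the trajectory")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_boot):
        sample = _circular_block_resample(dtraj.states, block_len, rng)
        try:
            values.append(estimator(sample))
        except ValueError:
            continue
    if len(values) < 3:
        raise ValueError("too few valid bootstrap replicates")
    values = np.asarray(values, dtype=float)
    return float(values.mean()), float(values.std(ddof=1))
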