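"""Phosphorylation and contact kinetics from first-passage event tables.

Rates come from the exponential maximum-likelihood estimator with a uniform
prior, r = (n+1)/Theta, where Theta is the total exposure: the sum of
observed first-phosphorylation times plus the full replica length for each
censored replica.  Survival curves are the normalized inverse cumulative
histogram of event times, fitted either by a single exponential or by the
binding-conditioned double-exponential model.  Order statistics (which Ser
fires first, how many fired before a given site) summarize the
phosphorylation pattern across replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr


@dataclass
class EventTable:
    """First-phosphorylation times per (replica, site); NaN = censored."""

    t_phospho: pd.DataFrame     # index: replica, columns: site, values: ns/us
    t_tot: float                # replica length, same time unit
    contact_times: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        vals = self.t_phospho.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(vals <= 0) or np.any(vals > self.t_tot + 1e-12):
                raise ValueError("event times must satisfy 0 < t <= t_tot")

    @property
    def n_sim(self) -> int:
        return len(self.t_phospho)

    @property
    def sites(self):
        return list(self.t_phospho.columns)

    def to_tsv(self, path):
        long = self.t_phospho.reset_index(names="replica").melt(
            id_vars="replica", var_name="site", value_name="t_phospho")
        long["t_tot"] = self.t_tot
        long.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        long = pd.read_csv(path, sep="\t", na_values="NA")
        t_tot = float(long["t_tot"].iloc[0])
        wide = long.pivot(index="replica", columns="site",
                          values="t_phospho")
        wide.columns = [int(c) if str(c).isdigit() else c
                        for c in wide.columns]
        return cls(t_phospho=wide, t_tot=t_tot)


@dataclass
class RateEstimate:
    """Posterior-mean exponential rate with its variance and exposure."""

    rate: float          # 1/time
    variance: float      # 1/time^2
    n_events: int
    exposure: float      # total observation time Theta

    @property
    def sem(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass
class SurvivalFit:
    model: str                   # "single" or "conditioned"
    r_p: float
    r_b: float | None = None     # conditioned only; labeled so r_b >= r_p
    residual_rms: float = np.nan


# ---------------------------------------------------------------------------
# rate estimators


def phospho_rate_mle(table: EventTable, site) -> RateEstimate:
    """r = (n+1)/Theta with Theta = sum(t_i) + (N - n) t_tot.

    Censored replicas contribute their full length to the exposure; the
    variance is (n+1)/Theta^2 = r/Theta.
    """
    times = table.t_phospho[site].to_numpy(dtype=float)
    observed = times[np.isfinite(times)]
    n = len(observed)
    theta = observed.sum() + (table.n_sim - n) * table.t_tot
    if theta <= 0:
        raise ValueError("zero total exposure")
    rate = (n + 1) / theta
    return RateEstimate(rate=float(rate), variance=float((n + 1) / theta**2),
                        n_events=n, exposure=float(theta))


def survival_curve(table: EventTable, site, n_bins: int = 50,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized inverse cumulative histogram of first-phosphorylation times.

    Bin b holds (events in bin b or later) / N_sim, evaluated at the left
    bin edges; right-censoring leaves the tail flat at zero counts beyond
    the last event.  Non-increasing by construction.
    """
    times = table.t_phospho[site].to_numpy(dtype=float)
    observed = times[np.isfinite(times)]
    if len(observed) == 0:
        raise ValueError(f"no events at site {site}; curve degenerate")
    edges = np.linspace(0.0, table.t_tot, n_bins + 1)
    counts, _ = np.histogram(observed, bins=edges)
    inv_cum = counts[::-1].cumsum()[::-1] / table.n_sim
    return edges[:-1], inv_cum


def conditioned_survival(t, r_b, r_p):
    """Complementary CDF of an exponential preceded by exponential binding."""
    t = np.asarray(t, dtype=float)
    if abs(r_b - r_p) < 1e-9 * max(r_b, r_p):
        # analytic r_b -> r_p limit: (1 + r t) e^{-r t}
        return (1.0 + r_p * t) * np.exp(-r_p * t)
    pref = r_b * r_p / (r_b - r_p)
    return pref * (np.exp(-r_p * t) / r_p - np.exp(-r_b * t) / r_b)


def fit_survival(t: np.ndarray, curve: np.ndarray,
                 model: str = "single") -> SurvivalFit:
    """Least-squares fit of the survival curve.

    ``single``       S(t) = a exp(-r_p t)   (a absorbs the censored fraction)
    ``conditioned``  S(t) = a * conditioned_survival(t; r_b, r_p)

    The conditioned fit resolves the r_b/r_p exchange symmetry by assigning
    the larger fitted rate to r_b; it reduces to the single model as
    r_b -> inf.
    """
    t = np.asarray(t, dtype=float)
    curve = np.asarray(curve, dtype=float)
    span = t[-1] - t[0] if len(t) > 1 else 1.0
    r0 = 1.0 / max(span / 3.0, 1e-12)
    if model == "single":
        def f(x, a, rp):
            return a * np.exp(-rp * x)
        popt, _ = curve_fit(f, t, curve, p0=(curve[0] or 1.0, r0),
                            maxfev=20000)
        fit = SurvivalFit(model="single", r_p=float(abs(popt[1])))
    elif model == "conditioned":
        def f(x, a, rb, rp):
            return a * conditioned_survival(x, abs(rb), abs(rp))
        popt, _ = curve_fit(f, t, curve, p0=(curve[0] or 1.0, 10 * r0, r0),
                            maxfev=50000)
        rb, rp = sorted((float(abs(popt[1])), float(abs(popt[2]))),
                        reverse=True)
        fit = SurvivalFit(model="conditioned", r_p=rp, r_b=rb)
        popt = (popt[0], rb, rp)
    else:
        raise ValueError(f"unknown survival model {model!r}")
    resid = curve - f(t, *popt)
    fit.residual_rms = float(np.sqrt(np.mean(resid**2)))
    return fit


# ---------------------------------------------------------------------------
# order statistics


def order_probability_matrix(table: EventTable) -> pd.DataFrame:
    """p(t_P(Ser_i) < t_P(Ser_j)) over replicas where the order is decidable.

    Decidable: both observed (compare times; ties are undecidable), or
    exactly one observed (the observed one counts as first).  Pairs with no
    decidable replica are NaN; the diagonal is NaN.
    """
    sites = table.sites
    times = table.t_phospho.to_numpy(dtype=float)
    n_sites = len(sites)
    p = np.full((n_sites, n_sites), np.nan)
    for a in range(n_sites):
        for b in range(n_sites):
            if a == b:
                continue
            ta, tb = times[:, a], times[:, b]
            both = np.isfinite(ta) & np.isfinite(tb) & (ta != tb)
            only_a = np.isfinite(ta) & ~np.isfinite(tb)
            only_b = ~np.isfinite(ta) & np.isfinite(tb)
            first_a = np.sum(ta[both] < tb[both]) + only_a.sum()
            decidable = both.sum() + only_a.sum() + only_b.sum()
            if decidable > 0:
                p[a, b] = first_a / decidable
    return pd.DataFrame(p, index=sites, columns=sites)


def arrival_order_histogram(table: EventTable, site) -> np.ndarray:
    """Counts over n = number of sites phosphorylated before ``site``.

    Replicas where ``site`` never fires are excluded; the returned counts
    sum to the number of replicas in which the site fired.
    """
    if site not in table.sites:
        raise KeyError(f"unknown site {site!r}")
    times = table.t_phospho.to_numpy(dtype=float)
    col = table.sites.index(site)
    n_sites = len(table.sites)
    hist = np.zeros(n_sites, dtype=int)
    for rep in range(table.n_sim):
        t_site = times[rep, col]
        if not np.isfinite(t_site):
            continue
        others = np.delete(times[rep], col)
        n_prior = int(np.sum(np.isfinite(others) & (others < t_site)))
        hist[n_prior] += 1
    return hist


# ---------------------------------------------------------------------------
# contacts


def contact_events_from_distances(distances: np.ndarray,
                                  cutoff: float = 1.0) -> int:
    """Rising edges of the all-three-distances contact condition."""
    d = np.asarray(distances, dtype=float)
    in_contact = np.all(d < cutoff, axis=1)
    rising = in_contact[1:] & ~in_contact[:-1]
    return int(rising.sum()) + int(in_contact[0])


def contact_rate(replica_counts: list[int] | np.ndarray,
                 replica_time: float) -> tuple[float, float]:
    """Contacts per unit time averaged over replicas, with replica SEM."""
    counts = np.asarray(replica_counts, dtype=float)
    if replica_time <= 0 or len(counts) == 0:
        raise ValueError("need positive replica time and >= 1 replica")
    rates = counts / replica_time
    sem = (rates.std(ddof=1) / np.sqrt(len(rates))
           if len(rates) > 1 else np.nan)
    return float(rates.mean()), float(sem)


def rate_contact_correlation(r_p: np.ndarray, r_c: np.ndarray) -> float:
    """Sample Pearson correlation of per-site phosphorylation vs contact rates."""
    r_p, r_c = np.asarray(r_p, float), np.asarray(r_c, float)
    if len(r_p) != len(r_c):
        raise ValueError("site lists differ in length")
    if len(r_p) < 3:
        raise ValueError("need at least 3 sites")
    return float(pearsonr(r_p, r_c).statistic)
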