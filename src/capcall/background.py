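"""Distance-decay and mean-dispersion background model.

The random re-ligation rate between a viewpoint and nearby chromatin falls
off with genomic distance as a power law.  On log-log axes the expected
normalized bin count is linear in distance:

    mu_i = intercept * d_i**(-delta),      intercept = e**k_decay - 1,

with d_i the distance in 2-kb bin units (d_1 = 1 at the first bin beyond
the exclusion zone).  Counts at a given distance are negative-binomially
distributed with variance beta_i * mu_i, where the dispersion is a linear
function of the mean:

    beta_i = alpha * mu_i + k_disp   (clamped to >= 1 at prediction time).

Together the two fits define the null distribution of interaction counts at
any distance, from which window p-values are computed as NB upper tails.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class DecayModel:
    """Fitted power-law decay for one cell line (distance in bin units)."""

    cell_line: str
    delta: float
    intercept: float
    k_decay: float
    n_bins: int
    loglik: float

    def predict(self, d: np.ndarray | float) -> np.ndarray | float:
        """Expected normalized count at model distance d (bin units)."""
        return self.intercept * np.asarray(d, dtype=float) ** (-self.delta)


@dataclass
class DispersionModel:
    """Linear mean-dispersion law beta(mu) = alpha*mu + k_disp."""

    cell_line: str
    alpha: float
    k_disp: float
    n_obs: int
    loglik: float

    def beta(self, mu: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(self.alpha * np.asarray(mu, dtype=float) + self.k_disp, 1.0)


def fit_decay_model(curve: pd.DataFrame, cell_line: str | None = None) -> DecayModel:
    """Fit (delta, intercept) by regressing log E[Ybar_i] on log d_i.

    Ordinary least squares on the log-log axes is the maximum-likelihood
    estimate under the log-linear Gaussian error model.  Requires at least
    5 positive bins spanning at least one decade of distance.
    """
    if cell_line is not None:
        curve = curve[curve["cell_line"] == cell_line]
    elif "cell_line" in curve.columns:
        uniq = curve["cell_line"].unique()
        if len(uniq) != 1:
            raise ValueError("curve contains several cell lines; pass cell_line=")
        cell_line = str(uniq[0])
    else:
        cell_line = ""
    d = curve["bin"].to_numpy(dtype=float)
    y = curve["expected"].to_numpy(dtype=float)
    pos = y > 0
    if pos.sum() == 0:
        raise ValueError("all bins are zero; cannot fit decay")
    d, y = d[pos], y[pos]
    if len(np.unique(d)) < 2:
        raise ValueError("need more than one distance to fit decay")
    if pos.sum() < 5:
        raise ValueError("need at least 5 positive bins to fit decay")
    if d.max() / d.min() < 10:
        raise ValueError("positive bins must span at least one decade of distance")
    slope, icpt = np.polyfit(np.log(d), np.log(y), 1)
    resid = np.log(y) - (icpt + slope * np.log(d))
    sigma2 = float(np.mean(resid**2))
    loglik = float(-0.5 * len(d) * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1))
    intercept = float(np.exp(icpt))
    return DecayModel(
        cell_line=cell_line, delta=float(-slope), intercept=intercept,
        k_decay=float(np.log1p(intercept)), n_bins=int(len(d)), loglik=loglik,
    )


def _nb_loglik(y: np.ndarray, mu: np.ndarray, beta: np.ndarray) -> float:
    """Sum of NB(mean mu, var beta*mu) log-pmf, Poisson where beta -> 1."""
    beta = np.maximum(beta, 1.0)
    pois = beta <= 1.0 + 1e-9
    ll = np.empty(len(y))
    if pois.any():
        ll[pois] = stats.poisson.logpmf(y[pois], mu[pois])
    nb = ~pois
    if nb.any():
        r = mu[nb] / (beta[nb] - 1.0)
        p = 1.0 / beta[nb]
        ll[nb] = stats.nbinom.logpmf(y[nb], r, p)
    return float(np.sum(ll))


def fit_dispersion_model(
    observations: pd.DataFrame, cell_line: str = "", tol: float = 1e-8
) -> DispersionModel:
    """Maximum-likelihood (alpha, k_disp) of the linear dispersion law.

    ``observations`` carries one row per (probe, experiment, arm, bin) with
    columns ``y`` (the bin's normalized count, rounded to an integer) and
    ``mu`` (the model mean at that bin, experiment-corrected).  The NB
    likelihood is maximized over alpha >= 0, k_disp >= 1 with a coarse-grid
    multistart and L-BFGS-B polish.
    """
    y = np.round(observations["y"].to_numpy(dtype=float))
    mu = observations["mu"].to_numpy(dtype=float)
    keep = (mu > 0) & (y >= 0) & np.isfinite(mu)
    y, mu = y[keep], mu[keep]
    if len(y) < 10:
        raise ValueError("need at least 10 usable bins to fit dispersion")

    def nll(params: np.ndarray) -> float:
        alpha, k = params
        return -_nb_loglik(y, mu, alpha * mu + k)

    starts = [(a, k) for a in (0.0, 0.01, 0.05, 0.2) for k in (1.0, 2.0, 5.0, 20.0)]
    best = None
    for s in starts:
        res = optimize.minimize(
            nll, x0=np.asarray(s), method="L-BFGS-B",
            bounds=[(0.0, 100.0), (1.0, 1e4)], options={"ftol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, k = best.x
    if alpha * mu.max() + k <= 1.0 + 1e-6:
        warnings.warn("fitted variance does not exceed the mean; Poisson fallback")
        alpha, k = 0.0, 1.0
    return DispersionModel(
        cell_line=cell_line, alpha=float(alpha), k_disp=float(k),
        n_obs=int(len(y)), loglik=float(-best.fun),
    )


def nb_upper_tail(
    x: np.ndarray | float, mu: np.ndarray | float, beta: np.ndarray | float
) -> np.ndarray | float:
    """P(Y > floor(x)) under NB with mean mu and variance beta*mu.

    Continuous normalized counts are floored before evaluating the discrete
    tail, which is conservative (never understates the p-value).  At
    beta = 1 this is the Poisson survival function.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(beta < 1.0):
        raise ValueError("beta < 1: use the Poisson model (beta = 1) instead")
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    x, mu, beta = np.broadcast_arrays(x, mu, beta)
    xf = np.floor(x)
    out = np.empty(x.shape, dtype=float)
    pois = beta <= 1.0 + 1e-12
    if pois.any():
        out[pois] = stats.poisson.sf(xf[pois], mu[pois])
    nb = ~pois
    if nb.any():
        r = mu[nb] / (beta[nb] - 1.0)
        p = 1.0 / beta[nb]
        out[nb] = stats.nbinom.sf(xf[nb], r, p)
    if out.ndim == 0:
        return float(out)
    return out


# -- serialization ----------------------------------------------------------

def save_models(
    decay: DecayModel, dispersion: DispersionModel, path: str | Path
) -> None:
    payload = {
        "cell_line": decay.cell_line,
        "delta": decay.delta, "k_decay": decay.k_decay,
        "intercept": decay.intercept,
        "alpha": dispersion.alpha, "k_disp": dispersion.k_disp,
        "n_bins": decay.n_bins, "loglik": decay.loglik,
        "dispersion_n_obs": dispersion.n_obs,
        "dispersion_loglik": dispersion.loglik,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path: str | Path) -> tuple[DecayModel, DispersionModel]:
    d = json.loads(Path(path).read_text())
    decay = DecayModel(
        cell_line=d["cell_line"], delta=d["delta"], intercept=d["intercept"],
        k_decay=d["k_decay"], n_bins=d["n_bins"], loglik=d["loglik"],
    )
    disp = DispersionModel(
        cell_line=d["cell_line"], alpha=d["alpha"], k_disp=d["k_disp"],
        n_obs=d.get("dispersion_n_obs", 0), loglik=d.get("dispersion_loglik", 0.0),
    )
    return decay, disp
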