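"""Sloan neutral community model: prediction, fitting, bootstrap, and
classification of taxa against the neutral envelope.

The model predicts the occurrence frequency of a taxon across local
communities from its mean (metacommunity) relative abundance p, the local
community size N, and the immigration rate m, through the single dispersal
parameter Nm. Under neutral drift-immigration balance the local relative
abundance x of a taxon follows Beta(Nm*p, Nm*(1-p)); a taxon is scored as
detected when x exceeds a detection limit d, so

    freq_pred(p) = 1 - I_d(Nm*p, Nm*(1-p))

with I the regularized incomplete beta function. Nm is estimated by bounded
nonlinear least squares of freq_pred against the observed detection
frequencies over taxa; fit quality is the coefficient of determination R^2,
and a taxon-resampling bootstrap yields the 95% confidence interval for Nm.

The default detection limit is d = ln(2)/N, the abundance at which the
probability of observing at least one read in a sample of depth N,
1-(1-x)^N, crosses one half. This calibrates the model's sharp detection
threshold to the smooth binomial detection process of count data; the
conventional d = 1/N systematically inflates fitted Nm on count tables
(see docs/methods.md) and remains available as an override.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betainc

from .io import AbundanceTable


@dataclass
class NCMFit:
    """Fitted Sloan model with per-taxon predictions."""

    Nm: float
    N: float
    m: float
    d: float
    r_squared: float
    per_taxon: pd.DataFrame
    n_samples: int
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "Nm": self.Nm,
            "N": self.N,
            "m": self.m,
            "d": self.d,
            "r_squared": self.r_squared,
            "n_samples": self.n_samples,
            "n_taxa_fit": int(len(self.per_taxon)),
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def ncm_predict(p, Nm: float, d: float):
    """Predicted occurrence frequency 1 - I_d(Nm*p, Nm*(1-p)).

    ``p`` may be a scalar or array of metacommunity relative abundances,
    each strictly inside (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("relative abundance p must lie strictly in (0, 1)")
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not 0 < d < 1:
        raise ValueError("detection limit d must lie in (0, 1)")
    out = 1.0 - betainc(Nm * p, Nm * (1.0 - p), d)
    return float(out) if out.ndim == 0 else out


def _fit_nm(p: np.ndarray, freq: np.ndarray, d: float, nm_max: float) -> float:
    """Bounded least squares for Nm over log(Nm).

    A coarse log-spaced grid brackets the optimum (guarding against local
    minima and boundary sticking), then a bounded scalar minimization
    refines it within the bracketing interval.
    """

    def sse(log_nm):
        pred = 1.0 - betainc(np.exp(log_nm) * p, np.exp(log_nm) * (1.0 - p), d)
        return float(np.sum((freq - pred) ** 2))

    lo, hi = np.log(1e-3), np.log(nm_max)
    grid = np.linspace(lo, hi, 25)
    k = int(np.argmin([sse(g) for g in grid]))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(sse, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


def fit_ncm(
    table: AbundanceTable,
    N: float | None = None,
    d: float | None = None,
) -> NCMFit:
    """Fit the Sloan model to an abundance table.

    ``N`` defaults to the mean per-sample total count (requiring a count
    table); ``d`` defaults to ln(2)/N. Taxa never detected are excluded.
    Returns the fit without bootstrap CI (see :func:`bootstrap_ncm`).
    """
    x = table.values
    totals = x.sum(axis=1)
    if x.sum() == 0:
        raise ValueError("all-zero abundance table")
    if N is None:
        if np.allclose(totals, 1.0, atol=1e-6):
            raise ValueError(
                "table appears to be relative abundances; pass an explicit "
                "community size N to fit the neutral model"
            )
        N = float(totals.mean())
    if d is None:
        d = float(np.log(2) / N)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals[:, None] > 0, x / totals[:, None], 0.0)
    p = rel.mean(axis=0)
    freq_obs = (x > 0).mean(axis=0)
    keep = freq_obs > 0
    if keep.sum() < 10:
        raise ValueError(
            f"only {int(keep.sum())} taxa detected; need at least 10 to fit"
        )
    taxa = np.asarray(table.taxon_ids)[keep]
    p, freq_obs = p[keep], freq_obs[keep]
    nm = _fit_nm(p, freq_obs, d, nm_max=10.0 * N)
    pred = ncm_predict(p, nm, d)
    ss_res = float(np.sum((freq_obs - pred) ** 2))
    ss_tot = float(np.sum((freq_obs - freq_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    per_taxon = pd.DataFrame(
        {"p": p, "freq_obs": freq_obs, "freq_pred": pred}, index=taxa
    )
    return NCMFit(
        Nm=nm, N=float(N), m=nm / float(N), d=float(d), r_squared=r2,
        per_taxon=per_taxon, n_samples=table.n_samples,
    )


def bootstrap_ncm(
    table: AbundanceTable,
    n_boot: int = 1000,
    seed: int | None = 0,
    N: float | None = None,
    d: float | None = None,
    max_failure_rate: float = 0.2,
) -> NCMFit:
    """Fit plus taxon-resampling bootstrap 95% CI for Nm.

    Taxa (the regression's observation units) are resampled with
    replacement ``n_boot`` times and Nm refit each time; the CI is the
    2.5/97.5 percentile range. Errors if more than ``max_failure_rate`` of
    refits fail.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fit = fit_ncm(table, N=N, d=d)
    p = fit.per_taxon["p"].to_numpy()
    freq = fit.per_taxon["freq_obs"].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(p)
    estimates = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            estimates.append(_fit_nm(p[idx], freq[idx], fit.d, 10.0 * fit.N))
        except Exception:
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(
            f"bootstrap failure rate {failures / n_boot:.0%} exceeds "
            f"{max_failure_rate:.0%}"
        )
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    fit.ci_low, fit.ci_high, fit.n_boot, fit.seed = float(lo), float(hi), n_boot, seed
    return fit


def classify_partitions(fit: NCMFit, alpha: float = 0.05) -> pd.DataFrame:
    """Classify each fitted taxon against the neutral envelope.

    The envelope is the Wilson score interval at level 1-alpha around
    freq_pred given the number of samples; taxa are 'above', 'within' or
    'below' by the position of freq_obs. Returns per_taxon extended with
    envelope bounds and class.
    """
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    n = fit.n_samples
    pt = fit.per_taxon.copy()
    fp = pt["freq_pred"].to_numpy()
    denom = 1 + z**2 / n
    center = (fp + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(fp * (1 - fp) / n + z**2 / (4 * n**2))
    pt["envelope_low"] = np.clip(center - half, 0.0, 1.0)
    pt["envelope_high"] = np.clip(center + half, 0.0, 1.0)
    fo = pt["freq_obs"].to_numpy()
    pt["class"] = np.where(
        fo > pt["envelope_high"], "above",
        np.where(fo < pt["envelope_low"], "below", "within"),
    )
    return pt
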