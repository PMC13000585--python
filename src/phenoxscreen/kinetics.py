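"""Effective rate-constant extraction from cumulative reaction counts.

The stability metric of the screen is the rate constant ``k`` of the
saturating exponential

    N(t) = N_inf * (1 - exp(-k t))

fitted to the average cumulative hydrogen-transfer count over the
independent realizations of a system. The saturation arises from the
finite reactant pool, so the form is a numerical summary rather than a
mechanistic model; ``N_inf`` is left free instead of being pinned to
the number of radicals. Lower ``k`` means a more stable radical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .trajectory import ReactionSeries

__all__ = ["KineticsFit", "average_series", "fit_rate", "rate_screen"]


@dataclass
class KineticsFit:
    N_inf: float
    k: float          # ns^-1
    rss: float
    converged: bool
    message: str = ""


def average_series(series_list: Sequence[ReactionSeries]) -> ReactionSeries:
    """Pointwise mean of reaction-count series sharing one time grid."""
    if not series_list:
        raise ValueError("no series to average")
    t0 = series_list[0].times_ns
    for s in series_list[1:]:
        if s.times_ns.shape != t0.shape or not np.allclose(s.times_ns, t0):
            raise ValueError("series have mismatched time grids")
    counts = np.mean([s.counts for s in series_list], axis=0)
    return ReactionSeries(times_ns=t0.copy(), counts=counts)


def _model(t: np.ndarray, n_inf: float, k: float) -> np.ndarray:
    return n_inf * (1.0 - np.exp(-k * t))


def fit_rate(series: ReactionSeries, max_iter: int = 500) -> KineticsFit:
    """Nonlinear least-squares fit of the saturating exponential.

    Initialization: ``N_inf = max(counts)``; ``k = ln 2 / t_half`` with
    ``t_half`` the first time the counts exceed half the plateau
    (fallback ``1 / t_max``). Degenerate inputs (all-zero counts, or
    saturation so fast that k is unidentifiable on the grid) are
    reported with ``converged=False`` rather than raised.
    """
    t, y = series.times_ns, series.counts
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.all(y == 0):
        return KineticsFit(N_inf=0.0, k=np.nan, rss=0.0, converged=False,
                           message="all-zero counts: k unidentifiable")
    n0 = float(y.max())
    above = np.flatnonzero(y > n0 / 2.0)
    k0 = np.log(2.0) / t[above[0]] if len(above) else 1.0 / t[-1]
    if y[0] >= n0:  # counts already saturated at the first grid point
        return KineticsFit(N_inf=n0, k=np.inf, rss=0.0, converged=False,
                           message="saturated before first frame: k unbounded")
    try:
        popt, _ = curve_fit(
            _model, t, y, p0=(n0, k0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            maxfev=max_iter * 10, xtol=1e-8, ftol=1e-12,
        )
    except RuntimeError as exc:
        return KineticsFit(N_inf=np.nan, k=np.nan, rss=np.nan, converged=False,
                           message=str(exc))
    rss = float(np.sum((y - _model(t, *popt)) ** 2))
    return KineticsFit(N_inf=float(popt[0]), k=float(popt[1]), rss=rss, converged=True)


def rate_screen(
    per_candidate_series: Mapping[int, Sequence[ReactionSeries]],
) -> pd.DataFrame:
    """Average-then-fit per candidate; never aborts on a bad candidate.

    Returns the histogram-ready table with columns
    (candidate_id, k_ns_inv, N_inf, rss, converged).
    """
    rows = []
    for cid in sorted(per_candidate_series):
        fit = fit_rate(average_series(per_candidate_series[cid]))
        rows.append((cid, fit.k, fit.N_inf, fit.rss, fit.converged))
    return pd.DataFrame(
        rows, columns=["candidate_id", "k_ns_inv", "N_inf", "rss", "converged"]
    )
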