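"""Nonparametric cohort comparisons of component fractions.

The cohort readout mirrors the study design: cardiac vs respiratory
fractions compared per region, direction and respiratory period with the
Mann-Whitney U test (exact two-sided by enumeration for small samples,
normal approximation with midranks and tie correction otherwise) and the
two-sample Kolmogorov-Smirnov test.  P-values are reported uncorrected by
default; Holm correction is available as an option.

Because rank tests are invariant to strictly monotone transforms and
``F_c = 1 - F_r``, a between-period comparison of the respiratory fraction
carries identical evidence to the cardiac one, so one row per period pair
is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MannWhitneyResult",
    "mann_whitney_u",
    "ks_two_sample",
    "metrics_to_table",
    "compare_fractions",
]

EXACT_LIMIT = 16  # enumerate all C(n+m, n) arrangements up to this pooled size


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float  # two-sided p
    method: str  # "exact" or "normal"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x against y via midranks (handles ties)."""
    n, m = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:n].sum() - n * (n + 1) / 2)


def _exact_p(u_obs: float, n: int, m: int) -> float:
    """Two-sided exact p by complete enumeration of rank arrangements.

    Under H0 every choice of which pooled ranks belong to x is equally
    likely; p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    total = comb(n + m, n)
    lo = hi = 0
    for ranks in combinations(range(1, n + m + 1), n):
        u = sum(ranks) - n * (n + 1) / 2
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def mann_whitney_u(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``mode``: "exact" (enumeration; requires no ties and pooled size <=
    16), "normal" (midrank normal approximation with tie correction and
    continuity correction), or "auto" (exact when admissible).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n + m
    u = _u_statistic(x, y)

    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n + m <= EXACT_LIMIT and not has_ties)
    if mode == "exact" and (has_ties or n + m > EXACT_LIMIT):
        raise ValueError(
            "exact mode requires tie-free samples with pooled size <= "
            f"{EXACT_LIMIT} (got n+m={n + m}, ties={has_ties})"
        )
    if use_exact:
        return MannWhitneyResult(u=u, p=_exact_p(u, n, m), method="exact")

    mu = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / ((n + m) * (n + m - 1))
    sigma2 = n * m / 12.0 * (n + m + 1 - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=u, p=1.0, method="normal")
    z = (u - mu - np.sign(u - mu) * 0.5) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return MannWhitneyResult(u=u, p=p, method="normal")


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (D, two-sided p).

    D is the supremum ECDF distance, computed by a direct sweep over the
    pooled sample points; the p-value uses the exact small-sample
    distribution when feasible and the asymptotic series otherwise.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pts = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pts, side="right") / x.size
    cdf_y = np.searchsorted(y, pts, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    p = float(sps.ks_2samp(x, y, method="auto").pvalue)
    return d, p


def metrics_to_table(metrics: list) -> pd.DataFrame:
    """Tidy fraction table from ComponentMetrics records.

    One row per subject x region x period x direction x metric x component,
    with the fraction value; input to :func:`compare_fractions`.
    """
    rows = []
    for rec in metrics:
        for metric, (f_c, f_r) in (
            ("velocity", (rec.f_c, rec.f_r)),
            ("displacement", (rec.f_c_disp, rec.f_r_disp)),
        ):
            for component, frac in (("cardiac", f_c), ("respiratory", f_r)):
                rows.append(
                    {
                        "subject": rec.subject_id,
                        "region": rec.region,
                        "resp_period": rec.resp_period,
                        "direction": rec.direction,
                        "metric": metric,
                        "component": component,
                        "fraction": frac,
                    }
                )
    return pd.DataFrame(rows)


def compare_fractions(
    table: pd.DataFrame, mode: str = "auto", holm: bool = False
) -> pd.DataFrame:
    """Cohort comparison table over region x direction x metric.

    For each cell: a cardiac-vs-respiratory fraction comparison at every
    respiratory period, plus one between-period comparison per period pair
    (on the respiratory fraction; equivalent by rank symmetry for the
    cardiac one).  Emits Mann-Whitney U and p plus KS D and p per row;
    ``greater`` names the component/period with the larger median fraction.
    """
    required = {"subject", "region", "resp_period", "direction", "metric", "component", "fraction"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"fraction table is missing columns {sorted(missing)}")
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a cohort comparison")

    periods = sorted(table["resp_period"].unique())
    rows = []
    for (region, direction, metric), g in table.groupby(["region", "direction", "metric"]):
        for period in periods:
            gp = g[g["resp_period"] == period]
            x = gp.loc[gp["component"] == "cardiac", "fraction"].to_numpy()
            y = gp.loc[gp["component"] == "respiratory", "fraction"].to_numpy()
            mwu = mann_whitney_u(x, y, mode=mode)
            d, p_ks = ks_two_sample(x, y)
            rows.append(
                {
                    "region": region,
                    "direction": direction,
                    "metric": metric,
                    "comparison": "cardiac_vs_respiratory",
                    "resp_period": period,
                    "n_x": len(x),
                    "n_y": len(y),
                    "U": mwu.u,
                    "p_mwu": mwu.p,
                    "mwu_method": mwu.method,
                    "ks_D": d,
                    "p_ks": p_ks,
                    "greater": (
                        "cardiac" if np.median(x) > np.median(y) else "respiratory"
                    ),
                }
            )
        gr = g[g["component"] == "respiratory"]
        for p1, p2 in combinations(periods, 2):
            x = gr.loc[gr["resp_period"] == p1, "fraction"].to_numpy()
            y = gr.loc[gr["resp_period"] == p2, "fraction"].to_numpy()
            mwu = mann_whitney_u(x, y, mode=mode)
            d, p_ks = ks_two_sample(x, y)
            rows.append(
                {
                    "region": region,
                    "direction": direction,
                    "metric": metric,
                    "comparison": f"period_{p1:g}s_vs_{p2:g}s",
                    "resp_period": np.nan,
                    "n_x": len(x),
                    "n_y": len(y),
                    "U": mwu.u,
                    "p_mwu": mwu.p,
                    "mwu_method": mwu.method,
                    "ks_D": d,
                    "p_ks": p_ks,
                    "greater": f"{p1:g}s" if np.median(x) > np.median(y) else f"{p2:g}s",
                }
            )
    out = pd.DataFrame(rows)
    if holm:
        out["p_mwu_holm"] = _holm(out["p_mwu"].to_numpy())
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    k = len(p)
    order = np.argsort(p)
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
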