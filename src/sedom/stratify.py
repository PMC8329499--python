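"""Depth stratification: trend fits, two-group split, unique molecules, LEfSe.

The study design splits a sediment core into an upper stratum (5-100 cm) and
a deep stratum (110-300 cm); bulk DOM parameters are modeled against depth
with linear and exponential curves, and molecules that differ between the two
strata are screened with a two-class LEfSe: a Kruskal-Wallis test per
molecule followed by a bootstrapped one-dimensional linear-discriminant
effect size on abundances scaled to one million, reported as log10 and
thresholded (conventionally at 2).

This is the two-class core of LEfSe only: the published tool's subclass and
one-against-all stages have no role in a two-stratum design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TrendFit",
    "fit_depth_trend",
    "split_groups",
    "unique_molecules",
    "lefse_two_class",
]


@dataclass(frozen=True)
class TrendFit:
    model: str  # "linear" | "exponential"
    params: dict
    r: float
    p: float
    n: int
    converged: bool
    message: str = ""


def _linear_fit(x: np.ndarray, y: np.ndarray) -> TrendFit:
    if np.allclose(y, y[0]):
        return TrendFit(
            "linear", {"slope": 0.0, "intercept": float(y[0])}, float("nan"),
            float("nan"), len(x), False, "constant response: r undefined",
        )
    res = stats.linregress(x, y)
    return TrendFit(
        "linear",
        {"slope": float(res.slope), "intercept": float(res.intercept)},
        float(res.rvalue),
        float(res.pvalue),
        len(x),
        True,
    )


def _exp_model(x, a, b, k):
    return a + b * np.exp(k * x)


def _exp_fit(x: np.ndarray, y: np.ndarray) -> TrendFit:
    n = len(x)
    scale = np.ptp(x) or 1.0
    sst = float(np.sum((y - y.mean()) ** 2))
    best = None
    # multi-start on the rate constant; log-linear seeds are unreliable when
    # the asymptote a is unknown, so try both signs at two magnitudes
    for k0 in (-3.0 / scale, -0.5 / scale, 0.5 / scale, 3.0 / scale):
        ampl = y[np.argmax(np.exp(k0 * x))] - y[np.argmin(np.exp(k0 * x))]
        p0 = (float(y.mean()), float(ampl) or 1.0, k0)
        try:
            popt, _ = optimize.curve_fit(_exp_model, x, y, p0=p0, maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = y - _exp_model(x, *popt)
        sse = float(np.sum(resid**2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return TrendFit("exponential", {}, float("nan"), float("nan"), n, False,
                        "nonlinear least squares did not converge")
    popt, sse = best
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    r = float(np.sqrt(max(r2, 0.0)))
    # F-test against the intercept-only model (3 parameters)
    df_resid = n - 3
    if df_resid > 0 and sst > sse:
        f = ((sst - sse) / 2.0) / (sse / df_resid) if sse > 0 else np.inf
        p = float(stats.f.sf(f, 2, df_resid))
    else:
        p = float("nan")
    return TrendFit(
        "exponential",
        {"a": float(popt[0]), "b": float(popt[1]), "k": float(popt[2])},
        r,
        p,
        n,
        True,
    )


def fit_depth_trend(depths, values) -> tuple[TrendFit, TrendFit]:
    """Fit linear and exponential (y = a + b*exp(k*depth)) depth trends.

    Returns the two fits; nonconvergence of the exponential model is flagged
    on the returned TrendFit, never silently dropped.
    """
    x = np.asarray(depths, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("depths and values must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if len(np.unique(x)) != len(x):
        raise ValueError("depths must be distinct")
    return _linear_fit(x, y), _exp_fit(x, y)


def split_groups(depths, boundary: tuple[float, float] = (100.0, 110.0)) -> np.ndarray:
    """Label each depth "upper" (<= boundary[0]) or "deep" (>= boundary[1])."""
    lo, hi = boundary
    x = np.asarray(depths, dtype=float)
    if (x <= 0).any():
        raise ValueError("depths must be positive")
    labels = np.empty(len(x), dtype=object)
    for i, d in enumerate(x):
        if d <= lo:
            labels[i] = "upper"
        elif d >= hi:
            labels[i] = "deep"
        else:
            raise ValueError(f"depth {d} lies strictly between strata ({lo}, {hi})")
    return labels


def unique_molecules(matrix: pd.DataFrame, groups) -> dict[str, set]:
    """Group-unique and shared molecule sets by detection (abundance > 0).

    Returns a dict with one key per group label holding the molecules detected
    only in that group, plus ``"shared"`` for molecules detected in more than
    one group. Undetected molecules appear in no set.
    """
    groups = np.asarray(groups)
    if len(groups) != matrix.shape[1]:
        raise ValueError("one group label per sample column required")
    labels = list(dict.fromkeys(groups))
    detected = {
        g: set(matrix.index[(matrix.loc[:, groups == g] > 0).any(axis=1)]) for g in labels
    }
    out: dict[str, set] = {}
    for g in labels:
        others = set().union(*(detected[h] for h in labels if h != g)) if len(labels) > 1 else set()
        out[g] = detected[g] - others
    all_detected = set().union(*detected.values())
    out["shared"] = all_detected - set().union(*(out[g] for g in labels))
    return out


def lefse_two_class(
    matrix: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-class LEfSe: Kruskal-Wallis screen plus bootstrapped LDA effect size.

    Parameters
    ----------
    matrix
        molecule x sample abundances (any positive scale; each sample is
        rescaled to a total of 1e6, the LEfSe convention).
    groups
        one label per sample; exactly two distinct labels, each with >= 3
        samples.
    alpha, lda_threshold
        significance cutoff for the screen and log10 effect-size cutoff.
    n_boot, seed
        bootstrap replicates for the effect size; deterministic given seed.

    Returns one row per molecule with columns ``group`` (higher-abundance
    class), ``kw_p``, ``lda_score`` (NaN when the screen failed) and
    ``significant`` (both cutoffs passed). For a single feature the LDA
    discriminant direction is the feature axis itself, so the effect size
    reduces to the absolute between-class difference of bootstrap means on
    the per-million scale.
    """
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError("exactly two group labels required")
    idx_a = np.nonzero(groups == labels[0])[0]
    idx_b = np.nonzero(groups == labels[1])[0]
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("each group needs at least 3 samples")
    values = matrix.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have positive total abundance")
    scaled = values / totals * 1e6

    kw_p = np.ones(len(matrix))
    for i in range(len(matrix)):
        a, b = scaled[i, idx_a], scaled[i, idx_b]
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            kw_p[i] = 1.0
            continue
        kw_p[i] = stats.kruskal(a, b).pvalue

    rng = np.random.default_rng(seed)
    boots_a = rng.integers(0, len(idx_a), size=(n_boot, len(idx_a)))
    boots_b = rng.integers(0, len(idx_b), size=(n_boot, len(idx_b)))
    lda_score = np.full(len(matrix), np.nan)
    sig_rows = np.nonzero(kw_p < alpha)[0]
    if len(sig_rows):
        sub_a = scaled[np.ix_(sig_rows, idx_a)]
        sub_b = scaled[np.ix_(sig_rows, idx_b)]
        effects = np.empty((n_boot, len(sig_rows)))
        for b in range(n_boot):
            ma = sub_a[:, boots_a[b]].mean(axis=1)
            mb = sub_b[:, boots_b[b]].mean(axis=1)
            effects[b] = np.abs(ma - mb)
        mean_effect = effects.mean(axis=0)
        with np.errstate(divide="ignore"):
            lda_score[sig_rows] = np.log10(np.maximum(mean_effect, 1e-30))

    higher = np.where(
        scaled[:, idx_a].mean(axis=1) >= scaled[:, idx_b].mean(axis=1), labels[0], labels[1]
    )
    out = pd.DataFrame(
        {
            "group": higher,
            "kw_p": kw_p,
            "lda_score": lda_score,
            "significant": (kw_p < alpha) & (lda_score > lda_threshold),
        },
        index=matrix.index,
    )
    out.index.name = "molecule"
    return out
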