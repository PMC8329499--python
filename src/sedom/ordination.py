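"""Distance-based multivariate statistics for community/composition tables.

All ordinations work from Bray-Curtis dissimilarities. PCoA is classical
scaling (double-centered -d^2/2, eigendecomposition); NMDS minimizes Kruskal
stress-1 by majorization with isotonic-regression disparities, best of
several restarts, one of them seeded from PCoA. envfit regresses external
variables onto ordination axes with a Monte-Carlo permutation test; CCorA
relates two multivariate tables through canonical correlations and Pillai's
trace; dbRDA regresses PCoA coordinates on predictors with permutation-based
forward selection and partitions explained variance between predictor blocks.

Every permutation p-value uses the add-one convention p = (b + 1)/(m + 1) and
is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "bray_curtis",
    "OrdinationResult",
    "pcoa",
    "nmds",
    "envfit",
    "CCorAResult",
    "ccora",
    "DbRDAResult",
    "dbrda_partition",
]

_EPS = 1e-12


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (columns) of an abundance table."""
    x = matrix.to_numpy(dtype=float).T
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def _as_distance_array(d) -> tuple[np.ndarray, list]:
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        arr = d.to_numpy(dtype=float)
    else:
        arr = np.asarray(d, dtype=float)
        ids = list(range(arr.shape[0]))
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return arr, ids


@dataclass
class OrdinationResult:
    method: str  # "PCoA" | "NMDS"
    coords: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray | None = None  # PCoA only (all, including negative)
    prop_explained: np.ndarray | None = None  # PCoA only, positive axes
    stress: float | None = None  # NMDS only (Kruskal stress-1)
    iterations: int = 0
    converged: bool = True


def pcoa(d, k: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis (classical scaling) of a distance matrix.

    Negative eigenvalues are reported but not corrected; coordinates come
    from the positive eigenvalues only, and percent variance explained is
    relative to the positive-eigenvalue sum.
    """
    arr, ids = _as_distance_array(d)
    n = arr.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (arr**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-10 if len(evals) else 0.0
    pos = evals > tol
    n_pos = int(pos.sum())
    if k is None:
        k = n_pos
    if k > n_pos:
        raise ValueError(f"requested {k} axes but only {n_pos} positive eigenvalues")
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    prop = evals[:n_pos] / evals[:n_pos].sum() if n_pos else np.empty(0)
    cols = [f"PCo{i + 1}" for i in range(k)]
    return OrdinationResult(
        method="PCoA",
        coords=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=evals,
        prop_explained=prop[:k],
    )


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom <= 0:
        return 1.0
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def _nmds_single(diss: np.ndarray, x0: np.ndarray, max_iter: int, tol: float):
    n = x0.shape[0]
    order = np.argsort(diss, kind="stable")
    x = x0.copy()
    stress = np.inf
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        dist = pdist(x)
        # monotone (isotonic) disparities in the order of the input dissimilarities
        disp_sorted = isotonic_regression(dist[order]).x
        disp = np.empty_like(disp_sorted)
        disp[order] = disp_sorted
        new_stress = _stress1(dist, disp)
        if new_stress > stress + _EPS:  # majorization overshoot: keep previous
            break
        if stress - new_stress < tol:
            stress = new_stress
            converged = True
            break
        stress = new_stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > _EPS, disp / dist, 0.0)
        bmat = -squareform(ratio)
        np.fill_diagonal(bmat, -bmat.sum(axis=1))
        x = bmat @ x / n
    return x, float(stress if np.isfinite(stress) else 1.0), it, converged


def nmds(
    d,
    k: int = 2,
    restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs ``restarts`` optimizations (the first seeded from PCoA, the rest from
    random configurations drawn from ``seed``) and keeps the lowest-stress
    solution. Nonconvergence is flagged on the result, not raised.
    """
    arr, ids = _as_distance_array(d)
    n = arr.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    diss = squareform(arr, checks=False)
    rng = np.random.default_rng(seed)
    inits = []
    try:
        p = pcoa(arr, k=None)
        xy = p.coords.to_numpy()
        if xy.shape[1] >= k:
            inits.append(xy[:, :k])
    except ValueError:
        pass
    while len(inits) < max(restarts, 1):
        inits.append(rng.standard_normal((n, k)))
    best = None
    for x0 in inits:
        x, stress, it, conv = _nmds_single(diss, np.asarray(x0, dtype=float), max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, it, conv)
    x, stress, it, conv = best
    x = x - x.mean(axis=0)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        method="NMDS",
        coords=pd.DataFrame(x, index=ids, columns=cols),
        stress=stress,
        iterations=it,
        converged=conv,
    )


def _orthonormal_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of a centered matrix."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > max(x.shape) * np.finfo(float).eps * max(
        np.abs(np.diag(r)).max(), 1.0
    )
    return q[:, keep]


def envfit(
    ordination: OrdinationResult | pd.DataFrame,
    variables: pd.DataFrame,
    permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Least-squares fit of external variables onto ordination axes.

    Per variable: a direction vector (unit norm) in axis space, the squared
    multiple correlation r2 of the variable with the axes, and a permutation
    p-value (fraction of label permutations reaching the observed r2, with
    the add-one rule). Constant variables are flagged with NaN statistics.
    """
    coords = ordination.coords if isinstance(ordination, OrdinationResult) else ordination
    missing = coords.index.difference(variables.index)
    if len(missing):
        raise ValueError(f"variables missing for samples: {list(missing)[:5]}")
    xc = coords.to_numpy(dtype=float)
    xc = xc - xc.mean(axis=0)
    q = _orthonormal_basis(xc)
    rng = np.random.default_rng(seed)
    n = xc.shape[0]
    rows = []
    for name in variables.columns:
        v = variables.loc[coords.index, name].to_numpy(dtype=float)
        vc = v - v.mean()
        sst = float(vc @ vc)
        if sst <= _EPS:
            rows.append({"variable": name, "r2": np.nan, "p": np.nan,
                         **{f"axis_{c}": np.nan for c in coords.columns}})
            continue
        beta, *_ = np.linalg.lstsq(xc, vc, rcond=None)
        r2 = float((q.T @ vc) @ (q.T @ vc) / sst)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        perm_idx = np.array([rng.permutation(n) for _ in range(permutations)])
        vp = vc[perm_idx.T]  # n x permutations
        r2_perm = ((q.T @ vp) ** 2).sum(axis=0) / sst
        p = (np.sum(r2_perm >= r2 - _EPS) + 1) / (permutations + 1)
        row = {"variable": name, "r2": r2, "p": float(p)}
        row.update({f"axis_{c}": float(b) for c, b in zip(coords.columns, direction)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


@dataclass(frozen=True)
class CCorAResult:
    correlations: np.ndarray  # descending, each in [0, 1]
    pillai: float  # sum of squared canonical correlations
    p: float  # permutation p-value for Pillai's trace
    permutations: int


def ccora(
    x: pd.DataFrame,
    y: pd.DataFrame,
    permutations: int = 999,
    seed: int | None = None,
) -> CCorAResult:
    """Canonical correlation analysis between two sample-aligned tables.

    Significance is assessed by permuting the rows of ``y`` and recomputing
    Pillai's trace.
    """
    if isinstance(x, pd.DataFrame) and isinstance(y, pd.DataFrame):
        if not x.index.equals(y.index):
            y = y.loc[x.index]
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape[0] != ya.shape[0]:
        raise ValueError("tables must share the same samples")
    n = xa.shape[0]
    xc = xa - xa.mean(axis=0)
    yc = ya - ya.mean(axis=0)
    qx = _orthonormal_basis(xc)
    qy = _orthonormal_basis(yc)
    if qx.shape[1] < xc.shape[1] or qy.shape[1] < yc.shape[1]:
        raise ValueError("rank-deficient table: use fewer ordination axes")
    rho = np.clip(np.linalg.svd(qx.T @ qy, compute_uv=False), 0.0, 1.0)
    pillai = float(np.sum(rho**2))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        rho_p = np.linalg.svd(qx.T @ qy[perm], compute_uv=False)
        if float(np.sum(np.clip(rho_p, 0, 1) ** 2)) >= pillai - _EPS:
            count += 1
    p = (count + 1) / (permutations + 1)
    return CCorAResult(correlations=rho, pillai=pillai, p=float(p), permutations=permutations)


# ---------------------------------------------------------------------------
# dbRDA


def _response_from_distance(d) -> np.ndarray:
    """PCoA-coordinate response matrix (positive axes, eigenvalue-scaled)."""
    res = pcoa(d)
    return res.coords.to_numpy(dtype=float)


def _r2(y: np.ndarray, x: np.ndarray | None) -> float:
    """Fraction of total variance of (centered) y explained by predictors x."""
    sst = float(np.sum(y**2))
    if x is None or x.shape[1] == 0:
        return 0.0
    q = _orthonormal_basis(x - x.mean(axis=0))
    fitted = q @ (q.T @ y)
    return float(np.sum(fitted**2) / sst)


def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class DbRDAResult:
    selected: list
    selected_env: list
    selected_community: list
    fractions: dict | None  # raw-R2 partition
    fractions_adjusted: dict | None
    r2_total: float
    r2_total_adjusted: float
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)


def dbrda_partition(
    dom_distance,
    env_table: pd.DataFrame,
    community_axes: pd.DataFrame,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> DbRDAResult:
    """dbRDA with permutation forward selection and variance partitioning.

    dbRDA is an RDA of the PCoA coordinates of ``dom_distance`` on the
    predictors. Forward selection considers environmental variables and
    community axes jointly: at each step the candidate with the best
    permutation p-value (ties by added variance) enters if p < alpha, with a
    double stop when the adjusted R2 of the growing model would exceed that
    of the full model. Variance is then partitioned between the selected
    environmental block E and the selected community block C:
    env-only = R2(E|C), community-only = R2(C|E),
    shared = R2(E) + R2(C) - R2(E+C), unexplained = 1 - R2(E+C).
    Both raw and adjusted fractions are reported; with no selected variable
    partitioning is skipped (``fractions is None``).
    """
    arr, ids = _as_distance_array(dom_distance)
    env_table = env_table.loc[ids]
    community_axes = community_axes.loc[ids]
    y = _response_from_distance(arr)
    y = y - y.mean(axis=0)
    n = y.shape[0]
    sst = float(np.sum(y**2))
    candidates = {f"env:{c}": env_table[c].to_numpy(dtype=float) for c in env_table.columns}
    candidates.update(
        {f"community:{c}": community_axes[c].to_numpy(dtype=float) for c in community_axes.columns}
    )
    full_x = np.column_stack(list(candidates.values()))
    full_adj = _adj_r2(_r2(y, full_x), n, full_x.shape[1])

    rng = np.random.default_rng(seed)
    selected: list[str] = []
    trace_rows = []
    while True:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        cur_x = (
            np.column_stack([candidates[c] for c in selected]) if selected else np.zeros((n, 0))
        )
        cur_q = _orthonormal_basis(cur_x - cur_x.mean(axis=0)) if selected else np.zeros((n, 0))
        cur_ss = float(np.sum((cur_q @ (cur_q.T @ y)) ** 2)) if selected else 0.0
        # adjusted-R2 double stop: once the selected model matches the full
        # model's adjusted fit, further variables would only overfit
        if selected and np.isfinite(full_adj):
            if _adj_r2(cur_ss / sst, n, len(selected)) > full_adj + 1e-12:
                break
        best = None
        for name in remaining:
            v = candidates[name]
            vc = v - v.mean()
            resid = vc - cur_q @ (cur_q.T @ vc)
            norm = np.linalg.norm(resid)
            if norm <= 1e-10:  # collinear with current model
                continue
            u = resid / norm
            add_ss = float(np.sum((u @ y) ** 2))
            # permutation null: shuffle the candidate's values across samples
            perm_idx = np.array([rng.permutation(n) for _ in range(permutations)])
            vp = vc[perm_idx.T]  # n x permutations
            rp = vp - cur_q @ (cur_q.T @ vp)
            norms = np.linalg.norm(rp, axis=0)
            ok = norms > 1e-10
            rp[:, ok] /= norms[ok]
            add_ss_perm = np.sum((rp.T @ y) ** 2, axis=1)
            add_ss_perm[~ok] = 0.0
            p = (np.sum(add_ss_perm >= add_ss - _EPS * sst) + 1) / (permutations + 1)
            if best is None or (p, -add_ss) < (best[1], -best[2]):
                best = (name, float(p), add_ss)
        if best is None:
            break
        name, p, add_ss = best
        if p >= alpha:
            break
        selected.append(name)
        trace_rows.append(
            {"variable": name, "p": p, "added_r2": add_ss / sst, "cum_r2": (cur_ss + add_ss) / sst}
        )

    sel_env = [c for c in selected if c.startswith("env:")]
    sel_com = [c for c in selected if c.startswith("community:")]

    def block(names):
        if not names:
            return None
        return np.column_stack([candidates[c] for c in names])

    r2_total = _r2(y, block(selected)) if selected else 0.0
    r2_total_adj = _adj_r2(r2_total, n, len(selected)) if selected else 0.0
    fractions = fractions_adj = None
    if selected:
        r2_e = _r2(y, block(sel_env)) if sel_env else 0.0
        r2_c = _r2(y, block(sel_com)) if sel_com else 0.0
        fractions = {
            "env": r2_total - r2_c,
            "community": r2_total - r2_e,
            "shared": r2_e + r2_c - r2_total,
            "unexplained": 1.0 - r2_total,
            "total": r2_total,
        }
        a_e = _adj_r2(r2_e, n, len(sel_env)) if sel_env else 0.0
        a_c = _adj_r2(r2_c, n, len(sel_com)) if sel_com else 0.0
        fractions_adj = {
            "env": r2_total_adj - a_c,
            "community": r2_total_adj - a_e,
            "shared": a_e + a_c - r2_total_adj,
            "unexplained": 1.0 - r2_total_adj,
            "total": r2_total_adj,
        }
    return DbRDAResult(
        selected=selected,
        selected_env=[c.split(":", 1)[1] for c in sel_env],
        selected_community=[c.split(":", 1)[1] for c in sel_com],
        fractions=fractions,
        fractions_adjusted=fractions_adj,
        r2_total=r2_total,
        r2_total_adjusted=r2_total_adj,
        trace=pd.DataFrame(trace_rows),
    )
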