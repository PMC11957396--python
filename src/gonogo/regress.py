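"""Trial-wise association analyses between neural activity and behavior.

Ten explanatory variables per trial: physical reward R (1 iff HIT), the
value-model quantities Q and dQ, cue-crossed lick counts in three response
windows (early 0-0.5 s, reward 0.5-2 s, late 2-4 s, separately for Go and
No-go cues) and the lick-latency fluctuation.  These feed

* partial least squares regression with VIP (variable importance in
  projection) scores, the component count chosen by 10-fold CV;
* sparse canonical correlation analysis between the four TC scores and the
  ten variables, by penalized matrix decomposition with L1 bounds 0.4 / 0.6
  (expressed as fractions of sqrt(p), as in the PMA convention);
* a linear mixed-effects slope with mouse as random intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .io import unpack_times

DESIGN_COLUMNS = [
    "R",
    "Q",
    "dQ",
    "go_elick",
    "nogo_elick",
    "go_rlick",
    "nogo_rlick",
    "go_llick",
    "nogo_llick",
    "latency_fluct",
]

LICK_WINDOWS = {"elick": (0.0, 0.5), "rlick": (0.5, 2.0), "llick": (2.0, 4.0)}


def build_design(trials: pd.DataFrame, qtrace) -> pd.DataFrame:
    """Per-trial explanatory variables (raw, unstandardized).

    ``trials`` needs cue, condition, lick_times (array) or lick_times_s
    (packed), lick_latency_s and mouse columns; ``qtrace`` supplies the
    aligned Q and dQ of the realized (cue, Lick) pair.  Latency fluctuation
    is |latency - mouse mean latency| computed separately for HIT and FA;
    MISS (resp. CR) trials are imputed with the mouse's HIT (resp. FA) mean
    fluctuation.
    """
    n = len(trials)
    if len(qtrace.delta_q) != n:
        raise ValueError("qtrace not aligned with trials")
    if "lick_times" in trials.columns:
        lick_times = [np.atleast_1d(t) for t in trials["lick_times"]]
    elif "lick_times_s" in trials.columns:
        lick_times = [unpack_times(t) for t in trials["lick_times_s"]]
    else:
        raise ValueError("trials missing lick-time data")

    cond = trials["condition"].to_numpy()
    cue_go = (trials["cue"] == "Go").to_numpy()
    out = pd.DataFrame(index=trials.index)
    out["R"] = (cond == "HIT").astype(float)
    q = np.where(cue_go, qtrace.q_go, qtrace.q_nogo)
    out["Q"] = q
    out["dQ"] = qtrace.delta_q

    for name, (lo, hi) in LICK_WINDOWS.items():
        counts = np.array([np.sum((t >= lo) & (t < hi)) for t in lick_times], float)
        out[f"go_{name}"] = np.where(cue_go, counts, 0.0)
        out[f"nogo_{name}"] = np.where(~cue_go, counts, 0.0)

    latency = trials["lick_latency_s"].to_numpy(dtype=float)
    fluct = np.full(n, np.nan)
    for mouse, idx in trials.groupby("mouse").indices.items():
        idx = np.asarray(idx)
        m_cond = cond[idx]
        means = {}
        for licked_cond, unlicked_cond in (("HIT", "MISS"), ("FA", "CR")):
            sel = idx[m_cond == licked_cond]
            if len(sel):
                f = np.abs(latency[sel] - np.nanmean(latency[sel]))
                fluct[sel] = f
                means[unlicked_cond] = float(np.mean(f))
            else:
                means[unlicked_cond] = 0.0
        for unlicked_cond in ("MISS", "CR"):
            fluct[idx[m_cond == unlicked_cond]] = means[unlicked_cond]
    out["latency_fluct"] = fluct
    return out[DESIGN_COLUMNS]


def standardize(x: np.ndarray | pd.DataFrame) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant column(s) at index {bad.tolist()}")
    return (x - x.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# PLS + VIP
# ---------------------------------------------------------------------------


@dataclass
class VIPResult:
    vip: np.ndarray
    n_components: int
    cv_error: np.ndarray  # mean squared CV prediction error per component count
    variable_names: list[str] | None = None


def _vip_scores(pls: PLSRegression, normalization: str = "standard") -> np.ndarray:
    """VIP_j from a fitted PLS model.

    ``standard``: VIP_j = sqrt(J * sum_f ss_f (w_jf/||w_f||)^2 / sum_f ss_f),
    which satisfies sum_j VIP_j^2 = J (the convention under which VIP > 1
    marks an important predictor).  ``literal`` keeps the total component
    count F in the denominator instead of the explained-variance total.
    """
    w = pls.x_weights_  # (J, F)
    t = pls.x_scores_  # (n, F)
    q = pls.y_loadings_  # (m, F)
    j, f = w.shape
    ss = np.sum(t**2, axis=0) * np.sum(q**2, axis=0)  # explained SSY per component
    w2 = (w / np.linalg.norm(w, axis=0)) ** 2
    if normalization == "standard":
        return np.sqrt(j * (w2 @ ss) / ss.sum())
    if normalization == "literal":
        # the printed form divides by F as well; loses the sum VIP^2 = J identity
        return np.sqrt(j * (w2 @ ss) / (ss.sum() * f))
    raise ValueError(f"unknown normalization {normalization!r}")


def pls_vip(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.DataFrame,
    max_components: int = 8,
    cv_folds: int = 10,
    seed: int = 0,
    normalization: str = "standard",
    variable_names: list[str] | None = None,
) -> VIPResult:
    """PLS regression of y on x with CV-selected component count and VIP.

    Inputs are standardized internally (constant columns rejected).  The
    component count minimizing 10-fold CV prediction error is used for the
    final fit; VIP carries no sign information.
    """
    if variable_names is None and isinstance(x, pd.DataFrame):
        variable_names = list(x.columns)
    xs = standardize(x)
    ys = standardize(np.asarray(y, float).reshape(len(xs), -1))
    n, j = xs.shape
    max_components = min(max_components, j, n - 1)
    if n <= max_components:
        raise ValueError("need more samples than components")

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_err = np.zeros(max_components)
    for f in range(1, max_components + 1):
        errs = []
        for tr, te in kf.split(xs):
            m = PLSRegression(n_components=f, scale=False).fit(xs[tr], ys[tr])
            errs.append(np.mean((ys[te] - m.predict(xs[te])) ** 2))
        cv_err[f - 1] = np.mean(errs)
    n_comp = int(np.argmin(cv_err)) + 1
    model = PLSRegression(n_components=n_comp, scale=False).fit(xs, ys)
    return VIPResult(
        vip=_vip_scores(model, normalization),
        n_components=n_comp,
        cv_error=cv_err,
        variable_names=variable_names,
    )


# ---------------------------------------------------------------------------
# sparse CCA by penalized matrix decomposition (Witten, Tibshirani & Hastie)
# ---------------------------------------------------------------------------


@dataclass
class SCCAResult:
    x_coefs: np.ndarray  # (p, K) coefficients for TC scores
    z_coefs: np.ndarray  # (q, K) coefficients for behavior variables
    correlations: np.ndarray  # (K,) canonical correlations


def _soft(a: np.ndarray, c: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - c, 0.0)


def _l1_project(a: np.ndarray, c: float) -> np.ndarray:
    """max_u u'a s.t. ||u||2<=1, ||u||1<=c, via binary-searched soft threshold."""
    if np.all(a == 0):
        return a
    u = a / np.linalg.norm(a)
    if np.sum(np.abs(u)) <= c:
        return u
    lo, hi = 0.0, np.max(np.abs(a))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        su = _soft(a, mid)
        nrm = np.linalg.norm(su)
        if nrm == 0:
            hi = mid
            continue
        if np.sum(np.abs(su / nrm)) > c:
            lo = mid
        else:
            hi = mid
    su = _soft(a, hi)
    return su / np.linalg.norm(su)


def sparse_cca(
    x: np.ndarray | pd.DataFrame,
    z: np.ndarray | pd.DataFrame,
    l1_x: float = 0.4,
    l1_z: float = 0.6,
    n_components: int = 4,
    max_iter: int = 200,
    resign: bool = True,
) -> SCCAResult:
    """Sparse CCA with LASSO penalties via penalized matrix decomposition.

    ``l1_x``/``l1_z`` are fractions in (0, 1]; the L1 bound on a weight
    vector of dimension p is max(1, l1 * sqrt(p)) (larger bound = less
    penalization).  With l1_x = 0.4 and four TC scores the bound is below 1,
    so each canonical variate selects exactly one TC score with coefficient
    +-1; ``resign`` flips each pair so the TC coefficient is +1.
    """
    xs = standardize(x)
    zs = standardize(z)
    p, q = xs.shape[1], zs.shape[1]
    if n_components > min(p, q):
        raise ValueError("n_components exceeds rank")
    cx = max(1.0, l1_x * np.sqrt(p))
    cz = max(1.0, l1_z * np.sqrt(q))
    m = xs.T @ zs / len(xs)

    us, vs, cors = [], [], []
    for _ in range(n_components):
        v = np.linalg.svd(m, full_matrices=False)[2][0]
        u = np.zeros(p)
        for _ in range(max_iter):
            u_new = _l1_project(m @ v, cx)
            v_new = _l1_project(m.T @ u_new, cz)
            if np.allclose(u_new, u, atol=1e-10) and np.allclose(v_new, v, atol=1e-10):
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        d = float(u @ m @ v)
        m = m - d * np.outer(u, v)
        a, b = xs @ u, zs @ v
        cor = 0.0
        if a.std() > 0 and b.std() > 0:
            cor = float(np.corrcoef(a, b)[0, 1])
        if resign:
            nz = u[np.abs(u) > 1e-12]
            s = np.sign(nz[0]) if len(nz) else 1.0
            u, v, cor = u * s, v * s, cor  # correlation invariant to joint flip
        us.append(u)
        vs.append(v)
        cors.append(cor)
    return SCCAResult(np.column_stack(us), np.column_stack(vs), np.array(cors))


def classical_cca(x: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unpenalized CCA via whitened SVD (oracle for the sparse variant)."""
    xs = standardize(x)
    zs = standardize(z)
    qx, rx = np.linalg.qr(xs - xs.mean(0))
    qz, rz = np.linalg.qr(zs - zs.mean(0))
    u, s, vt = np.linalg.svd(qx.T @ qz)
    a = np.linalg.solve(rx, u)
    b = np.linalg.solve(rz, vt.T)
    return a, b, np.clip(s, 0, 1)


# ---------------------------------------------------------------------------
# mixed-effects slope
# ---------------------------------------------------------------------------


def mixed_model_slope(
    y: np.ndarray, x: np.ndarray, group: np.ndarray, reml: bool = False
) -> tuple[float, float]:
    """Fixed-effect slope of y on x with a per-group random intercept.

    With a single group the model reduces to ordinary least squares.
    Returns (slope, Wald p-value).
    """
    df = pd.DataFrame({"y": np.asarray(y, float), "x": np.asarray(x, float), "g": group})
    if df["x"].groupby(df["g"]).std(ddof=0).max() == 0:
        raise ValueError("zero within-group variance of x")
    if df["g"].nunique() < 2:
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        return float(ols.params.iloc[1]), float(ols.pvalues.iloc[1])
    res = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=reml)
    return float(res.params["x"]), float(res.pvalues["x"])
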