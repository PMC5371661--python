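"""Scene-patch featurization and linear mixed models of fixation density.

Each 1200 x 900 scene is divided into a 12 x 9 grid of 100 x 100 px patches.
Per participant x scene, every patch gets a relative fixation density (patch
mean / mean of patch means), and per scene a relative saliency, relative
head coverage, relative body coverage (same normalization) and the distance
of the patch center from the scene center. Pooled over the cohort, the four
standardized predictors (plus saliency x head and saliency x body
interactions) enter linear mixed models of relative fixation density with
crossed random intercepts for participant and scene.

The mixed models are fitted by a profiled-deviance solver specialized to
two crossed random-intercept factors: with Z the indicator matrix of the
participant and scene codes and Lambda(theta) the diagonal relative-SD
scaling, the deviance is profiled over the fixed effects and the residual
variance so that only theta = (sd_participant, sd_scene) / sd_residual is
optimized numerically. All linear algebra runs on precomputed cross-product
matrices (q = n_participants + n_scenes columns), so each deviance
evaluation costs O(q^3) regardless of the number of rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cholesky, solve_triangular

from .density import DensityMap
from .roi import RoiSet
from .saliency import SaliencyMap

__all__ = [
    "MODEL_TERMS",
    "MixedModelFit",
    "patchify",
    "standardize_predictors",
    "fit_mixed_model",
    "compare_models",
    "decile_bin_summary",
]

PREDICTORS = ("dist_center", "rel_saliency", "rel_head", "rel_body")

#: fixed-effect sets of the incremental model ladder ("0" = intercept only)
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "0": (),
    "1a": ("dist_center",),
    "1b": ("rel_saliency",),
    "1c": ("rel_head",),
    "1d": ("rel_body",),
    "2": ("dist_center", "rel_saliency"),
    "3a": ("dist_center", "rel_saliency", "rel_head"),
    "3b": ("dist_center", "rel_saliency", "rel_body"),
    "4": PREDICTORS,
    "5a": PREDICTORS + ("sal_x_head",),
    "5b": PREDICTORS + ("sal_x_body",),
    "6": PREDICTORS + ("sal_x_head", "sal_x_body"),
}


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def _patch_means(v: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    h, w = v.shape
    if h % n_rows or w % n_cols:
        raise ValueError(f"image {v.shape} not divisible by a {n_cols} x {n_rows} grid")
    return v.reshape(n_rows, h // n_rows, n_cols, w // n_cols).mean(axis=(1, 3))


def _relative(v: np.ndarray, what: str) -> np.ndarray:
    m = v.mean()
    if m <= 0:
        if v.any():
            raise ValueError(f"negative mass in {what}")
        warnings.warn(f"scene has no {what}; relative values set to 0")
        return np.zeros_like(v)
    return v / m


def scene_patch_features(
    saliency: SaliencyMap,
    roi_set: RoiSet | None,
    *,
    n_rows: int = 9,
    n_cols: int = 12,
) -> pd.DataFrame:
    """Scene-level patch predictors, shared by all trials on the scene.

    Relative quantities are each patch's mean (or coverage fraction)
    divided by the scene-wide mean over patches, so their per-scene mean is
    exactly 1; a scene with no head (or body) pixels gets 0 everywhere for
    that feature. ``dist_center`` is the Euclidean distance (px) from the
    patch center to the image center.
    """
    sv = saliency.values
    h, w = sv.shape
    rel_sal = _relative(_patch_means(sv, n_rows, n_cols), "saliency")
    if roi_set is not None:
        rel_head = _relative(_patch_means(roi_set.head_mask.astype(float), n_rows, n_cols), "head pixels")
        rel_body = _relative(_patch_means(roi_set.body_mask.astype(float), n_rows, n_cols), "body pixels")
    else:
        rel_head = np.zeros((n_rows, n_cols))
        rel_body = np.zeros((n_rows, n_cols))

    rows_idx, cols_idx = np.mgrid[0:n_rows, 0:n_cols]
    cy = (rows_idx + 0.5) * (h / n_rows)
    cx = (cols_idx + 0.5) * (w / n_cols)
    dist = np.hypot(cx - w / 2.0, cy - h / 2.0)

    return pd.DataFrame(
        {
            "patch_row": rows_idx.ravel(),
            "patch_col": cols_idx.ravel(),
            "rel_saliency": rel_sal.ravel(),
            "rel_head": rel_head.ravel(),
            "rel_body": rel_body.ravel(),
            "dist_center": dist.ravel(),
        }
    )


def patch_response(density: DensityMap, *, n_rows: int = 9, n_cols: int = 12) -> np.ndarray:
    """Relative mean fixation density per patch (per-scene mean exactly 1)."""
    return _relative(_patch_means(density.values, n_rows, n_cols), "fixation density").ravel()


def patchify(
    density: DensityMap,
    saliency: SaliencyMap,
    roi_set: RoiSet | None,
    *,
    n_rows: int = 9,
    n_cols: int = 12,
) -> pd.DataFrame:
    """One row per grid patch with the four predictors and the response."""
    if density.values.shape != saliency.values.shape:
        raise ValueError("density and saliency shapes differ")
    out = scene_patch_features(saliency, roi_set, n_rows=n_rows, n_cols=n_cols)
    out.insert(0, "participant_id", density.participant_id)
    out.insert(1, "scene_id", density.scene_id)
    out["rel_fix_density"] = patch_response(density, n_rows=n_rows, n_cols=n_cols)
    return out


def standardize_predictors(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Standardize the four predictors to mean 0, SD 1 over the pooled table.

    Interaction columns (``sal_x_head``, ``sal_x_body``) are products of the
    standardized mains and are NOT re-standardized. Returns the design table
    and a scaling report {predictor: (mean, sd)} for back-transformation.
    """
    design = records.copy()
    report: dict[str, tuple[float, float]] = {}
    for col in PREDICTORS:
        m = float(design[col].mean())
        sd = float(design[col].std(ddof=1))
        if sd == 0:
            raise ValueError(f"zero-variance predictor {col!r}")
        design[col] = (design[col] - m) / sd
        report[col] = (m, sd)
    design["sal_x_head"] = design["rel_saliency"] * design["rel_head"]
    design["sal_x_body"] = design["rel_saliency"] * design["rel_body"]
    return design, report


# ---------------------------------------------------------------------------
# mixed-model solver
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    model_id: str
    terms: tuple[str, ...]
    fixed_effects: dict[str, dict]  # name -> {beta, se, p}
    loglik_ml: float
    loglik_reml: float
    aic: float
    r2_analog: float
    random_intercept_vars: dict[str, float]
    residual_var: float
    n_obs: int
    n_params: int
    converged: bool = True
    notes: list[str] = field(default_factory=list)


class _CrossedLMM:
    """Profiled REML/ML for y = X b + u_participant + u_scene + e."""

    def __init__(self, X: np.ndarray, y: np.ndarray, part: np.ndarray, scene: np.ndarray):
        self.n, self.p = X.shape
        self.P = int(part.max()) + 1
        self.S = int(scene.max()) + 1
        q = self.P + self.S
        self.q = q
        self.part, self.scene = part, scene
        self.X, self.y = X, y

        # cross-products; Z = [indicator(part) indicator(scene)]
        ZtZ = np.zeros((q, q))
        ZtZ[np.arange(self.P), np.arange(self.P)] = np.bincount(part, minlength=self.P)
        ZtZ[self.P :, self.P :][np.arange(self.S), np.arange(self.S)] = np.bincount(
            scene, minlength=self.S
        )
        cross = np.zeros((self.P, self.S))
        np.add.at(cross, (part, scene), 1.0)
        ZtZ[: self.P, self.P :] = cross
        ZtZ[self.P :, : self.P] = cross.T
        self.ZtZ = ZtZ

        ZtX = np.zeros((q, self.p))
        np.add.at(ZtX, part, X)
        np.add.at(ZtX, self.P + scene, X)
        self.ZtX = ZtX
        Zty = np.bincount(part, weights=y, minlength=self.P)
        Zty = np.concatenate([Zty, np.bincount(scene, weights=y, minlength=self.S)])
        self.Zty = Zty
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _solve(self, theta: np.ndarray):
        d = np.concatenate([np.full(self.P, theta[0]), np.full(self.S, theta[1])])
        A = self.ZtZ * np.outer(d, d)
        A[np.diag_indices_from(A)] += 1.0
        L = cholesky(A, lower=True)
        cu = solve_triangular(L, d * self.Zty, lower=True)
        RZX = solve_triangular(L, d[:, None] * self.ZtX, lower=True)
        RXtRX = self.XtX - RZX.T @ RZX
        RX = cholesky(RXtRX, lower=True)
        cb = solve_triangular(RX, self.Xty - RZX.T @ cu, lower=True)
        beta = solve_triangular(RX.T, cb, lower=False)
        pwrss = max(self.yty - float(cu @ cu) - float(cb @ cb), 1e-12)
        logdet_L = 2.0 * float(np.sum(np.log(np.diag(L))))
        logdet_RX = 2.0 * float(np.sum(np.log(np.diag(RX))))
        return L, RZX, RXtRX, cu, beta, pwrss, logdet_L, logdet_RX

    def _deviance(self, theta: np.ndarray, reml: bool) -> float:
        try:
            _, _, _, _, _, pwrss, logdet_L, logdet_RX = self._solve(theta)
        except np.linalg.LinAlgError:
            return np.inf
        n, p = self.n, self.p
        if reml:
            df = n - p
            return logdet_L + logdet_RX + df * (1.0 + np.log(2.0 * np.pi * pwrss / df))
        return logdet_L + n * (1.0 + np.log(2.0 * np.pi * pwrss / n))

    def fit(self, reml: bool, tol: float = 1e-8):
        best = None
        for start in ([1.0, 1.0], [0.1, 0.1], [3.0, 0.3]):
            res = optimize.minimize(
                lambda th: self._deviance(np.abs(th), reml),
                start,
                method="L-BFGS-B",
                bounds=[(0.0, None), (0.0, None)],
                options={"ftol": tol, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        theta = np.abs(best.x)
        L, RZX, RXtRX, cu, beta, pwrss, logdet_L, logdet_RX = self._solve(theta)
        df = self.n - self.p if reml else self.n
        sigma2 = pwrss / df
        loglik = -0.5 * self._deviance(theta, reml)
        vcov = sigma2 * np.linalg.inv(RXtRX)
        # conditional modes (BLUPs) for fitted values
        d = np.concatenate([np.full(self.P, theta[0]), np.full(self.S, theta[1])])
        u = solve_triangular(L.T, cu - RZX @ beta, lower=False)
        b = d * u
        fitted = self.X @ beta + b[self.part] + b[self.P + self.scene]
        return {
            "theta": theta,
            "beta": beta,
            "se": np.sqrt(np.diag(vcov)),
            "sigma2": float(sigma2),
            "var_participant": float(sigma2 * theta[0] ** 2),
            "var_scene": float(sigma2 * theta[1] ** 2),
            "loglik": float(loglik),
            "fitted": fitted,
            "converged": bool(best.success),
        }


def fit_mixed_model(design: pd.DataFrame, model_id: str, *, response: str = "rel_fix_density") -> MixedModelFit:
    """Fit one model of the ladder with crossed random intercepts.

    Coefficients, standard errors and the conditional (BLUP-including)
    fitted values come from the REML fit; the ML log-likelihood and AIC are
    retained for likelihood-ratio comparison. Fixed-effect p-values use the
    Wald statistic against the normal reference — with hundreds of
    thousands of rows this is indistinguishable from a finite-df
    approximation.
    """
    if model_id not in MODEL_TERMS:
        raise ValueError(f"unknown model_id {model_id!r}; one of {sorted(MODEL_TERMS)}")
    terms = MODEL_TERMS[model_id]
    part, part_levels = pd.factorize(design["participant_id"], sort=True)
    scene, scene_levels = pd.factorize(design["scene_id"], sort=True)
    y = design[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(design))] + [design[t].to_numpy(dtype=float) for t in terms])

    solver = _CrossedLMM(X, y, part, scene)
    reml = solver.fit(reml=True)
    ml = solver.fit(reml=False)

    names = ("intercept",) + terms
    z = reml["beta"] / reml["se"]
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    fixed = {
        nm: {"beta": float(b), "se": float(s), "p": float(p)}
        for nm, b, s, p in zip(names, reml["beta"], reml["se"], pvals)
    }
    k = X.shape[1] + 3  # fixed effects + 2 random-intercept variances + residual
    aic = 2.0 * k - 2.0 * ml["loglik"]
    r = np.corrcoef(y, reml["fitted"])[0, 1]
    notes = []
    if min(reml["theta"]) == 0.0:
        notes.append("singular fit: a random-intercept variance estimated at 0")
        warnings.warn(notes[-1])
    return MixedModelFit(
        model_id=model_id,
        terms=terms,
        fixed_effects=fixed,
        loglik_ml=ml["loglik"],
        loglik_reml=reml["loglik"],
        aic=float(aic),
        r2_analog=float(r**2),
        random_intercept_vars={
            "participant": reml["var_participant"],
            "scene": reml["var_scene"],
        },
        residual_var=reml["sigma2"],
        n_obs=len(design),
        n_params=k,
        converged=reml["converged"] and ml["converged"],
        notes=notes,
    )


def compare_models(fits: list[tuple[MixedModelFit, MixedModelFit]]) -> pd.DataFrame:
    """Likelihood-ratio tests for ordered (smaller, larger) nested pairs.

    Uses the ML log-likelihoods; chi2 = 2 * delta loglik with df = delta
    parameter count. Non-nested pairs get an AIC-only row (LRT refused).
    """
    rows = []
    for small, large in fits:
        nested = set(small.terms) <= set(large.terms)
        row = {
            "model_small": small.model_id,
            "model_large": large.model_id,
            "delta_aic": large.aic - small.aic,
        }
        if not nested:
            warnings.warn(
                f"models {small.model_id} and {large.model_id} are not nested; AIC only"
            )
            row.update({"chi2": np.nan, "df": np.nan, "p": np.nan})
        else:
            chi2 = max(2.0 * (large.loglik_ml - small.loglik_ml), 0.0)
            dof = large.n_params - small.n_params
            row.update(
                {
                    "chi2": chi2,
                    "df": dof,
                    "p": 1.0 if dof == 0 else float(stats.chi2.sf(chi2, dof)),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def decile_bin_summary(records: pd.DataFrame, predictor: str, *, response: str = "rel_fix_density") -> pd.DataFrame:
    """Mean response +/- SEM per decile bin of a predictor.

    For head and body coverage, patches with zero coverage form a separate
    "0" bin and the deciles are taken over the positive-coverage patches.
    Distance-from-center has only 27 distinct values on the grid, so its
    decile bins are uneven (roughly 7-13% of patches each); duplicate bin
    edges are merged with a flag.
    """
    df = records[[predictor, response]].copy()
    rows = []
    if predictor in ("rel_head", "rel_body"):
        zero = df[df[predictor] == 0]
        if len(zero):
            rows.append(_bin_row("0", zero[response]))
        df = df[df[predictor] > 0]
    vals = df[predictor].to_numpy()
    if len(np.unique(vals)) < 10:
        warnings.warn(f"{predictor}: fewer than 10 distinct positive values; coarser bins")
    edges = np.unique(np.quantile(vals, np.linspace(0, 1, 11)))
    cats = pd.cut(df[predictor], bins=edges, include_lowest=True, duplicates="drop")
    for i, (iv, grp) in enumerate(df.groupby(cats, observed=True), start=1):
        rows.append(_bin_row(str(i), grp[response]))
    return pd.DataFrame(rows)


def _bin_row(label: str, values: pd.Series) -> dict:
    n = len(values)
    return {
        "bin": label,
        "n": n,
        "mean": float(values.mean()),
        "sem": float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
    }
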