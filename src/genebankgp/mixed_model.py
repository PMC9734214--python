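"""REML variance-component estimation and BLUP prediction.

Model families:

* single-kernel models (additive-kernel BLUP and its fixed-marker
  extension) are fit by an eigendecomposition fast path: the restricted
  likelihood is profiled over the variance ratio after projecting out the
  fixed effects, maximized by grid search plus bounded refinement;
* multi-kernel models (epistatic extension, general + subpopulation-
  specific ridge models in kernel space) are fit by a fixed-point warm
  start followed by average-information steps with step halving, variance
  components constrained non-negative by boundary pinning.

Prediction always uses the conditional Gaussian expectation with
cross-kernel blocks: for each random component b,
``u_b = sigma2_b * K_b[:, train] @ V^{-1} (y_train - X_train beta)``.
All fitters accept fixed variance components, in which case estimation is
skipped and only the GLS/conditional-mean step runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from genebankgp.kernels import DesignMatrices

logger = logging.getLogger(__name__)

_LOWER_FRAC = 1e-6  # variance-component floor as a fraction of var(y)
_MAX_ITER = 300
# loglik tolerance: parameter error scales like the square root of the
# loglik gap near the optimum, so a tight tolerance is needed for the
# 1e-6-level prediction agreement the reduction identities demand
_LL_TOL = 1e-10


@dataclass
class ModelSpec:
    """Declarative description of one of the model variants."""

    family: str  # GBLUP | EGBLUP | WBLUP | GSA_RRBLUP | RRBLUP
    name: str | None = None
    marker_strategy: str | None = None  # W-BLUP: S1..S4
    k: int | None = None
    admixed: bool = False

    def __post_init__(self) -> None:
        allowed = {"GBLUP", "EGBLUP", "WBLUP", "GSA_RRBLUP", "RRBLUP"}
        if self.family not in allowed:
            raise ValueError(f"family must be one of {sorted(allowed)}")
        if self.family == "WBLUP" and self.marker_strategy not in {"S1", "S2", "S3", "S4"}:
            raise ValueError("WBLUP requires marker_strategy in {S1..S4}")
        if self.name is None:
            self.name = self._default_name()

    def _default_name(self) -> str:
        if self.family == "WBLUP":
            return f"W-BLUP_{self.marker_strategy}"
        if self.family == "GSA_RRBLUP":
            adm = "_adm" if self.admixed else ""
            return f"GSA-RRBLUP{adm}_k{self.k}"
        return {"GBLUP": "G-BLUP", "EGBLUP": "EG-BLUP", "RRBLUP": "RR-BLUP"}[self.family]


@dataclass
class ModelFit:
    """Estimated variance components, effects and predictions."""

    variance_components: dict[str, float]
    fixed_effects: dict[str, float]
    random_blups: dict[str, np.ndarray]
    fitted_train: np.ndarray
    predicted_test: np.ndarray
    loglik_reml: float
    converged: bool
    n_iter: int
    marker_effects: dict[str, np.ndarray] = field(default_factory=dict)


def _gls(x: np.ndarray, vinv_y: np.ndarray, vinv_x: np.ndarray) -> np.ndarray:
    xtvx = x.T @ vinv_x
    return np.linalg.solve(xtvx, x.T @ vinv_y)


def _chol_inv_mul(v: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        c = cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.mean(np.diag(v)) + 1e-12
        c = cho_factor(v + jitter * np.eye(v.shape[0]), lower=True)
    return cho_solve(c, b)


def _predict(
    y: np.ndarray,
    x_full: np.ndarray,
    comp_kernels: list[tuple[str, np.ndarray, float]],
    sigma_e: float,
    train: np.ndarray,
    test: np.ndarray,
) -> tuple[dict[str, float], dict[str, np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    """GLS fixed effects + conditional-mean BLUPs for each component."""
    n_tr = train.size
    v_tt = sigma_e * np.eye(n_tr)
    for _, k_full, s2 in comp_kernels:
        v_tt += s2 * k_full[np.ix_(train, train)]
    x_tr = x_full[train]
    vinv_x = _chol_inv_mul(v_tt, x_tr)
    vinv_y = _chol_inv_mul(v_tt, y)
    beta = _gls(x_tr, vinv_y, vinv_x)
    alpha = _chol_inv_mul(v_tt, y - x_tr @ beta)
    blups: dict[str, np.ndarray] = {}
    u_train = np.zeros(n_tr)
    u_test = np.zeros(test.size)
    for name, k_full, s2 in comp_kernels:
        u_all = s2 * (k_full[:, train] @ alpha)
        blups[name] = u_all
        u_train += u_all[train]
        u_test += u_all[test]
    fitted_train = x_tr @ beta + u_train
    predicted_test = x_full[test] @ beta + u_test
    fixed = {"mu": float(beta[0])}
    for i in range(1, beta.size):
        fixed[f"beta_{i}"] = float(beta[i])
    return fixed, blups, fitted_train, predicted_test, beta


# ---------------------------------------------------------------------------
# single-kernel REML (eigendecomposition fast path)
# ---------------------------------------------------------------------------

def _reml_single(
    y: np.ndarray, x: np.ndarray, k: np.ndarray
) -> tuple[float, float, float, bool]:
    """REML for V = sigma2_g*K + sigma2_e*I with fixed design X.

    Profiles the restricted likelihood over delta = sigma2_e/sigma2_g on
    the spectrum of S K S (S the projection orthogonal to X).  Returns
    (sigma2_g, sigma2_e, loglik, converged).
    """
    n, p = x.shape
    q = n - p
    if q <= 1:
        raise ValueError("not enough residual degrees of freedom for REML")
    xtx_inv = np.linalg.pinv(x.T @ x)
    s = np.eye(n) - x @ xtx_inv @ x.T
    sks = s @ k @ s
    sks = 0.5 * (sks + sks.T)
    evals, evecs = np.linalg.eigh(sks)
    order = np.argsort(evals)[::-1]
    lam = np.clip(evals[order][:q], 0.0, None)
    u = evecs[:, order][:, :q]
    eta2 = (u.T @ y) ** 2

    def neg_restricted_ll(log_delta: float) -> float:
        d = 10.0**log_delta
        denom = lam + d
        rss = float(np.sum(eta2 / denom))
        ll = 0.5 * (q * np.log(q / (2 * np.pi)) - q - q * np.log(rss) - np.sum(np.log(denom)))
        return -ll

    grid = np.linspace(-8.0, 8.0, 161)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    i_best = int(vals.argmin())
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    log_delta = float(res.x) if res.fun <= vals[i_best] else grid[i_best]
    delta = 10.0**log_delta
    sigma2_g = float(np.sum(eta2 / (lam + delta)) / q)
    sigma2_e = delta * sigma2_g
    ll = -neg_restricted_ll(log_delta)
    converged = bool(res.success)
    # boundary: delta at the grid edge means a variance ratio outside the
    # searched range; the estimate is still the constrained optimum
    if log_delta <= grid[0] + 1e-9 or log_delta >= grid[-1] - 1e-9:
        logger.info("variance ratio at search boundary (log10 delta = %.1f)", log_delta)
    return sigma2_g, sigma2_e, ll, converged


def fit_gblup(
    y: np.ndarray,
    G: np.ndarray,
    train_ids: np.ndarray,
    test_ids: np.ndarray,
    var_components: dict[str, float] | None = None,
) -> ModelFit:
    """Additive-kernel BLUP with intercept-only fixed effects.

    ``y`` holds phenotypes for the training samples (aligned with
    ``train_ids``, integer positions into ``G``).  When
    ``var_components`` (keys ``sigma2_g``, ``sigma2_e``) is given, REML is
    skipped.
    """
    train = np.asarray(train_ids)
    test = np.asarray(test_ids)
    y = np.asarray(y, dtype=float)
    x_full = np.ones((G.shape[0], 1))
    if var_components is None:
        s2g, s2e, ll, conv = _reml_single(y, x_full[train], G[np.ix_(train, train)])
        n_iter = 1
    else:
        s2g, s2e = var_components["sigma2_g"], var_components["sigma2_e"]
        ll, conv, n_iter = np.nan, True, 0
    fixed, blups, fitted, pred, _ = _predict(
        y, x_full, [("g", G, s2g)], s2e, train, test
    )
    return ModelFit(
        variance_components={"sigma2_g": s2g, "sigma2_e": s2e},
        fixed_effects=fixed,
        random_blups=blups,
        fitted_train=fitted,
        predicted_test=pred,
        loglik_reml=ll,
        converged=conv,
        n_iter=n_iter,
    )


def fit_wblup(
    y: np.ndarray,
    G_r: np.ndarray,
    F_G: np.ndarray,
    train_ids: np.ndarray,
    test_ids: np.ndarray,
    var_components: dict[str, float] | None = None,
) -> ModelFit:
    """Fixed-marker BLUP: fixed effects [1, F_G], random g ~ N(0, G_r s2g).

    Collinear columns of ``F_G`` (including columns constant across the
    training set, which alias the intercept) are dropped with a warning.
    """
    train = np.asarray(train_ids)
    test = np.asarray(test_ids)
    y = np.asarray(y, dtype=float)
    f = np.atleast_2d(np.asarray(F_G, dtype=float))
    if f.shape[0] != G_r.shape[0]:
        f = f.T
    if f.shape[1] == 0:
        raise ValueError("no fixed markers; fall back to the plain additive model")
    x_full = np.column_stack([np.ones(G_r.shape[0]), f])
    # rank check on the training design
    qr_r = np.linalg.qr(x_full[train], mode="r")
    diag = np.abs(np.diag(qr_r))
    keep = [0]
    for j in range(1, x_full.shape[1]):
        sub = x_full[train][:, keep + [j]]
        if np.linalg.matrix_rank(sub, tol=1e-8 * max(1.0, diag.max())) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping collinear fixed-marker column %d", j - 1)
    if len(keep) == 1:
        raise ValueError("all fixed-marker columns collinear with the intercept")
    x_full = x_full[:, keep]
    if var_components is None:
        s2g, s2e, ll, conv = _reml_single(y, x_full[train], G_r[np.ix_(train, train)])
        n_iter = 1
    else:
        s2g, s2e = var_components["sigma2_g"], var_components["sigma2_e"]
        ll, conv, n_iter = np.nan, True, 0
    fixed, blups, fitted, pred, beta = _predict(
        y, x_full, [("g", G_r, s2g)], s2e, train, test
    )
    fixed = {"mu": float(beta[0])}
    for idx, j in enumerate(keep[1:]):
        fixed[f"a_F_{j - 1}"] = float(beta[idx + 1])
    return ModelFit(
        variance_components={"sigma2_g": s2g, "sigma2_e": s2e},
        fixed_effects=fixed,
        random_blups=blups,
        fitted_train=fitted,
        predicted_test=pred,
        loglik_reml=ll,
        converged=conv,
        n_iter=n_iter,
    )


def genomic_heritability(fit: ModelFit, kernels: dict[str, np.ndarray]) -> float:
    """Genomic heritability implied by a fit.

    The genetic variance of component b is ``sigma2_b * mean(diag(K_b))``
    (inbred panels have kernel diagonals near 2, so the raw variance
    component alone understates the genetic variance).
    """
    var_g = 0.0
    for name, k in kernels.items():
        var_g += fit.variance_components[f"sigma2_{name}"] * float(np.mean(np.diag(k)))
    return var_g / (var_g + fit.variance_components["sigma2_e"])


# ---------------------------------------------------------------------------
# multi-kernel REML (fixed-point warm start + average-information steps)
# ---------------------------------------------------------------------------

def _reml_multi(
    y: np.ndarray,
    x: np.ndarray,
    kernels: list[np.ndarray],
    fixed: dict[int, float] | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _LL_TOL,
    n_warm: int = 10,
) -> tuple[np.ndarray, float, float, bool, int]:
    """REML over V = sum_b sigma2_b K_b + sigma2_e I.

    ``fixed`` pins components by index (index ``len(kernels)`` is the
    residual).  Returns (sigmas incl. residual last, sigma_e, loglik,
    converged, n_iter).
    """
    n = y.size
    q = len(kernels)
    vy = float(np.var(y, ddof=1)) or 1.0
    lower = _LOWER_FRAC * vy
    fixed = fixed or {}
    sig = np.full(q + 1, vy / (q + 1))
    for idx, val in fixed.items():
        sig[idx] = val
    ks = kernels + [np.eye(n)]
    free = [b for b in range(q + 1) if b not in fixed]
    eye = np.eye(n)

    def build_v(sig_vec: np.ndarray) -> np.ndarray:
        v = sig_vec[-1] * eye
        for s, k in zip(sig_vec[:-1], ks[:-1]):
            v = v + s * k
        return v

    def chol(v: np.ndarray):
        try:
            return cho_factor(v, lower=True)
        except np.linalg.LinAlgError:
            return cho_factor(v + 1e-8 * vy * eye, lower=True)

    def loglik_only(sig_vec: np.ndarray) -> float:
        c = chol(build_v(sig_vec))
        vinv_x = cho_solve(c, x)
        xtvx = x.T @ vinv_x
        beta = np.linalg.solve(xtvx, vinv_x.T @ y)
        r = y - x @ beta
        py = cho_solve(c, r)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
        _, logdet_x = np.linalg.slogdet(xtvx)
        return -0.5 * (logdet_v + logdet_x + float(r @ py)
                       + (n - x.shape[1]) * np.log(2 * np.pi))

    def full_state(sig_vec: np.ndarray):
        c = chol(build_v(sig_vec))
        vinv = cho_solve(c, eye)
        vinv_x = vinv @ x
        xtvx = x.T @ vinv_x
        beta = np.linalg.solve(xtvx, vinv_x.T @ y)
        r = y - x @ beta
        py = vinv @ r
        p = vinv - vinv_x @ np.linalg.solve(xtvx, vinv_x.T)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
        _, logdet_x = np.linalg.slogdet(xtvx)
        ll = -0.5 * (logdet_v + logdet_x + float(r @ py)
                     + (n - x.shape[1]) * np.log(2 * np.pi))
        return p, py, ll

    p, py, ll = full_state(sig)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tr_pk = np.array([np.sum(p * ks[b]) for b in range(q + 1)])
        kpy = [ks[b] @ py for b in range(q + 1)]
        ypkpy = np.array([float(py @ kpy[b]) for b in range(q + 1)])
        score = 0.5 * (ypkpy - tr_pk)
        # active set: free components not pinned at the lower bound with an
        # inward-pointing (negative) gradient
        active = [b for b in free if not (sig[b] <= lower * 1.0001 and score[b] < 0)]
        if not active:
            converged = True
            break
        if it <= n_warm:
            new = sig.copy()
            for b in active:
                if tr_pk[b] > 0 and ypkpy[b] > 0:
                    new[b] = float(np.clip(sig[b] * ypkpy[b] / tr_pk[b], lower, 50 * vy))
                else:
                    new[b] = lower
            ll_new = loglik_only(new)
        else:
            ai = np.empty((len(active), len(active)))
            pkpy = {b: p @ kpy[b] for b in active}
            for bi, b in enumerate(active):
                for ci in range(bi, len(active)):
                    c2 = active[ci]
                    ai[bi, ci] = ai[ci, bi] = 0.5 * float(kpy[b] @ pkpy[c2])
            ai += 1e-8 * np.trace(ai) / max(len(active), 1) * np.eye(len(active))
            try:
                delta = np.linalg.solve(ai, score[active])
            except np.linalg.LinAlgError:
                delta = score[active] / np.maximum(np.diag(ai), 1e-12)
            step = 1.0
            ll_new = -np.inf
            for _ in range(12):
                new = sig.copy()
                new[active] = np.clip(sig[active] + step * delta, lower, None)
                ll_new = loglik_only(new)
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            else:
                # AI failed to improve; fall back to a fixed-point update
                new = sig.copy()
                for b in active:
                    if tr_pk[b] > 0 and ypkpy[b] > 0:
                        new[b] = float(np.clip(sig[b] * ypkpy[b] / tr_pk[b], lower, 50 * vy))
                ll_new = loglik_only(new)
        d_ll = abs(ll_new - ll)
        sig = new
        p, py, ll = full_state(sig)
        if d_ll < tol and it > 1:
            converged = True
            break
    if not converged:
        logger.warning("multi-kernel REML did not converge in %d iterations", it)
    return sig, float(sig[-1]), ll, converged, it


def fit_multikernel(
    y: np.ndarray,
    kernels: list[tuple[str, np.ndarray]],
    train_ids: np.ndarray,
    test_ids: np.ndarray,
    var_components: dict[str, float] | None = None,
    fixed_components: dict[str, float] | None = None,
) -> ModelFit:
    """Multiple-variance-component BLUP (e.g. additive + epistatic kernels).

    ``kernels`` is a list of (name, full n x n kernel).  ``var_components``
    (name -> value, plus ``sigma2_e``) skips REML entirely;
    ``fixed_components`` pins a subset during REML (e.g. the epistatic
    component at 0 to recover the single-kernel model).
    """
    if len(kernels) < 1:
        raise ValueError("at least one kernel required")
    train = np.asarray(train_ids)
    test = np.asarray(test_ids)
    y = np.asarray(y, dtype=float)
    n_full = kernels[0][1].shape[0]
    x_full = np.ones((n_full, 1))
    names = [nm for nm, _ in kernels]
    k_tr = [k[np.ix_(train, train)] for _, k in kernels]
    if var_components is not None:
        sig = np.array([var_components[f"sigma2_{nm}"] for nm in names] + [var_components["sigma2_e"]])
        ll, conv, n_iter = np.nan, True, 0
    else:
        fixed_idx: dict[int, float] = {}
        if fixed_components:
            for nm, val in fixed_components.items():
                key = nm[7:] if nm.startswith("sigma2_") else nm
                if key == "e":
                    fixed_idx[len(names)] = val
                else:
                    fixed_idx[names.index(key)] = val
        sig, _, ll, conv, n_iter = _reml_multi(y, x_full[train], k_tr, fixed=fixed_idx)
    comp = [(nm, k, float(sig[i])) for i, (nm, k) in enumerate(kernels)]
    fixed, blups, fitted, pred, _ = _predict(y, x_full, comp, float(sig[-1]), train, test)
    vc = {f"sigma2_{nm}": float(sig[i]) for i, nm in enumerate(names)}
    vc["sigma2_e"] = float(sig[-1])
    return ModelFit(
        variance_components=vc,
        fixed_effects=fixed,
        random_blups=blups,
        fitted_train=fitted,
        predicted_test=pred,
        loglik_reml=ll,
        converged=conv,
        n_iter=n_iter,
    )


def fit_rr_family(
    y: np.ndarray,
    design: DesignMatrices,
    spec: ModelSpec,
    train_ids: np.ndarray,
    test_ids: np.ndarray,
    var_components: dict[str, float] | None = None,
) -> ModelFit:
    """General + subpopulation-specific ridge models, solved in kernel space.

    Each design block Z_b contributes the kernel Z_b Z_b' (shared scaling
    absorbed into its variance component); marker-effect BLUPs are
    recovered by back-solving and reported in ``marker_effects``.
    Subpopulations with no training sample are dropped with a warning.
    """
    train = np.asarray(train_ids)
    test = np.asarray(test_ids)
    y = np.asarray(y, dtype=float)
    blocks: list[tuple[str, np.ndarray]] = [("a", design.Z_A)]
    if spec.family == "GSA_RRBLUP":
        per_pop = design.Z_Sadm if spec.admixed else design.Z_S
        if per_pop is None:
            raise ValueError("design matrices do not match the requested mode")
        for c, z in enumerate(per_pop):
            blocks.append((f"S{c + 1}", z))
    elif spec.family != "RRBLUP":
        raise ValueError("fit_rr_family handles RRBLUP and GSA_RRBLUP only")

    scale = float(np.trace(design.Z_A @ design.Z_A.T)) / design.Z_A.shape[0]
    if scale <= 0:
        raise ValueError("degenerate design matrix")
    kept: list[tuple[str, np.ndarray, np.ndarray]] = []
    for nm, z in blocks:
        k_full = (z @ z.T) / scale
        if nm != "a" and np.allclose(np.diag(k_full)[train], 0.0):
            logger.warning("subpopulation block %s has no training samples; dropped", nm)
            continue
        kept.append((nm, k_full, z))
    fit = fit_multikernel(
        y, [(nm, k) for nm, k, _ in kept], train, test, var_components=var_components
    )
    # marker-effect BLUPs: a_b = (sigma2_b/scale) Z_b' V^{-1} (y - mu)
    n_tr = train.size
    v_tt = fit.variance_components["sigma2_e"] * np.eye(n_tr)
    for nm, k_full, _ in kept:
        v_tt += fit.variance_components[f"sigma2_{nm}"] * k_full[np.ix_(train, train)]
    alpha = _chol_inv_mul(v_tt, y - fit.fixed_effects["mu"])
    for nm, _, z in kept:
        fit.marker_effects[nm] = (
            fit.variance_components[f"sigma2_{nm}"] / scale * (z[train].T @ alpha)
        )
    return fit
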