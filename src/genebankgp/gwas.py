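"""Mixed-linear-model association scan and marker-set selection.

The scan is P3D-style: the null model's variance components are estimated
once on the kinship matrix, then each marker is tested as a fixed effect by
generalized least squares under the fixed V, with a Wald p-value.  The
effective number of independent tests is derived from the marker
correlation spectrum (blockwise for large panels) and replaces the raw
marker count in the Bonferroni-style threshold alpha / m_eff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from genebankgp.genotype_qc import GenotypeMatrix
from genebankgp.mixed_model import _chol_inv_mul, _reml_single

logger = logging.getLogger(__name__)

SIMPLEM_BLOCK_SIZE = 133
SIMPLEM_VAR_THRESHOLD = 0.995


@dataclass
class GwasResult:
    """Per-marker scan results with multiple-testing correction."""

    marker_ids: list[str]
    effects: np.ndarray
    p_values: np.ndarray
    m_eff: int
    threshold: float
    significant: list[str]
    variance_explained: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.05


@dataclass
class MarkerSetStrategy:
    """One of the four fixed-marker selection strategies.

    S1: single strongest-association marker, significant or not.
    S2: the significant marker with the largest explained variance.
    S3: minimal prefix of significant markers (sorted by descending
        explained variance) jointly explaining >= 10% of the variance.
    S4: all significant markers.
    """

    strategy: str

    def __post_init__(self) -> None:
        if self.strategy not in {"S1", "S2", "S3", "S4"}:
            raise ValueError("strategy must be one of S1..S4")


def mlm_scan(
    y: np.ndarray,
    g: GenotypeMatrix,
    G: np.ndarray,
    train_ids: np.ndarray,
    var_components: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-marker mixed-model scan on the training samples.

    Returns per-marker effects (dosage scale) and two-sided Wald p-values.
    Markers monomorphic in the training set get effect 0 and p = 1.
    """
    train = np.asarray(train_ids)
    y = np.asarray(y, dtype=float)
    k_tr = G[np.ix_(train, train)]
    n = train.size
    ones = np.ones((n, 1))
    if var_components is None:
        s2g, s2e, _, _ = _reml_single(y, ones, k_tr)
    else:
        s2g, s2e = var_components["sigma2_g"], var_components["sigma2_e"]
    v = s2g * k_tr + s2e * np.eye(n)
    vinv = _chol_inv_mul(v, np.eye(n))

    z = g.dosage[train]
    if np.isnan(z).any():
        raise ValueError("missing data present; run apply_qc first")
    mono = z.std(axis=0) == 0
    w1 = vinv @ np.ones(n)
    wy = vinv @ y
    s11 = float(np.ones(n) @ w1)
    s1y = float(np.ones(n) @ wy)
    wz = vinv @ z  # n x m
    sx1 = z.T @ w1
    sxy = z.T @ wy
    sxx = np.einsum("ij,ij->j", z, wz)
    det = s11 * sxx - sx1**2
    safe = det > 1e-12
    effects = np.zeros(z.shape[1])
    se = np.full(z.shape[1], np.inf)
    effects[safe] = (s11 * sxy[safe] - sx1[safe] * s1y) / det[safe]
    se[safe] = np.sqrt(s11 / det[safe])
    zstat = np.where(np.isfinite(se) & (se > 0), effects / se, 0.0)
    p_values = 2.0 * stats.norm.sf(np.abs(zstat))
    p_values = np.clip(p_values, np.finfo(float).tiny, 1.0)
    effects[mono] = 0.0
    p_values[mono] = 1.0
    if mono.any():
        logger.info("%d markers monomorphic in training set", int(mono.sum()))
    return effects, p_values


def simple_m(
    g: GenotypeMatrix,
    var_threshold: float = SIMPLEM_VAR_THRESHOLD,
    train_ids: np.ndarray | None = None,
    block_size: int = SIMPLEM_BLOCK_SIZE,
) -> int:
    """Effective number of independent tests from the marker correlation spectrum.

    Per block of markers, the composite correlation matrix is
    eigendecomposed and the effective count is the smallest number of
    leading eigenvalues whose cumulative share reaches ``var_threshold``;
    block counts are summed.  Zero-variance markers are excluded.
    """
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must be in (0, 1]")
    dosage = g.dosage if train_ids is None else g.dosage[np.asarray(train_ids)]
    if np.isnan(dosage).any():
        raise ValueError("missing data present; run apply_qc first")
    keep = dosage.std(axis=0) > 0
    dosage = dosage[:, keep]
    m = dosage.shape[1]
    if m == 0:
        return 0
    m_eff = 0
    for start in range(0, m, block_size):
        block = dosage[:, start:start + block_size]
        corr = np.corrcoef(block, rowvar=False)
        corr = np.atleast_2d(corr)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        evals = np.clip(evals, 0.0, None)
        cum = np.cumsum(evals) / evals.sum()
        m_eff += int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    return m_eff


def variance_explained(
    y: np.ndarray,
    marker_dosages: np.ndarray,
    effect: float,
) -> float:
    """Share of phenotypic variance explained by one scanned marker.

    Computed as var(marker dosage) * effect^2 / var(y), capped at 1.  For a
    Hardy-Weinberg diploid locus this equals the textbook 2p(1-p) * a^2
    form; for fully inbred panels the dosage variance is 4p(1-p), which the
    empirical variance captures directly.
    """
    vy = float(np.var(y))
    if vy <= 0:
        return 0.0
    share = float(np.var(marker_dosages)) * effect**2 / vy
    return min(share, 1.0)


def run_gwas(
    y: np.ndarray,
    g: GenotypeMatrix,
    G: np.ndarray,
    train_ids: np.ndarray,
    alpha: float = 0.05,
    var_threshold: float = SIMPLEM_VAR_THRESHOLD,
) -> GwasResult:
    """Full association step: scan, multiple-testing correction, shares."""
    train = np.asarray(train_ids)
    effects, p_values = mlm_scan(y, g, G, train)
    m_eff = simple_m(g, var_threshold=var_threshold, train_ids=train)
    m_eff = max(m_eff, 1)
    threshold = alpha / m_eff
    sig_idx = np.where(p_values < threshold)[0]
    significant = [g.marker_ids[i] for i in sig_idx]
    shares = {
        g.marker_ids[i]: variance_explained(y, g.dosage[train, i], effects[i])
        for i in sig_idx
    }
    return GwasResult(
        marker_ids=list(g.marker_ids),
        effects=effects,
        p_values=p_values,
        m_eff=m_eff,
        threshold=threshold,
        significant=significant,
        variance_explained=shares,
        alpha=alpha,
    )


def select_marker_set(
    scan: GwasResult, strategy: MarkerSetStrategy | str
) -> tuple[list[str], bool]:
    """Apply one of the four fixed-marker strategies to a scan result.

    Returns (marker list, feasible).  S1 is always feasible; S2 and S4
    require at least one significant marker; S3 additionally requires the
    significant markers' cumulative explained-variance shares (descending)
    to reach 10%.  Infeasible strategies return an empty list.
    """
    if isinstance(strategy, str):
        strategy = MarkerSetStrategy(strategy)
    s = strategy.strategy
    if s == "S1":
        best = int(np.argmin(scan.p_values))
        return [scan.marker_ids[best]], True
    if not scan.significant:
        return [], False
    ranked = sorted(
        scan.significant, key=lambda m: scan.variance_explained[m], reverse=True
    )
    if s == "S2":
        return [ranked[0]], True
    if s == "S4":
        return list(scan.significant), True
    # S3: minimal prefix with cumulative share >= 0.10
    cum = 0.0
    for r, mid in enumerate(ranked, start=1):
        cum += scan.variance_explained[mid]
        if cum >= 0.10:
            return ranked[:r], True
    return [], False
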