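"""Population structure: Rogers' distances, PCoA, admixture, contrasts.

The admixture estimator is a masked alternating least-squares factorization
of the individual allele-frequency matrix into a row-simplex ancestry matrix
Q and an ancestral-frequency matrix F, scored by binomial cross-entropy on a
held-out fraction of entries; the best of several random restarts is kept.
It mirrors the interface of sparse-NMF ancestry tools (k scan, repeats,
cross-entropy model choice) without reproducing their exact algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from genebankgp.genotype_qc import GenotypeMatrix

logger = logging.getLogger(__name__)

_FREQ_EPS = 1e-3


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample IDs."""

    ids: list[str]
    values: np.ndarray
    metric_name: str = "rogers"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("id count must match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class AdmixtureResult:
    """Estimated ancestry proportions with model-choice score."""

    Q: np.ndarray
    ancestral_freqs: np.ndarray
    k: int
    cross_entropy: float
    labels: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.Q, dtype=float)
        if (q < -1e-9).any() or not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must lie on the simplex")
        if not np.array_equal(self.labels, q.argmax(axis=1)):
            raise ValueError("labels must be the row-argmax of Q")


def rogers_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Rogers' distances between individuals.

    Per marker, with per-individual allele frequencies p = dosage/2, the
    distance between individuals i and j is sqrt(0.5 * sum over the two
    alleles of (p_i - p_j)^2) = |p_i - p_j| for a biallelic locus; the
    overall distance is the unweighted mean over markers, in [0, 1].
    """
    if np.isnan(g.dosage).any():
        raise ValueError("missing data present; run apply_qc first")
    p = g.dosage / 2.0
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(p, metric="cityblock") / g.n_markers)
    return DistanceMatrix(ids=list(g.sample_ids), values=d, metric_name="rogers")


def pcoa(d: DistanceMatrix, n_axes: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Classical scaling (principal coordinate analysis) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and returns coordinates
    (eigenvectors scaled by sqrt(eigenvalue), descending order) together
    with explained-variance shares computed over positive eigenvalues only.
    ``n_axes`` beyond the positive-eigenvalue count is truncated with a
    warning.
    """
    dm = d.values
    n = dm.shape[0]
    b = dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ b @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if n else 0.0
    positive = evals > tol
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues", n_axes, n_pos)
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    explained = evals[:n_axes] / evals[positive].sum()
    return coords, explained


def _project_rows_to_simplex(q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = q.shape
    u = np.sort(q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(q - theta[:, None], 0.0)


def _cross_entropy(dosage: np.ndarray, pred: np.ndarray, mask: np.ndarray) -> float:
    """Binomial log-loss of predicted allele frequencies on masked entries."""
    p = np.clip(pred, _FREQ_EPS, 1 - _FREQ_EPS)
    d = dosage[mask]
    pm = p[mask]
    return float(-np.mean(d * np.log(pm) + (2.0 - d) * np.log(1.0 - pm)))


def _als_fit(
    x: np.ndarray,
    dosage: np.ndarray,
    obs: np.ndarray,
    mask: np.ndarray,
    k: int,
    max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    n, m = x.shape
    ridge = 1e-6
    q = rng.dirichlet(np.ones(k), size=n)
    of = obs.astype(float)
    xo = x * of
    eye = ridge * np.eye(k)
    f = np.clip(np.tile(x.mean(axis=0), (k, 1)), _FREQ_EPS, 1 - _FREQ_EPS)
    for _ in range(max_iter):
        # F update: per-marker masked normal equations (batched k x k solves)
        a = np.einsum("ik,ij,il->jkl", q, of, q) + eye
        b = q.T @ xo  # k x m
        f = np.linalg.solve(a, b.T[:, :, None])[:, :, 0].T
        f = np.clip(f, _FREQ_EPS, 1 - _FREQ_EPS)
        # Q update: per-sample masked normal equations, then simplex projection
        a = np.einsum("kj,ij,lj->ikl", f, of, f) + eye
        b = xo @ f.T  # n x k
        q_new = np.linalg.solve(a, b[:, :, None])[:, :, 0]
        q_new = _project_rows_to_simplex(q_new)
        delta = np.abs(q_new - q).max()
        q = q_new
        if delta < 1e-5:
            break
    ce = _cross_entropy(dosage, q @ f, mask)
    return q, f, ce


def estimate_admixture(
    g: GenotypeMatrix,
    k: int,
    n_repeats: int = 5,
    max_iter: int = 100,
    masked_fraction: float = 0.05,
    seed: int = 0,
) -> AdmixtureResult:
    """Estimate ancestry proportions for ``k`` ancestral populations.

    Runs ``n_repeats`` random restarts of masked alternating least squares
    and returns the solution with the lowest held-out cross-entropy.  Hard
    subpopulation labels are the row-argmax of Q (ties broken toward the
    lowest index).
    """
    if np.isnan(g.dosage).any():
        raise ValueError("missing data present; run apply_qc first")
    if not 1 <= k <= g.n_samples:
        raise ValueError(f"k={k} out of range [1, {g.n_samples}]")
    rng = np.random.default_rng(seed)
    dosage = g.dosage
    x = dosage / 2.0
    n, m = x.shape
    mask = rng.random((n, m)) < masked_fraction
    if not mask.any():  # ensure a non-empty scoring set
        mask[rng.integers(n), rng.integers(m)] = True
    obs = ~mask

    if k == 1:
        f = np.clip(x.mean(axis=0, where=obs, keepdims=True), _FREQ_EPS, 1 - _FREQ_EPS)
        q = np.ones((n, 1))
        ce = _cross_entropy(dosage, q @ f, mask)
        return AdmixtureResult(Q=q, ancestral_freqs=f, k=1, cross_entropy=ce,
                               labels=np.zeros(n, dtype=int), sample_ids=list(g.sample_ids))

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_repeats):
        q, f, ce = _als_fit(x, dosage, obs, mask, k, max_iter, rng)
        if best is None or ce < best[2]:
            best = (q, f, ce)
    q, f, ce = best
    labels = q.argmax(axis=1)
    return AdmixtureResult(Q=q, ancestral_freqs=f, k=k, cross_entropy=ce,
                           labels=labels, sample_ids=list(g.sample_ids))


def choose_k(
    g: GenotypeMatrix,
    k_range,
    n_repeats: int = 5,
    max_iter: int = 100,
    masked_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-entropy model choice over a range of k.

    Each k is fit ``n_repeats`` times (independent restarts and hold-out
    masks); returns per-k mean and sd of the cross-entropy criterion.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for k in k_range:
        scores = []
        for _ in range(n_repeats):
            res = estimate_admixture(
                g, k, n_repeats=1, max_iter=max_iter,
                masked_fraction=masked_fraction, seed=int(rng.integers(2**31)),
            )
            scores.append(res.cross_entropy)
        rows.append({"k": k, "mean_cross_entropy": float(np.mean(scores)),
                     "sd_cross_entropy": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0})
    return pd.DataFrame(rows)


def phenotype_euclidean(
    blues: pd.DataFrame,
    traits: list[str],
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distances on trait BLUEs, complete cases only.

    Restricted to samples with a BLUE for every requested trait; traits are
    standardized to unit variance first (disable with ``standardize=False``)
    because they live on incommensurate scales.
    """
    wide = blues.pivot_table(index="sample_id", columns="trait", values="value")
    missing_traits = [t for t in traits if t not in wide.columns]
    if missing_traits:
        raise ValueError(f"traits absent from BLUE table: {missing_traits}")
    wide = wide[traits].dropna()
    if wide.empty:
        raise ValueError("no sample has complete records for the requested traits")
    values = wide.to_numpy(dtype=float)
    if standardize:
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(values, metric="euclidean"))
    return DistanceMatrix(ids=[str(s) for s in wide.index], values=d,
                          metric_name="euclidean_phenotype")


def subpopulation_contrast(d: DistanceMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Mean +/- sd of cross-group pairwise distances for every label pair.

    Returns a table sorted by descending mean distance; the first row is the
    most contrasting subpopulation pair.  A single label yields an empty
    table.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != d.values.shape[0]:
        raise ValueError("labels must match distance matrix size")
    uniq = np.unique(labels)
    rows = []
    for ai in range(len(uniq)):
        for bi in range(ai + 1, len(uniq)):
            a, b = uniq[ai], uniq[bi]
            block = d.values[np.ix_(labels == a, labels == b)].ravel()
            rows.append({
                "subpop_1": a,
                "subpop_2": b,
                "mean_distance": float(block.mean()),
                "sd_distance": float(block.std(ddof=1)) if block.size > 1 else 0.0,
                "n_pairs": int(block.size),
            })
    df = pd.DataFrame(rows, columns=["subpop_1", "subpop_2", "mean_distance",
                                     "sd_distance", "n_pairs"])
    return df.sort_values("mean_distance", ascending=False).reset_index(drop=True)
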