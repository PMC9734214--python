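"""Genomic relationship kernels and marker design matrices.

The additive kernel G follows VanRaden's first method: dosages centered by
twice the observed allele frequency, G = ZZ' / (2 * sum p(1-p)).  The
additive-by-additive epistatic kernel is the Hadamard square H = G o G.
Design matrices back the ridge-regression model family: a general centered
dosage matrix plus either hard-label masked or admixture-weighted
per-subpopulation copies.

Centering frequencies are always computed from the full panel (training and
test jointly) — predictions target a single genotyped collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from genebankgp.genotype_qc import GenotypeMatrix
from genebankgp.popstructure import AdmixtureResult

logger = logging.getLogger(__name__)

_PSD_TOL = 1e-8


@dataclass
class KernelSet:
    """Named additive and epistatic covariance kernels for one panel."""

    G: np.ndarray
    H: np.ndarray
    sample_ids: list[str]


@dataclass
class DesignMatrices:
    """Marker design matrices for the ridge-regression model family.

    ``Z_A`` is the centered dosage matrix; ``Z_S`` holds one masked copy
    per subpopulation (rows of non-members zeroed); ``Z_Sadm`` holds one
    admixture-weighted copy per subpopulation (row i scaled by Q[i, k]).
    """

    Z_A: np.ndarray
    Z_S: list[np.ndarray] | None
    Z_Sadm: list[np.ndarray] | None
    sample_ids: list[str]
    k: int


def _centered(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered dosages, allele frequencies and the polymorphic-marker mask."""
    if np.isnan(g.dosage).any():
        raise ValueError("missing data present; run apply_qc first")
    p = g.dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        logger.warning("excluding %d monomorphic markers from kernel", int((~poly).sum()))
    z = g.dosage[:, poly] - 2.0 * p[poly]
    return z, p[poly], poly


def vanraden_g(g: GenotypeMatrix) -> np.ndarray:
    """Additive genomic relationship matrix (VanRaden method 1)."""
    z, p, _ = _centered(g)
    if z.shape[1] == 0:
        raise ValueError("no polymorphic markers")
    denom = 2.0 * np.sum(p * (1.0 - p))
    gmat = (z @ z.T) / denom
    return _psd_repair(gmat)


def epistatic_h(gmat: np.ndarray) -> np.ndarray:
    """Epistatic relationship matrix: elementwise square of G (Hadamard)."""
    return gmat * gmat


def build_kernels(g: GenotypeMatrix) -> KernelSet:
    gmat = vanraden_g(g)
    return KernelSet(G=gmat, H=epistatic_h(gmat), sample_ids=list(g.sample_ids))


def _psd_repair(k: np.ndarray) -> np.ndarray:
    """Add diagonal jitter when the smallest eigenvalue dips below -1e-8."""
    k = 0.5 * (k + k.T)
    min_eig = np.linalg.eigvalsh(k)[0]
    if min_eig < -_PSD_TOL:
        jitter = _PSD_TOL * np.mean(np.diag(k)) - min_eig
        logger.warning("PSD repair: adding jitter %.3e (min eigenvalue %.3e)", jitter, min_eig)
        k = k + jitter * np.eye(k.shape[0])
    return k


def centered_design(g: GenotypeMatrix) -> np.ndarray:
    """Centered dosage matrix Z_A (monomorphic markers excluded)."""
    z, _, _ = _centered(g)
    return z


def build_design(
    g: GenotypeMatrix,
    admixture: AdmixtureResult,
    mode: str = "admixed",
    k: int | None = None,
) -> DesignMatrices:
    """Build the general + per-subpopulation design matrices.

    ``hard`` mode zeroes the rows of samples not assigned to a
    subpopulation; ``admixed`` mode scales row i of each copy by the
    sample's admixture coefficient for that subpopulation (so the copies
    sum to Z_A when Q rows sum to 1).
    """
    if mode not in {"hard", "admixed"}:
        raise ValueError("mode must be 'hard' or 'admixed'")
    z = centered_design(g)
    q = np.asarray(admixture.Q, dtype=float)
    if k is None:
        k = q.shape[1]
    if k != q.shape[1]:
        raise ValueError(f"k={k} does not match admixture with {q.shape[1]} components")
    if q.shape[0] != z.shape[0]:
        raise ValueError("admixture rows must match samples")
    z_s = None
    z_sadm = None
    if mode == "hard":
        labels = admixture.labels
        z_s = []
        for c in range(k):
            copy = np.zeros_like(z)
            member = labels == c
            copy[member] = z[member]
            z_s.append(copy)
    else:
        z_sadm = [q[:, c][:, None] * z for c in range(k)]
    return DesignMatrices(Z_A=z, Z_S=z_s, Z_Sadm=z_sadm,
                          sample_ids=list(g.sample_ids), k=k)


def reduced_g(g: GenotypeMatrix, excluded_markers: list[str]) -> np.ndarray:
    """VanRaden G rebuilt from the panel minus the given markers (W-BLUP G_r)."""
    excluded = set(excluded_markers)
    keep = [i for i, mid in enumerate(g.marker_ids) if mid not in excluded]
    if not keep:
        raise ValueError("all markers excluded; cannot build reduced kernel")
    return vanraden_g(g.subset_markers(np.array(keep)))


def allele_content(g: GenotypeMatrix, marker_ids: list[str]) -> np.ndarray:
    """Raw allele-content matrix F for selected markers (uncentered 0/1/2)."""
    index = {mid: i for i, mid in enumerate(g.marker_ids)}
    missing = [m for m in marker_ids if m not in index]
    if missing:
        raise KeyError(f"markers not in panel: {missing}")
    cols = [index[m] for m in marker_ids]
    return g.dosage[:, cols].copy()
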