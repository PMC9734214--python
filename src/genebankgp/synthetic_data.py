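"""Simulation of admixed inbred genotype panels and trait BLUEs.

Genotypes: ancestral allele frequencies are drawn per population around a
shared base frequency through a Balding–Nichols-style beta perturbation
scaled by a single divergence parameter; an optional outgroup population
receives elevated divergence.  Per-sample ancestry proportions come from a
Dirichlet centred on one dominant population, so small concentration values
give near-pure members and large values strong admixture.  Individuals are
fully homozygous apart from a configurable heterozygote rate, with missing
calls sprinkled in for QC testing.

Traits: phenotype = intercept + general additive effects + admixture-
weighted subpopulation-specific additive deviations + additive-by-additive
pairwise products + optional major-QTL effects + Gaussian noise at a target
heritability.  Component scales are calibrated empirically on the simulated
panel so realized variance shares track their targets.  Effect sizes are
Gaussian by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from genebankgp.genotype_qc import GenotypeMatrix

_OUTGROUP_DIVERGENCE_FACTOR = 3.0


@dataclass
class SimulationConfig:
    """Parameters of the admixed-panel genotype simulator."""

    n_samples: int = 500
    n_markers: int = 2000
    k_pops: int = 5
    fst_like_divergence: float = 0.1
    outgroup_index: int | None = None
    admixture_concentration: float = 0.2
    pop_size_weights: np.ndarray | None = None
    missing_rate: float = 0.0
    het_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_markers < 1 or self.k_pops < 1:
            raise ValueError("counts must be >= 1")
        if self.n_markers < self.k_pops:
            raise ValueError(
                "n_markers < k_pops: allele-frequency profiles unidentifiable"
            )
        if not 0 < self.fst_like_divergence < 1:
            raise ValueError("fst_like_divergence must be in (0, 1)")
        if self.admixture_concentration <= 0:
            raise ValueError("admixture_concentration must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.het_rate < 1:
            raise ValueError("het_rate must be in [0, 1)")
        if self.outgroup_index is not None and not 0 <= self.outgroup_index < self.k_pops:
            raise ValueError("outgroup_index out of range")
        if self.pop_size_weights is None:
            self.pop_size_weights = np.full(self.k_pops, 1.0 / self.k_pops)
        else:
            w = np.asarray(self.pop_size_weights, dtype=float)
            if w.shape != (self.k_pops,) or (w < 0).any():
                raise ValueError("pop_size_weights must be a non-negative k-vector")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("pop_size_weights must sum to 1")
            self.pop_size_weights = w


@dataclass
class TraitArchitecture:
    """Genetic architecture of a simulated trait."""

    n_additive_qtl: int = 100
    n_epistatic_pairs: int = 0
    subpop_effect_sd: float = 0.0
    n_major_qtl: int = 0
    major_qtl_variance_share: float = 0.0
    heritability: float = 0.8
    phenotyped_fraction: float = 1.0
    hard_subpop_labels: bool = False
    stratified_phenotyping: np.ndarray | None = None
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heritability <= 0 or self.heritability > 1:
            raise ValueError("heritability must be in (0, 1]")
        if not 0 <= self.major_qtl_variance_share < 1:
            raise ValueError("major_qtl_variance_share must be in [0, 1)")
        if self.n_major_qtl > 0 and self.major_qtl_variance_share > self.heritability:
            raise ValueError("major QTL share cannot exceed heritability")
        if not 0 < self.phenotyped_fraction <= 1:
            raise ValueError("phenotyped_fraction must be in (0, 1]")
        for name in ("n_additive_qtl", "n_epistatic_pairs", "n_major_qtl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated trait, for recovery tests."""

    general_effects: np.ndarray
    subpop_effects: np.ndarray
    epistatic_pairs: list[tuple[int, int, float]]
    major_qtl: list[tuple[int, float]]
    true_genetic_values: np.ndarray
    true_admixture: np.ndarray
    realized_h2: float
    intercept: float = 0.0


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate an admixed panel of inbred lines.

    Returns the genotype matrix (dosages in {0, 1, 2}, NaN missing) and the
    true n x k admixture matrix (rows on the simplex).
    """
    rng = np.random.default_rng(config.seed)
    n, m, k = config.n_samples, config.n_markers, config.k_pops

    base = rng.uniform(0.1, 0.9, size=m)
    div = np.full(k, config.fst_like_divergence)
    if config.outgroup_index is not None:
        div[config.outgroup_index] = min(
            0.95, _OUTGROUP_DIVERGENCE_FACTOR * config.fst_like_divergence
        )
    # Balding-Nichols: freq_c,j ~ Beta(p(1-F)/F, (1-p)(1-F)/F).  The
    # per-marker perturbations are then recentered on the base frequency
    # across populations, so divergence spreads the population profiles
    # apart (negative cross-population covariance) instead of acting as
    # shared drift — between-cluster distances grow monotonically with it.
    pop_freqs = np.empty((k, m))
    for c in range(k):
        f = div[c]
        a = base * (1 - f) / f
        b = (1 - base) * (1 - f) / f
        pop_freqs[c] = rng.beta(a, b)
    if k > 1:
        pop_freqs += base - pop_freqs.mean(axis=0)
    pop_freqs = np.clip(pop_freqs, 0.01, 0.99)

    primary = rng.choice(k, size=n, p=config.pop_size_weights)
    alpha = np.full((n, k), config.admixture_concentration)
    alpha[np.arange(n), primary] += 1.0
    # standard-gamma construction keeps the draw vectorized per sample
    gam = rng.standard_gamma(alpha)
    q_true = gam / gam.sum(axis=1, keepdims=True)

    ind_freq = q_true @ pop_freqs  # n x m individual allele frequencies
    hom_alt = rng.random((n, m)) < ind_freq
    dosage = np.where(hom_alt, 2.0, 0.0)
    if config.het_rate > 0:
        het = rng.random((n, m)) < config.het_rate
        dosage[het] = 1.0
    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosage[miss] = np.nan

    g = GenotypeMatrix(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        marker_ids=[f"M{j:05d}" for j in range(m)],
        dosage=dosage,
    )
    return g, q_true


def _centered_dosage(dosage: np.ndarray) -> np.ndarray:
    filled = dosage.copy()
    if np.isnan(filled).any():
        col_mean = np.nanmean(filled, axis=0)
        rows, cols = np.where(np.isnan(filled))
        filled[rows, cols] = col_mean[cols]
    return filled - filled.mean(axis=0)


def _scale_to_var(x: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Rescale x to the target variance; returns (scaled, factor)."""
    v = x.var()
    if v <= 0 or target_var <= 0:
        return np.zeros_like(x), 0.0
    factor = np.sqrt(target_var / v)
    return x * factor, factor


def simulate_trait(
    genotypes: GenotypeMatrix,
    admixture: np.ndarray,
    arch: TraitArchitecture,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one trait and its BLUE table on a simulated panel.

    The BLUE table has columns ``sample_id, trait, value`` and carries
    exactly ``ceil(phenotyped_fraction * n)`` samples.  The remaining
    samples are unphenotyped, emulating incomplete genebank phenotyping.
    """
    if arch.heritability <= 0:
        raise ValueError("heritability must be > 0")
    rng = np.random.default_rng(arch.seed)
    n, m = genotypes.dosage.shape
    q = np.asarray(admixture, dtype=float)
    if q.shape[0] != n:
        raise ValueError("admixture rows must match samples")
    k = q.shape[1]
    if max(arch.n_additive_qtl, arch.n_major_qtl) > m:
        raise ValueError("QTL counts cannot exceed n_markers")

    z = _centered_dosage(genotypes.dosage)
    h2 = arch.heritability
    major_share = arch.major_qtl_variance_share if arch.n_major_qtl else 0.0
    # split the non-major genetic share equally over the active components
    active = [arch.n_additive_qtl > 0, arch.n_epistatic_pairs > 0,
              arch.subpop_effect_sd > 0 and arch.n_additive_qtl > 0]
    n_active = sum(active)
    minor_share = (h2 - major_share) / n_active if n_active else 0.0

    general = np.zeros(m)
    g_add = np.zeros(n)
    qtl_idx = np.array([], dtype=int)
    if arch.n_additive_qtl > 0:
        qtl_idx = rng.choice(m, size=arch.n_additive_qtl, replace=False)
        eff = rng.standard_normal(arch.n_additive_qtl)
        raw = z[:, qtl_idx] @ eff
        g_add, factor = _scale_to_var(raw, minor_share)
        general[qtl_idx] = eff * factor

    g_epi = np.zeros(n)
    epi_pairs: list[tuple[int, int, float]] = []
    if arch.n_epistatic_pairs > 0:
        ii = rng.choice(m, size=arch.n_epistatic_pairs)
        jj = rng.choice(m, size=arch.n_epistatic_pairs)
        eff = rng.standard_normal(arch.n_epistatic_pairs)
        raw = (z[:, ii] * z[:, jj]) @ eff
        g_epi, factor = _scale_to_var(raw, minor_share)
        epi_pairs = [(int(a), int(b), float(e * factor)) for a, b, e in zip(ii, jj, eff)]

    g_sub = np.zeros(n)
    subpop = np.zeros((k, m))
    if arch.subpop_effect_sd > 0 and arch.n_additive_qtl > 0:
        dev = rng.normal(0.0, arch.subpop_effect_sd, size=(k, arch.n_additive_qtl))
        if arch.hard_subpop_labels:
            w = np.zeros_like(q)
            w[np.arange(n), q.argmax(axis=1)] = 1.0
        else:
            w = q
        raw = np.einsum("ic,ij,cj->i", w, z[:, qtl_idx], dev)
        g_sub, factor = _scale_to_var(raw, minor_share)
        subpop[:, qtl_idx] = dev * factor

    g_major = np.zeros(n)
    major: list[tuple[int, float]] = []
    if arch.n_major_qtl > 0 and major_share > 0:
        avail = np.setdiff1d(np.arange(m), qtl_idx)
        pool = avail if avail.size >= arch.n_major_qtl else np.arange(m)
        midx = rng.choice(pool, size=arch.n_major_qtl, replace=False)
        eff = rng.standard_normal(arch.n_major_qtl)
        eff[np.abs(eff) < 0.3] = 0.3  # keep every major QTL non-trivial
        raw = z[:, midx] @ eff
        g_major, factor = _scale_to_var(raw, major_share)
        major = [(int(j), float(e * factor)) for j, e in zip(midx, eff)]
        general[midx] += eff * factor

    g_total = g_add + g_epi + g_sub + g_major
    var_g = g_total.var()
    noise_var = var_g * (1 - h2) / h2 if h2 < 1 else 0.0
    noise = rng.standard_normal(n) * np.sqrt(noise_var) if noise_var > 0 else np.zeros(n)
    y = g_total + noise
    var_y = y.var()
    realized_h2 = float(var_g / var_y) if var_y > 0 else 1.0

    n_pheno = int(np.ceil(arch.phenotyped_fraction * n))
    if arch.stratified_phenotyping is not None:
        fractions = np.asarray(arch.stratified_phenotyping, dtype=float)
        labels = q.argmax(axis=1)
        chosen: list[int] = []
        for c in range(k):
            members = np.where(labels == c)[0]
            n_c = int(np.ceil(fractions[c] * members.size))
            chosen.extend(rng.choice(members, size=n_c, replace=False))
        pheno_idx = np.sort(np.array(chosen, dtype=int))
    else:
        pheno_idx = np.sort(rng.choice(n, size=n_pheno, replace=False))

    blues = pd.DataFrame(
        {
            "sample_id": [genotypes.sample_ids[i] for i in pheno_idx],
            "trait": arch.trait_name,
            "value": y[pheno_idx],
        }
    )
    truth = SyntheticTruth(
        general_effects=general,
        subpop_effects=subpop,
        epistatic_pairs=epi_pairs,
        major_qtl=major,
        true_genetic_values=g_total,
        true_admixture=q,
        realized_h2=realized_h2,
    )
    return blues, truth


def write_blues(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, index=False)


def read_blues(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "trait", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"BLUE table must have columns {sorted(required)}")
    return df


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize ground truth to a JSON bundle."""
    import json

    payload = {
        "general_effects": truth.general_effects.tolist(),
        "subpop_effects": truth.subpop_effects.tolist(),
        "epistatic_pairs": [[i, j, e] for i, j, e in truth.epistatic_pairs],
        "major_qtl": [[j, e] for j, e in truth.major_qtl],
        "true_genetic_values": truth.true_genetic_values.tolist(),
        "true_admixture": truth.true_admixture.tolist(),
        "realized_h2": truth.realized_h2,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
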