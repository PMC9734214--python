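"""Genotype container, file I/O and the marker QC / imputation pipeline.

Dosages are stored as a float ``n_samples x n_markers`` array with values in
``{0, 1, 2}`` and ``NaN`` for missing calls.  QC filters markers only (never
samples) in three strict steps: (1) drop markers by missingness, per-allele
homozygote count and heterozygosity; (2) impute missing calls to the
homozygous dosage of the marker's dominant (modal) allele; (3) drop markers
whose post-imputation minor allele frequency falls below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EmptyPanelError(ValueError):
    """Raised when a QC step removes every marker."""


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-dosage matrix with missing-data support.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows).
    marker_ids : list of str
        Unique marker identifiers (columns).
    dosage : ndarray of shape (n_samples, n_markers)
        Allele dosages in ``{0, 1, 2}``; ``NaN`` marks missing calls.
    major_allele_freq : ndarray of shape (n_markers,), optional
        Per-marker major-allele frequency; populated after QC.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    major_allele_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D array")
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over observed calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def subset_samples(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in indices],
            marker_ids=list(self.marker_ids),
            dosage=self.dosage[indices].copy(),
            major_allele_freq=None if self.major_allele_freq is None else self.major_allele_freq.copy(),
        )

    def subset_markers(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            marker_ids=[self.marker_ids[i] for i in indices],
            dosage=self.dosage[:, indices].copy(),
            major_allele_freq=None if self.major_allele_freq is None else self.major_allele_freq[indices].copy(),
        )


@dataclass
class QcConfig:
    """Thresholds of the marker filtering pipeline.

    Boundary conventions are strict where stated strict: markers with
    missingness strictly above ``max_missing``, fewer than
    ``min_homozygous_per_allele`` homozygotes for either allele, or
    heterozygosity strictly above ``max_het`` are removed in step 1;
    post-imputation MAF must be ``>= min_maf`` (inclusive) to survive step 3.
    """

    max_missing: float = 0.10
    min_homozygous_per_allele: int = 10
    max_het: float = 0.01
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing < 1:
            raise ValueError("max_missing must be in [0, 1)")
        if self.min_homozygous_per_allele < 0:
            raise ValueError("min_homozygous_per_allele must be >= 0")
        if not 0 <= self.max_het < 1:
            raise ValueError("max_het must be in [0, 1)")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class QcReport:
    """Per-step marker removal counts; ``retained + removed_step1 + removed_step3 == input``."""

    n_input_markers: int
    removed_missingness: int
    removed_homozygote_count: int
    removed_heterozygosity: int
    removed_step1: int
    imputed_calls: int
    removed_maf: int
    retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a TSV dosage table or a VCF.

    TSV layout: one header row of marker IDs, first column sample IDs,
    entries in {0, 1, 2} or ``NA``/empty for missing.  VCF: GT fields are
    mapped to alt-allele dosage (het -> 1); any half-missing or missing GT
    -> missing; non-biallelic sites are skipped with a logged count.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed dosage table {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
        rows, cols = np.where(~np.isnan(values) & ~np.isin(values, (0.0, 1.0, 2.0)))
        # +2: header row and 1-based line numbering
        raise ValueError(
            f"malformed dosage table {path}: invalid dosage at line {rows[0] + 2}, "
            f"marker {df.columns[cols[0]]!r}"
        )
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        marker_ids=[str(c) for c in df.columns],
        dosage=values,
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not Path(path).exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        # genotypes: list of [allele1, allele2, phased]; -1 encodes missing
        gts = np.array([gt[:2] for gt in variant.genotypes], dtype=float)
        dose = gts.sum(axis=1)
        dose[(gts < 0).any(axis=1)] = np.nan
        columns.append(dose)
        vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}"
        marker_ids.append(vid)
    if n_skipped:
        logger.info("skipped %d non-biallelic sites in %s", n_skipped, path)
    if not columns:
        raise ValueError(f"no biallelic sites in {path}")
    return GenotypeMatrix(
        sample_ids=samples,
        marker_ids=marker_ids,
        dosage=np.column_stack(columns),
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a genotype matrix as a TSV dosage table or a minimal VCF.

    The VCF writer synthesizes chromosome/position (single chromosome,
    consecutive positions) and encodes dosages as unphased GT calls.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(g.dosage, index=g.sample_ids, columns=g.marker_ids)
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")
        return
    if format != "vcf":
        raise ValueError(f"unknown format {format!r}")
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        for j, mid in enumerate(g.marker_ids):
            calls = "\t".join(
                "./." if np.isnan(d) else gt_code[d] for d in g.dosage[:, j]
            )
            fh.write(f"1\t{j + 1}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def apply_qc(g: GenotypeMatrix, cfg: QcConfig | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the three-step marker QC pipeline.

    Step 1 removes markers with missingness above ``max_missing``, fewer
    than ``min_homozygous_per_allele`` homozygous calls for either allele,
    or heterozygosity above ``max_het`` (all computed over observed calls).
    Step 2 imputes every remaining missing call to the homozygous dosage of
    the marker's most frequent allele — never to a heterozygote.  Step 3
    removes markers whose MAF is below ``min_maf``.

    Returns the filtered, fully imputed matrix (with
    ``major_allele_freq`` populated) and a :class:`QcReport`.
    """
    if cfg is None:
        cfg = QcConfig()
    dosage = g.dosage
    n, m_in = dosage.shape
    missing = np.isnan(dosage)
    n_obs = (~missing).sum(axis=0)
    miss_frac = np.where(n_obs < n, missing.sum(axis=0) / n, 0.0)

    n_hom_ref = np.nansum(dosage == 0, axis=0)
    n_hom_alt = np.nansum(dosage == 2, axis=0)
    n_het = np.nansum(dosage == 1, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_obs > 0, n_het / np.maximum(n_obs, 1), 1.0)

    fail_miss = miss_frac > cfg.max_missing
    fail_hom = (n_hom_ref < cfg.min_homozygous_per_allele) | (
        n_hom_alt < cfg.min_homozygous_per_allele
    )
    fail_het = het_frac > cfg.max_het
    keep1 = ~(fail_miss | fail_hom | fail_het)
    removed_step1 = int((~keep1).sum())
    if not keep1.any():
        raise EmptyPanelError("step-1 filters removed every marker")

    kept = g.subset_markers(np.where(keep1)[0])
    dosage = kept.dosage
    # step 2: impute to the modal allele's homozygous dosage (0 or 2)
    missing = np.isnan(dosage)
    n_imputed = int(missing.sum())
    if n_imputed:
        alt_freq = np.nanmean(dosage, axis=0) / 2.0
        fill = np.where(alt_freq > 0.5, 2.0, 0.0)
        rows, cols = np.where(missing)
        dosage[rows, cols] = fill[cols]

    # step 3: re-filter on minor allele frequency
    p_alt = dosage.mean(axis=0) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    keep3 = maf >= cfg.min_maf
    removed_maf = int((~keep3).sum())
    if not keep3.any():
        raise EmptyPanelError("MAF re-filter removed every marker")

    final = kept.subset_markers(np.where(keep3)[0])
    p_alt_final = final.dosage.mean(axis=0) / 2.0
    final.major_allele_freq = np.maximum(p_alt_final, 1.0 - p_alt_final)

    report = QcReport(
        n_input_markers=m_in,
        removed_missingness=int(fail_miss.sum()),
        removed_homozygote_count=int(fail_hom.sum()),
        removed_heterozygosity=int(fail_het.sum()),
        removed_step1=removed_step1,
        imputed_calls=n_imputed,
        removed_maf=removed_maf,
        retained=final.n_markers,
    )
    logger.info(
        "QC: %d -> %d markers (step1 removed %d, imputed %d calls, MAF removed %d)",
        m_in, report.retained, removed_step1, n_imputed, removed_maf,
    )
    return final, report
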