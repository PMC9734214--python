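"""Repeated fivefold cross-validation and prediction-ability evaluation.

The protocol: phenotyped samples are split into five (near-)equally sized
parts, each part serves once as the masked test set, the five test-fold
prediction vectors are concatenated and correlated with the observed BLUEs
— one Pearson correlation (the prediction ability) per repeat, never a
per-fold average.  All models of one trait share the same fold plans.
Marker discovery for the fixed-marker models runs inside each training
fold; admixture assignment is panel-wide (it uses no phenotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from genebankgp.genotype_qc import GenotypeMatrix
from genebankgp.gwas import run_gwas, select_marker_set
from genebankgp.kernels import (
    KernelSet,
    allele_content,
    build_design,
    reduced_g,
)
from genebankgp.mixed_model import (
    ModelFit,
    ModelSpec,
    fit_gblup,
    fit_multikernel,
    fit_rr_family,
    fit_wblup,
)
from genebankgp.popstructure import AdmixtureResult

logger = logging.getLogger(__name__)


@dataclass
class CvPlan:
    """Fold assignments for repeated k-fold cross-validation.

    ``fold_assignments[r]`` maps each phenotyped sample (by position in
    ``sample_ids``) to its fold index for repeat ``r``.
    """

    sample_ids: list[str]
    n_folds: int
    n_repeats: int
    fold_assignments: np.ndarray  # n_repeats x n_samples
    stratify_labels: np.ndarray | None
    seed: int


@dataclass
class CvReport:
    """Tidy per-(model, repeat) prediction abilities with summaries."""

    records: pd.DataFrame  # columns: model, repeat, scope, ability
    infeasible: dict[str, str] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        df = self.records.dropna(subset=["ability"])
        return (
            df.groupby(["model", "scope"])["ability"]
            .agg(mean="mean", sd="std", n="count")
            .reset_index()
        )


def _split_sizes(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def make_cv_plan(
    sample_ids: list[str],
    n_folds: int = 5,
    n_repeats: int = 100,
    stratify_labels: np.ndarray | None = None,
    seed: int = 0,
) -> CvPlan:
    """Build deterministic fold assignments, optionally stratified.

    In stratified mode each stratum is partitioned into ``n_folds``
    near-equal parts independently and corresponding parts are merged.
    Remainder samples are spread one per fold.
    """
    n = len(sample_ids)
    if n < n_folds:
        raise ValueError(f"{n} samples cannot fill {n_folds} folds")
    if stratify_labels is not None:
        stratify_labels = np.asarray(stratify_labels)
        if stratify_labels.shape[0] != n:
            raise ValueError("stratify_labels must match sample count")
        for lab in np.unique(stratify_labels):
            size = int((stratify_labels == lab).sum())
            if size < n_folds:
                raise ValueError(
                    f"stratum {lab!r} has {size} samples, fewer than {n_folds} folds"
                )
    master = np.random.SeedSequence(seed)
    repeat_seeds = master.spawn(n_repeats)
    assignments = np.empty((n_repeats, n), dtype=int)
    for r in range(n_repeats):
        rng = np.random.default_rng(repeat_seeds[r])
        folds = np.empty(n, dtype=int)
        if stratify_labels is None:
            groups = [np.arange(n)]
        else:
            groups = [np.where(stratify_labels == lab)[0] for lab in np.unique(stratify_labels)]
        for grp in groups:
            perm = rng.permutation(grp)
            sizes = _split_sizes(perm.size, n_folds)
            start = 0
            for f, size in enumerate(sizes):
                folds[perm[start:start + size]] = f
                start += size
        assignments[r] = folds
    return CvPlan(
        sample_ids=list(sample_ids),
        n_folds=n_folds,
        n_repeats=n_repeats,
        fold_assignments=assignments,
        stratify_labels=stratify_labels,
        seed=seed,
    )


def prediction_ability(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation of observed BLUEs with concatenated predictions.

    Returns NaN (recorded as missing, never 0) when either vector is
    constant.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.std() == 0 or predicted.std() == 0:
        logger.warning("constant vector in prediction-ability computation")
        return np.nan
    return float(np.corrcoef(observed, predicted)[0, 1])


class ModelInfeasibleError(RuntimeError):
    """A model's precondition (e.g. significant markers) is not met."""


@dataclass
class PanelData:
    """Everything a model fit needs, aligned on one genotype panel."""

    genotypes: GenotypeMatrix
    kernels: KernelSet
    admixture: AdmixtureResult | None = None
    _design_cache: dict = field(default_factory=dict, repr=False)

    def design(self, mode: str, k: int):
        key = (mode, k)
        if key not in self._design_cache:
            if self.admixture is None:
                raise ValueError("admixture required for subpopulation models")
            self._design_cache[key] = build_design(self.genotypes, self.admixture, mode=mode, k=k)
        return self._design_cache[key]


def fit_model(
    spec: ModelSpec,
    data: PanelData,
    y_train: np.ndarray,
    train_ids: np.ndarray,
    test_ids: np.ndarray,
) -> ModelFit:
    """Dispatch one model variant; GWAS-based marker discovery is nested
    inside the training set for the fixed-marker family."""
    if spec.family == "GBLUP":
        return fit_gblup(y_train, data.kernels.G, train_ids, test_ids)
    if spec.family == "EGBLUP":
        return fit_multikernel(
            y_train, [("g", data.kernels.G), ("g1", data.kernels.H)], train_ids, test_ids
        )
    if spec.family in {"RRBLUP", "GSA_RRBLUP"}:
        if spec.family == "RRBLUP":
            from genebankgp.kernels import DesignMatrices, centered_design

            if "rrblup" not in data._design_cache:
                z = centered_design(data.genotypes)
                data._design_cache["rrblup"] = DesignMatrices(
                    Z_A=z, Z_S=None, Z_Sadm=None,
                    sample_ids=list(data.genotypes.sample_ids), k=0,
                )
            design = data._design_cache["rrblup"]
        else:
            mode = "admixed" if spec.admixed else "hard"
            design = data.design(mode, spec.k or (data.admixture.k if data.admixture else 0))
        return fit_rr_family(y_train, design, spec, train_ids, test_ids)
    if spec.family == "WBLUP":
        scan = run_gwas(y_train, data.genotypes, data.kernels.G, train_ids)
        markers, feasible = select_marker_set(scan, spec.marker_strategy)
        if not feasible:
            raise ModelInfeasibleError(
                f"{spec.name}: precondition not met (no qualifying markers)"
            )
        g_r = reduced_g(data.genotypes, markers)
        f_g = allele_content(data.genotypes, markers)
        return fit_wblup(y_train, g_r, f_g, train_ids, test_ids)
    raise ValueError(f"unknown family {spec.family}")


def run_cv(
    plan: CvPlan,
    model_specs: list[ModelSpec],
    data: PanelData,
    blues: pd.DataFrame,
    trait: str | None = None,
    scope_labels: np.ndarray | None = None,
) -> CvReport:
    """Run the repeated-CV comparison of several models on one trait.

    ``blues`` must carry a BLUE for every sample in the plan.  Predictions
    of the five test folds are concatenated per repeat and correlated with
    the observed BLUEs; with ``scope_labels`` the correlation is
    additionally computed within each label group ("combined" covers all).
    A model whose precondition fails in any fold is marked infeasible.
    """
    tb = blues if trait is None else blues[blues["trait"] == trait]
    value_by_id = dict(zip(tb["sample_id"].astype(str), tb["value"].astype(float)))
    missing = [s for s in plan.sample_ids if s not in value_by_id]
    if missing:
        raise ValueError(f"samples without BLUE in plan: {missing[:5]}...")
    panel_index = {sid: i for i, sid in enumerate(data.genotypes.sample_ids)}
    plan_panel_idx = np.array([panel_index[s] for s in plan.sample_ids])
    y_plan = np.array([value_by_id[s] for s in plan.sample_ids])

    records = []
    infeasible: dict[str, str] = {}
    for spec in model_specs:
        if spec.name in infeasible:
            continue
        for r in range(plan.n_repeats):
            folds = plan.fold_assignments[r]
            predicted = np.empty(len(plan.sample_ids))
            try:
                for f in range(plan.n_folds):
                    test_mask = folds == f
                    train_ids = plan_panel_idx[~test_mask]
                    test_ids = plan_panel_idx[test_mask]
                    fit = fit_model(spec, data, y_plan[~test_mask], train_ids, test_ids)
                    predicted[test_mask] = fit.predicted_test
            except ModelInfeasibleError as exc:
                logger.warning("model %s infeasible: %s", spec.name, exc)
                infeasible[spec.name] = str(exc)
                break
            records.append({
                "model": spec.name, "repeat": r, "scope": "combined",
                "ability": prediction_ability(y_plan, predicted),
            })
            if scope_labels is not None:
                for lab in np.unique(scope_labels):
                    mask = scope_labels == lab
                    records.append({
                        "model": spec.name, "repeat": r, "scope": f"subpop_{lab}",
                        "ability": prediction_ability(y_plan[mask], predicted[mask]),
                    })
    df = pd.DataFrame(records, columns=["model", "repeat", "scope", "ability"])
    return CvReport(records=df, infeasible=infeasible)


def contrast_scenario(
    data: PanelData,
    blues: pd.DataFrame,
    distance: "DistanceMatrix",
    labels: np.ndarray,
    model_specs: list[ModelSpec],
    trait: str | None = None,
    equalize: bool = False,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[CvReport, tuple]:
    """CV restricted to the two most contrasting subpopulations.

    Picks the arg-max pair from the pairwise between-group mean distances,
    optionally downsamples the larger group to the smaller's size (seeded),
    and runs stratified CV, reporting combined and per-subpopulation
    abilities.
    """
    from genebankgp.popstructure import subpopulation_contrast

    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two subpopulations")
    table = subpopulation_contrast(distance, labels)
    pair = (table.loc[0, "subpop_1"], table.loc[0, "subpop_2"])

    tb = blues if trait is None else blues[blues["trait"] == trait]
    phenotyped = set(tb["sample_id"].astype(str))
    panel_ids = np.array(data.genotypes.sample_ids)
    dist_index = {sid: i for i, sid in enumerate(distance.ids)}
    members: dict[object, list[str]] = {pair[0]: [], pair[1]: []}
    for sid in panel_ids:
        if sid not in phenotyped or sid not in dist_index:
            continue
        lab = labels[dist_index[sid]]
        if lab in members:
            members[lab].append(sid)
    rng = np.random.default_rng(seed)
    if equalize:
        n_min = min(len(v) for v in members.values())
        for lab in members:
            if len(members[lab]) > n_min:
                members[lab] = list(rng.choice(members[lab], size=n_min, replace=False))
    chosen = members[pair[0]] + members[pair[1]]
    strat = np.array([0] * len(members[pair[0]]) + [1] * len(members[pair[1]]))
    plan = make_cv_plan(chosen, n_folds=n_folds, n_repeats=n_repeats,
                        stratify_labels=strat, seed=seed)
    report = run_cv(plan, model_specs, data, blues, trait=trait, scope_labels=strat)
    return report, pair
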