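"""Canned study setups at the two published dataset scales.

The morbidity task uses 1,412 positive genes per balanced dataset and the
druggability task 257, matching the positive-class sizes the method was
originally evaluated with.  Synthetic matrices are sized so the planted
prevalence yields at least that many positives and an equally large
negative pool: 3,400 genes at prevalence 0.45 for the morbidity scale and
900 genes at prevalence 0.35 for the druggability scale; the first 1,412
(resp. 257) planted positives are used.
"""

from __future__ import annotations

import pandas as pd

from .datasets import LabeledDataset, build_balanced_datasets, shuffle_dataset_labels
from .learning import EnsembleConfig, EvalResult, cross_validate
from .simulate import SyntheticSpec, druggability_like, generate_study, morbidity_like

MORBIDITY_POSITIVES = 1412
DRUGGABILITY_POSITIVES = 257

N_REPLICATES = 10
N_FOLDS = 10


def morbidity_scale_spec(seed: int) -> SyntheticSpec:
    return morbidity_like(n_genes=3400, prevalence=0.45, seed=seed)


def druggability_scale_spec(seed: int) -> SyntheticSpec:
    return druggability_like(n_genes=900, prevalence=0.35, seed=seed)


def study_matrix(task: str, seed: int) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic feature matrix and the task's positive list at reference scale."""
    if task == "morbidity":
        spec, n_pos = morbidity_scale_spec(seed), MORBIDITY_POSITIVES
    elif task == "druggability":
        spec, n_pos = druggability_scale_spec(seed), DRUGGABILITY_POSITIVES
    else:
        raise ValueError(f"unknown task {task!r}")
    matrix, planted = generate_study(spec)
    if len(planted) < n_pos or len(matrix) - n_pos < n_pos:
        raise RuntimeError(
            f"{task} study too small: {len(planted)} positives of {len(matrix)} genes"
        )
    return matrix, planted[:n_pos]


def replicate_datasets(
    matrix: pd.DataFrame, positives: list[str], seed: int, task: str
) -> tuple[list[LabeledDataset], list[LabeledDataset]]:
    """The 10 normal datasets and their label-shuffled counterparts."""
    normal = build_balanced_datasets(
        matrix, positives, n_replicates=N_REPLICATES, seed=seed, task=task
    )
    shuffled = [
        shuffle_dataset_labels(d, seed=(seed * 100 + i) % 2**31)
        for i, d in enumerate(normal)
    ]
    return normal, shuffled


def cv_all(datasets: list[LabeledDataset], seed: int) -> list[EvalResult]:
    """10-fold CV of the default ensemble on every dataset replicate."""
    results = []
    for i, d in enumerate(datasets):
        config = EnsembleConfig(seed=(seed * 1000 + i) % 2**31)
        results.append(cross_validate(d, config, folds=N_FOLDS))
    return results
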