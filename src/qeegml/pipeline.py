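"""End-to-end study pipeline on one diagnostic stratum.

Chains the full analysis: synthesise (or accept) a cohort, extract the 152
relative band-power features, hold out a stratified test fraction, double
the positive training class by split-half augmentation, run the
generational feature search, compose the voting ensemble, fit the score
cutoff on training-side scores, and evaluate on the untouched holdout.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import EEGRecording
from .ensemble import (
    CutoffConfig,
    EnsembleModel,
    EvaluationReport,
    evaluate_ensemble,
    fit_cutoff,
    out_of_fold_scores,
    select_submodels,
)
from .prep import TEST, TRAIN, augment_positives, holdout_split, split_half_reliability
from .search import SearchConfig, SearchResult, run_heuristic
from .synthetic import CohortDesign, cohort_to_feature_table, generate_cohort


#: Pool schedule used for desk-scale runs of the full five-generation search:
#: C(40,2)=780, C(25,3)=2,300, C(20,4)=4,845, C(16,5)=4,368 evaluations.
DESK_POOL_SIZES = {2: 40, 3: 25, 4: 20, 5: 16}


def desk_search_config(seed: int = 0, **overrides) -> SearchConfig:
    """A search configuration sized for a single workstation CPU.

    The generation-1 scan stays exhaustive over all 152 features; every
    later generation runs on a frequency-reduced pool so the whole search
    evaluates ~12,500 combinations instead of hundreds of millions.
    """
    kw = dict(
        k_max=5,
        k_exhaustive=1,
        pool_sizes=DESK_POOL_SIZES,
        retention_accuracy=0.75,
        seed=seed,
    )
    kw.update(overrides)
    return SearchConfig(**kw)


@dataclass
class StudyResult:
    """Everything a run of :func:`run_study` produced."""

    diagnosis: str
    table: pd.DataFrame            # split + augmented feature table
    search: SearchResult
    ensemble: EnsembleModel
    cutoff: CutoffConfig
    report: EvaluationReport
    scores: pd.DataFrame           # per-test-subject score/prediction/truth
    train_scores: pd.DataFrame
    reliability: pd.DataFrame | None = None


def run_study(
    design: CohortDesign,
    search_cfg: SearchConfig | None = None,
    holdout_fraction: float = 0.2,
    n_submodels: int = 20,
    cutoff_method: str = "youden",
    fixed_cutoff: float | None = None,
    signal_level: bool = True,
    selection: str = "inner",
) -> StudyResult:
    """Run the complete pipeline on one synthetic diagnostic stratum.

    ``signal_level=True`` synthesises raw recordings and extracts features
    (and augments positives by re-extracting features from each temporal
    half); ``False`` draws feature tables directly and uses degraded
    row-duplication augmentation.  All randomness derives from
    ``design.seed`` and ``search_cfg.seed``.
    """
    search_cfg = search_cfg or desk_search_config(seed=design.seed)
    recordings: dict[str, EEGRecording] = {}
    reliability = None
    if signal_level:
        cohort = generate_cohort(design)
        recordings = {s.subject_id: s.recording for s in cohort}
        table = cohort_to_feature_table(cohort)
        reliability = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in cohort],
                "min_split_half_corr": [
                    float(split_half_reliability(s.recording).min()) for s in cohort
                ],
            }
        )
    else:
        from .synthetic import generate_feature_table

        table = generate_feature_table(design)
    split = holdout_split(table, fraction=holdout_fraction, seed=design.seed)
    import warnings as _warnings

    with _warnings.catch_warnings():
        if not signal_level:
            _warnings.simplefilter("ignore")  # degraded duplication is intentional here
        prepared = augment_positives(split, recordings or None)
    train = prepared[prepared["split"] == TRAIN].reset_index(drop=True)
    test = prepared[prepared["split"] == TEST].reset_index(drop=True)

    search = run_heuristic(train, search_cfg)
    candidates = search.candidates or ([search.best] if search.best else [])
    if not candidates:
        raise RuntimeError("search produced no usable candidate models")
    ens = select_submodels(
        candidates,
        train,
        search_cfg,
        n=n_submodels,
        selection=selection,
        holdout_table=test if selection == "holdout" else None,
        diagnosis=design.diagnosis,
    )

    # Cutoff is fit on out-of-fold vote scores of the original (unaugmented)
    # training subjects: training-side only, but free of the in-sample
    # optimism of the refit sub-models.
    train_orig = split[split["split"] == TRAIN]
    tr_scores = out_of_fold_scores(ens, train, train_orig, search_cfg)
    tr_truth = (train_orig["amyloid_label"] == "positive").to_numpy()
    if cutoff_method == "fixed":
        cutoff = fit_cutoff(tr_scores, tr_truth, method="fixed", fixed=fixed_cutoff)
    else:
        cutoff = fit_cutoff(tr_scores, tr_truth, method=cutoff_method)
    train_scores = pd.DataFrame(
        {
            "subject_id": train_orig["subject_id"].to_numpy(),
            "score": tr_scores,
            "truth": train_orig["amyloid_label"].to_numpy(),
        }
    )

    report, detail = evaluate_ensemble(
        ens, cutoff, test, strict=(selection != "holdout")
    )
    return StudyResult(
        diagnosis=design.diagnosis,
        table=prepared,
        search=search,
        ensemble=ens,
        cutoff=cutoff,
        report=report,
        scores=detail,
        train_scores=train_scores,
        reliability=reliability,
    )
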