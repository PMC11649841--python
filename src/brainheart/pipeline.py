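"""End-to-end experiment orchestration.

Wires the stages together: simulate (or load) a cohort, derive minute
panels, extract WTLCC matrices for a signal pair, train the matrix scorer
on a patient-grouped split, and evaluate both the scorer and the tabular
comparison (averages vs embeddings, each adjusted for CRASH covariates).

The single-cohort layout splits patients within one cohort; the
two-cohort layout trains on cohort A and validates on cohort B with a
structural disjointness check (the cohorts are never mixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import cnn, indices, signal_io, tabular
from .evaluation import classification_report
from .synth import SimCohortSpec, simulate_cohort
from .types import MinutePanel, PatientRecord, WaveformSignal
from .wtlcc import WTLCCMatrix, WTLCCParams, extract_matrices

__all__ = [
    "derive_panel",
    "Cohort",
    "simulate_minute_cohort",
    "run_single_cohort_experiment",
    "pair_search",
]


def derive_panel(
    abp: WaveformSignal, icp: WaveformSignal, patient_id: str = ""
) -> MinutePanel:
    """Full index derivation from a waveform pair to an aligned minute panel."""
    abp_min = signal_io.integrate_60s(abp)
    icp_min = signal_io.integrate_60s(icp)
    n = min(len(abp_min), len(icp_min))

    def _trim(s):
        from .types import MinuteSeries
        return MinuteSeries(s.values[:n], start_min=s.start_min, missing=s.missing[:n])

    abp_min, icp_min = _trim(abp_min), _trim(icp_min)
    cpp = indices.compute_cpp(abp_min, icp_min)
    prx = indices.compute_prx(abp, icp)
    beats = indices.detect_systolic_peaks(abp)
    brs = indices.compute_brs(beats)
    lfhf = indices.compute_lfhf(beats)
    return signal_io.crop_align(
        {"icp": icp_min, "cpp": cpp, "prx": prx, "brs": brs, "lfhf": lfhf},
        patient_id=patient_id,
        length=n,
    )


@dataclass
class Cohort:
    """Records plus per-patient minute panels and a matrix cache."""

    records: List[PatientRecord]
    panels: Dict[str, MinutePanel]
    outcome_attr: str = "outcome_short"
    _matrix_cache: dict = field(default_factory=dict, repr=False)

    @property
    def labels(self) -> Dict[str, str]:
        return {r.patient_id: getattr(r, self.outcome_attr) for r in self.records}

    def matrices(
        self, pair: Tuple[str, str], params: WTLCCParams
    ) -> Dict[str, List[WTLCCMatrix]]:
        key = (pair, params.N, params.S, params.K, params.J)
        if key not in self._matrix_cache:
            self._matrix_cache[key] = {
                pid: extract_matrices(panel, pair, params)
                for pid, panel in self.panels.items()
            }
        return self._matrix_cache[key]


def simulate_minute_cohort(spec: SimCohortSpec) -> Cohort:
    """Simulate a minute-fidelity cohort into the experiment container."""
    if spec.fidelity != "minute":
        raise ValueError("use derive_panel for waveform-fidelity cohorts")
    data = simulate_cohort(spec)
    records = [rec for rec, _ in data]
    panels = {rec.patient_id: panel for rec, panel in data}
    return Cohort(records=records, panels=panels)


def _flatten(
    by_patient: Mapping[str, Sequence[WTLCCMatrix]], ids: Sequence[str]
) -> List[WTLCCMatrix]:
    out: List[WTLCCMatrix] = []
    for pid in ids:
        out.extend(by_patient.get(pid, ()))
    return out


#: Training-score spread below which the network is considered collapsed
#: (dead ReLUs leave a constant-output solution; healthy fits spread well
#: above this even on uninformative inputs).
_COLLAPSE_SPREAD = 1e-3


def _is_collapsed(scorer: cnn.TrainedScorer,
                  matrices: Sequence[WTLCCMatrix]) -> bool:
    probe = matrices[:: max(1, len(matrices) // 64)]
    return float(np.std(scorer.score_matrices(probe))) < _COLLAPSE_SPREAD


def _train_with_restarts(
    matrices: Sequence[WTLCCMatrix],
    labels: Mapping[str, str],
    config: cnn.CNNConfig,
    max_restarts: int = 2,
) -> cnn.TrainedScorer:
    """Train, restarting with a re-derived seed if optimisation collapses.

    Collapse (constant scores from dead ReLUs) is detected on *training*
    matrices only; no validation information is used. Deterministic:
    restart seeds derive from the configured seed.
    """
    import dataclasses as _dc

    rng = np.random.default_rng(config.seed)
    scorer = cnn.train(matrices, labels, config)
    for _ in range(max_restarts):
        if not _is_collapsed(scorer, matrices):
            break
        retry = _dc.replace(config, seed=int(rng.integers(0, 2**31)))
        scorer = cnn.train(matrices, labels, retry)
    return scorer


def _patient_scores(
    scorer: cnn.TrainedScorer,
    by_patient: Mapping[str, Sequence[WTLCCMatrix]],
    ids: Sequence[str],
) -> Tuple[List[str], np.ndarray]:
    kept, scores = [], []
    for pid in ids:
        mats = by_patient.get(pid, ())
        if len(mats) == 0:
            continue
        kept.append(pid)
        scores.append(scorer.score_patient(mats)[0])
    return kept, np.asarray(scores)


def run_single_cohort_experiment(
    cohort: Cohort,
    pair: Tuple[str, str],
    wtlcc_params: WTLCCParams,
    config: cnn.CNNConfig,
    val_frac: float = 0.33,
    seed: int = 0,
    with_tabular: bool = True,
) -> dict:
    """Patient-grouped split, scorer training and full evaluation.

    Returns a dict with the fitted scorer, the split, the patient-level
    CNN report and (optionally) the averages-vs-embeddings tabular reports
    computed on the identical patient partition.
    """
    labels = cohort.labels
    train_ids, val_ids = cnn.split_patients(labels, val_frac=val_frac, seed=seed)
    by_patient = cohort.matrices(pair, wtlcc_params)

    scorer = _train_with_restarts(_flatten(by_patient, train_ids), labels, config)
    kept, scores = _patient_scores(scorer, by_patient, val_ids)
    cnn_report = classification_report(scores, [labels[p] for p in kept])

    out = {
        "scorer": scorer,
        "train_ids": train_ids,
        "val_ids": val_ids,
        "pair": pair,
        "wtlcc_params": wtlcc_params,
        "cnn_report": cnn_report,
        "patient_scores": dict(zip(kept, scores)),
    }
    if not with_tabular:
        return out

    rec_by_id = {r.patient_id: r for r in cohort.records}
    for mode in ("averages", "embeddings"):
        kwargs = dict(
            mode=mode,
            panels=cohort.panels,
            matrices=by_patient,
            scorer=scorer,
            outcome_attr=cohort.outcome_attr,
        )
        t_train, _ = tabular.build_features([rec_by_id[p] for p in train_ids], **kwargs)
        t_val, _ = tabular.build_features([rec_by_id[p] for p in val_ids], **kwargs)
        out[f"{mode}_report"] = tabular.fit_evaluate(t_train, t_val, seed=seed)
    return out


def pair_search(
    cohort: Cohort,
    space: cnn.SearchSpace,
    config: cnn.CNNConfig,
    val_frac: float = 0.33,
    seed: int = 0,
    max_train_matrices: Optional[int] = None,
) -> Tuple[dict, float, list]:
    """Hyperparameter search with validation patient-level AUC objective.

    The patient split is drawn once (from ``seed``) and shared by all
    trials; per-trial randomness covers network initialisation and, when
    ``max_train_matrices`` caps the load, the matrix subsample.
    """
    labels = cohort.labels
    train_ids, val_ids = cnn.split_patients(labels, val_frac=val_frac, seed=seed)

    def objective(cand: dict, trial_seed: int) -> float:
        params = WTLCCParams(N=cand["N"], S=cand["S"], K=cand["K"])
        by_patient = cohort.matrices(cand["pair"], params)
        train_mats = _flatten(by_patient, train_ids)
        if not train_mats:
            raise RuntimeError("no training matrices for this geometry")
        rng = np.random.default_rng(trial_seed)
        if max_train_matrices and len(train_mats) > max_train_matrices:
            idx = rng.choice(len(train_mats), max_train_matrices, replace=False)
            train_mats = [train_mats[i] for i in sorted(idx)]
        import dataclasses as _dc
        cfg = _dc.replace(config, learning_rate=cand["lr"],
                          seed=int(rng.integers(0, 2**31)))
        scorer = _train_with_restarts(train_mats, labels, cfg)
        kept, scores = _patient_scores(scorer, by_patient, val_ids)
        report = classification_report(scores, [labels[p] for p in kept])
        return report.auc

    return cnn.search(space, objective, seed=seed)
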