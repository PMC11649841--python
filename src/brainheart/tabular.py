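"""Gradient-boosted-trees comparison on per-patient feature tables.

Two feature sets, each adjusted for the CRASH clinical covariates (age,
GCS, pupil reactivity, major extracranial injury):

* ``averages``   — the 72-h means of the five neuromonitoring indices;
  deliberately blind to temporal coupling structure.
* ``embeddings`` — patient-level embeddings from the fitted matrix scorer.

Patients with a missing covariate are excluded (not imputed) with a logged
count. The patient partition must be the one used for the scorer; it is
passed in, never re-drawn here.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .cnn import TrainedScorer
from .evaluation import EvalReport, classification_report
from .types import MinutePanel, OUTCOME_UNFAV, PANEL_INDICES, PatientRecord
from .wtlcc import WTLCCMatrix

__all__ = ["build_features", "fit_evaluate"]

logger = logging.getLogger(__name__)

PUPIL_ORDINAL = {"bilateral": 0, "unilateral": 1, "nonreactive": 2}
CRASH_COLS = ("age", "gcs", "pupils", "extracranial")


def _crash_row(rec: PatientRecord) -> Optional[dict]:
    if rec.age is None or rec.gcs is None or rec.pupils is None:
        return None
    return {
        "age": float(rec.age),
        "gcs": int(rec.gcs),
        "pupils": PUPIL_ORDINAL[rec.pupils],
        "extracranial": int(bool(rec.extracranial_injury)),
    }


def build_features(
    records: Sequence[PatientRecord],
    mode: str,
    panels: Optional[Mapping[str, MinutePanel]] = None,
    matrices: Optional[Mapping[str, Sequence[WTLCCMatrix]]] = None,
    scorer: Optional[TrainedScorer] = None,
    outcome_attr: str = "outcome_short",
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """One row per patient: feature set + CRASH covariates + label.

    Returns ``(table, excluded)`` where ``excluded`` maps dropped patient
    ids to the reason (missing covariate, no valid minutes, no matrices).
    """
    if mode not in ("averages", "embeddings"):
        raise ValueError("mode must be 'averages' or 'embeddings'")
    if mode == "averages" and panels is None:
        raise ValueError("averages mode requires panels")
    if mode == "embeddings" and (matrices is None or scorer is None):
        raise ValueError("embeddings mode requires matrices and a fitted scorer")

    rows: List[dict] = []
    index: List[str] = []
    excluded: Dict[str, str] = {}
    for rec in records:
        crash = _crash_row(rec)
        if crash is None:
            missing = [c for c, v in (("age", rec.age), ("gcs", rec.gcs),
                                      ("pupils", rec.pupils)) if v is None]
            excluded[rec.patient_id] = f"missing covariate: {','.join(missing)}"
            continue
        if mode == "averages":
            panel = panels.get(rec.patient_id)
            if panel is None:
                excluded[rec.patient_id] = "no panel"
                continue
            feats = {}
            bad = None
            for name in PANEL_INDICES:
                s = panel[name]
                if s.n_valid == 0:
                    bad = name
                    break
                feats[name] = float(np.nanmean(s.masked()))
            if bad is not None:
                excluded[rec.patient_id] = f"no valid minutes for {bad}"
                continue
        else:
            mats = matrices.get(rec.patient_id, ())
            if len(mats) == 0:
                excluded[rec.patient_id] = "no matrices"
                continue
            emb = scorer.embed(mats)
            feats = {f"emb_{i}": float(v) for i, v in enumerate(emb)}
        feats.update(crash)
        feats["label"] = getattr(rec, outcome_attr)
        rows.append(feats)
        index.append(rec.patient_id)

    if excluded:
        logger.info("excluded %d patients: %s", len(excluded), excluded)
    return pd.DataFrame(rows, index=index), excluded


def fit_evaluate(
    table_train: pd.DataFrame,
    table_val: pd.DataFrame,
    seed: int = 0,
    threshold: float = 0.5,
    max_depth: int = 3,
    n_estimators: int = 200,
    learning_rate: float = 0.1,
    early_stopping_rounds: Optional[int] = None,
) -> EvalReport:
    """Fit gradient-boosted trees (logistic objective) and report metrics.

    Tables must be patient-disjoint with identical feature columns. Splits
    use the exact greedy method: histogram binning derives candidate
    thresholds from training quantiles only, which on small cohorts can
    place every validation row in one leaf; exact midpoint splits do not.
    Early stopping on validation loss is available but off by default —
    with a handful of validation patients it is noisy and reuses the
    validation set during fitting.
    """
    overlap = set(table_train.index) & set(table_val.index)
    if overlap:
        raise ValueError(f"patients appear in both tables: {sorted(overlap)}")
    cols_t = [c for c in table_train.columns if c != "label"]
    cols_v = [c for c in table_val.columns if c != "label"]
    if cols_t != cols_v:
        raise ValueError(
            f"feature column mismatch: train={cols_t} vs val={cols_v}"
        )
    y_train = (table_train["label"] == OUTCOME_UNFAV).astype(int).to_numpy()
    y_val = (table_val["label"] == OUTCOME_UNFAV).astype(int).to_numpy()
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")

    model = XGBClassifier(
        max_depth=max_depth,
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        objective="binary:logistic",
        eval_metric="logloss",
        early_stopping_rounds=early_stopping_rounds,
        tree_method="exact",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    X_train = table_train[cols_t].to_numpy(float)
    X_val = table_val[cols_t].to_numpy(float)
    if early_stopping_rounds:
        model.fit(X_train, y_train, eval_set=[(X_val, y_val)], verbose=False)
    else:
        model.fit(X_train, y_train)
    scores = model.predict_proba(X_val)[:, 1]
    return classification_report(
        scores, table_val["label"].tolist(), threshold=threshold
    )
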