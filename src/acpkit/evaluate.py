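"""Cross-validation protocols and the four performance metrics.

Sensitivity, specificity, overall accuracy and Matthews correlation are
computed from pooled confusion counts::

    Sn  = 100 * TP / (TP + FN)
    Sp  = 100 * TN / (TN + FP)
    Qa  = 100 * (TP + TN) / (TP + FN + TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

``Qa`` is the prevalence-weighted mean of Sn and Sp, an identity that holds
exactly on unrounded values.  Percentages are reported rounded half-up to
2 decimals and MCC to 3, matching the precision such results are usually
printed at; unrounded values are always exposed too.

Two cross-validation schemes are provided: the jackknife (leave-one-out,
one model per record) and seed-controlled stratified k-fold.  Hyperparameter
tuning can run once on the full data (``tuning_mode="global"``, the cheap
protocol many sequence-classification papers use, which leaks the test
record into tuning) or inside every training split (``"per_fold"``, the
statistically honest variant).  Reports always record which mode was used.

``recover_confusion`` inverts printed (Sn, Sp) percentages and class sizes
back to integer confusion counts, enabling arithmetic-consistency checks of
published result tables without the underlying data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .features import EncoderConfig, encode_aac, encode_combined
from .io import CANONICAL_ALPHABET, PeptideDataset
from .model import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    ScalerParams,
    fit_scaler,
    grid_search,
)
from sklearn.svm import SVC


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.5 always away from zero toward +inf)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n_pos(self) -> int:
        return self.TP + self.FN

    @property
    def n_neg(self) -> int:
        return self.TN + self.FP

    @classmethod
    def from_predictions(
        cls, true: Sequence[str], predicted: Sequence[str]
    ) -> "ConfusionCounts":
        if len(true) != len(predicted):
            raise ValueError("true/predicted length mismatch")
        tp = fn = fp = tn = 0
        for t, p in zip(true, predicted):
            if t == "positive":
                if p == "positive":
                    tp += 1
                else:
                    fn += 1
            elif t == "negative":
                if p == "negative":
                    tn += 1
                else:
                    fp += 1
            else:
                raise ValueError(f"unknown true label {t!r}")
        return cls(TP=tp, FN=fn, FP=fp, TN=tn)


@dataclass
class MetricsReport:
    """Sn/Sp/Qa (percent), MCC, and the counts they derive from."""

    counts: ConfusionCounts
    sn: float
    sp: float
    qa: float
    mcc: float
    mcc_degenerate: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def sn_rounded(self) -> float:
        return round_half_up(self.sn, 2)

    @property
    def sp_rounded(self) -> float:
        return round_half_up(self.sp, 2)

    @property
    def qa_rounded(self) -> float:
        return round_half_up(self.qa, 2)

    @property
    def mcc_rounded(self) -> float:
        return round_half_up(self.mcc, 3)

    def as_dict(self) -> dict:
        c = self.counts
        return {
            "counts": {"TP": c.TP, "FN": c.FN, "FP": c.FP, "TN": c.TN},
            "rounded": {
                "Sn": self.sn_rounded,
                "Sp": self.sp_rounded,
                "Qa": self.qa_rounded,
                "MCC": self.mcc_rounded,
            },
            "unrounded": {
                "Sn": self.sn,
                "Sp": self.sp,
                "Qa": self.qa,
                "MCC": self.mcc,
            },
            "mcc_degenerate": self.mcc_degenerate,
            **self.extras,
        }

    def tsv_row(self) -> str:
        c = self.counts
        return "\t".join(
            str(v)
            for v in (
                c.TP, c.FN, c.FP, c.TN,
                self.sn_rounded, self.sp_rounded, self.qa_rounded,
                self.mcc_rounded,
            )
        )


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sn, Sp, Qa and MCC from confusion counts.

    Requires at least one true positive-class and one true negative-class
    sample.  If any factor of the MCC denominator is zero, MCC is defined
    as 0 and flagged degenerate.
    """
    if counts.n_pos < 1 or counts.n_neg < 1:
        raise ValueError("need at least one sample of each class")
    tp, fn, fp, tn = counts.TP, counts.FN, counts.FP, counts.TN
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    qa = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    if degenerate:
        warnings.warn(
            "MCC denominator has a zero factor; reporting MCC = 0", stacklevel=2
        )
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        counts=counts, sn=sn, sp=sp, qa=qa, mcc=mcc, mcc_degenerate=degenerate
    )


def recover_confusion(
    sn_pct: float, sp_pct: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Invert printed Sn/Sp percentages and class sizes to integer counts.

    TP = round-half-up(Sn/100 * n_pos), TN likewise; FN and FP by complement.
    If the re-derived 2-decimal Sn/Sp do not match the inputs, the printed
    percentages are mutually inconsistent with the class sizes and a
    consistency warning is emitted (the counts are still returned).
    """
    if not (0 <= sn_pct <= 100 and 0 <= sp_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    tp = int(round_half_up(sn_pct / 100.0 * n_pos, 0))
    tn = int(round_half_up(sp_pct / 100.0 * n_neg, 0))
    counts = ConfusionCounts(TP=tp, FN=n_pos - tp, FP=n_neg - tn, TN=tn)
    rep = compute_metrics(counts)
    if rep.sn_rounded != round_half_up(sn_pct, 2) or rep.sp_rounded != round_half_up(
        sp_pct, 2
    ):
        warnings.warn(
            f"recovered counts re-derive Sn={rep.sn_rounded}, Sp={rep.sp_rounded}, "
            f"inconsistent with inputs ({sn_pct}, {sp_pct})",
            stacklevel=2,
        )
    return counts


def qa_weighted(sn_pct: float, sp_pct: float, n_pos: int, n_neg: int) -> float:
    """Prevalence-weighted mean of Sn and Sp (the Qa identity).

    On unrounded Sn/Sp this equals Qa exactly; applied to *printed* (rounded)
    Sn/Sp it is the reading under which published Qa values are usually
    reproduced, and can differ from counts-based Qa in the last digit.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    return (n_pos * sn_pct + n_neg * sp_pct) / (n_pos + n_neg)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    scheme: str = "jackknife"
    k: int = 5
    seed: int = 0
    tuning_mode: str = "global"

    def __post_init__(self) -> None:
        if self.scheme not in ("jackknife", "kfold"):
            raise ValueError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2 for k-fold CV")
        if self.tuning_mode not in ("global", "per_fold"):
            raise ValueError(f"unknown tuning mode {self.tuning_mode!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Fixed (C, γ) if both given, otherwise a grid to search."""

    C: float | None = None
    gamma: float | None = None
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    tuning_folds: int = 5

    @property
    def fixed(self) -> bool:
        return self.C is not None and self.gamma is not None


@dataclass
class FoldDetail:
    fold: int
    train_index: np.ndarray
    test_index: np.ndarray
    C: float
    gamma: float
    scaler: ScalerParams


@dataclass
class CVResult:
    report: MetricsReport
    predictions: pd.DataFrame
    plan: CVPlan
    chosen_params: list[tuple[float, float]]
    fold_details: list[FoldDetail]


def _cv_splits(y: np.ndarray, plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    if plan.scheme == "jackknife":
        return list(LeaveOneOut().split(y))
    n_min = int(min(np.sum(y == 1), np.sum(y == 0)))
    if plan.k > n_min:
        raise ValueError(
            f"k={plan.k} exceeds the smaller class size ({n_min}) for "
            "stratified k-fold CV"
        )
    skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    return list(skf.split(np.zeros_like(y), y))


def run_cv(
    dataset: PeptideDataset,
    encoder: EncoderConfig | None = None,
    model: ModelConfig | None = None,
    plan: CVPlan | None = None,
) -> CVResult:
    """Cross-validate the full encode/scale/train/predict pipeline.

    Every record is predicted exactly once by a model trained without it
    (jackknife) or without its fold (stratified k-fold).  Feature scaling is
    re-fit on each fold's training rows, so test rows never influence the
    (min, max) parameters.  Metrics come from the pooled predictions.
    """
    encoder = encoder or EncoderConfig()
    model = model or ModelConfig()
    plan = plan or CVPlan()

    labels = dataset.labels
    if any(l is None for l in labels):
        raise ValueError("every record must be labeled for cross-validation")
    y = np.array([1 if l == "positive" else 0 for l in labels], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")

    matrix = encode_combined(dataset, encoder)
    X = matrix.X
    splits = _cv_splits(y, plan)

    if model.fixed:
        global_params = (float(model.C), float(model.gamma))
    elif plan.tuning_mode == "global":
        global_params = grid_search(
            X,
            labels,
            c_values=model.c_grid,
            gamma_values=model.gamma_grid,
            folds=model.tuning_folds,
            seed=plan.seed,
        )
    else:
        global_params = None

    n = len(dataset)
    pred = np.empty(n, dtype=object)
    decision = np.full(n, np.nan)
    fold_of = np.full(n, -1, dtype=int)
    chosen: list[tuple[float, float]] = []
    details: list[FoldDetail] = []

    for fold, (train_idx, test_idx) in enumerate(splits):
        if global_params is not None:
            C, gamma = global_params
        else:
            C, gamma = grid_search(
                X[train_idx],
                [labels[i] for i in train_idx],
                c_values=model.c_grid,
                gamma_values=model.gamma_grid,
                folds=model.tuning_folds,
                seed=plan.seed,
            )
        scaler = fit_scaler(X[train_idx])
        svc = SVC(C=C, gamma=gamma, kernel="rbf")
        svc.fit(scaler.transform(X[train_idx]), y[train_idx])
        dv = svc.decision_function(scaler.transform(X[test_idx]))
        for j, i in enumerate(test_idx):
            decision[i] = dv[j]
            pred[i] = "positive" if dv[j] >= 0 else "negative"
            fold_of[i] = fold
        chosen.append((C, gamma))
        details.append(
            FoldDetail(
                fold=fold,
                train_index=train_idx,
                test_index=test_idx,
                C=C,
                gamma=gamma,
                scaler=scaler,
            )
        )

    predictions = pd.DataFrame(
        {
            "id": dataset.ids,
            "true": labels,
            "predicted": list(pred),
            "decision": decision,
            "fold": fold_of,
        }
    )
    counts = ConfusionCounts.from_predictions(labels, list(pred))
    report = compute_metrics(counts)
    report.extras = {
        "cv": {
            "scheme": plan.scheme,
            "k": plan.k if plan.scheme == "kfold" else len(splits),
            "seed": plan.seed,
            "tuning_mode": "fixed" if model.fixed else plan.tuning_mode,
            "leakage_note": (
                "hyperparameters tuned on the full dataset before CV; the "
                "test record of each fold influenced (C, gamma)"
                if (not model.fixed and plan.tuning_mode == "global")
                else None
            ),
        },
        "params": {
            "C": chosen[0][0] if len({p for p in chosen}) == 1 else None,
            "gamma": chosen[0][1] if len({p for p in chosen}) == 1 else None,
            "per_fold": [list(p) for p in chosen],
        },
        "encoder": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in matrix.encoder_meta.items()
        },
    }
    return CVResult(
        report=report,
        predictions=predictions,
        plan=plan,
        chosen_params=chosen,
        fold_details=details,
    )


# ---------------------------------------------------------------------------
# composition analysis
# ---------------------------------------------------------------------------

def class_mean_composition(dataset: PeptideDataset) -> pd.DataFrame:
    """Per-class mean amino-acid composition (unweighted mean of per-peptide
    frequency vectors), one column per class present; rows are residues.

    Each class column sums to 1.  This is the computation behind the usual
    bar plot contrasting anticancer and non-anticancer residue usage.
    """
    classes = [l for l in ("positive", "negative") if l in set(dataset.labels)]
    if not classes:
        raise ValueError("dataset has no labeled records")
    cols = {}
    for cls in classes:
        vecs = [encode_aac(r) for r in dataset if r.label == cls]
        if not vecs:
            raise ValueError(f"class {cls!r} is empty")
        cols[cls] = np.mean(vecs, axis=0)
    return pd.DataFrame(cols, index=list(CANONICAL_ALPHABET))
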