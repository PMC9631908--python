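"""Multiple-linear-regression QSAR: selection, fitting, validation.

The model-building recipe is:

1. keep descriptors whose |Pearson r| with activity exceeds a threshold,
   pruning cross-correlated pairs in favour of the member more correlated
   with activity;
2. fit ordinary least squares and report the training r²;
3. report a leave-one-out cross-validated q² = 1 − PRESS/SS_tot (hat-matrix
   shortcut, identical to explicit refits);
4. backward-eliminate descriptors until the model obeys the
   one-descriptor-per-five-compounds rule and the r²–q² gap closes,
   preferring the smallest model whose r² is near the best attainable;
5. predict the test set, report r² (squared Pearson correlation) and a
   predictive r², and flag outliers with the generalized extreme
   studentized deviate (Rosner) test.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import DescriptorTable, apply_scaling

__all__ = [
    "QsarModel",
    "ModelReport",
    "select_descriptors",
    "fit_mlr",
    "loo_q2",
    "reduce_model",
    "predict",
    "correction_factor_analysis",
    "esd_outliers",
]


@dataclass(frozen=True)
class QsarModel:
    """A fitted linear model on max-scaled descriptors."""

    target: str
    descriptor_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    training_ids: tuple[str, ...]
    r2: float
    q2: float | None = None
    scaling_maxima: pd.Series | None = None
    elimination_trace: tuple[dict, ...] = ()

    def __post_init__(self):
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")
        max_desc = len(self.training_ids) // 5 if self.training_ids else None
        if max_desc is not None and max_desc >= 1 and len(self.descriptor_names) > max_desc:
            warnings.warn(
                f"{len(self.descriptor_names)} descriptors for "
                f"{len(self.training_ids)} training compounds exceeds one per five",
                stacklevel=2,
            )

    def predict_scaled(self, x: pd.DataFrame) -> np.ndarray:
        xm = x[list(self.descriptor_names)].to_numpy(dtype=float)
        return xm @ self.coefficients + self.intercept

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "descriptors": list(self.descriptor_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "training_ids": list(self.training_ids),
            "r2": float(self.r2),
            "q2": None if self.q2 is None else float(self.q2),
            "scaling_maxima": None
            if self.scaling_maxima is None
            else {k: float(v) for k, v in self.scaling_maxima.items()},
            "elimination_trace": [dict(step) for step in self.elimination_trace],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "QsarModel":
        return cls(
            target=d["target"],
            descriptor_names=tuple(d["descriptors"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            training_ids=tuple(d["training_ids"]),
            r2=float(d["r2"]),
            q2=None if d.get("q2") is None else float(d["q2"]),
            scaling_maxima=None
            if d.get("scaling_maxima") is None
            else pd.Series(d["scaling_maxima"]),
            elimination_trace=tuple(d.get("elimination_trace", ())),
        )


@dataclass(frozen=True)
class ModelReport:
    """Per-compound predictions with test statistics and outlier flags."""

    target: str
    compound_ids: tuple[str, ...]
    observed: np.ndarray
    predicted: np.ndarray
    r2_test: float
    r2_predictive: float
    esd_flags: np.ndarray
    esd_statistics: tuple[dict, ...] = ()

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.predicted

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": self.observed,
                "predicted": self.predicted,
                "residual": self.residuals,
                "esd_flag": self.esd_flags,
            },
            index=pd.Index(self.compound_ids, name="compound_id"),
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def select_descriptors(
    t: DescriptorTable,
    y,
    activity_threshold: float = 0.7,
    cross_threshold: float = 0.7,
) -> list[str]:
    """Activity-correlation filter plus cross-correlation pruning.

    Keeps descriptors with |Pearson r| against activity above
    ``activity_threshold``, ordered by |r| descending, then walks the list
    keeping a descriptor only if its |r| with every already-kept
    descriptor is at most ``cross_threshold`` (so of a cross-correlated
    pair the member more correlated with activity survives).
    """
    if not t.scaled:
        raise ValueError("descriptor table must be scaled before selection")
    yv = np.asarray(y, dtype=float)
    if len(yv) != len(t.values):
        raise ValueError("activity vector length does not match table rows")
    corr = {
        name: abs(_pearson(t.values[name].to_numpy(dtype=float), yv))
        for name in t.values.columns
    }
    passed = sorted(
        (n for n, r in corr.items() if r > activity_threshold),
        key=lambda n: (-corr[n], n),
    )
    if not passed:
        warnings.warn(
            f"no descriptor exceeds |r| = {activity_threshold} with activity; "
            "consider lowering the threshold",
            stacklevel=2,
        )
        return []
    kept: list[str] = []
    for name in passed:
        xs = t.values[name].to_numpy(dtype=float)
        if all(
            abs(_pearson(xs, t.values[other].to_numpy(dtype=float))) <= cross_threshold
            for other in kept
        ):
            kept.append(name)
    return kept


def _design(t: DescriptorTable, names) -> np.ndarray:
    missing = [n for n in names if n not in t.values.columns]
    if missing:
        raise KeyError(f"descriptor columns missing from table: {missing}")
    return t.values[list(names)].to_numpy(dtype=float)


def fit_mlr(t: DescriptorTable, y, names, target: str = "") -> QsarModel:
    """Ordinary least squares of activity on the named scaled descriptors."""
    names = list(names)
    yv = np.asarray(y, dtype=float)
    x = _design(t, names)
    n, p = x.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} compounds to fit {p} descriptors, got {n}")
    xd = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(xd) < p + 1:
        # identify dependent columns by rank increments
        dependent = []
        rank = 1
        for k, name in enumerate(names):
            new_rank = np.linalg.matrix_rank(xd[:, : k + 2])
            if new_rank == rank:
                dependent.append(name)
            rank = new_rank
        raise ValueError(f"singular design; linearly dependent columns: {dependent}")
    beta, *_ = np.linalg.lstsq(xd, yv, rcond=None)
    fitted = xd @ beta
    sst = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(np.sum((yv - fitted) ** 2)) / sst if sst > 0 else 0.0
    return QsarModel(
        target=target,
        descriptor_names=tuple(names),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        training_ids=tuple(t.compound_ids),
        r2=r2,
        scaling_maxima=t.scaling_maxima,
    )


def loo_q2(t: DescriptorTable, y, names) -> float:
    """Leave-one-out cross-validated q² = 1 − PRESS/SS_tot.

    Uses the hat-matrix identity e_(i) = e_i / (1 − h_ii), which equals
    refitting the model n times with each point held out.
    """
    names = list(names)
    yv = np.asarray(y, dtype=float)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst <= 0:
        raise ValueError("activity has zero variance; q2 undefined")
    x = _design(t, names)
    n, p = x.shape
    if n < p + 3:
        raise ValueError(f"need at least {p + 3} compounds for LOO with {p} descriptors")
    xd = np.column_stack([np.ones(n), x])
    hat = xd @ np.linalg.solve(xd.T @ xd, xd.T)
    leverage = np.diag(hat)
    if np.any(leverage >= 1.0 - 1e-10):
        # a held-out point is fully determined by the fit: LOO undefined,
        # treat as maximally pessimistic
        return -np.inf
    resid = yv - hat @ yv
    press_resid = resid / (1.0 - leverage)
    return 1.0 - float(np.sum(press_resid**2)) / sst


def reduce_model(
    t: DescriptorTable,
    y,
    candidates,
    target: str = "",
    max_desc: int | None = None,
    gap_tol: float = 0.2,
    r2_slack: float = 0.02,
) -> QsarModel:
    """Backward elimination to the smallest adequate model.

    Starting from ``candidates``, the descriptor whose removal costs the
    least r² is dropped repeatedly down to a single descriptor. A state is
    *valid* when it has at most ``max_desc`` descriptors (default
    ⌊n/5⌋) and its r² − q² gap is at most ``gap_tol``. Among valid states,
    the one with the fewest descriptors whose r² is within ``r2_slack``
    of the best valid r² wins — the best model attainable with the fewest
    descriptors. The full elimination trace is stored on the model.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate descriptors to reduce")
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if max_desc is None:
        max_desc = max(n // 5, 1)
    if max_desc < 1:
        raise ValueError("max_desc must allow at least one descriptor")

    def state(names):
        model = fit_mlr(t, yv, names, target=target)
        q2 = loo_q2(t, yv, names) if n >= len(names) + 3 else None
        return model, q2

    current = candidates
    trace: list[dict] = []
    states: list[tuple[tuple[str, ...], float, float | None]] = []
    while True:
        model, q2 = state(current)
        gap = None if q2 is None else model.r2 - q2
        trace.append(
            {
                "descriptors": list(current),
                "r2": round(model.r2, 6),
                "q2": None if q2 is None else round(q2, 6),
            }
        )
        states.append((tuple(current), model.r2, q2))
        if len(current) == 1:
            break
        # drop the descriptor whose removal hurts r² least
        best_drop, best_r2 = None, -np.inf
        for name in current:
            reduced = [c for c in current if c != name]
            r2_without = fit_mlr(t, yv, reduced, target=target).r2
            if best_drop is None or r2_without > best_r2 or (
                r2_without == best_r2 and name < best_drop
            ):
                best_drop, best_r2 = name, r2_without
        current = [c for c in current if c != best_drop]

    valid = [
        (names, r2, q2)
        for names, r2, q2 in states
        if len(names) <= max_desc and q2 is not None and (r2 - q2) <= gap_tol
    ]
    if not valid:
        # fall back to the best state within the size constraint
        valid = [(names, r2, q2) for names, r2, q2 in states if len(names) <= max_desc]
    if not valid:
        raise ValueError(f"cannot build a model with at most {max_desc} descriptors")
    best_r2 = max(r2 for _, r2, _ in valid)
    chosen = min(
        (s for s in valid if s[1] >= best_r2 - r2_slack),
        key=lambda s: (len(s[0]), -s[1]),
    )
    model, q2 = state(list(chosen[0]))
    return QsarModel(
        target=target,
        descriptor_names=model.descriptor_names,
        coefficients=model.coefficients,
        intercept=model.intercept,
        training_ids=model.training_ids,
        r2=model.r2,
        q2=q2,
        scaling_maxima=model.scaling_maxima,
        elimination_trace=tuple(trace),
    )


def predict(
    model: QsarModel,
    t: DescriptorTable,
    y_test,
    esd_alpha: float = 0.05,
    esd_k_max: int | None = None,
) -> ModelReport:
    """Predict held-out compounds and evaluate the model.

    ``t`` may be unscaled (the model's stored training maxima are applied)
    or already on the model's scale. Reports the squared Pearson
    correlation between observed and predicted (``r2_test``) plus a
    predictive r² (1 − SSE/SST about the observed mean), and runs the
    generalized ESD outlier test on the predictions.
    """
    if not t.scaled:
        if model.scaling_maxima is None:
            raise ValueError("model has no scaling maxima to apply")
        t = apply_scaling(t, model.scaling_maxima)
    yv = np.asarray(y_test, dtype=float)
    pred = model.predict_scaled(t.values)
    if len(yv) != len(pred):
        raise ValueError("y_test length does not match table rows")
    r = _pearson(yv, pred)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    r2_pred = 1.0 - float(np.sum((yv - pred) ** 2)) / sst if sst > 0 else 0.0
    if len(yv) >= 3:
        flags, stats_ = esd_outliers(pred, alpha=esd_alpha, k_max=esd_k_max)
    else:
        flags, stats_ = np.zeros(len(yv), dtype=bool), ()
    return ModelReport(
        target=model.target,
        compound_ids=tuple(t.compound_ids),
        observed=yv,
        predicted=pred,
        r2_test=r * r,
        r2_predictive=r2_pred,
        esd_flags=flags,
        esd_statistics=stats_,
    )


def correction_factor_analysis(model: QsarModel, name: str, constant: float) -> QsarModel:
    """Replace a descriptor term with a constant folded into the intercept.

    Used to probe whether a term (e.g. a binary lead-likeness indicator)
    acts as a mere correction factor: compounds whose term value equals
    the constant predict identically; all others shift by the difference.
    """
    if name not in model.descriptor_names:
        raise KeyError(f"descriptor {name!r} not in model {model.descriptor_names}")
    keep = [i for i, n in enumerate(model.descriptor_names) if n != name]
    return QsarModel(
        target=model.target,
        descriptor_names=tuple(model.descriptor_names[i] for i in keep),
        coefficients=model.coefficients[keep],
        intercept=model.intercept + constant,
        training_ids=model.training_ids,
        r2=model.r2,
        q2=model.q2,
        scaling_maxima=model.scaling_maxima,
    )


def esd_outliers(
    values, alpha: float = 0.05, k_max: int | None = None
) -> tuple[np.ndarray, tuple[dict, ...]]:
    """Generalized (Rosner) extreme studentized deviate test.

    Tests for up to ``k_max`` outliers (default ⌈0.1·n⌉, at least 1):
    repeatedly remove the point with the largest studentized deviate,
    compare each step's statistic against its t-distribution critical
    value, and flag all points up to the largest significant step.
    Returns a boolean flag vector aligned with the input and the per-step
    statistics.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("ESD test requires at least 3 observations")
    if k_max is None:
        k_max = max(int(math.ceil(0.1 * n)), 1)
    if k_max >= n / 2:
        raise ValueError(f"k_max={k_max} too large for n={n} (must be < n/2)")
    if np.std(x, ddof=1) == 0:
        warnings.warn("zero variance; no outliers detectable", stacklevel=2)
        return np.zeros(n, dtype=bool), ()

    remaining = list(range(n))
    steps: list[dict] = []
    removed_order: list[int] = []
    for step in range(1, k_max + 1):
        sub = x[remaining]
        mean, sd = sub.mean(), sub.std(ddof=1)
        if sd == 0:
            break
        deviates = np.abs(sub - mean) / sd
        local = int(np.argmax(deviates))
        idx = remaining[local]
        r_stat = float(deviates[local])
        m = len(remaining)
        p = 1.0 - alpha / (2.0 * m)
        t_crit = stats.t.ppf(p, m - 2)
        lam = ((m - 1) * t_crit) / math.sqrt((m - 2 + t_crit**2) * m)
        steps.append(
            {"step": step, "index": idx, "statistic": r_stat, "critical": float(lam),
             "significant": r_stat > lam}
        )
        removed_order.append(idx)
        remaining.remove(idx)

    flags = np.zeros(n, dtype=bool)
    significant_steps = [s["step"] for s in steps if s["significant"]]
    if significant_steps:
        for idx in removed_order[: max(significant_steps)]:
            flags[idx] = True
    return flags, tuple(steps)
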