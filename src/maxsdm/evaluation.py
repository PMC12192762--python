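"""Model evaluation: replicated splits, discrimination metrics, variable
importance and response curves."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid_io import EnvGridStack
from .maxent_core import FeatureSet, MaxEntModel, SuitabilityMap, fit_maxent, predict
from .preprocess import SampleMatrix

__all__ = [
    "EvalReport",
    "ImportanceTable",
    "auc",
    "tss_and_omission",
    "or10_threshold",
    "evaluate_replicates",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gains",
    "response_curve",
]


def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count 0.5."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))
    rp = ranks[: p.size].sum()
    return float((rp - p.size * (p.size + 1) / 2) / (p.size * b.size))


def or10_threshold(training_presence_scores) -> float:
    """Default omission threshold: 10th percentile of training presence
    scores."""
    return float(np.percentile(np.asarray(training_presence_scores, dtype=float), 10))


def tss_and_omission(
    presence_scores_test,
    background_scores,
    omission_threshold: float | None = None,
) -> tuple[float, float, float]:
    """Maximise TSS = sensitivity + specificity − 1 over all distinct scores.

    Returns ``(max_tss, tss_threshold, omission_rate)`` where the omission
    rate is the fraction of test presences scoring strictly below
    ``omission_threshold`` (defaults to the TSS-maximising threshold).
    A presence counts as predicted-present when its score >= threshold.
    """
    p = np.asarray(presence_scores_test, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    cand = np.unique(np.concatenate([p, b]))
    sens = (p[:, None] >= cand[None, :]).mean(axis=0)
    spec = (b[:, None] < cand[None, :]).mean(axis=0)
    tss = sens + spec - 1.0
    k = int(np.argmax(tss))
    t_star = float(cand[k])
    thr = t_star if omission_threshold is None else float(omission_threshold)
    omission = float((p < thr).mean())
    return float(tss[k]), t_star, omission


@dataclass
class EvalReport:
    """Per-replicate metrics plus their aggregates and the averaged map."""

    records: pd.DataFrame
    n_replicates: int
    split_fraction: float
    averaged_map: SuitabilityMap | None = None
    models: list[MaxEntModel] = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.records.mean(numeric_only=True)

    @property
    def sd(self) -> pd.Series:
        return self.records.std(numeric_only=True, ddof=1)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def evaluate_replicates(
    samples: SampleMatrix,
    features: FeatureSet,
    rm: float = 1.0,
    n_replicates: int = 10,
    test_fraction: float = 0.25,
    seed: int | None = None,
    stack: EnvGridStack | None = None,
    max_iterations: int = 5000,
    tolerance: float = 1e-5,
    keep_models: bool = False,
) -> EvalReport:
    """Repeated random presence splits (background shared across replicates).

    Each replicate fits on the training presences, scores logistic output,
    and records train/test AUC, omission at the 10th-percentile training
    threshold, and max TSS on the test set.  When ``stack`` is given, the
    averaged map is the cellwise mean of the replicate logistic maps.
    """
    n_p = samples.n_presence
    n_test = int(round(n_p * test_fraction))
    if test_fraction > 0 and (n_test < 1 or n_p - n_test < 1):
        raise ValueError(
            f"{n_p} presences cannot support a test fraction of {test_fraction}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    maps = []
    models = []
    for rep in range(n_replicates):
        perm = rng.permutation(n_p)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        train = samples.take_presences(train_idx)
        model = fit_maxent(
            train, features, rm=rm, max_iterations=max_iterations, tolerance=tolerance
        )
        bg_scores = model.logistic(samples.background_values)
        train_scores = model.logistic(samples.presence_values[train_idx])
        rec = {
            "replicate": rep,
            "train_auc": auc(train_scores, bg_scores),
            "training_gain": model.training_gain,
        }
        thr = or10_threshold(train_scores)
        rec["omission_threshold"] = thr
        if n_test > 0:
            test_scores = model.logistic(samples.presence_values[test_idx])
            max_tss, tss_thr, omission = tss_and_omission(
                test_scores, bg_scores, omission_threshold=thr
            )
            rec.update(
                test_auc=auc(test_scores, bg_scores),
                test_omission=omission,
                max_tss=max_tss,
                tss_threshold=tss_thr,
            )
        else:
            rec.update(test_auc=np.nan, test_omission=np.nan, max_tss=np.nan,
                       tss_threshold=np.nan)
        rows.append(rec)
        if stack is not None:
            maps.append(predict(model, stack, transform="logistic"))
        if keep_models:
            models.append(model)
    averaged = None
    if maps:
        tmpl = maps[0].grid
        mean_vals = np.mean([mp.grid.values for mp in maps], axis=0)
        averaged = SuitabilityMap(
            grid=tmpl.like(mean_vals, nodata_mask=tmpl.mask),
            transform="logistic",
            scenario=stack.label if stack is not None else "",
        )
    return EvalReport(
        records=pd.DataFrame(rows),
        n_replicates=n_replicates,
        split_fraction=1.0 - test_fraction,
        averaged_map=averaged,
        models=models,
    )


@dataclass
class ImportanceTable:
    """Per-variable contribution/permutation percentages and jackknife gains."""

    table: pd.DataFrame  # index: variable; columns incl. percent_contribution, ...

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def percent_contribution(model: MaxEntModel) -> dict[str, float]:
    """Percent contribution from the fit's per-variable gain credits,
    rescaled to sum to 100."""
    if model.contributions is None:
        raise ValueError("fit was run without contribution tracking")
    credits = model.contributions
    total = sum(credits.values())
    if total <= 0:
        return {v: 0.0 for v in credits}
    return {v: 100.0 * c / total for v, c in credits.items()}


def permutation_importance(
    model: MaxEntModel, samples: SampleMatrix, seed: int | None = None
) -> dict[str, float]:
    """Shuffle each variable's column (presence + background rows jointly),
    measure the training-AUC drop, and normalise the non-negative drops to
    sum to 100."""
    rng = np.random.default_rng(seed)
    pres = samples.is_presence
    base_scores = model.logistic(samples.values)
    base_auc = auc(base_scores[pres], base_scores[~pres])
    drops = {}
    for j, name in enumerate(samples.variable_names):
        perm_vals = samples.values.copy()
        perm_vals[:, j] = rng.permutation(perm_vals[:, j])
        s = model.logistic(perm_vals)
        drops[name] = max(0.0, base_auc - auc(s[pres], s[~pres]))
    total = sum(drops.values())
    if total <= 0:
        return {v: 0.0 for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


def jackknife_gains(
    samples: SampleMatrix,
    features: FeatureSet,
    rm: float = 1.0,
    variables: Sequence[str] | None = None,
    max_iterations: int = 2000,
    tolerance: float = 1e-5,
) -> dict[str, tuple[float, float, float]]:
    """Training gain with only / without each variable, next to the full
    gain."""
    names = list(variables) if variables is not None else list(samples.variable_names)
    if len(samples.variable_names) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    full = fit_maxent(
        samples, features, rm=rm, max_iterations=max_iterations, tolerance=tolerance
    ).training_gain
    out = {}
    for name in names:
        v = samples.variable_names.index(name)
        only_fs = features.subset(features.indices_with_only(v))
        without_fs = features.subset(features.indices_without(v))
        g_only = (
            fit_maxent(samples, only_fs, rm=rm, max_iterations=max_iterations,
                       tolerance=tolerance).training_gain
            if only_fs.n_features
            else 0.0
        )
        g_without = (
            fit_maxent(samples, without_fs, rm=rm, max_iterations=max_iterations,
                       tolerance=tolerance).training_gain
            if without_fs.n_features
            else 0.0
        )
        out[name] = (g_only, g_without, full)
    return out


def importance_table(
    contribution: dict[str, float],
    permutation: dict[str, float],
    jackknife: dict[str, tuple[float, float, float]] | None = None,
) -> ImportanceTable:
    names = sorted(contribution, key=lambda v: -contribution[v])
    df = pd.DataFrame(
        {
            "percent_contribution": [contribution[v] for v in names],
            "permutation_importance": [permutation.get(v, 0.0) for v in names],
        },
        index=pd.Index(names, name="variable"),
    )
    if jackknife is not None:
        df["gain_with_only"] = [jackknife.get(v, (np.nan,) * 3)[0] for v in names]
        df["gain_without"] = [jackknife.get(v, (np.nan,) * 3)[1] for v in names]
        df["gain_full"] = [jackknife.get(v, (np.nan,) * 3)[2] for v in names]
    return ImportanceTable(table=df)


def response_curve(
    model: MaxEntModel,
    samples: SampleMatrix,
    variable: str,
    n_points: int = 101,
) -> pd.DataFrame:
    """Marginal response: sweep one variable across its training range with
    the others fixed at their presence means; returns (value, logistic)."""
    if variable not in model.feature_set.variable_names:
        raise KeyError(f"variable {variable!r} not in model")
    j = model.feature_set.variable_names.index(variable)
    lo, hi = model.feature_set.var_min[j], model.feature_set.var_max[j]
    sweep = np.linspace(lo, hi, n_points)
    base = samples.presence_values.mean(axis=0)
    X = np.tile(base, (n_points, 1))
    X[:, j] = sweep
    return pd.DataFrame({"value": sweep, "logistic": model.logistic(X)})
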