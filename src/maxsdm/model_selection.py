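"""Candidate-model tuning: regularization-multiplier × feature-class grid,
AICc scoring over the landscape, and rule-based selection."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .grid_io import EnvGridStack
from .maxent_core import MaxEntModel, build_features, fit_maxent, predict
from .preprocess import SampleMatrix
from .evaluation import evaluate_replicates

__all__ = [
    "CandidateRecord",
    "candidate_grid",
    "aicc",
    "aicc_formula",
    "evaluate_candidates",
    "select_model",
    "candidate_table",
]

log = logging.getLogger(__name__)

#: canonical ordering of feature-class letters in combination labels
CLASS_ORDER = "LQHPT"


@dataclass
class CandidateRecord:
    """Diagnostics for one tuning-grid cell."""

    feature_classes: str
    rm: float
    aicc: float = float("nan")
    delta_aicc: float = float("nan")
    mean_test_omission: float = float("nan")
    mean_test_auc: float = float("nan")
    se_test_auc: float = float("nan")
    n_nonzero: int = 0
    significant: bool = False
    relaxed_selection: bool = False


def candidate_grid(
    rm_min: float = 0.1,
    rm_max: float = 4.0,
    rm_step: float = 0.1,
    classes: Sequence[str] = ("L", "Q", "H", "P", "T"),
) -> list[tuple[str, float]]:
    """Cartesian product of decimal-exact RM values and every nonempty
    feature-class combination (canonically ordered)."""
    if rm_step <= 0:
        raise ValueError("rm_step must be > 0")
    classes = list(dict.fromkeys(c.upper() for c in classes))
    if not classes:
        raise ValueError("class set must be nonempty")
    n = int(round((rm_max - rm_min) / rm_step)) + 1
    rms = [round(rm_min + k * rm_step, 10) for k in range(n)]
    rms = [r for r in rms if r <= rm_max + 1e-12]
    ordered = sorted(classes, key=lambda c: CLASS_ORDER.index(c) if c in CLASS_ORDER else 99)
    combos = []
    for k in range(1, len(ordered) + 1):
        for subset in itertools.combinations(ordered, k):
            combos.append("".join(subset))
    return [(combo, rm) for combo in combos for rm in rms]


def aicc_formula(k: int, ln_l: float, n: int) -> float:
    """AICc = 2k − 2 ln L + 2k(k+1)/(n − k − 1); +inf when the correction
    denominator is non-positive."""
    if n - k - 1 <= 0:
        return float("inf")
    return float(2 * k - 2 * ln_l + 2 * k * (k + 1) / (n - k - 1))


def aicc(
    model: MaxEntModel,
    presence_coords: np.ndarray,
    stack: EnvGridStack,
) -> float:
    """Small-sample-corrected AIC of the presence likelihood.

    The raw output is renormalised to sum to 1 over all valid landscape
    cells; ln L sums the log-probability of the cell containing each
    presence; k = number of nonzero coefficients.  Returns +inf when
    ``n − k − 1 <= 0`` or any presence falls on a zero-probability cell.
    """
    pts = np.atleast_2d(np.asarray(presence_coords, dtype=float))
    n = pts.shape[0]
    k = model.n_nonzero
    if n - k - 1 <= 0:
        return float("inf")
    raw_map = predict(model, stack, transform="raw")
    m = raw_map.valid_mask
    raw = raw_map.values[m]
    total = raw.sum()
    if total <= 0:
        return float("inf")
    p = np.zeros_like(raw_map.values)
    p[m] = raw / total
    tmpl = stack.template
    lnl = 0.0
    for x, y in pts:
        rc = tmpl.cell_of(x, y)
        if rc is None or not m[rc]:
            return float("inf")
        pi = p[rc]
        if pi <= 0:
            return float("inf")
        lnl += np.log(pi)
    return aicc_formula(k, lnl, n)


def evaluate_candidates(
    samples: SampleMatrix,
    stack: EnvGridStack,
    grid: Sequence[tuple[str, float]],
    n_replicates: int = 3,
    test_fraction: float = 0.25,
    seed: int | None = None,
    knots_per_variable: int = 10,
    max_iterations: int = 500,
    tolerance: float = 1e-4,
) -> list[CandidateRecord]:
    """Score every (feature-class combo, RM) candidate.

    Each candidate gets a reduced replicate evaluation (omission, AUC) and
    a full-data fit for AICc; delta AICc is filled in afterwards.  The
    replicate seed is shared so candidates see identical splits.
    """
    feature_cache: dict[str, object] = {}
    records: list[CandidateRecord] = []
    pres_coords = samples.coords[samples.is_presence]
    for i, (combo, rm) in enumerate(grid):
        if combo not in feature_cache:
            feature_cache[combo] = build_features(
                samples, classes=tuple(combo), knots_per_variable=knots_per_variable
            )
        feats = feature_cache[combo]
        rep = evaluate_replicates(
            samples,
            feats,
            rm=rm,
            n_replicates=n_replicates,
            test_fraction=test_fraction,
            seed=seed,
            max_iterations=max_iterations,
            tolerance=tolerance,
        )
        full = fit_maxent(
            samples, feats, rm=rm, max_iterations=max_iterations, tolerance=tolerance
        )
        a = aicc(full, pres_coords, stack)
        mean_auc = float(rep.records["test_auc"].mean())
        sd_auc = float(rep.records["test_auc"].std(ddof=1)) if n_replicates > 1 else 0.0
        se_auc = sd_auc / np.sqrt(n_replicates) if n_replicates > 1 else float("nan")
        significant = bool(
            n_replicates > 1 and np.isfinite(se_auc) and mean_auc - 2 * se_auc > 0.5
        )
        records.append(
            CandidateRecord(
                feature_classes=combo,
                rm=rm,
                aicc=a,
                mean_test_omission=float(rep.records["test_omission"].mean()),
                mean_test_auc=mean_auc,
                se_test_auc=se_auc,
                n_nonzero=full.n_nonzero,
                significant=significant,
            )
        )
        if (i + 1) % 25 == 0:
            log.info("scored %d/%d candidates", i + 1, len(grid))
    _fill_delta(records)
    return records


def _fill_delta(records: list[CandidateRecord]) -> None:
    finite = [r.aicc for r in records if np.isfinite(r.aicc)]
    if not finite:
        return
    best = min(finite)
    for r in records:
        r.delta_aicc = r.aicc - best if np.isfinite(r.aicc) else float("inf")


def select_model(candidates: Sequence[CandidateRecord]) -> CandidateRecord:
    """Pick the winner under the omission (<5%) and delta-AICc (<=2) rules.

    Eligible candidates have mean test omission < 0.05 and delta AICc <= 2;
    the winner is the eligible candidate with the smallest AICc, ties broken
    by smaller omission, fewer nonzero coefficients, lexicographic class
    label, then smaller RM.  If nothing is eligible the omission rule is
    relaxed and the returned record is flagged.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("no candidates")
    if not any(np.isfinite(c.aicc) for c in cands):
        raise ValueError("all candidate AICc values are infinite")
    if any(not np.isfinite(c.delta_aicc) and np.isfinite(c.aicc) for c in cands):
        _fill_delta(cands)

    def sort_key(c: CandidateRecord):
        return (c.aicc, c.mean_test_omission, c.n_nonzero, c.feature_classes, c.rm)

    eligible = [
        c
        for c in cands
        if np.isfinite(c.aicc) and c.mean_test_omission < 0.05 and c.delta_aicc <= 2.0
    ]
    if eligible:
        return min(eligible, key=sort_key)
    fallback = [c for c in cands if np.isfinite(c.aicc) and c.delta_aicc <= 2.0]
    winner = min(fallback, key=sort_key)
    return replace(winner, relaxed_selection=True)


def candidate_table(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_classes": r.feature_classes,
                "rm": r.rm,
                "aicc": r.aicc,
                "delta_aicc": r.delta_aicc,
                "mean_test_omission": r.mean_test_omission,
                "mean_test_auc": r.mean_test_auc,
                "se_test_auc": r.se_test_auc,
                "n_nonzero": r.n_nonzero,
                "significant": r.significant,
            }
            for r in records
        ]
    )
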