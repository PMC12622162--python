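"""Score-set evaluation against labeled datasets and continuous assay scores.

Classification is summarized by AUC (Mann-Whitney formulation, ties count
half) and accuracy at a threshold; agreement with continuous assay
measurements by the R^2 of a penalized-spline smooth of assay score on
predictor score, with tool-study pairs under 10 shared variants excluded.
Per-tool circularity masking is applied before any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .circularity import ClosureMap
from .dataset import AssayStudy

#: Sentinel for tool-study pairs with too few shared variants to evaluate.
EXCLUDED = "EXCLUDED"

MIN_PAIRS = 10


@dataclass(frozen=True)
class BenchmarkResult:
    tool_id: str
    dataset_id: str
    n_used: int
    metric: str
    value: float
    circular_masked: int = 0
    missing_scores: int = 0


def auc(scores, labels) -> float:
    """Area under the ROC curve; tied scores contribute 0.5 per pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes are required to compute AUC")
    return float(roc_auc_score(labels, scores))


def smooth_r2(predictor_scores, assay_scores, min_pairs: int = MIN_PAIRS):
    """R^2 of a penalized-spline regression of assay score on predictor score.

    Smoothness is selected by generalized cross-validation. Returns the
    EXCLUDED sentinel when fewer than ``min_pairs`` pairs are available;
    zero-variance assay scores define R^2 = 0.
    """
    x = np.asarray(predictor_scores, dtype=float)
    y = np.asarray(assay_scores, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_pairs:
        return EXCLUDED
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0 or np.ptp(x) == 0.0:
        return 0.0
    fitted = _pspline_fit(x, y)
    ss_res = float(np.sum((y - fitted) ** 2))
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def _pspline_fit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gaussian GAM fit with GCV-selected penalty on a B-spline basis."""
    from statsmodels.gam.api import BSplines, GLMGam
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    df = int(np.clip(len(x) // 5, 4, 10))
    # jitter breaks exact knot ties when x has heavy duplication
    basis = BSplines(x[:, None], df=[df], degree=[3], include_intercept=False)
    gam = GLMGam(y, exog=np.ones((len(y), 1)), smoother=basis, alpha=[1.0])
    try:
        gam.fit()  # sets the scale select_penweight needs
        best_alpha = gam.select_penweight(criterion="gcv")[0]
        res = GLMGam(
            y, exog=np.ones((len(y), 1)), smoother=basis, alpha=best_alpha
        ).fit()
        return np.asarray(res.fittedvalues)
    except (np.linalg.LinAlgError, ValueError, PerfectSeparationError):
        # degenerate design (e.g. an exact relation): fall back to a line
        coef = np.polyfit(x, y, 1)
        return np.polyval(coef, x)


def accuracy_at_threshold(scores, labels, threshold: float) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    return float(np.mean((scores >= threshold).astype(int) == labels))


def evaluate_tool(
    tool_id: str,
    scores: dict,
    labels: dict,
    closure: ClosureMap | None = None,
    dataset_id: str = "dataset",
) -> BenchmarkResult:
    """AUC of one tool on a labeled dataset with circularity-aware exclusions.

    Variants in the tool's effective training set are masked first; variants
    without a score are counted as missing. n_used + exclusions equals the
    dataset size.
    """
    effective = closure.get(tool_id, frozenset()) if closure else frozenset()
    keys = sorted(labels)
    used_scores, used_labels = [], []
    circular = missing = 0
    for k in keys:
        if k in effective:
            circular += 1
            continue
        s = scores.get(k)
        if s is None or not np.isfinite(s):
            missing += 1
            continue
        used_scores.append(s)
        used_labels.append(labels[k])
    value = auc(used_scores, used_labels)
    return BenchmarkResult(
        tool_id=tool_id,
        dataset_id=dataset_id,
        n_used=len(used_scores),
        metric="auc",
        value=value,
        circular_masked=circular,
        missing_scores=missing,
    )


def mave_benchmark(
    tools: dict,
    studies: list[AssayStudy],
    closure: ClosureMap | None = None,
    min_pairs: int = MIN_PAIRS,
):
    """Mean smooth-fit R^2 per tool across assay studies.

    For each tool, circular variants are masked, R^2 is computed per study,
    EXCLUDED studies are dropped from the mean, and a tool with zero eligible
    studies is reported as not evaluable (NaN mean).

    Returns (per-tool DataFrame, per-study long DataFrame).
    """
    study_rows = []
    tool_rows = []
    for tool_id in sorted(tools):
        tool_scores = tools[tool_id]
        effective = closure.get(tool_id, frozenset()) if closure else frozenset()
        r2s = []
        for study in studies:
            shared = sorted(
                k for k in study.scores if k in tool_scores and k not in effective
            )
            r2 = smooth_r2(
                [tool_scores[k] for k in shared],
                [study.scores[k] for k in shared],
                min_pairs=min_pairs,
            )
            study_rows.append(
                {
                    "tool_id": tool_id,
                    "study_id": study.study_id,
                    "n_pairs": len(shared),
                    "r2": np.nan if r2 == EXCLUDED else r2,
                    "excluded": r2 == EXCLUDED,
                }
            )
            if r2 != EXCLUDED:
                r2s.append(r2)
        tool_rows.append(
            {
                "tool_id": tool_id,
                "n_studies": len(r2s),
                "mean_r2": float(np.mean(r2s)) if r2s else np.nan,
                "evaluable": bool(r2s),
            }
        )
    return pd.DataFrame(tool_rows), pd.DataFrame(study_rows)
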