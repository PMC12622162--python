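"""ACMG PP3/BP4 evidence calibration and point-based classification.

Continuous predictor scores become clinical evidence by estimating, in sliding
windows over the score axis, the local probability that a variant is
pathogenic, converting it to a likelihood ratio against a fixed prior
(default 10%), monotonizing with isotonic regression, and mapping LR intervals
to evidence strengths. With an LR ceiling of 350 (the odds-of-pathogenicity
scale), supporting/moderate/strong correspond to the 1/8, 1/4 and 1/2 powers
of the ceiling, and benign-side cutoffs are their reciprocals. Evidence items
combine additively on the standard points scale (supporting 1, moderate 2,
strong 4, very strong 8; benign negative) into P/LP/VUS/LB/B classes, with
the uncertain band subdivided into VUS-high/mid/low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from sklearn.isotonic import IsotonicRegression

stats_norm_ppf = _norm.ppf

STRENGTHS = ("supporting", "moderate", "strong", "very_strong")
EVIDENCE_LEVELS = (
    "BP4_strong",
    "BP4_moderate",
    "BP4_supporting",
    "none",
    "PP3_supporting",
    "PP3_moderate",
    "PP3_strong",
)


def posterior_from_lr(prior: float, lr: float) -> float:
    """Posterior pathogenicity probability from prior and likelihood ratio."""
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    return lr * prior / (lr * prior + (1 - prior))


def strength_cutoffs(lr_ceiling: float = 350.0) -> dict:
    """LR cutoffs per evidence strength.

    Pathogenic side: supporting = ceiling^(1/8), moderate = ceiling^(1/4),
    strong = ceiling^(1/2); benign-side cutoffs are the reciprocals.
    """
    if lr_ceiling <= 1:
        raise ValueError("lr_ceiling must exceed 1")
    path = {
        "supporting": lr_ceiling ** 0.125,
        "moderate": lr_ceiling ** 0.25,
        "strong": lr_ceiling ** 0.5,
    }
    benign = {k: 1.0 / v for k, v in path.items()}
    return {"pathogenic": path, "benign": benign}


@dataclass
class ScoreInterval:
    low: float
    high: float
    local_ppv: float
    local_npv: float
    lr: float
    evidence: str


@dataclass
class CalibrationTable:
    """Ordered score intervals with local PPV/NPV, LR and evidence strength."""

    prior: float
    lr_ceiling: float
    intervals: list[ScoreInterval] = field(default_factory=list)

    def __post_init__(self):
        lrs = [iv.lr for iv in self.intervals]
        if any(b < a - 1e-12 for a, b in zip(lrs, lrs[1:])):
            raise ValueError("interval LRs must be monotone non-decreasing in score")

    def lr_at(self, score: float) -> float:
        return self._lookup(score).lr

    def _lookup(self, score: float) -> ScoreInterval:
        if not self.intervals:
            raise ValueError("empty calibration table")
        if score <= self.intervals[0].high:
            return self.intervals[0]
        for iv in self.intervals:
            if iv.low <= score <= iv.high:
                return iv
        return self.intervals[-1]  # clamp above the fitted range

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "low": [iv.low for iv in self.intervals],
                "high": [iv.high for iv in self.intervals],
                "local_ppv": [iv.local_ppv for iv in self.intervals],
                "local_npv": [iv.local_npv for iv in self.intervals],
                "lr": [iv.lr for iv in self.intervals],
                "evidence": [iv.evidence for iv in self.intervals],
            }
        )

    def save(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "prior", self.prior)
        df.insert(1, "lr_ceiling", self.lr_ceiling)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def load(cls, path) -> "CalibrationTable":
        df = pd.read_csv(path, sep="\t")
        intervals = [
            ScoreInterval(
                low=row.low,
                high=row.high,
                local_ppv=row.local_ppv,
                local_npv=row.local_npv,
                lr=row.lr,
                evidence=row.evidence,
            )
            for row in df.itertuples(index=False)
        ]
        return cls(
            prior=float(df["prior"].iloc[0]),
            lr_ceiling=float(df["lr_ceiling"].iloc[0]),
            intervals=intervals,
        )


def _evidence_for_lr(lr: float, cutoffs: dict) -> str:
    p, b = cutoffs["pathogenic"], cutoffs["benign"]
    if lr >= p["strong"]:
        return "PP3_strong"
    if lr >= p["moderate"]:
        return "PP3_moderate"
    if lr >= p["supporting"]:
        return "PP3_supporting"
    if lr <= b["strong"]:
        return "BP4_strong"
    if lr <= b["moderate"]:
        return "BP4_moderate"
    if lr <= b["supporting"]:
        return "BP4_supporting"
    return "none"


def fit_calibration(
    scores,
    labels,
    prior: float = 0.1,
    window_min: int = 100,
    lr_ceiling: float = 350.0,
    n_windows: int = 200,
) -> CalibrationTable:
    """Estimate local likelihood ratios across score intervals.

    Sliding windows over the sorted scores each hold at least ``window_min``
    calibration variants. The within-window positive/negative count ratio,
    rescaled by the global class ratio, estimates the local likelihood ratio
    (equivalently: empirical odds reweighted to the target prior, divided by
    the prior odds). The raw per-window log-LRs are smoothed with a
    local-linear (lowess) pass to remove window noise, then isotonic
    regression enforces that evidence strength never oscillates with score,
    and intervals between window centers are assigned PP3/BP4 strengths via
    `strength_cutoffs`. Rank-based windowing makes the fit invariant to
    strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    if n != len(labels):
        raise ValueError("scores and labels must align")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are required for calibration")
    if n < 2 * window_min:
        raise ValueError(f"need at least {2 * window_min} variants, got {n}")

    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]

    half = max(window_min, n // 25) // 2
    centers = np.unique(
        np.clip(np.linspace(half, n - 1 - half, num=min(n_windows, n)).astype(int), half, n - 1 - half)
    )
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])

    center_scores = s_sorted[centers]
    raw_lr = np.empty(len(centers))
    # LR ~ (window positives / total positives) / (window negatives / total negatives),
    # i.e. a density-ratio estimate; a half-count guards empty cells.
    for i, c in enumerate(centers):
        lo, hi = c - half, c + half + 1
        wp = cum_pos[hi] - cum_pos[lo]
        wn = (hi - lo) - wp
        raw_lr[i] = ((wp + 0.5) / (n_pos + 0.5)) / ((wn + 0.5) / (n_neg + 0.5))

    log_lr = np.log(raw_lr)
    # smoothing axis: normal quantile of the window's rank position. Depending
    # on ranks only keeps the whole fit invariant to strictly monotone
    # transforms of the scores, while decompressing the tails so local-linear
    # smoothing tracks steep tail likelihood ratios.
    z_axis = stats_norm_ppf((centers + 0.5) / n)
    if len(centers) >= 5:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        log_lr = lowess(log_lr, z_axis, frac=0.5, return_sorted=False)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    lr_fit = np.exp(iso.fit_transform(z_axis, log_lr))
    lr_fit = np.clip(lr_fit, 1.0 / lr_ceiling, lr_ceiling)

    cutoffs = strength_cutoffs(lr_ceiling)
    prior_odds = prior / (1 - prior)
    bounds = np.concatenate(
        [[-np.inf], (center_scores[:-1] + center_scores[1:]) / 2.0, [np.inf]]
    )
    intervals = []
    for i in range(len(centers)):
        post_odds = lr_fit[i] * prior_odds
        ppv = post_odds / (1 + post_odds)
        intervals.append(
            ScoreInterval(
                low=float(bounds[i]),
                high=float(bounds[i + 1]),
                local_ppv=float(ppv),
                local_npv=float(1 - ppv),
                lr=float(lr_fit[i]),
                evidence=_evidence_for_lr(float(lr_fit[i]), cutoffs),
            )
        )
    return CalibrationTable(prior=prior, lr_ceiling=lr_ceiling, intervals=intervals)


def assign_evidence(score: float, table: CalibrationTable):
    """(code, strength) for a score, or None when the interval is uninformative.

    Scores outside the fitted range clamp to the nearest interval.
    """
    ev = table._lookup(float(score)).evidence
    if ev == "none":
        return None
    code, strength = ev.split("_", 1)
    return code, strength


POINTS = {"supporting": 1, "moderate": 2, "strong": 4, "very_strong": 8}
_BENIGN_CODES = ("BP4", "BS1", "BS2", "BS3", "BS4", "BP1", "BP2", "BP3", "BP5", "BP7", "BA1")


@dataclass(frozen=True)
class EvidenceProfile:
    """Per-variant set of (criterion code, strength) evidence items."""

    variant_key: str
    criteria: frozenset  # of (code, strength) pairs

    def __post_init__(self):
        codes = [c for c, _ in self.criteria]
        if "PP3" in codes and "BP4" in codes:
            raise ValueError(
                f"{self.variant_key}: PP3 and BP4 are mutually exclusive"
            )
        for code, strength in self.criteria:
            if strength not in POINTS:
                raise ValueError(f"unknown strength {strength!r}")


ACMG_CLASSES = ("P", "LP", "VUS_high", "VUS_mid", "VUS_low", "LB", "B")


@dataclass(frozen=True)
class AcmgClass:
    points: int
    label: str


def combine_points(profile: EvidenceProfile) -> AcmgClass:
    """Sum evidence points and band them into a class.

    Pathogenic evidence adds points, benign evidence subtracts them. Bands:
    P >= 10, LP 6..9, VUS 0..5 (high 4..5, mid 2..3, low 0..1), LB -6..-1,
    B <= -7. Summation is order-free, so the result is permutation-invariant
    in the criteria set.
    """
    points = 0
    for code, strength in profile.criteria:
        value = POINTS[strength]
        points += -value if code in _BENIGN_CODES else value
    return AcmgClass(points=points, label=class_from_points(points))


def class_from_points(points: int) -> str:
    if points >= 10:
        return "P"
    if points >= 6:
        return "LP"
    if points >= 4:
        return "VUS_high"
    if points >= 2:
        return "VUS_mid"
    if points >= 0:
        return "VUS_low"
    if points >= -6:
        return "LB"
    return "B"


def classification_metrics(classes, labels, vus_high_pathogenic: bool = False) -> dict:
    """Concordance, conclusiveness, and sensitivity/specificity.

    Concordance is the fraction of all variants whose class agrees in sign
    with the truth label: P/LP (plus VUS_high when ``vus_high_pathogenic``)
    count as pathogenic calls, B/LB as benign calls, and remaining VUS bands
    count against concordance. Conclusiveness is 1 minus the VUS_mid fraction.
    Sensitivity and specificity are computed over the definitive (non-VUS)
    calls only.
    """
    classes = list(classes)
    labels = np.asarray(labels, dtype=int)
    if len(classes) != len(labels):
        raise ValueError("classes and labels must align")
    n = len(classes)
    if n == 0:
        raise ValueError("empty inputs")

    path_calls = {"P", "LP"} | ({"VUS_high"} if vus_high_pathogenic else set())
    benign_calls = {"B", "LB"}
    concordant = sum(
        1
        for c, y in zip(classes, labels)
        if (c in path_calls and y == 1) or (c in benign_calls and y == 0)
    )
    vus_mid = sum(1 for c in classes if c == "VUS_mid")

    tp = fn = tn = fp = 0
    for c, y in zip(classes, labels):
        definitive_path = c in path_calls
        definitive_benign = c in benign_calls
        if not (definitive_path or definitive_benign):
            continue
        if y == 1:
            tp += definitive_path
            fn += definitive_benign
        else:
            tn += definitive_benign
            fp += definitive_path
    return {
        "concordance": concordant / n,
        "conclusiveness": 1.0 - vus_mid / n,
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }
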