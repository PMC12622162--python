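"""Protein-language-model-derived features and informative-missingness repair.

PLM features quantify how a substitution perturbs sequence plausibility under
a protein language model: the drop in mean log-likelihood, the rise in
perplexity, the shift of the mean embedding, and the log-likelihood change at
the mutated site itself. The statistics come from an abstract provider so the
pipeline is testable without a model checkpoint.

Features whose missingness depends on the class label ("informative
missingness") would leak labels through the missing pattern; they are detected
with a two-proportion test and filled by gradient-boosted regressors trained
on unlabeled background variants only, preserving natural score distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

from .core_io import FeatureMatrix


@dataclass(frozen=True)
class SequenceStats:
    """Per-position natural-log likelihoods and a mean embedding vector."""

    log_likelihoods: tuple
    mean_embedding: tuple

    def __post_init__(self):
        ll = np.asarray(self.log_likelihoods, dtype=float)
        if not np.all(np.isfinite(ll)):
            raise ValueError("log-likelihoods must be finite")


@dataclass(frozen=True)
class PlmFeatures:
    mean_loglik_diff: float
    perplexity_diff: float
    embedding_shift: float
    site_loglik_diff: float


def perplexity(stats: SequenceStats) -> float:
    """exp(-mean per-position log-likelihood)."""
    return float(np.exp(-np.mean(stats.log_likelihoods)))


def plm_feature_set(wt: SequenceStats, mut: SequenceStats, site: int) -> PlmFeatures:
    """Compute the four PLM metrics for one substitution.

    ``site`` is the 0-based mutated position. Difference features are signed
    wild-type minus mutant for log-likelihoods (positive = mutant less
    plausible) and mutant minus wild-type for perplexity (positive = mutant
    more surprising), so that larger values consistently indicate damage.
    """
    wt_ll = np.asarray(wt.log_likelihoods, dtype=float)
    mut_ll = np.asarray(mut.log_likelihoods, dtype=float)
    if wt_ll.shape != mut_ll.shape:
        raise ValueError(
            f"sequence length mismatch: wild-type {wt_ll.shape[0]}, mutant {mut_ll.shape[0]}"
        )
    if not 0 <= site < wt_ll.shape[0]:
        raise ValueError(f"site {site} outside sequence of length {wt_ll.shape[0]}")
    wt_emb = np.asarray(wt.mean_embedding, dtype=float)
    mut_emb = np.asarray(mut.mean_embedding, dtype=float)
    if wt_emb.shape != mut_emb.shape:
        raise ValueError("embedding dimension mismatch")
    return PlmFeatures(
        mean_loglik_diff=float(np.mean(wt_ll) - np.mean(mut_ll)),
        perplexity_diff=perplexity(mut) - perplexity(wt),
        embedding_shift=float(np.linalg.norm(wt_emb - mut_emb)),
        site_loglik_diff=float(wt_ll[site] - mut_ll[site]),
    )


def flag_biased_missingness(
    matrix: FeatureMatrix, labels, alpha: float = 0.01
) -> list[str]:
    """Names of features whose missingness rate differs between classes.

    A feature is flagged when the two-proportion z-test of its per-class
    missingness rates gives p < alpha; a fully missing feature is flagged
    unconditionally (no information to test, nothing to train on either).
    Fully observed features are never flagged.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != len(matrix.variants):
        raise ValueError("labels must align with matrix rows")
    mask = matrix.missing_mask
    flagged = []
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    for j, feat in enumerate(matrix.features):
        col_missing = mask[:, j]
        if col_missing.all():
            flagged.append(feat.name)
            continue
        if not col_missing.any():
            continue
        m1 = int(np.sum(col_missing & (labels == 1)))
        m0 = int(np.sum(col_missing & (labels == 0)))
        if n1 == 0 or n0 == 0:
            continue
        _, p = proportions_ztest([m1, m0], [n1, n0])
        if np.isfinite(p) and p < alpha:
            flagged.append(feat.name)
    return flagged


def impute_features(
    matrix: FeatureMatrix,
    flagged,
    background: FeatureMatrix,
    seed: int = 0,
) -> FeatureMatrix:
    """Fill missing cells of flagged features with gradient-boosted regressors.

    For each flagged feature a LightGBM regressor is trained on the background
    rows where the feature is observed, using all other features as predictors
    (trees route missing predictor values natively). Labels never enter; only
    the unlabeled background does. Observed cells are never altered, and
    imputed cells are recorded in the matrix's provenance.
    """
    import lightgbm as lgb

    names = matrix.feature_names
    bg_names = background.feature_names
    for name in flagged:
        if name not in names:
            raise KeyError(f"flagged feature {name!r} absent from the matrix catalog")
        if name not in bg_names:
            raise KeyError(f"flagged feature {name!r} absent from the background catalog")

    out = matrix.copy()
    if not out.missing_mask.any():
        return out

    for name in flagged:
        j = names.index(name)
        to_fill = np.where(np.isnan(out.values[:, j]))[0]
        if to_fill.size == 0:
            continue
        bj = bg_names.index(name)
        observed = ~np.isnan(background.values[:, bj])
        if not observed.any():
            raise ValueError(
                f"feature {name!r}: zero observed background rows, cannot impute"
            )
        import pandas as pd

        predictor_cols = [k for k, n in enumerate(bg_names) if n != name]
        predictor_names = [bg_names[k] for k in predictor_cols]
        x_train = pd.DataFrame(
            background.values[np.ix_(observed, predictor_cols)], columns=predictor_names
        )
        y_train = background.values[observed, bj]
        reg = lgb.LGBMRegressor(
            n_estimators=200,
            num_leaves=31,
            learning_rate=0.05,
            random_state=seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
        reg.fit(x_train, y_train)
        matrix_predictor_cols = [names.index(n) for n in predictor_names]
        x_fill = pd.DataFrame(
            out.values[np.ix_(to_fill, matrix_predictor_cols)], columns=predictor_names
        )
        out.values[to_fill, j] = reg.predict(x_fill)
        out.imputed.setdefault(name, []).extend(int(i) for i in to_fill)
    return out
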