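"""Balanced functional and clinical training-set construction.

Functional labels come from three heterogeneous sources — multiplexed assay
(MAVE-style) studies binarized after clinical calibration, literature-curated
annotations, and text-mined functional evidence — plus weakly-labeled
proxy-benign population variants down-weighted by normalized log allele
frequency. Clinical labels come from high-review-status archive records with
splice-confounded variants removed. Both datasets are balanced per gene so no
single gene's class skew dominates training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import LabeledVariant, Variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayStudy:
    """One multiplexed functional assay: per-variant scores for one gene."""

    study_id: str
    gene: str
    scores: dict  # variant key -> assay score
    orientation: str = "unknown"  # higher_is_damaging | lower_is_damaging | unknown

    def __post_init__(self):
        if len(self.scores) < 1:
            raise ValueError(f"study {self.study_id}: needs >= 1 scored variant")
        vals = np.asarray(list(self.scores.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"study {self.study_id}: scores must be finite")


@dataclass(frozen=True)
class CalibratedStudy:
    """An assay study after clinical calibration.

    ``accepted`` means the study separates pathogenic from benign overlap
    variants at the Bonferroni-corrected level and has enough overlap to
    binarize reliably.
    """

    study: AssayStudy
    auc_vs_clinical: float
    p_value: float
    accepted: bool
    binarization_threshold: float
    orientation: str = "unknown"
    rejection_reason: str | None = None


@dataclass
class LabeledDataset:
    """De-duplicated labeled variants with per-gene index."""

    records: list[LabeledVariant] = field(default_factory=list)

    def __post_init__(self):
        keys = [r.variant.key for r in self.records]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate variant keys in dataset: {dupes[:5]}")

    def __len__(self):
        return len(self.records)

    @property
    def gene_index(self) -> dict:
        idx: dict[str, list[int]] = {}
        for i, r in enumerate(self.records):
            idx.setdefault(r.variant.gene, []).append(i)
        return idx

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.sample_weight for r in self.records], dtype=float)

    @property
    def keys(self) -> list[str]:
        return [r.variant.key for r in self.records]


def calibrate_assay_study(
    study: AssayStudy,
    clinical_labels: dict,
    alpha: float = 0.05,
    n_studies: int = 1,
    min_overlap: int = 10,
) -> CalibratedStudy:
    """Calibrate one assay study against clinical labels.

    Orientation is auto-resolved (scores flipped when rank AUC < 0.5), the
    separation p-value comes from a one-sided Mann-Whitney rank-sum test, and
    acceptance requires p <= alpha / n_studies with at least ``min_overlap``
    labeled overlap variants. The binarization threshold maximizes balanced
    accuracy on the labeled overlap; ties break toward the midpoint of tying
    cuts. Being rank-based, the whole procedure is invariant to strictly
    monotone transforms of the assay scores.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")

    overlap = sorted(k for k in study.scores if k in clinical_labels)
    if len(overlap) < min_overlap:
        return CalibratedStudy(
            study=study,
            auc_vs_clinical=float("nan"),
            p_value=float("nan"),
            accepted=False,
            binarization_threshold=float("nan"),
            orientation=study.orientation,
            rejection_reason="insufficient_overlap",
        )

    scores = np.array([study.scores[k] for k in overlap], dtype=float)
    labels = np.array([clinical_labels[k] for k in overlap], dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return CalibratedStudy(
            study=study,
            auc_vs_clinical=float("nan"),
            p_value=float("nan"),
            accepted=False,
            binarization_threshold=float("nan"),
            orientation=study.orientation,
            rejection_reason="single_class_overlap",
        )

    auc = _rank_auc(pos, neg)
    orientation = "higher_is_damaging"
    if auc < 0.5:
        scores, pos, neg = -scores, -pos, -neg
        auc = 1.0 - auc
        orientation = "lower_is_damaging"

    p_value = float(stats.mannwhitneyu(pos, neg, alternative="greater").pvalue)
    accepted = p_value <= alpha / n_studies
    threshold = _balanced_accuracy_cut_midpoint(scores, labels)
    return CalibratedStudy(
        study=study,
        auc_vs_clinical=float(auc),
        p_value=p_value,
        accepted=accepted,
        binarization_threshold=threshold,
        orientation=orientation,
        rejection_reason=None if accepted else "below_performance_threshold",
    )


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _balanced_accuracy_cut_midpoint(scores: np.ndarray, labels: np.ndarray) -> float:
    """Balanced-accuracy-optimal cut; ties break to the midpoint of tying cuts."""
    order = np.argsort(scores, kind="mergesort")
    s, y = scores[order], labels[order]
    uniq = np.unique(s)
    if len(uniq) == 1:
        return float(uniq[0])
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    best_ba, best_cuts = -1.0, []
    for c in cuts:
        pred = s >= c
        tp = int(np.sum(pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        ba = 0.5 * (tp / n_pos + tn / n_neg)
        if ba > best_ba + 1e-12:
            best_ba, best_cuts = ba, [c]
        elif abs(ba - best_ba) <= 1e-12:
            best_cuts.append(c)
    return float((best_cuts[0] + best_cuts[-1]) / 2.0)


def compute_proxy_weights(allele_freqs) -> np.ndarray:
    """Min-max-normalized log10 allele frequency in [0, 1].

    w_i = (log10 AF_i - min_j log10 AF_j) / (max_j - min_j); an all-equal
    input degenerates to weight 1.0 everywhere.
    """
    afs = np.asarray(list(allele_freqs), dtype=float)
    if afs.size == 0:
        return np.array([])
    if np.any(afs <= 0) or np.any(afs >= 1):
        raise ValueError("allele frequencies must be in the open interval (0, 1)")
    logs = np.log10(afs)
    lo, hi = logs.min(), logs.max()
    if hi == lo:
        return np.ones_like(logs)
    return (logs - lo) / (hi - lo)


def exclude_splice_confounded(records, splice_scores: dict, cutoff: float = 0.2):
    """Drop records whose splice-disruption score is strictly above ``cutoff``.

    Records without a splice score are retained: absence of evidence for
    splice disruption is not treated as evidence of it.
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    kept = []
    for r in records:
        key = r.variant.key if isinstance(r, LabeledVariant) else r.key
        score = splice_scores.get(key)
        if score is not None and float(score) > cutoff:
            continue
        kept.append(r)
    return kept


def balance_per_gene(
    records, seed: int = 0, single_class_policy: str = "drop"
) -> LabeledDataset:
    """Down-sample the majority class to the minority count within each gene.

    Genes with a single class are dropped by default; ``keep_capped`` retains
    them capped at the median per-class size of the balanced genes (at least
    one record). Output order is deterministic for a fixed seed.
    """
    if single_class_policy not in ("drop", "keep_capped"):
        raise ValueError(f"unknown single_class_policy {single_class_policy!r}")
    if not records:
        return LabeledDataset([])

    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[LabeledVariant]] = {}
    for r in records:
        by_gene.setdefault(r.variant.gene, []).append(r)

    balanced_sizes = []
    two_class_out: dict[str, list[LabeledVariant]] = {}
    single_class_genes = []
    for gene in sorted(by_gene):
        recs = sorted(by_gene[gene], key=lambda r: r.variant.key)
        pos = [r for r in recs if r.label == 1]
        neg = [r for r in recs if r.label == 0]
        if pos and neg:
            n = min(len(pos), len(neg))
            balanced_sizes.append(n)
            if len(pos) > n:
                pos = [pos[i] for i in sorted(rng.choice(len(pos), n, replace=False))]
            if len(neg) > n:
                neg = [neg[i] for i in sorted(rng.choice(len(neg), n, replace=False))]
            two_class_out[gene] = sorted(pos + neg, key=lambda r: r.variant.key)
        else:
            single_class_genes.append(gene)

    out: list[LabeledVariant] = []
    cap = max(1, int(np.median(balanced_sizes))) if balanced_sizes else 1
    for gene in sorted(set(list(two_class_out) + single_class_genes)):
        if gene in two_class_out:
            out.extend(two_class_out[gene])
        elif single_class_policy == "keep_capped":
            recs = sorted(by_gene[gene], key=lambda r: r.variant.key)
            if len(recs) > cap:
                idx = sorted(rng.choice(len(recs), cap, replace=False))
                recs = [recs[i] for i in idx]
            out.extend(recs)
    return LabeledDataset(out)


def binarize_study(calibrated: CalibratedStudy) -> list[LabeledVariant]:
    """Turn an accepted calibrated study into labeled records.

    Scores are oriented so higher means more damaging, then cut at the
    study's balanced-accuracy threshold.
    """
    if not calibrated.accepted:
        raise ValueError(f"study {calibrated.study.study_id} was not accepted")
    flip = calibrated.orientation == "lower_is_damaging"
    records = []
    for key, raw in sorted(calibrated.study.scores.items()):
        score = -raw if flip else raw
        label = 1 if score >= calibrated.binarization_threshold else 0
        chrom, pos, ref, alt = key.split(":")
        records.append(
            LabeledVariant(
                variant=Variant(chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                                gene=calibrated.study.gene),
                label=label,
                source="mave",
            )
        )
    return records


_SOURCE_PRECEDENCE = ("curated", "mave", "text_mined")


def build_functional_dataset(
    mave: list[CalibratedStudy],
    curated: list[LabeledVariant],
    text_mined: list[LabeledVariant],
    proxy_benign: list[tuple[Variant, float]],
    seed: int = 0,
    single_class_policy: str = "drop",
) -> LabeledDataset:
    """Merge functional label sources into one balanced training set.

    Accepted assay studies are binarized at their calibrated thresholds.
    Sources merge with precedence curated > mave > text_mined: a variant takes
    its label from the highest-precedence source containing it, and variants
    with conflicting labels inside one precedence level are dropped.
    Proxy-benign population variants are excluded wherever a labeled source
    already covers the key, then attached with min-max-normalized log10-AF
    sample weights. Per-gene balancing is applied last.
    """
    mave_records: list[LabeledVariant] = []
    for cs in mave:
        if cs.accepted:
            mave_records.extend(binarize_study(cs))

    by_source = {"curated": curated, "mave": mave_records, "text_mined": text_mined}
    merged: dict[str, LabeledVariant] = {}
    for source in _SOURCE_PRECEDENCE:
        level: dict[str, LabeledVariant] = {}
        conflicted = set()
        for r in by_source[source]:
            k = r.variant.key
            if k in level and level[k].label != r.label:
                conflicted.add(k)
            level[k] = r
        for k in conflicted:
            del level[k]
        for k, r in level.items():
            if k not in merged:  # higher precedence already decided this key
                merged[k] = r

    labeled_keys = set(merged)
    proxy_kept = [(v, af) for v, af in proxy_benign if v.key not in labeled_keys]
    if proxy_kept:
        weights = compute_proxy_weights([af for _, af in proxy_kept])
        for (v, _af), w in zip(proxy_kept, weights):
            merged[v.key] = LabeledVariant(
                variant=v, label=0, source="proxy_benign", sample_weight=float(w)
            )

    records = [merged[k] for k in sorted(merged)]
    return balance_per_gene(records, seed=seed, single_class_policy=single_class_policy)


_CLASS_MAP = {
    "pathogenic": 1,
    "likely pathogenic": 1,
    "likely_pathogenic": 1,
    "benign": 0,
    "likely benign": 0,
    "likely_benign": 0,
}


def build_clinical_dataset(
    clinvar_records,
    splice_scores: dict,
    splice_cutoff: float = 0.2,
    min_stars: int = 2,
    seed: int = 0,
    single_class_policy: str = "drop",
) -> LabeledDataset:
    """Build the clinical training set from archive rows.

    Keeps rows with review status >= ``min_stars`` and a conclusive
    pathogenic / likely pathogenic / benign / likely benign class (collapsed
    to binary); rows with any other class string are skipped and counted.
    Splice-confounded variants (score > cutoff) are removed and per-gene
    balancing applied.

    ``clinvar_records`` is an iterable of (Variant, stars, class_string).
    """
    records = []
    skipped = 0
    for variant, stars, clin_class in clinvar_records:
        if int(stars) < min_stars:
            continue
        label = _CLASS_MAP.get(str(clin_class).strip().lower())
        if label is None:
            skipped += 1
            continue
        records.append(LabeledVariant(variant=variant, label=label, source="clinvar"))
    if skipped:
        logger.info("build_clinical_dataset: skipped %d rows with unknown class", skipped)
    records = exclude_splice_confounded(records, splice_scores, cutoff=splice_cutoff)
    return balance_per_gene(records, seed=seed, single_class_policy=single_class_policy)
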