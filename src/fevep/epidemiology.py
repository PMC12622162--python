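"""Gene-level genetic epidemiology under Hardy-Weinberg assumptions.

From the cumulative allele frequency (CAF) of a gene's qualifying variants,
carrier frequency (CrF, probability of carrying at least one allele) and
genetic prevalence (GP, frequency of an affected genotype) follow per
inheritance mode. X-linked GP uses the pooled-population formulas
GP_XLR = CAF(CAF+1)/2 and GP_XLD = (1-CAF)CAF + CAF(CAF+1)/2 (the male
hemizygote term contributes CAF/2 and the female genotype terms the rest,
assuming a 50/50 sex ratio). Penetrance is the Bayesian inversion
P(D|C) = P(D) P(C|D) / P(C). Variant masks aggregate qualifying variants for
burden-style association testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INHERITANCE_MODES = ("AD", "AR", "XLR", "XLD")


@dataclass(frozen=True)
class GeneEpiRecord:
    gene: str
    inheritance: str
    caf: float
    crf: float
    gp: float
    population_size: int = 0

    def __post_init__(self):
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def cumulative_allele_frequency(afs) -> float:
    """Sum of qualifying allele frequencies, clamped at 1.0 (with a warning)."""
    afs = np.asarray(list(afs), dtype=float)
    if afs.size == 0:
        return 0.0
    if np.any(afs < 0) or np.any(afs > 1):
        raise ValueError("allele frequencies must be in [0, 1]")
    total = float(afs.sum())
    if total > 1.0:
        logger.warning("cumulative allele frequency %.4g clamped to 1.0", total)
        return 1.0
    return total


def genetic_prevalence(caf: float, inheritance: str) -> float:
    """Affected-genotype frequency per inheritance mode."""
    if not 0 <= caf <= 1:
        raise ValueError("CAF must be in [0, 1]")
    if inheritance == "AR":
        return caf**2
    if inheritance == "AD":
        return 1 - (1 - caf) ** 2
    if inheritance == "XLR":
        return caf * (caf + 1) / 2
    if inheritance == "XLD":
        return (1 - caf) * caf + caf * (caf + 1) / 2
    raise ValueError(f"unknown inheritance mode {inheritance!r}")


def carrier_frequency(caf: float, inheritance: str) -> float:
    """Probability of carrying at least one qualifying allele.

    Autosomal: 1 - (1 - CAF)^2. X-linked (50/50 sex ratio): males carry with
    probability CAF (hemizygous), females with 1 - (1 - CAF)^2.
    """
    if not 0 <= caf <= 1:
        raise ValueError("CAF must be in [0, 1]")
    if inheritance in ("AD", "AR"):
        return 1 - (1 - caf) ** 2
    if inheritance in ("XLR", "XLD"):
        return 0.5 * caf + 0.5 * (1 - (1 - caf) ** 2)
    raise ValueError(f"unknown inheritance mode {inheritance!r}")


@dataclass(frozen=True)
class PenetranceInput:
    prevalence: float  # P(D)
    carrier_in_cases: float  # P(C|D)
    carrier_in_population: float  # P(C)

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 < self.carrier_in_cases <= 1:
            raise ValueError("P(C|D) must be in (0, 1]")
        if not 0 < self.carrier_in_population <= 1:
            raise ValueError("P(C) must be in (0, 1]")


def penetrance(inp: PenetranceInput) -> float:
    """P(D|C) = P(D) P(C|D) / P(C), clamped at 1 with a warning."""
    p = inp.prevalence * inp.carrier_in_cases / inp.carrier_in_population
    if p > 1.0:
        logger.warning("penetrance estimate %.4g clamped to 1.0 (noisy inputs)", p)
        return 1.0
    return p


def cohort_carriage(records) -> dict:
    """Cohort-level carriage under cross-gene independence.

    p_any_carrier = 1 - prod(1 - CrF_g); expected_genotypes = sum GP_g.
    """
    crfs = np.array([r.crf for r in records], dtype=float)
    gps = np.array([r.gp for r in records], dtype=float)
    p_any = 1.0 - float(np.prod(1.0 - crfs)) if len(crfs) else 0.0
    return {"p_any_carrier": p_any, "expected_genotypes": float(gps.sum())}


def rank_gp(target_gene_gp: float, comparator_gps) -> int:
    """Dense rank of the target among all genes by descending GP (1 = largest).

    Ties share the smaller rank.
    """
    comparators = list(comparator_gps)
    if not comparators:
        raise ValueError("comparator list must be non-empty")
    distinct_larger = len({g for g in comparators if g > target_gene_gp})
    return distinct_larger + 1


# ---------------------------------------------------------------------------
# PheWAS variant masks

AF_THRESHOLDS = ("0.5", "0.1", "0.01", "singleton")
PRED_DAMAGING_CUTOFF = 0.631  # CTE-model optimized decision threshold

MASK_NAMES = (
    "P",
    "P+LP",
    "P+LP+VUS-H",
    "P+LP+VUS-H+pred-D",
    "pred-D",
    "PVS1-VS",
    "PVS1-S",
    "PVS1-M",
    "PVS1-P",
    "PVS1-VS+S",
    "PVS1-VS+S+M",
    "PVS1-VS+S+M+P",
    "synonymous",
)

_REQUIRED_MASK_COLUMNS = (
    "key",
    "consequence",
    "acmg_class",
    "pvs1_strength",
    "score",
    "af",
    "ac",
    "splice_score",
)


@dataclass(frozen=True)
class VariantMask:
    mask_id: str
    af_threshold: str
    members: frozenset


def _class_rule(df: pd.DataFrame, mask_id: str, damaging_cutoff: float) -> pd.Series:
    cls = df["acmg_class"]
    pred_d = (
        (df["consequence"] == "missense")
        & cls.isin(["P", "LP", "VUS_high", "VUS_mid", "VUS_low"])
        & (df["score"] > damaging_cutoff)
    )
    rules = {
        "P": cls == "P",
        "P+LP": cls.isin(["P", "LP"]),
        "P+LP+VUS-H": cls.isin(["P", "LP", "VUS_high"]),
        "P+LP+VUS-H+pred-D": cls.isin(["P", "LP", "VUS_high"]) | pred_d,
        "pred-D": pred_d,
        "PVS1-VS": df["pvs1_strength"] == "very_strong",
        "PVS1-S": df["pvs1_strength"] == "strong",
        "PVS1-M": df["pvs1_strength"] == "moderate",
        "PVS1-P": df["pvs1_strength"] == "supporting",
        "PVS1-VS+S": df["pvs1_strength"].isin(["very_strong", "strong"]),
        "PVS1-VS+S+M": df["pvs1_strength"].isin(["very_strong", "strong", "moderate"]),
        "PVS1-VS+S+M+P": df["pvs1_strength"].isin(
            ["very_strong", "strong", "moderate", "supporting"]
        ),
        "synonymous": (df["consequence"] == "synonymous") & (df["splice_score"] < 0.2),
    }
    return rules[mask_id]


def build_masks(
    classified_variants: pd.DataFrame, damaging_cutoff: float = PRED_DAMAGING_CUTOFF
) -> list[VariantMask]:
    """Materialize the 13 variant masks crossed with 4 allele-frequency strata.

    Expects columns: key, consequence, acmg_class, pvs1_strength, score, af,
    ac, splice_score. The predictor-damaging rule keeps missense variants of
    any non-definitive-benign class whose score exceeds ``damaging_cutoff``
    (a config default equal to the CTE model's published decision threshold,
    overridable per trained model).
    """
    missing = [c for c in _REQUIRED_MASK_COLUMNS if c not in classified_variants.columns]
    if missing:
        raise KeyError(f"classified variant table lacks columns: {missing}")
    df = classified_variants
    masks = []
    af_rules = {
        "0.5": df["af"] <= 0.5,
        "0.1": df["af"] <= 0.1,
        "0.01": df["af"] <= 0.01,
        "singleton": df["ac"] == 1,
    }
    for mask_id in MASK_NAMES:
        in_class = _class_rule(df, mask_id, damaging_cutoff)
        for thr in AF_THRESHOLDS:
            members = frozenset(df.loc[in_class & af_rules[thr], "key"])
            masks.append(VariantMask(mask_id=mask_id, af_threshold=thr, members=members))
    return masks


def gene_epi_table(
    af_table: pd.DataFrame,
    inheritance: dict,
    population_sizes: dict | None = None,
) -> list[GeneEpiRecord]:
    """Per-gene CAF/CrF/GP records from a variant-level AF table.

    ``af_table`` needs columns gene and af (one row per qualifying variant);
    ``inheritance`` maps gene -> mode.
    """
    records = []
    for gene, group in af_table.groupby("gene", sort=True):
        mode = inheritance.get(gene)
        if mode is None:
            raise KeyError(f"no inheritance mode for gene {gene!r}")
        caf = cumulative_allele_frequency(group["af"])
        records.append(
            GeneEpiRecord(
                gene=str(gene),
                inheritance=mode,
                caf=caf,
                crf=carrier_frequency(caf, mode),
                gp=genetic_prevalence(caf, mode),
                population_size=int((population_sizes or {}).get(gene, 0)),
            )
        )
    return records
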