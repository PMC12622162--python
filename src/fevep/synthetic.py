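"""Synthetic fixtures with controllable ground truth for every pipeline input.

Every generator draws from a single integer-seeded PCG64 generator with a
documented sub-stream per input kind (``default_rng([seed, stream_id])``), so
composite fixtures are bit-reproducible for a fixed seed across platforms.

The defaults emulate the shape of the real inputs at desk scale: a couple of
thousand variants across a few dozen genes, a feature catalog spanning all
seven categories (so the three feature regimes are exercisable), Gaussian
informative features with a two-standard-deviation class shift, assay studies
with random orientation, log-uniform allele frequencies and a random acyclic
tool registry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    FeatureMatrix,
    FeatureMeta,
    LabeledVariant,
    ToolEntry,
    ToolRegistry,
    Variant,
    save_tool_registry,
    write_feature_matrix,
    write_feature_meta,
)
from .dataset import AssayStudy, LabeledDataset

# sub-stream ids; each generator derives its own stream from (seed, id)
_STREAMS = {
    "variants": 1,
    "features": 2,
    "assays": 3,
    "population": 4,
    "clinical": 5,
    "sources": 6,
    "background": 7,
}

_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Knobs for the synthetic generators; the seed fixes every draw."""

    n_genes: int = 20
    variants_per_gene: int = 100
    p_damaging: float = 0.5
    # feature catalog: category -> count; all seven categories present so the
    # CTI/CTE/SP regimes differ
    n_features: dict = field(
        default_factory=lambda: {
            "vep_score": 6,
            "conservation": 3,
            "structural": 3,
            "residue_constraint": 2,
            "substitution_matrix": 2,
            "plm": 4,
            "gene_level": 5,
        }
    )
    n_clinical_trained: int = 2  # of the vep_score features
    n_informative: int = 5  # non-predictor informative features
    shift: float = 2.0  # class-mean shift in sd units
    mcar_rate: float = 0.02
    n_biased_missing: int = 2  # noise features with class-dependent missingness
    biased_rates: tuple = (0.3, 0.02)  # missing rate in class 1 vs class 0
    # assays
    assay_effect: float = 2.0
    assay_noise: float = 0.5
    flip_prob: float = 0.5
    uninformative_studies: bool = False
    # population
    af_bounds: tuple = (1e-6, 1e-2)
    singleton_rate: float = 0.1
    allele_number: int = 1_000_000
    registry_edge_prob: float = 0.3
    registry_training_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0 or self.variants_per_gene < 0:
            raise ValueError("counts must be >= 0")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        total_non_vep = sum(v for k, v in self.n_features.items() if k != "vep_score")
        if self.n_informative > total_non_vep:
            raise ValueError(
                f"n_informative={self.n_informative} exceeds the "
                f"{total_non_vep} non-predictor features"
            )


SMALL = SimConfig(n_genes=8, variants_per_gene=40)
FULL = SimConfig(n_genes=20, variants_per_gene=100)


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream]])


def simulate_labeled_variants(cfg: SimConfig):
    """Genes x variants with Bernoulli(p_damaging) labels.

    Returns ``(dataset, labels)``; the labels array is the ground truth the
    other generators condition on.
    """
    rng = _rng(cfg, "variants")
    records = []
    for g in range(cfg.n_genes):
        gene = f"GENE{g + 1:03d}"
        chrom = str((g % 22) + 1)
        for i in range(cfg.variants_per_gene):
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            label = int(rng.random() < cfg.p_damaging)
            records.append(
                LabeledVariant(
                    variant=Variant(
                        chrom=chrom,
                        pos=g * 100_000 + i * 3 + 1,
                        ref=str(ref),
                        alt=str(alt),
                        gene=gene,
                    ),
                    label=label,
                    source="curated",
                )
            )
    dataset = LabeledDataset(records)
    return dataset, dataset.labels


def build_catalog(cfg: SimConfig) -> list[FeatureMeta]:
    """Feature catalog spanning all categories, with registry-linked predictors."""
    catalog = []
    for cat, count in cfg.n_features.items():
        for i in range(count):
            if cat == "vep_score":
                catalog.append(
                    FeatureMeta(
                        name=f"vep_TOOL{i + 1:02d}",
                        category=cat,
                        clinical_trained=i < cfg.n_clinical_trained,
                        tool_id=f"TOOL{i + 1:02d}",
                    )
                )
            else:
                catalog.append(FeatureMeta(name=f"{cat}_{i + 1:02d}", category=cat))
    return catalog


def _informative_names(catalog, cfg: SimConfig) -> list[str]:
    # round-robin across non-predictor categories so every regime can learn
    by_cat: dict[str, list[str]] = {}
    for f in catalog:
        if f.category != "vep_score":
            by_cat.setdefault(f.category, []).append(f.name)
    names, depth = [], 0
    cats = sorted(by_cat)
    while len(names) < cfg.n_informative:
        for c in cats:
            if depth < len(by_cat[c]) and len(names) < cfg.n_informative:
                names.append(by_cat[c][depth])
        depth += 1
    return names


def simulate_feature_matrix(dataset: LabeledDataset, cfg: SimConfig, stream: str = "features"):
    """Feature matrix with known informative features and missingness.

    Informative features are N(label * shift, 1); the rest are N(0, 1).
    MCAR missingness applies everywhere; the first ``n_biased_missing`` noise
    features additionally go missing at class-dependent rates (informative
    missingness). Returns ``(matrix, informative_feature_names)``.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    rng = _rng(cfg, stream)
    catalog = build_catalog(cfg)
    informative = _informative_names(catalog, cfg)
    labels = dataset.labels
    n, p = len(dataset), len(catalog)
    values = rng.standard_normal((n, p))
    for j, feat in enumerate(catalog):
        if feat.name in informative:
            values[:, j] += cfg.shift * labels

    if cfg.mcar_rate > 0:
        values[rng.random((n, p)) < cfg.mcar_rate] = np.nan

    noise_noninformative = [
        f.name
        for f in catalog
        if f.category != "vep_score" and f.name not in informative
    ]
    biased = noise_noninformative[: cfg.n_biased_missing]
    names = [f.name for f in catalog]
    for name in biased:
        j = names.index(name)
        rate = np.where(labels == 1, cfg.biased_rates[0], cfg.biased_rates[1])
        values[rng.random(n) < rate, j] = np.nan

    matrix = FeatureMatrix([r.variant for r in dataset.records], catalog, values)
    return matrix, informative


def simulate_assay_studies(dataset: LabeledDataset, cfg: SimConfig) -> list[AssayStudy]:
    """One assay study per gene: score = label * effect + noise.

    Each study is independently orientation-flipped with probability
    ``flip_prob`` (scores negated, orientation left unknown), emulating assays
    where low score means loss of function. With ``uninformative_studies`` the
    scores are pure noise.
    """
    rng = _rng(cfg, "assays")
    labels = dataset.labels
    studies = []
    for gene, idx in sorted(dataset.gene_index.items()):
        keys = [dataset.records[i].variant.key for i in idx]
        y = labels[list(idx)]
        if cfg.uninformative_studies:
            raw = rng.normal(0.0, 1.0, size=len(keys))
        else:
            raw = y * cfg.assay_effect + rng.normal(0.0, cfg.assay_noise, size=len(keys))
        if rng.random() < cfg.flip_prob:
            raw = -raw
        studies.append(
            AssayStudy(
                study_id=f"STUDY_{gene}",
                gene=gene,
                scores=dict(zip(keys, raw.tolist())),
                orientation="unknown",
            )
        )
    return studies


def simulate_population(genes, cfg: SimConfig, variant_keys=None):
    """Allele-frequency table, inheritance modes, and a tool-registry fixture.

    AFs are log-uniform within ``af_bounds``; singletons (AC = 1) are injected
    at ``singleton_rate``. The registry is a random DAG by construction (edges
    only point from higher- to lower-indexed tools) whose tool ids match the
    catalog's predictor columns.

    Returns ``(af_table, inheritance, registry)``.
    """
    rng = _rng(cfg, "population")
    genes = list(genes)
    if variant_keys is None:
        variant_keys = []
        for g, gene in enumerate(genes):
            for i in range(cfg.variants_per_gene):
                variant_keys.append((f"{(g % 22) + 1}:{g * 100_000 + i * 3 + 1}:A:G", gene))
    lo, hi = np.log10(cfg.af_bounds[0]), np.log10(cfg.af_bounds[1])
    rows = []
    for key, gene in variant_keys:
        af = 10 ** rng.uniform(lo, hi)
        if rng.random() < cfg.singleton_rate:
            ac = 1
            af = 1.0 / cfg.allele_number
        else:
            ac = max(2, int(round(af * cfg.allele_number)))
        rows.append({"key": key, "gene": gene, "af": af, "ac": ac, "an": cfg.allele_number})
    af_table = pd.DataFrame(rows)

    modes = ("AD", "AR", "XLR", "XLD")
    inheritance = {gene: modes[int(rng.integers(len(modes)))] for gene in genes}

    n_tools = cfg.n_features["vep_score"]
    all_keys = [k for k, _ in variant_keys]
    tools = {}
    for i in range(n_tools):
        tid = f"TOOL{i + 1:02d}"
        components = frozenset(
            f"TOOL{j + 1:02d}" for j in range(i) if rng.random() < cfg.registry_edge_prob
        )
        n_train = int(round(cfg.registry_training_frac * len(all_keys)))
        train = rng.choice(len(all_keys), size=min(n_train, len(all_keys)), replace=False)
        tools[tid] = ToolEntry(
            training_variants=frozenset(all_keys[t] for t in train),
            components=components,
            clinical_trained=i < cfg.n_clinical_trained,
        )
    return af_table, inheritance, ToolRegistry(tools)


def simulate_clinical_records(dataset: LabeledDataset, cfg: SimConfig):
    """Archive-style rows (variant, stars, class string) plus splice scores.

    Stars are 0-4 (most >= 2); class strings follow the truth label with a mix
    of definitive and "likely" assertions plus a few inconclusive rows; splice
    scores are mostly low with occasional high values to exercise the filter.
    """
    rng = _rng(cfg, "clinical")
    path_classes = ("pathogenic", "likely pathogenic")
    benign_classes = ("benign", "likely benign")
    rows = []
    splice = {}
    for rec in dataset.records:
        stars = int(rng.choice([0, 1, 2, 3, 4], p=[0.1, 0.1, 0.5, 0.2, 0.1]))
        u = rng.random()
        if u < 0.05:
            clin = "uncertain significance"
        elif rec.label == 1:
            clin = path_classes[int(rng.random() < 0.4)]
        else:
            clin = benign_classes[int(rng.random() < 0.4)]
        rows.append((rec.variant, stars, clin))
        splice[rec.variant.key] = float(rng.beta(0.5, 8.0))
    return rows, splice


def simulate_functional_sources(dataset: LabeledDataset, cfg: SimConfig):
    """Curated / text-mined record lists plus proxy-benign variants with AFs.

    Curated records copy the truth labels; text-mined records carry 5% label
    noise; proxy-benign variants are a disjoint variant set with log-uniform
    AFs (singletons already removed upstream by construction).
    """
    rng = _rng(cfg, "sources")
    curated, text_mined = [], []
    for rec in dataset.records:
        u = rng.random()
        if u < 0.4:
            curated.append(
                LabeledVariant(variant=rec.variant, label=rec.label, source="curated")
            )
        elif u < 0.7:
            label = rec.label if rng.random() > 0.05 else 1 - rec.label
            text_mined.append(
                LabeledVariant(variant=rec.variant, label=label, source="text_mined")
            )
    lo, hi = np.log10(cfg.af_bounds[0]), np.log10(cfg.af_bounds[1])
    proxy = []
    n_proxy = max(1, len(dataset) // 4)
    genes = sorted({r.variant.gene for r in dataset.records})
    for i in range(n_proxy):
        gene = genes[i % len(genes)]
        g = genes.index(gene)
        v = Variant(
            chrom=str((g % 22) + 1),
            pos=50_000_000 + i * 3 + 1,
            ref="A",
            alt="G",
            gene=gene,
        )
        proxy.append((v, float(10 ** rng.uniform(lo, hi))))
    return curated, text_mined, proxy


# ---------------------------------------------------------------------------
# fixture tree for the CLI

def generate_fixture_tree(cfg: SimConfig, outdir) -> dict:
    """Write the full TSV/JSON fixture tree a pipeline run consumes.

    Returns the config dict (also saved as config.json) mapping logical input
    names to the files written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    dataset, labels = simulate_labeled_variants(cfg)
    clin_rows, splice = simulate_clinical_records(dataset, cfg)
    curated, text_mined, proxy = simulate_functional_sources(dataset, cfg)
    # proxy-benign variants need feature rows too: the functional training set
    # includes them
    with_proxy = LabeledDataset(
        dataset.records
        + [
            LabeledVariant(variant=v, label=0, source="proxy_benign", sample_weight=1.0)
            for v, _af in proxy
        ]
    )
    matrix, informative = simulate_feature_matrix(with_proxy, cfg)
    bg_cfg = SimConfig(**{**cfg.__dict__, "n_genes": max(4, cfg.n_genes // 2),
                          "mcar_rate": 0.0, "n_biased_missing": 0,
                          "seed": cfg.seed + 1_000_003})
    bg_dataset, _ = simulate_labeled_variants(bg_cfg)
    background, _ = simulate_feature_matrix(bg_dataset, bg_cfg, stream="background")
    studies = simulate_assay_studies(dataset, cfg)
    af_table, inheritance, registry = simulate_population(
        sorted(dataset.gene_index),
        cfg,
        variant_keys=[(r.variant.key, r.variant.gene) for r in dataset.records],
    )

    _write_labeled(with_proxy, out / "labels.tsv")  # truth for every matrix row
    write_feature_matrix(matrix, out / "features.tsv")
    write_feature_meta(matrix.features, out / "feature_meta.tsv")
    write_feature_matrix(background, out / "background.tsv")
    pd.DataFrame(
        [
            {"study_id": s.study_id, "gene": s.gene, "key": k, "score": v}
            for s in studies
            for k, v in sorted(s.scores.items())
        ]
    ).to_csv(out / "assays.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(
        [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.gene, "stars": stars, "clinical_class": clin,
            }
            for v, stars, clin in clin_rows
        ]
    ).to_csv(out / "clinvar.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"key": k, "splice_score": s} for k, s in sorted(splice.items())]
    ).to_csv(out / "splice_scores.tsv", sep="\t", index=False, float_format="%.10g")
    _write_labeled(LabeledDataset(curated), out / "curated.tsv")
    _write_labeled(LabeledDataset(text_mined), out / "text_mined.tsv")
    pd.DataFrame(
        [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "gene": v.gene, "af": af}
            for v, af in proxy
        ]
    ).to_csv(out / "proxy_benign.tsv", sep="\t", index=False, float_format="%.10g")
    af_table.to_csv(out / "af.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(
        sorted(inheritance.items()), columns=["gene", "mode"]
    ).to_csv(out / "inheritance.tsv", sep="\t", index=False)
    save_tool_registry(registry, out / "registry.json")

    config = {
        "seed": cfg.seed,
        "informative_features": informative,
        "paths": {
            name: str(out / fname)
            for name, fname in [
                ("labels", "labels.tsv"),
                ("features", "features.tsv"),
                ("feature_meta", "feature_meta.tsv"),
                ("background", "background.tsv"),
                ("assays", "assays.tsv"),
                ("clinvar", "clinvar.tsv"),
                ("splice_scores", "splice_scores.tsv"),
                ("curated", "curated.tsv"),
                ("text_mined", "text_mined.tsv"),
                ("proxy_benign", "proxy_benign.tsv"),
                ("af", "af.tsv"),
                ("inheritance", "inheritance.tsv"),
                ("registry", "registry.json"),
            ]
        },
    }
    with open(out / "config.json", "w") as fh:
        json.dump(config, fh, indent=1, sort_keys=True)
    return config


def _write_labeled(dataset: LabeledDataset, path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.variant.chrom, "pos": r.variant.pos,
                "ref": r.variant.ref, "alt": r.variant.alt,
                "gene": r.variant.gene, "label": r.label,
                "source": r.source, "sample_weight": r.sample_weight,
            }
            for r in dataset.records
        ],
        columns=["chrom", "pos", "ref", "alt", "gene", "label", "source", "sample_weight"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_labeled(path) -> LabeledDataset:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    records = [
        LabeledVariant(
            variant=Variant(chrom=row.chrom, pos=int(row.pos), ref=row.ref,
                            alt=row.alt, gene=row.gene),
            label=int(row.label),
            source=row.source,
            sample_weight=float(row.sample_weight),
        )
        for row in df.itertuples(index=False)
    ]
    return LabeledDataset(records)


def write_labeled(dataset: LabeledDataset, path) -> None:
    _write_labeled(dataset, path)
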