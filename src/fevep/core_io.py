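"""Domain types and readers/writers shared by the pipeline.

Coordinates are 1-based and fully closed, matching VCF. Variant keys are
``chrom:pos:ref:alt`` with chromosome names normalized by stripping a leading
``chr``, so tables from different sources merge safely. Missing feature values
are NaN in TSV and ``.`` in VCF INFO fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A malformed on-disk table or registry."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom)
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide (or small) variant, optionally protein-annotated."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    aa_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "pos", int(self.pos))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


VALID_SOURCES = ("mave", "curated", "text_mined", "clinvar", "proxy_benign")


@dataclass(frozen=True)
class LabeledVariant:
    """A variant with a binary damaging/pathogenic (1) vs neutral/benign (0) label.

    ``sample_weight`` is 1.0 for every source except proxy-benign population
    variants, which are down-weighted by normalized log allele frequency.
    """

    variant: Variant
    label: int
    source: str
    sample_weight: float = 1.0

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not 0.0 <= self.sample_weight <= 1.0:
            raise ValueError("sample_weight must be in [0, 1]")
        if self.source != "proxy_benign" and self.sample_weight != 1.0:
            raise ValueError("sample_weight != 1 is only valid for proxy_benign")
        if self.source == "proxy_benign" and self.label != 0:
            raise ValueError("proxy_benign records are always labeled 0")


FEATURE_CATEGORIES = (
    "vep_score",
    "conservation",
    "structural",
    "residue_constraint",
    "substitution_matrix",
    "plm",
    "gene_level",
)


@dataclass(frozen=True)
class FeatureMeta:
    """Name, category and provenance of one feature column.

    ``clinical_trained`` marks predictor scores whose upstream tool learned
    from clinical labels (excluded in the CTE regime); ``tool_id`` links a
    predictor score to the tool registry for circularity masking.
    """

    name: str
    category: str
    clinical_trained: bool = False
    tool_id: str | None = None

    def __post_init__(self):
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.clinical_trained and self.category != "vep_score":
            raise ValueError("clinical_trained is only meaningful for vep_score")
        if (self.tool_id is not None) != (self.category == "vep_score"):
            raise ValueError("tool_id must be present iff category is vep_score")


@dataclass
class FeatureMatrix:
    """Variants x features grid with NaN as the explicit missing marker."""

    variants: list[Variant]
    features: list[FeatureMeta]
    values: np.ndarray
    # feature name -> row indices whose cells were filled by imputation
    imputed: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.variants), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.variants)} variants x {len(self.features)} features"
            )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            list(self.variants),
            list(self.features),
            self.values.copy(),
            {k: list(v) for k, v in self.imputed.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variant_keys, columns=self.feature_names)


@dataclass(frozen=True)
class ToolEntry:
    training_variants: frozenset
    components: frozenset
    clinical_trained: bool = False
    training_unknown: bool = False


@dataclass
class ToolRegistry:
    """Per-tool training-variant sets and component-tool edges.

    The component graph must be acyclic and every component id must resolve;
    both are validated at construction.
    """

    tools: dict[str, ToolEntry]

    def __post_init__(self):
        for tid, entry in self.tools.items():
            for comp in entry.components:
                if comp not in self.tools:
                    raise FormatError(f"tool {tid!r} references unknown component {comp!r}")
        cycle = _find_cycle(self.tools)
        if cycle:
            raise FormatError("component graph has a cycle: " + " -> ".join(cycle))

    def __contains__(self, tool_id: str) -> bool:
        return tool_id in self.tools

    def __iter__(self):
        return iter(self.tools)


def _find_cycle(tools: dict[str, ToolEntry]) -> list[str] | None:
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {t: WHITE for t in tools}
    stack: list[str] = []

    def visit(t: str) -> list[str] | None:
        color[t] = GRAY
        stack.append(t)
        for c in sorted(tools[t].components):
            if color[c] == GRAY:
                return stack[stack.index(c):] + [c]
            if color[c] == WHITE:
                found = visit(c)
                if found:
                    return found
        stack.pop()
        color[t] = BLACK
        return None

    for t in sorted(tools):
        if color[t] == WHITE:
            found = visit(t)
            if found:
                return found
    return None


# ---------------------------------------------------------------------------
# readers / writers

_TSV_REQUIRED = ("chrom", "pos", "ref", "alt")


def read_variant_table(path, dialect: str = "tsv"):
    """Read a variant table from TSV (mandatory header) or VCF.

    Returns ``(variants, extras)`` where ``extras`` is a DataFrame of any
    additional columns (TSV) or None (VCF); numeric extras keep NaN for
    missing entries.
    """
    if dialect == "tsv":
        return _read_tsv_variants(path)
    if dialect == "vcf":
        return _read_vcf_variants(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv_variants(path):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    variants = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            v = Variant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=str(getattr(row, "gene", "") or ""),
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {line_no}: {exc}") from exc
        if v.key in seen:
            raise FormatError(
                f"{path}: line {line_no}: duplicate variant key {v.key} "
                f"(first seen on line {seen[v.key]})"
            )
        seen[v.key] = line_no
        variants.append(v)
    extra_cols = [c for c in df.columns if c not in _TSV_REQUIRED + ("gene",)]
    extras = df[extra_cols] if extra_cols else None
    return variants, extras


def _read_vcf_variants(path):
    from cyvcf2 import VCF

    variants = []
    seen = set()
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            v = Variant(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt)
            if v.key in seen:
                raise FormatError(f"{path}: duplicate variant key {v.key}")
            seen.add(v.key)
            variants.append(v)
    return variants, None


def write_predictions(variants, scores, classes, path, dialect: str = "tsv"):
    """Write per-variant scores and class calls; round-trips to >= 6 s.f."""
    if not (len(variants) == len(scores) == len(classes)):
        raise ValueError(
            f"length mismatch: {len(variants)} variants, "
            f"{len(scores)} scores, {len(classes)} classes"
        )
    if dialect == "tsv":
        rows = []
        for v, s, c in zip(variants, scores, classes):
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": v.gene,
                    "score": "" if _is_missing(s) else f"{float(s):.10g}",
                    "class": c,
                }
            )
        pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "gene", "score", "class"]
        ).to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=SCORE,Number=1,Type=Float,Description="Prediction score">\n')
            fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Prediction class">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v, s, c in zip(variants, scores, classes):
                sval = "." if _is_missing(s) else f"{float(s):.10g}"
                fh.write(
                    f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                    f"SCORE={sval};CLASS={c}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def read_predictions(path, dialect: str = "tsv"):
    """Inverse of :func:`write_predictions`; returns (variants, scores, classes)."""
    if dialect == "tsv":
        variants, extras = _read_tsv_variants(path)
        scores = extras["score"].to_numpy(dtype=float) if extras is not None else np.array([])
        classes = list(extras["class"]) if extras is not None else []
        return variants, scores, classes
    if dialect == "vcf":
        variants, scores, classes = [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")[:8]
                kv = dict(item.split("=", 1) for item in info.split(";") if "=" in item)
                variants.append(Variant(chrom=chrom, pos=int(pos), ref=ref, alt=alt))
                sval = kv.get("SCORE", ".")
                scores.append(float("nan") if sval == "." else float(sval))
                classes.append(kv.get("CLASS", ""))
        return variants, np.asarray(scores), classes
    raise ValueError(f"unknown dialect {dialect!r}")


def load_tool_registry(path) -> ToolRegistry:
    """Load and validate a JSON tool registry.

    Schema: ``{tool_id: {"training_variants": [keys], "components": [tool_ids],
    "clinical_trained": bool, "training_unknown": bool}}``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: registry must be a JSON object")
    tools = {}
    for tid, spec in raw.items():
        tools[tid] = ToolEntry(
            training_variants=frozenset(spec.get("training_variants", [])),
            components=frozenset(spec.get("components", [])),
            clinical_trained=bool(spec.get("clinical_trained", False)),
            training_unknown=bool(spec.get("training_unknown", False)),
        )
    return ToolRegistry(tools)


def save_tool_registry(registry: ToolRegistry, path) -> None:
    raw = {
        tid: {
            "training_variants": sorted(e.training_variants),
            "components": sorted(e.components),
            "clinical_trained": e.clinical_trained,
            "training_unknown": e.training_unknown,
        }
        for tid, e in registry.tools.items()
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1, sort_keys=True)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """TSV with variant key columns followed by one column per feature."""
    df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in matrix.variants],
            "pos": [v.pos for v in matrix.variants],
            "ref": [v.ref for v in matrix.variants],
            "alt": [v.alt for v in matrix.variants],
            "gene": [v.gene for v in matrix.variants],
        }
    )
    for j, name in enumerate(matrix.feature_names):
        df[name] = matrix.values[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_feature_meta(features: list[FeatureMeta], path) -> None:
    pd.DataFrame(
        {
            "name": [f.name for f in features],
            "category": [f.category for f in features],
            "clinical_trained": [f.clinical_trained for f in features],
            "tool_id": [f.tool_id or "" for f in features],
        }
    ).to_csv(path, sep="\t", index=False)


def read_feature_matrix(matrix_path, meta_path) -> FeatureMatrix:
    variants, extras = _read_tsv_variants(matrix_path)
    meta_df = pd.read_csv(meta_path, sep="\t", keep_default_na=False)
    features = [
        FeatureMeta(
            name=row["name"],
            category=row["category"],
            clinical_trained=str(row["clinical_trained"]).lower() == "true",
            tool_id=row["tool_id"] or None,
        )
        for _, row in meta_df.iterrows()
    ]
    if extras is None:
        raise FormatError(f"{matrix_path}: no feature columns")
    missing = [f.name for f in features if f.name not in extras.columns]
    if missing:
        raise FormatError(f"{matrix_path}: feature columns absent: {missing}")
    values = extras[[f.name for f in features]].to_numpy(dtype=float)
    return FeatureMatrix(variants, features, values)
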