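"""Variant-level circularity elimination.

A predictor evaluated on variants it (or any tool feeding into it) was trained
on reports inflated performance. The fix is recursive: each tool's effective
training set is the union of its own training variants and those of every
component tool reachable through the meta-predictor graph, and any feature
cell whose variant falls in that effective set is masked to missing.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .core_io import FeatureMatrix, ToolRegistry


class ClosureMap(dict):
    """tool_id -> effective training set (own union all transitive components')."""


def expand_component_closure(registry: ToolRegistry) -> ClosureMap:
    """Effective training set per tool by graph reachability.

    The registry validates acyclicity at load; reachability over the component
    DAG (inclusive of the tool itself) gives the recursive exclusion set.
    """
    g = nx.DiGraph()
    g.add_nodes_from(registry.tools)
    for tid, entry in registry.tools.items():
        for comp in entry.components:
            g.add_edge(tid, comp)
    if not nx.is_directed_acyclic_graph(g):  # pre-blocked at load; belt and braces
        raise ValueError("component graph has a cycle")
    closure = ClosureMap()
    for tid in registry.tools:
        effective = set(registry.tools[tid].training_variants)
        for reached in nx.descendants(g, tid):
            effective |= registry.tools[reached].training_variants
        closure[tid] = frozenset(effective)
    return closure


def mask_circular_scores(matrix: FeatureMatrix, closure: ClosureMap):
    """Mask predictor-score cells for variants in each tool's effective set.

    Only ``vep_score`` features are touched; every such feature must carry a
    tool_id resolvable in the closure. Returns the masked matrix and a
    per-tool count of newly masked cells. Idempotent: masked cells are NaN and
    stay NaN.
    """
    out = matrix.copy()
    report: dict[str, int] = {}
    keys = np.array(matrix.variant_keys)
    for j, feat in enumerate(matrix.features):
        if feat.category != "vep_score":
            continue
        if feat.tool_id not in closure:
            raise KeyError(
                f"feature {feat.name!r} references tool {feat.tool_id!r} "
                "absent from the registry closure"
            )
        effective = closure[feat.tool_id]
        if not effective:
            report.setdefault(feat.tool_id, 0)
            continue
        hit = np.isin(keys, list(effective))
        newly = int(np.sum(hit & ~np.isnan(out.values[:, j])))
        out.values[hit, j] = np.nan
        report[feat.tool_id] = report.get(feat.tool_id, 0) + newly
    return out, report
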