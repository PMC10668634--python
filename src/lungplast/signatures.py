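"""Cell-type signature derivation from reference expression panels.

A signature for a cell type is the top-N genes ranked by signal-to-noise
ratio in a one-vs-rest contrast (the cell type's samples against all other
samples of the panel pooled).  By default only upregulated genes are
eligible — signatures are used as enrichment probes, where positive
markers are the convention — but ranking by |SNR| is available via
``direction="abs"``.  Ties are broken by gene id so derivation is fully
deterministic.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .diffexp import differential_expression
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleAnnotation,
    ValidationError,
)

REST_LABEL = "__rest__"


def _one_vs_rest_annotation(annotation: SampleAnnotation, cell_type: str) -> SampleAnnotation:
    groups = annotation.groups
    if cell_type not in set(groups):
        raise KeyError(f"cell type {cell_type!r} not present in annotation")
    collapsed = {
        s: (cell_type if g == cell_type else REST_LABEL) for s, g in groups.items()
    }
    return SampleAnnotation.from_groups(collapsed)


def derive_signature(
    panel: ExpressionMatrix,
    annotation: SampleAnnotation,
    cell_type: str,
    n_top: int = 100,
    panel_name: str = "panel",
    direction: str = "up",
) -> GeneSet:
    """Top-``n_top`` most differentially expressed genes for one cell type."""
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    if n_top > panel.shape[0]:
        raise ValidationError(
            f"n_top = {n_top} exceeds the {panel.shape[0]} genes in the panel"
        )
    if direction not in ("up", "abs"):
        raise ValidationError("direction must be 'up' or 'abs'")

    ovr = _one_vs_rest_annotation(annotation, cell_type)
    table = differential_expression(panel, ovr, cell_type, REST_LABEL)
    key = table["snr"] if direction == "up" else table["snr"].abs()
    ranked = (
        pd.DataFrame({"gene_id": table["gene_id"], "key": key})
        .sort_values(["key", "gene_id"], ascending=[False, True], kind="stable")
    )
    top = ranked["gene_id"].head(n_top).tolist()
    return GeneSet(
        name=f"{panel_name}_{cell_type}",
        description=f"top {n_top} {direction}-ranked genes for {cell_type} (one-vs-rest SNR)",
        genes=tuple(top),
    )


def derive_all(
    panels: Mapping[str, tuple[ExpressionMatrix, SampleAnnotation]],
    n_top: int = 100,
    direction: str = "up",
    focal_types: Mapping[str, list[str]] | None = None,
) -> GeneSetCollection:
    """Derive one signature per (panel, cell type) pair.

    By default every group label of a panel except the pooled ``"other"``
    background is treated as a focal cell type; ``focal_types`` overrides
    the per-panel list.
    """
    if not panels:
        raise ValidationError("no panels given")
    sets = []
    for panel_name, (matrix, annotation) in panels.items():
        if focal_types is not None:
            types = focal_types[panel_name]
        else:
            types = [g for g in dict.fromkeys(annotation.groups) if g != "other"]
        for cell_type in types:
            sets.append(
                derive_signature(
                    matrix, annotation, cell_type, n_top,
                    panel_name=panel_name, direction=direction,
                )
            )
    return GeneSetCollection(sets)
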