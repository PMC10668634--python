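"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of its parameters and a seed, so each
downstream stage (differential expression, signature derivation, ssGSEA,
information-coefficient association, NMF clustering, state-map projection,
gating, qPCR quantification) can be exercised end to end without any
external download.

The bulk expression model is log2-Normal: a per-gene baseline drawn once
from Normal(5, 1), plus additive group-specific program effects in log2
units, plus per-entry Normal noise.  Cell-type structure is planted as
*gene programs* — index sets with a per-group mean shift — mirroring the
biology at the level where it is testable: the dual-positive group carries
the type I and the type II program simultaneously, plus an embryonic
program of its own, so dual-positive samples literally share planted
structure with both single-positive groups.

Gene identifiers are a single shared space ``G0000 ... G{n-1}`` across the
study matrix, the reference panels and the oncogene-module panel, so that
signatures derived from one generator apply to the output of another.

Seeding: a single user seed is mapped to per-operation child seeds by
fixed offsets (see ``SEED_OFFSETS``), keeping independent stages decoupled
while the whole pipeline stays reproducible from one integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    SampleAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: fixed offsets mapping one global seed to per-operation child seeds
SEED_OFFSETS = {
    "study": 101,
    "panels": 211,
    "kras": 307,
    "cells": 401,
    "ct": 503,
}

_SEED_MOD = 2**31


def child_seed(seed: int, operation: str) -> int:
    """Derive the per-operation child seed from a global seed."""
    return (int(seed) + SEED_OFFSETS[operation]) % _SEED_MOD


def gene_id(i: int) -> str:
    return f"G{i:04d}"


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneProgram:
    """A planted expression program: gene indices plus per-group log2 shifts.

    ``effect_log2`` must name every group of the enclosing design;
    ``dispersion`` is the per-entry Normal noise sd (log2 units) applied to
    the program's genes.
    """

    name: str
    gene_indices: tuple[int, ...]
    effect_log2: Mapping[str, float]
    dispersion: float = 0.25

    def __post_init__(self) -> None:
        if len(set(self.gene_indices)) != len(self.gene_indices):
            raise ValidationError(f"program {self.name!r} has duplicate gene indices")
        if self.dispersion <= 0:
            raise ValidationError(f"program {self.name!r} needs positive dispersion")
        object.__setattr__(self, "gene_indices", tuple(int(i) for i in self.gene_indices))
        object.__setattr__(self, "effect_log2", dict(self.effect_log2))


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a simulated bulk RNA-seq study.

    ``groups`` is an ordered list of (label, n_samples); ``programs`` plant
    the cell-type structure.  ``noise_sd`` is the background per-entry noise
    for genes not covered by any program.
    """

    n_genes: int = 2000
    groups: tuple[tuple[str, int], ...] = (("typeI", 3), ("typeII", 3), ("dualpos", 3))
    programs: tuple[GeneProgram, ...] = ()
    noise_sd: float = 0.25
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate group labels")
        for _, n in self.groups:
            if n < 1:
                raise ValidationError("each group needs >= 1 sample")
        for prog in self.programs:
            for i in prog.gene_indices:
                if not 0 <= i < self.n_genes:
                    raise ValidationError(
                        f"program {prog.name!r} index {i} outside [0, {self.n_genes})"
                    )
            missing = set(labels) - set(prog.effect_log2)
            if missing:
                raise ValidationError(
                    f"program {prog.name!r} lacks effects for groups {sorted(missing)}"
                )

    @property
    def group_labels(self) -> list[str]:
        return [g for g, _ in self.groups]

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)


def _default_programs(effect: float = 2.0, dispersion: float = 0.25) -> tuple[GeneProgram, ...]:
    """The default planted structure: type I, type II and embryonic programs.

    The dual-positive group is shifted up on *both* single-positive programs
    and is the only group carrying the embryonic program.
    """
    zero = {"typeI": 0.0, "typeII": 0.0, "dualpos": 0.0}
    return (
        GeneProgram(
            "typeI",
            tuple(range(0, 150)),
            {**zero, "typeI": effect, "dualpos": effect},
            dispersion,
        ),
        GeneProgram(
            "typeII",
            tuple(range(150, 300)),
            {**zero, "typeII": effect, "dualpos": effect},
            dispersion,
        ),
        GeneProgram(
            "embryonic",
            tuple(range(300, 600)),
            {**zero, "dualpos": effect},
            dispersion,
        ),
    )


def default_study_design(seed: int = 7) -> StudyDesign:
    """Three groups (typeI, typeII, dualpos) x 3 samples, 2,000 genes."""
    return StudyDesign(programs=_default_programs(), seed=seed)


def simulate_study(design: StudyDesign) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Simulate a log2-scale study matrix from a :class:`StudyDesign`."""
    rng = np.random.default_rng(design.seed)
    n_genes, n_samples = design.n_genes, design.n_samples

    covered: set[int] = set()
    for prog in design.programs:
        overlap = covered & set(prog.gene_indices)
        if overlap:
            logger.info(
                "program %r overlaps %d genes of earlier programs", prog.name, len(overlap)
            )
        covered |= set(prog.gene_indices)

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=n_genes)
    group_of_sample: list[str] = []
    sample_ids: list[str] = []
    for label, n in design.groups:
        for r in range(n):
            sample_ids.append(f"{label}_{r + 1}")
            group_of_sample.append(label)

    values = np.tile(baseline[:, None], (1, n_samples))
    noise_sd = np.full(n_genes, design.noise_sd)
    for prog in design.programs:
        idx = np.asarray(prog.gene_indices, dtype=int)
        noise_sd[idx] = prog.dispersion
        for j, label in enumerate(group_of_sample):
            values[idx, j] += prog.effect_log2[label]
    values += rng.normal(0.0, 1.0, size=values.shape) * noise_sd[:, None]

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=[gene_id(i) for i in range(n_genes)], columns=sample_ids),
        scale_tag="log2",
    )
    annotation = SampleAnnotation.from_groups(dict(zip(sample_ids, group_of_sample)))
    return matrix, annotation


# ---------------------------------------------------------------------------
# reference panels for signature derivation
# ---------------------------------------------------------------------------

#: panel name -> (focal cell type, planted gene index range)
#: The two progenitor panels plant their programs inside the study's
#: embryonic program block (indices 300-599) so that signatures derived from
#: them probe the dual-positive group's embryonic component; the
#: differentiated panel sits outside every study program and acts as the
#: negative control signature.
REFERENCE_PANEL_LAYOUT = {
    "E11.5-progenitor": ("E11.5", range(300, 450)),
    "E17.5-progenitor": ("E17.5", range(450, 600)),
    "differentiated": ("differentiated", range(600, 750)),
}


def simulate_reference_panels(
    seed: int = 7,
    n_genes: int = 2000,
    n_samples_per_group: int = 4,
    effect: float = 3.0,
    dispersion: float = 0.25,
) -> dict[str, tuple[ExpressionMatrix, SampleAnnotation]]:
    """Simulate the developmental reference panels used to derive signatures.

    Returns three labelled panels (early progenitor, late progenitor,
    differentiated epithelium), each with ``n_samples_per_group`` samples of
    the focal cell type and as many pooled "other" samples, and 150 genes
    truly upregulated in the focal type — comfortably more than the 100
    selected downstream, so top-N selection is well defined.
    """
    base = child_seed(seed, "panels")
    panels: dict[str, tuple[ExpressionMatrix, SampleAnnotation]] = {}
    for offset, (panel_name, (cell_type, idx_range)) in enumerate(
        REFERENCE_PANEL_LAYOUT.items()
    ):
        program = GeneProgram(
            name=f"{panel_name}_program",
            gene_indices=tuple(idx_range),
            effect_log2={cell_type: effect, "other": 0.0},
            dispersion=dispersion,
        )
        design = StudyDesign(
            n_genes=n_genes,
            groups=((cell_type, n_samples_per_group), ("other", n_samples_per_group)),
            programs=(program,),
            noise_sd=dispersion,
            seed=(base + offset) % _SEED_MOD,
        )
        panels[panel_name] = simulate_study(design)
    return panels


# ---------------------------------------------------------------------------
# oncogene-module cell-line panel
# ---------------------------------------------------------------------------


class KrasPanel(NamedTuple):
    """Simulated cell-line compendium restricted to a KRAS-responsive module.

    ``matrix`` is raw-scale (nonnegative) genes x cell lines; ``module`` is
    the planted KRAS-responsive gene set; ``states`` annotates each cell
    line with its planted latent state; ``W_true``/``H_true`` are the
    planted factors over the module genes (for parameter-recovery tests and
    for planting matched activity into study samples).
    """

    matrix: ExpressionMatrix
    module: GeneSet
    states: SampleAnnotation
    W_true: pd.DataFrame
    H_true: pd.DataFrame


def simulate_kras_panel(
    n_cell_lines: int = 60,
    module_size: int = 1000,
    n_states: int = 3,
    n_genes: int = 2000,
    noise_sd: float = 0.05,
    seed: int = 7,
) -> KrasPanel:
    """Simulate a cell-line panel with a planted low-rank oncogenic module.

    The module genes carry a nonnegative rank-``n_states`` structure:
    every cell line belongs to one latent state and its module expression is
    dominated by that state's factor, with a small admixture of the others
    plus Normal noise (truncated at zero).  Genes outside the module are
    state-independent background.
    """
    if module_size < 10:
        raise ValidationError("module_size must be >= 10")
    if module_size > n_genes:
        raise ValidationError("module_size cannot exceed n_genes")
    if n_cell_lines < 3 * n_states:
        raise ValidationError("need at least 3 cell lines per planted state")
    rng = np.random.default_rng(child_seed(seed, "kras"))

    module_idx = np.arange(module_size)
    module_genes = tuple(gene_id(int(i)) for i in module_idx)
    factor_names = [f"state{s}" for s in range(n_states)]

    # each state's factor: a distinct block of module genes strongly on
    W = rng.gamma(shape=1.0, scale=0.5, size=(module_size, n_states))
    block = module_size // n_states
    for s in range(n_states):
        W[s * block : (s + 1) * block, s] += rng.uniform(3.0, 5.0, size=block)

    state_of_line = np.repeat(np.arange(n_states), int(np.ceil(n_cell_lines / n_states)))[
        :n_cell_lines
    ]
    rng.shuffle(state_of_line)
    H = rng.uniform(0.0, 0.05, size=(n_states, n_cell_lines))
    H[state_of_line, np.arange(n_cell_lines)] += rng.uniform(0.8, 1.2, size=n_cell_lines)

    line_ids = [f"line{j:03d}" for j in range(n_cell_lines)]
    values = rng.gamma(shape=2.0, scale=0.5, size=(n_genes, n_cell_lines))
    values[module_idx] = W @ H + rng.normal(0.0, noise_sd, size=(module_size, n_cell_lines))
    np.maximum(values, 0.0, out=values)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=[gene_id(i) for i in range(n_genes)], columns=line_ids),
        scale_tag="raw",
    )
    module = GeneSet("KRAS_module", "planted KRAS-responsive gene module", module_genes)
    states = SampleAnnotation.from_groups(
        {line_ids[j]: factor_names[state_of_line[j]] for j in range(n_cell_lines)}
    )
    return KrasPanel(
        matrix=matrix,
        module=module,
        states=states,
        W_true=pd.DataFrame(W, index=list(module_genes), columns=factor_names),
        H_true=pd.DataFrame(H, index=factor_names, columns=line_ids),
    )


def plant_module_activity(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    panel: KrasPanel,
    group_states: Mapping[str, str],
    strength: float = 6.0,
) -> ExpressionMatrix:
    """Overlay state-specific module activity onto study samples.

    For every sample whose group appears in ``group_states``, the planted
    factor of the named state (max-normalized) is added to the sample's
    module-gene expression, scaled by ``strength`` log2 units.  Used to
    simulate study populations that occupy a known oncogenic state of the
    reference map.
    """
    data = matrix.data.copy()
    genes = [g for g in panel.module.genes if g in data.index]
    if len(genes) < len(panel.module) / 2:
        raise ValidationError("study matrix covers less than half of the module genes")
    for sample in data.columns:
        group = annotation.groups.get(sample)
        if group in group_states:
            w = panel.W_true.loc[genes, group_states[group]].to_numpy()
            data.loc[genes, sample] += strength * w / w.max()
    return ExpressionMatrix(data, matrix.scale_tag)


# ---------------------------------------------------------------------------
# flow-cytometry-like cell populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellPopulationSpec:
    """Mixture of labelled cell populations with Normal marker intensities.

    ``fractions`` gives the mixing proportions (must sum to 1);
    ``marker_means`` gives, per label, the mean log10 intensity of every
    marker; all populations share one spherical ``marker_sd``.
    """

    n_cells: int
    fractions: Mapping[str, float]
    marker_means: Mapping[str, Mapping[str, float]]
    marker_sd: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValidationError("n_cells must be positive")
        fr = dict(self.fractions)
        if any(not 0.0 <= f <= 1.0 for f in fr.values()):
            raise ValidationError("fractions must lie in [0, 1]")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1")
        if set(fr) != set(self.marker_means):
            raise ValidationError("fractions and marker_means must share labels")
        marker_sets = [frozenset(m) for m in self.marker_means.values()]
        if len(set(marker_sets)) != 1:
            raise ValidationError("marker set must be identical across labels")
        if self.marker_sd <= 0:
            raise ValidationError("marker_sd must be positive")
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(
            self, "marker_means", {k: dict(v) for k, v in self.marker_means.items()}
        )

    @property
    def markers(self) -> list[str]:
        first = next(iter(self.marker_means.values()))
        return sorted(first)


#: default marker intensity levels (log10 scale): "low" is autofluorescence
#: background, "high" is a brightly stained population; four decades of
#: separation so midpoint gates misclassify a negligible cell fraction.
MARKER_LOW = 1.0
MARKER_HIGH = 5.0


def dual_positive_spec(
    dualpos_fraction: float,
    typeI_fraction: float | None = None,
    n_cells: int = 100_000,
    marker_sd: float = 0.5,
    seed: int = 7,
) -> CellPopulationSpec:
    """Spec for the PDPN/TdTomato sorting experiment.

    ``dualpos_fraction`` is the dual-positive share of total epithelial
    cells; the remainder splits between single-positive type I and type II
    (type I defaults to a third of the remainder, echoing the preponderance
    of type II cells in alveolar preparations).
    """
    if typeI_fraction is None:
        typeI_fraction = (1.0 - dualpos_fraction) / 3.0
    typeII_fraction = 1.0 - dualpos_fraction - typeI_fraction
    return CellPopulationSpec(
        n_cells=n_cells,
        fractions={
            "typeI": typeI_fraction,
            "typeII": typeII_fraction,
            "dualpos": dualpos_fraction,
        },
        marker_means={
            "typeI": {"PDPN": MARKER_HIGH, "TdTm": MARKER_LOW},
            "typeII": {"PDPN": MARKER_LOW, "TdTm": MARKER_HIGH},
            "dualpos": {"PDPN": MARKER_HIGH, "TdTm": MARKER_HIGH},
        },
        marker_sd=marker_sd,
        seed=seed,
    )


def notch_reporter_spec(
    positive_fraction: float,
    n_cells: int = 100_000,
    marker_sd: float = 0.5,
    seed: int = 7,
) -> CellPopulationSpec:
    """Spec for a single Notch-reporter (Venus) gate within one population."""
    return CellPopulationSpec(
        n_cells=n_cells,
        fractions={"notch_pos": positive_fraction, "notch_neg": 1.0 - positive_fraction},
        marker_means={
            "notch_pos": {"Venus": MARKER_HIGH},
            "notch_neg": {"Venus": MARKER_LOW},
        },
        marker_sd=marker_sd,
        seed=seed,
    )


def simulate_cells(spec: CellPopulationSpec) -> pd.DataFrame:
    """Draw a cell table (cell_id, marker intensities, true_label).

    Each cell's label is multinomial in the spec fractions; marker
    intensities are independent Normals around the label's means.
    """
    rng = np.random.default_rng(child_seed(spec.seed, "cells"))
    labels = list(spec.fractions)
    probs = np.array([spec.fractions[k] for k in labels])
    assignment = rng.choice(len(labels), size=spec.n_cells, p=probs)
    markers = spec.markers
    means = np.array([[spec.marker_means[k][m] for m in markers] for k in labels])
    intensities = means[assignment] + rng.normal(
        0.0, spec.marker_sd, size=(spec.n_cells, len(markers))
    )
    table = pd.DataFrame(intensities, columns=markers)
    table.insert(0, "cell_id", [f"cell{i:06d}" for i in range(spec.n_cells)])
    table["true_label"] = [labels[a] for a in assignment]
    return table


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    true_fold_changes: Mapping[str, float],
    housekeeping_gene: str = "GAPDH",
    housekeeping_ct: float = 18.0,
    control_target_ct: float = 24.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 7,
) -> pd.DataFrame:
    """Construct a CT table whose ddCT fold changes equal a given truth.

    CT values are built by inverting the relative-quantification formula:
    the treated target CT is lowered by log2(fold change) relative to the
    control target CT (lower CT = more template).  With ``noise_sd`` = 0
    the recovered fold change is exact; otherwise iid Normal noise is added
    to every CT measurement.
    """
    for gene, fc in true_fold_changes.items():
        if fc <= 0:
            raise ValidationError(f"fold change for {gene!r} must be positive")
    rng = np.random.default_rng(child_seed(seed, "ct"))
    rows = []
    for condition in ("control", "treated"):
        for rep in range(1, n_replicates + 1):
            sample = f"{condition}_{rep}"
            rows.append((sample, condition, housekeeping_gene, housekeeping_ct))
            for gene, fc in true_fold_changes.items():
                ct = control_target_ct
                if condition == "treated":
                    ct -= np.log2(fc)
                rows.append((sample, condition, gene, ct))
    table = pd.DataFrame(rows, columns=["sample_id", "condition", "gene_id", "ct"])
    if noise_sd > 0:
        table["ct"] = table["ct"] + rng.normal(0.0, noise_sd, size=len(table))
    return table
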