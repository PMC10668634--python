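"""Bespoke quantifications: ddCT fold change, gated population fractions,
and 2x2 engraftment-count comparison.

ddCT relative quantification: per condition, dCT = CT(target) - CT(house-
keeping), with replicate CTs averaged first; ddCT = dCT(treated) -
dCT(control); fold change = 2^-ddCT.

Gating assigns every cell a population label from the sign pattern of its
marker intensities against fixed thresholds (no automatic gate inference,
mirroring manual cytometry gates) and reports counts and percentages.

Tumor-take comparisons use the two-sided Fisher exact test with a
Haldane-corrected odds ratio (0.5 added to every cell when any cell of the
2x2 table is zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

CT_MAX_CYCLES = 45.0
DEFAULT_HOUSEKEEPING = "GAPDH"


# ---------------------------------------------------------------------------
# ddCT
# ---------------------------------------------------------------------------


def _validate_ct_table(table: pd.DataFrame, housekeeping_gene: str) -> None:
    required = {"sample_id", "condition", "gene_id", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"CT table missing columns: {sorted(missing)}")
    bad = ~table["condition"].isin(["control", "treated"])
    if bad.any():
        raise ValidationError("condition must be 'control' or 'treated'")
    ct = table["ct"].to_numpy(dtype=float)
    if np.any((ct <= 0) | (ct >= CT_MAX_CYCLES)):
        raise ValidationError(f"CT values must lie in (0, {CT_MAX_CYCLES})")
    for condition in ("control", "treated"):
        sub = table[table["condition"] == condition]
        if not (sub["gene_id"] == housekeeping_gene).any():
            raise ValidationError(
                f"no housekeeping ({housekeeping_gene!r}) rows in {condition} condition"
            )


def fold_change(
    table: pd.DataFrame,
    target_gene: str,
    housekeeping_gene: str = DEFAULT_HOUSEKEEPING,
) -> float:
    """2^-ddCT fold change of ``target_gene``, treated over control."""
    _validate_ct_table(table, housekeeping_gene)
    dct = {}
    for condition in ("control", "treated"):
        sub = table[table["condition"] == condition]
        target = sub.loc[sub["gene_id"] == target_gene, "ct"]
        if target.empty:
            raise ValidationError(f"no {target_gene!r} rows in {condition} condition")
        housekeeping = sub.loc[sub["gene_id"] == housekeeping_gene, "ct"]
        dct[condition] = float(target.mean() - housekeeping.mean())
    ddct = dct["treated"] - dct["control"]
    return float(2.0 ** (-ddct))


def fold_changes(
    table: pd.DataFrame, housekeeping_gene: str = DEFAULT_HOUSEKEEPING
) -> pd.DataFrame:
    """Fold change for every non-housekeeping gene in the table."""
    genes = [g for g in table["gene_id"].unique() if g != housekeeping_gene]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "fold_change": [fold_change(table, g, housekeeping_gene) for g in genes],
        }
    )


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GateSpec:
    """Threshold gates on marker intensities.

    ``thresholds`` maps marker name to its positivity cutoff; ``rules``
    maps each +/- sign pattern (a tuple of booleans in sorted marker
    order) to a population label and must cover all 2^m patterns.
    """

    thresholds: Mapping[str, float]
    rules: Mapping[tuple[bool, ...], str]

    def __post_init__(self) -> None:
        thresholds = dict(self.thresholds)
        if not thresholds:
            raise ValidationError("gate needs at least one marker threshold")
        if not all(np.isfinite(list(thresholds.values()))):
            raise ValidationError("thresholds must be finite")
        m = len(thresholds)
        patterns = set(product([False, True], repeat=m))
        if set(self.rules) != patterns:
            raise ValidationError(
                f"label rules must cover all {2**m} sign patterns exactly"
            )
        object.__setattr__(self, "thresholds", thresholds)
        object.__setattr__(self, "rules", dict(self.rules))

    @property
    def markers(self) -> list[str]:
        return sorted(self.thresholds)


def two_marker_gatespec(
    marker_a: str = "PDPN",
    marker_b: str = "TdTm",
    threshold: float = 3.0,
    labels: Mapping[str, str] | None = None,
) -> GateSpec:
    """The standard dual-marker sort: A+B- / A-B+ / A+B+ / A-B-."""
    labels = labels or {
        "a_only": "typeI",
        "b_only": "typeII",
        "both": "dualpos",
        "neither": "negative",
    }
    a_first = sorted([marker_a, marker_b])[0] == marker_a

    def pattern(a_pos: bool, b_pos: bool) -> tuple[bool, ...]:
        return (a_pos, b_pos) if a_first else (b_pos, a_pos)

    return GateSpec(
        thresholds={marker_a: threshold, marker_b: threshold},
        rules={
            pattern(True, False): labels["a_only"],
            pattern(False, True): labels["b_only"],
            pattern(True, True): labels["both"],
            pattern(False, False): labels["neither"],
        },
    )


def single_marker_gatespec(
    marker: str = "Venus",
    threshold: float = 3.0,
    positive_label: str = "notch_pos",
    negative_label: str = "notch_neg",
) -> GateSpec:
    return GateSpec(
        thresholds={marker: threshold},
        rules={(True,): positive_label, (False,): negative_label},
    )


def gate_cells(cells: pd.DataFrame, gates: GateSpec) -> pd.DataFrame:
    """Label every cell by its gate pattern; tabulate counts and percentages.

    Returns a DataFrame indexed by population label with ``count`` and
    ``percent`` columns; percentages sum exactly to 100 (the last label
    absorbs the rounding-free remainder since no rounding is applied).
    """
    if len(cells) == 0:
        raise ValidationError("empty cell table")
    missing = [m for m in gates.markers if m not in cells.columns]
    if missing:
        raise KeyError(f"markers absent from cell table: {missing}")

    signs = np.column_stack(
        [cells[m].to_numpy(dtype=float) > gates.thresholds[m] for m in gates.markers]
    )
    labels = np.array(
        [gates.rules[tuple(row)] for row in signs.astype(bool)], dtype=object
    )
    label_order = list(dict.fromkeys(gates.rules.values()))
    counts = pd.Series(labels).value_counts()
    counts = counts.reindex(label_order, fill_value=0)
    out = pd.DataFrame(
        {
            "count": counts.astype(int),
            "percent": 100.0 * counts / len(cells),
        }
    )
    out.index.name = "population"
    return out


# ---------------------------------------------------------------------------
# 2x2 count comparison
# ---------------------------------------------------------------------------


def compare_fractions(
    a: tuple[int, int], b: tuple[int, int]
) -> tuple[float, float]:
    """Odds ratio (Haldane-corrected) and two-sided Fisher exact p.

    ``a`` and ``b`` are (successes, total) pairs — e.g. tumors formed per
    transplants carried out for two engrafted populations.
    """
    (ka, na), (kb, nb) = a, b
    for k, n in ((ka, na), (kb, nb)):
        if n < 1:
            raise ValidationError("totals must be >= 1")
        if not 0 <= k <= n:
            raise ValidationError("count must lie in [0, total]")
    table = np.array([[ka, na - ka], [kb, nb - kb]], dtype=float)
    _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    if (table == 0).any():
        table = table + 0.5
    odds_ratio = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(odds_ratio), float(p)
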