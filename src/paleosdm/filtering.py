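"""Environmental-space occurrence filtering and background/pseudo-absence draws.

Presence records harvested from collections and literature are spatially and
environmentally biased. The filter implemented here balances the *calibration*
set in environmental space: the axes named by the filter (by default
temperature seasonality bio4 and the wettest/driest-quarter precipitations
bio16/bio17, each with a width of 200 raw layer units) partition environmental
space into hyper-rectangular cells, and exactly one record per occupied cell —
picked uniformly at random under a logged seed — is kept for calibration.
Every record not selected goes to the *testing* set, which is what the
evaluation stage scores against an equal number of random pseudo-absences
(prevalence 0.5).

Cells are anchored at each filter variable's observed minimum: cell k along a
variable with width w covers ``[min + k*w, min + (k+1)*w)``. The calibration
count therefore equals the number of occupied environmental cells and does not
depend on the seed; only which record represents a cell does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import EnvSample, EnvStack, OccurrenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "FilterResult",
    "filter_environmental",
    "sample_background",
    "sample_pseudoabsences",
]


@dataclass(frozen=True)
class FilterSpec:
    """Environmental filter definition: one positive width per filter variable,
    in that variable's native units."""

    filter_variables: tuple[str, ...] = ("bio4", "bio16", "bio17")
    cell_widths: tuple[float, ...] = (200.0, 200.0, 200.0)
    seed: int = 0
    #: Optional fixed grid anchors, one per variable. When None (default) the
    #: anchor is each variable's observed minimum over the records being
    #: filtered. Fixed anchors make filtering exactly idempotent on its own
    #: calibration output; min-anchors re-derive the origin from the data.
    anchors: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.filter_variables) != len(self.cell_widths):
            raise ValueError("one cell width per filter variable required")
        if not self.filter_variables:
            raise ValueError("at least one filter variable required")
        if any(w <= 0 for w in self.cell_widths):
            raise ValueError("cell widths must be positive")
        if self.anchors is not None and len(self.anchors) != len(self.filter_variables):
            raise ValueError("one anchor per filter variable required")


@dataclass
class FilterResult:
    """Outcome of environmental filtering.

    ``cell_assignment`` maps each input record index to its environmental-cell
    index tuple (the audit trail behind the calibration/testing split).
    """

    calibration: OccurrenceSet
    testing: OccurrenceSet
    cell_assignment: dict[int, tuple[int, ...]]
    calibration_indices: list[int]
    testing_indices: list[int]
    anchors: tuple[float, ...] = ()

    @property
    def n_cells_occupied(self) -> int:
        return len(set(self.cell_assignment.values()))


def environmental_cells(
    env: EnvSample, spec: FilterSpec
) -> tuple[list[tuple[int, ...]], tuple[float, ...]]:
    """Environmental-cell index tuples for every row of ``env``, plus the
    anchors used.

    Cell index along each filter variable is ``floor((x - anchor) / width)``;
    the anchor is the variable's observed minimum unless the spec fixes it.
    """
    columns = []
    anchors = []
    for k, (var, width) in enumerate(zip(spec.filter_variables, spec.cell_widths)):
        x = env.column(var)
        anchor = float(x.min()) if spec.anchors is None else float(spec.anchors[k])
        anchors.append(anchor)
        idx = np.floor((x - anchor) / width).astype(int)
        columns.append(idx)
    cells = [tuple(int(col[i]) for col in columns) for i in range(len(env))]
    return cells, tuple(anchors)


def filter_environmental(
    env: EnvSample, occ: OccurrenceSet, spec: FilterSpec
) -> FilterResult:
    """Split ``occ`` into a balanced calibration set and a testing set.

    ``env`` rows must correspond one-to-one (and in order) with ``occ``
    records. One record per occupied environmental cell — chosen uniformly at
    random under ``spec.seed`` — is assigned to calibration; all remaining
    records go to testing.
    """
    if len(occ) == 0:
        raise ValueError("cannot filter an empty occurrence set")
    if len(env) != len(occ):
        raise ValueError(
            f"env sample has {len(env)} rows but occurrence set has {len(occ)} records"
        )
    cells, anchors = environmental_cells(env, spec)
    by_cell: dict[tuple[int, ...], list[int]] = {}
    for i, cell in enumerate(cells):
        by_cell.setdefault(cell, []).append(i)

    rng = np.random.default_rng(spec.seed)
    calibration_idx: list[int] = []
    # iterate cells in first-occurrence order for a stable, data-driven order
    for cell, members in by_cell.items():
        pick = members[int(rng.integers(len(members)))]
        calibration_idx.append(pick)
    calibration_set = set(calibration_idx)
    testing_idx = [i for i in range(len(occ)) if i not in calibration_set]
    logger.info(
        "environmental filter (seed=%d): %d records -> %d calibration (occupied cells), "
        "%d testing",
        spec.seed, len(occ), len(calibration_idx), len(testing_idx),
    )
    return FilterResult(
        calibration=occ.subset(sorted(calibration_idx), role="calibration"),
        testing=occ.subset(testing_idx, role="testing"),
        cell_assignment={i: cells[i] for i in range(len(occ))},
        calibration_indices=sorted(calibration_idx),
        testing_indices=testing_idx,
        anchors=anchors,
    )


def _sample_cells(stack: EnvStack, n: int, seed: int, kind: str) -> EnvSample:
    if n < 1:
        raise ValueError(f"{kind} sample size must be >= 1")
    rows, cols = stack.valid_cells()
    if rows.size == 0:
        raise ValueError("stack has no valid cells to sample from")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, rows.size, size=n)
    r, c = rows[pick], cols[pick]
    return EnvSample(
        point_ids=[f"{kind}{i}" for i in range(n)],
        matrix=stack.matrix_at_cells(r, c),
        variable_names=stack.layer_names,
        cell_rows=r,
        cell_cols=c,
    )


def sample_background(stack: EnvStack, n: int, seed: int) -> EnvSample:
    """Draw ``n`` background cells uniformly with replacement from the
    unmasked study extent and return their environment matrix."""
    return _sample_cells(stack, n, seed, "bg")


def sample_pseudoabsences(stack: EnvStack, n: int, seed: int) -> EnvSample:
    """Draw ``n`` pseudo-absence cells uniformly with replacement.

    Identical mechanics to :func:`sample_background`; kept as a distinct named
    operation because its count is tied to the testing-presence count so that
    evaluation runs at prevalence 0.5.
    """
    return _sample_cells(stack, n, seed, "pa")
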