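"""Experimental design: treatments, blocks and leaf-out groups.

The experiment manipulates the carbon source-sink balance of potted birch
saplings by removing a fixed percentage of leaves (carbon source) and/or
buds (carbon sink).  Eight treatments form two removal gradients plus a
combined arm and a control:

* 25 / 50 / 75 % leaf removal
* 25 / 50 / 75 % bud removal
* 50 % leaf + 50 % bud removal
* control (nothing removed)

Ten trees are assigned to every treatment and eleven to the control
(81 trees total).  Trees are arranged in ten spatial blocks holding one
tree per treatment; the extra control tree makes one block of nine.
Because the saplings differed in leaf-out stage at planting, each tree
carries one of five leaf-out groups, spread as evenly as arithmetic
allows within every treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TreatmentSpec", "TreatmentError", "TREATMENTS", "TreeRecord", "generate_design"]

_ALLOWED_PCT = (0, 25, 50, 75)


class TreatmentError(ValueError):
    """Raised for a treatment outside the experiment's removal grid."""


@dataclass(frozen=True)
class TreatmentSpec:
    """One removal treatment: percent of leaves and of buds removed."""

    name: str
    leaf_removal_pct: int
    bud_removal_pct: int

    def __post_init__(self) -> None:
        if self.leaf_removal_pct not in _ALLOWED_PCT or self.bud_removal_pct not in _ALLOWED_PCT:
            raise TreatmentError(
                f"removal percentages must be one of {_ALLOWED_PCT}, "
                f"got ({self.leaf_removal_pct}, {self.bud_removal_pct})"
            )


#: The eight treatments of the experiment, keyed by label.
TREATMENTS: dict[str, TreatmentSpec] = {
    t.name: t
    for t in (
        TreatmentSpec("control", 0, 0),
        TreatmentSpec("L25", 25, 0),
        TreatmentSpec("L50", 50, 0),
        TreatmentSpec("L75", 75, 0),
        TreatmentSpec("B25", 0, 25),
        TreatmentSpec("B50", 0, 50),
        TreatmentSpec("B75", 0, 75),
        TreatmentSpec("LB50", 50, 50),
    )
}

N_BLOCKS = 10
N_LEAFOUT_GROUPS = 5
N_PER_TREATMENT = 10
N_CONTROL = 11
N_TREES = 81


@dataclass(frozen=True)
class TreeRecord:
    """One experimental unit (a potted sapling) and its design assignment."""

    tree_id: str
    treatment: TreatmentSpec
    block_id: int
    leaf_out_group: int

    @property
    def leaf_removal_pct(self) -> int:
        return self.treatment.leaf_removal_pct

    @property
    def bud_removal_pct(self) -> int:
        return self.treatment.bud_removal_pct


def generate_design(seed: int) -> list[TreeRecord]:
    """Randomize the 81-tree design.

    Every treatment contributes one tree to each of the ten blocks; the
    eleventh control tree lands in a random block.  Leaf-out groups are
    balanced within treatment (two trees per group, a random third group
    for the extra control tree) and shuffled across blocks.

    Parameters
    ----------
    seed : int
        Seed for the block / leaf-out randomization.  The same seed
        always yields the same design.

    Returns
    -------
    list of TreeRecord
        81 records, ordered by treatment then block.
    """
    rng = np.random.default_rng(seed)
    records: list[TreeRecord] = []
    counter = 0
    for name, spec in TREATMENTS.items():
        n = N_CONTROL if name == "control" else N_PER_TREATMENT
        blocks = list(rng.permutation(np.arange(1, N_BLOCKS + 1)))
        if n == N_CONTROL:  # the extra control tree doubles up in one block
            blocks.append(int(rng.integers(1, N_BLOCKS + 1)))
        groups = [g for g in range(1, N_LEAFOUT_GROUPS + 1) for _ in range(2)]
        if n == N_CONTROL:
            groups.append(int(rng.integers(1, N_LEAFOUT_GROUPS + 1)))
        groups = list(rng.permutation(groups))
        for b, g in zip(blocks, groups):
            counter += 1
            records.append(
                TreeRecord(
                    tree_id=f"T{counter:02d}",
                    treatment=spec,
                    block_id=int(b),
                    leaf_out_group=int(g),
                )
            )
    assert len(records) == N_TREES
    return records


def design_frame(design: list[TreeRecord]) -> pd.DataFrame:
    """Tabulate a design as the ``trees.csv`` schema."""
    return pd.DataFrame(
        {
            "tree_id": [t.tree_id for t in design],
            "treatment": [t.treatment.name for t in design],
            "leaf_removal_pct": [t.leaf_removal_pct for t in design],
            "bud_removal_pct": [t.bud_removal_pct for t in design],
            "block_id": [t.block_id for t in design],
            "leaf_out_group": [t.leaf_out_group for t in design],
        }
    )


def design_from_frame(df: pd.DataFrame) -> list[TreeRecord]:
    """Rebuild TreeRecords from a ``trees.csv`` table."""
    out = []
    for row in df.itertuples(index=False):
        spec = TREATMENTS.get(row.treatment)
        if spec is None:
            spec = TreatmentSpec(row.treatment, int(row.leaf_removal_pct), int(row.bud_removal_pct))
        out.append(
            TreeRecord(
                tree_id=row.tree_id,
                treatment=spec,
                block_id=int(row.block_id),
                leaf_out_group=int(row.leaf_out_group),
            )
        )
    return out
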