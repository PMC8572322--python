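"""Burden-adjusted quadrant prioritization of front-line workers.

Each worker is placed in the (ability, adjusted burden) plane — ability is the
Rasch person parameter theta in logits, adjusted burden for their centre is
SAM + 0.5 x MAM (a moderately malnourished child weighted half a severely
malnourished one). Median splits on both axes define four segments:

    P1  low ability,  high burden   (priority)
    P2  low ability,  low burden    (priority)
    P3  high ability, high burden
    P4  high ability, low burden

Workers at or below a median fall on the "low" side of that axis, a
deterministic tie rule that errs toward supervision priority on the ability
axis. P1 and P2 are flagged as priority segments for supportive supervision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, UnmatchedWorkerError

__all__ = [
    "BurdenTable",
    "QuadrantAllocation",
    "adjusted_burden",
    "allocate_quadrants",
    "quadrant_plotdata",
]


def adjusted_burden(sam, mam, mam_weight: float = 0.5):
    """Weighted malnutrition burden: sam + mam_weight * mam.

    Accepts scalars or arrays; counts must be non-negative and the weight in
    [0, 1] (default 0.5, giving a MAM child half the weight of a SAM child).
    """
    sam_arr = np.asarray(sam, dtype=float)
    mam_arr = np.asarray(mam, dtype=float)
    if np.any(sam_arr < 0) or np.any(mam_arr < 0):
        raise DomainError("SAM/MAM counts must be non-negative")
    if not (0.0 <= mam_weight <= 1.0):
        raise DomainError("mam_weight must lie in [0, 1]")
    out = sam_arr + mam_weight * mam_arr
    return float(out) if out.ndim == 0 else out


@dataclass
class BurdenTable:
    """Per-centre SAM and MAM counts with the weighted total burden."""

    centre_ids: list
    sam_count: np.ndarray
    mam_count: np.ndarray
    mam_weight: float = 0.5

    def __post_init__(self) -> None:
        self.centre_ids = [str(c) for c in self.centre_ids]
        self.sam_count = np.asarray(self.sam_count, dtype=int)
        self.mam_count = np.asarray(self.mam_count, dtype=int)
        n = len(self.centre_ids)
        if self.sam_count.shape != (n,) or self.mam_count.shape != (n,):
            raise DomainError("count vectors must match the number of centres")
        if len(set(self.centre_ids)) != n:
            raise DomainError("centre ids are not unique")
        if np.any(self.sam_count < 0) or np.any(self.mam_count < 0):
            raise DomainError("SAM/MAM counts must be non-negative")

    @property
    def adjusted(self) -> np.ndarray:
        return adjusted_burden(self.sam_count, self.mam_count, self.mam_weight)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "centre_id": self.centre_ids,
                "sam": self.sam_count,
                "mam": self.mam_count,
                "adjusted_burden": self.adjusted,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mam_weight: float = 0.5) -> "BurdenTable":
        return cls(
            centre_ids=df["centre_id"].tolist(),
            sam_count=df["sam"].to_numpy(),
            mam_count=df["mam"].to_numpy(),
            mam_weight=mam_weight,
        )


@dataclass
class QuadrantAllocation:
    """Segment assignment of every worker plus the median cutoffs used.

    ``table`` columns: respondent_id, centre_id, ability, sam, mam,
    adjusted_burden, segment (P1-P4), priority (True for P1/P2).
    """

    table: pd.DataFrame
    ability_median: float
    burden_median: float

    def segment_counts(self) -> pd.Series:
        return (
            self.table["segment"]
            .value_counts()
            .reindex(["P1", "P2", "P3", "P4"], fill_value=0)
        )


_SEGMENTS = {
    (True, True): "P1",  # low ability, high burden
    (True, False): "P2",  # low ability, low burden
    (False, True): "P3",  # high ability, high burden
    (False, False): "P4",  # high ability, low burden
}


def allocate_quadrants(abilities, burdens: BurdenTable, join) -> QuadrantAllocation:
    """Assign each worker to a supervision segment by double median split.

    Parameters
    ----------
    abilities
        Mapping (dict or Series) respondent_id -> ability theta in logits.
    burdens
        Centre burden table.
    join
        Mapping respondent_id -> centre_id.

    Medians are computed over the allocated workers themselves. A worker at or
    below the ability median counts as low ability; at or below the burden
    median as low burden. Raises if any worker lacks a join entry or their
    centre lacks a burden record; warns when fewer than 4 workers make the
    quadrants degenerate.
    """
    abilities = pd.Series(dict(abilities) if not isinstance(abilities, pd.Series) else abilities)
    join = pd.Series(dict(join) if not isinstance(join, pd.Series) else join).astype(str)
    workers = abilities.index.astype(str)
    abilities.index = workers

    missing_join = [w for w in workers if w not in join.index]
    if missing_join:
        raise UnmatchedWorkerError(missing_join, what="centre mapping")
    bdf = burdens.to_dataframe().set_index("centre_id")
    centre = join.reindex(workers)
    missing_centre = [w for w, c in centre.items() if c not in bdf.index]
    if missing_centre:
        raise UnmatchedWorkerError(missing_centre, what="burden record")

    if len(workers) < 4:
        warnings.warn("fewer than 4 workers: quadrants are degenerate", UserWarning)

    burden = bdf["adjusted_burden"].reindex(centre.to_numpy()).to_numpy()
    theta = abilities.to_numpy(dtype=float)
    ability_median = float(np.median(theta))
    burden_median = float(np.median(burden))
    low_ability = theta <= ability_median
    high_burden = burden > burden_median
    segment = [_SEGMENTS[(la, hb)] for la, hb in zip(low_ability, high_burden)]
    table = pd.DataFrame(
        {
            "respondent_id": workers,
            "centre_id": centre.to_numpy(),
            "ability": theta,
            "sam": bdf["sam"].reindex(centre.to_numpy()).to_numpy(),
            "mam": bdf["mam"].reindex(centre.to_numpy()).to_numpy(),
            "adjusted_burden": burden,
            "segment": segment,
        }
    )
    table["priority"] = table["segment"].isin(["P1", "P2"])
    return QuadrantAllocation(
        table=table, ability_median=ability_median, burden_median=burden_median
    )


def quadrant_plotdata(allocation: QuadrantAllocation) -> pd.DataFrame:
    """Scatter data for the quadrant plot: x = adjusted burden, y = ability,
    colour keyed by SAM count, point size by MAM count, plus the two median
    reference lines repeated as constant columns for the renderer."""
    t = allocation.table
    return pd.DataFrame(
        {
            "respondent_id": t["respondent_id"],
            "x_adjusted_burden": t["adjusted_burden"],
            "y_ability": t["ability"],
            "colour_sam": t["sam"],
            "size_mam": t["mam"],
            "segment": t["segment"],
            "priority": t["priority"],
            "burden_median_line": allocation.burden_median,
            "ability_median_line": allocation.ability_median,
        }
    )
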