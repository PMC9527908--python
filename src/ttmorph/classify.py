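"""Tubule vs fragment classification by sarcolemmal connectivity.

A proper t-tubule is continuous with the sarcolemma and hence with
extracellular space; a *fragment* is a luminal remnant with no such
connection (electrically orphaned).  With label-volume input the
operational criterion is voxel connectivity: a component face-adjacent to
the extracellular partition is a tubule; an interior component touching
nothing is a fragment; a component whose only external contact is the
crop face is *indeterminate* — its connection status is unknowable within
the analysed portion.  (On greyscale EM, fragments are recognized by a
retained basement-membrane dark ring; with pre-segmented labels that
check is a labelling-time responsibility.)
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import MeasurementError
from .morphometry import TubuleComponent

__all__ = ["classify_component", "fragment_summary", "FragmentSummary"]


@dataclass(frozen=True)
class FragmentSummary:
    """Per-cell fragment aggregates."""

    cell_id: str
    fragment_count: int
    fragment_density: float            # µm⁻³
    mean_fragment_volume: float | None  # µm³; None when no fragments
    fragment_volume_fraction: float    # % of cell volume
    indeterminate_count: int = 0


def classify_component(component: TubuleComponent) -> str:
    """``tubule`` | ``fragment`` | ``indeterminate`` for one component.

    Invariant to voxel order and labelling: the decision uses only the
    connectivity flags set at labelling time.
    """
    if component.touches_extracellular:
        return "tubule"
    if component.touches_crop_boundary:
        return "indeterminate"
    return "fragment"


def fragment_summary(records: pd.DataFrame, cell_volume_um3: float,
                     cell_id: str = "") -> FragmentSummary:
    """Fragment count, density, mean volume and volume fraction for one cell.

    Indeterminate components are excluded from every fragment statistic
    and reported separately.
    """
    if cell_volume_um3 <= 0:
        raise MeasurementError("cell volume must be positive")
    if len(records):
        frag = records[records["class"] == "fragment"]
        indet = int((records["class"] == "indeterminate").sum())
    else:
        frag = records
        indet = 0
    n = int(len(frag))
    total_v = float(frag["volume_um3"].sum()) if n else 0.0
    return FragmentSummary(
        cell_id=cell_id,
        fragment_count=n,
        fragment_density=n / cell_volume_um3,
        mean_fragment_volume=(total_v / n) if n else None,
        fragment_volume_fraction=total_v / cell_volume_um3 * 100.0,
        indeterminate_count=indet,
    )
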