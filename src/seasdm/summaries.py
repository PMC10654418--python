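"""Area summaries over stacked binary distribution maps.

Per-species distribution area, the split of each species' area into
cells it occupies alone versus together with at least one other studied
species, and the group co-habitation breakdown of occupied cells (both
groups present / angiosperms only / charophytes only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import ANGIOSPERM, CHAROPHYTE


@dataclass
class BinaryMapStack:
    """Aligned per-species binary presence grids sharing one valid-data
    mask; cells outside the mask never count as presence or absence."""

    maps: dict[str, np.ndarray]
    cell_size: float
    mask: np.ndarray | None = None
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError(f"maps are not aligned: shapes {shapes}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        shape = next(iter(shapes)) if shapes else None
        if self.mask is None and shape is not None:
            # NaN anywhere marks no-data
            self.mask = ~np.any([np.isnan(np.asarray(m, dtype=float)) for m in self.maps.values()], axis=0)
        if self.mask is not None and shape is not None and self.mask.shape != shape:
            raise ValueError("mask shape does not match maps")

    @property
    def species(self) -> list[str]:
        return list(self.maps)

    def presence(self, species: str) -> np.ndarray:
        """Boolean presence inside the mask."""
        arr = np.asarray(self.maps[species], dtype=float)
        return (arr == 1) & self.mask


def distribution_area(binary_map: np.ndarray, cell_size: float) -> float:
    """Area in km^2 of the presence cells of one binary map (NaN = no
    data, never counted)."""
    arr = np.asarray(binary_map, dtype=float)
    n = int(np.nansum(arr == 1))
    return n * cell_size**2 / 1e6


def single_vs_multi_area(stack: BinaryMapStack) -> pd.DataFrame:
    """Per species: area occupied alone vs together with >= 1 other
    studied species; the two parts sum exactly to the total area."""
    if len(stack.maps) < 2:
        raise ValueError("need at least two species to partition areas")
    presence = {s: stack.presence(s) for s in stack.species}
    total_count = np.sum(list(presence.values()), axis=0)
    cell_km2 = stack.cell_size**2 / 1e6
    rows = []
    for s, pres in presence.items():
        alone = int((pres & (total_count == 1)).sum())
        multi = int((pres & (total_count > 1)).sum())
        alone_km2 = alone * cell_km2
        multi_km2 = multi * cell_km2
        rows.append({
            "species": s,
            # total as the sum of the parts keeps the partition identity
            # exact in floating point
            "total_km2": alone_km2 + multi_km2,
            "alone_km2": alone_km2,
            "co_occurring_km2": multi_km2,
        })
    return pd.DataFrame(rows).set_index("species")


def cohabitation_breakdown(
    stack: BinaryMapStack,
    groups: dict[str, str] | None = None,
    denominator: str = "occupied",
) -> dict[str, float | str]:
    """Fractions of cells occupied by both groups / only angiosperms /
    only charophytes.

    With the default ``denominator="occupied"`` the three fractions
    partition the occupied cells and sum to 1; ``denominator="valid"``
    divides by every valid cell of the modeling area instead (the three
    fractions then sum to the occupied share).
    """
    groups = groups or stack.groups
    missing = [s for s in stack.species if s not in groups]
    if missing:
        raise ValueError(f"species without a group label: {missing}")
    if denominator not in ("occupied", "valid"):
        raise ValueError("denominator must be 'occupied' or 'valid'")
    any_angio = np.zeros_like(stack.mask, dtype=bool)
    any_charo = np.zeros_like(stack.mask, dtype=bool)
    for s in stack.species:
        if groups[s] == ANGIOSPERM:
            any_angio |= stack.presence(s)
        elif groups[s] == CHAROPHYTE:
            any_charo |= stack.presence(s)
        else:
            raise ValueError(f"unknown group {groups[s]!r} for {s}")
    occupied = any_angio | any_charo
    if not occupied.any():
        raise ValueError("no occupied cells; breakdown undefined")
    denom = int(occupied.sum()) if denominator == "occupied" else int(stack.mask.sum())
    return {
        "both_groups": int((any_angio & any_charo).sum()) / denom,
        "angiosperms_only": int((any_angio & ~any_charo).sum()) / denom,
        "charophytes_only": int((any_charo & ~any_angio).sum()) / denom,
        "denominator": denominator,
    }
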