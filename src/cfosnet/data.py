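"""Activation-matrix data model, readers/writers and IC/TA normalization.

The central object is :class:`ActivationMatrix`: one row per individual, one
column per brain region, cells holding the normalized activation measure
IC/TA — the number of c-fos immunopositive cells counted over a 10,000 μm²
sampled area, divided by the total area (μm²) of the analysed brain-hemisphere
section.  IC/TA therefore carries units of cells·μm⁻² and realistic values sit
around 10⁻⁴.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical telencephalic nuclei, in display order
DEFAULT_REGIONS = ("Vv", "Vd", "Dm", "Dl")
#: canonical treatment groups and sizes of the study design
DEFAULT_GROUP_SIZES = {"NAE": 6, "OR": 6, "OnR": 9}

LONG_COLUMNS = ("individual_id", "group", "region")


class DataError(ValueError):
    """Malformed or inconsistent activation-table input."""


def normalize_ic_ta(ic_count: float, hemisphere_area: float) -> float:
    """Normalize an immunopositive-cell count by hemisphere total area.

    Parameters
    ----------
    ic_count
        Nonnegative number of c-fos immunopositive cells summed over the
        sampled 10,000 μm² of a region.
    hemisphere_area
        Positive total area of the analysed hemisphere section, in μm².

    Returns
    -------
    float
        IC/TA in cells·μm⁻².
    """
    if hemisphere_area <= 0:
        raise DataError(f"hemisphere_area must be positive, got {hemisphere_area}")
    if ic_count < 0:
        raise DataError(f"ic_count must be nonnegative, got {ic_count}")
    return ic_count / hemisphere_area


@dataclass
class StudyDesign:
    """Group sizes and region order of an activation study."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    region_names: tuple[str, ...] = DEFAULT_REGIONS

    @property
    def n_individuals(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_sizes)


@dataclass
class ActivationMatrix:
    """Individuals × regions table of IC/TA values with group labels.

    ``data`` is a complete numeric DataFrame indexed by individual id with one
    column per region; ``groups`` maps each individual (same index) to its
    treatment label.  Region order is fixed at construction and preserved by
    every pipeline stage.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            raise DataError("data and groups must share one individual index")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"duplicate individual {dup!r}")
        if self.data.isna().any().any():
            bad = self.data.isna().stack()
            ind, reg = bad[bad].index[0]
            raise DataError(f"missing cell for individual {ind!r}, region {reg!r}")
        if (self.data.to_numpy() < 0).any():
            raise DataError("negative activation value")
        counts = self.groups.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise DataError(
                f"every group needs >= 2 members; too small: {dict(small)}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def individuals(self) -> list[str]:
        return list(self.data.index)

    @property
    def regions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def group_labels(self) -> list[str]:
        """Group names in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.groups == g).sum()) for g in self.group_labels}

    def group_values(self, group: str) -> pd.DataFrame:
        if group not in set(self.groups):
            raise DataError(f"unknown group {group!r}")
        return self.data.loc[self.groups == group]

    # -- operations --------------------------------------------------------
    def subset_by_groups(self, keep) -> "ActivationMatrix":
        """Row-subset to the given group labels, preserving order."""
        keep = set(keep)
        unknown = keep - set(self.groups)
        if unknown:
            raise DataError(f"unknown group label(s): {sorted(unknown)}")
        mask = self.groups.isin(keep)
        return ActivationMatrix(self.data.loc[mask].copy(), self.groups.loc[mask].copy())

    def to_wide_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "group", self.groups)
        out.index.name = "individual_id"
        return out

    def write_csv(self, path) -> None:
        """Write the wide CSV schema; IC/TA values round-trip bit-exactly."""
        self.to_wide_frame().to_csv(path, float_format="%.17g")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")


def _check_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DataError(f"{path}: non-numeric {col!r} at data row {row}")
    neg = vals < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0])
        raise DataError(f"{path}: negative {col!r} at data row {row}")
    return vals


def load_activation_table(
    path,
    schema: str = "long",
    region_order=None,
    on_incomplete: str = "drop",
) -> ActivationMatrix:
    """Read a long or wide activation CSV into an :class:`ActivationMatrix`.

    Long schema: ``individual_id, group, region, ic_count,
    hemisphere_area_um2`` (or a precomputed ``ic_ta`` column); IC/TA
    normalization is applied when the raw columns are present.  Wide schema:
    ``individual_id, group`` plus one numeric column per region.

    Individuals with any missing region are dropped with a logged warning by
    default (the multivariate stages need complete rows and n is too small to
    impute); pass ``on_incomplete="error"`` to fail instead.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if schema == "long":
        _require_columns(df, LONG_COLUMNS, path)
        dup = df.duplicated(subset=["individual_id", "region"])
        if dup.any():
            r = df.loc[dup, ["individual_id", "region"]].iloc[0]
            raise DataError(
                f"{path}: duplicate entry for individual {r['individual_id']!r}, "
                f"region {r['region']!r}"
            )
        if "ic_ta" in df.columns:
            icta = _check_numeric(df, "ic_ta", path)
        else:
            _require_columns(df, ("ic_count", "hemisphere_area_um2"), path)
            counts = _check_numeric(df, "ic_count", path)
            areas = _check_numeric(df, "hemisphere_area_um2", path)
            if (areas <= 0).any():
                row = int(np.flatnonzero(areas <= 0)[0])
                raise DataError(f"{path}: non-positive hemisphere area at data row {row}")
            icta = counts / areas
        work = df[["individual_id", "group", "region"]].copy()
        work["ic_ta"] = icta
        regions = list(region_order) if region_order is not None else list(
            dict.fromkeys(work["region"])
        )
        unknown = set(work["region"]) - set(regions)
        if unknown:
            raise DataError(f"{path}: unknown region name(s) {sorted(unknown)}")
        wide = work.pivot(index="individual_id", columns="region", values="ic_ta")
        wide = wide.reindex(index=list(dict.fromkeys(work["individual_id"])), columns=regions)
        groups = work.drop_duplicates("individual_id").set_index("individual_id")["group"]
        groups = groups.reindex(wide.index)
    else:
        if schema != "wide":
            raise DataError(f"unknown schema {schema!r}; expected 'long' or 'wide'")
        _require_columns(df, ("individual_id", "group"), path)
        if df["individual_id"].duplicated().any():
            dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise DataError(f"{path}: duplicate individual {dup!r}")
        region_cols = [c for c in df.columns if c not in ("individual_id", "group")]
        if region_order is not None:
            unknown = set(region_cols) - set(region_order)
            if unknown:
                raise DataError(f"{path}: unknown region name(s) {sorted(unknown)}")
            region_cols = [r for r in region_order if r in region_cols]
        for c in region_cols:
            _check_numeric(df, c, path)
        wide = df.set_index("individual_id")[region_cols].astype(float)
        groups = df.set_index("individual_id")["group"]

    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        detail = {
            str(ind): [r for r in wide.columns if pd.isna(wide.loc[ind, r])]
            for ind in wide.index[incomplete]
        }
        if on_incomplete == "error":
            ind, regs = next(iter(detail.items()))
            raise DataError(f"{path}: missing cell for individual {ind!r}, region(s) {regs}")
        logger.warning("dropping incomplete individuals: %s", detail)
        wide = wide.loc[~incomplete]
        groups = groups.loc[~incomplete]

    wide.columns.name = None
    return ActivationMatrix(wide, groups.rename("group"))
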