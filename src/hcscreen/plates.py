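"""384-/96-well plate arm: layouts, dilution accounting, and normalization.

The screen reads each plate twice — an immunostain read (target-protein
fluorescence) and a viability read (alamarBlue-style resazurin reduction) —
and anchors both to in-plate controls:

* cell controls (DMSO only) anchor the baseline immunostain signal,
* positive controls (ALLN, a proteasome inhibitor) anchor the raised signal,
* viability controls (Hyamine) anchor zero viability.

Per-well scores are then

.. math::

    \\text{fold increase} = \\frac{\\text{DataValue}}{\\mathrm{median}\\ \\text{cell control}}

    \\%\\ \\text{viability} = 100 \\cdot
        \\frac{\\text{DataValue} - \\mathrm{median}\\ \\text{Hyamine}}
             {\\mathrm{median}\\ \\text{cell control} - \\mathrm{median}\\ \\text{Hyamine}}

    \\text{normalized fold increase} = \\frac{\\text{fold increase}}{\\text{viability (fraction)}}

Medians are plate-local; all normalization is relative to controls on the
same plate.  Values below the Hyamine median give negative viability, which
is reported, not clipped.  Division by near-zero viability is guarded by a
configurable floor (default 0.1, i.e. 10%): wells below it get a missing
normalized fold increase with the raw ratio retained in an auxiliary
column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LayoutError, NormalizationError, ParameterError
from .wells import normalize_well

logger = logging.getLogger(__name__)

ROLES = ("cell_control", "positive_control", "viability_control", "test")
CONTROL_ROLES = ("cell_control", "positive_control", "viability_control")

LAYOUT_COLUMNS = ["well", "role", "compound_id", "concentration"]
READ_COLUMNS = ["well", "value"]


@dataclass
class PlateLayout:
    """Well-role map of one plate.

    ``table`` is indexed by canonical well name with columns ``role``,
    ``compound_id`` and ``concentration`` (test wells carry a compound ID;
    control wells have an empty one).
    """

    plate_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "well" in t.columns:
            t = t.set_index("well")
        t.index = [normalize_well(w) for w in t.index]
        t.index.name = "well"
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].unique().tolist()
            raise LayoutError(f"plate {self.plate_id}: duplicate wells {dup}")
        bad_roles = set(t["role"]) - set(ROLES)
        if bad_roles:
            raise LayoutError(f"plate {self.plate_id}: unknown roles {sorted(bad_roles)}")
        for role in CONTROL_ROLES:
            n = int((t["role"] == role).sum())
            if n < 2:
                raise LayoutError(
                    f"plate {self.plate_id}: needs >=2 wells with role {role!r}, found {n}"
                )
        if "compound_id" not in t.columns:
            t["compound_id"] = ""
        t["compound_id"] = t["compound_id"].fillna("")
        is_test = t["role"] == "test"
        if (is_test & (t["compound_id"] == "")).any():
            missing = t.index[is_test & (t["compound_id"] == "")].tolist()
            raise LayoutError(f"plate {self.plate_id}: test wells without compound_id: {missing}")
        if "concentration" not in t.columns:
            t["concentration"] = np.nan
        self.table = t[["role", "compound_id", "concentration"]]

    @property
    def wells(self) -> list[str]:
        return self.table.index.tolist()

    def wells_with_role(self, role: str) -> list[str]:
        return self.table.index[self.table["role"] == role].tolist()

    @classmethod
    def from_csv(cls, path: str | Path, plate_id: str | None = None) -> "PlateLayout":
        df = pd.read_csv(path, dtype={"well": str, "role": str, "compound_id": str})
        return cls(plate_id or Path(path).stem, df)

    def to_csv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, index=False)


@dataclass
class PlateRead:
    """One plate-reader pass: a well -> DataValue (AFU) mapping."""

    plate_id: str
    read_kind: str  # "immunostain" or "viability"
    values: pd.Series

    def __post_init__(self) -> None:
        if self.read_kind not in ("immunostain", "viability"):
            raise ParameterError(f"unknown read_kind {self.read_kind!r}")
        s = pd.Series(self.values, dtype=float)
        s.index = [normalize_well(w) for w in s.index]
        s.index.name = "well"
        if s.index.has_duplicates:
            raise ParameterError(f"plate {self.plate_id}: duplicate wells in {self.read_kind} read")
        if (s.dropna() < 0).any():
            raise ParameterError(
                f"plate {self.plate_id}: negative values in {self.read_kind} read"
            )
        self.values = s

    @classmethod
    def from_csv(
        cls, path: str | Path, read_kind: str, plate_id: str | None = None
    ) -> "PlateRead":
        df = pd.read_csv(path, dtype={"well": str})
        s = pd.Series(df["value"].to_numpy(float), index=df["well"])
        return cls(plate_id or Path(path).stem, read_kind, s)

    def to_csv(self, path: str | Path) -> None:
        self.values.rename("value").reset_index().to_csv(path, index=False)


def _control_median(values: list | np.ndarray, what: str, plate_id: str) -> float:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise NormalizationError(f"plate {plate_id}: no usable {what} values")
    return float(np.median(arr))


def fold_increase(value, cell_control_values, plate_id: str = "?"):
    """DataValue divided by the median of same-plate cell-control wells.

    Accepts a scalar or array ``value``.  The median uses the standard
    midpoint rule for even counts.  A non-positive control median cannot
    anchor the scale and raises :class:`NormalizationError`.
    """
    med = _control_median(cell_control_values, "cell-control", plate_id)
    if med <= 0:
        raise NormalizationError(
            f"plate {plate_id}: cell-control median {med} is not positive"
        )
    return np.asarray(value, dtype=float) / med if np.ndim(value) else float(value) / med


def viability(value, hyamine_values, cell_control_values, plate_id: str = "?"):
    """Percent and fractional viability anchored to Hyamine (0%) and cell controls (100%).

    Returns ``(percent, fraction)``; fraction = percent / 100.  Values below
    the Hyamine median yield negative viability, reported as-is.
    """
    med_hya = _control_median(hyamine_values, "Hyamine-control", plate_id)
    med_cell = _control_median(cell_control_values, "cell-control", plate_id)
    if med_cell == med_hya:
        raise NormalizationError(
            f"plate {plate_id}: cell-control and Hyamine medians are equal ({med_cell}); "
            "viability anchors degenerate"
        )
    v = np.asarray(value, dtype=float) if np.ndim(value) else float(value)
    fraction = (v - med_hya) / (med_cell - med_hya)
    return 100.0 * fraction, fraction


def normalized_fold_increase(fold, viability_fraction, floor: float = 0.1):
    """Fold increase divided by fractional viability, with a low-viability guard.

    Returns ``(guarded, raw)``: ``raw`` is the plain ratio; ``guarded``
    is NaN wherever viability is at or below ``floor`` (default 10%), since
    dividing by near-zero viability amplifies dead-well noise without
    bound.  Non-positive viability always yields a NaN guarded value and a
    NaN raw ratio (the ratio is meaningless below the death anchor).
    """
    if floor < 0:
        raise ParameterError(f"viability floor must be >= 0, got {floor}")
    f = np.asarray(fold, dtype=float)
    v = np.asarray(viability_fraction, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(v > 0, f / v, np.nan)
    guarded = np.where(v > floor, raw, np.nan)
    if np.ndim(fold) == 0 and np.ndim(viability_fraction) == 0:
        return float(guarded), float(raw)
    return guarded, raw


@dataclass(frozen=True)
class DilutionStep:
    """One dilution: either an overall factor or a transfer into a receiving volume.

    ``dilution_factor`` divides the concentration by that factor;
    alternatively ``transfer_volume`` into ``receiving_volume`` multiplies
    it by transfer / (transfer + receiving).  Volumes share any one unit.
    """

    dilution_factor: float | None = None
    transfer_volume: float | None = None
    receiving_volume: float | None = None

    def __post_init__(self) -> None:
        by_factor = self.dilution_factor is not None
        by_volume = self.transfer_volume is not None or self.receiving_volume is not None
        if by_factor == by_volume:
            raise ParameterError(
                "DilutionStep needs exactly one of dilution_factor or "
                "transfer_volume+receiving_volume"
            )
        if by_factor and self.dilution_factor <= 0:
            raise ParameterError(f"dilution_factor must be positive, got {self.dilution_factor}")
        if by_volume:
            if self.transfer_volume is None or self.receiving_volume is None:
                raise ParameterError("transfer_volume and receiving_volume must both be given")
            if self.transfer_volume <= 0 or self.receiving_volume <= 0:
                raise ParameterError("transfer and receiving volumes must be positive")

    def apply(self, concentration: float) -> float:
        if self.dilution_factor is not None:
            return concentration / self.dilution_factor
        return concentration * self.transfer_volume / (self.transfer_volume + self.receiving_volume)


def final_concentration(stock_concentration: float, steps: list[DilutionStep]) -> float:
    """Concentration after applying dilution steps in sequence.

    Example: a 10 mM stock diluted 500-fold and then added in equal volume
    gives 10000/500/2 = 10 uM.
    """
    if stock_concentration <= 0:
        raise ParameterError(f"stock concentration must be positive, got {stock_concentration}")
    conc = float(stock_concentration)
    for step in steps:
        conc = step.apply(conc)
    return conc


#: dilution scheme of the imaging screen: 10 mM stock, 500-fold, equal volume
IMAGING_SCREEN_DILUTION = [
    DilutionStep(dilution_factor=500),
    DilutionStep(transfer_volume=1, receiving_volume=1),
]

#: dilution scheme of the plate screen: 150 uM working solution, 5 ul into 25 ul
PLATE_SCREEN_DILUTION = [DilutionStep(transfer_volume=5, receiving_volume=25)]


SCORE_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "compound_id",
    "concentration",
    "stain_value",
    "viability_value",
    "fold_increase",
    "viability_percent",
    "viability_fraction",
    "normalized_fold_increase",
    "normalized_fold_increase_raw",
    "flag",
]


def score_plate(
    layout: PlateLayout,
    immunostain: PlateRead,
    viability_read: PlateRead,
    viability_floor: float = 0.1,
) -> pd.DataFrame:
    """Score every well of one plate against its in-plate controls.

    Returns one row per layout well (test wells and controls alike, the
    latter kept for QC) with the three normalized readouts.  Wells missing
    from either read are flagged and excluded from the control medians;
    their own scores are NaN.
    """
    extra = set(immunostain.values.index) | set(viability_read.values.index)
    extra -= set(layout.wells)
    if extra:
        raise LayoutError(
            f"plate {layout.plate_id}: read wells not in layout: {sorted(extra)}"
        )
    stain = immunostain.values.reindex(layout.wells)
    viab = viability_read.values.reindex(layout.wells)
    usable = stain.notna() & viab.notna()

    cc_wells = layout.wells_with_role("cell_control")
    hy_wells = layout.wells_with_role("viability_control")
    cc_stain = stain[cc_wells][usable[cc_wells]]
    cc_viab = viab[cc_wells][usable[cc_wells]]
    hy_viab = viab[hy_wells][usable[hy_wells]]

    fold = fold_increase(stain.to_numpy(), cc_stain.to_numpy(), layout.plate_id)
    viab_pct, viab_frac = viability(
        viab.to_numpy(), hy_viab.to_numpy(), cc_viab.to_numpy(), layout.plate_id
    )
    nfi, nfi_raw = normalized_fold_increase(fold, viab_frac, viability_floor)

    flag = np.where(usable, "", "missing_read")
    n_missing = int((~usable).sum())
    if n_missing:
        missing_wells = stain.index[~usable].tolist()
        logger.warning(
            "plate %s: %d wells missing a read, flagged: %s",
            layout.plate_id,
            n_missing,
            missing_wells,
        )
    low_viab = usable.to_numpy() & (viab_frac <= viability_floor)
    flag = np.where(low_viab, "low_viability", flag)

    out = pd.DataFrame(
        {
            "plate_id": layout.plate_id,
            "well": layout.wells,
            "role": layout.table["role"].to_numpy(),
            "compound_id": layout.table["compound_id"].to_numpy(),
            "concentration": layout.table["concentration"].to_numpy(),
            "stain_value": stain.to_numpy(),
            "viability_value": viab.to_numpy(),
            "fold_increase": fold,
            "viability_percent": viab_pct,
            "viability_fraction": viab_frac,
            "normalized_fold_increase": nfi,
            "normalized_fold_increase_raw": nfi_raw,
            "flag": flag,
        },
        columns=SCORE_COLUMNS,
    )
    out.loc[~usable.to_numpy(), ["fold_increase", "viability_percent", "viability_fraction",
                                 "normalized_fold_increase", "normalized_fold_increase_raw"]] = np.nan
    return out
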