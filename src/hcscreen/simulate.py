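"""Ground-truthed synthetic inputs for both screening arms.

No dataset from the original screens is available, so this module stands in
for the instruments: it renders two-channel microscope fields with known
per-compartment intensities, and draws 384-/96-well plate reads with known
control separations and spiked hit compounds.  Every generated object is
returned together with its ground truth, so each downstream stage can be
tested against exact expected values.

Cells are rendered as concentric disks — nucleus, perinuclear band,
cytoplasm, plasma-membrane band — so the compartment geometry matches the
analysis ROIs by construction and noiseless parameter-recovery tests are
exact rather than approximate.  The DNA-stain channel mimics a DRAQ5-style
dye: bright nuclei over a dim cytoplasmic stain, enabling two-level
thresholding downstream.  Noise is additive Gaussian, clipped at zero
(Poisson/optics realism is a non-goal).

Reproducibility: a single ``seed`` governs each simulator through a fixed
sub-seeding rule — ``default_rng([seed, k])`` with k = 0 for cell
placement, k = 1 for image noise, and k = 2 for plate noise — so placement
is unchanged when only the noise level changes.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile

from .errors import LayoutError, ParameterError, PlacementError
from .imaging import CellRecord, FieldImage, _STRUCTS
from .plates import PlateLayout, PlateRead
from .wells import PLATE_DIMS, well_name

logger = logging.getLogger(__name__)

_PLACE, _IMG_NOISE, _PLATE_NOISE = 0, 1, 2


@dataclass(frozen=True)
class ImageSimSpec:
    """Parameters of one simulated microscope field.

    Intensities are in arbitrary fluorescence units (AFU).  The target
    channel paints ``intensity_cytoplasm`` over the cell disk, then the
    perinuclear band, then the plasma-membrane band (PM wins any overlap);
    the DNA-stain channel paints ``cyto_stain`` over the cell disk and
    ``nucleus_stain`` over the nucleus.
    """

    field_shape: tuple[int, int] = (256, 256)
    n_cells: int = 25
    nucleus_radius: float = 5.0
    cell_radius: float = 14.0
    intensity_pm: float = 500.0
    intensity_perinuclear: float = 300.0
    intensity_cytoplasm: float = 100.0
    intensity_background: float = 5.0
    nucleus_stain: float = 1000.0
    cyto_stain: float = 200.0
    stain_background: float = 2.0
    noise_sd: float = 20.0
    pm_width: int = 2
    perinuclear_width: int = 5
    allow_border: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.cell_radius > self.nucleus_radius > 0):
            raise ParameterError(
                f"need cell_radius > nucleus_radius > 0, got "
                f"{self.cell_radius} / {self.nucleus_radius}"
            )
        for name in (
            "intensity_pm",
            "intensity_perinuclear",
            "intensity_cytoplasm",
            "intensity_background",
            "nucleus_stain",
            "cyto_stain",
            "stain_background",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.pm_width <= 0 or self.perinuclear_width <= 0:
            raise ParameterError("ring widths must be positive")
        if len(self.field_shape) != 2 or min(self.field_shape) < 1:
            raise ParameterError(f"bad field_shape {self.field_shape}")


@dataclass
class FieldGroundTruth:
    """Exact masks and per-compartment means used to paint a simulated field."""

    centers: np.ndarray  # (n_cells, 2) row/col
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    pm_labels: np.ndarray
    perinuclear_labels: np.ndarray
    records: list[CellRecord]

    def to_frame(self) -> pd.DataFrame:
        from .imaging import cell_records_to_frame

        df = cell_records_to_frame(self.records)
        df.insert(3, "center_row", self.centers[:, 0])
        df.insert(4, "center_col", self.centers[:, 1])
        return df


def _place_centers(spec: ImageSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping cell centers.

    Centers keep Euclidean distance >= 2*cell_radius + 2 from each other
    (at least one background pixel between cells, so segmentation can
    separate them) and, unless ``allow_border``, stay cell_radius + 1 away
    from the field border.
    """
    n_rows, n_cols = spec.field_shape
    margin = 0.0 if spec.allow_border else spec.cell_radius + 1
    lo_r, hi_r = margin, n_rows - 1 - margin
    lo_c, hi_c = margin, n_cols - 1 - margin
    if spec.n_cells > 0 and (hi_r < lo_r or hi_c < lo_c):
        raise PlacementError(
            f"field {spec.field_shape} too small for cells of radius {spec.cell_radius} "
            f"with border margin {margin}"
        )
    min_sep = 2 * spec.cell_radius + 2
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 1000 * max(spec.n_cells, 1)
    while len(centers) < spec.n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {spec.n_cells} non-overlapping cells of radius "
                f"{spec.cell_radius} on a {spec.field_shape} field after {attempts} "
                f"attempts (min center separation {min_sep} px)"
            )
        attempts += 1
        # integer centers: every cell has identical pixel geometry, so the
        # painted compartment means do not depend on placement
        r = float(rng.integers(int(np.ceil(lo_r)), int(np.floor(hi_r)) + 1))
        c = float(rng.integers(int(np.ceil(lo_c)), int(np.floor(hi_c)) + 1))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((float(r), float(c)))
    return np.array(centers, dtype=float).reshape(spec.n_cells, 2)


def _measure(target: np.ndarray, roi: np.ndarray) -> tuple[float, int, float]:
    sel = target[roi]
    if sel.size == 0:
        return float("nan"), 0, float("nan")
    return float(sel.mean()), int(sel.size), float(sel.sum())


def simulate_field(
    spec: ImageSimSpec, well_id: str = "A01", field_index: int = 0
) -> tuple[FieldImage, FieldGroundTruth]:
    """Render one two-channel field and return it with its exact ground truth.

    Ground-truth per-cell means are measured from the painted noiseless
    target channel over the painted compartment masks, so they remain exact
    even where compartments overlap; increasing ``noise_sd`` changes only
    the rendered image, never the ground truth.  Bit-reproducible for a
    fixed seed.
    """
    rng_place = np.random.default_rng([spec.seed, _PLACE])
    rng_noise = np.random.default_rng([spec.seed, _IMG_NOISE])
    centers = _place_centers(spec, rng_place)

    n_rows, n_cols = spec.field_shape
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    nucleus_labels = np.zeros(spec.field_shape, dtype=np.int32)
    cell_labels = np.zeros(spec.field_shape, dtype=np.int32)
    pm_labels = np.zeros(spec.field_shape, dtype=np.int32)
    peri_labels = np.zeros(spec.field_shape, dtype=np.int32)

    struct = _STRUCTS["chebyshev"]
    for lab, (cr, cc) in enumerate(centers, start=1):
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        cell = d2 <= spec.cell_radius**2
        nucleus = d2 <= spec.nucleus_radius**2
        interior = ndi.binary_erosion(cell, structure=struct, iterations=spec.pm_width,
                                      border_value=0)
        halo = ndi.binary_dilation(nucleus, structure=struct,
                                   iterations=spec.perinuclear_width, border_value=0)
        cell_labels[cell] = lab
        nucleus_labels[nucleus] = lab
        pm_labels[cell & ~interior] = lab
        peri_labels[halo & ~nucleus & cell] = lab

    target = np.full(spec.field_shape, spec.intensity_background, dtype=float)
    target[cell_labels > 0] = spec.intensity_cytoplasm
    target[peri_labels > 0] = spec.intensity_perinuclear
    target[pm_labels > 0] = spec.intensity_pm
    nuclear = np.full(spec.field_shape, spec.stain_background, dtype=float)
    nuclear[cell_labels > 0] = spec.cyto_stain
    nuclear[nucleus_labels > 0] = spec.nucleus_stain

    records: list[CellRecord] = []
    for lab in range(1, spec.n_cells + 1):
        mean_pm, area_pm, _ = _measure(target, pm_labels == lab)
        mean_peri, area_peri, _ = _measure(target, peri_labels == lab)
        mean_tot, area_tot, sum_tot = _measure(target, cell_labels == lab)
        records.append(
            CellRecord(
                cell_id=lab,
                mean_pm=mean_pm,
                mean_perinuclear=mean_peri,
                mean_total=mean_tot,
                area_pm=area_pm,
                area_perinuclear=area_peri,
                area_total=area_tot,
                integrated_total=sum_tot,
                well_id=well_id,
                field_index=field_index,
            )
        )

    if spec.noise_sd > 0:
        nuclear = nuclear + rng_noise.normal(0.0, spec.noise_sd, spec.field_shape)
        target = target + rng_noise.normal(0.0, spec.noise_sd, spec.field_shape)
        np.clip(nuclear, 0, None, out=nuclear)
        np.clip(target, 0, None, out=target)

    image = FieldImage(nuclear, target, well_id=well_id, field_index=field_index)
    truth = FieldGroundTruth(centers, nucleus_labels, cell_labels, pm_labels, peri_labels, records)
    return image, truth


def simulate_well_fields(
    spec: ImageSimSpec, well_id: str, n_fields: int = 9
) -> tuple[list[FieldImage], list[FieldGroundTruth]]:
    """Simulate all fields of one well, sub-seeding per field for independence."""
    fields, truths = [], []
    for i in range(n_fields):
        # distinct but reproducible per-field seed derived from (seed, well, field)
        well_key = zlib.crc32(well_id.encode()) % (2**31)
        sub = int(np.random.default_rng([spec.seed, well_key, i]).integers(2**31))
        f, t = simulate_field(replace(spec, seed=sub), well_id=well_id, field_index=i)
        fields.append(f)
        truths.append(t)
    return fields, truths


def write_field_tiff(path: str | Path, image: FieldImage) -> None:
    """Write a field as a 16-bit multi-page TIFF (page 0 nuclear, page 1 target)."""
    stack = np.stack([image.nuclear_channel, image.target_channel])
    stack = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), stack)


def read_field_tiff(
    path: str | Path,
    well_id: str = "",
    field_index: int = 0,
    channel_order: tuple[int, int] = (0, 1),
) -> FieldImage:
    """Read a two-page TIFF field; ``channel_order`` maps (nuclear, target) pages."""
    pages = tifffile.imread(str(path))
    if pages.ndim != 3 or pages.shape[0] < 2:
        raise ParameterError(f"{path}: expected a multi-page two-channel TIFF")
    nuc, tgt = channel_order
    return FieldImage(
        pages[nuc].astype(float), pages[tgt].astype(float), well_id=well_id,
        field_index=field_index,
    )


# ---------------------------------------------------------------------------
# plate arm
# ---------------------------------------------------------------------------


def default_layout(
    plate_format: int = 384,
    plate_id: str = "plate01",
    compound_prefix: str = "CMPD",
    compound_offset: int = 0,
    concentration: float = 25.0,
) -> PlateLayout:
    """Canonical screening layout: control columns framing a test-compound block.

    Columns 1 and 2 hold cell and positive (ALLN) controls; the last two
    columns hold viability (Hyamine) and additional cell controls; all
    remaining wells are test compounds with sequential IDs
    ``{prefix}-{serial:05d}`` (serial starts at ``compound_offset``).  For
    384-well plates this gives 320 test wells; for 96-well, 64.
    Concentration is in micromolar.
    """
    n_rows, n_cols = PLATE_DIMS[int(plate_format)]
    rows = []
    serial = compound_offset
    for r in range(n_rows):
        for c in range(n_cols):
            if c == 0:
                role, cid = "cell_control", ""
            elif c == 1:
                role, cid = "positive_control", ""
            elif c == n_cols - 2:
                role, cid = "viability_control", ""
            elif c == n_cols - 1:
                role, cid = "cell_control", ""
            else:
                role, cid = "test", f"{compound_prefix}-{serial:05d}"
                serial += 1
            rows.append(
                {
                    "well": well_name(r, c),
                    "role": role,
                    "compound_id": cid,
                    "concentration": concentration if role == "test" else np.nan,
                }
            )
    return PlateLayout(plate_id, pd.DataFrame(rows))


@dataclass(frozen=True)
class PlateSimSpec:
    """Parameters of one simulated plate pair (immunostain + viability reads).

    ``mu_cell_control`` and ``mu_positive`` set the immunostain means of
    cell-control and ALLN wells; test wells draw around
    ``mu_cell_control * multiplier`` (multiplier 1 unless the compound is in
    ``hit_ids``).  ``mu_viable`` and ``mu_viability_control`` set the
    viability-read means of live wells and of Hyamine-killed wells;
    ``stain_dead_fraction`` scales the immunostain of Hyamine wells.  All
    values are drawn Normal(mu, cv*mu), clipped at zero.  These defaults
    are synthetic working values, not estimates of the original screen.
    """

    plate_format: int = 384
    layout: PlateLayout | None = None
    mu_cell_control: float = 2.0e5
    mu_positive: float = 6.0e5
    mu_viability_control: float = 4.0e5
    mu_viable: float = 4.0e6
    stain_dead_fraction: float = 0.1
    cv: float = 0.05
    hit_ids: dict = dc_field(default_factory=dict)  # compound_id -> effect multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plate_format not in PLATE_DIMS:
            raise ParameterError(f"unsupported plate format {self.plate_format}")
        if self.cv < 0:
            raise ParameterError("cv must be >= 0")
        for mu in (self.mu_cell_control, self.mu_positive, self.mu_viability_control,
                   self.mu_viable):
            if mu <= 0:
                raise ParameterError("all control means must be positive")
        if not 0 <= self.stain_dead_fraction <= 1:
            raise ParameterError("stain_dead_fraction must be in [0, 1]")
        bad = [cid for cid, m in self.hit_ids.items() if m <= 0]
        if bad:
            raise ParameterError(f"effect multipliers must be positive: {bad}")

    def resolved_layout(self, plate_id: str = "plate01") -> PlateLayout:
        if self.layout is not None:
            return self.layout
        return default_layout(self.plate_format, plate_id=plate_id)


def simulate_plate(
    spec: PlateSimSpec, plate_id: str = "plate01"
) -> tuple[PlateRead, PlateRead, pd.DataFrame]:
    """Draw one plate's immunostain and viability reads plus its truth table.

    The truth table has one row per well: role, compound_id, effect
    multiplier, ``is_hit`` (whether the well was spiked), and the exact
    expected (noise-free) means of both reads.  Spiked compounds leave the
    viability read untouched — the emulated hits raise target-protein
    signal without measurable toxicity.  Reproducible for a fixed seed.
    """
    layout = spec.resolved_layout(plate_id)
    table = layout.table
    known = set(table.loc[table["role"] == "test", "compound_id"])
    unknown = set(spec.hit_ids) - known
    if unknown:
        raise LayoutError(
            f"plate {layout.plate_id}: hit_ids not among layout test compounds: "
            f"{sorted(unknown)}"
        )

    mult = np.ones(len(table))
    is_test = (table["role"] == "test").to_numpy()
    for i, cid in enumerate(table["compound_id"]):
        if cid in spec.hit_ids:
            mult[i] = float(spec.hit_ids[cid])

    stain_mu = np.empty(len(table))
    viab_mu = np.empty(len(table))
    role = table["role"].to_numpy()
    stain_mu[role == "cell_control"] = spec.mu_cell_control
    stain_mu[role == "positive_control"] = spec.mu_positive
    stain_mu[role == "viability_control"] = spec.stain_dead_fraction * spec.mu_cell_control
    stain_mu[is_test] = spec.mu_cell_control * mult[is_test]
    viab_mu[:] = spec.mu_viable
    viab_mu[role == "viability_control"] = spec.mu_viability_control

    rng = np.random.default_rng([spec.seed, _PLATE_NOISE])
    if spec.cv > 0:
        stain_vals = rng.normal(stain_mu, spec.cv * stain_mu)
        viab_vals = rng.normal(viab_mu, spec.cv * viab_mu)
        np.clip(stain_vals, 0, None, out=stain_vals)
        np.clip(viab_vals, 0, None, out=viab_vals)
    else:
        stain_vals, viab_vals = stain_mu.copy(), viab_mu.copy()

    wells = table.index
    stain = PlateRead(layout.plate_id, "immunostain", pd.Series(stain_vals, index=wells))
    viab = PlateRead(layout.plate_id, "viability", pd.Series(viab_vals, index=wells))
    truth = pd.DataFrame(
        {
            "plate_id": layout.plate_id,
            "well": wells,
            "role": role,
            "compound_id": table["compound_id"].to_numpy(),
            "multiplier": mult,
            "is_hit": is_test & (mult != 1.0),
            "expected_stain": stain_mu,
            "expected_viability": viab_mu,
        }
    ).reset_index(drop=True)
    return stain, viab, truth


def simulate_screen(
    spec: PlateSimSpec, n_plates: int = 1, plate_prefix: str = "plate"
) -> tuple[list[PlateLayout], list[tuple[PlateRead, PlateRead]], pd.DataFrame]:
    """Simulate several plates with distinct compound blocks and pooled truth.

    Plate i reuses ``spec`` with seed ``[seed, i]``-derived noise and a
    layout whose test-compound serials continue from the previous plate, so
    compound IDs are unique across the screen.
    """
    layouts: list[PlateLayout] = []
    reads: list[tuple[PlateRead, PlateRead]] = []
    truths: list[pd.DataFrame] = []
    n_rows, n_cols = PLATE_DIMS[spec.plate_format]
    per_plate = n_rows * (n_cols - 4)
    for i in range(n_plates):
        plate_id = f"{plate_prefix}{i + 1:02d}"
        layout = (
            spec.layout
            if spec.layout is not None and n_plates == 1
            else default_layout(spec.plate_format, plate_id, compound_offset=i * per_plate)
        )
        sub_seed = int(np.random.default_rng([spec.seed, 3, i]).integers(2**31))
        plate_spec = PlateSimSpec(
            plate_format=spec.plate_format,
            layout=layout,
            mu_cell_control=spec.mu_cell_control,
            mu_positive=spec.mu_positive,
            mu_viability_control=spec.mu_viability_control,
            mu_viable=spec.mu_viable,
            stain_dead_fraction=spec.stain_dead_fraction,
            cv=spec.cv,
            hit_ids={
                cid: m
                for cid, m in spec.hit_ids.items()
                if cid in set(layout.table["compound_id"])
            },
            seed=sub_seed,
        )
        stain, viab, truth = simulate_plate(plate_spec, plate_id=plate_id)
        layouts.append(layout)
        reads.append((stain, viab))
        truths.append(truth)
    return layouts, reads, pd.concat(truths, ignore_index=True)
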