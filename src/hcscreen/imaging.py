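"""High-content imaging arm: segmentation, ring ROIs, per-cell measurement.

Implements the image-analysis scheme of the immunofluorescence screen:
nuclei are segmented from the high-contrast DNA stain by intensity
threshold, the cytoplasm associated with each nucleus is defined from the
lower-contrast cytoplasmic staining of the same dye, and three regions of
interest are derived per cell:

* plasma membrane (PM): a ring of configurable width (default 2 px) along
  the cell margin,
* perinuclear region: a ring of configurable width (default 5 px)
  encircling the outside of the nuclear mask, clipped to the cell,
* total: the whole cell mask.

Ring widths are measured in morphological steps: under the default
Chebyshev metric one step is one erosion/dilation with a 3x3 square
structuring element, so "2 pixels wide" means all cell pixels within
Chebyshev distance 2 of the nearest non-cell pixel.  The per-well readout
is the mean fluorescence over all cells pooled across a well's fields.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import LabelingError, ParameterError, SegmentationError

logger = logging.getLogger(__name__)

#: structuring elements, one morphological step per unit of ring width
_STRUCTS = {
    "chebyshev": np.ones((3, 3), dtype=bool),
    "manhattan": ndi.generate_binary_structure(2, 1),
}


def _structure(metric: str) -> np.ndarray:
    try:
        return _STRUCTS[metric]
    except KeyError:
        raise ParameterError(
            f"unknown metric {metric!r}; expected one of {sorted(_STRUCTS)}"
        ) from None


@dataclass
class FieldImage:
    """One imaged microscope field of a well: DNA-stain and target channels."""

    nuclear_channel: np.ndarray
    target_channel: np.ndarray
    well_id: str = "A01"
    field_index: int = 0

    def __post_init__(self) -> None:
        self.nuclear_channel = np.asarray(self.nuclear_channel, dtype=float)
        self.target_channel = np.asarray(self.target_channel, dtype=float)
        if self.nuclear_channel.shape != self.target_channel.shape:
            raise ParameterError(
                "nuclear and target channels differ in shape: "
                f"{self.nuclear_channel.shape} vs {self.target_channel.shape}"
            )
        if self.nuclear_channel.ndim != 2:
            raise ParameterError("channels must be 2-D intensity arrays")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear_channel.shape


@dataclass
class SegmentationMasks:
    """Nucleus and cell labelings of one field plus the ring-width settings.

    Labels are positive integers with 0 as background; every nucleus label
    has exactly one matching cell label and nucleus pixels are contained in
    the corresponding cell.
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    pm_roi_width: int = 2
    perinuclear_width: int = 5
    metric: str = "chebyshev"

    def __post_init__(self) -> None:
        self.nucleus_labels = np.asarray(self.nucleus_labels)
        self.cell_labels = np.asarray(self.cell_labels)
        if self.nucleus_labels.shape != self.cell_labels.shape:
            raise LabelingError("nucleus and cell labelings differ in shape")
        check_label_consistency(self.nucleus_labels, self.cell_labels)

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of cell labels present."""
        lab = np.unique(self.cell_labels)
        return lab[lab > 0]


@dataclass
class CellRecord:
    """Per-cell compartment measurements (mean intensities and pixel areas).

    An empty compartment yields a NaN mean, never a silent zero.
    ``integrated_total`` is the summed (not mean) target intensity over the
    whole cell, kept as an auxiliary readout.
    """

    cell_id: int
    mean_pm: float
    mean_perinuclear: float
    mean_total: float
    area_pm: int
    area_perinuclear: int
    area_total: int
    integrated_total: float = float("nan")
    well_id: str = ""
    field_index: int = 0


@dataclass
class WellImageSummary:
    """Pooled per-well readout: all cells across a well's fields weighted equally."""

    well_id: str
    n_cells: int
    mean_pm: float
    mean_perinuclear: float
    mean_total: float
    n_fields: int = 0


def check_label_consistency(nucleus_labels: np.ndarray, cell_labels: np.ndarray) -> None:
    """Raise LabelingError unless every nucleus sits inside its same-label cell."""
    nuc = set(np.unique(nucleus_labels[nucleus_labels > 0]).tolist())
    cell = set(np.unique(cell_labels[cell_labels > 0]).tolist())
    if nuc != cell:
        raise LabelingError(
            f"label sets differ: nuclei-only {sorted(nuc - cell)}, "
            f"cells-only {sorted(cell - nuc)}"
        )
    inside = nucleus_labels == 0
    inside |= nucleus_labels == cell_labels
    if not inside.all():
        bad = np.unique(nucleus_labels[~inside])
        raise LabelingError(f"nuclei not contained in their cells: {bad.tolist()}")


def auto_nuclear_threshold(channel: np.ndarray) -> float:
    """Threshold isolating bright nuclei from dimmer cytoplasm and background.

    Hierarchical Otsu: a first Otsu cut separates background from stained
    pixels, a second Otsu over the stained pixels separates the dim
    cytoplasmic stain from the bright nuclei.  With a purely bimodal image
    (no cytoplasmic stain) the second cut degenerates to the first and the
    plain Otsu threshold is returned.
    """
    t1 = float(threshold_otsu(channel))
    stained = channel[channel >= t1]
    if stained.size == 0 or np.ptp(stained) == 0:
        return t1
    return float(threshold_otsu(stained))


def auto_cyto_threshold(channel: np.ndarray, nucleus_labels: np.ndarray) -> float:
    """Otsu threshold over non-nucleus pixels, separating cytoplasm from background."""
    outside = channel[nucleus_labels == 0]
    if outside.size == 0 or np.ptp(outside) == 0:
        raise SegmentationError("cannot derive cytoplasm threshold: no contrast outside nuclei")
    return float(threshold_otsu(outside))


def segment_nuclei(
    field: FieldImage,
    threshold: float | str = "auto",
    min_area: int = 10,
) -> np.ndarray:
    """Label nuclei as connected components of thresholded DNA-stain pixels.

    Parameters
    ----------
    threshold
        Intensity cutoff in AFU; pixels >= threshold are foreground.
        ``"auto"`` selects the cutoff by multi-Otsu (see
        :func:`auto_nuclear_threshold`).
    min_area
        Components smaller than this pixel count are discarded as specks.

    Returns a labeled integer image (0 = background).  An all-background
    image yields an empty labeling; a threshold at or below the global
    minimum (everything foreground) is an error.
    """
    chan = field.nuclear_channel
    if chan.size == 0:
        raise SegmentationError("empty nuclear channel")
    thr = auto_nuclear_threshold(chan) if threshold == "auto" else float(threshold)
    if thr <= chan.min():
        raise SegmentationError(
            f"nuclear threshold {thr} <= image minimum {chan.min()}: all-foreground"
        )
    fg = chan >= thr
    labels, n = ndi.label(fg, structure=_STRUCTS["chebyshev"])
    if n and min_area > 1:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area)
        if small.size:
            labels[np.isin(labels, small)] = 0
    # relabel sequentially so labels are 1..n with no gaps
    kept = np.unique(labels)
    kept = kept[kept > 0]
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=labels.dtype)
    remap[kept] = np.arange(1, kept.size + 1)
    labels = remap[labels]
    logger.debug("segment_nuclei: threshold=%.4g, %d nuclei kept", thr, kept.size)
    return labels


def segment_cells(
    field: FieldImage,
    nucleus_labels: np.ndarray,
    cyto_threshold: float | str = "auto",
) -> np.ndarray:
    """Assign cytoplasmic foreground to nuclei by geodesic nearest-seed growth.

    Foreground is the set of DNA-stain pixels at or above ``cyto_threshold``
    (a lower cutoff than the nuclear one, capturing the dim cytoplasmic
    staining), always including the nuclei themselves.  Each foreground
    pixel is assigned to the nucleus it reaches first by repeated one-step
    label dilation constrained to the foreground — i.e. the nearest seed
    under the geodesic Chebyshev distance measured within the foreground.
    Distance ties go to the larger label (deterministic).  Foreground
    components containing no nucleus stay background and are counted in the
    log.

    The cell label of each cell equals its nucleus label.
    """
    chan = field.nuclear_channel
    if cyto_threshold == "auto":
        thr = auto_cyto_threshold(chan, nucleus_labels)
    else:
        thr = float(cyto_threshold)
    fg = (chan >= thr) | (nucleus_labels > 0)
    cells = np.where(fg, nucleus_labels, 0)
    struct = _STRUCTS["chebyshev"]
    # multi-source BFS: one grey-dilation per geodesic distance unit
    while True:
        grown = ndi.grey_dilation(cells, footprint=struct)
        newly = fg & (cells == 0) & (grown > 0)
        if not newly.any():
            break
        cells[newly] = grown[newly]
    orphans = int((fg & (cells == 0)).sum())
    if orphans:
        logger.info(
            "segment_cells: %d foreground pixels in components without a nucleus "
            "left as background (field %s/%d)",
            orphans,
            field.well_id,
            field.field_index,
        )
    return cells


def _label_boxes(labels: np.ndarray, pad: int) -> dict[int, tuple[slice, slice]]:
    """Bounding boxes per label, padded and clipped to the image."""
    boxes = {}
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rows = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labels.shape[0]))
        cols = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labels.shape[1]))
        boxes[lab] = (rows, cols)
    return boxes


def derive_pm_roi(
    cell_labels: np.ndarray,
    width: int = 2,
    metric: str = "chebyshev",
) -> np.ndarray:
    """Plasma-membrane ring per cell: the cell margin band of given width.

    The ring of a cell is the set of its pixels whose distance to the
    nearest non-cell pixel (other cells, background, or outside the field)
    is <= ``width`` under ``metric``.  Equivalently: the cell mask minus its
    ``width``-step morphological erosion.  Returns a labeled image carrying
    the cell labels on ring pixels.
    """
    width = int(width)
    if width <= 0:
        raise ParameterError(f"ring width must be positive, got {width}")
    struct = _structure(metric)
    rings = np.zeros_like(cell_labels)
    for lab, box in _label_boxes(cell_labels, pad=1).items():
        mask = cell_labels[box] == lab
        interior = ndi.binary_erosion(mask, structure=struct, iterations=width, border_value=0)
        rings[box][mask & ~interior] = lab
    return rings


def derive_perinuclear_roi(
    nucleus_labels: np.ndarray,
    cell_labels: np.ndarray,
    width: int = 5,
    metric: str = "chebyshev",
) -> np.ndarray:
    """Perinuclear ring per cell: a band encircling the outside of the nucleus.

    The ring is the set of pixels outside the nucleus, inside the cell mask,
    within distance ``width`` of the nucleus under ``metric`` — i.e. the
    ``width``-step dilation of the nuclear mask, minus the nucleus, clipped
    to the cell.  Overlap with the PM ring is permitted; it is computed
    independently and can be quantified with :func:`roi_overlap`.
    """
    width = int(width)
    if width <= 0:
        raise ParameterError(f"ring width must be positive, got {width}")
    check_label_consistency(nucleus_labels, cell_labels)
    struct = _structure(metric)
    rings = np.zeros_like(cell_labels)
    for lab, box in _label_boxes(cell_labels, pad=width + 1).items():
        nuc = nucleus_labels[box] == lab
        cell = cell_labels[box] == lab
        halo = ndi.binary_dilation(nuc, structure=struct, iterations=width, border_value=0)
        rings[box][halo & ~nuc & cell] = lab
    return rings


def roi_overlap(pm_rings: np.ndarray, perinuclear_rings: np.ndarray) -> pd.Series:
    """Pixel count of PM/perinuclear overlap per cell label (small-cell diagnostic)."""
    both = (pm_rings > 0) & (pm_rings == perinuclear_rings)
    labs = pm_rings[both]
    counts = pd.Series(labs).value_counts().sort_index() if labs.size else pd.Series(dtype=int)
    counts.index.name = "cell_id"
    return counts


def _border_labels(cell_labels: np.ndarray) -> set[int]:
    edge = np.concatenate(
        [cell_labels[0], cell_labels[-1], cell_labels[:, 0], cell_labels[:, -1]]
    )
    return set(np.unique(edge[edge > 0]).tolist())


def measure_cells(field: FieldImage, masks: SegmentationMasks) -> list[CellRecord]:
    """Mean target-channel intensity per compartment for every interior cell.

    Cells touching the field border are excluded (their PM ring is truncated
    by the field edge) and counted in the log.  Empty compartments yield NaN
    means.
    """
    if masks.cell_labels.shape != field.shape:
        raise LabelingError("masks were not derived from this field (shape mismatch)")
    pm = derive_pm_roi(masks.cell_labels, masks.pm_roi_width, masks.metric)
    peri = derive_perinuclear_roi(
        masks.nucleus_labels, masks.cell_labels, masks.perinuclear_width, masks.metric
    )
    border = _border_labels(masks.cell_labels)
    if border:
        logger.info(
            "measure_cells: excluding %d border-touching cells in field %s/%d",
            len(border),
            field.well_id,
            field.field_index,
        )
    target = field.target_channel
    records: list[CellRecord] = []
    for lab in masks.labels:
        if int(lab) in border:
            continue
        compartments = {}
        for name, roi in (("pm", pm), ("perinuclear", peri), ("total", masks.cell_labels)):
            sel = target[roi == lab]
            compartments[name] = (
                float(sel.mean()) if sel.size else float("nan"),
                int(sel.size),
                float(sel.sum()),
            )
        records.append(
            CellRecord(
                cell_id=int(lab),
                mean_pm=compartments["pm"][0],
                mean_perinuclear=compartments["perinuclear"][0],
                mean_total=compartments["total"][0],
                area_pm=compartments["pm"][1],
                area_perinuclear=compartments["perinuclear"][1],
                area_total=compartments["total"][1],
                integrated_total=compartments["total"][2],
                well_id=field.well_id,
                field_index=field.field_index,
            )
        )
    return records


def quantify_field(
    field: FieldImage,
    nuclear_threshold: float | str = "auto",
    cyto_threshold: float | str = "auto",
    pm_width: int = 2,
    perinuclear_width: int = 5,
    min_nucleus_area: int = 10,
    metric: str = "chebyshev",
) -> list[CellRecord]:
    """Full per-field pipeline: segment nuclei and cells, measure all compartments."""
    nuclei = segment_nuclei(field, nuclear_threshold, min_area=min_nucleus_area)
    cells = segment_cells(field, nuclei, cyto_threshold)
    masks = SegmentationMasks(nuclei, cells, pm_width, perinuclear_width, metric)
    return measure_cells(field, masks)


def _pooled_mean(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    return float(finite.mean()) if finite.size else float("nan")


def summarize_well(
    records: Sequence[Iterable[CellRecord]] | Iterable[CellRecord],
    well_id: str | None = None,
) -> WellImageSummary:
    """Pool per-cell means over all fields of a well.

    Every cell is weighted equally regardless of which field it came from
    (a pooled cell-level mean, not a mean of per-field means).  Missing
    compartment means (NaN) are excluded from their compartment's pool.
    ``records`` may be a flat iterable of CellRecord or one iterable per
    field.
    """
    flat: list[CellRecord] = []
    n_fields = 0
    items = list(records)
    if items and isinstance(items[0], CellRecord):
        flat = items  # type: ignore[assignment]
        n_fields = len({r.field_index for r in flat}) or 1
    else:
        for fld in items:
            flat.extend(fld)
            n_fields += 1
        if n_fields == 0:
            raise ParameterError("summarize_well requires at least one field")
    if well_id is None:
        well_id = flat[0].well_id if flat else ""
    if not flat:
        nan = float("nan")
        return WellImageSummary(well_id, 0, nan, nan, nan, n_fields)
    return WellImageSummary(
        well_id=well_id,
        n_cells=len(flat),
        mean_pm=_pooled_mean(np.array([r.mean_pm for r in flat])),
        mean_perinuclear=_pooled_mean(np.array([r.mean_perinuclear for r in flat])),
        mean_total=_pooled_mean(np.array([r.mean_total for r in flat])),
        n_fields=n_fields,
    )


def cell_records_to_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Tabulate CellRecords (one row per cell) for TSV output."""
    cols = [
        "well_id",
        "field_index",
        "cell_id",
        "mean_pm",
        "mean_perinuclear",
        "mean_total",
        "integrated_total",
        "area_pm",
        "area_perinuclear",
        "area_total",
    ]
    rows = [{c: getattr(r, c) for c in cols} for r in records]
    return pd.DataFrame(rows, columns=cols)


def well_summaries_to_frame(summaries: Iterable[WellImageSummary]) -> pd.DataFrame:
    cols = ["well_id", "n_cells", "n_fields", "mean_pm", "mean_perinuclear", "mean_total"]
    rows = [{c: getattr(s, c) for c in cols} for s in summaries]
    return pd.DataFrame(rows, columns=cols)
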