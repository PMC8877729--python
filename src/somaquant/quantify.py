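"""Per-cell measurement, glial screening, positivity calling and binning.

A *cell table* is a :class:`pandas.DataFrame` with one row per detected cell
and the stable column order :data:`CELL_TABLE_COLUMNS`: identity, compartment
volumes (µm³), the nuclear-to-cellular volume ratio (NCVR), and cumulative /
mean / maximum intensity of each marker in each compartment (cumulative =
total amount of marker, mean = its concentration).

The glial screen removes presumptive glia: cells whose volume falls strictly
below a cut equal to the 99th percentile of the double-negative
(Nissl−/NeuN−) population (231.77 µm³ in the reference dataset), or whose
NCVR strictly exceeds 0.5.  Anucleate cells have NCVR 0 and can only be
screened by volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .geometry import VoxelGrid
from .preprocessing import ChannelThresholds

__all__ = [
    "MARKERS",
    "COMPARTMENTS",
    "CELL_TABLE_COLUMNS",
    "BOOL_COLUMNS",
    "QUINTILE_LABELS",
    "ScreeningParams",
    "measure_cells",
    "classify_positivity",
    "compute_volume_threshold",
    "screen_glia",
    "normalize_pcjun",
    "normalize_neun",
    "assign_volume_quintiles",
]

MARKERS = ("neurotrace", "neun", "pcjun")
COMPARTMENTS = ("whole", "nucleus", "cytoplasm")
QUINTILE_LABELS = ("Ex-S", "S", "M", "L", "Ex-L")

_STAT_COLUMNS = [
    f"{stat}_{m}_{c}"
    for m in MARKERS
    for c in COMPARTMENTS
    for stat in ("cum", "mean", "max")
]

CELL_TABLE_COLUMNS = [
    "cell_id",
    "animal_id",
    "group",
    "section",
    "has_nucleus",
    "cell_volume_um3",
    "nuclear_volume_um3",
    "cytoplasm_volume_um3",
    "ncvr",
    *_STAT_COLUMNS,
    "nt_pos",
    "nn_pos",
    "pcj_pos",
]

BOOL_COLUMNS = ("has_nucleus", "nt_pos", "nn_pos", "pcj_pos")


@dataclass(frozen=True)
class ScreeningParams:
    """Glial-screen settings.

    volume_percentile : percentile of the Nissl−/NeuN− cell-volume
        distribution defining the data-driven cut (default 99).
    fixed_volume_threshold_um3 : explicit cut in µm³ overriding the
        data-driven rule (the reference dataset's value is 231.77 µm³).
    ncvr_max : NCVR above which (strictly) a cell is called glial.
    """

    volume_percentile: float = 99.0
    fixed_volume_threshold_um3: float | None = None
    ncvr_max: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.volume_percentile < 100:
            raise ValueError("volume_percentile must be in (0, 100)")
        if not 0 < self.ncvr_max <= 1:
            raise ValueError("ncvr_max must be in (0, 1]")


def _per_label(values: np.ndarray, labels: np.ndarray, index: np.ndarray, stat: str):
    if stat == "count":
        return ndi.sum_labels(np.ones_like(labels, dtype=np.float64), labels, index)
    if stat == "sum":
        return ndi.sum_labels(values.astype(np.float64), labels, index)
    if stat == "max":
        out = ndi.labeled_comprehension(
            values, labels, index, np.max, np.float64, 0.0
        )
        return np.nan_to_num(out, nan=0.0)
    raise ValueError(stat)


def measure_cells(
    cells: np.ndarray,
    nuclei: np.ndarray,
    cytoplasm: np.ndarray,
    retained: dict[str, np.ndarray],
    grid: VoxelGrid,
    animal_id: str = "A1",
    group: str = "SH",
    section: str = "s1",
) -> pd.DataFrame:
    """Build the cell table from label volumes and retained intensities.

    ``retained`` maps marker name → thresholded (sub-threshold-zeroed)
    intensity array.  For each cell and compartment: cumulative intensity is
    the sum over the compartment's voxels, mean is cumulative divided by the
    voxel count (0 for an empty compartment), max is the compartment's
    maximum retained intensity.  Volumes are voxel counts times the grid's
    voxel volume.
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    cytoplasm = np.asarray(cytoplasm)
    inside = nuclei > 0
    if not np.array_equal(cells[inside], nuclei[inside]):
        raise ValueError("inconsistent label volumes: nucleus outside its cell")
    n = int(cells.max())
    index = np.arange(1, n + 1)
    if n == 0:
        return pd.DataFrame(columns=CELL_TABLE_COLUMNS)
    vv = grid.voxel_volume()
    compartments = {"whole": cells, "nucleus": nuclei, "cytoplasm": cytoplasm}
    counts = {
        c: _per_label(None, lab, index, "count") for c, lab in compartments.items()
    }
    data: dict[str, np.ndarray] = {
        "cell_id": index,
        "animal_id": animal_id,
        "group": group,
        "section": section,
        "has_nucleus": counts["nucleus"] > 0,
        "cell_volume_um3": counts["whole"] * vv,
        "nuclear_volume_um3": counts["nucleus"] * vv,
        "cytoplasm_volume_um3": counts["cytoplasm"] * vv,
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        ncvr = np.where(
            counts["whole"] > 0, counts["nucleus"] / counts["whole"], 0.0
        )
    data["ncvr"] = ncvr
    for m in MARKERS:
        values = np.asarray(retained[m])
        for c, lab in compartments.items():
            cum = _per_label(values, lab, index, "sum")
            cnt = counts[c]
            data[f"cum_{m}_{c}"] = cum
            data[f"mean_{m}_{c}"] = np.where(cnt > 0, cum / np.maximum(cnt, 1), 0.0)
            data[f"max_{m}_{c}"] = _per_label(values, lab, index, "max")
    table = pd.DataFrame(data)
    for col in ("nt_pos", "nn_pos", "pcj_pos"):
        table[col] = False
    return table[CELL_TABLE_COLUMNS]


_POSITIVITY_FLAGS = {"neurotrace": "nt_pos", "neun": "nn_pos", "pcjun": "pcj_pos"}


def classify_positivity(
    table: pd.DataFrame,
    thresholds: ChannelThresholds,
    rule: str = "max",
) -> pd.DataFrame:
    """Call per-marker positivity on whole-cell intensity.

    Default rule: a cell is positive for a marker when its maximum whole-cell
    voxel intensity is at or above the channel threshold (inclusive, matching
    the voxel-level convention).  A mean-based rule is available for
    sensitivity analysis.
    """
    if rule not in ("max", "mean"):
        raise ValueError(f"unknown positivity rule {rule!r}")
    table = table.copy()
    for marker, flag in _POSITIVITY_FLAGS.items():
        table[flag] = table[f"{rule}_{marker}_whole"] >= thresholds[marker]
    return table


def compute_volume_threshold(
    table: pd.DataFrame, percentile: float = 99.0
) -> float:
    """Volume cut (µm³): percentile of the Nissl−/NeuN− cell volumes.

    Uses the linear-interpolation percentile definition.  Raises when the
    table has no double-negative cells; supply
    ``ScreeningParams.fixed_volume_threshold_um3`` in that case.
    """
    neg = table.loc[~table["nt_pos"] & ~table["nn_pos"], "cell_volume_um3"]
    if neg.empty:
        raise ValueError(
            "no NeuroTrace-/NeuN- cells; set fixed_volume_threshold_um3 instead"
        )
    return float(np.percentile(neg.to_numpy(), percentile))


def screen_glia(
    table: pd.DataFrame, params: ScreeningParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Split the table into retained cells and screened-out presumptive glia.

    A cell is excluded iff its volume is strictly below the volume cut OR its
    NCVR strictly exceeds ``ncvr_max`` — both boundaries retain.  The report
    carries the threshold used and counts per exclusion reason.
    """
    params = params or ScreeningParams()
    if params.fixed_volume_threshold_um3 is not None:
        cut = float(params.fixed_volume_threshold_um3)
        cut_source = "fixed"
    else:
        cut = compute_volume_threshold(table, params.volume_percentile)
        cut_source = f"percentile_{params.volume_percentile:g}"
    small = table["cell_volume_um3"].to_numpy() < cut
    high_ncvr = table["ncvr"].to_numpy() > params.ncvr_max
    excluded_mask = small | high_ncvr
    retained = table.loc[~excluded_mask].copy()
    excluded = table.loc[excluded_mask].copy()
    report = {
        "volume_threshold_um3": cut,
        "volume_threshold_source": cut_source,
        "ncvr_max": params.ncvr_max,
        "n_input": int(len(table)),
        "n_retained": int(len(retained)),
        "n_excluded": int(excluded_mask.sum()),
        "n_excluded_small_volume": int(small.sum()),
        "n_excluded_high_ncvr": int(high_ncvr.sum()),
        "n_excluded_both": int((small & high_ncvr).sum()),
    }
    return retained, excluded, report


def normalize_pcjun(table: pd.DataFrame, thresholds: ChannelThresholds) -> pd.DataFrame:
    """Express p-c-Jun intensities in units of the positivity threshold.

    Adds ``norm_mean_pcjun_*`` and ``norm_cum_pcjun_*`` columns (raw value /
    threshold); a normalized mean of 1.0 marks the positivity boundary.
    """
    t = thresholds["pcjun"]
    if t <= 0:
        raise ValueError("p-c-Jun threshold must be positive")
    table = table.copy()
    for c in COMPARTMENTS:
        table[f"norm_mean_pcjun_{c}"] = table[f"mean_pcjun_{c}"] / t
        table[f"norm_cum_pcjun_{c}"] = table[f"cum_pcjun_{c}"] / t
    return table


def normalize_neun(
    table: pd.DataFrame,
    reference: pd.DataFrame,
    reference_rule: str = "sh_median",
) -> pd.DataFrame:
    """Normalize NeuN intensities to a reference population's median.

    ``reference`` is the reference cell table (e.g. the sham group, or the
    sham group's p-c-Jun− cells — the choice is the caller's explicit
    parameter, recorded in the output's attrs).  Scale-invariant: doubling
    all intensities leaves normalized values unchanged.
    """
    if reference.empty:
        raise ValueError("reference population is empty")
    table = table.copy()
    for stat in ("mean", "cum"):
        ref_median = float(reference[f"{stat}_neun_whole"].median())
        if ref_median == 0:
            raise ValueError(f"reference median {stat} NeuN intensity is zero")
        table[f"norm_{stat}_neun_whole"] = table[f"{stat}_neun_whole"] / ref_median
    table.attrs["neun_reference_rule"] = reference_rule
    return table


def assign_volume_quintiles(table: pd.DataFrame) -> pd.DataFrame:
    """Per-animal cell-volume quintiles Ex-S / S / M / L / Ex-L.

    Cells are ranked by volume within each animal (ties broken by stable
    cell_id order) and cut at the 20/40/60/80 percentiles of rank, so bin
    occupancy within an animal differs by at most one cell.  Requires at
    least five cells per animal.
    """
    table = table.copy()
    table["volume_quintile"] = ""
    for animal, idx in table.groupby("animal_id").groups.items():
        sub = table.loc[idx]
        n = len(sub)
        if n < 5:
            raise ValueError(f"animal {animal!r} has {n} cells; need >= 5")
        order = np.lexsort((sub["cell_id"].to_numpy(), sub["cell_volume_um3"].to_numpy()))
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(n)
        bins = (ranks * 5) // n
        table.loc[idx, "volume_quintile"] = np.take(QUINTILE_LABELS, bins)
    return table
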