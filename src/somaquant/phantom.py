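"""Synthetic tissue phantoms with complete voxel- and cell-level ground truth.

The generator emulates the cell populations a neocortical layer-V field
presents to the pipeline:

- **neurons** — nucleated ellipsoidal somata; cytoplasm Nissl+ (NeuroTrace),
  a configurable fraction NeuN+ (default 0.87, the sham-level fraction) and a
  configurable fraction p-c-Jun+ (defaults span the sham ≈1.5% to
  acute-repetitive ≈10.3% range) with nuclear-enriched p-c-Jun signal;
- **glia** — screenable by construction, in two regimes: small somata whose
  cell volume falls below the glial volume cut, and nucleus-dominated
  profiles (NCVR > 0.5) whose Nissl reaction is confined to the nucleus;
- **anucleate somata** — Nissl+ cells without a DNA-channel nucleus,
  exercising the leftover-signal rescue path;
- **debris** — DNA-only detections with no somatic signal, exercising the
  surrogate-cell path.

Channels are composed from the planted truth, blurred by a Gaussian PSF and
degraded with Poisson photon noise plus Gaussian read noise (EMCCD-style
phenomenology, coarse level).  Somata are axis-aligned ellipsoids so truth
volumes are analytic voxel counts; generation is deterministic given
``(spec, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import VoxelGrid, DEFAULT_VOXEL_SIZE_UM
from .imaging import CHANNEL_NAMES, MultiChannelStack, write_stack
from .preprocessing import ChannelThresholds
from .quantify import CELL_TABLE_COLUMNS

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "truth_cell_table",
    "recommended_thresholds",
    "named_specs",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic stack.

    Size/placement
    --------------
    shape : grid voxel counts (nz, ny, nx).
    voxel_size_um : (dz, dy, dx) in µm.
    n_neurons, n_glia, n_anucleate, n_debris : planted population sizes.
    min_gap_voxels : minimum empty shell between planted somata, in voxels.

    Morphology (µm)
    ---------------
    soma_radius_median_um, soma_radius_sigma : lognormal soma radius for
        neurons (median ≈4.6 µm gives ≈470 µm³ somata); clipped to
        ``soma_radius_range_um`` so 10 constrained-growth rounds always reach
        the soma surface.
    nucleus_ratio_mean, nucleus_ratio_sd : nucleus-to-soma radius ratio
        (mean 0.49 reproduces a ≈0.12 nuclear-to-cellular volume ratio).
    glia_small_radius_um : small-glia soma radius (volume below the cut).
    glia_ncvr_nucleus_um : nucleus radius of nucleus-dominated glia; their
        soma is only 1.12× larger, so the true NCVR ≈ 0.71.
    glia_ncvr_fraction : fraction of glia in the nucleus-dominated regime.
    debris_nucleus_um : radius of DNA-only debris nuclei.

    Marker model
    ------------
    p_neun : P(NeuN+ | neuron), default 0.87.
    p_pcjun : P(p-c-Jun+ | nucleated neuron).
    Intensity levels are photon counts above ``background``; p-c-Jun is
    nuclear-enriched (nuclear : cytoplasmic = 4 : 1 by default).

    Optics / noise
    --------------
    psf_sigma_xy_um, psf_sigma_z_um : Gaussian PSF; 0 disables blur.
    read_noise_sd : Gaussian read noise; ``poisson_noise`` toggles shot
        noise.  Both off yields a noise-free phantom.
    """

    shape: tuple[int, int, int] = (48, 256, 256)
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    n_neurons: int = 120
    n_glia: int = 30
    n_anucleate: int = 6
    n_debris: int = 6
    min_gap_voxels: int = 3
    soma_radius_median_um: float = 4.6
    soma_radius_sigma: float = 0.13
    soma_radius_range_um: tuple[float, float] = (3.6, 5.6)
    nucleus_ratio_mean: float = 0.49
    nucleus_ratio_sd: float = 0.03
    nucleus_ratio_range: tuple[float, float] = (0.45, 0.60)
    glia_small_radius_um: float = 2.6
    glia_small_radius_sd: float = 0.2
    glia_ncvr_nucleus_um: float = 3.6
    glia_ncvr_soma_factor: float = 1.12
    glia_ncvr_fraction: float = 0.5
    debris_nucleus_um: float = 1.8
    p_neun: float = 0.87
    p_pcjun: float = 0.015
    background: float = 20.0
    neurotrace_level: float = 120.0
    neun_level: float = 140.0
    draq5_level: float = 160.0
    pcjun_nuclear_level: float = 400.0
    pcjun_cyto_level: float = 100.0
    psf_sigma_xy_um: float = 0.3
    psf_sigma_z_um: float = 0.6
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    group: str = "SH"
    animal_id: str = "A1"
    max_place_tries: int = 400

    def __post_init__(self) -> None:
        for p in (self.p_neun, self.p_pcjun, self.glia_ncvr_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.soma_radius_median_um, self.glia_small_radius_um,
               self.glia_ncvr_nucleus_um, self.debris_nucleus_um) <= 0:
            raise ValueError("radii must be positive")
        if self.min_gap_voxels < 1:
            raise ValueError("min_gap_voxels must be >= 1")

    def grid(self) -> VoxelGrid:
        dz, dy, dx = self.voxel_size_um
        return VoxelGrid(*self.shape, dz, dy, dx)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("shape", "voxel_size_um", "soma_radius_range_um", "nucleus_ratio_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("shape", "voxel_size_um", "soma_radius_range_um", "nucleus_ratio_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """True labels and per-cell attributes of a generated phantom."""

    spec: PhantomSpec
    seed: int
    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    records: pd.DataFrame  # one row per planted cell


def _ellipsoid_mask(shape, center, radii) -> tuple[tuple[slice, ...], np.ndarray]:
    """Bounding-box slices and boolean ellipsoid for an axis-aligned soma."""
    slices, offsets = [], []
    for ax in range(3):
        lo = max(0, int(np.floor(center[ax] - radii[ax])) - 1)
        hi = min(shape[ax], int(np.ceil(center[ax] + radii[ax])) + 2)
        slices.append(slice(lo, hi))
        offsets.append(np.arange(lo, hi, dtype=float) - center[ax])
    zz, yy, xx = np.meshgrid(*offsets, indexing="ij")
    inside = (
        (zz / radii[0]) ** 2 + (yy / radii[1]) ** 2 + (xx / radii[2]) ** 2
    ) <= 1.0
    return tuple(slices), inside


def _radii_vox(radius_um: float, grid: VoxelGrid) -> tuple[float, float, float]:
    return (radius_um / grid.dz, radius_um / grid.dy, radius_um / grid.dx)


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[MultiChannelStack, GroundTruth]:
    """Generate a 4-channel stack and its ground truth.

    Deterministic given ``(spec, seed)``.  Raises when the requested
    populations cannot be packed with the required gaps after bounded
    retries.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid()
    shape = grid.shape
    vv = grid.voxel_volume()

    # Per-cell plans: (kind, soma_radius_um, nucleus_radius_um)
    plans: list[tuple[str, float, float]] = []
    lo, hi = spec.soma_radius_range_um
    for _ in range(spec.n_neurons):
        r = float(np.clip(
            rng.lognormal(np.log(spec.soma_radius_median_um), spec.soma_radius_sigma),
            lo, hi,
        ))
        eta = float(np.clip(
            rng.normal(spec.nucleus_ratio_mean, spec.nucleus_ratio_sd),
            *spec.nucleus_ratio_range,
        ))
        plans.append(("neuron", r, r * eta))
    n_ncvr = int(round(spec.n_glia * spec.glia_ncvr_fraction))
    for i in range(spec.n_glia):
        if i < n_ncvr:
            rn = float(max(0.5, rng.normal(spec.glia_ncvr_nucleus_um, 0.2)))
            plans.append(("glia_ncvr", rn * spec.glia_ncvr_soma_factor, rn))
        else:
            r = float(max(1.2, rng.normal(spec.glia_small_radius_um, spec.glia_small_radius_sd)))
            plans.append(("glia_small", r, r * 0.55))
    for _ in range(spec.n_anucleate):
        r = float(np.clip(
            rng.lognormal(np.log(spec.soma_radius_median_um), spec.soma_radius_sigma),
            lo, hi,
        ))
        plans.append(("anucleate", r, 0.0))
    for _ in range(spec.n_debris):
        plans.append(("debris", 0.0, spec.debris_nucleus_um))

    claimed = np.zeros(shape, dtype=bool)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nuclei_labels = np.zeros(shape, dtype=np.int32)
    channels = {c: np.full(shape, spec.background, dtype=np.float64) for c in CHANNEL_NAMES}

    rows = []
    gap = spec.min_gap_voxels
    for cell_id, (kind, r_soma, r_nuc) in enumerate(plans, start=1):
        r_outer = max(r_soma, r_nuc)
        radii = _radii_vox(r_outer, grid)
        lo_hi = [
            (radii[ax] + 1, shape[ax] - radii[ax] - 2) for ax in range(3)
        ]
        if any(hi_ <= lo_ for lo_, hi_ in lo_hi):
            raise RuntimeError(
                f"grid {shape} too small (crowded) for a cell of radius "
                f"{r_outer:.2f} um"
            )
        placed = False
        for _ in range(spec.max_place_tries):
            center = tuple(rng.uniform(lo_, hi_) for lo_, hi_ in lo_hi)
            pad = tuple(radii[ax] + gap for ax in range(3))
            sl, inside = _ellipsoid_mask(shape, center, pad)
            if not claimed[sl][inside].any():
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {cell_id} ({kind}) after "
                f"{spec.max_place_tries} tries; grid too crowded"
            )

        soma_vox = nuc_vox = 0
        if r_soma > 0:
            sl_s, in_s = _ellipsoid_mask(shape, center, _radii_vox(r_soma, grid))
            claimed[sl_s][in_s] = True
            cell_labels[sl_s][in_s] = cell_id
            soma_vox = int(in_s.sum())
        if r_nuc > 0:
            sl_n, in_n = _ellipsoid_mask(shape, center, _radii_vox(r_nuc, grid))
            claimed[sl_n][in_n] = True
            nuclei_labels[sl_n][in_n] = cell_id
            if r_soma == 0:  # debris: the nucleus is the whole object
                cell_labels[sl_n][in_n] = cell_id
            nuc_vox = int(in_n.sum())
            channels["draq5"][sl_n][in_n] += spec.draq5_level

        # marker states
        nn_state = pcj_state = False
        if kind == "neuron":
            nn_state = bool(rng.random() < spec.p_neun)
            pcj_state = bool(rng.random() < spec.p_pcjun)
            channels["neurotrace"][sl_s][in_s] += spec.neurotrace_level
            if nn_state:
                channels["neun"][sl_s][in_s] += spec.neun_level
            if pcj_state:
                channels["pcjun"][sl_s][in_s] += spec.pcjun_cyto_level
                channels["pcjun"][sl_n][in_n] += (
                    spec.pcjun_nuclear_level - spec.pcjun_cyto_level
                )
        elif kind == "anucleate":
            nn_state = bool(rng.random() < spec.p_neun)
            channels["neurotrace"][sl_s][in_s] += spec.neurotrace_level
            if nn_state:
                channels["neun"][sl_s][in_s] += spec.neun_level
        elif kind == "glia_small":
            channels["neurotrace"][sl_s][in_s] += spec.neurotrace_level
        elif kind == "glia_ncvr":
            # Nissl reaction confined to the nucleus: no cytoplasmic signal
            channels["neurotrace"][sl_n][in_n] += spec.neurotrace_level

        total_vox = soma_vox if r_soma > 0 else nuc_vox
        rows.append(
            {
                "cell_id": cell_id,
                "kind": kind,
                "is_neuron": kind in ("neuron", "anucleate"),
                "has_nucleus": r_nuc > 0,
                "center_z": center[0],
                "center_y": center[1],
                "center_x": center[2],
                "soma_radius_um": r_soma,
                "nucleus_radius_um": r_nuc,
                "cell_volume_um3": total_vox * vv,
                "nuclear_volume_um3": nuc_vox * vv,
                "ncvr": (nuc_vox / total_vox) if total_vox else 0.0,
                "nt_pos": kind in ("neuron", "anucleate", "glia_small", "glia_ncvr"),
                "nn_pos": nn_state,
                "pcj_pos": pcj_state,
            }
        )

    # optics and noise
    sz = spec.psf_sigma_z_um / grid.dz
    sxy_y = spec.psf_sigma_xy_um / grid.dy
    sxy_x = spec.psf_sigma_xy_um / grid.dx
    from scipy import ndimage as ndi

    for name in CHANNEL_NAMES:
        img = channels[name]
        if max(sz, sxy_y, sxy_x) > 0:
            img = ndi.gaussian_filter(img, (sz, sxy_y, sxy_x))
        if spec.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0, None).astype(np.float32)

    stack = MultiChannelStack(grid, channels)
    truth = GroundTruth(
        spec=spec,
        seed=seed,
        nuclei_labels=nuclei_labels,
        cell_labels=cell_labels,
        records=pd.DataFrame(rows),
    )
    return stack, truth


def truth_cell_table(truth: GroundTruth) -> pd.DataFrame:
    """Ground truth in the pipeline's cell-table schema.

    Intensity statistics are filled with the planted mean levels where the
    truth defines them and 0 elsewhere; volumes, NCVR and marker flags are
    exact voxel-count truths.
    """
    spec = truth.spec
    rec = truth.records
    if rec.empty:
        return pd.DataFrame(columns=CELL_TABLE_COLUMNS)
    table = pd.DataFrame({c: np.zeros(len(rec)) for c in CELL_TABLE_COLUMNS})
    table["cell_id"] = rec["cell_id"].to_numpy()
    table["animal_id"] = spec.animal_id
    table["group"] = spec.group
    table["section"] = "truth"
    table["has_nucleus"] = rec["has_nucleus"].to_numpy()
    table["cell_volume_um3"] = rec["cell_volume_um3"].to_numpy()
    table["nuclear_volume_um3"] = rec["nuclear_volume_um3"].to_numpy()
    table["cytoplasm_volume_um3"] = (
        rec["cell_volume_um3"] - rec["nuclear_volume_um3"]
    ).to_numpy()
    table["ncvr"] = rec["ncvr"].to_numpy()
    nt = rec["nt_pos"].to_numpy()
    nn = rec["nn_pos"].to_numpy()
    pcj = rec["pcj_pos"].to_numpy()
    table["mean_neurotrace_whole"] = np.where(nt, spec.neurotrace_level, 0.0)
    table["max_neurotrace_whole"] = np.where(nt, spec.neurotrace_level + spec.background, 0.0)
    table["mean_neun_whole"] = np.where(nn, spec.neun_level, 0.0)
    table["max_neun_whole"] = np.where(nn, spec.neun_level + spec.background, 0.0)
    table["mean_pcjun_nucleus"] = np.where(pcj, spec.pcjun_nuclear_level, 0.0)
    table["max_pcjun_whole"] = np.where(pcj, spec.pcjun_nuclear_level + spec.background, 0.0)
    table["nt_pos"] = nt
    table["nn_pos"] = nn
    table["pcj_pos"] = pcj
    for col in ("has_nucleus", "nt_pos", "nn_pos", "pcj_pos"):
        table[col] = table[col].astype(bool)
    return table


def recommended_thresholds(spec: PhantomSpec) -> ChannelThresholds:
    """Static thresholds matched to a spec's intensity levels.

    Placed at background + 35% of the channel's signal level: far above the
    noise-driven maxima of negative cells and far below positive-cell
    plateaus, mirroring how static thresholds separate the bimodal intensity
    distributions in real data.
    """
    return ChannelThresholds(
        neurotrace=spec.background + 0.35 * spec.neurotrace_level,
        neun=spec.background + 0.35 * spec.neun_level,
        pcjun=spec.background + 0.35 * spec.pcjun_nuclear_level,
        draq5=spec.background + 0.35 * spec.draq5_level,
    )


def named_specs(small: bool = True) -> dict[str, PhantomSpec]:
    """The named fixture family used throughout the test suite.

    - ``clean``: blur- and noise-free, well-separated somata (exact-recovery
      surface; no debris so every planted object is a soma).
    - ``noisy``: default optics and noise.
    - ``crowded``: tighter packing (2-voxel gaps) at higher density.
    - ``glia_heavy``: glial and debris contamination dominates.
    - ``sh_like`` / ``ar_like``: sham-level (1.5%) and acute-repetitive-level
      (10.3%) p-c-Jun+ fractions.

    ``small=True`` shrinks populations for fast unit tests; the acceptance
    checks regenerate the same specs at their full study sizes.
    """
    base: dict[str, dict] = {
        "clean": dict(
            n_neurons=170, n_glia=24, n_anucleate=6, n_debris=0,
            psf_sigma_xy_um=0.0, psf_sigma_z_um=0.0,
            read_noise_sd=0.0, poisson_noise=False,
            shape=(48, 300, 300),
        ),
        "noisy": dict(n_neurons=120, n_glia=30, n_anucleate=6, n_debris=6),
        "crowded": dict(
            n_neurons=160, n_glia=40, n_anucleate=8, n_debris=8,
            min_gap_voxels=2, shape=(48, 280, 280),
        ),
        "glia_heavy": dict(n_neurons=40, n_glia=80, n_anucleate=4, n_debris=20),
        "sh_like": dict(
            p_pcjun=0.015, group="SH",
            n_neurons=500, n_glia=60, n_anucleate=10, n_debris=10,
            shape=(48, 512, 512),
        ),
        "ar_like": dict(
            p_pcjun=0.103, group="AR",
            n_neurons=500, n_glia=60, n_anucleate=10, n_debris=10,
            shape=(48, 512, 512),
        ),
    }
    if small:
        shrink = {
            "clean": dict(n_neurons=30, n_glia=8, n_anucleate=2, shape=(40, 160, 160)),
            "noisy": dict(n_neurons=24, n_glia=8, n_anucleate=2, n_debris=2, shape=(40, 160, 160)),
            "crowded": dict(n_neurons=30, n_glia=8, n_anucleate=2, n_debris=2, shape=(40, 160, 160)),
            "glia_heavy": dict(n_neurons=8, n_glia=20, n_anucleate=2, n_debris=6, shape=(40, 160, 160)),
            "sh_like": dict(n_neurons=60, n_glia=10, n_anucleate=2, n_debris=2, shape=(40, 220, 220)),
            "ar_like": dict(n_neurons=60, n_glia=10, n_anucleate=2, n_debris=2, shape=(40, 220, 220)),
        }
        for name, overrides in shrink.items():
            base[name].update(overrides)
    return {name: PhantomSpec(**kw) for name, kw in base.items()}


def make_fixture_suite(
    out_dir: str | Path, small: bool = True, base_seed: int = 20_000
) -> dict:
    """Write the named phantom suite with truths and a reproducibility manifest.

    Each fixture gets an OME-TIFF stack, a truth cell-table CSV and a
    manifest entry (spec dictionary + seed) sufficient to regenerate it
    bit-for-bit.  Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"fixtures": {}}
    for i, (name, spec) in enumerate(named_specs(small=small).items()):
        seed = base_seed + i
        stack, truth = generate_phantom(spec, seed)
        stack_path = out_dir / f"{name}.ome.tif"
        truth_path = out_dir / f"{name}_truth.csv"
        write_stack(stack, stack_path)
        truth_cell_table(truth).to_csv(truth_path, index=False)
        manifest["fixtures"][name] = {
            "stack": stack_path.name,
            "truth": truth_path.name,
            "seed": seed,
            "spec": spec.to_dict(),
        }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
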