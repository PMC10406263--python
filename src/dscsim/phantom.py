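"""Digital perfusion phantom: a labeled 3D geometry rendered to 4D data.

The default phantom is a 32x32x8 grid with a CSF rim, a cortical GM
ribbon, a WM core, and single-column artery and vein running through all
slices.  Every voxel of a region carries the same compartment model, so
the noiseless 4D dataset contains one distinct time course per region;
optional Gaussian noise (standard deviation expressed as a fraction of the
regional baseline signal, optionally higher in the vessels to mimic
physiological noise) is added on top.  Companion ground-truth maps (label,
CBV, MTT) accompany the data for end-to-end pipeline validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contrast_inputs import TimeGrid
from .forward_signal import (
    PhysicsConstants,
    VoxelLabel,
    VoxelModel,
    arterial_voxel,
    csf_voxel,
    simulate_signal_timecourse,
    tissue_voxel,
    venous_voxel,
)
from .paradigms import ParadigmSpec, make_inlet
from .tracer_transport import (
    BiexponentialResidue,
    MonoexponentialResidue,
    TransportSpec,
)

__all__ = [
    "PhantomSpec",
    "PhantomData",
    "build_phantom",
    "default_region_geometry",
    "segmentation_phantom_spec",
]

LABEL_CODES = {
    VoxelLabel.CSF: 1,
    VoxelLabel.GM: 2,
    VoxelLabel.WM: 3,
    VoxelLabel.ARTERIAL: 4,
    VoxelLabel.VENOUS: 5,
}


def default_region_geometry(shape=(32, 32, 8)) -> dict[VoxelLabel, np.ndarray]:
    """Disjoint boolean masks: CSF rim, GM ribbon, WM core, vessel columns."""
    nx, ny, nz = shape
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    edge = np.minimum.reduce([ix, iy, nx - 1 - ix, ny - 1 - iy])
    csf2d = edge < 2
    gm2d = (edge >= 2) & (edge < 5)
    wm2d = edge >= 5
    masks = {
        VoxelLabel.CSF: np.repeat(csf2d[:, :, None], nz, axis=2),
        VoxelLabel.GM: np.repeat(gm2d[:, :, None], nz, axis=2),
        VoxelLabel.WM: np.repeat(wm2d[:, :, None], nz, axis=2),
    }
    artery = np.zeros(shape, dtype=bool)
    artery[nx // 4, ny // 4, :] = True
    vein = np.zeros(shape, dtype=bool)
    vein[3 * nx // 4, 3 * ny // 4, :] = True
    for m in masks.values():
        m &= ~(artery | vein)
    masks[VoxelLabel.ARTERIAL] = artery
    masks[VoxelLabel.VENOUS] = vein
    return masks


@dataclass
class PhantomSpec:
    """Geometry, voxel models, acquisition and noise settings."""

    grid_shape: tuple = (32, 32, 8)
    region_geometry: dict | None = None        # VoxelLabel -> bool mask
    voxel_models: dict | None = None           # VoxelLabel -> VoxelModel
    noise_sigma: float | dict = 0.0            # fraction of regional S0
    seed: int = 0
    TR: float = 1.5
    duration: float = 120.0
    dt: float = 0.1
    tissue_transport: TransportSpec = field(
        default_factory=lambda: TransportSpec(BiexponentialResidue(), delay=1.0)
    )
    venous_transport: TransportSpec = field(
        default_factory=lambda: TransportSpec(MonoexponentialResidue(4.0), delay=2.0)
    )
    # slow drainage seen by CSF voxels with a residual venous partial volume
    csf_transport: TransportSpec = field(
        default_factory=lambda: TransportSpec(MonoexponentialResidue(12.0), delay=3.0)
    )
    csf_partial_venous_cbv: float = 0.0   # percent

    def sigma_for(self, label: VoxelLabel) -> float:
        if isinstance(self.noise_sigma, dict):
            return float(self.noise_sigma.get(label, 0.0))
        return float(self.noise_sigma)


@dataclass
class PhantomData:
    """Rendered 4D dataset plus ground truth and reference voxel indices."""

    data: np.ndarray                   # (x, y, z, t)
    labels: np.ndarray                 # int codes, see LABEL_CODES
    cbv_map: np.ndarray                # percent
    mtt_map: np.ndarray                # s (NaN where undefined)
    aif_index: tuple
    vof_index: tuple
    TR: float
    TE: float
    baseline_window: np.ndarray
    meta: dict = field(default_factory=dict)


def _default_models(
    paradigm: ParadigmSpec, csf_partial_venous_cbv: float = 0.0
) -> dict[VoxelLabel, VoxelModel]:
    base = paradigm.arterial_baseline
    return {
        VoxelLabel.ARTERIAL: arterial_voxel(90.0, y0=base),
        VoxelLabel.VENOUS: venous_voxel(90.0),
        VoxelLabel.GM: tissue_voxel(4.0, VoxelLabel.GM),
        VoxelLabel.WM: tissue_voxel(2.0, VoxelLabel.WM),
        VoxelLabel.CSF: csf_voxel(csf_partial_venous_cbv),
    }


def segmentation_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Phantom configured for segmentation testing: noiseless tissue,
    physiological noise in the vessel columns, and CSF with a slow venous
    partial volume so its apparent MTT is long, as in real data."""
    return PhantomSpec(
        noise_sigma={VoxelLabel.ARTERIAL: 0.05, VoxelLabel.VENOUS: 0.05},
        csf_partial_venous_cbv=1.0,
        seed=seed,
    )


def build_phantom(
    spec: PhantomSpec,
    paradigm: ParadigmSpec,
    k: PhysicsConstants = PhysicsConstants(),
) -> PhantomData:
    """Render the phantom to a 4D signal array for one contrast paradigm.

    Deterministic for a fixed seed.  Raises if region masks overlap.
    """
    geometry = spec.region_geometry or default_region_geometry(spec.grid_shape)
    overlap = np.zeros(spec.grid_shape, dtype=int)
    for mask in geometry.values():
        overlap += mask.astype(int)
    if overlap.max() > 1:
        raise ValueError("region masks overlap")
    models = spec.voxel_models or _default_models(
        paradigm, spec.csf_partial_venous_cbv
    )

    grid = TimeGrid(dt=spec.dt, duration=spec.duration)
    inlet = make_inlet(paradigm, grid)
    courses: dict[VoxelLabel, np.ndarray] = {}
    baseline = None
    for label, model in models.items():
        tc = simulate_signal_timecourse(
            inlet, model, spec.tissue_transport, TR=spec.TR,
            venous_spec=spec.venous_transport, csf_spec=spec.csf_transport,
            k=k,
        )
        courses[label] = tc.samples
        if label is VoxelLabel.ARTERIAL:
            # pre-arrival window of the earliest (undelayed) course
            baseline = tc.baseline_window

    n_t = len(next(iter(courses.values())))
    data = np.zeros(spec.grid_shape + (n_t,))
    labels = np.zeros(spec.grid_shape, dtype=int)
    cbv_map = np.zeros(spec.grid_shape)
    mtt_map = np.full(spec.grid_shape, np.nan)
    true_mtt = {
        VoxelLabel.GM: _spec_mtt(spec.tissue_transport),
        VoxelLabel.WM: _spec_mtt(spec.tissue_transport),
        VoxelLabel.VENOUS: _spec_mtt(spec.venous_transport),
        VoxelLabel.ARTERIAL: 0.0,
    }
    if spec.csf_partial_venous_cbv > 0:
        true_mtt[VoxelLabel.CSF] = _spec_mtt(spec.csf_transport)
    if baseline is None:
        baseline = np.arange(min(10, n_t))
    rng = np.random.default_rng(spec.seed)
    for label, mask in geometry.items():
        if label not in courses:
            continue
        series = courses[label]
        data[mask] = series
        sigma = spec.sigma_for(label)
        if sigma > 0:
            s0 = series[baseline].mean()
            data[mask] += rng.normal(
                0.0, sigma * s0, size=(int(mask.sum()), n_t)
            )
        labels[mask] = LABEL_CODES[label]
        cbv_map[mask] = models[label].total_CBV
        if label in true_mtt:
            mtt_map[mask] = true_mtt[label]

    aif_index = tuple(np.argwhere(geometry[VoxelLabel.ARTERIAL])[0])
    vof_index = tuple(np.argwhere(geometry[VoxelLabel.VENOUS])[0])
    return PhantomData(
        data=data,
        labels=labels,
        cbv_map=cbv_map,
        mtt_map=mtt_map,
        aif_index=aif_index,
        vof_index=vof_index,
        TR=spec.TR,
        TE=k.TE,
        baseline_window=baseline,
        meta={"paradigm": paradigm.name, "seed": spec.seed,
              "noise_sigma": spec.noise_sigma},
    )


def _spec_mtt(transport_spec: TransportSpec) -> float:
    from .tracer_transport import residue_mtt

    return residue_mtt(transport_spec.residue)
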