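"""Mechanistic plate simulator with known ground truth.

Generates everything the analysis pipeline reads — plate traces, layout
tables, calibration standards, titration tables — from a forward model of
the assay: a decaying metabolic flux produces acid (or base) equivalents,
the buffered medium converts production into pH via the charge balance,
the indicator converts pH into fluorescence, and the detector adds
Gaussian read noise.  Because every stage of the forward model is the
exact inverse of the corresponding analysis stage, pipeline correctness
is verifiable end-to-end by parameter recovery.

Default conditions emulate the long-term acidification assay they are
meant to test: 30-min sampling for 336 h (2 weeks), 2.5e7 cells/mL
metadata, acidification starting at pH 6.5 and staying above ~pH 5.7 with
under 20 mM lactate produced, a carboxyfluorescein-like indicator read at
roughly 37,000 RFU near the start pH, detector noise of 1250 RFU, and a
first-order rate decline of ~15.9-fold over the two weeks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .chemistry import (
    BufferSystem,
    TitrationCurve,
    default_assay_medium,
    model_titration,
    solve_ph_many,
)
from .errors import LayoutError, SimulationError, SolverError
from .quantify import WellMeta, WellSeries

#: 15.86-fold decline (the ratio of a 3.98e-4 to a 2.51e-5 M/h rate) over
#: a two-week (336 h) assay, expressed as a first-order decay constant
DEFAULT_FOLD_DECLINE = 3.98e-4 / 2.51e-5
DEFAULT_DURATION_H = 336.0
DEFAULT_DECAY_K = float(np.log(DEFAULT_FOLD_DECLINE) / DEFAULT_DURATION_H)

#: default initial flux, chosen so the default well traverses pH 6.5 ->
#: ~5.75 with ~15 mM of lactate over 336 h on the default medium
DEFAULT_R0 = 1.3e-4

DEFAULT_START_PH = {"acid": 6.5, "base": 5.5}
DEFAULT_RFU_NOISE_SD = 1250.0

#: default titration grids span the assay windows with margin
#: (acid curve reaches below pH 4.0, base curve above pH 7.0)
DEFAULT_TITRATION_GRIDS = {
    "acid": np.arange(0.0, 0.0245 + 1e-12, 5e-5),
    "base": np.arange(0.0, 0.0305 + 1e-12, 5e-5),
}


def default_fluorophore() -> CalibrationCurve:
    """Forward model of the indicator: log-sigmoid with apparent pKa 6.4,
    asymptotes 2,000/65,000 RFU, valid over the pH 4-7 standards range.

    At pH 6.5 this reads ~37,000 RFU, matching the constant-gain signal
    level around which detector noise of order 1,000-1,500 RFU is
    expected.
    """
    return CalibrationCurve(
        r_min=2000.0,
        r_max=65000.0,
        apparent_pka=6.4,
        hill_slope=1.0,
        valid_ph_range=(4.0, 7.0),
    )


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters for one simulated well.

    ``decay_order`` 0 means a constant rate; 1 and 2 the first- and
    second-order decline laws.  ``initial_rate_r0 = 0`` marks a
    negative-control well (medium, indicator, no active cells).  ``medium``
    and ``fluorophore`` default to the standard surrogates; ``start_ph``
    defaults to 6.5 in acid mode and 5.5 in base mode.
    """

    mode: str = "acid"
    initial_rate_r0: float = DEFAULT_R0
    decay_order: int = 1
    decay_constant_k: float = DEFAULT_DECAY_K
    start_ph: float | None = None
    medium: BufferSystem | None = None
    fluorophore: CalibrationCurve | None = None
    rfu_noise_sd: float = DEFAULT_RFU_NOISE_SD
    sampling_interval: float = 0.5
    duration: float = DEFAULT_DURATION_H
    seed: int = 0
    well_id: str = "A01"
    strain: str = "NCDO712"
    pre_culture: str = "lactose"
    substrate: str = "lactose"
    cell_density: float = 2.5e7
    role: str | None = None

    def __post_init__(self):
        if self.mode not in ("acid", "base"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.initial_rate_r0 < 0 or self.decay_constant_k < 0:
            raise ValueError("r0 and k must be >= 0")
        if self.decay_order not in (0, 1, 2):
            raise ValueError("decay_order must be 0, 1 or 2")
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("duration and sampling_interval must be positive")

    @property
    def resolved_start_ph(self) -> float:
        return DEFAULT_START_PH[self.mode] if self.start_ph is None else self.start_ph

    @property
    def resolved_role(self) -> str:
        if self.role is not None:
            return self.role
        return "negative_control" if self.initial_rate_r0 == 0 else "sample"

    def resolved_medium(self) -> BufferSystem:
        medium = self.medium if self.medium is not None else default_assay_medium()
        return medium.poised_at(self.resolved_start_ph)

    def resolved_fluorophore(self) -> CalibrationCurve:
        return self.fluorophore if self.fluorophore is not None else default_fluorophore()

    def meta(self) -> WellMeta:
        return WellMeta(
            role=self.resolved_role,
            strain=self.strain,
            pre_culture=self.pre_culture,
            substrate=self.substrate,
            mode=self.mode,
            cell_density=self.cell_density,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth for one simulated well."""

    well_id: str
    times: np.ndarray
    cumulative: np.ndarray
    ph: np.ndarray
    r0: float
    k: float
    order: int
    mode: str


def simulate_production(params: SimulationParams):
    """Closed-form true cumulative production (mol/L) on the sampling grid.

    order 0: P = r0 t
    order 1: P = (r0/k)(1 - exp(-k t))
    order 2: P = (1/k) ln(1 + r0 k t)

    (orders 1 and 2 fall back to the linear law when k = 0).
    """
    times = np.arange(0.0, params.duration + 1e-9, params.sampling_interval)
    r0, k = params.initial_rate_r0, params.decay_constant_k
    if params.decay_order == 0 or k == 0.0:
        cumulative = r0 * times
    elif params.decay_order == 1:
        cumulative = (r0 / k) * (1.0 - np.exp(-k * times))
    else:
        cumulative = np.log1p(r0 * k * times) / k
    return times, cumulative


def simulate_well(params: SimulationParams, rng: np.random.Generator | None = None):
    """Forward-model one well: production -> pH -> RFU -> noisy RFU.

    Acid-mode production enters the medium's charge balance as strong
    acid, base-mode (ammonium) production as strong base.  Raises
    :class:`SimulationError` if the noiseless pH trajectory leaves the
    fluorophore's valid range — the simulated experiment would saturate
    the detector, so reduce the rate, shorten the assay, or buffer the
    medium more strongly.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    times, cumulative = simulate_production(params)
    system = params.resolved_medium()
    sign = 1.0 if params.mode == "acid" else -1.0
    try:
        ph = solve_ph_many(system, sign * cumulative)
    except SolverError as exc:
        raise SimulationError(
            "simulated production overwhelms the medium buffering entirely; "
            "lower initial_rate_r0 or shorten duration"
        ) from exc
    cal = params.resolved_fluorophore()
    lo, hi = cal.valid_ph_range
    if ph.min() < lo or ph.max() > hi:
        raise SimulationError(
            f"simulated pH excursion [{ph.min():.2f}, {ph.max():.2f}] leaves "
            f"the fluorophore range [{lo}, {hi}]; lower initial_rate_r0, "
            "shorten duration, or strengthen the medium buffering"
        )
    rfu = cal.ph_to_rfu(ph)
    if params.rfu_noise_sd > 0:
        rfu = rfu + rng.normal(0.0, params.rfu_noise_sd, size=rfu.shape)
    well = WellSeries(
        well_id=params.well_id, times=times, rfu=rfu, meta=params.meta()
    )
    truth = GroundTruth(
        well_id=params.well_id,
        times=times,
        cumulative=cumulative,
        ph=ph,
        r0=params.initial_rate_r0,
        k=params.decay_constant_k,
        order=params.decay_order,
        mode=params.mode,
    )
    return well, truth


_ROWS = "ABCDEFGHIJKLMNOP"


def plate_well_ids(n: int):
    """First ``n`` row-major well ids of a 384-well plate (A01..P24)."""
    if n > 384:
        raise LayoutError(f"a 384-well plate holds at most 384 wells, got {n}")
    return [f"{_ROWS[i // 24]}{i % 24 + 1:02d}" for i in range(n)]


def default_plate(
    mode: str = "acid",
    replicates: int = 4,
    n_control_wells: int = 4,
    include_other_mode_controls: bool = True,
    **overrides,
) -> list[SimulationParams]:
    """Layout for a minimal default plate.

    ``replicates`` sample wells of the default condition in the requested
    mode, ``n_control_wells`` negative controls at the same start pH, and
    (by default) the same number of negative controls for the other mode's
    start pH, mirroring an assay plate that carries controls at both pH
    6.5 and pH 5.5.  ``overrides`` are applied to the sample wells.
    """
    other = "base" if mode == "acid" else "acid"
    n_other = n_control_wells if include_other_mode_controls else 0
    ids = iter(plate_well_ids(replicates + n_control_wells + n_other))
    layout = [
        SimulationParams(mode=mode, well_id=next(ids), **overrides)
        for _ in range(replicates)
    ]
    layout += [
        SimulationParams(
            mode=mode, initial_rate_r0=0.0, well_id=next(ids),
            strain="", pre_culture="", substrate="",
        )
        for _ in range(n_control_wells)
    ]
    layout += [
        SimulationParams(
            mode=other, initial_rate_r0=0.0, well_id=next(ids),
            strain="", pre_culture="", substrate="",
        )
        for _ in range(n_other)
    ]
    return layout


def simulate_plate(layouts: Sequence[SimulationParams], seed: int = 0):
    """Simulate a whole plate deterministically from a single seed.

    Returns ``(plate, layout, truths)``: a long-format plate table
    (well_id, time_h, rfu), a layout table, and a dict of per-well
    :class:`GroundTruth`.  Per-well noise streams are spawned from one
    seed sequence, so the same seed always yields byte-identical tables
    regardless of how individual wells' own ``seed`` fields are set.
    """
    layouts = list(layouts)
    ids = [p.well_id for p in layouts]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise LayoutError(f"duplicate well ids in layout: {dupes}")
    if len(layouts) > 384:
        raise LayoutError(f"a 384-well plate holds at most 384 wells, got {len(layouts)}")
    streams = np.random.SeedSequence(seed).spawn(len(layouts))
    plate_rows, layout_rows, truths = [], [], {}
    for params, stream in zip(layouts, streams):
        well, truth = simulate_well(params, rng=np.random.default_rng(stream))
        truths[params.well_id] = truth
        plate_rows.append(
            pd.DataFrame(
                {"well_id": params.well_id, "time_h": well.times, "rfu": well.rfu}
            )
        )
        layout_rows.append(
            {
                "well_id": params.well_id,
                "role": params.resolved_role,
                "strain": params.strain,
                "pre_culture": params.pre_culture,
                "substrate": params.substrate,
                "mode": params.mode,
                "cell_density": params.cell_density,
            }
        )
    plate = pd.concat(plate_rows, ignore_index=True)
    layout = pd.DataFrame(layout_rows)
    return plate, layout, truths


def make_calibration_standards(
    fluorophore: CalibrationCurve | None = None,
    ph_grid: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Standards table (ph, rfu) from the forward fluorophore model.

    Default grid is pH 4.0 to 7.0 in 0.5 steps, the range over which the
    reader gain is set; grids must stay within pH 2-12.
    """
    cal = fluorophore if fluorophore is not None else default_fluorophore()
    grid = np.asarray(
        ph_grid if ph_grid is not None else np.arange(4.0, 7.0 + 1e-9, 0.5),
        dtype=float,
    )
    if grid.min() < 2.0 or grid.max() > 12.0:
        raise ValueError("standards grid must lie within pH 2-12")
    rfu = cal._forward(grid)
    if noise_sd > 0:
        rfu = rfu + np.random.default_rng(seed).normal(0.0, noise_sd, grid.shape)
    return pd.DataFrame({"ph": grid, "rfu": rfu})


def make_titration_table(
    medium: BufferSystem | None = None,
    mode: str = "acid",
    grid: Sequence[float] | None = None,
    start_ph: float | None = None,
) -> TitrationCurve:
    """Modelled titration curve for the assay medium.

    Defaults reproduce the operational ranges of the assay: acid-mode
    curves run from the pH 6.5 resting point down past pH 4.0, base-mode
    curves from pH 5.5 up past 7.0.
    """
    if mode not in ("acid", "base"):
        raise ValueError(f"unknown mode {mode!r}")
    resolved_start = DEFAULT_START_PH[mode] if start_ph is None else start_ph
    system = (medium if medium is not None else default_assay_medium()).poised_at(
        resolved_start
    )
    if grid is None:
        return model_titration(system, mode, DEFAULT_TITRATION_GRIDS[mode])
    # custom grids are the caller's responsibility; skip the window check
    return model_titration(system, mode, grid, required_ph_window=None)
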