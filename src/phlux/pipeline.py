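"""File ingestion, run orchestration, agreement statistics and reporting.

All on-disk formats are plain delimited text:

* plate:      ``well_id,time_h,rfu`` (long format, one row per reading)
* layout:     ``well_id,role,strain,pre_culture,substrate,mode,cell_density``
* standards:  ``ph,rfu``
* titration:  ``added_equivalents_mol_per_L,ph`` with a ``# mode: acid``
              comment line
* calibration: ``key: value`` lines

Concentrations are mol/L in every file; human-readable report text uses
millimolar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import linregress

from . import calibration as _calibration
from .calibration import CalibrationCurve, fit_calibration
from .chemistry import TitrationCurve
from .errors import ConfigError, DataError, PhluxError
from .kinetics import (
    DecayFit,
    RateSeries,
    bin_rates,
    extrapolate_yield,
    fit_decay,
    fold_decline,
)
from .quantify import (
    NoiseThreshold,
    ProductionSeries,
    WellMeta,
    WellSeries,
    censor_below_threshold,
    estimate_noise_threshold,
    well_to_production,
)

PLATE_COLUMNS = ("well_id", "time_h", "rfu")
LAYOUT_COLUMNS = (
    "well_id", "role", "strain", "pre_culture", "substrate", "mode", "cell_density",
)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, required_columns):
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"{path}: unparseable delimited text ({exc})") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    return df


def _require_numeric(df, columns, path):
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            lines = (df.index[coerced.isna()] + 2).tolist()[:8]
            raise DataError(
                f"{path}: unparseable numeric values in column {col!r} "
                f"(data lines {lines})"
            )
        df[col] = coerced
    return df


def read_layout(path) -> pd.DataFrame:
    df = _read_table(path, LAYOUT_COLUMNS)
    df = _require_numeric(df, ["cell_density"], path)
    df = df.fillna({"strain": "", "pre_culture": "", "substrate": ""})
    dup = df["well_id"].duplicated()
    if dup.any():
        raise DataError(
            f"{path}: duplicated well ids {sorted(df['well_id'][dup].unique())}"
        )
    return df


def read_plate(path, layout=None) -> list[WellSeries]:
    """Assemble per-well series from a long-format plate table.

    ``layout`` may be a path or a DataFrame; when given, metadata is
    joined onto each well and wells present in the data but absent from
    the layout are excluded with a warning.  Duplicated (well, time) rows
    and unparseable numerics are data errors reported with line numbers.
    """
    df = _read_table(path, PLATE_COLUMNS)
    df = _require_numeric(df, ["time_h", "rfu"], path)
    dup = df.duplicated(subset=["well_id", "time_h"], keep=False)
    if dup.any():
        first_lines = (df.index[dup] + 2).tolist()[:8]
        raise DataError(
            f"{path}: duplicated (well_id, time_h) rows at data lines "
            f"{first_lines}"
        )
    meta_by_well = {}
    if layout is not None:
        layout_df = layout if isinstance(layout, pd.DataFrame) else read_layout(layout)
        for row in layout_df.itertuples(index=False):
            meta_by_well[row.well_id] = WellMeta(
                role=row.role,
                strain=str(row.strain),
                pre_culture=str(row.pre_culture),
                substrate=str(row.substrate),
                mode=row.mode,
                cell_density=float(row.cell_density),
            )
    wells = []
    for well_id, group in df.groupby("well_id", sort=True):
        if layout is not None and well_id not in meta_by_well:
            warnings.warn(
                f"well {well_id} present in plate data but not in the "
                "layout; excluded",
                stacklevel=2,
            )
            continue
        group = group.sort_values("time_h")
        wells.append(
            WellSeries(
                well_id=str(well_id),
                times=group["time_h"].to_numpy(),
                rfu=group["rfu"].to_numpy(),
                meta=meta_by_well.get(well_id, WellMeta()),
            )
        )
    return wells


def read_standards(path) -> list[tuple[float, float]]:
    df = _read_table(path, ("ph", "rfu"))
    df = _require_numeric(df, ["ph", "rfu"], path)
    return list(zip(df["ph"], df["rfu"]))


def read_titration(path, mode: str | None = None) -> TitrationCurve:
    """Read a titration table; mode comes from a ``# mode:`` comment line
    unless given explicitly."""
    path = Path(path)
    if mode is None:
        for line in path.read_text().splitlines():
            if line.startswith("#") and "mode:" in line:
                mode = line.split("mode:")[1].strip()
                break
    if mode is None:
        raise ConfigError(
            f"{path}: titration mode not declared (add a '# mode: acid' "
            "comment line or pass mode explicitly)"
        )
    df = _read_table(path, ("added_equivalents_mol_per_L", "ph"))
    df = _require_numeric(df, ["added_equivalents_mol_per_L", "ph"], path)
    return TitrationCurve(
        added_equivalents=df["added_equivalents_mol_per_L"].to_numpy(),
        ph=df["ph"].to_numpy(),
        mode=mode,
        source="empirical",
    )


def write_titration(curve: TitrationCurve, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# mode: {curve.mode}\n# source: {curve.source}\n")
        curve.to_frame().to_csv(fh, index=False)


def save_calibration(curve: CalibrationCurve, path) -> None:
    """Serialize a calibration curve to a key-value text file."""
    path = Path(path)
    lines = [
        f"r_min: {curve.r_min!r}",
        f"r_max: {curve.r_max!r}",
        f"apparent_pka: {curve.apparent_pka!r}",
        f"hill_slope: {curve.hill_slope!r}",
        f"valid_ph_min: {curve.valid_ph_range[0]!r}",
        f"valid_ph_max: {curve.valid_ph_range[1]!r}",
        f"fit_residual_rms: {curve.fit_residual_rms!r}",
    ]
    if curve.fallback_points is not None:
        ph, rfu = curve.fallback_points
        lines.append("fallback_ph: " + ",".join(repr(v) for v in ph))
        lines.append("fallback_rfu: " + ",".join(repr(v) for v in rfu))
    path.write_text("\n".join(lines) + "\n")


def load_calibration(path) -> CalibrationCurve:
    entries = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        entries[key.strip()] = value.strip()
    fallback = None
    if "fallback_ph" in entries:
        fallback = (
            np.array([float(v) for v in entries["fallback_ph"].split(",")]),
            np.array([float(v) for v in entries["fallback_rfu"].split(",")]),
        )
    return CalibrationCurve(
        r_min=float(entries["r_min"]),
        r_max=float(entries["r_max"]),
        apparent_pka=float(entries["apparent_pka"]),
        hill_slope=float(entries["hill_slope"]),
        valid_ph_range=(float(entries["valid_ph_min"]), float(entries["valid_ph_max"])),
        fit_residual_rms=float(entries["fit_residual_rms"]),
        fallback_points=fallback,
    )


# ---------------------------------------------------------------------------
# configuration and run result


@dataclass
class RunConfig:
    """Everything a full analysis run needs.

    ``x_variable`` (the abscissa of the decay fits: ``'time'`` or
    ``'cumulative_product'``) must be chosen explicitly — reports never
    silently default it, because the two conventions give differently
    scaled decay constants.
    """

    plate: str | Path = ""
    layout: str | Path = ""
    standards: str | Path = ""
    titration: str | Path = ""
    output_dir: str | Path | None = None
    mode: str = "acid"
    x_variable: str | None = None
    bin_width: float = 0.001
    decay_orders: tuple[int, ...] = (1, 2)
    threshold_multiplier: float = 1.0
    explicit_threshold: float | None = None
    baseline_points: int = 5
    smooth: bool = False
    smooth_window_h: float = 12.0
    calibration_interpolation: bool = False
    horizons: tuple[float, ...] = (1440.0,)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("decay_orders", "horizons"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("plate", "layout", "standards", "titration"):
            value = getattr(self, name)
            if not value:
                raise ConfigError(f"config field {name!r} is required")
            if not Path(value).exists():
                raise ConfigError(f"{name} file not found: {value}")
        if self.mode not in ("acid", "base"):
            raise ConfigError(f"mode must be 'acid' or 'base', got {self.mode!r}")
        if self.x_variable not in ("time", "cumulative_product"):
            raise ConfigError(
                "x_variable must be set explicitly to 'time' or "
                "'cumulative_product'"
            )
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if any(o not in (1, 2) for o in self.decay_orders):
            raise ConfigError("decay_orders may contain only 1 and 2")


@dataclass
class WellResult:
    """Per-well outcome of a pipeline run."""

    well_id: str
    production: ProductionSeries
    rates: RateSeries | None = None
    fits: dict = field(default_factory=dict)  # order -> DecayFit
    fold_decline: dict = field(default_factory=dict)  # order -> float
    yields: dict = field(default_factory=dict)  # (order, horizon) -> float
    error: str | None = None


@dataclass
class RunResult:
    """Aggregated outcome of :func:`run_pipeline`."""

    config: RunConfig
    calibration: CalibrationCurve
    titration: TitrationCurve
    threshold: NoiseThreshold
    wells: dict  # well_id -> WellResult (sample wells)
    controls: dict  # well_id -> ProductionSeries
    failures: dict = field(default_factory=dict)  # well_id -> message
    warnings: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """One row per sample well, both fitted orders side by side."""
        rows = []
        for well_id, res in sorted(self.wells.items()):
            meta = res.production.meta
            row = {
                "well_id": well_id,
                "strain": meta.strain,
                "pre_culture": meta.pre_culture,
                "substrate": meta.substrate,
                "mode": meta.mode,
                "cell_density": meta.cell_density,
                "threshold_mol_per_L": float(self.threshold),
                "n_bins": res.rates.n_bins if res.rates is not None else 0,
                "error": res.error or "",
            }
            best = None
            for order in sorted(res.fits):
                fit = res.fits[order]
                row[f"r0_order{order}"] = fit.initial_rate_r0
                row[f"k_order{order}"] = fit.decay_constant_k
                row[f"r2_order{order}"] = fit.r_squared
                row[f"fold_decline_order{order}"] = res.fold_decline.get(order)
                for horizon in self.config.horizons:
                    key = (order, horizon)
                    if key in res.yields:
                        row[f"yield_{horizon:g}h_order{order}"] = res.yields[key]
                if best is None or fit.r_squared > res.fits[best].r_squared:
                    best = order
            row["best_order"] = best
            rows.append(row)
        return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """calibrate -> quantify -> threshold -> censor -> bin -> fit.

    Deterministic given inputs and configuration.  A failing well is
    recorded in ``result.failures`` (and on its ``WellResult``) without
    aborting the run; mode mismatches between config, titration table and
    layout are rejected before any computation.
    """
    config.validate()
    collected: list[str] = []

    tit = read_titration(config.titration)
    if tit.mode != config.mode:
        raise ConfigError(
            f"run mode is {config.mode!r} but the titration table is "
            f"{tit.mode!r}-mode"
        )
    cal = fit_calibration(
        read_standards(config.standards),
        force_interpolation=config.calibration_interpolation,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        wells = read_plate(config.plate, layout=config.layout)
        matching = [w for w in wells if w.meta.mode == config.mode]
        skipped = [w.well_id for w in wells if w.meta.mode != config.mode]
        if skipped:
            warnings.warn(
                f"wells {skipped} are not {config.mode}-mode; excluded from "
                "this run"
            )
        if not matching:
            raise ConfigError(
                f"no {config.mode}-mode wells in the layout; nothing to analyse"
            )

        controls, samples, failures = {}, {}, {}
        for well in matching:
            # controls are never smoothed: the noise threshold must
            # characterize the raw conversion-chain noise
            is_control = well.meta.role == "negative_control"
            try:
                prod = well_to_production(
                    well, cal, tit,
                    baseline_points=config.baseline_points,
                    smooth=config.smooth and not is_control,
                    smooth_window_h=config.smooth_window_h,
                )
            except PhluxError as exc:
                failures[well.well_id] = str(exc)
                continue
            if is_control:
                controls[well.well_id] = prod
            elif well.meta.role == "sample":
                samples[well.well_id] = prod

        if config.explicit_threshold is not None:
            threshold = NoiseThreshold(
                float(config.explicit_threshold), {}, multiplier=1.0
            )
        else:
            threshold = estimate_noise_threshold(
                controls.values(), multiplier=config.threshold_multiplier
            )

        well_results = {}
        for well_id, prod in samples.items():
            censored = censor_below_threshold(prod, float(threshold))
            res = WellResult(well_id=well_id, production=censored)
            well_results[well_id] = res
            try:
                res.rates = bin_rates(
                    censored, bin_width=config.bin_width, smooth=config.smooth
                )
                for order in config.decay_orders:
                    fit = fit_decay(res.rates, order, config.x_variable)
                    res.fits[order] = fit
                    x = res.rates.x(config.x_variable)
                    res.fold_decline[order] = fold_decline(
                        fit, window_start=float(x[0]), window_end=float(x[-1])
                    )
                    if config.x_variable == "time":
                        for horizon in config.horizons:
                            res.yields[(order, horizon)] = float(
                                extrapolate_yield(fit, horizon)
                            )
            except PhluxError as exc:
                res.error = str(exc)
                failures[well_id] = str(exc)

    collected.extend(str(w.message) for w in caught)
    return RunResult(
        config=config,
        calibration=cal,
        titration=tit,
        threshold=threshold,
        wells=well_results,
        controls=controls,
        failures=failures,
        warnings=collected,
    )


# ---------------------------------------------------------------------------
# agreement statistic


@dataclass(frozen=True)
class Agreement:
    """Least-squares agreement between derived and reference series."""

    r_squared: float
    slope: float
    intercept: float
    n: int


def agreement_r2(derived, reference) -> Agreement:
    """Coefficient of determination of derived vs reference concentrations.

    Used to compare indicator-derived production with an independent
    chemical reference measurement (e.g. chromatography) at matched time
    points.  Requires >= 3 matched points and a non-constant reference.
    """
    derived = np.asarray(derived, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if derived.shape != reference.shape or derived.ndim != 1:
        raise DataError("derived and reference must be matching 1-D series")
    if len(derived) < 3:
        raise DataError("need at least 3 matched points")
    if np.ptp(reference) == 0:
        raise DataError("reference series is constant; r-squared undefined")
    res = linregress(reference, derived)
    return Agreement(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(derived),
    )


# ---------------------------------------------------------------------------
# reporting


def _fit_record(well_id: str, fit: DecayFit, fold: float | None) -> str:
    parts = [
        f"well: {well_id}",
        f"order: {fit.order}",
        f"x_variable: {fit.x_variable}",
        f"slope: {fit.slope!r}",
        f"intercept: {fit.intercept!r}",
        f"r0_M_per_h: {fit.initial_rate_r0!r}",
        f"k_per_x: {fit.decay_constant_k!r}",
        f"r_squared: {fit.r_squared!r}",
        f"n_bins: {fit.n_points}",
    ]
    if fold is not None:
        parts.append(f"fold_decline_observed_window: {fold!r}")
    return "\n".join(parts) + "\n"


def write_report(result: RunResult, outdir, plots: bool = False) -> Path:
    """Write the summary table, per-well traces, fit records and run log.

    Deterministic: regenerating the report from the same ``RunResult``
    produces byte-identical files.  With ``plots=True`` a four-panel
    figure (signal is not stored, so pH, cumulative production, rate vs
    production, and transformed-rate fits) is saved per well.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = result.summary()
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)

    records = []
    for well_id, res in sorted(result.wells.items()):
        trace = pd.DataFrame(
            {
                "time_h": res.production.times,
                "cumulative_mol_per_L": res.production.cumulative,
            }
        )
        trace["censored"] = np.arange(len(trace)) <= res.production.censored_prefix_end
        trace.to_csv(outdir / f"well_{well_id}_trace.tsv", sep="\t", index=False)
        for order, fit in sorted(res.fits.items()):
            records.append(_fit_record(well_id, fit, res.fold_decline.get(order)))
    (outdir / "fits.txt").write_text("\n".join(records))

    log_lines = ["run configuration (all values, defaults included):"]
    for key, value in asdict(result.config).items():
        log_lines.append(f"  {key}: {value}")
    log_lines.append(f"noise_threshold_mol_per_L: {float(result.threshold)!r}")
    for well_id, maximum in sorted(result.threshold.per_control.items()):
        log_lines.append(f"  control {well_id} max |production|: {maximum!r}")
    for message in result.warnings:
        log_lines.append(f"warning: {message}")
    for well_id, message in sorted(result.failures.items()):
        log_lines.append(f"failed well {well_id}: {message}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    if plots:
        _write_plots(result, outdir)
    return outdir / "summary.tsv"


def _write_plots(result: RunResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for well_id, res in sorted(result.wells.items()):
        prod = res.production
        fig, axes = plt.subplots(2, 2, figsize=(9, 7))
        ph = result.titration.ph
        axes[0, 0].plot(prod.times, prod.cumulative * 1e3)
        axes[0, 0].axhline(prod.noise_threshold * 1e3, ls="--", c="grey")
        axes[0, 0].set(xlabel="time (h)", ylabel="production (mM)")
        axes[0, 1].plot(result.titration.added_equivalents * 1e3, ph)
        axes[0, 1].set(xlabel="added equivalents (mM)", ylabel="pH",
                       title="titration curve")
        if res.rates is not None:
            axes[1, 0].plot(res.rates.bin_mid_cumulative * 1e3, res.rates.rate, "o")
            axes[1, 0].set(xlabel="cumulative production (mM)",
                           ylabel="rate (M/h)")
            x = res.rates.x(result.config.x_variable)
            axes[1, 1].semilogy(x, res.rates.rate, "o")
            for order, fit in sorted(res.fits.items()):
                axes[1, 1].semilogy(x, fit.rate_at(x), label=f"order {order}")
            axes[1, 1].legend()
            axes[1, 1].set(xlabel=result.config.x_variable, ylabel="rate (M/h)")
        fig.suptitle(f"well {well_id}")
        fig.tight_layout()
        fig.savefig(outdir / f"well_{well_id}.png", dpi=110)
        plt.close(fig)


# ---------------------------------------------------------------------------
# result persistence (for report regeneration)


def save_result(result: RunResult, outdir) -> None:
    """Persist the analysis outcome (fits, threshold, traces) as text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
            for k, v in asdict(result.config).items()
        },
        "threshold": {
            "threshold": float(result.threshold),
            "per_control": result.threshold.per_control,
            "multiplier": result.threshold.multiplier,
        },
        "wells": {},
        "failures": result.failures,
        "warnings": result.warnings,
    }
    for well_id, res in result.wells.items():
        payload["wells"][well_id] = {
            "meta": asdict(res.production.meta),
            "times": res.production.times.tolist(),
            "cumulative": res.production.cumulative.tolist(),
            "censored_prefix_end": res.production.censored_prefix_end,
            "n_bins": res.rates.n_bins if res.rates is not None else 0,
            "error": res.error,
            "fits": {
                str(order): asdict(fit) for order, fit in res.fits.items()
            },
            "fold_decline": {str(o): v for o, v in res.fold_decline.items()},
            "yields": {
                f"{o}:{h:g}": v for (o, h), v in res.yields.items()
            },
        }
    (outdir / "result.json").write_text(json.dumps(payload, indent=1))
    save_calibration(result.calibration, outdir / "calibration.txt")
    write_titration(result.titration, outdir / "titration.csv")


def load_result(outdir) -> RunResult:
    """Reload a saved run sufficient to regenerate its report."""
    outdir = Path(outdir)
    payload = json.loads((outdir / "result.json").read_text())
    cfg_raw = dict(payload["config"])
    for key in ("decay_orders", "horizons"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = RunConfig(**cfg_raw)
    threshold = NoiseThreshold(
        payload["threshold"]["threshold"],
        payload["threshold"]["per_control"],
        payload["threshold"]["multiplier"],
    )
    wells = {}
    for well_id, w in payload["wells"].items():
        meta = WellMeta(**w["meta"])
        prod = ProductionSeries(
            well_id=well_id,
            times=np.array(w["times"]),
            cumulative=np.array(w["cumulative"]),
            mode=meta.mode,
            noise_threshold=float(threshold),
            censored_prefix_end=w["censored_prefix_end"],
            meta=meta,
        )
        res = WellResult(well_id=well_id, production=prod, error=w["error"])
        for order_str, fit_raw in w["fits"].items():
            res.fits[int(order_str)] = DecayFit(**fit_raw)
        res.fold_decline = {int(o): v for o, v in w["fold_decline"].items()}
        res.yields = {
            (int(key.split(":")[0]), float(key.split(":")[1])): v
            for key, v in w["yields"].items()
        }
        if w["n_bins"]:
            # enough to rebuild n_bins-dependent summary columns
            res.rates = _rates_stub(w["n_bins"])
        wells[well_id] = res
    return RunResult(
        config=config,
        calibration=load_calibration(outdir / "calibration.txt"),
        titration=read_titration(outdir / "titration.csv"),
        threshold=threshold,
        wells=wells,
        controls={},
        failures=payload["failures"],
        warnings=payload["warnings"],
    )


def _rates_stub(n_bins: int) -> RateSeries:
    edges = np.arange(n_bins + 1, dtype=float)
    return RateSeries(
        bin_edges=edges,
        bin_mid_cumulative=0.5 * (edges[:-1] + edges[1:]),
        bin_mid_time=0.5 * (edges[:-1] + edges[1:]),
        rate=np.ones(n_bins),
        bin_width=1.0,
    )
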