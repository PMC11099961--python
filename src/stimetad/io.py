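"""File formats, configuration, reports, and the end-to-end pipeline.

Plain-text formats only: FPT lists are one positive number (ns) per line
with ``#`` comments; configuration is INI-style with sections
``[simulation]``, ``[metad]``, ``[inference]``, ``[bootstrap]``; reports
carry a human-readable block plus a machine-readable ``key = value`` block
that round-trips to the same floats; the run manifest is JSON and records
everything needed to reproduce a run bit-for-bit (config snapshot, master
seed, per-trajectory outcomes).
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import FormatError
from .inference import (
    BootstrapSummary,
    ExpFitResult,
    STFitResult,
    bootstrap_mfpt,
    fit_exponential_imetad,
    speedup,
    st_fit,
)
from .potential import Position2D
from .rescaling import FPTSample, rescale_fpt, write_bias_series
from .simulator import (
    MetaDConfig,
    SimulationConfig,
    deposition_rate_to_period,
    run_fpt_trajectory,
)

__all__ = [
    "read_fpt_list",
    "write_fpt_list",
    "load_config",
    "RunConfig",
    "RunManifest",
    "InferenceReport",
    "infer_both",
    "write_report",
    "parse_report",
    "end_to_end",
]

logger = logging.getLogger(__name__)

VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# FPT lists
# ---------------------------------------------------------------------------


def read_fpt_list(path: str | Path) -> FPTSample:
    """Read a one-value-per-line FPT file (ns); ``#`` comments and blanks ok."""
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.split("#", 1)[0].strip()
            if not text:
                continue
            try:
                v = float(text)
            except ValueError:
                raise FormatError(f"non-numeric value {text!r}", line=lineno) from None
            if v <= 0:
                raise FormatError(f"non-positive FPT {v}", line=lineno)
            values.append(v)
    return FPTSample(values=np.asarray(values), label=path.stem)


def write_fpt_list(
    sample: FPTSample, path: str | Path, header: dict[str, Any] | None = None
) -> None:
    """Write an FPT list with provenance recorded as ``#`` header comments."""
    with Path(path).open("w") as fh:
        if sample.label:
            fh.write(f"# label: {sample.label}\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        for v in sample.values:
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; mirrors the config-file sections."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    metad: MetaDConfig | None = field(default_factory=MetaDConfig)
    n_traj: int = 200
    seed: int = 0
    min_points: int = 5
    fit_method: str = "both"  # imetad | st-imetad | both
    bootstrap: bool = True
    n_batches: int = 1000
    batch_size: int = 200


def load_config(path: str | Path) -> RunConfig:
    """Parse an INI config; every key is optional and defaults to the
    reference Wolfe–Quapp conditions."""
    cp = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    read = cp.read(path)
    if not read:
        raise FormatError(f"cannot read config file {path}")

    sim_kwargs: dict[str, Any] = {}
    sim = cp["simulation"] if cp.has_section("simulation") else {}
    for key, cast in [
        ("mass", float),
        ("temperature", float),
        ("timestep", float),
        ("friction", float),
        ("stop_check_stride", int),
        ("max_steps", lambda s: int(float(s))),
        ("target_x_max", float),
        ("target_y_min", float),
        ("potential_scale", float),
    ]:
        if key in sim:
            sim_kwargs[key] = cast(sim[key])
    if "start_x" in sim or "start_y" in sim:
        sim_kwargs["start"] = Position2D(
            float(sim.get("start_x", 1.564)), float(sim.get("start_y", -1.334))
        )
    simulation = SimulationConfig(**sim_kwargs)

    metad: MetaDConfig | None = None
    md = cp["metad"] if cp.has_section("metad") else {}
    if str(md.get("enabled", "true")).lower() not in ("false", "0", "no"):
        md_kwargs: dict[str, Any] = {}
        for key, cast in [
            ("hill_height_h0", float),
            ("bias_factor_gamma", float),
            ("hill_width_sigma", float),
            ("grid_spacing", float),
            ("deposition_period", int),
            ("cv_angle_theta", float),
            ("grid_min", float),
            ("grid_max", float),
        ]:
            if key in md:
                md_kwargs[key] = cast(md[key])
        if "deposition_rate" in md:
            md_kwargs["deposition_period"] = deposition_rate_to_period(
                float(md["deposition_rate"]), simulation.timestep
            )
        metad = MetaDConfig(**md_kwargs)

    cfg = RunConfig(simulation=simulation, metad=metad)
    if "n_traj" in sim:
        cfg.n_traj = int(sim["n_traj"])
    if "seed" in sim:
        cfg.seed = int(sim["seed"])
    inf = cp["inference"] if cp.has_section("inference") else {}
    if "min_points" in inf:
        cfg.min_points = int(inf["min_points"])
    if "method" in inf:
        cfg.fit_method = str(inf["method"])
    bs = cp["bootstrap"] if cp.has_section("bootstrap") else {}
    if "enabled" in bs:
        cfg.bootstrap = str(bs["enabled"]).lower() not in ("false", "0", "no")
    if "n_batches" in bs:
        cfg.n_batches = int(bs["n_batches"])
    if "batch_size" in bs:
        cfg.batch_size = int(bs["batch_size"])
    return cfg


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class InferenceReport:
    """Joint result of both inference routes on one FPT sample."""

    label: str
    n: int
    standard: ExpFitResult | None = None
    short_time: STFitResult | None = None
    bootstrap_standard: BootstrapSummary | None = None
    bootstrap_short_time: BootstrapSummary | None = None
    speedup: float | None = None

    def machine_fields(self) -> dict[str, Any]:
        out: dict[str, Any] = {"label": self.label, "n": self.n}
        if self.standard is not None:
            out["imetad_mfpt_ns"] = self.standard.mfpt
            out["imetad_ks_statistic"] = self.standard.ks_statistic
            out["imetad_ks_pvalue"] = self.standard.p_value
        if self.short_time is not None:
            out["st_mfpt_ns"] = self.short_time.mfpt
            out["st_rate_per_ns"] = self.short_time.rate_k
            out["st_t_star_ns"] = self.short_time.t_star
            out["st_r_squared"] = self.short_time.r_squared
            out["st_n_points"] = self.short_time.n_points
        for name, bs in [
            ("imetad", self.bootstrap_standard),
            ("st", self.bootstrap_short_time),
        ]:
            if bs is not None:
                out[f"{name}_boot_median_ns"] = bs.median
                out[f"{name}_boot_q1_ns"] = bs.q1
                out[f"{name}_boot_q3_ns"] = bs.q3
                out[f"{name}_boot_whisker_lo_ns"] = bs.whisker_lo
                out[f"{name}_boot_whisker_hi_ns"] = bs.whisker_hi
                out[f"{name}_boot_n_failed"] = bs.n_failed
        if self.speedup is not None:
            out["speedup"] = self.speedup
        return out


def infer_both(
    sample: FPTSample,
    method: str = "both",
    min_points: int = 5,
    bootstrap: bool = False,
    n_batches: int = 1000,
    batch_size: int = 200,
    seed: int | None = None,
    unbiased_mfpt: float | None = None,
    biased_physical_fpts: np.ndarray | None = None,
) -> InferenceReport:
    """Run the requested estimator(s), optionally with bootstrap and speedup."""
    rep = InferenceReport(label=sample.label, n=len(sample))
    do_std = method in ("imetad", "both")
    do_st = method in ("st-imetad", "both")
    if do_std:
        rep.standard = fit_exponential_imetad(sample)
        if bootstrap:
            rep.bootstrap_standard = bootstrap_mfpt(
                sample, "standard", n_batches, batch_size, seed=seed
            )
    if do_st:
        rep.short_time = st_fit(sample, min_points=min_points)
        if bootstrap:
            rep.bootstrap_short_time = bootstrap_mfpt(
                sample,
                "short_time",
                n_batches,
                batch_size,
                seed=None if seed is None else seed + 1,
                min_points=min_points,
            )
    if unbiased_mfpt is not None and biased_physical_fpts is not None:
        rep.speedup = speedup(unbiased_mfpt, biased_physical_fpts)
    return rep


_MACHINE_MARK = "# --- machine-readable ---"


def write_report(report: InferenceReport, path: str | Path) -> None:
    """Write a report: rounded human-readable block, then full-precision
    ``key = value`` lines.  Absent quantities are written as ``absent``,
    never as zero."""
    lines = [f"Kinetics inference report for '{report.label}' (n = {report.n})", ""]
    if report.standard is not None:
        s = report.standard
        lines += [
            f"Standard whole-sample exponential fit: MFPT = {s.mfpt:.4g} ns",
            f"  KS statistic {s.ks_statistic:.3g}, p-value {s.p_value:.3g} "
            f"({'reliable' if s.p_value > 0.05 else 'UNRELIABLE'} at p > 0.05)",
        ]
    if report.short_time is not None:
        st = report.short_time
        lines += [
            f"Short-time survival fit: MFPT = {st.mfpt:.4g} ns "
            f"(k = {st.rate_k:.4g} /ns)",
            f"  cutoff t* = {st.t_star:.4g} ns using {st.n_points} points, "
            f"R^2 = {st.r_squared:.4f}",
        ]
    for name, bs in [
        ("standard", report.bootstrap_standard),
        ("short-time", report.bootstrap_short_time),
    ]:
        if bs is not None:
            lines.append(
                f"Bootstrap ({name}, {bs.n_batches} batches of {bs.batch_size}): "
                f"median {bs.median:.4g} ns, IQR [{bs.q1:.4g}, {bs.q3:.4g}], "
                f"whiskers [{bs.whisker_lo:.4g}, {bs.whisker_hi:.4g}]"
            )
    if report.speedup is not None:
        lines.append(f"Speedup (unbiased MFPT / mean biased FPT): {report.speedup:.4g}")
    lines += ["", _MACHINE_MARK]
    fields = report.machine_fields()
    for key in _all_report_keys():
        val = fields.get(key, "absent")
        if isinstance(val, float):
            val = repr(val)
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def _all_report_keys() -> list[str]:
    return [
        "label",
        "n",
        "imetad_mfpt_ns",
        "imetad_ks_statistic",
        "imetad_ks_pvalue",
        "st_mfpt_ns",
        "st_rate_per_ns",
        "st_t_star_ns",
        "st_r_squared",
        "st_n_points",
        "imetad_boot_median_ns",
        "imetad_boot_q1_ns",
        "imetad_boot_q3_ns",
        "imetad_boot_whisker_lo_ns",
        "imetad_boot_whisker_hi_ns",
        "imetad_boot_n_failed",
        "st_boot_median_ns",
        "st_boot_q1_ns",
        "st_boot_q3_ns",
        "st_boot_whisker_lo_ns",
        "st_boot_whisker_hi_ns",
        "st_boot_n_failed",
        "speedup",
    ]


def parse_report(path: str | Path) -> dict[str, Any]:
    """Re-parse the machine-readable block of a report to exact values."""
    out: dict[str, Any] = {}
    seen = False
    for raw in Path(path).read_text().splitlines():
        if raw.strip() == _MACHINE_MARK:
            seen = True
            continue
        if not seen or "=" not in raw:
            continue
        key, val = (part.strip() for part in raw.split("=", 1))
        if val == "absent":
            out[key] = None
        else:
            try:
                out[key] = int(val)
            except ValueError:
                try:
                    out[key] = float(val)
                except ValueError:
                    out[key] = val
    if not seen:
        raise FormatError(f"no machine-readable block in {path}")
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility record of one end-to-end run."""

    config: dict[str, Any]
    master_seed: int
    version: str
    timestamp: str
    fpts_physical_ns: list[float]
    fpts_rescaled_ns: list[float]
    accelerations: list[float]
    reached: list[bool]
    n_censored: int
    report: dict[str, Any]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _config_snapshot(cfg: RunConfig) -> dict[str, Any]:
    snap = {
        "simulation": dataclasses.asdict(cfg.simulation),
        "metad": None if cfg.metad is None else dataclasses.asdict(cfg.metad),
        "n_traj": cfg.n_traj,
        "seed": cfg.seed,
        "min_points": cfg.min_points,
        "fit_method": cfg.fit_method,
        "bootstrap": cfg.bootstrap,
        "n_batches": cfg.n_batches,
        "batch_size": cfg.batch_size,
    }
    snap["simulation"]["start"] = list(cfg.simulation.start)
    return snap


def end_to_end(
    cfg: RunConfig,
    outdir: str | Path,
    write_colvar: bool = False,
) -> RunManifest:
    """Run the full pipeline: simulate N trajectories, rescale, infer, report.

    Every random draw descends from ``cfg.seed`` through a SeedSequence
    spawn, so reruns with the same config reproduce identical estimates.
    Censored trajectories are excluded from inference and counted in the
    manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    traj_seeds = ss.spawn(cfg.n_traj)
    boot_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    physical: list[float] = []
    rescaled: list[float] = []
    accels: list[float] = []
    reached: list[bool] = []
    for i, child in enumerate(traj_seeds):
        rng = np.random.default_rng(child)
        traj = run_fpt_trajectory(
            cfg.simulation,
            cfg.metad,
            rng,
            record_bias=cfg.metad is not None,
        )
        reached.append(traj.reached)
        if not traj.reached:
            logger.warning("trajectory %d censored at max_steps; excluded", i)
            continue
        if cfg.metad is None:
            physical.append(traj.fpt_physical)
            rescaled.append(traj.fpt_physical)
            accels.append(1.0)
        else:
            r = rescale_fpt(traj)
            physical.append(r.physical_fpt)
            rescaled.append(r.value)
            accels.append(r.acceleration)
        if write_colvar and traj.cv_series is not None:
            write_bias_series(traj, outdir / f"COLVAR.{i}")
        logger.info(
            "trajectory %d/%d: fpt = %.4g ns%s",
            i + 1,
            cfg.n_traj,
            traj.fpt_physical,
            "" if cfg.metad is None else f", acceleration = {accels[-1]:.3g}",
        )

    n_censored = int(sum(not r for r in reached))
    sample = FPTSample(np.asarray(rescaled), label="rescaled" if cfg.metad else "unbiased")
    write_fpt_list(
        sample,
        outdir / "fpt_rescaled.dat",
        header={"seed": cfg.seed, "n_traj": cfg.n_traj, "n_censored": n_censored},
    )
    report = infer_both(
        sample,
        method=cfg.fit_method,
        min_points=cfg.min_points,
        bootstrap=cfg.bootstrap,
        n_batches=cfg.n_batches,
        batch_size=cfg.batch_size,
        seed=boot_seed,
    )
    write_report(report, outdir / "report.txt")

    manifest = RunManifest(
        config=_config_snapshot(cfg),
        master_seed=cfg.seed,
        version=VERSION,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        fpts_physical_ns=[float(v) for v in physical],
        fpts_rescaled_ns=[float(v) for v in rescaled],
        accelerations=[float(a) for a in accels],
        reached=[bool(r) for r in reached],
        n_censored=n_censored,
        report=report.machine_fields(),
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
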