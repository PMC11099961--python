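"""First-passage-time rescaling by the bias-dependent acceleration factor.

Infrequent metadynamics recovers unbiased kinetics by stretching each
biased trajectory's first-passage time according to the bias it actually
experienced:

    tau = sum_i  dt * exp(beta * V(s(t_i), t_i))

a left-Riemann sum over the per-step instantaneous bias at the walker's CV
position (the bias is piecewise constant between depositions, so the
left-Riemann form is exact for the deposition semantics).  The ratio
tau / t_physical is the acceleration factor; with nonnegative bias it is
always >= 1.

Bias energies are stored in k_B T, so beta = 1 internally; any unit
conversion belongs at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, NotReachedError
from .simulator import BiasTrajectory

__all__ = [
    "RescaledFPT",
    "FPTSample",
    "rescale_fpt",
    "load_bias_series",
    "write_bias_series",
]


@dataclass(frozen=True)
class RescaledFPT:
    """One rescaled first-passage time (ns) with its provenance."""

    value: float  # ns, rescaled
    physical_fpt: float  # ns, as simulated
    acceleration: float  # value / physical_fpt

    def __post_init__(self) -> None:
        if self.physical_fpt > 0 and not np.isclose(
            self.value, self.physical_fpt * self.acceleration, rtol=1e-9
        ):
            raise ValueError("value must equal physical_fpt * acceleration")


@dataclass
class FPTSample:
    """A set of positive first-passage times (ns), unbiased or rescaled."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size and self.values.min() <= 0:
            raise ValueError(
                "FPT samples must be strictly positive; censored or zero "
                "first-passage times cannot enter the inference"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n(self) -> int:
        return len(self)


def rescale_fpt(traj: BiasTrajectory, beta: float = 1.0) -> RescaledFPT:
    """Rescale a biased trajectory's FPT by its accumulated acceleration.

    ``beta`` is in inverse bias-energy units; with the bias recorded in
    k_B T (the package convention) beta = 1.  A trajectory with an empty
    bias series (unbiased run) rescales to its physical FPT unchanged.

    Raises :class:`NotReachedError` for censored trajectories.
    """
    if not traj.reached:
        raise NotReachedError(
            "cannot rescale a censored trajectory that never reached the target"
        )
    dt_ns = traj.timestep * 1e-6
    if traj.bias_series.size == 0:
        value = traj.fpt_physical
    else:
        value = dt_ns * float(np.sum(np.exp(beta * traj.bias_series)))
    accel = value / traj.fpt_physical if traj.fpt_physical > 0 else 1.0
    return RescaledFPT(value=value, physical_fpt=traj.fpt_physical, acceleration=accel)


# ---------------------------------------------------------------------------
# COLVAR-style I/O
# ---------------------------------------------------------------------------

_HEADER_PREFIX = "#! FIELDS"


def write_bias_series(traj: BiasTrajectory, path: str | Path) -> None:
    """Write a per-trajectory COLVAR-style table: time (fs), cv (nm), bias (k_B T)."""
    path = Path(path)
    n = traj.bias_series.size
    cv = traj.cv_series if traj.cv_series is not None else np.zeros(n)
    with path.open("w") as fh:
        fh.write(f"{_HEADER_PREFIX} time cv bias\n")
        for i in range(n):
            t = (i + 1) * traj.timestep
            fh.write(f"{t:.6f} {cv[i]:.9f} {traj.bias_series[i]:.9f}\n")


def load_bias_series(path: str | Path) -> BiasTrajectory:
    """Parse a COLVAR-style table back into a :class:`BiasTrajectory`.

    Columns are identified by the ``#! FIELDS`` header, so any column order
    is accepted as long as ``time`` and ``bias`` are present.  The timestep
    is inferred from consecutive times (which must be uniform), and the last
    time is taken as the physical FPT.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith(_HEADER_PREFIX):
            raise FormatError(
                f"missing '{_HEADER_PREFIX}' header in {path.name}", line=1
            )
        fields = first[len(_HEADER_PREFIX):].split()
        if "time" not in fields or "bias" not in fields:
            raise FormatError("header must declare 'time' and 'bias' fields", line=1)
        i_time = fields.index("time")
        i_bias = fields.index("bias")
        i_cv = fields.index("cv") if "cv" in fields else None

        times: list[float] = []
        biases: list[float] = []
        cvs: list[float] = []
        for lineno, raw in enumerate(fh, start=2):
            text = raw.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) < len(fields):
                raise FormatError(
                    f"expected {len(fields)} columns, got {len(parts)}", line=lineno
                )
            try:
                t = float(parts[i_time])
                b = float(parts[i_bias])
            except ValueError as exc:
                raise FormatError(f"non-numeric value: {exc}", line=lineno) from None
            if b < 0:
                raise FormatError(f"negative bias {b}", line=lineno)
            times.append(t)
            biases.append(b)
            if i_cv is not None:
                cvs.append(float(parts[i_cv]))

    if not times:
        raise FormatError(f"{path.name} contains a header but no data rows")
    t_arr = np.asarray(times)
    if len(t_arr) == 1:
        dt = t_arr[0]
    else:
        steps = np.diff(t_arr)
        dt = float(np.median(steps))
        if dt <= 0 or np.max(np.abs(steps - dt)) > 1e-6 * dt:
            raise FormatError("time column is not uniformly spaced")
    return BiasTrajectory(
        timestep=dt,
        bias_series=np.asarray(biases),
        fpt_physical=float(t_arr[-1]) * 1e-6,
        reached=True,
        cv_series=np.asarray(cvs) if i_cv is not None else None,
    )


def write_hills(traj: BiasTrajectory, path: str | Path) -> None:
    """Write a HILLS-style table of the deposited hills."""
    if traj.hills is None:
        raise ValueError("trajectory carries no hill record")
    h = traj.hills
    with Path(path).open("w") as fh:
        fh.write(f"{_HEADER_PREFIX} time center sigma height biasf\n")
        for t, c, ht in zip(h.deposit_times, h.centers, h.heights):
            fh.write(f"{t:.6f} {c:.9f} {h.width:.9f} {ht:.9f} {h.bias_factor:.6f}\n")
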