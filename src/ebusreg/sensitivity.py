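"""Parameter-sensitivity harness for the registration method.

Reproduces, on synthetic phantoms, the one-at-a-time sensitivity protocol
used to characterize the registration: a single search parameter is swept
over a range (positions in [-10, 10] mm at 2.5 mm steps, angles in
[-100, 100] degrees at 25-degree steps, or the stability count ``T`` from
5 to 25 in steps of 5) while all others stay at their defaults.  Every
run starts from a ground-truth pose analog; position/direction/needle
errors against that pose are aggregated per swept value as mean ± std and
[min, max], one table row per value.

Two sweep semantics are supported (a deliberate ambiguity in the
protocol's phrasing): ``mode='offset'`` (default) perturbs the initial
pose by the swept amount before registering, matching runs that "start at
the ground-truth pose" and then displace it; ``mode='increment'`` instead
sets the corresponding initial-simplex increment.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import Pose
from .metrics import DEFAULT_NEEDLE_LENGTH, evaluate_poses
from .phantom import EBUSNoiseSpec, Phantom, simulate_ebus_frame
from .registration import RegistrationConfig, register

__all__ = ["SweepSpec", "run_sweep", "table_to_markdown", "SWEEP_PARAMETERS"]

SWEEP_PARAMETERS = ("dtx", "dty", "dtz", "da", "db", "dc", "T")

# parameter name -> (pose field, default swept values)
_POSITIONAL = {"dtx": "tx", "dty": "ty", "dtz": "tz"}
_ANGULAR = {"da": "a", "db": "b", "dc": "c"}
_DEFAULT_VALUES = {
    **{p: tuple(np.arange(-10.0, 10.1, 2.5)) for p in _POSITIONAL},
    **{p: tuple(np.arange(-100.0, 100.1, 25.0)) for p in _ANGULAR},
    "T": (5, 10, 15, 20, 25),
}
_INCREMENT_INDEX = {"da": 0, "db": 1, "dc": 2, "dtx": 3, "dty": 4, "dtz": 5}


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep definition."""

    parameter: str
    values: tuple[float, ...] = ()
    trials: int = 10
    mode: str = "offset"          # 'offset' | 'increment'
    noise: EBUSNoiseSpec = field(default_factory=EBUSNoiseSpec)
    lN: float = DEFAULT_NEEDLE_LENGTH

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise InvalidInputError(
                f"parameter must be one of {SWEEP_PARAMETERS}, "
                f"got {self.parameter!r}")
        if self.mode not in ("offset", "increment"):
            raise InvalidInputError("mode must be 'offset' or 'increment'")
        if self.trials < 1:
            raise InvalidInputError("trials must be >= 1")
        if not self.values:
            object.__setattr__(self, "values",
                               _DEFAULT_VALUES[self.parameter])


def _perturb(pose: Pose, parameter: str, value: float) -> Pose:
    fld = _POSITIONAL.get(parameter) or _ANGULAR.get(parameter)
    d = pose.to_dict()
    d[fld] += value
    return Pose.from_dict(d)


def run_sweep(phantoms: list[Phantom], sweep: SweepSpec,
              cfg: RegistrationConfig | None = None) -> pd.DataFrame:
    """Run the sweep and tabulate ep / eN / ed statistics per swept value.

    Trials cycle over the phantoms' ground-truth poses; each trial
    simulates a speckled pseudo-EBUS frame at the ground truth (seeded per
    trial, so the sweep is deterministic), registers from the initial pose
    implied by the sweep semantics, and scores the result against the
    ground truth.  Failed registrations are counted, not fatal.

    Returns one row per value with columns ``<metric>_{mean,std,min,max}``
    for ep (mm), eN (mm), ed (deg), plus ``time_mean`` (s), ``n`` and
    ``n_failed``.
    """
    if cfg is None:
        cfg = RegistrationConfig()
    if not phantoms or not any(ph.gt_poses for ph in phantoms):
        raise InvalidInputError("need at least one phantom with ground truth")
    cases = [(ph, pg) for ph in phantoms for pg in ph.gt_poses]
    rows = []
    for value in sweep.values:
        run_cfg = cfg
        if sweep.parameter == "T":
            run_cfg = replace(cfg, T=int(value))
        elif sweep.mode == "increment":
            inc = list(cfg.increments)
            inc[_INCREMENT_INDEX[sweep.parameter]] = float(value)
            run_cfg = replace(cfg, increments=tuple(inc))
        eps, ens, eds, times = [], [], [], []
        n_failed = 0
        for trial in range(sweep.trials):
            ph, pg = cases[trial % len(cases)]
            noise = replace(sweep.noise, seed=sweep.noise.seed + trial)
            frame = simulate_ebus_frame(ph.ct, ph.labels, pg, cfg.fan,
                                        noise=noise)
            pi = pg
            if sweep.parameter != "T" and sweep.mode == "offset":
                pi = _perturb(pg, sweep.parameter, float(value))
            t0 = time.perf_counter()
            try:
                result = register(ph.ct, ph.labels, ph.surface, frame, pi,
                                  run_cfg)
            except Exception:
                n_failed += 1
                continue
            times.append(time.perf_counter() - t0)
            m = evaluate_poses(result.po, pg, lN=sweep.lN, fan=cfg.fan)
            eps.append(m.ep)
            ens.append(m.eN)
            eds.append(m.ed)
        row = {"value": value, "n": len(eps), "n_failed": n_failed,
               "time_mean": float(np.mean(times)) if times else np.nan}
        for name, vals in (("ep", eps), ("eN", ens), ("ed", eds)):
            arr = np.asarray(vals, dtype=float)
            row[f"{name}_mean"] = float(arr.mean()) if arr.size else np.nan
            row[f"{name}_std"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            row[f"{name}_min"] = float(arr.min()) if arr.size else np.nan
            row[f"{name}_max"] = float(arr.max()) if arr.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def table_to_markdown(table: pd.DataFrame, parameter: str) -> str:
    """Render a sweep table as a mean ± std / [min, max] Markdown table."""
    lines = [f"| {parameter} | ep (mm) | eN (mm) | ed (deg) | time (s) |",
             "|---|---|---|---|---|"]
    for _, r in table.iterrows():
        cells = [f"{r['value']:g}"]
        for m in ("ep", "eN", "ed"):
            cells.append(f"{r[f'{m}_mean']:.1f} ± {r[f'{m}_std']:.1f} "
                         f"[{r[f'{m}_min']:.1f}, {r[f'{m}_max']:.1f}]")
        cells.append(f"{r['time_mean']:.1f}")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
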