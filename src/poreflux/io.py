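"""File formats: cycle JSON, trajectory TSV, rate/fit/i-V CSV, run manifests.

All tabular output is plain TSV/CSV written at full float precision with
fixed headers; cycle definitions are a small documented JSON schema. Two
cycle files ship with the package (``builtin_cycle``), parameterized for the
ANT-5-like and ANT-6-like pores.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from collections.abc import Iterable, Mapping
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError
from .estimation import RateEstimate, RateFit, TransitionCounts, TransitionFit
from .iv_analysis import IVCurve, IVPoint
from .kinetic_model import (
    PermeationCycle,
    Transition,
    VoltageRate,
    state_from_label,
)
from .trajectories import Trajectory

__all__ = [
    "read_cycle",
    "write_cycle",
    "builtin_cycle",
    "BUILTIN_CYCLES",
    "write_trajectory",
    "read_trajectory",
    "write_rate_table",
    "read_rate_table",
    "write_fit_table",
    "read_fit_table",
    "write_iv_table",
    "read_iv_table",
    "RunManifest",
    "transition_label",
    "parse_transition_label",
]

BUILTIN_CYCLES = {"ANT-5": "ant_minus5.json", "ANT-6": "ant_minus6.json"}


def transition_label(key: tuple[str, str]) -> str:
    return f"{key[0]}->{key[1]}"


def parse_transition_label(label: str) -> tuple[str, str]:
    parts = label.split("->")
    if len(parts) != 2 or not all(parts):
        raise SchemaError(f"bad transition label {label!r}; expected 'FROM->TO'")
    return (parts[0], parts[1])


def _require(obj: Mapping[str, Any], key: str, typ, path: str):
    if key not in obj:
        raise SchemaError(f"{path}: missing required field {key!r}")
    val = obj[key]
    if typ is float and isinstance(val, int):
        val = float(val)
    if not isinstance(val, typ):
        raise SchemaError(
            f"{path}.{key}: expected {getattr(typ, '__name__', typ)}, got {type(val).__name__}"
        )
    return val


def _transition_from_json(obj: Any, path: str, known_states: set[str]) -> Transition:
    if not isinstance(obj, Mapping):
        raise SchemaError(f"{path}: expected an object")
    src = _require(obj, "from", str, path)
    dst = _require(obj, "to", str, path)
    for end, label in (("from", src), ("to", dst)):
        if label not in known_states:
            raise SchemaError(f"{path}.{end}: unknown state {label!r}")
    k0 = _require(obj, "k0_ns_inv", float, path)
    d = _require(obj, "d", float, path)
    sign = obj.get("delta_E_sign")
    return Transition(
        from_state=src, to_state=dst, rate=VoltageRate(k0=k0, d=d), delta_E_sign=sign
    )


def cycle_from_dict(doc: Mapping[str, Any], path: str = "cycle") -> PermeationCycle:
    """Build and validate a PermeationCycle from a parsed JSON document."""
    name = _require(doc, "name", str, path)
    raw_states = _require(doc, "states", list, path)
    states = tuple(state_from_label(s) for s in raw_states)
    known = {s.label for s in states}
    raw_tr = _require(doc, "transitions", list, path)
    transitions = tuple(
        _transition_from_json(t, f"{path}.transitions[{i}]", known)
        for i, t in enumerate(raw_tr)
    )
    perm = _require(doc, "permeation_transition", Mapping, path)
    perm_key = (
        _require(perm, "from", str, f"{path}.permeation_transition"),
        _require(perm, "to", str, f"{path}.permeation_transition"),
    )
    raw_back = doc.get("backward_transitions", [])
    backward = tuple(
        _transition_from_json(t, f"{path}.backward_transitions[{i}]", known)
        for i, t in enumerate(raw_back)
    )
    return PermeationCycle(
        name=name,
        states=states,
        transitions=transitions,
        permeation_transition=perm_key,
        backward_transitions=backward,
    )


def cycle_to_dict(cycle: PermeationCycle) -> dict[str, Any]:
    def tr_json(tr: Transition) -> dict[str, Any]:
        out = {
            "from": tr.from_state,
            "to": tr.to_state,
            "k0_ns_inv": tr.rate.k0,
            "d": tr.rate.d,
        }
        if tr.delta_E_sign is not None:
            out["delta_E_sign"] = tr.delta_E_sign
        return out

    return {
        "name": cycle.name,
        "states": list(cycle.labels),
        "transitions": [tr_json(t) for t in cycle.transitions],
        "permeation_transition": {
            "from": cycle.permeation_transition[0],
            "to": cycle.permeation_transition[1],
        },
        "backward_transitions": [tr_json(t) for t in cycle.backward_transitions],
    }


def read_cycle(path: str | Path) -> PermeationCycle:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except FileNotFoundError as exc:
        raise SchemaError(f"cycle file not found: {path}") from exc
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return cycle_from_dict(doc, path=str(path))


def write_cycle(cycle: PermeationCycle, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cycle_to_dict(cycle), indent=2) + "\n")


def builtin_cycle(name: str) -> PermeationCycle:
    """Load a bundled cycle ("ANT-5" or "ANT-6")."""
    if name not in BUILTIN_CYCLES:
        raise SchemaError(f"unknown builtin cycle {name!r}; choose from {sorted(BUILTIN_CYCLES)}")
    text = resources.files("poreflux.data").joinpath(BUILTIN_CYCLES[name]).read_text()
    return cycle_from_dict(json.loads(text), path=f"builtin:{name}")


# ---------------------------------------------------------------------------
# trajectories: <prefix>.tsv (time_ns, state; one row per segment),
#               <prefix>.events.tsv (one event time per line),
#               <prefix>.json (voltage, duration, seed)

def write_trajectory(traj: Trajectory, prefix: str | Path) -> dict[str, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    seg_path = prefix.with_suffix(".tsv")
    ev_path = prefix.with_suffix(".events.tsv")
    hdr_path = prefix.with_suffix(".json")
    pd.DataFrame({"time_ns": traj.entry_times, "state": traj.states}).to_csv(
        seg_path, sep="\t", index=False
    )
    pd.DataFrame({"event_time_ns": traj.permeation_times}).to_csv(
        ev_path, sep="\t", index=False
    )
    hdr_path.write_text(
        json.dumps(
            {
                "voltage_mV": traj.voltage,
                "duration_ns": traj.duration,
                "seed_used": traj.seed_used,
            },
            indent=2,
        )
        + "\n"
    )
    return {"segments": seg_path, "events": ev_path, "header": hdr_path}


def read_trajectory(prefix: str | Path) -> Trajectory:
    prefix = Path(prefix)
    seg = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    ev = pd.read_csv(prefix.with_suffix(".events.tsv"), sep="\t")
    hdr = json.loads(prefix.with_suffix(".json").read_text())
    entry = seg["time_ns"].to_numpy(dtype=float)
    duration = float(hdr["duration_ns"])
    dwells = np.append(np.diff(entry), duration - entry[-1])
    return Trajectory(
        voltage=float(hdr["voltage_mV"]),
        states=[str(s) for s in seg["state"]],
        entry_times=entry,
        dwells=dwells,
        duration=duration,
        permeation_times=ev["event_time_ns"].to_numpy(dtype=float),
        seed_used=int(hdr["seed_used"]),
    )


# ---------------------------------------------------------------------------
# rate / fit / i-V tables

RATE_COLUMNS = ["transition", "voltage_mV", "k_ns_inv", "n_transitions", "dwell_ns", "occupancy"]
FIT_COLUMNS = ["transition", "k0_ns_inv", "d", "r_squared", "n_voltages"]
IV_COLUMNS = ["voltage_mV", "current_pA", "n_events", "total_time_ns"]


def rate_table(estimates: Iterable[RateEstimate]) -> pd.DataFrame:
    rows = []
    for est in estimates:
        occ = est.counts.occupancy
        for key, k in sorted(est.rates.items()):
            src = key[0]
            rows.append(
                {
                    "transition": transition_label(key),
                    "voltage_mV": est.voltage,
                    "k_ns_inv": np.nan if k is None else k,
                    "n_transitions": est.counts.n_ij[key],
                    "dwell_ns": est.counts.dwell.get(src, 0.0),
                    "occupancy": occ.get(src, 0.0),
                }
            )
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def write_rate_table(estimates: Iterable[RateEstimate], path: str | Path) -> None:
    rate_table(estimates).to_csv(path, index=False)


def read_rate_table(path: str | Path) -> list[RateEstimate]:
    """Rebuild per-voltage RateEstimates from a rate CSV.

    Permeation-event counts are not part of the rate-table format; the
    reconstructed TransitionCounts carry n_permeations=0.
    """
    df = pd.read_csv(path)
    missing_cols = set(RATE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {sorted(missing_cols)}")
    out = []
    for v, grp in df.groupby("voltage_mV", sort=True):
        n_ij: dict[tuple[str, str], int] = {}
        dwell: dict[str, float] = {}
        for _, row in grp.iterrows():
            key = parse_transition_label(row["transition"])
            n_ij[key] = int(row["n_transitions"])
            dwell[key[0]] = float(row["dwell_ns"])
        pos = grp[grp["occupancy"] > 0]
        if len(pos):
            total_time = float(pos.iloc[0]["dwell_ns"]) / float(pos.iloc[0]["occupancy"])
        else:
            total_time = float(sum(dwell.values()))
        # states never left out of: occupancy row absent; pad so dwells sum to total
        residual = total_time - sum(dwell.values())
        if residual > 1e-9 * total_time:
            dwell["__unobserved__"] = residual
        counts = TransitionCounts(
            voltage=float(v), n_ij=n_ij, dwell=dwell, total_time=total_time, n_permeations=0
        )
        rates = {
            k: (None if n == 0 else n / dwell[k[0]]) for k, n in n_ij.items()
        }
        stderr = {
            k: (None if n == 0 else rates[k] / np.sqrt(n)) for k, n in n_ij.items()
        }
        out.append(RateEstimate(voltage=float(v), rates=rates, stderr=stderr, counts=counts))
    return out


def fit_table(fit: RateFit) -> pd.DataFrame:
    rows = [
        {
            "transition": transition_label(key),
            "k0_ns_inv": f.k0,
            "d": f.d,
            "r_squared": f.r_squared,
            "n_voltages": f.n_voltages,
        }
        for key, f in sorted(fit.fits.items())
    ]
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def write_fit_table(fit: RateFit, path: str | Path) -> None:
    fit_table(fit).to_csv(path, index=False)


def read_fit_table(path: str | Path) -> RateFit:
    df = pd.read_csv(path)
    missing_cols = set(FIT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {sorted(missing_cols)}")
    fits = {
        parse_transition_label(row["transition"]): TransitionFit(
            k0=float(row["k0_ns_inv"]),
            d=float(row["d"]),
            r_squared=float(row["r_squared"]),
            n_voltages=int(row["n_voltages"]),
        )
        for _, row in df.iterrows()
    }
    return RateFit(fits=fits)


def write_iv_table(curve: IVCurve, path: str | Path) -> None:
    df = curve.to_frame()
    df.columns = IV_COLUMNS
    df.to_csv(path, index=False)


def read_iv_table(path: str | Path, source: str = "events") -> IVCurve:
    df = pd.read_csv(path)
    missing_cols = {"voltage_mV", "current_pA"} - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {sorted(missing_cols)}")
    points = [
        IVPoint(
            voltage=float(row["voltage_mV"]),
            current=float(row["current_pA"]),
            n_events=None if pd.isna(row.get("n_events", np.nan)) else int(row["n_events"]),
            total_time=None
            if pd.isna(row.get("total_time_ns", np.nan))
            else float(row["total_time_ns"]),
        )
        for _, row in df.sort_values("voltage_mV").iterrows()
    ]
    return IVCurve(points=points, source=source)


# ---------------------------------------------------------------------------
# run manifest

@dataclass
class RunManifest:
    """Provenance record written beside every CLI output set.

    Echoes the configuration and master seed so a run can be reproduced
    bit-for-bit, and lists every file a stage read or wrote.
    """

    config: dict[str, Any]
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        doc = json.loads(Path(path).read_text())
        return cls(**doc)
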