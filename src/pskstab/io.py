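"""CSV readers/writers and run-configuration plumbing.

CSV schemas (headers mandatory, UTF-8, '.' decimal, fractions written with
12 significant digits so likelihoods are reproducible on re-read):

* loss curves:   replicate_id, passage, fraction, n_events
* events:        fsc, ssc, fl1[, label]
* growth:        time_min, od, label
* competition:   initial_fraction, final_fraction, replicate_id
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .passaging import LossCurve
from .synthesize import EventTable, GrowthCurve

__all__ = [
    "write_loss_curves",
    "read_loss_curves",
    "write_events",
    "read_events",
    "write_growth_curve",
    "read_growth_curves",
    "write_competition",
    "read_competition",
    "write_config",
    "read_config",
]

_FLOAT_FMT = "%.17g"  # lossless float64 round trip


def write_loss_curves(curves: list[LossCurve], path: str | Path) -> None:
    df = pd.concat([c.to_frame() for c in curves], ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_loss_curves(path: str | Path) -> list[LossCurve]:
    df = pd.read_csv(path)
    required = {"replicate_id", "passage", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"loss-curve file {path} missing columns {sorted(missing)}")
    bad = df.index[(df["fraction"] < 0) | (df["fraction"] > 1) | df["fraction"].isna()]
    if len(bad):
        raise ValueError(
            f"loss-curve file {path}: fraction outside [0, 1] at row {int(bad[0]) + 2}"
        )
    curves = []
    for rep, grp in df.groupby("replicate_id", sort=True):
        grp = grp.sort_values("passage")
        n_events = None
        if "n_events" in grp.columns and not grp["n_events"].isna().all():
            n_events = grp["n_events"].to_numpy()
        curves.append(
            LossCurve(
                replicate_id=str(rep),
                passage=grp["passage"].to_numpy(),
                fraction=grp["fraction"].to_numpy(),
                n_events=n_events,
            )
        )
    return curves


def write_events(events: EventTable, path: str | Path) -> None:
    events.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path: str | Path, channels: tuple[str, str, str] = ("fsc", "ssc", "fl1")) -> EventTable:
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        raise NotImplementedError(
            "binary FCS ingestion is not supported in this build; export the "
            "events to CSV with columns fsc, ssc, fl1 first"
        )
    df = pd.read_csv(path)
    missing = set(channels) - set(df.columns)
    if missing:
        raise ValueError(f"event file {path} missing channels {sorted(missing)}")
    fsc, ssc, fl1 = (df[c].to_numpy() for c in channels)
    label = df["label"].to_numpy() if "label" in df.columns else None
    return EventTable(fsc=fsc, ssc=ssc, fl1=fl1, label=label)


def write_growth_curve(curve: GrowthCurve, path: str | Path, append: bool = False) -> None:
    df = curve.to_frame()
    if append and Path(path).exists():
        df.to_csv(path, mode="a", header=False, index=False, float_format=_FLOAT_FMT)
    else:
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    required = {"time_min", "od"}
    if required - set(df.columns):
        raise ValueError(f"growth file {path} missing columns {sorted(required - set(df.columns))}")
    if "label" not in df.columns:
        df["label"] = ""
    out = []
    for label, grp in df.groupby("label", sort=True, dropna=False):
        grp = grp.sort_values("time_min")
        out.append(
            GrowthCurve(
                time=grp["time_min"].to_numpy(),
                od=grp["od"].to_numpy(),
                label="" if pd.isna(label) else str(label),
            )
        )
    return out


def write_competition(pairs: np.ndarray, path: str | Path, replicate_ids=None) -> None:
    arr = np.asarray(pairs, dtype=float)
    df = pd.DataFrame(
        {
            "initial_fraction": arr[:, 0],
            "final_fraction": arr[:, 1],
            "replicate_id": replicate_ids if replicate_ids is not None else "rep01",
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_competition(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    required = {"initial_fraction", "final_fraction"}
    if required - set(df.columns):
        raise ValueError(f"competition file {path} missing columns {sorted(required)}")
    for colname in ("initial_fraction", "final_fraction"):
        bad = df.index[(df[colname] < 0) | (df[colname] > 1) | df[colname].isna()]
        if len(bad):
            raise ValueError(f"competition file {path}: {colname} invalid at row {int(bad[0]) + 2}")
    return df[["initial_fraction", "final_fraction"]].to_numpy()


def write_config(obj, path: str | Path) -> None:
    """Echo a run configuration (dataclass or dict) to a YAML sidecar."""

    def convert(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {k: convert(v) for k, v in dataclasses.asdict(x).items()}
        if isinstance(x, dict):
            return {k: convert(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [convert(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        if hasattr(x, "value") and not isinstance(x, (int, float, str, bool)):
            return x.value  # enums
        return x

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(convert(obj), fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
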