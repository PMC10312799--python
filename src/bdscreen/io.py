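"""Reading and writing screen datasets and fit results.

The interchange format is a long-format CSV with header
``time,dose,replicate,cell_count`` — one row per observation, time-0 rows
carrying the known seeding count — plus an optional JSON sidecar recording
the design and, for synthetic data, the generating parameters and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import HillParams, SubpopulationParams
from .moments import ModelParams
from .simulate import ExperimentDesign, ScreenDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "dataset_from_frame",
    "write_fit_result",
]

REQUIRED_COLUMNS = ("time", "dose", "replicate", "cell_count")


def _params_to_dict(params: ModelParams) -> dict:
    return {
        "fractions": list(params.fractions),
        "subpops": [
            {
                "beta": sp.beta,
                "nu": sp.nu,
                "b": sp.hill.b,
                "E": sp.hill.E,
                "m": sp.hill.m,
            }
            for sp in params.subpops
        ],
        "noise_c": params.noise_c,
    }


def params_from_dict(d: dict) -> ModelParams:
    return ModelParams(
        fractions=tuple(d["fractions"]),
        subpops=tuple(
            SubpopulationParams(
                beta=sp["beta"],
                nu=sp["nu"],
                hill=HillParams(sp["b"], sp["E"], sp["m"]),
            )
            for sp in d["subpops"]
        ),
        noise_c=d.get("noise_c", 0.0),
    )


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_dataset(data: ScreenDataset, path, sidecar: bool = True) -> None:
    """Write the long-format CSV (with time-0 rows) and a JSON sidecar."""
    # %.17g keeps float64 values bit-exact through the round trip
    data.to_frame(include_t0=True).to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = {
            "times": list(data.design.times),
            "doses": list(data.design.doses),
            "n_replicates": data.design.n_replicates,
            "n_initial": data.design.n_initial,
            "assay": data.design.assay,
            "seed": data.seed,
            "params": _params_to_dict(data.params) if data.params else None,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def dataset_from_frame(
    frame: pd.DataFrame,
    assay: str = "live_cell",
    n_initial: int | None = None,
    params: ModelParams | None = None,
    seed: int | None = None,
) -> ScreenDataset:
    """Build a validated ScreenDataset from a long-format table.

    Time-0 rows, if present, are interpreted as the known seeding count and
    consumed (they must agree with each other and with ``n_initial`` when
    given).  Every (time, dose, replicate) combination of the implied grid
    must appear exactly once.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in REQUIRED_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")

    dup = df.duplicated(subset=["time", "dose", "replicate"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise ValueError(f"duplicate (time, dose, replicate) keys at rows {rows}")

    t0 = df[df["time"] == 0.0]
    if not t0.empty:
        vals = t0["cell_count"].unique()
        if vals.size != 1:
            raise ValueError(f"time-0 rows disagree on the seeding count: {vals}")
        inferred = int(round(float(vals[0])))
        if n_initial is not None and inferred != n_initial:
            raise ValueError(
                f"time-0 rows give n={inferred} but n_initial={n_initial} was passed"
            )
        n_initial = inferred
    if n_initial is None:
        raise ValueError("n_initial unknown: pass it or include time-0 rows")
    df = df[df["time"] > 0.0]

    times = np.sort(df["time"].unique())
    doses = np.sort(df["dose"].unique())
    reps = np.sort(df["replicate"].unique())
    design = ExperimentDesign(
        times=tuple(times),
        doses=tuple(doses),
        n_replicates=len(reps),
        n_initial=int(n_initial),
        assay=assay,
    )
    pivot = df.set_index(["time", "dose", "replicate"])["cell_count"]
    full = pd.MultiIndex.from_product([times, doses, reps], names=pivot.index.names)
    absent = full.difference(pivot.index)
    if len(absent):
        raise ValueError(
            f"incomplete design: {len(absent)} missing (time, dose, replicate) "
            f"combinations, first {list(absent[:5])}"
        )
    counts = pivot.reindex(full).to_numpy().reshape(len(times), len(doses), len(reps))
    return ScreenDataset(design=design, counts=counts, params=params, seed=seed)


def read_dataset(path, assay: str | None = None, n_initial: int | None = None) -> ScreenDataset:
    """Read a long-format CSV screen, using its JSON sidecar when present."""
    frame = pd.read_csv(path, float_precision="round_trip")
    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    if assay is None:
        assay = meta.get("assay", "live_cell")
    if n_initial is None and meta.get("n_initial") is not None:
        n_initial = int(meta["n_initial"])
    params = params_from_dict(meta["params"]) if meta.get("params") else None
    return dataset_from_frame(
        frame, assay=assay, n_initial=n_initial, params=params, seed=meta.get("seed")
    )


def write_fit_result(result, prefix) -> None:
    """Serialize a FitResult as key-value summary + per-clone CSV table."""
    prefix = Path(prefix)
    lines = [
        f"method: {result.method}",
        f"S: {result.S}",
        f"loglik: {result.loglik!r}",
        f"aic: {result.aic!r}",
        f"bic: {result.bic!r}",
        f"converged: {result.converged}",
        f"n_restarts_used: {result.n_restarts_used}",
        f"at_bounds: {list(result.at_bounds)}",
    ]
    prefix.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    result.summary().to_csv(prefix.with_suffix(".csv"), index=False)
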