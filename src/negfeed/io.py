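"""File formats: traces, snapshots, chains and run configuration.

All outputs are delimited text with ``#``-prefixed metadata headers that
embed the resolved configuration (JSON) and the seed, so any result file is
regenerable from its own header.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .params import ExpressionTrace, ModelParameters, ObservedTrace
from .sampling import Chain, Prior, PriorSpec
from .smfish import MrnaSnapshot

__all__ = [
    "config_hash", "load_config", "dump_config",
    "write_trace", "read_expression_trace", "read_observed_trace",
    "write_snapshot", "read_snapshot", "write_chain", "read_chain",
    "write_likelihood_table",
]

PathLike = Union[str, Path]


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(config: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _write_with_meta(path: PathLike, df: pd.DataFrame, meta: dict) -> None:
    meta = dict(meta)
    meta["config_hash"] = config_hash(meta)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {json.dumps(value, default=str)}\n")
        df.to_csv(fh, index=False)


def _read_meta(path: PathLike) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            try:
                meta[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = value.strip()
    return meta


def write_trace(path: PathLike, trace: Union[ExpressionTrace, ObservedTrace],
                meta: Optional[dict] = None) -> None:
    """Trace file: time_min plus protein (and mrna for simulation output)."""
    meta = dict(meta or {})
    if isinstance(trace, ExpressionTrace):
        df = pd.DataFrame({"time_min": trace.times, "protein": trace.protein,
                           "mrna": trace.mrna})
        if trace.params is not None:
            meta.setdefault("params", trace.params.as_dict())
        if trace.seed is not None:
            meta.setdefault("seed", trace.seed)
    else:
        df = pd.DataFrame({"time_min": trace.times, "protein": trace.y})
        meta = {**trace.meta, **meta}
    _write_with_meta(path, df, meta)


def _read_table(path: PathLike) -> tuple[pd.DataFrame, dict]:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    return df, meta


def read_expression_trace(path: PathLike) -> ExpressionTrace:
    df, meta = _read_table(path)
    params = ModelParameters.from_dict(meta["params"]) if "params" in meta else None
    return ExpressionTrace(times=df["time_min"].to_numpy(),
                           mrna=df["mrna"].to_numpy(),
                           protein=df["protein"].to_numpy(),
                           params=params, seed=meta.get("seed"))


def read_observed_trace(path: PathLike) -> ObservedTrace:
    df, meta = _read_table(path)
    col = "protein" if "protein" in df else df.columns[1]
    return ObservedTrace(times=df["time_min"].to_numpy(),
                         y=df[col].to_numpy(), meta=meta)


def write_likelihood_table(path: PathLike, y: ObservedTrace, result,
                           meta: Optional[dict] = None) -> None:
    """Per-observation filter debug table: observation, predictive mean and
    variance, and log-density contribution."""
    df = pd.DataFrame({
        "time_min": y.times, "observed": y.y,
        "predicted_mean": result.predicted_means,
        "predicted_variance": result.predicted_variances,
        "log_density": result.per_obs,
    })
    _write_with_meta(path, df, {"loglik": result.loglik, **(meta or {})})


def write_snapshot(path: PathLike, snapshot: MrnaSnapshot,
                   meta: Optional[dict] = None) -> None:
    """Snapshot file: one integer mRNA count per line after the header."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {json.dumps(value, default=str)}\n")
        fh.write("mrna\n")
        for c in snapshot.counts:
            fh.write(f"{int(round(c))}\n")


def read_snapshot(path: PathLike) -> MrnaSnapshot:
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or not line.lstrip("-").isdigit():
                continue
            values.append(int(line))
    return MrnaSnapshot(counts=np.asarray(values, dtype=float))


def write_chain(path: PathLike, chain: Chain) -> None:
    df = pd.DataFrame(chain.samples, columns=list(chain.names))
    df["logpost"] = chain.logpost
    df["accepted"] = chain.accepted.astype(int)
    df["step_size"] = chain.step_size_trace
    meta = {
        "seed": chain.seed, "warmup": chain.warmup,
        "names": list(chain.names),
        "priors": {n: [chain.priors[n].kind, chain.priors[n].low, chain.priors[n].high]
                   for n in chain.names},
        **chain.metadata,
    }
    _write_with_meta(path, df, meta)


def read_chain(path: PathLike) -> Chain:
    df, meta = _read_table(path)
    names = tuple(meta["names"])
    priors = PriorSpec({n: Prior(*meta["priors"][n]) for n in names})
    return Chain(samples=df[list(names)].to_numpy(),
                 logpost=df["logpost"].to_numpy(),
                 accepted=df["accepted"].to_numpy().astype(bool),
                 step_size_trace=df["step_size"].to_numpy(),
                 names=names, priors=priors, seed=meta.get("seed", -1),
                 warmup=int(meta.get("warmup", 0)),
                 metadata={k: v for k, v in meta.items()
                           if k not in ("seed", "warmup", "names", "priors")})
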