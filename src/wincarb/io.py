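"""Readers and writers for the delimited-text formats and the YAML config.

All tabular data are small dated tables, stored as comma-separated text
with an ISO-8601 ``date`` column and an optional provenance header of
``#``-prefixed comment lines (config hash, seed, package version).

The weather format has columns ``date, tmin, tmean, tmax`` (degC; tmean
may be missing and is then reconstructed as the tmin/tmax midpoint).  The
observation format has ``date, gfs, starch`` (mg per g DM) plus either a
``wc`` column (g water per g DM) or fresh/dry mass columns ``fm, dm`` from
which WC = (FM - DM)/DM is computed; an optional ``fh`` column holds
measured frost hardiness (degC, negative = hardier).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .carbon import ModelParams
from .frost import FHParams
from .kinetics import ReactionParams, RespirationParams
from .phenology import PhenologyParams

__all__ = [
    "read_weather",
    "read_observations",
    "write_table",
    "load_config",
    "save_config",
    "model_params_from_config",
    "model_params_to_config",
]


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def read_weather(path) -> pd.DataFrame:
    """Validated, date-sorted daily weather series."""
    df = _read_csv(path)
    if "date" not in df.columns:
        raise ValueError(f"{path}: missing 'date' column")
    if not ({"tmean"} <= set(df.columns) or {"tmin", "tmax"} <= set(df.columns)):
        raise ValueError(f"{path}: need a 'tmean' column or both 'tmin' and 'tmax'")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable date ({exc})") from exc
    dup = df["date"].duplicated()
    if dup.any():
        first = df.loc[dup, "date"].iloc[0].date()
        raise ValueError(f"{path}: duplicated date {first}")
    return df.sort_values("date").reset_index(drop=True)


def read_observations(path) -> pd.DataFrame:
    """Observation series with WC computed from masses when necessary."""
    df = _read_csv(path)
    for col in ("date", "gfs", "starch"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing '{col}' column")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    if "wc" not in df.columns:
        if not {"fm", "dm"} <= set(df.columns):
            raise ValueError(f"{path}: need a 'wc' column or both 'fm' and 'dm'")
        bad = df.index[df["fm"] < df["dm"]]
        if len(bad):
            raise ValueError(
                f"{path}: row {bad[0] + 1}: fresh mass below dry mass (negative WC)"
            )
        df["wc"] = (df["fm"] - df["dm"]) / df["dm"]
    neg = df.index[(df["gfs"] < 0) | (df["starch"] < 0)]
    if len(neg):
        raise ValueError(f"{path}: row {neg[0] + 1}: negative carbohydrate pool")
    dup = df["date"].duplicated()
    if dup.any():
        first = df.loc[dup, "date"].iloc[0].date()
        raise ValueError(f"{path}: duplicated date {first}")
    cols = ["date", "gfs", "starch", "wc"] + (["fh"] if "fh" in df.columns else [])
    return df.sort_values("date").reset_index(drop=True)[cols]


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a table as CSV with an optional ``#``-comment provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(fh, index=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(config: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def phenology_params_from_config(cfg: dict) -> PhenologyParams:
    return PhenologyParams(**cfg.get("phenology", {}))


def fh_params_from_config(cfg: dict) -> FHParams:
    return FHParams(**cfg.get("frost_hardiness", {}))


def model_params_from_config(cfg: dict) -> ModelParams:
    """Build ModelParams from the ``model`` block of a config mapping.

    The block names the variant and one sub-block per reaction (k1c, k1m,
    k2) plus ``respiration``; reaction rate keys are named per variant in
    the file (the units differ) but map onto the same dataclass."""
    block = cfg["model"]
    variant = block["variant"]
    rps = {}
    for name in ("k1c", "k1m", "k2"):
        sub = dict(block[name])
        rps[name] = ReactionParams(**sub)
    resp = RespirationParams(**block["respiration"])
    return ModelParams(variant=variant, k1c=rps["k1c"], k1m=rps["k1m"], k2=rps["k2"], resp=resp)


def model_params_to_config(params: ModelParams) -> dict:
    def rp(r: ReactionParams) -> dict:
        d = {
            "k_trans": r.k_trans,
            "d_endo": r.d_endo,
            "d_eco": r.d_eco,
            "mu": r.mu,
            "sigma": r.sigma,
        }
        if r.km is not None:
            d["km"] = r.km
        return d

    return {
        "model": {
            "variant": params.variant,
            "k1c": rp(params.k1c),
            "k1m": rp(params.k1m),
            "k2": rp(params.k2),
            "respiration": {
                "r_max": params.resp.r_max,
                "a3": params.resp.a3,
                "b3": params.resp.b3,
                "q10": params.resp.q10,
                "t_ref": params.resp.t_ref,
            },
        }
    }
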