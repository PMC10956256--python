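"""Readers and writers for the plain-text formats the toolkit consumes.

Genotypes come either as a delimited matrix (first column individual id,
header row of marker ids) or in the PLINK ``.raw`` additive dialect
(FID IID PAT MAT SEX PHENOTYPE followed by one allele-count column per
marker).  Phenotypes are tab-separated with ``NA`` marking held-out records;
prediction tables exist in wide (one column per method) and long
(individual_id / method / value) forms, and optimizer / chain / simulation
configurations are YAML files whose keys mirror the dataclass fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import BasePredictionSet, SwarmConfig
from .learners import ChainConfig, GenotypeMatrix, PhenotypeTable
from .simulate import SimulationDesign

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_predictions",
    "write_predictions",
    "read_swarm_config",
    "read_chain_config",
    "read_design",
    "write_manifest",
]

PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _impute_or_fail(codes: np.ndarray, markers, impute_missing: bool) -> np.ndarray:
    """Mean-impute per-marker missing codes, or reject when imputation is off."""
    missing = np.isnan(codes)
    if not missing.any():
        return codes
    if not impute_missing:
        bad = np.flatnonzero(missing.any(axis=0))
        raise ValueError(
            f"missing genotype codes in markers {[str(markers[k]) for k in bad[:5]]}"
            " and imputation is disabled"
        )
    col_means = np.nanmean(codes, axis=0)
    if np.isnan(col_means).any():
        raise ValueError("a marker is missing for every individual")
    idx = np.where(missing)
    codes[idx] = col_means[idx[1]]
    return codes


def read_genotypes(
    path, fmt: str = "csv_matrix", impute_missing: bool = True
) -> GenotypeMatrix:
    """Load a genotype matrix from ``csv_matrix`` or ``plink_raw`` format."""
    path = Path(path)
    if fmt == "csv_matrix":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        ids = df.index.astype(str).to_numpy()
        markers = df.columns.astype(str).to_numpy()
        codes = df.to_numpy(dtype=float)
    elif fmt == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        missing_meta = [c for c in PLINK_META_COLS if c not in df.columns]
        if missing_meta:
            raise ValueError(f"not a PLINK .raw file: missing columns {missing_meta}")
        ids = df["IID"].astype(str).to_numpy()
        marker_cols = [c for c in df.columns if c not in PLINK_META_COLS]
        markers = np.asarray(marker_cols, dtype=str)
        codes = df[marker_cols].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if len(set(ids.tolist())) != len(ids):
        dup = pd.Series(ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise ValueError(f"duplicate individual id {dup!r} in {path}")
    codes = _impute_or_fail(codes, markers, impute_missing)
    if np.nanmin(codes) < 0 or np.nanmax(codes) > 2:
        bad = np.flatnonzero(((codes < 0) | (codes > 2)).any(axis=1))
        raise ValueError(
            f"genotype codes outside [0, 2] at data rows {bad[:5].tolist()} in {path}"
        )
    return GenotypeMatrix(ids, markers, codes)


def write_genotypes(path, genotypes: GenotypeMatrix) -> None:
    df = pd.DataFrame(
        genotypes.codes,
        index=pd.Index(genotypes.individual_ids, name="individual_id"),
        columns=genotypes.marker_ids,
    )
    df.to_csv(path)


def read_phenotypes(path) -> PhenotypeTable:
    """Tab-separated ``individual_id  trait  [covariates...]``; ``NA`` masks."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs at least id and trait columns")
    ids = df.iloc[:, 0].astype(str).to_numpy()
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    covs = None
    if df.shape[1] > 2:
        covs = df.iloc[:, 2:].to_numpy(dtype=float)
    return PhenotypeTable(ids, values, covariates=covs)


def write_phenotypes(path, table: PhenotypeTable, trait_name: str = "trait") -> None:
    out = pd.DataFrame({"individual_id": table.individual_ids, trait_name: table.values})
    masked = out[trait_name].isna() | pd.Series(table.mask)
    out[trait_name] = out[trait_name].astype(object)
    out.loc[masked, trait_name] = "NA"
    out.to_csv(path, sep="\t", index=False)


def read_predictions(path, form: str = "wide") -> BasePredictionSet:
    """Load a prediction table.

    Wide form: ``individual_id`` then one column per method.  Long form:
    ``individual_id  method  value`` (an optional ``replicate`` column is
    averaged over); the table must be complete.
    """
    if form == "wide":
        df = pd.read_csv(path, sep="\t")
        ids = df.iloc[:, 0].astype(str).to_numpy()
        methods = list(df.columns[1:])
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError(f"missing prediction cells in {path}")
        return BasePredictionSet(ids, methods, values)
    if form == "long":
        df = pd.read_csv(path, sep="\t")
        required = {"individual_id", "method", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long table must have columns {sorted(required)}")
        methods = list(dict.fromkeys(df["method"]))  # preserve first-seen order
        ids = list(dict.fromkeys(df["individual_id"].astype(str)))
        wide = (
            df.groupby(["individual_id", "method"], sort=False)["value"]
            .mean()
            .unstack("method")
        )
        wide = wide.reindex(index=ids, columns=methods)
        if wide.isna().any().any():
            missing = wide.isna().stack()
            ind, meth = missing[missing].index[0]
            raise ValueError(
                f"method {meth!r} missing for individual {ind!r} in {path}"
            )
        return BasePredictionSet(np.asarray(ids), methods, wide.to_numpy(dtype=float))
    raise ValueError(f"unknown prediction form {form!r}")


def write_predictions(path, predictions: BasePredictionSet, form: str = "wide") -> None:
    if form == "wide":
        df = pd.DataFrame(
            predictions.values,
            columns=predictions.method_names,
        )
        df.insert(0, "individual_id", predictions.individual_ids)
        df.to_csv(path, sep="\t", index=False)
    elif form == "long":
        rows = []
        for j, m in enumerate(predictions.method_names):
            for i, ind in enumerate(predictions.individual_ids):
                rows.append((ind, m, predictions.values[i, j]))
        pd.DataFrame(rows, columns=["individual_id", "method", "value"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown prediction form {form!r}")


def _config_from_yaml(path, cls):
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "freq_range" in data and data["freq_range"] is not None:
        data["freq_range"] = tuple(data["freq_range"])
    return cls(**data)


def read_swarm_config(path=None, **overrides) -> SwarmConfig:
    cfg = _config_from_yaml(path, SwarmConfig)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def read_chain_config(path=None, **overrides) -> ChainConfig:
    cfg = _config_from_yaml(path, ChainConfig)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def read_design(path=None, **overrides) -> SimulationDesign:
    cfg = _config_from_yaml(path, SimulationDesign)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seed, inputs) -> Path:
    """Record everything needed to re-run a CLI invocation bit-identically."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "argv": sys.argv,
        "config": config,
        "seed": seed,
        "inputs": {
            str(p): _checksum(Path(p)) for p in inputs if p and Path(p).exists()
        },
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
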