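"""Tab-delimited I/O for summary statistics, haplotypes and configs.

Formats
-------
Summary statistics: header ``ID CHR POS EA OA BETA SE P`` plus one
``FREQ_<region>`` column per region; numeric fields are written with
12 significant digits so a write/read round trip is lossless at that
precision.  Positions are 1-based.

Haplotypes: a site-by-haplotype 0/1 matrix (rows = sites) plus a
variant map (``ID CHR POS REF ALT``).

Scenario configs: a YAML key/value mapping, either an explicit
parameter set or a named scenario constructor with its arguments.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, DataError, SchemaError
from . import synthetic
from .synthetic import ScenarioConfig

__all__ = [
    "REQUIRED_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize_alleles",
    "write_haplotypes",
    "read_haplotypes",
    "read_scenario_config",
    "write_scenario_config",
]

REQUIRED_COLUMNS = ["ID", "CHR", "POS", "EA", "OA", "BETA", "SE", "P"]
_NUMERIC = ["POS", "BETA", "SE", "P"]
_FLOAT_FORMAT = "%.12g"


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write a summary-statistic table (tab-delimited, 12 sig. digits)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"summary statistics are missing column(s): {missing}")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_summary_stats(path) -> pd.DataFrame:
    """Read and validate a summary-statistic table.

    Raises
    ------
    SchemaError
        Naming any missing required column.
    DataError
        Naming the 1-based file line of the first malformed numeric
        value.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"summary statistics are missing column(s): {missing}")
    freq_cols = [c for c in raw.columns if c.startswith("FREQ_")]
    out = raw.copy()
    for col in _NUMERIC + freq_cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise DataError(
                f"malformed numeric value {raw.loc[bad.idxmax(), col]!r} "
                f"in column {col} at line {line}")
        out[col] = converted
    out["POS"] = out["POS"].astype(int)
    return out


def harmonize_alleles(df: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Orient records to a reference effect/other allele assignment.

    Rows whose (EA, OA) pair is swapped relative to ``ref`` (matched on
    ``ID``) get EA/OA exchanged, BETA negated and every ``FREQ_*``
    column complemented; rows already oriented pass through.  Allele
    pairs that match the reference in neither orientation are a data
    error.
    """
    ref_map = {row.ID: (row.EA, row.OA) for row in ref.itertuples()}
    out = df.copy()
    freq_cols = [c for c in df.columns if c.startswith("FREQ_")]
    for idx, row in df.iterrows():
        if row["ID"] not in ref_map:
            continue
        ea, oa = ref_map[row["ID"]]
        if (row["EA"], row["OA"]) == (ea, oa):
            continue
        if (row["EA"], row["OA"]) == (oa, ea):
            out.loc[idx, ["EA", "OA"]] = [ea, oa]
            out.loc[idx, "BETA"] = -row["BETA"]
            for c in freq_cols:
                out.loc[idx, c] = 1.0 - row[c]
        else:
            raise DataError(
                f"alleles for {row['ID']} ({row['EA']}/{row['OA']}) match the "
                f"reference ({ea}/{oa}) in neither orientation")
    return out


def write_haplotypes(haps: np.ndarray, variant_map: pd.DataFrame,
                     matrix_path, map_path) -> None:
    """Write a (haplotype x site) matrix as site-by-haplotype rows,
    plus its variant map (``ID CHR POS REF ALT``)."""
    h = np.asarray(haps)
    if h.ndim != 2 or not np.isin(h, (0, 1)).all():
        raise DataError("haplotypes must be a 2-D 0/1 matrix")
    for col in ("ID", "CHR", "POS", "REF", "ALT"):
        if col not in variant_map.columns:
            raise SchemaError(f"variant map is missing column: {col}")
    if len(variant_map) != h.shape[1]:
        raise DataError("variant map length must equal the number of sites")
    np.savetxt(matrix_path, h.T, fmt="%d", delimiter="\t")
    variant_map.to_csv(map_path, sep="\t", index=False)


def read_haplotypes(matrix_path, map_path) -> tuple[np.ndarray, pd.DataFrame]:
    """Inverse of :func:`write_haplotypes`; returns haplotype-major rows."""
    mat = np.loadtxt(matrix_path, dtype=np.int8, delimiter="\t", ndmin=2)
    vmap = pd.read_csv(map_path, sep="\t")
    if len(vmap) != mat.shape[0]:
        raise DataError("variant map does not match the matrix site count")
    return mat.T, vmap


_SCENARIO_BUILDERS = {
    "null": synthetic.null_scenario,
    "heterogeneous_beta": synthetic.heterogeneous_beta_scenario,
    "drifted_freq": synthetic.drifted_freq_scenario,
}


def read_scenario_config(path) -> ScenarioConfig:
    """Load a scenario from a YAML config file.

    Two layouts are accepted: an explicit parameter mapping (keys
    ``regions, n_cases, n_controls, p_anc, f_drift, beta, seed``) or a
    named constructor, e.g.::

        scenario: heterogeneous_beta
        m_variants: 90
        n_hetero: 10
        delta_beta: 0.2
        seed: 7
        region_sizes:
          West: [1780, 1739]
          East: [835, 667]
          South: [1348, 1103]
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    except OSError as exc:
        raise ConfigError(f"cannot read {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path} must contain a key/value mapping")
    if "scenario" in doc:
        kind = doc.pop("scenario")
        if kind not in _SCENARIO_BUILDERS:
            raise ConfigError(
                f"unknown scenario {kind!r}; expected one of {sorted(_SCENARIO_BUILDERS)}")
        if "region_sizes" in doc:
            doc["region_sizes"] = {str(k): (int(v[0]), int(v[1]))
                                   for k, v in doc["region_sizes"].items()}
        positional = {}
        for key in ("m_variants", "n_hetero", "delta_beta", "f_drift"):
            if key in doc:
                positional[key] = doc.pop(key)
        try:
            return _SCENARIO_BUILDERS[kind](**positional, **doc)
        except TypeError as exc:
            raise ConfigError(f"bad arguments for scenario {kind!r}: {exc}") from exc
    return ScenarioConfig.from_dict(doc)


def write_scenario_config(config: ScenarioConfig, path) -> None:
    """Serialise a config (explicit layout) to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=False)
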