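"""CSV formats for censored datasets, imputed datasets and result tables.

Censored data travels as explicit status flags, never as sentinel numbers:
columns ``sample_id,value,status`` with status OBS (value present, inside
[LC, UC]), BC or AC (value empty). The cutoffs themselves are configuration,
supplied alongside the file. Imputed output is long format
``sample_id,imputation_index,value,provenance``.

Every file written here starts with ``#``-prefixed metadata lines carrying
the seed and a configuration hash, enough to regenerate the artifact.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imputation import ImputedDatasets, PROV_OBSERVED
from .measurement import CensoredDataset

__all__ = [
    "read_censored_csv",
    "write_censored_csv",
    "write_imputed_csv",
    "read_imputed_csv",
    "write_table_csv",
    "read_values_csv",
    "config_hash",
]

STATUS_TOKENS = ("OBS", "BC", "AC")


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping (12 hex chars)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _meta_header(meta: Mapping | None) -> str:
    if not meta:
        return ""
    lines = [f"# {key}={value}" for key, value in meta.items()]
    lines.append(f"# config_hash={config_hash(meta)}")
    return "\n".join(lines) + "\n"


def _write_frame(df: pd.DataFrame, path: str | Path, meta: Mapping | None, **to_csv_kw):
    buf = io.StringIO()
    buf.write(_meta_header(meta))
    df.to_csv(buf, **to_csv_kw)
    Path(path).write_text(buf.getvalue())


def read_censored_csv(path: str | Path, lc: float, uc: float) -> CensoredDataset:
    """Read a ``sample_id,value,status`` file into a :class:`CensoredDataset`.

    OBS rows must carry a numeric value inside [lc, uc]; BC/AC rows must have
    an empty value. Violations raise :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(
        path, comment="#", dtype={"sample_id": str, "status": str},
        float_precision="round_trip",
    )
    required = {"sample_id", "value", "status"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    observed = []
    n_bc = n_ac = 0
    for idx, row in df.iterrows():
        status = row["status"]
        has_value = pd.notna(row["value"])
        if status == "OBS":
            if not has_value:
                raise ValidationError(f"{path} row {idx}: OBS row is missing a value")
            value = float(row["value"])
            if not lc <= value <= uc:
                raise ValidationError(
                    f"{path} row {idx}: OBS value {value} outside [{lc}, {uc}]"
                )
            observed.append(value)
        elif status in ("BC", "AC"):
            if has_value:
                raise ValidationError(
                    f"{path} row {idx}: {status} row must have an empty value"
                )
            if status == "BC":
                n_bc += 1
            else:
                n_ac += 1
        else:
            raise ValidationError(
                f"{path} row {idx}: unknown status {status!r}; expected one of "
                f"{STATUS_TOKENS}"
            )
    return CensoredDataset(
        observed=np.asarray(observed, dtype=float), n_bc=n_bc, n_ac=n_ac,
        lc=float(lc), uc=float(uc),
    )


def write_censored_csv(
    data: CensoredDataset, path: str | Path, meta: Mapping | None = None
) -> None:
    """Write a censored dataset in the shared ``sample_id,value,status`` dialect."""
    n = data.n
    ids = [f"s{i + 1:0{len(str(n))}d}" for i in range(n)]
    values = [repr(float(v)) for v in data.observed] + [""] * (data.n_bc + data.n_ac)
    status = ["OBS"] * data.n_obs + ["BC"] * data.n_bc + ["AC"] * data.n_ac
    df = pd.DataFrame({"sample_id": ids, "value": values, "status": status})
    _write_frame(df, path, meta, index=False)


def write_imputed_csv(
    imputed: ImputedDatasets, path: str | Path, meta: Mapping | None = None
) -> None:
    """Write completed datasets in long format with per-record provenance.

    Values are written with ``repr`` (full double precision) so a re-read
    round-trips bit-exactly.
    """
    rows = []
    n = len(imputed.provenance)
    ids = [f"s{i + 1:0{len(str(max(n, 1)))}d}" for i in range(n)]
    for m_idx, dataset in enumerate(imputed.datasets):
        prov = (
            imputed.provenance
            if dataset.size == n
            else tuple(p for p in imputed.provenance if p == PROV_OBSERVED)
        )
        kept_ids = ids if dataset.size == n else [
            ids[i] for i, p in enumerate(imputed.provenance) if p == PROV_OBSERVED
        ]
        for sid, value, p in zip(kept_ids, dataset, prov):
            rows.append({
                "sample_id": sid,
                "imputation_index": m_idx,
                "value": repr(float(value)),
                "provenance": p,
            })
    df = pd.DataFrame(rows, columns=["sample_id", "imputation_index", "value", "provenance"])
    full_meta = dict(meta or {})
    full_meta.setdefault("method", imputed.spec.method)
    full_meta.setdefault("m", imputed.spec.m)
    full_meta.setdefault("seed", imputed.spec.seed)
    full_meta.setdefault("lc", imputed.lc)
    full_meta.setdefault("uc", imputed.uc)
    _write_frame(df, path, full_meta, index=False)


def read_imputed_csv(path: str | Path) -> list[np.ndarray]:
    """Read a long-format imputed CSV back into one array per imputation."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"sample_id", "imputation_index", "value", "provenance"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    return [
        group["value"].to_numpy(dtype=float)
        for _, group in df.groupby("imputation_index", sort=True)
    ]


def write_table_csv(
    df: pd.DataFrame, path: str | Path, meta: Mapping | None = None, index: bool = True
) -> None:
    """Write a results table with the standard metadata header."""
    _write_frame(df, path, meta, index=index)


def read_values_csv(path: str | Path) -> np.ndarray:
    """Read a plain ``sample_id,value`` file (e.g. true simulated values)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "value" not in df.columns:
        raise ValidationError(f"{path}: expected a 'value' column")
    values = df["value"].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValidationError(f"{path}: non-finite values present")
    return values
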