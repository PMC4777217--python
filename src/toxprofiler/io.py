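"""CSV/TSV readers and writers for the pipeline's file formats.

All outputs carry a ``# seed=...`` provenance header comment; readers skip
comment lines.  Formats:

- plate CSV: plate_id, well, role in {compound,pos,dmso}, compound_id,
  assay, replicate, concentration_M, raw_signal
- profile / fingerprint CSV: compound x feature matrix, index column
  ``compound_id``
- annotation TSV: compound_id, term_id (one row per term; unannotated
  compounds absent)
- endpoint CSV: compound_id, endpoint, value, replicate_index
- assignment TSV: compound_id, map_kind, cluster_label
- fits CSV: compound_id, assay, replicate, ac50_M, efficacy_pct,
  hill_slope, r2, curve_class, curve_rank
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .endpoints import EndpointMeta, EndpointTable
from .som import ClusterAssignment


def _write_csv(df: pd.DataFrame, path, seed=None, index=False, sep=",") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=index, sep=sep)


def _read_csv(path, sep=",", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def write_matrix(df: pd.DataFrame, path, seed=None) -> None:
    out = df.copy()
    out.index.name = "compound_id"
    _write_csv(out, path, seed=seed, index=True)


def read_matrix(path) -> pd.DataFrame:
    df = _read_csv(path, index_col="compound_id")
    df.index.name = None
    return df


def write_annotations(annotations: Mapping[str, set], path, seed=None) -> None:
    rows = [
        (cid, term)
        for cid in sorted(annotations)
        for term in sorted(annotations[cid])
    ]
    _write_csv(
        pd.DataFrame(rows, columns=["compound_id", "term_id"]),
        path, seed=seed, sep="\t",
    )


def read_annotations(path) -> dict[str, set]:
    df = _read_csv(path, sep="\t")
    out: dict[str, set] = {}
    for cid, term in zip(df["compound_id"], df["term_id"]):
        out.setdefault(str(cid), set()).add(str(term))
    return out


def write_endpoint_table(table: EndpointTable, csv_path, meta_path=None,
                         seed=None) -> None:
    _write_csv(table.entries, csv_path, seed=seed)
    if meta_path is not None:
        payload = {
            name: {
                "endpoint_type": m.endpoint_type,
                "components": list(m.components),
                "lower_is_toxic": m.lower_is_toxic,
                "species": m.species,
                "route": m.route,
            }
            for name, m in table.meta.items()
        }
        Path(meta_path).parent.mkdir(parents=True, exist_ok=True)
        with open(meta_path, "w") as fh:
            yaml.safe_dump(payload, fh)


def read_endpoint_table(csv_path, meta_path=None) -> EndpointTable:
    entries = _read_csv(csv_path)
    meta: dict[str, EndpointMeta] = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            payload = yaml.safe_load(fh) or {}
        for name, m in payload.items():
            meta[name] = EndpointMeta(
                name=name,
                endpoint_type=m["endpoint_type"],
                components=tuple(m.get("components", ())),
                lower_is_toxic=bool(m.get("lower_is_toxic", True)),
                species=m.get("species", ""),
                route=m.get("route", ""),
            )
    return EndpointTable(entries=entries, meta=meta)


def write_assignment(assignment: ClusterAssignment, path, seed=None) -> None:
    rows = [
        (cid, assignment.map_kind, lab)
        for cid, lab in sorted(assignment.labels.items())
    ]
    _write_csv(
        pd.DataFrame(rows, columns=["compound_id", "map_kind", "cluster_label"]),
        path, seed=seed, sep="\t",
    )


def read_assignment(path) -> ClusterAssignment:
    df = _read_csv(path, sep="\t")
    kinds = set(df["map_kind"])
    if len(kinds) != 1:
        raise ValueError(f"assignment file mixes map kinds: {sorted(kinds)}")
    labels = dict(zip(df["compound_id"].astype(str),
                      df["cluster_label"].astype(str)))
    return ClusterAssignment(labels=labels, map_kind=kinds.pop())


def write_calls(calls_df: pd.DataFrame, path, seed=None) -> None:
    _write_csv(calls_df, path, seed=seed)


def read_calls(path) -> pd.DataFrame:
    df = _read_csv(path)
    df["toxic"] = df["toxic"].astype(bool)
    return df
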