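"""Validated readers/writers for the pipeline's tab-separated formats.

All tables are UTF-8, tab-separated, with a header row.  Validation errors
name the offending line (1-based, counting the header as line 1).  Gene-set
collections use the standard GMT layout: ``set_id<TAB>description<TAB>
member...`` with at least one member.  JSON reports are written with sorted
keys and floats trimmed to nine significant digits so that identical runs
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .screening import CompoundRecord
from .synthetic import INDEX_NAMES


class TableFormatError(ValueError):
    """A table violates its declared schema; the message names the line."""


COMPOUND_COLUMNS = [
    "compound_id", "name", "herbs", "ob", "caco2", "dl",
    "whitelisted", "whitelist_reason", "descriptor",
]
PREDICTION_COLUMNS = [
    "compound_id", "target", "source", "max_tc", "possibility", "species",
]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _to_float(df: pd.DataFrame, col: str, path, allow_empty: bool = False) -> pd.Series:
    raw = df[col].str.strip()
    out = pd.to_numeric(raw.replace("", "nan") if allow_empty else raw, errors="coerce")
    bad = out.isna() & (raw != "") if allow_empty else out.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise TableFormatError(
            f"{path}: malformed number {raw[bad.idxmax()]!r} in column {col}, line {line}"
        )
    return out


def read_compounds(path) -> list[CompoundRecord]:
    """Read a compound table into :class:`CompoundRecord` objects.

    Columns: ``compound_id, name, herbs`` (semicolon-separated),
    ``ob, caco2, dl`` (numbers, empty allowed), ``whitelisted``
    (true/false), ``whitelist_reason``, ``descriptor`` (comma-separated
    floats, empty allowed).  Duplicate compound ids raise with the line
    number.
    """
    df = _read_tsv(path, COMPOUND_COLUMNS)
    dup = df["compound_id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise TableFormatError(
            f"{path}: duplicate compound_id {df['compound_id'][dup.idxmax()]!r} at line {line}"
        )
    for col in ("ob", "caco2", "dl"):
        df[col] = _to_float(df, col, path, allow_empty=True)
    records = []
    for i, row in df.iterrows():
        line = i + 2
        herbs = frozenset(h for h in row["herbs"].split(";") if h)
        if not herbs:
            raise TableFormatError(f"{path}: empty herb attribution at line {line}")
        desc = None
        if row["descriptor"]:
            try:
                desc = tuple(float(v) for v in row["descriptor"].split(","))
            except ValueError:
                raise TableFormatError(
                    f"{path}: malformed descriptor at line {line}"
                ) from None
        wl = str(row["whitelisted"]).strip().lower()
        if wl not in ("true", "false", "1", "0", ""):
            raise TableFormatError(f"{path}: malformed whitelisted flag at line {line}")
        records.append(
            CompoundRecord(
                compound_id=row["compound_id"],
                name=row["name"],
                herb_ids=herbs,
                ob=None if pd.isna(row["ob"]) else float(row["ob"]),
                caco2=None if pd.isna(row["caco2"]) else float(row["caco2"]),
                dl=None if pd.isna(row["dl"]) else float(row["dl"]),
                descriptor=desc,
                whitelisted=wl in ("true", "1"),
                whitelist_reason=row["whitelist_reason"],
            )
        )
    return records


def write_compounds(records_or_frame, path) -> None:
    """Write compounds (records or an already-conforming frame) as TSV."""
    if isinstance(records_or_frame, pd.DataFrame):
        df = records_or_frame.copy()
        df["whitelisted"] = (
            df["whitelisted"].astype(bool).map({True: "true", False: "false"})
        )
    else:
        rows = []
        for r in records_or_frame:
            rows.append(
                {
                    "compound_id": r.compound_id,
                    "name": r.name,
                    "herbs": ";".join(sorted(r.herb_ids)),
                    "ob": "" if r.ob is None else r.ob,
                    "caco2": "" if r.caco2 is None else r.caco2,
                    "dl": "" if r.dl is None else r.dl,
                    "whitelisted": "true" if r.whitelisted else "false",
                    "whitelist_reason": r.whitelist_reason,
                    "descriptor": ",".join(map(str, r.descriptor)) if r.descriptor else "",
                }
            )
        df = pd.DataFrame(rows, columns=COMPOUND_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    """Read a compound-target prediction table (scores may be empty)."""
    df = _read_tsv(path, PREDICTION_COLUMNS)
    for col in ("max_tc", "possibility"):
        df[col] = _to_float(df, col, path, allow_empty=True)
    return df


def write_predictions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_module_annotations(path) -> dict[str, tuple[str, ...]]:
    """Read ``target<TAB>modules`` rows (modules semicolon-separated)."""
    df = _read_tsv(path, ["target", "modules"])
    return {
        row["target"]: tuple(m for m in row["modules"].split(";") if m)
        for _, row in df.iterrows()
    }


def write_module_annotations(annotations: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target\tmodules\n")
        for t in sorted(annotations):
            fh.write(f"{t}\t{';'.join(annotations[t])}\n")


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT gene-set file: ``id<TAB>description<TAB>member...``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableFormatError(
                    f"{path}: GMT line {lineno} needs id, description and >= 1 member"
                )
            cid, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise TableFormatError(f"{path}: GMT line {lineno} has no members")
            if cid in sets:
                raise TableFormatError(f"{path}: duplicate set id {cid!r} at line {lineno}")
            sets[cid] = (desc, frozenset(members))
    return sets


def write_gmt(sets: Mapping[str, tuple[str, frozenset[str]]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid in sorted(sets):
            desc, members = sets[cid]
            fh.write("\t".join([cid, desc, *sorted(members)]) + "\n")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV: ``group`` column plus the ten index columns."""
    df = _read_tsv(path, ["group", *INDEX_NAMES])
    for col in INDEX_NAMES:
        df[col] = _to_float(df, col, path)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# deterministic JSON reports

def _round_floats(obj):
    if isinstance(obj, dict):
        return {str(k): _round_floats(obj[k]) for k in obj}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if not math.isfinite(v) else float(f"{v:.9g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return obj


def write_json_report(obj, path) -> None:
    """Write JSON with sorted keys and 9-significant-digit floats."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
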