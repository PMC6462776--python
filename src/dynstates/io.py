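"""Flat-text I/O: subject time-course TSVs, manifest CSVs, run configs."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .postproc import TimecourseSet

__all__ = ["read_timecourse_tsv", "read_timecourses", "read_manifest",
           "read_config", "write_json"]


def read_timecourse_tsv(path: str | Path, tr: float, subject_id: str | None = None) -> TimecourseSet:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty time-course file") from exc
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 time points")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else -1
            raise ValueError(f"{path}: non-numeric value at row {row}, column {col!r}")
    return TimecourseSet(
        data=df.to_numpy(dtype=float),
        tr=tr,
        network_names=list(df.columns),
        subject_id=subject_id or path.stem,
    )


def read_timecourses(directory: str | Path, manifest: pd.DataFrame,
                     tr: float) -> list[TimecourseSet]:
    """Read one TSV per manifest subject_id from ``directory``.

    Subjects with a missing file raise; files present on disk but absent
    from the manifest are warned about and excluded.  All subjects must
    share the same set of network columns.
    """
    directory = Path(directory)
    on_disk = {p.stem for p in directory.glob("*.tsv")}
    wanted = list(manifest["subject_id"])
    extra = on_disk - set(wanted)
    if extra:
        warnings.warn(f"excluding {len(extra)} file(s) not in manifest: {sorted(extra)[:5]}")
    missing = [s for s in wanted if s not in on_disk]
    if missing:
        raise FileNotFoundError(f"missing time-course files for subjects: {missing[:5]}")
    tcs = [read_timecourse_tsv(directory / f"{sid}.tsv", tr, sid) for sid in wanted]
    cols = {tuple(tc.network_names) for tc in tcs}
    if len(cols) > 1:
        counts = sorted({tc.n_networks for tc in tcs})
        offenders = [tc.subject_id for tc in tcs
                     if tuple(tc.network_names) != max(cols, key=lambda c: sum(
                         tuple(t.network_names) == c for t in tcs))]
        raise ValueError(
            f"inconsistent network columns across subjects (column counts {counts}); "
            f"offending subjects: {offenders[:5]}"
        )
    return tcs


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError("manifest must have subject_id and group columns")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_ids in manifest: {dups}")
    return df


def read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
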