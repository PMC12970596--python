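"""Reading study inputs and writing the result bundle.

Input format: a CSV/TSV abundance matrix (lipid species in rows by default,
samples in columns, non-negative intensities or concentrations) plus a
two-column sample-to-group CSV.  Orientation can be auto-detected from
which axis labels parse as lipid names.  All tabular outputs are written
with 6 significant digits and the literal ``NA`` for missing values so the
bundle is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import NamedTuple, Optional

import pandas as pd

from .nomenclature import parse_profile

log = logging.getLogger("lipidindex")

FLOAT_FORMAT = "%.6g"
NA_REP = "NA"


class StudyInput(NamedTuple):
    abundance: pd.DataFrame  # lipids x samples
    groups: pd.Series  # sample -> group
    parse_skipped: list  # (name, reason)


def _sniff_sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _parse_rate(labels) -> float:
    report = None
    try:
        report = parse_profile(labels, max_failure_fraction=1.1)
    except ValueError:
        return 0.0
    return len(report.records) / max(len(list(labels)), 1)


def read_lipid_matrix(path, orientation: str = "auto") -> tuple[pd.DataFrame, list]:
    """Read a lipid abundance matrix.

    ``orientation``: "rows" (lipids in rows, the default layout), "columns",
    or "auto" (keep whichever axis parses better as lipid names in rows).
    Unparseable lipid rows are skipped and reported; negative values are a
    hard failure with their coordinates; missing cells become 0 (logged).
    Duplicate lipid names are suffixed; duplicate sample ids are a hard
    failure.
    """
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation not in ("auto", "rows", "columns"):
        raise ValueError("orientation must be 'auto', 'rows' or 'columns'")
    if orientation == "columns":
        df = df.T
    elif orientation == "auto":
        if _parse_rate(df.columns) > _parse_rate(df.index):
            df = df.T
            log.info("auto-detected lipids in columns; matrix transposed")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate sample ids: {dups}")
    if df.index.duplicated().any():
        counts: dict[str, int] = {}
        new_index = []
        for name in df.index:
            if name in counts:
                counts[name] += 1
                new_index.append(f"{name}_dup{counts[name]}")
            else:
                counts[name] = 0
                new_index.append(name)
        n_dup = sum(1 for n in new_index if "_dup" in n)
        log.warning("suffixed %d duplicate lipid names", n_dup)
        df.index = new_index

    df = df.apply(pd.to_numeric, errors="coerce")
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        log.warning("treated %d missing cells as 0", n_missing)
        df = df.fillna(0.0)
    neg = df < 0
    if neg.to_numpy().any():
        r = neg.any(axis=1).idxmax()
        c = neg.loc[r].idxmax()
        raise ValueError(
            f"negative abundance at lipid {r!r}, sample {c!r}: {df.loc[r, c]}"
        )

    report = parse_profile(df.index)
    skipped = report.skipped
    if skipped:
        log.warning(
            "skipped %d unparseable lipid rows (e.g. %r)", len(skipped), skipped[0][0]
        )
        df = df.loc[[n for n in df.index if n in report.records]]
    return df, skipped


def read_group_map(path) -> pd.Series:
    """Read a sample,group CSV into a sample -> group label series."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.shape[1] < 2:
        raise ValueError("group map needs two columns: sample, group")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        raise ValueError("duplicate sample ids in the group map")
    return pd.Series(
        df[group_col].astype(str).to_numpy(),
        index=df[sample_col].astype(str),
        name="group",
    )


def read_study(matrix_path, groups_path, orientation: str = "auto") -> StudyInput:
    """Read and cross-validate the abundance matrix and group map."""
    abundance, skipped = read_lipid_matrix(matrix_path, orientation)
    groups = read_group_map(groups_path)
    unlabelled = [c for c in abundance.columns if c not in groups.index]
    if unlabelled:
        raise ValueError(f"samples without a group label: {unlabelled}")
    groups = groups.loc[list(abundance.columns)]
    return StudyInput(abundance, groups, skipped)


def write_table(df: pd.DataFrame, path, index: bool = False, index_label=None) -> None:
    df.to_csv(
        path, na_rep=NA_REP, float_format=FLOAT_FORMAT, index=index,
        index_label=index_label,
    )


def write_study(study, matrix_path, groups_path) -> None:
    """Write a (possibly simulated) study to disk in the input format."""
    study.abundance.to_csv(matrix_path, index_label="lipid")
    study.groups.rename_axis("sample").reset_index().to_csv(groups_path, index=False)


def write_run_log(path, **entries) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
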