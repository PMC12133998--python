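"""Behavioral-table preparation and merging with force-plate statistics.

Behavioral exports (one DSV per subject or per subject × block, header row
included) rarely carry subject/block columns — identity lives in the
filename, exactly as for the raw force-plate files.  Preparation parses
each file, drops unwanted rows and columns, injects subject/block from the
filename, numbers trials 1..n within (subject, block) by row order when no
trial column exists, and concatenates everything.

Trial alignment between behavioral and force-plate data is *positional*
within (subject, block) when neither side carries explicit trial IDs; a
merge therefore refuses to join when the two sides disagree on any key.
Row exclusion is an explicit user predicate — the pipeline never decides
which trials are outliers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .fileio import KEY_COLUMNS, parse_data_filename

__all__ = ["prep_exp_data", "combine_data", "exclude_rows"]


def prep_exp_data(paths: Sequence[str | Path],
                  keep_columns: Sequence[str] | None = None,
                  row_filter: Callable[[pd.Series], bool] | None = None,
                  delimiter: str = ",") -> pd.DataFrame:
    """Read, clean and concatenate behavioral trial tables.

    Per file: parse with a header row, keep only ``keep_columns`` (plus
    keys), drop rows failing ``row_filter``, inject subject/block from the
    filename when the table lacks those columns, and number trials within
    (subject, block) by row order when no ``trial`` column exists.

    Raises
    ------
    ValueError
        If the concatenated table contains duplicate (subject, block,
        trial) keys.
    """
    frames = []
    for path in paths:
        path = Path(path)
        rec_id = parse_data_filename(path)
        df = pd.read_csv(path, sep=delimiter)
        if row_filter is not None:
            mask = df.apply(row_filter, axis=1).astype(bool)
            df = df.loc[mask].reset_index(drop=True)
        if keep_columns is not None:
            keep = [c for c in df.columns
                    if c in keep_columns or c in KEY_COLUMNS]
            df = df[keep]
        if "subject" not in df.columns:
            df.insert(0, "subject", rec_id.subject)
        if "block" not in df.columns:
            df.insert(1, "block", rec_id.block if rec_id.block is not None
                      else pd.NA)
        if "trial" not in df.columns:
            df.insert(2, "trial",
                      df.groupby(["subject", "block"], dropna=False)
                        .cumcount() + 1)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for k in KEY_COLUMNS:
        out[k] = out[k].astype("Int64")
    dup = out.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        offenders = out.loc[dup, list(KEY_COLUMNS)].drop_duplicates()
        raise ValueError(
            f"duplicate (subject, block, trial) keys after preparation: "
            f"{offenders.values.tolist()}")
    return out


def _key_view(df: pd.DataFrame) -> pd.DataFrame:
    return df[list(KEY_COLUMNS)].astype("Int64")


def combine_data(a: pd.DataFrame, b: pd.DataFrame,
                 suffixes: tuple[str, str] = ("_a", "_b")) -> pd.DataFrame:
    """Merge two keyed tables column-wise or stack them row-wise.

    If the two tables' (subject, block, trial) key sets are identical the
    result is a column-wise join (one row per key, overlapping non-key
    column names suffixed by source); if the key sets are disjoint the
    tables are stacked row-wise.  Partial key overlap on a column join is
    an error naming the unmatched keys — no silent row loss.
    """
    for name, df in (("first", a), ("second", b)):
        missing = [k for k in KEY_COLUMNS if k not in df.columns]
        if missing:
            raise ValueError(f"{name} table lacks key columns {missing}")
    keys_a = set(map(tuple, _key_view(a).itertuples(index=False)))
    keys_b = set(map(tuple, _key_view(b).itertuples(index=False)))
    if keys_a == keys_b:
        return pd.merge(a, b, on=list(KEY_COLUMNS), how="inner",
                        suffixes=suffixes, validate="one_to_one")
    if keys_a.isdisjoint(keys_b):
        return pd.concat([a, b], ignore_index=True)
    unmatched = sorted(keys_a.symmetric_difference(keys_b))
    raise ValueError(
        f"key sets overlap partially; {len(unmatched)} unmatched "
        f"(subject, block, trial) keys: {unmatched[:10]}"
        + (" ..." if len(unmatched) > 10 else ""))


def exclude_rows(table: pd.DataFrame,
                 predicate: Callable[[pd.Series], bool],
                 verbose: bool = False) -> pd.DataFrame:
    """Drop rows for which ``predicate`` is true; report the count removed.

    The predicate is a pure function of a row's values; referencing a
    column the table lacks raises ``KeyError``.
    """
    if len(table) == 0:
        return table.copy()
    mask = table.apply(predicate, axis=1).astype(bool)
    removed = int(mask.sum())
    if verbose:
        print(f"exclude_rows: removed {removed} of {len(table)} rows")
    out = table.loc[~mask].reset_index(drop=True)
    out.attrs["n_removed"] = removed
    return out
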