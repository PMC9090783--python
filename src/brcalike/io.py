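"""Readers and writers for the plain-text formats used across the pipeline.

All genomic coordinates are 0-based half-open (BED convention).  Bin grids
travel as 6-column TSV (chrom, start, end, gc, mappability, blacklist),
counts as 4-column TSV, cohorts as CSV with a documented header, and
classifier models as JSON.  Every writer can emit a sidecar provenance JSON
recording the generating configuration, including the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

#: Autosome names accepted on input, normalized to bare "1".."22".
AUTOSOMES = tuple(str(i) for i in range(1, 23))
_AUTOSOME_SET = frozenset(AUTOSOMES)

BIN_COLUMNS = ["chrom", "start", "end", "gc", "mappability", "blacklist"]
COUNT_COLUMNS = ["chrom", "start", "end", "count"]

COHORT_COLUMNS = [
    "id", "arm", "marker", "time_to_recurrence", "time_to_death",
    "followup_time", "age", "who_ps", "surgery", "axillary_surgery",
    "t_stage", "nodes", "histology", "grade",
]


def normalize_chrom(name: object) -> str:
    """Normalize a chromosome name to a bare autosome label ("1".."22").

    Accepts names with or without a "chr" prefix.  Anything that is not an
    autosome is rejected with a message naming the offender.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s not in _AUTOSOME_SET:
        raise ValueError(f"not an autosome: {name!r} (expected 1-22, optionally chr-prefixed)")
    return s


def is_autosome(name: object) -> bool:
    try:
        normalize_chrom(name)
        return True
    except ValueError:
        return False


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-like file into a frame of 0-based half-open intervals.

    Comment (#) and track/browser lines are skipped; columns past the third
    are ignored.  A malformed line raises with its line number.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates: {line!r}") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((fields[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).astype(
        {"start": np.int64, "end": np.int64}
    )


def _write_sidecar(path: Path, config: dict | None) -> None:
    if config is None:
        return
    sidecar = path.with_name(path.name + ".provenance.json")
    sidecar.write_text(json.dumps(config, indent=2, sort_keys=True, default=str) + "\n")


def write_bins(bins: pd.DataFrame, path: str | Path, config: dict | None = None) -> None:
    path = Path(path)
    bins.loc[:, BIN_COLUMNS].assign(blacklist=bins["blacklist"].astype(int)).to_csv(
        path, sep="\t", index=False
    )
    _write_sidecar(path, config)


def read_bins(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in BIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing bin columns {missing}")
    df["blacklist"] = df["blacklist"].astype(bool)
    return df[BIN_COLUMNS]


def write_counts(bins: pd.DataFrame, counts: np.ndarray, path: str | Path,
                 config: dict | None = None) -> None:
    path = Path(path)
    out = bins.loc[:, ["chrom", "start", "end"]].copy()
    out["count"] = np.asarray(counts)
    out.to_csv(path, sep="\t", index=False)
    _write_sidecar(path, config)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing count columns {missing}")
    return df[COUNT_COLUMNS]


def write_cohort(cohort: pd.DataFrame, path: str | Path, config: dict | None = None) -> None:
    path = Path(path)
    cohort.to_csv(path, index=False)
    _write_sidecar(path, config)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("id", "arm", "marker", "followup_time") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing cohort columns {missing}")
    return df


def write_profile(profile, path: str | Path, config: dict | None = None) -> None:
    """Write a GenomicProfile as TSV (chrom, start, end, log2_ratio, included)."""
    path = Path(path)
    out = profile.bins.loc[:, ["chrom", "start", "end"]].copy()
    out["log2_ratio"] = profile.log2_ratio
    out["included"] = profile.included.astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    meta = dict(profile.provenance)
    if config:
        meta.update(config)
    _write_sidecar(path, meta)


def read_profile(path: str | Path):
    from .cnv import GenomicProfile  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    needed = ["chrom", "start", "end", "log2_ratio", "included"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing profile columns {missing}")
    bins = df[["chrom", "start", "end"]].copy()
    return GenomicProfile(
        bins=bins,
        log2_ratio=df["log2_ratio"].to_numpy(dtype=float),
        included=df["included"].to_numpy().astype(bool),
        provenance={"source": str(path)},
    )


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file into a flat dict."""
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
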