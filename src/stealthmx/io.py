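"""File-format plumbing: TSV tables, YAML configs, JSON reports.

All delimited output is tab-separated UTF-8 with a mandatory header row and
'.' as the decimal separator.  JSON reports carry sorted keys plus the
package version and the seed so runs diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .inference import ObservedCounts
from .model import ExperimentDesign, equal_design
from .simulate import MULTIPLET_TOKEN, UNASSIGNED_TOKEN, UNLABELLED_TOKEN

__all__ = [
    "DEFAULT_TOKEN_MAP",
    "read_design_config",
    "read_counts_table",
    "write_counts_table",
    "read_call_table",
    "write_call_table",
    "read_score_table",
    "write_table",
    "write_json_report",
]

PathLike = Union[str, Path]

# demultiplexer dialect tokens normalised by the call-table reader
DEFAULT_TOKEN_MAP: dict[str, str] = {
    "multiplet": MULTIPLET_TOKEN,
    "doublet": MULTIPLET_TOKEN,
    "negative": UNLABELLED_TOKEN,
    "unlabelled": UNLABELLED_TOKEN,
    "unlabeled": UNLABELLED_TOKEN,
    "unassigned": UNASSIGNED_TOKEN,
    "ambiguous": UNASSIGNED_TOKEN,
}


def read_design_config(path: PathLike) -> ExperimentDesign:
    """Experiment design from a YAML config.

    Either ``samples`` + ``abar`` (+ ``lam``) for an equal design, or
    explicit ``fractions`` and ``efficiencies`` vectors.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config {path} does not hold a mapping")
    lam = float(cfg["lam"])
    if "fractions" in cfg or "efficiencies" in cfg:
        r = np.asarray(cfg["fractions"], dtype=float)
        a = np.asarray(cfg["efficiencies"], dtype=float)
        names = tuple(cfg.get("names", ()))
        return ExperimentDesign(r=r, a=a, lam=lam, names=names)
    return equal_design(int(cfg["samples"]), float(cfg["abar"]), lam)


def read_counts_table(path: PathLike) -> ObservedCounts:
    """Observed class tallies from a two-column TSV (class, count).

    Classes are ``sample:<name>``, ``unlabelled`` and ``multilabelled``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"class", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    per_sample: dict[str, int] = {}
    n_unlab = n_multi = 0
    for _, row in df.iterrows():
        cls, count = str(row["class"]), int(row["count"])
        if cls.startswith("sample:"):
            per_sample[cls.split(":", 1)[1]] = count
        elif cls == "unlabelled":
            n_unlab = count
        elif cls == "multilabelled":
            n_multi = count
        else:
            raise ValueError(f"unknown class {cls!r} in counts table {path}")
    return ObservedCounts(
        n_mono_total=0,
        n_mono_per_sample=per_sample or None,
        n_unlabelled=n_unlab,
        n_multilabelled=n_multi,
    )


def write_counts_table(counts: ObservedCounts, path: PathLike) -> None:
    rows = []
    if counts.n_mono_per_sample:
        rows += [
            {"class": f"sample:{name}", "count": n}
            for name, n in counts.n_mono_per_sample.items()
        ]
    else:
        rows.append({"class": "sample:pooled", "count": counts.n_mono_total})
    rows.append({"class": "unlabelled", "count": counts.n_unlabelled})
    rows.append({"class": "multilabelled", "count": counts.n_multilabelled})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_call_table(
    path: PathLike,
    token_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Call table from a TSV with columns (barcode, call).

    Dialect tokens (Doublet, Negative, ...) are normalised case-insensitively
    to the reserved tokens via :data:`DEFAULT_TOKEN_MAP`, extended or
    overridden by ``token_map``; calls naming several samples with '+'
    normalise to MULTIPLET.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"barcode", "call"}.issubset(df.columns):
        raise ValueError(f"call table {path} needs columns barcode, call")
    mapping = dict(DEFAULT_TOKEN_MAP)
    if token_map:
        mapping.update({k.lower(): v for k, v in token_map.items()})

    def _norm(call: str) -> str:
        low = call.strip().lower()
        if low in mapping:
            return mapping[low]
        if "+" in call:
            return MULTIPLET_TOKEN
        return call.strip()

    out = df[["barcode", "call"]].copy()
    out["call"] = out["call"].map(_norm)
    return out


def write_call_table(calls: pd.DataFrame, path: PathLike) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_score_table(path: PathLike, barcode_column: str = "barcode") -> pd.DataFrame:
    """Per-droplet marker scores: barcode column plus one column per lineage."""
    df = pd.read_csv(path, sep="\t")
    if barcode_column not in df.columns:
        raise ValueError(f"score table {path} lacks column {barcode_column!r}")
    return df


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json_report(
    payload: Mapping,
    path: PathLike,
    seed: Optional[int] = None,
    config: Optional[Mapping] = None,
) -> None:
    """JSON report with provenance (package version, seed, config echo)."""
    from . import __version__

    report = dict(payload)
    report["provenance"] = {
        "package": "stealthmx",
        "version": __version__,
        "seed": seed,
        "config": dict(config) if config else None,
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
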