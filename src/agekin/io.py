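"""File formats: labeling / abundance / biomass TSV, model config, run tables.

TSV dialect: tab-separated, '.' decimal, no quoting, UTF-8, header required.
The labeling table has columns ``species_id, time, fraction_labeled`` and an
optional ``replicate``.  Fractions outside [0, 1] by at most 0.02 are
clipped with a warning; larger violations are rejected with line numbers.
Undefined parameters are serialized as literal "NA".
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cmodel import CompartmentalModel
from .curves import GrowthModel, LabelingCurve
from .simulate import LabelingDataset

__all__ = [
    "read_labeling_tsv",
    "write_labeling_tsv",
    "read_abundance_tsv",
    "read_biomass_tsv",
    "fraction_from_intensities",
    "read_model_config",
    "write_model_config",
    "write_parameter_table",
]

_CLIP_TOL = 0.02
_UNIT_TO_MIN = {"min": 1.0, "minutes": 1.0, "s": 1.0 / 60, "seconds": 1.0 / 60,
                "h": 60.0, "hours": 60.0, "d": 1440.0, "days": 1440.0}


class FormatError(ValueError):
    """Malformed input file."""


def _time_factor(unit: str) -> float:
    try:
        return _UNIT_TO_MIN[unit.lower()]
    except KeyError:
        raise FormatError(f"unknown time unit {unit!r}; "
                          f"expected one of {sorted(_UNIT_TO_MIN)}") from None


def read_labeling_tsv(path: str | Path, time_unit: str = "min") -> LabelingDataset:
    """Read a labeling time-course TSV into a :class:`LabelingDataset`.

    Times are converted to minutes on read.  Duplicate
    (species, replicate, time) rows and fractions beyond the 0.02 clipping
    tolerance are rejected with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str})
    required = {"species_id", "time", "fraction_labeled"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}")
    if df[list(required)].isna().any().any():
        lines = (df[list(required)].isna().any(axis=1)).to_numpy().nonzero()[0] + 2
        raise FormatError(f"{path}: missing values on lines {lines.tolist()}")

    frac = df["fraction_labeled"].to_numpy(dtype=float)
    bad = (frac < -_CLIP_TOL) | (frac > 1 + _CLIP_TOL)
    if bad.any():
        lines = (np.nonzero(bad)[0] + 2).tolist()
        raise FormatError(
            f"{path}: fraction_labeled outside [-{_CLIP_TOL}, {1 + _CLIP_TOL}] "
            f"on lines {lines}")
    clipped = (frac < 0) | (frac > 1)
    if clipped.any():
        warnings.warn(f"{path}: clipped {int(clipped.sum())} fraction values "
                      f"to [0, 1] (within {_CLIP_TOL} tolerance)", stacklevel=2)
        frac = np.clip(frac, 0.0, 1.0)
    df = df.assign(fraction_labeled=frac)

    rep_col = df["replicate"] if "replicate" in df.columns else pd.Series(
        [None] * len(df), index=df.index)
    key = pd.DataFrame({"s": df["species_id"], "r": rep_col, "t": df["time"]})
    dup = key.duplicated()
    if dup.any():
        lines = (np.nonzero(dup.to_numpy())[0] + 2).tolist()
        raise FormatError(f"{path}: duplicate (species, replicate, time) rows "
                          f"on lines {lines}")

    factor = _time_factor(time_unit)
    curves: dict[str, LabelingCurve] = {}
    for (sid, rep), grp in df.groupby([df["species_id"], rep_col.fillna("")],
                                      sort=True):
        grp = grp.sort_values("time")
        key_id = sid if rep in ("", None) else f"{sid}/{rep}"
        curves[key_id] = LabelingCurve(
            species_id=sid, times=grp["time"].to_numpy(dtype=float) * factor,
            values=grp["fraction_labeled"].to_numpy(dtype=float),
            replicate=rep or None)
    return LabelingDataset(curves=curves)


def write_labeling_tsv(dataset: LabelingDataset, path: str | Path) -> None:
    """Write a dataset back to the labeling TSV format (times in minutes)."""
    rows = []
    for c in dataset.curves.values():
        for t, v in zip(c.times, c.values):
            row = {"species_id": c.species_id, "time": repr(float(t)),
                   "fraction_labeled": repr(float(v))}
            if c.replicate is not None:
                row["replicate"] = c.replicate
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_abundance_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str})
    if not {"species_id", "abundance"}.issubset(df.columns):
        raise FormatError(f"{path}: needs columns species_id, abundance")
    ab = df.set_index("species_id")["abundance"].astype(float)
    if (ab < 0).any():
        raise FormatError(f"{path}: abundance must be >= 0")
    return ab.to_dict()


def read_biomass_tsv(path: str | Path, time_unit: str = "min"):
    df = pd.read_csv(path, sep="\t")
    if not {"time", "biomass"}.issubset(df.columns):
        raise FormatError(f"{path}: needs columns time, biomass")
    factor = _time_factor(time_unit)
    return (df["time"].to_numpy(dtype=float) * factor,
            df["biomass"].to_numpy(dtype=float))


def fraction_from_intensities(light: float, heavy: float) -> float:
    """Labeled (light) fraction from light/heavy channel intensities.

    Returns NaN (undefined) when both channels are zero.
    """
    if light < 0 or heavy < 0:
        raise ValueError("intensities must be >= 0")
    total = light + heavy
    if total == 0:
        return float("nan")
    return light / total


# ---------------------------------------------------------------------------
# model config
# ---------------------------------------------------------------------------

def write_model_config(model: CompartmentalModel, path: str | Path) -> None:
    """Serialize a compartmental model to YAML (decimals kept bit-exact via repr)."""
    doc = {
        "states": list(model.labels),
        "M": [[repr(float(x)) for x in row] for row in model.M],
        "s": [repr(float(x)) for x in model.s],
        "mu": repr(float(model.mu)),
        "observed": [bool(b) for b in model.observed],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_model_config(path: str | Path) -> CompartmentalModel:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        M = np.array([[float(x) for x in row] for row in doc["M"]])
        s = np.array([float(x) for x in doc["s"]])
        mu = float(doc["mu"])
        observed = np.array(doc.get("observed", [True] * len(s)), dtype=bool)
        labels = tuple(doc.get("states") or ())
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed model config ({exc})") from exc
    return CompartmentalModel(M=M, s=s, mu=mu, observed=observed,
                              labels=labels or None)


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def _na(x) -> str:
    if x is None:
        return "NA"
    try:
        if not np.isfinite(x):
            return "NA"
    except TypeError:
        return str(x)
    return repr(float(x))


def write_parameter_table(parameters: dict[str, dict], path: str | Path,
                          bootstrap: dict | None = None) -> None:
    """Write the per-species parameter TSV of the workflow.

    Columns: species_id, pool_class, mean ages (minutes and in units of
    1/mu), half-life, conditioned decay rate / residence time, per-template
    BICs and bootstrap CVs.  Undefined values appear as NA.
    """
    rows = []
    for sid in sorted(parameters):
        p = parameters[sid]
        row = {"species_id": sid, "pool_class": p["pool_class"],
               "mean_age_min": _na(p["mean_age_min"]),
               "mean_age_over_mu_inv": _na(p["mean_age_over_mu_inv"]),
               "half_life_min": _na(p["half_life_min"]),
               "kappa_cond": _na(p["kappa_cond"]),
               "T_cond": _na(p["T_cond"])}
        for name, b in sorted(p.get("bic_table", {}).items()):
            row[f"bic_{name}"] = _na(b)
        if bootstrap and sid in bootstrap:
            for q in ("mean_age", "half_life", "kappa_cond", "T_cond"):
                row[f"cv_{q}"] = _na(bootstrap[sid].cv(q))
        if "naive_mean_age_min" in p:
            row["naive_mean_age_min"] = _na(p["naive_mean_age_min"])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (seeds, options, input-model parameters...)."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    Path(path).write_text(json.dumps(entries, indent=2, default=default),
                          encoding="utf-8")
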