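"""Event-record datasets and file formats.

The rectangular event dataset follows the field-standard conventions:
one row per dose or observation, columns ID, TIME, AMT, DV, EVID, CVRC,
CREA (EVID 1 = dose with AMT in mg, EVID 0 = observation with DV in
ng/mL), optional demographic columns, "." or empty accepted as missing.
Parameter files are flat ``key = value`` text.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PKEventDataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "read_params_config",
    "write_params_config",
]

MANDATORY_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "CVRC", "CREA")
OPTIONAL_COLUMNS = ("WT", "AGE", "SEX", "CYP3A5", "CYP2C19")


class DatasetError(ValueError):
    """Malformed event dataset (carries row/line context where known)."""


@dataclass
class PKEventDataset:
    """Per-subject dosing and observation records with time-varying covariates.

    Wraps a validated DataFrame; invariants enforced at construction:
    times non-negative and non-decreasing within subject, every observation
    preceded by at least one dose for that subject, and at least one
    observation per subject.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing mandatory column(s): {', '.join(missing)}")
        df = df.copy()
        for col in ("TIME", "AMT", "DV", "CVRC", "CREA"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["EVID"] = df["EVID"].astype(int)
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if not set(df["EVID"]).issubset({0, 1}):
            raise DatasetError("EVID must be 0 (observation) or 1 (dose)")
        if (df["TIME"] < 0).any():
            row = int(df.index[df["TIME"] < 0][0])
            raise DatasetError(f"negative TIME at data row {row}")
        dose_with_dv = (df["EVID"] == 1) & df["DV"].notna()
        if dose_with_dv.any():
            row = int(df.index[dose_with_dv][0])
            raise DatasetError(f"DV present on a dose (EVID=1) row: data row {row}")
        obs = df["EVID"] == 0
        if df.loc[obs, "DV"].isna().any():
            row = int(df.index[obs & df["DV"].isna()][0])
            raise DatasetError(f"missing DV on observation row: data row {row}")
        if df.loc[df["EVID"] == 1, "AMT"].isna().any() or (
            df.loc[df["EVID"] == 1, "AMT"] < 0
        ).any():
            raise DatasetError("dose rows must carry a non-negative AMT")
        if df.loc[obs, ["CVRC", "CREA"]].isna().any().any():
            raise DatasetError("observation rows must carry CVRC and CREA")
        if (df.loc[obs, "CVRC"] < 0).any():
            raise DatasetError("CVRC must be >= 0")
        if (df.loc[obs, "CREA"] <= 0).any():
            raise DatasetError("CREA must be > 0")
        for sid, g in df.groupby("ID", sort=False):
            t = g["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise DatasetError(f"times not non-decreasing within subject {sid}")
            if not (g["EVID"] == 0).any():
                raise DatasetError(f"subject {sid} has no observations")
            first_dose = g.loc[g["EVID"] == 1, "TIME"]
            if first_dose.empty:
                raise DatasetError(f"subject {sid} has no doses")
            first_obs = g.loc[g["EVID"] == 0, "TIME"].iloc[0]
            if first_obs < first_dose.iloc[0]:
                raise DatasetError(
                    f"subject {sid}: observation at t={first_obs} precedes first dose"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0].copy()

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1].copy()

    def subset(self, subject_ids, relabel: bool = False) -> "PKEventDataset":
        """Dataset restricted to ``subject_ids`` (with replacement allowed).

        ``relabel=True`` assigns fresh sequential IDs so that a bootstrap
        resample containing the same subject twice keeps both copies.
        """
        parts = []
        for new_id, sid in enumerate(subject_ids, start=1):
            g = self.df[self.df["ID"] == sid].copy()
            if g.empty:
                raise DatasetError(f"unknown subject id {sid!r}")
            if relabel:
                g["ID"] = new_id
            parts.append(g)
        return PKEventDataset(pd.concat(parts, ignore_index=True))

    def time_after_dose(self) -> pd.Series:
        """TAD for every observation row: time minus most recent prior dose time."""
        out = {}
        for sid, g in self.df.groupby("ID", sort=False):
            dose_t = g.loc[g["EVID"] == 1, "TIME"].to_numpy()
            for idx, row in g[g["EVID"] == 0].iterrows():
                prior = dose_t[dose_t <= row["TIME"]]
                if prior.size == 0:
                    raise DatasetError(f"subject {sid}: observation before any dose")
                out[idx] = row["TIME"] - prior.max()
        return pd.Series(out, name="TAD").sort_index()


def read_dataset(path: str | Path | _io.TextIOBase) -> PKEventDataset:
    """Read an event CSV, validating the dialect with line-number errors."""
    df = pd.read_csv(path, na_values=["."], skipinitialspace=True)
    try:
        return PKEventDataset(df)
    except DatasetError as err:
        msg = str(err)
        # data row i lives on file line i+2 (header is line 1)
        if "data row " in msg:
            row = int(msg.rsplit("data row ", 1)[1].rstrip(")"))
            msg = f"{msg} (file line {row + 2})"
        raise DatasetError(msg) from None


def write_dataset(ds: PKEventDataset, path: str | Path) -> None:
    """Write the event CSV dialect back out ('.' for missing values)."""
    df = ds.df.copy()
    df.to_csv(path, index=False, na_rep=".")


# -- flat key-value parameter files -------------------------------------------

_PARAM_KEYS = (
    "tvKa",
    "tvV",
    "tvCL",
    "theta_vrc_v",
    "theta_vrc_cl",
    "theta_crea_v",
    "theta_crea_cl",
    "crea_ref",
    "omega2_v",
    "omega2_cl",
    "sigma_add",
    "covariate_form",
)


def read_params_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` parameter file (``#`` starts a comment)."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _PARAM_KEYS:
            raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
        out[key] = value if key == "covariate_form" else float(value)
    return out


def write_params_config(params: dict, path: str | Path) -> None:
    lines = [f"{k} = {params[k]}" for k in _PARAM_KEYS if k in params]
    extra = set(params) - set(_PARAM_KEYS)
    if extra:
        raise ValueError(f"unknown parameter key(s): {sorted(extra)}")
    Path(path).write_text("\n".join(lines) + "\n")
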