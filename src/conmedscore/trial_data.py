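"""Domain types and delimited-text I/O for longitudinal trial records.

The canonical in-memory container is :class:`TrialDataset`, a bundle of
pandas DataFrames with fixed logical column names:

* ``med_logs``     — one row per (subject, day, medication) from the
  monthly visit medication logs, with an optional per-visit compliance
  code and, for insulin records, an average daily dose.
* ``annual_logs``  — one row per (subject, day, medication_class) from
  annual physical-exam records, carrying an on/off flag.
* ``phenotypes``   — dated phenotype measurements (e.g. ``hba1c_pct``,
  ``ldl_mgdl``).
* ``baselines``    — one row per subject of baseline covariates.

Time is represented throughout as integer days since randomization
(day 0); any calendar dates in the raw extracts must be converted before
or at load.  Compliance is ACCORD-style categorical: 1 = 80–100%,
2 = 1–79%, 3 = 0%, 4 = more than prescribed (treated as full
compliance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Valid per-visit compliance codes.
COMPLIANCE_CODES = frozenset({1, 2, 3, 4})

#: Codes treated as full (80–100%) compliance; 4 (over-use) counts as full.
FULL_COMPLIANCE_CODES = frozenset({1, 4})

#: Code meaning 0% compliance.
ZERO_COMPLIANCE_CODE = 3

MED_LOG_COLUMNS = ["subject_id", "day", "medication", "compliance", "insulin_units_per_day"]
ANNUAL_LOG_COLUMNS = ["subject_id", "day", "medication_class", "on_flag"]
PHENOTYPE_COLUMNS = ["subject_id", "day", "phenotype", "value"]


class TrialDataError(ValueError):
    """Schema- or invariant-level fault in a trial-data extract."""


@dataclass
class LoadReport:
    """Row accounting for one loaded table."""

    table: str
    n_read: int
    n_dropped: int

    @property
    def n_kept(self) -> int:
        return self.n_read - self.n_dropped


@dataclass
class TrialDataset:
    """Validated longitudinal trial records for one study extract."""

    med_logs: pd.DataFrame
    annual_logs: pd.DataFrame
    phenotypes: pd.DataFrame
    baselines: pd.DataFrame
    medication_class_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        """Enforce type invariants; raise :class:`TrialDataError` on fault."""
        m = self.med_logs
        if len(m):
            bad = m.loc[m["compliance"].notna() & ~m["compliance"].isin(COMPLIANCE_CODES)]
            if len(bad):
                row = bad.iloc[0]
                raise TrialDataError(
                    f"unknown compliance code {row['compliance']!r} for subject "
                    f"{row['subject_id']} at day {row['day']}"
                )
            dup = m.duplicated(["subject_id", "day", "medication"])
            if dup.any():
                row = m.loc[dup].iloc[0]
                raise TrialDataError(
                    "duplicate medication-log key "
                    f"({row['subject_id']}, {row['day']}, {row['medication']})"
                )
            if (m["day"] < 0).any():
                raise TrialDataError("medication-log day before randomization (day < 0)")
        a = self.annual_logs
        if len(a) and a.duplicated(["subject_id", "day", "medication_class"]).any():
            row = a.loc[a.duplicated(["subject_id", "day", "medication_class"])].iloc[0]
            raise TrialDataError(
                "duplicate annual-log key "
                f"({row['subject_id']}, {row['day']}, {row['medication_class']})"
            )
        p = self.phenotypes
        if len(p) and (p["day"] < -365).any():
            raise TrialDataError("phenotype observation more than 365 days pre-randomization")
        if self.baselines["subject_id"].duplicated().any():
            raise TrialDataError("duplicate subject_id in baselines")
        known = set(self.baselines["subject_id"])
        for name, tbl in (("med_logs", m), ("annual_logs", a), ("phenotypes", p)):
            extra = set(tbl["subject_id"]) - known
            if extra:
                raise TrialDataError(
                    f"{name} contains subject ids absent from baselines: {sorted(extra)[:5]}"
                )

    # -- convenience ----------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.baselines["subject_id"])

    def _group_cache(self, table: str) -> dict[str, pd.DataFrame]:
        """Per-subject subframes of ``table``; dataset treated as immutable."""
        key = f"_groups_{table}"
        cache = self.__dict__.get(key)
        if cache is None:
            df = getattr(self, table)
            cache = {sid: g for sid, g in df.groupby("subject_id", sort=False)} if len(df) else {}
            self.__dict__[key] = cache
        return cache

    def _empty_like(self, table: str) -> pd.DataFrame:
        return getattr(self, table).iloc[0:0]

    def class_members(self, class_name: str) -> list[str]:
        """Medication names mapped to ``class_name`` (may be empty)."""
        return [m for m, c in self.medication_class_map.items() if c == class_name]

    def medication_names(self, medication_or_class: str) -> list[str]:
        """The medication itself plus any class members it names.

        A query may be an individual medication, a class name, or both
        (a medication that is also the name of its class); members of
        the medication's own class are included either way.
        """
        names = {medication_or_class}
        names.update(self.class_members(medication_or_class))
        own_class = self.medication_class_map.get(medication_or_class)
        if own_class is not None:
            names.update(self.class_members(own_class))
        return sorted(names)

    def subject_med_logs(self, subject_id: str) -> pd.DataFrame:
        return self._group_cache("med_logs").get(subject_id, self._empty_like("med_logs"))

    def subject_phenotypes(self, subject_id: str) -> pd.DataFrame:
        return self._group_cache("phenotypes").get(subject_id, self._empty_like("phenotypes"))

    def subject_annual_logs(self, subject_id: str) -> pd.DataFrame:
        return self._group_cache("annual_logs").get(subject_id, self._empty_like("annual_logs"))

    def equals(self, other: "TrialDataset") -> bool:
        def _norm(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            return df.sort_values(keys).reset_index(drop=True)

        return (
            _norm(self.med_logs, ["subject_id", "day", "medication"]).equals(
                _norm(other.med_logs, ["subject_id", "day", "medication"])
            )
            and _norm(self.annual_logs, ["subject_id", "day", "medication_class"]).equals(
                _norm(other.annual_logs, ["subject_id", "day", "medication_class"])
            )
            and _norm(self.phenotypes, ["subject_id", "day", "phenotype"]).equals(
                _norm(other.phenotypes, ["subject_id", "day", "phenotype"])
            )
            and _norm(self.baselines, ["subject_id"]).equals(
                _norm(other.baselines, ["subject_id"])
            )
            and self.medication_class_map == other.medication_class_map
        )


DEFAULT_SCHEMA: dict[str, dict[str, str]] = {
    "med_logs": {c: c for c in MED_LOG_COLUMNS},
    "annual_logs": {c: c for c in ANNUAL_LOG_COLUMNS},
    "phenotypes": {c: c for c in PHENOTYPE_COLUMNS},
    "baselines": {"subject_id": "subject_id"},
    "class_map": {"medication": "medication", "medication_class": "medication_class"},
}

_REQUIRED = {
    "med_logs": ["subject_id", "day", "medication"],
    "annual_logs": ANNUAL_LOG_COLUMNS,
    "phenotypes": PHENOTYPE_COLUMNS,
    "baselines": ["subject_id"],
}


def _read_table(path: Path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        # sniff: tab wins if present in the header line
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    return pd.read_csv(
        path, sep=delimiter, dtype={"subject_id": str}, float_precision="round_trip"
    )


def _coerce_numeric(df: pd.DataFrame, cols: Mapping[str, str]) -> tuple[pd.DataFrame, int]:
    """Coerce day/value columns; drop rows whose required numerics fail to parse."""
    df = df.copy()
    n0 = len(df)
    for col, kind in cols.items():
        if col not in df.columns:
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if kind == "required":
            df = df.loc[df[col].notna()]
    return df, n0 - len(df)


def load_dataset(
    paths: Mapping[str, str | Path],
    schema_config: Mapping[str, Mapping[str, str]] | None = None,
    delimiter: str | None = None,
) -> TrialDataset:
    """Read and validate a delimited-text trial extract.

    Parameters
    ----------
    paths
        Mapping with keys ``med_logs``, ``annual_logs``, ``phenotypes``,
        ``baselines`` and optionally ``class_map``, each a CSV/TSV path.
    schema_config
        Per-table mapping of logical field name -> column name in the
        file; omitted fields default to the logical name itself.
    delimiter
        Field delimiter; auto-detected per file when ``None``.

    Raises
    ------
    TrialDataError
        On a missing file, missing required column, duplicate record
        key, or unknown compliance code.  Rows with unparseable numeric
        fields are dropped with a logged count rather than raised.
    """
    schema = {t: dict(DEFAULT_SCHEMA[t]) for t in DEFAULT_SCHEMA}
    if schema_config:
        for t, mapping in schema_config.items():
            schema.setdefault(t, {}).update(mapping)

    tables: dict[str, pd.DataFrame] = {}
    reports: list[LoadReport] = []
    for name in ("med_logs", "annual_logs", "phenotypes", "baselines"):
        if name not in paths:
            raise TrialDataError(f"missing input table: {name}")
        path = Path(paths[name])
        if not path.exists():
            raise TrialDataError(f"input file not found: {path}")
        raw = _read_table(path, delimiter)
        rename = {v: k for k, v in schema[name].items() if v in raw.columns}
        df = raw.rename(columns=rename)
        missing = [c for c in _REQUIRED[name] if c not in df.columns]
        if missing:
            raise TrialDataError(f"{name}: missing required column(s) {missing} in {path}")
        n_read = len(df)
        if name == "med_logs":
            for c in ("compliance", "insulin_units_per_day"):
                if c not in df.columns:
                    df[c] = float("nan")
            df, n_drop = _coerce_numeric(
                df,
                {"day": "required", "compliance": "optional", "insulin_units_per_day": "optional"},
            )
            df["compliance"] = df["compliance"].astype("Float64")
            df = df[MED_LOG_COLUMNS]
        elif name == "annual_logs":
            df, n_drop = _coerce_numeric(df, {"day": "required"})
            df["on_flag"] = df["on_flag"].astype(str).str.lower().isin(
                {"1", "true", "t", "yes", "y", "1.0"}
            )
            df = df[ANNUAL_LOG_COLUMNS]
        elif name == "phenotypes":
            df, n_drop = _coerce_numeric(df, {"day": "required", "value": "required"})
            df = df[PHENOTYPE_COLUMNS]
        else:
            n_drop = 0
        if "day" in df.columns:
            df["day"] = df["day"].astype(int)
        tables[name] = df.reset_index(drop=True)
        reports.append(LoadReport(name, n_read, n_drop))

    class_map: dict[str, str] = {}
    if "class_map" in paths and paths["class_map"] is not None:
        path = Path(paths["class_map"])
        if not path.exists():
            raise TrialDataError(f"input file not found: {path}")
        cm = _read_table(path, delimiter)
        rename = {v: k for k, v in schema["class_map"].items() if v in cm.columns}
        cm = cm.rename(columns=rename)
        class_map = dict(zip(cm["medication"], cm["medication_class"]))

    for r in reports:
        logger.info("loaded %s: %d rows read, %d dropped, %d kept", r.table, r.n_read, r.n_dropped, r.n_kept)

    return TrialDataset(
        med_logs=tables["med_logs"],
        annual_logs=tables["annual_logs"],
        phenotypes=tables["phenotypes"],
        baselines=tables["baselines"],
        medication_class_map=class_map,
    )


def write_dataset(ds: TrialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Dump a dataset as canonical TSV tables; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "med_logs": out / "med_logs.tsv",
        "annual_logs": out / "annual_logs.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "baselines": out / "baselines.tsv",
    }
    fmt = "%.17g"  # full float round-trip precision
    ds.med_logs.to_csv(paths["med_logs"], sep="\t", index=False, float_format=fmt)
    ds.annual_logs.to_csv(paths["annual_logs"], sep="\t", index=False, float_format=fmt)
    ds.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False, float_format=fmt)
    ds.baselines.to_csv(paths["baselines"], sep="\t", index=False, float_format=fmt)
    if ds.medication_class_map:
        paths["class_map"] = out / "class_map.tsv"
        pd.DataFrame(
            sorted(ds.medication_class_map.items()), columns=["medication", "medication_class"]
        ).to_csv(paths["class_map"], sep="\t", index=False)
    return paths


def check_record_consistency(ds: TrialDataset, medication: str) -> pd.Series:
    """Flag subjects whose annual and monthly records disagree.

    A subject is flagged (True = inconsistent) when the annual records
    say the medication's class was taken at some annual visit, yet no
    monthly medication-log entry for the medication — or any member of
    its class — exists anywhere for that subject.  The rule is
    one-directional: monthly records without annual ones are fine.
    """
    names = ds.medication_names(medication)
    class_name = ds.medication_class_map.get(medication, medication)
    known = (
        medication in ds.medication_class_map
        or medication in set(ds.medication_class_map.values())
        or (len(ds.med_logs) and (ds.med_logs["medication"] == medication).any())
        or (len(ds.annual_logs) and (ds.annual_logs["medication_class"] == medication).any())
    )
    flags = pd.Series(False, index=pd.Index(ds.subject_ids, name="subject_id"))
    if not known:
        logger.warning("medication %r not found in class map or any log; all flags False", medication)
        return flags
    ann = ds.annual_logs
    ann_on = ann.loc[(ann["medication_class"] == class_name) & ann["on_flag"], "subject_id"]
    monthly = ds.med_logs.loc[ds.med_logs["medication"].isin(names), "subject_id"]
    has_monthly = set(monthly)
    for sid in set(ann_on):
        if sid not in has_monthly and sid in flags.index:
            flags.loc[sid] = True
    return flags
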