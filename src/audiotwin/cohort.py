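"""Twin-cohort container and plain-CSV interchange.

A cohort is a flat list of subjects grouped into zygosity-labelled pairs.
The CSV dialect is one row per subject with columns::

    subject_id, pair_id, zygosity, age, sex,
    thr_L_<freq>, ..., thr_R_<freq>, ..., snr

with one ``thr_*`` column per test frequency in kHz (dot decimal mark) and
empty cells for missing values.  Generated cohorts carry a sidecar YAML with
the full simulation configuration and a sidecar ``*.latent.csv`` holding the
hidden latent factor truth (written/read automatically, never used by any
estimator).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ZYGOSITIES = ("MZ", "DZ", "singleton")


class CohortError(ValueError):
    """Raised for malformed cohorts or cohort files."""


@dataclass
class SubjectRecord:
    """One subject: identifiers, covariates, per-frequency thresholds, SNR."""

    subject_id: str
    pair_id: str
    zygosity: str
    age: float
    sex: str
    thresholds_left: np.ndarray
    thresholds_right: np.ndarray
    snr: float | None = None
    latent_truth: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.thresholds_left = np.asarray(self.thresholds_left, dtype=float)
        self.thresholds_right = np.asarray(self.thresholds_right, dtype=float)

    def equals_observed(self, other: "SubjectRecord") -> bool:
        """Record equality on observed fields only (latent truth ignored)."""
        snr_eq = (
            (self.snr is None and other.snr is None)
            or (self.snr is not None and other.snr is not None and np.isclose(self.snr, other.snr))
        )
        return (
            self.subject_id == other.subject_id
            and self.pair_id == other.pair_id
            and self.zygosity == other.zygosity
            and np.isclose(self.age, other.age)
            and self.sex == other.sex
            and np.allclose(self.thresholds_left, other.thresholds_left)
            and np.allclose(self.thresholds_right, other.thresholds_right)
            and snr_eq
        )


@dataclass
class TwinCohort:
    """A validated collection of :class:`SubjectRecord`."""

    records: list[SubjectRecord]
    freqs: tuple[float, ...]
    config: object | str = "observed"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.freqs = tuple(float(f) for f in self.freqs)
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        seen_ids: set[str] = set()
        pair_counts: dict[str, int] = {}
        pair_zyg: dict[str, str] = {}
        for rec in self.records:
            if rec.subject_id in seen_ids:
                raise CohortError(f"duplicated subject_id {rec.subject_id!r}")
            seen_ids.add(rec.subject_id)
            if rec.zygosity not in ZYGOSITIES:
                raise CohortError(
                    f"subject {rec.subject_id!r}: zygosity {rec.zygosity!r} not in {ZYGOSITIES}"
                )
            pair_counts[rec.pair_id] = pair_counts.get(rec.pair_id, 0) + 1
            prev = pair_zyg.setdefault(rec.pair_id, rec.zygosity)
            if prev != rec.zygosity:
                raise CohortError(f"pair {rec.pair_id!r} has inconsistent zygosity labels")
        for pid, count in pair_counts.items():
            zyg = pair_zyg[pid]
            expected = 1 if zyg == "singleton" else 2
            if count != expected:
                raise CohortError(
                    f"pair {pid!r} ({zyg}) occurs {count} times, expected {expected}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self, zygosity: str | None = None) -> list[tuple[SubjectRecord, SubjectRecord]]:
        """Complete MZ/DZ pairs, optionally restricted to one zygosity."""
        by_pair: dict[str, list[SubjectRecord]] = {}
        for rec in self.records:
            if rec.zygosity == "singleton":
                continue
            if zygosity is not None and rec.zygosity != zygosity:
                continue
            by_pair.setdefault(rec.pair_id, []).append(rec)
        return [tuple(v) for v in by_pair.values() if len(v) == 2]

    def singletons(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.zygosity == "singleton"]

    # -- tabular views -----------------------------------------------------
    def to_frame(self, include_latent: bool = False) -> pd.DataFrame:
        cols: dict[str, list] = {
            "subject_id": [],
            "pair_id": [],
            "zygosity": [],
            "age": [],
            "sex": [],
        }
        for side in ("L", "R"):
            for f in self.freqs:
                cols[f"thr_{side}_{f:g}"] = []
        cols["snr"] = []
        latent_keys: list[str] = []
        if include_latent and self.records and self.records[0].latent_truth:
            latent_keys = sorted(self.records[0].latent_truth)
            for k in latent_keys:
                cols[k] = []
        for rec in self.records:
            cols["subject_id"].append(rec.subject_id)
            cols["pair_id"].append(rec.pair_id)
            cols["zygosity"].append(rec.zygosity)
            cols["age"].append(rec.age)
            cols["sex"].append(rec.sex)
            for i, f in enumerate(self.freqs):
                cols[f"thr_L_{f:g}"].append(rec.thresholds_left[i])
            for i, f in enumerate(self.freqs):
                cols[f"thr_R_{f:g}"].append(rec.thresholds_right[i])
            cols["snr"].append(np.nan if rec.snr is None else rec.snr)
            for k in latent_keys:
                cols[k].append(rec.latent_truth.get(k, np.nan) if rec.latent_truth else np.nan)
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        config: object | str = "observed",
        provenance: str = "",
        latent: pd.DataFrame | None = None,
    ) -> "TwinCohort":
        required = {"subject_id", "pair_id", "zygosity", "age", "sex"}
        missing = required - set(frame.columns)
        if missing:
            raise CohortError(f"missing mandatory columns: {sorted(missing)}")
        lfreqs = sorted(
            float(c[len("thr_L_"):]) for c in frame.columns if c.startswith("thr_L_")
        )
        rfreqs = sorted(
            float(c[len("thr_R_"):]) for c in frame.columns if c.startswith("thr_R_")
        )
        if not lfreqs or lfreqs != rfreqs:
            raise CohortError("threshold columns for left/right ears do not match")
        if len(frame) == 0:
            raise CohortError("no records")
        latent_by_id = {}
        if latent is not None:
            latent_by_id = {
                row["subject_id"]: {k: row[k] for k in latent.columns if k != "subject_id"}
                for _, row in latent.iterrows()
            }
        records = []
        for idx, row in frame.iterrows():
            try:
                snr = row.get("snr", np.nan)
                records.append(
                    SubjectRecord(
                        subject_id=str(row["subject_id"]),
                        pair_id=str(row["pair_id"]),
                        zygosity=str(row["zygosity"]),
                        age=float(row["age"]),
                        sex=str(row["sex"]),
                        thresholds_left=np.array(
                            [row[f"thr_L_{f:g}"] for f in lfreqs], dtype=float
                        ),
                        thresholds_right=np.array(
                            [row[f"thr_R_{f:g}"] for f in lfreqs], dtype=float
                        ),
                        snr=None if pd.isna(snr) else float(snr),
                        latent_truth=latent_by_id.get(str(row["subject_id"])),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise CohortError(f"malformed row at line {idx + 2}: {exc}") from exc
        return cls(records=records, freqs=tuple(lfreqs), config=config, provenance=provenance)


def _latent_path(path: Path) -> Path:
    return path.with_suffix(".latent.csv")


def _config_path(path: Path) -> Path:
    return path.with_suffix(".config.yaml")


def write_cohort(cohort: TwinCohort, path: str | Path, include_latent: bool = True) -> Path:
    """Write a cohort CSV plus optional latent-truth and config sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_frame().to_csv(path, index=False)
    has_latent = any(r.latent_truth for r in cohort.records)
    if include_latent and has_latent:
        latent_cols: dict[str, list] = {"subject_id": []}
        keys = sorted(next(r.latent_truth for r in cohort.records if r.latent_truth))
        for k in keys:
            latent_cols[k] = []
        for rec in cohort.records:
            latent_cols["subject_id"].append(rec.subject_id)
            for k in keys:
                latent_cols[k].append(
                    rec.latent_truth.get(k, np.nan) if rec.latent_truth else np.nan
                )
        pd.DataFrame(latent_cols).to_csv(_latent_path(path), index=False)
    if not isinstance(cohort.config, str) and dataclasses.is_dataclass(cohort.config):
        with open(_config_path(path), "w") as fh:
            yaml.safe_dump(dataclasses.asdict(cohort.config), fh, sort_keys=False)
    return path


def read_cohort(path: str | Path) -> TwinCohort:
    """Read a cohort CSV (and latent-truth sidecar, if present)."""
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such cohort file: {path}")
    if path.stat().st_size == 0:
        raise CohortError("no records")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortError("no records") from exc
    latent = None
    if _latent_path(path).exists():
        latent = pd.read_csv(_latent_path(path))
    provenance = f"read from {path}"
    return TwinCohort.from_frame(frame, config="observed", provenance=provenance, latent=latent)
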