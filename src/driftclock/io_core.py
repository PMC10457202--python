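"""Shared domain types and readers/writers for on-disk artifacts.

The pipeline's universal currency is the *beta matrix*: per-CpG, per-sample
DNA-methylation fractions (β ∈ [0, 1]) with CpGs in rows and samples in
columns, following the GEO series-matrix convention.  Transposed input is a
hard error rather than auto-detected — silent transposition is the classic
methylation-pipeline bug.

On-disk dialects are fixed: beta matrices are tab-separated, sample sheets
and probe annotations comma-separated; the missing-value token is ``NA`` and
the decimal separator is ``.`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "5'UTR"})
BODY_REGIONS = frozenset({"Body", "1stExon", "3'UTR"})
REGION_CLASSES = frozenset({"promoter", "body", "other"})

COHORT_LABELS = frozenset({"identification", "validation", "unassigned"})


class DriftClockError(ValueError):
    """Base error for malformed inputs anywhere in the pipeline."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise DriftClockError(f"duplicate {what}: {dups[:10]}")


@dataclass
class BetaMatrix:
    """Bounded methylation levels per CpG (rows) per sample (columns).

    Parameters
    ----------
    cpg_ids, sample_ids
        Ordered, unique identifiers.
    values
        Array of shape ``(len(cpg_ids), len(sample_ids))``; ``NaN`` marks a
        missing (failed-probe) call, every non-missing value must lie in
        ``[0, 1]``.
    """

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.cpg_ids, "cpg_ids")
        _check_unique(self.sample_ids, "sample_ids")
        expected = (len(self.cpg_ids), len(self.sample_ids))
        if self.values.shape != expected:
            raise DriftClockError(
                f"beta matrix shape {self.values.shape} does not match "
                f"(|cpg_ids|, |sample_ids|) = {expected}; note that CpGs must "
                "be rows and samples columns — transposed input is rejected"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DriftClockError(
                f"beta value out of [0,1] at CpG {self.cpg_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}: {self.values[r, c]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.cpg_ids, name="cpg_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(float))

    def select_cpgs(self, cpg_ids) -> "BetaMatrix":
        """Row-subset in the given order; unknown ids are an error."""
        idx = pd.Index(self.cpg_ids)
        pos = idx.get_indexer(list(cpg_ids))
        if (pos < 0).any():
            missing = [c for c, p in zip(cpg_ids, pos) if p < 0]
            raise DriftClockError(f"unknown CpG ids: {missing[:10]}")
        return BetaMatrix(list(cpg_ids), list(self.sample_ids), self.values[pos])

    def select_samples(self, sample_ids) -> "BetaMatrix":
        idx = pd.Index(self.sample_ids)
        pos = idx.get_indexer(list(sample_ids))
        if (pos < 0).any():
            missing = [s for s, p in zip(sample_ids, pos) if p < 0]
            raise DriftClockError(f"unknown sample ids: {missing[:10]}")
        return BetaMatrix(list(self.cpg_ids), list(sample_ids), self.values[:, pos])


#: Sample-sheet columns with a declared meaning; anything else is kept as-is.
SAMPLE_SHEET_NUMERIC = (
    "days_in_culture", "cumulative_pd", "age", "os_time", "os_event",
    "crs", "icans",
)
SAMPLE_SHEET_STRING = ("sample_id", "donor_id", "condition", "trial", "disease", "cohort")


@dataclass
class SampleSheet:
    """Per-sample covariates: culture time, donor, trial, survival, toxicity.

    Wraps a DataFrame indexed by position with a unique ``sample_id`` column.
    Optional columns may be absent entirely or hold missing values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "sample_id" not in df.columns:
            raise DriftClockError("sample sheet requires a sample_id column")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample_id")
        for col in SAMPLE_SHEET_NUMERIC:
            if col in df.columns:
                try:
                    df[col] = pd.to_numeric(df[col])
                except (ValueError, TypeError) as exc:
                    raise DriftClockError(f"non-numeric value in column {col}: {exc}")
        if "days_in_culture" in df.columns:
            d = df["days_in_culture"]
            if (d.dropna() < 0).any():
                raise DriftClockError("negative days_in_culture")
        if "os_time" in df.columns:
            has_time = df["os_time"].notna()
            if "os_event" not in df.columns:
                if has_time.any():
                    raise DriftClockError("os_time present without os_event column")
            else:
                orphan = has_time & df["os_event"].isna()
                if orphan.any():
                    raise DriftClockError(
                        "os_event missing for samples with os_time: "
                        f"{df.loc[orphan, 'sample_id'].tolist()[:10]}"
                    )
            if (df.loc[has_time, "os_time"] <= 0).any():
                raise DriftClockError("os_time must be > 0")
        if "cohort" in df.columns:
            labels = set(df["cohort"].dropna().astype(str)) - COHORT_LABELS
            if labels:
                raise DriftClockError(f"unknown cohort labels: {sorted(labels)}")
        else:
            df["cohort"] = "unassigned"
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise DriftClockError(f"sample sheet has no column {name!r}")
        return pd.Series(self.data[name].to_numpy(), index=self.sample_ids, name=name)


@dataclass
class ProbeAnnotation:
    """Per-probe metadata: chromosome, SNP MAF, cross-reactivity, region class.

    ``region_class`` uses the fixed vocabulary promoter / body / other, where
    promoter collapses TSS1500, TSS200 and 5'UTR and body collapses Body,
    1stExon and 3'UTR from the array annotation file.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"cpg_id", "chromosome", "snp_maf", "cross_reactive", "region_class"}
        missing = required - set(df.columns)
        if missing:
            raise DriftClockError(f"probe annotation missing columns: {sorted(missing)}")
        df["cpg_id"] = df["cpg_id"].astype(str)
        _check_unique(df["cpg_id"], "cpg_id")
        df["chromosome"] = df["chromosome"].astype(str)
        df["snp_maf"] = pd.to_numeric(df["snp_maf"])
        maf = df["snp_maf"].dropna()
        if ((maf < 0) | (maf > 1)).any():
            raise DriftClockError("snp_maf outside [0,1]")
        if df["cross_reactive"].dtype != bool:
            df["cross_reactive"] = (
                df["cross_reactive"].astype(str).str.lower()
                .map({"true": True, "false": False, "1": True, "0": False})
            )
            if df["cross_reactive"].isna().any():
                raise DriftClockError("cross_reactive must be boolean")
        bad = set(df["region_class"].astype(str)) - REGION_CLASSES
        if bad:
            raise DriftClockError(
                f"region_class outside {sorted(REGION_CLASSES)}: {sorted(bad)}"
            )
        self.data = df.set_index("cpg_id", drop=False)

    @property
    def cpg_ids(self) -> list[str]:
        return self.data["cpg_id"].tolist()


def classify_region(raw_group: str) -> str:
    """Map an array-annotation gene-region group to promoter/body/other."""
    if raw_group in PROMOTER_REGIONS:
        return "promoter"
    if raw_group in BODY_REGIONS:
        return "body"
    return "other"


# ---------------------------------------------------------------------------
# Readers / writers


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a tab-separated beta matrix (first column cpg_id, header = samples).

    Non-numeric non-missing cells and values outside [0, 1] raise
    :class:`DriftClockError` naming the offending CpG.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=[MISSING_TOKEN],
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise DriftClockError(f"{path}: beta matrix needs a cpg_id column plus samples")
    df = df.set_index(df.columns[0])
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise DriftClockError(
                f"{path}: non-numeric beta value {bad.iloc[0]!r} at "
                f"CpG {bad.index[0]!r}, sample {col!r}"
            )
    return BetaMatrix(list(df.index), list(df.columns), df.to_numpy(float))


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    beta.to_frame().to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.17g")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a comma-separated sample sheet; unknown columns are preserved."""
    df = pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=False,
                     dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index=False, na_rep=MISSING_TOKEN, float_format="%.17g")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=False)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    ann.data.to_csv(path, index=False, na_rep=MISSING_TOKEN, float_format="%.17g")
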