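"""Reference-based cell-type deconvolution from methylation profiles.

Estimates the leukocyte-subset composition of a sample by projecting its β
profile at discriminating CpGs onto reference mean profiles of purified cell
types, Houseman-style: constrained least squares with non-negative fractions
summing to one.  In this pipeline it serves as the QC consistency check that
the inferred CD4+/CD8+ ratio declines with culture time, mirroring flow
cytometry.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_core import DriftClockError

_SUM_TOL = 1e-10


@dataclass
class ReferenceProfiles:
    """Mean β per discriminating CpG (rows) per cell type (columns)."""

    cpg_ids: list[str]
    cell_types: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.cell_types = [str(t) for t in self.cell_types]
        self.profiles = np.asarray(self.profiles, dtype=float)
        if len(self.cell_types) < 2:
            raise DriftClockError("reference needs >= 2 cell types")
        if self.profiles.shape != (len(self.cpg_ids), len(self.cell_types)):
            raise DriftClockError("reference profile shape mismatch")
        if not np.isfinite(self.profiles).all():
            raise DriftClockError("reference profiles must be finite")
        if ((self.profiles < 0) | (self.profiles > 1)).any():
            raise DriftClockError("reference profiles outside [0,1]")
        # centered columns detect affine collinearity (e.g. duplicated types)
        centered = self.profiles - self.profiles.mean(axis=0)
        rank = np.linalg.matrix_rank(centered, tol=1e-10)
        if rank < len(self.cell_types) - 1 or np.linalg.matrix_rank(self.profiles) < len(self.cell_types):
            corr = np.corrcoef(self.profiles.T)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise DriftClockError(
                "rank-deficient reference; collinear cell types: "
                f"{self.cell_types[i]!r} and {self.cell_types[j]!r}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceProfiles":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=pd.Index(self.cpg_ids, name="cpg_id"),
                            columns=self.cell_types)


def estimate_fractions(
    sample_beta,
    ref: ReferenceProfiles,
    max_missing: float = 0.10,
) -> tuple[pd.Series, float]:
    """Cell-type fractions minimising ‖sample − ref·f‖₂ with f ≥ 0, Σf = 1.

    ``sample_beta`` is a vector over the reference CpGs (a pandas Series is
    aligned by CpG id; a bare array is taken in reference row order).  Up to
    ``max_missing`` of entries may be missing and are imputed by the
    reference row mean.  Returns (fractions, residual L2 norm).
    """
    if isinstance(sample_beta, pd.Series):
        missing_ids = [c for c in ref.cpg_ids if c not in sample_beta.index]
        if missing_ids:
            raise DriftClockError(f"sample lacks reference CpGs: {missing_ids[:10]}")
        s = sample_beta.reindex(ref.cpg_ids).to_numpy(float)
    else:
        s = np.asarray(sample_beta, dtype=float)
        if s.shape != (len(ref.cpg_ids),):
            raise DriftClockError("sample vector length must match reference CpGs")
    bad = ~np.isfinite(s)
    if bad.all():
        raise DriftClockError("sample β all missing")
    if bad.mean() > max_missing:
        raise DriftClockError(
            f"{bad.sum()}/{bad.size} sample values missing (> {max_missing:.0%})"
        )
    if bad.any():
        s = np.where(bad, ref.profiles.mean(axis=1), s)

    # sum-to-one enforced by an augmented row whose weight grows until the
    # NNLS solution meets the constraint, then exact renormalisation
    ones = np.ones(len(ref.cell_types))
    f = None
    for w in (1e2, 1e4, 1e6, 1e8):
        aug_a = np.vstack([ref.profiles, w * ones])
        aug_b = np.concatenate([s, [w]])
        f, _ = nnls(aug_a, aug_b)
        if abs(f.sum() - 1.0) < _SUM_TOL:
            break
    if f.sum() <= 0:
        raise DriftClockError("deconvolution failed: all-zero solution")
    f = f / f.sum()
    residual = float(np.linalg.norm(s - ref.profiles @ f))
    return pd.Series(f, index=ref.cell_types, name="fraction"), residual


def load_synthetic_reference() -> ReferenceProfiles:
    """Packaged synthetic CD4/CD8 reference (60 discriminating CpGs).

    Synthetic: generated to have CD4/CD8 mean-β contrasts of the size seen
    between sorted T-cell subsets; it is not derived from any measured
    reference dataset.
    """
    path = importlib.resources.files("driftclock") / "data" / "synthetic_cd4_cd8_reference.csv"
    frame = pd.read_csv(str(path), index_col=0)
    return ReferenceProfiles.from_frame(frame)
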