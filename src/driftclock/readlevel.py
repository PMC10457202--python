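"""Per-read bisulfite-amplicon analysis.

Distinguishes stochastic methylation drift from coordinated regulation: if a
targeted writer complex methylated a region, neighbouring CpGs on the same
DNA strand would switch together, whereas drift produces reads whose
methylated/unmethylated sequence looks random at fixed per-CpG means.  The
within-read coherence statistic formalises this: the mean absolute phi
coefficient over CpG pairs, tested against a null built by independently
permuting each CpG column across reads (marginals preserved, within-read
linkage destroyed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .drift_screen import correlate_with_time
from .io_core import BetaMatrix, DriftClockError, MISSING_TOKEN


@dataclass
class ReadSet:
    """Binary per-read × per-CpG calls for one amplicon in one sample.

    ``calls`` holds 1 (methylated), 0 (unmethylated) or NaN (missing) with
    one row per sequenced read; ``cpg_positions`` are 1-based genomic
    coordinates on the reference strand, strictly increasing.
    """

    amplicon_id: str
    cpg_positions: list[int]
    calls: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.cpg_positions = [int(p) for p in self.cpg_positions]
        self.calls = np.atleast_2d(np.asarray(self.calls, dtype=float))
        if self.calls.shape[0] < 1:
            raise DriftClockError("read set needs >= 1 read")
        if self.calls.shape[1] != len(self.cpg_positions):
            raise DriftClockError("calls width must match cpg_positions")
        diffs = np.diff(self.cpg_positions)
        if (diffs <= 0).any():
            raise DriftClockError("cpg_positions must be strictly increasing")
        finite = np.isfinite(self.calls)
        vals = self.calls[finite]
        if not np.isin(vals, (0.0, 1.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0))][0]
            raise DriftClockError(f"calls must be 0/1/missing; found {bad}")
        if (~finite).all(axis=1).any():
            raise DriftClockError("every read needs >= 1 non-missing call")

    @property
    def n_reads(self) -> int:
        return self.calls.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.calls.shape[1]


def read_amplicon_calls(
    path: str | Path, amplicon_id: str | None = None, sample_id: str = ""
) -> ReadSet:
    """Read a per-read call TSV (header = CpG positions, cells 0/1/NA)."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN],
                     keep_default_na=False)
    if df.empty:
        raise DriftClockError(f"{path}: no reads")
    try:
        positions = [int(c) for c in df.columns]
    except ValueError:
        raise DriftClockError(f"{path}: header must be integer CpG positions")
    if amplicon_id is None:
        amplicon_id = Path(path).stem
    return ReadSet(amplicon_id, positions, df.to_numpy(float), sample_id)


def write_amplicon_calls(rs: ReadSet, path: str | Path) -> None:
    df = pd.DataFrame(rs.calls, columns=[str(p) for p in rs.cpg_positions])
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN,
              float_format="%.0f")


def mean_methylation(rs: ReadSet) -> pd.Series:
    """Per-CpG β: methylated calls over non-missing calls."""
    finite = np.isfinite(rs.calls)
    n = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        beta = np.where(finite, rs.calls, 0.0).sum(axis=0) / n
    if (n == 0).any():
        empty = [rs.cpg_positions[i] for i in np.flatnonzero(n == 0)]
        warnings.warn(f"CpGs with zero non-missing calls: {empty}")
        beta = np.where(n == 0, np.nan, beta)
    return pd.Series(beta, index=rs.cpg_positions, name="beta")


def neighbor_time_correlation(
    sample_betas: pd.DataFrame, days
) -> tuple[pd.Series, int]:
    """Per-CpG Pearson r of amplicon β with culture time across samples.

    ``sample_betas`` has CpG positions as rows and samples as columns.
    Returns the per-position r and the position with maximal r (ties go to
    the lowest coordinate); if every CpG is degenerate (all r = 0 or NaN)
    the argmax is flagged with a warning.
    """
    frame = sample_betas.sort_index()
    beta = BetaMatrix(
        [str(p) for p in frame.index], [str(s) for s in frame.columns],
        frame.to_numpy(float),
    )
    r = correlate_with_time(beta, days)
    r.index = frame.index
    filled = r.fillna(-np.inf)
    argmax_pos = int(filled.idxmax())
    if not (filled > 0).any():
        warnings.warn("no CpG positively correlates with time; argmax degenerate")
    return r, argmax_pos


def _phi_from_counts(a, b, c, d):
    """phi of a 2×2 table [[a, b], [c, d]] = (ad−bc)/√ of margin products."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (a * d - b * c) / np.sqrt(denom)
    return np.where(denom > 0, phi, 0.0)


def pairwise_phi(calls: np.ndarray) -> np.ndarray:
    """Pairwise phi matrix over CpG columns, pairwise-complete in reads.

    A CpG that is constant within the complete subset of a pair contributes
    phi = 0 for that pair (degenerate table).
    """
    calls = np.atleast_2d(np.asarray(calls, dtype=float))
    p = calls.shape[1]
    finite = np.isfinite(calls)
    x = np.where(finite, calls, 0.0)
    # pairwise-complete counts via masked cross-products
    n11 = x.T @ x
    n1_ = x.T @ finite.astype(float)          # i methylated, j observed
    n_1 = finite.astype(float).T @ x          # j methylated, i observed
    n = finite.astype(float).T @ finite.astype(float)
    a = n11
    b = n1_ - n11
    c = n_1 - n11
    d = n - n1_ - n_1 + n11
    phi = _phi_from_counts(a, b, c, d)
    np.fill_diagonal(phi, 1.0)
    return phi


def within_read_coherence(
    rs: ReadSet, n_permutations: int = 1000, seed: int = 0
) -> dict:
    """Test whether CpGs switch together within reads.

    Computes all pairwise phi coefficients, summarises them as mean |phi|,
    and compares against a permutation null in which each CpG column is
    permuted independently across reads.  The add-one convention bounds the
    p-value away from zero: p = (1 + #{null ≥ observed}) / (1 + B).
    """
    if rs.n_cpgs < 2:
        raise DriftClockError("coherence needs >= 2 CpGs")
    if rs.n_reads < 20:
        raise DriftClockError("coherence needs >= 20 reads")
    rng = np.random.default_rng(seed)

    phi = pairwise_phi(rs.calls)
    iu = np.triu_indices(rs.n_cpgs, k=1)
    observed = float(np.abs(phi[iu]).mean())

    constant = [
        rs.cpg_positions[j] for j in range(rs.n_cpgs)
        if np.unique(rs.calls[np.isfinite(rs.calls[:, j]), j]).size <= 1
    ]
    if constant:
        warnings.warn(f"CpGs with all-identical calls (phi = 0 convention): {constant}")

    null = np.empty(n_permutations)
    calls = rs.calls
    for b in range(n_permutations):
        perm = np.empty_like(calls)
        for j in range(rs.n_cpgs):
            perm[:, j] = calls[rng.permutation(rs.n_reads), j]
        null[b] = np.abs(pairwise_phi(perm)[iu]).mean()
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)

    pair_table = pd.DataFrame({
        "pos_i": [rs.cpg_positions[i] for i in iu[0]],
        "pos_j": [rs.cpg_positions[j] for j in iu[1]],
        "phi": phi[iu],
    })
    return {"pairwise_phi": pair_table, "mean_abs_phi": observed,
            "p_value": float(p), "null_mean_abs_phi": null}
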