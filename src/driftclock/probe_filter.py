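"""Probe-level exclusion rules applied before any drift analysis.

Array probes are removed when they overlap common SNPs (MAF > 1%), sit on the
X or Y chromosome, or are known cross-reactive.  Because the CD4+/CD8+ ratio
shifts during culture expansion, CpGs that are differentially methylated
between purified CD4+ and CD8+ cells are additionally excluded so that
composition changes are not mistaken for drift.

Each removed CpG is attributed to exactly one rule, in the fixed order
SNP → XY → cross-reactive → composition.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._stats import bh_adjust, two_group_test
from .io_core import (
    BetaMatrix,
    DriftClockError,
    ProbeAnnotation,
    read_beta_matrix,
    read_probe_annotation,
)


@dataclass
class FilterReport:
    n_input: int
    n_removed_snp: int
    n_removed_xy: int
    n_removed_crossreactive: int
    n_removed_composition: int
    n_retained: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def filter_probes(
    beta: BetaMatrix,
    ann: ProbeAnnotation,
    maf_threshold: float = 0.01,
    composition_cpgs=None,
    mode: str = "strict",
) -> tuple[BetaMatrix, FilterReport]:
    """Remove SNP-overlapping, sex-chromosome, cross-reactive and (optionally)
    cell-composition CpGs from a beta matrix.

    ``mode="strict"`` errors on CpGs missing from the annotation;
    ``mode="lenient"`` retains them with a warning.  Row order is preserved.
    """
    if mode not in {"strict", "lenient"}:
        raise DriftClockError(f"unknown mode {mode!r}")
    comp = {str(c) for c in composition_cpgs} if composition_cpgs is not None else set()

    known = set(ann.cpg_ids)
    unannotated = [c for c in beta.cpg_ids if c not in known]
    if unannotated:
        if mode == "strict":
            raise DriftClockError(
                f"{len(unannotated)} CpGs missing from annotation: {unannotated[:10]}"
            )
        warnings.warn(
            f"{len(unannotated)} unannotated CpGs retained (lenient mode)"
        )

    removed: dict[str, list[str]] = {
        "snp": [], "xy": [], "crossreactive": [], "composition": []
    }
    keep: list[str] = []
    adf = ann.data
    for cpg in beta.cpg_ids:
        if cpg not in known:
            keep.append(cpg)
            continue
        row = adf.loc[cpg]
        maf = row["snp_maf"]
        if np.isfinite(maf) and maf > maf_threshold:
            removed["snp"].append(cpg)
        elif str(row["chromosome"]) in {"X", "Y"}:
            removed["xy"].append(cpg)
        elif bool(row["cross_reactive"]):
            removed["crossreactive"].append(cpg)
        elif cpg in comp:
            removed["composition"].append(cpg)
        else:
            keep.append(cpg)

    report = FilterReport(
        n_input=len(beta.cpg_ids),
        n_removed_snp=len(removed["snp"]),
        n_removed_xy=len(removed["xy"]),
        n_removed_crossreactive=len(removed["crossreactive"]),
        n_removed_composition=len(removed["composition"]),
        n_retained=len(keep),
        removed_ids=removed,
    )
    return beta.select_cpgs(keep), report


def composition_dmps(
    beta_ref: BetaMatrix,
    groups,
    delta: float = 0.10,
    alpha: float = 0.05,
    method: str = "moderated",
) -> set[str]:
    """CpGs differentially methylated between two reference cell types.

    Selection is the union rule: |mean difference| > ``delta`` OR BH-adjusted
    two-sided p < ``alpha``.  ``groups`` is a two-level label per sample
    column of ``beta_ref``.
    """
    groups = np.asarray([str(g) for g in groups])
    if groups.size != len(beta_ref.sample_ids):
        raise DriftClockError("groups must align with reference sample columns")
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise DriftClockError(f"need exactly two group levels, got {levels}")
    idx_a = np.flatnonzero(groups == levels[0])
    idx_b = np.flatnonzero(groups == levels[1])
    if idx_a.size < 2 or idx_b.size < 2:
        raise DriftClockError("each cell-type group needs >= 2 samples")
    a = beta_ref.values[:, idx_a]
    b = beta_ref.values[:, idx_b]
    d, _, p = two_group_test(a, b, method=method)
    p_adj = bh_adjust(p)
    hit = (np.abs(d) > delta) | (p_adj < alpha)
    return {beta_ref.cpg_ids[i] for i in np.flatnonzero(hit)}


def load_demo_filter_fixture() -> tuple[BetaMatrix, ProbeAnnotation]:
    """Packaged 10-CpG demonstration fixture: 2 SNP, 1 chrX, 1 cross-reactive,
    6 clean probes, with a matching 2-sample beta matrix."""
    data = importlib.resources.files("driftclock") / "data"
    ann = read_probe_annotation(str(data / "filter_demo_annotation.csv"))
    beta = read_beta_matrix(str(data / "filter_demo_beta.tsv"))
    return beta, ann
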