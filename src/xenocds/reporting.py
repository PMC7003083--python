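"""Per-assembly summary statistics and the fragmentation regression.

One :class:`AssemblyReport` mirrors the per-species bookkeeping a
multi-assembly contamination survey needs: category counts, contaminant
scaffold counts and cumulative span, the headline percentages (with
documented denominators), and the assembly N50.  Proportions are
logit-transformed before regression; the fragmentation effect is
summarized by an OLS fit of logit(uncertain fraction) on log10(N50),
whose slope is expected negative — fragmented assemblies strand foreign
candidates alone on small scaffolds, where synteny cannot adjudicate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .model import FOREIGN_GROUP_NAMES, Stage1, Stage2, XenocdsError
from .synteny_classification import ScaffoldTable
from .taxonomic_assignment import CdsAnnotation
from .validation import contaminant_scaffolds


def compute_n50(lengths: Sequence[int]) -> int:
    """N50: smallest length L with the sum of lengths >= L at least half
    the total."""
    if not lengths:
        raise XenocdsError("compute_n50: empty length list")
    if any(x <= 0 for x in lengths):
        raise XenocdsError("compute_n50: lengths must be positive")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    raise AssertionError("unreachable")


def logit(p: float, adjustment: float = 0.025) -> float:
    """log(p'/(1-p')) with p' squeezed into [adjustment, 1-adjustment].

    The squeeze is the usual remedy for proportions of exactly 0 or 1,
    which have no finite logit.
    """
    if not 0.0 <= p <= 1.0:
        raise XenocdsError(f"logit: p must be in [0,1], got {p}")
    if adjustment >= 0.5 or adjustment < 0.0:
        raise XenocdsError(f"logit: adjustment must be in [0, 0.5), got {adjustment}")
    p_adj = min(max(p, adjustment), 1.0 - adjustment)
    return math.log(p_adj / (1.0 - p_adj))


@dataclass(frozen=True)
class AssemblyReport:
    """Per-assembly counts and percentages.

    Denominators: ``pct_contaminant_of_all`` is over all CDS;
    ``pct_*_of_assigned`` are over CDS with a stage-1 category other than
    orphan/unassigned (the CDS for which a taxonomic assignment was
    possible); ``pct_uncertain_of_foreign`` is over foreign candidates.
    """

    n_cds_total: int
    n_orphan: int
    n_unassigned: int
    n_assigned: int
    n_confident_arthropod: int
    n_other_metazoa: int
    foreign_counts: Dict[str, int]
    n_contaminant_cds: int
    n_hgt_cds: int
    n_uncertain_cds: int
    n_contaminant_scaffolds: int
    contaminant_scaffold_cumulative_bp: Optional[int]
    pct_contaminant_of_all: float
    pct_contaminant_of_assigned: float
    pct_hgt_of_assigned: float
    pct_uncertain_of_foreign: float
    n50_bp: int

    @property
    def n_foreign(self) -> int:
        return sum(self.foreign_counts.values())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else 0.0


def summarize(
    annotations: Sequence[CdsAnnotation],
    table: ScaffoldTable,
    scaffold_lengths: Mapping[str, int],
) -> AssemblyReport:
    """Compute the full per-assembly report after stage 2.

    A contaminant scaffold holds at least two contaminant CDS and no
    resident CDS; cumulative bp is summed over those scaffolds and
    reported as unknown (None, with a warning) when any length is
    missing.
    """
    n_total = len(annotations)
    tally = {s: 0 for s in Stage1}
    foreign_counts = {g: 0 for g in FOREIGN_GROUP_NAMES}
    stage2_tally = {s: 0 for s in Stage2}
    for a in annotations:
        tally[a.stage1] += 1
        stage2_tally[a.stage2] += 1
        if a.stage1 is Stage1.FOREIGN:
            foreign_counts[a.foreign_group] += 1

    n_assigned = n_total - tally[Stage1.ORPHAN] - tally[Stage1.UNASSIGNED]
    contam_scaffolds = contaminant_scaffolds(table, annotations)
    cumulative: Optional[int] = 0
    for sid in contam_scaffolds:
        if sid in scaffold_lengths:
            cumulative += scaffold_lengths[sid]
        else:
            warnings.warn(f"length unknown for contaminant scaffold {sid}")
            cumulative = None
            break

    n_foreign = sum(foreign_counts.values())
    return AssemblyReport(
        n_cds_total=n_total,
        n_orphan=tally[Stage1.ORPHAN],
        n_unassigned=tally[Stage1.UNASSIGNED],
        n_assigned=n_assigned,
        n_confident_arthropod=tally[Stage1.CONFIDENT_ARTHROPOD],
        n_other_metazoa=tally[Stage1.OTHER_METAZOA],
        foreign_counts=foreign_counts,
        n_contaminant_cds=stage2_tally[Stage2.CONTAMINANT_CANDIDATE],
        n_hgt_cds=stage2_tally[Stage2.HGT_CANDIDATE],
        n_uncertain_cds=stage2_tally[Stage2.UNCERTAIN],
        n_contaminant_scaffolds=len(contam_scaffolds),
        contaminant_scaffold_cumulative_bp=cumulative,
        pct_contaminant_of_all=_pct(stage2_tally[Stage2.CONTAMINANT_CANDIDATE], n_total),
        pct_contaminant_of_assigned=_pct(
            stage2_tally[Stage2.CONTAMINANT_CANDIDATE], n_assigned),
        pct_hgt_of_assigned=_pct(stage2_tally[Stage2.HGT_CANDIDATE], n_assigned),
        pct_uncertain_of_foreign=_pct(stage2_tally[Stage2.UNCERTAIN], n_foreign),
        n50_bp=compute_n50(list(scaffold_lengths.values())),
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def n50_uncertain_regression(
    reports: Sequence[AssemblyReport],
    adjustment: float = 0.025,
) -> RegressionResult:
    """OLS of logit(uncertain fraction of foreign candidates) on log10(N50).

    Needs at least three reports with nonzero foreign candidates and
    variation in N50; the two-sided p-value of the slope comes from the
    usual t distribution.
    """
    usable = [r for r in reports if r.n_foreign > 0]
    if len(usable) < 3:
        raise XenocdsError("regression needs >= 3 reports with foreign candidates")
    x = np.array([math.log10(r.n50_bp) for r in usable])
    y = np.array([logit(r.pct_uncertain_of_foreign / 100.0, adjustment)
                  for r in usable])
    if np.ptp(x) == 0:
        raise XenocdsError("regression: zero variance in log10(N50)")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=len(usable),
    )
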