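"""N50, logit, per-assembly summary, and the fragmentation regression."""

import math

import numpy as np
import pytest

from oracles import n50_oracle
from xenocds.model import Stage1, Stage2, Thresholds, XenocdsError
from xenocds.reporting import (AssemblyReport, compute_n50, logit,
                               n50_uncertain_regression, summarize)
from xenocds.synteny_classification import ScaffoldTable
from xenocds.taxonomic_assignment import CdsAnnotation


# ------------------------------------------------------------------ N50 ----

@pytest.mark.parametrize("lengths,expected", [
    ([70, 10, 10, 10], 70),
    ([5, 5, 5, 5], 5),
    ([1], 1),
    ([10, 10, 10, 70], 70),
])
def test_n50_examples(lengths, expected):
    assert compute_n50(lengths) == expected


def test_n50_matches_definition_on_random_lists():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        lengths = rng.integers(1, 10000, size=int(rng.integers(1, 40))).tolist()
        assert compute_n50(lengths) == n50_oracle(lengths)


def test_n50_rejects_bad_input():
    with pytest.raises(XenocdsError):
        compute_n50([])
    with pytest.raises(XenocdsError):
        compute_n50([10, 0])


# ---------------------------------------------------------------- logit ----

def test_logit_symmetry_and_antisymmetry():
    assert logit(0.5) == pytest.approx(0.0, abs=1e-12)
    for p in (0.1, 0.3, 0.42, 0.9):
        assert logit(p) + logit(1 - p) == pytest.approx(0.0, abs=1e-12)


def test_logit_squeeze_at_boundaries():
    assert logit(0.0, adjustment=0.025) == pytest.approx(math.log(0.025 / 0.975))
    assert logit(1.0, adjustment=0.025) == pytest.approx(-math.log(0.025 / 0.975))


def test_logit_rejects_bad_adjustment():
    with pytest.raises(XenocdsError):
        logit(0.5, adjustment=0.5)
    with pytest.raises(XenocdsError):
        logit(1.5)


# -------------------------------------------------------------- summary ----

def _mk_ann(cid, stage1, group=None, stage2=Stage2.NOT_APPLICABLE, scaffolds=()):
    return CdsAnnotation(cid, stage1, foreign_group=group, stage2=stage2,
                         scaffolds=scaffolds)


def _stage2_fixture():
    anns = [
        _mk_ann("a1", Stage1.CONFIDENT_ARTHROPOD, scaffolds=("host1",)),
        _mk_ann("a2", Stage1.CONFIDENT_ARTHROPOD, scaffolds=("host1",)),
        _mk_ann("m1", Stage1.OTHER_METAZOA),
        _mk_ann("o1", Stage1.ORPHAN),
        _mk_ann("u1", Stage1.UNASSIGNED),
        _mk_ann("h1", Stage1.FOREIGN, "eubacteria", Stage2.HGT_CANDIDATE, ("host1",)),
        _mk_ann("c1", Stage1.FOREIGN, "eubacteria", Stage2.CONTAMINANT_CANDIDATE, ("bact1",)),
        _mk_ann("c2", Stage1.FOREIGN, "eubacteria", Stage2.CONTAMINANT_CANDIDATE, ("bact1",)),
        _mk_ann("c3", Stage1.FOREIGN, "fungi", Stage2.CONTAMINANT_CANDIDATE, ("fung1",)),
        _mk_ann("c4", Stage1.FOREIGN, "fungi", Stage2.CONTAMINANT_CANDIDATE, ("fung1",)),
        _mk_ann("x1", Stage1.FOREIGN, "eubacteria", Stage2.UNCERTAIN, ("lone1",)),
    ]
    table = ScaffoldTable()
    for a in anns:
        for s in a.scaffolds:
            table.members.setdefault(s, []).append((a.cds_id, a.stage1))
    lengths = {"host1": 50000, "bact1": 4000, "fung1": 3000, "lone1": 900}
    return anns, table, lengths


def test_summarize_counts_and_denominators():
    anns, table, lengths = _stage2_fixture()
    rep = summarize(anns, table, lengths)
    assert rep.n_cds_total == 11
    assert rep.n_orphan == 1 and rep.n_unassigned == 1
    assert rep.n_assigned == 9
    assert rep.foreign_counts == {"eubacteria": 4, "archaea": 0, "fungi": 2,
                                  "viridiplantae": 0, "protists": 0}
    assert (rep.n_contaminant_cds, rep.n_hgt_cds, rep.n_uncertain_cds) == (4, 1, 1)
    # conservation: categories partition the CDS set
    assert (rep.n_orphan + rep.n_unassigned + rep.n_confident_arthropod
            + rep.n_other_metazoa + rep.n_foreign) == rep.n_cds_total
    assert rep.n_contaminant_cds + rep.n_hgt_cds + rep.n_uncertain_cds == rep.n_foreign
    assert rep.n_contaminant_scaffolds == 2
    assert rep.contaminant_scaffold_cumulative_bp == 7000
    assert rep.pct_contaminant_of_all == pytest.approx(100 * 4 / 11)
    assert rep.pct_contaminant_of_assigned == pytest.approx(100 * 4 / 9)
    assert rep.pct_hgt_of_assigned == pytest.approx(100 * 1 / 9)
    assert rep.pct_uncertain_of_foreign == pytest.approx(100 * 1 / 6)
    assert rep.n50_bp == 50000


def test_summarize_missing_length_warns_and_reports_unknown():
    anns, table, lengths = _stage2_fixture()
    del lengths["bact1"]
    lengths["bact1_replacement"] = 100   # keep N50 computable
    with pytest.warns(UserWarning):
        rep = summarize(anns, table, lengths)
    assert rep.contaminant_scaffold_cumulative_bp is None


def test_summarize_zero_foreign_still_reports():
    anns = [_mk_ann("a1", Stage1.CONFIDENT_ARTHROPOD, scaffolds=("s1",))]
    table = ScaffoldTable()
    table.members["s1"] = [("a1", Stage1.CONFIDENT_ARTHROPOD)]
    rep = summarize(anns, table, {"s1": 1000})
    assert rep.n_contaminant_cds == 0 and rep.n_contaminant_scaffolds == 0
    assert rep.pct_uncertain_of_foreign == 0.0


# ----------------------------------------------------------- regression ----

def _report(n50, pct_uncertain, n_foreign=10):
    return AssemblyReport(
        n_cds_total=100, n_orphan=0, n_unassigned=0, n_assigned=100,
        n_confident_arthropod=90, n_other_metazoa=0,
        foreign_counts={"eubacteria": n_foreign, "archaea": 0, "fungi": 0,
                        "viridiplantae": 0, "protists": 0},
        n_contaminant_cds=0, n_hgt_cds=0,
        n_uncertain_cds=round(n_foreign * pct_uncertain / 100),
        n_contaminant_scaffolds=0, contaminant_scaffold_cumulative_bp=0,
        pct_contaminant_of_all=0.0, pct_contaminant_of_assigned=0.0,
        pct_hgt_of_assigned=0.0, pct_uncertain_of_foreign=pct_uncertain,
        n50_bp=n50)


def test_regression_perfectly_collinear_points():
    # parameters chosen so proportions stay inside the logit squeeze band
    slope, intercept = -0.8, 0.5
    reports = []
    for n50 in (1000, 5000, 10000, 100000):
        y = slope * math.log10(n50) + intercept
        p = 100 / (1 + math.exp(-y))          # invert the logit exactly
        reports.append(_report(n50, p))
    res = n50_uncertain_regression(reports)
    assert res.r_squared == pytest.approx(1.0, abs=1e-9)
    assert res.slope == pytest.approx(slope, abs=1e-6)
    assert res.intercept == pytest.approx(intercept, abs=1e-6)


def test_regression_recovers_known_negative_slope_within_2_se():
    rng = np.random.default_rng(3)
    true_slope, true_intercept, sigma = -0.5, 0.8, 0.25
    reports = []
    for _ in range(40):
        n50 = int(10 ** rng.uniform(3.5, 6.5))
        y = true_slope * math.log10(n50) + true_intercept + rng.normal(0, sigma)
        p = 100 / (1 + math.exp(-y))
        reports.append(_report(n50, p))
    res = n50_uncertain_regression(reports)
    import statsmodels.api as sm
    x = np.array([math.log10(r.n50_bp) for r in reports])
    yv = np.array([logit(r.pct_uncertain_of_foreign / 100) for r in reports])
    se = float(sm.OLS(yv, sm.add_constant(x)).fit().bse[1])
    assert abs(res.slope - true_slope) < 2 * se
    assert res.slope < 0 and res.p_value < 0.05


def test_regression_preconditions():
    with pytest.raises(XenocdsError):
        n50_uncertain_regression([_report(1000, 10.0)] * 2)
    with pytest.raises(XenocdsError):
        n50_uncertain_regression([_report(1000, 10.0)] * 5)   # zero x variance
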