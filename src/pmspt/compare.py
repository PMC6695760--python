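"""Condition comparison: per-condition summaries and pairwise Welch tests.

Welch's unequal-variance t-test is used for all pairwise comparisons (group
variances routinely differ between treatment arms); with more than two
conditions the pairwise p-values are Holm-corrected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import RefusalError


@dataclass
class ConditionSummary:
    label: str
    mean: float
    sd: float
    n: int


@dataclass
class PairwiseTest:
    label_a: str
    label_b: str
    difference: float
    t_stat: float
    p_value: float
    p_holm: float


@dataclass
class ConditionComparison:
    summaries: list[ConditionSummary]
    tests: list[PairwiseTest]
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "summaries": [vars(s) for s in self.summaries],
            "tests": [vars(t) for t in self.tests],
            "note": self.note,
        }


def compare_conditions(values_by_label: dict) -> ConditionComparison:
    """Mean +/- SD per condition and Welch pairwise tests (Holm-corrected).

    Conditions with a single replicate get a summary but no test (refusing
    to test is explicit in the note). Identical samples give p = 1.
    """
    summaries = []
    clean: dict[str, np.ndarray] = {}
    for label, values in values_by_label.items():
        v = np.asarray(list(values), dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            raise RefusalError(f"condition {label!r} has no finite values")
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        summaries.append(ConditionSummary(str(label), float(v.mean()), sd, len(v)))
        clean[str(label)] = v

    testable = [s.label for s in summaries if s.n >= 2]
    skipped = [s.label for s in summaries if s.n < 2]
    tests: list[PairwiseTest] = []
    raw_p = []
    for a, b in itertools.combinations(testable, 2):
        va, vb = clean[a], clean[b]
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        if math.isnan(p):
            # both samples constant: equal means -> no evidence of difference
            p = 1.0 if math.isclose(va.mean(), vb.mean()) else 0.0
            t = 0.0 if p == 1.0 else math.inf
        tests.append(PairwiseTest(a, b, float(va.mean() - vb.mean()),
                                  float(t), float(p), float(p)))
        raw_p.append(float(p))
    if len(raw_p) > 1:
        _, p_holm, _, _ = multipletests(raw_p, method="holm")
        for test, ph in zip(tests, p_holm):
            test.p_holm = float(ph)
    note = ""
    if skipped:
        note = ("no test for single-replicate condition(s): "
                + ", ".join(skipped))
    return ConditionComparison(summaries, tests, note)
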