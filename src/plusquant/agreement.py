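"""Inter-rater and intra-rater agreement for binary Plus/non-Plus grading.

Cohen's kappa corrects raw percent agreement for chance: with the 2x2
contingency (a: both Plus, b: first-only Plus, c: second-only Plus, d: both
non-Plus) and n = a+b+c+d,

    p_o = (a + d) / n
    p_e = ((a+b)(a+c) + (c+d)(b+d)) / n^2
    kappa = (p_o - p_e) / (1 - p_e)

Absolute agreement is 100 * p_o.  When a rater is constant (p_e = 1), kappa
is undefined and reported as missing rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core_io import PLUS, RaterLabelTable, logger, reference_standard
from .classify import classification_metrics


@dataclass(frozen=True)
class AgreementResult:
    kappa: float | None  # chance-corrected agreement in [-1, 1]; None if undefined
    absolute_agreement: float  # percent in [0, 100]
    n: int
    contingency: tuple[int, int, int, int]  # (a, b, c, d)
    first: str = ""
    second: str = ""

    def to_dict(self) -> dict:
        a, b, c, d = self.contingency
        return {
            "first": self.first,
            "second": self.second,
            "kappa": self.kappa,
            "absolute_agreement_pct": self.absolute_agreement,
            "n": self.n,
            "contingency": {"a_both_plus": a, "b_first_only": b, "c_second_only": c, "d_both_nonplus": d},
        }


def kappa_from_contingency(
    a: int, b: int, c: int, d: int, first: str = "", second: str = ""
) -> AgreementResult:
    """Cohen's kappa and absolute agreement from 2x2 contingency counts."""
    n = a + b + c + d
    if n < 2:
        raise ValueError("agreement needs >= 2 paired labels")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e >= 1.0:
        logger.warning("degenerate contingency (constant rater); kappa undefined")
        kappa = None
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return AgreementResult(
        kappa=kappa,
        absolute_agreement=100.0 * p_o,
        n=n,
        contingency=(a, b, c, d),
        first=first,
        second=second,
    )


def cohens_kappa(
    labels_a: pd.Series | np.ndarray,
    labels_b: pd.Series | np.ndarray,
    first: str = "",
    second: str = "",
) -> AgreementResult:
    """Cohen's kappa between two binary label vectors paired by image id.

    Series inputs are aligned on their index (unpaired ids are an error);
    array inputs must have equal length and be in corresponding order.
    """
    if isinstance(labels_a, pd.Series) and isinstance(labels_b, pd.Series):
        if set(labels_a.index) != set(labels_b.index):
            unpaired = set(labels_a.index) ^ set(labels_b.index)
            raise ValueError(f"unpaired image ids: {sorted(unpaired)}")
        labels_b = labels_b.reindex(labels_a.index)
    va, vb = np.asarray(labels_a), np.asarray(labels_b)
    if len(va) != len(vb):
        raise ValueError(f"label vectors differ in length: {len(va)} vs {len(vb)}")
    if len(va) < 2:
        raise ValueError("agreement needs >= 2 paired labels")
    pa, pb = va == PLUS, vb == PLUS
    a = int((pa & pb).sum())
    b = int((pa & ~pb).sum())
    c = int((~pa & pb).sum())
    d = int((~pa & ~pb).sum())
    return kappa_from_contingency(a, b, c, d, first=first, second=second)


def pairwise_agreement(table: RaterLabelTable, session_id: object) -> list[AgreementResult]:
    """One agreement result per unordered rater pair in a session."""
    raters = table.raters(session_id)
    if len(raters) < 2:
        raise ValueError(f"session {session_id!r} needs >= 2 raters")
    results = []
    for r1, r2 in combinations(raters, 2):
        results.append(
            cohens_kappa(
                table.label_vector(r1, session_id),
                table.label_vector(r2, session_id),
                first=str(r1),
                second=str(r2),
            )
        )
    return results


def intra_rater_agreement(
    table: RaterLabelTable, session_1: object, session_2: object
) -> list[AgreementResult]:
    """Per-rater agreement between the rater's two labeling sessions."""
    raters = sorted(set(table.raters(session_1)) & set(table.raters(session_2)))
    if not raters:
        raise ValueError("no rater labeled both sessions")
    return [
        cohens_kappa(
            table.label_vector(r, session_1),
            table.label_vector(r, session_2),
            first=str(r),
            second=str(r),
        )
        for r in raters
    ]


def rater_vs_reference(
    table: RaterLabelTable, session_id: object
) -> list[tuple[AgreementResult, dict]]:
    """Each rater against the majority-vote reference standard.

    Returns, per rater, the agreement result plus classification metrics
    (sensitivity, specificity, PPV, NPV) treating Plus as positive and the
    reference as truth.
    """
    reference = reference_standard(table, session_id)
    out = []
    for r in table.raters(session_id):
        res = cohens_kappa(
            table.label_vector(r, session_id), reference, first=str(r), second="reference"
        )
        a, b, c, d = res.contingency
        metrics = classification_metrics(tp=a, fn=c, fp=b, tn=d)
        out.append((res, metrics))
    return out


def agreement_summary(results: list[AgreementResult]) -> dict[str, float]:
    """Mean and sample SD of the absolute agreements of a block of results."""
    vals = np.array([r.absolute_agreement for r in results], dtype=float)
    return {
        "mean_agreement_pct": float(vals.mean()),
        "sd_agreement_pct": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    }
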