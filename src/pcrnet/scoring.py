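"""Mean causal/effect association scores and cause-vs-effect comparisons.

A symptom's *mean causal association* (C) is the average of the present PCR
ratings it receives as the cause ("How much do your problems with X CAUSE your
problems with Y?") across all rated partners; its *mean effect association*
(E) averages the ratings where it occupies the effect slot.  Per symptom, the
across-participant paired contrast of C against E (t, df, p, Cohen's d,
Pearson r between C and E) says whether the symptom is perceived more as a
cause or as an outcome of the other problems present; family-wise error over
the 40 contrasts is controlled with the Holm-Bonferroni step-down procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import SymptomCatalog
from .records import ParticipantRecord


def _present_mean(values: list[int]) -> float | None:
    return float(np.mean(values)) if values else None


def mean_causal_association(
    record: ParticipantRecord,
    symptom: int,
    catalog: SymptomCatalog,
    scope: str | Iterable[int] | None = None,
) -> float | None:
    """Average present PCR with ``symptom`` as cause, partners within scope."""
    partners = set(catalog.resolve(scope)) - {symptom}
    catalog.item(symptom)  # raises on unknown id
    values = [
        v
        for (c, e), v in record.pcr_present().items()
        if c == symptom and e in partners
    ]
    return _present_mean(values)


def mean_effect_association(
    record: ParticipantRecord,
    symptom: int,
    catalog: SymptomCatalog,
    scope: str | Iterable[int] | None = None,
) -> float | None:
    """Average present PCR with ``symptom`` as effect, partners within scope."""
    partners = set(catalog.resolve(scope)) - {symptom}
    catalog.item(symptom)
    values = [
        v
        for (c, e), v in record.pcr_present().items()
        if e == symptom and c in partners
    ]
    return _present_mean(values)


def pcr_subset_score(
    record: ParticipantRecord,
    cause_scope: str | Iterable[int],
    effect_scope: str | Iterable[int],
    catalog: SymptomCatalog,
) -> float | None:
    """Within-participant mean of present PCR from one item set to another.

    This is the composite behind quantities like PCR_ANX->DEP: the average of
    every answered causal-association question whose cause lies in the first
    scope and whose effect lies in the second.
    """
    causes = set(catalog.resolve(cause_scope))
    effects = set(catalog.resolve(effect_scope))
    values = [
        v
        for (c, e), v in record.pcr_present().items()
        if c in causes and e in effects
    ]
    return _present_mean(values)


def cohens_d_from_t(t: float, df: int) -> float:
    """Paired-comparison effect size from a t statistic: d = |t| / sqrt(df + 1).

    With df = n - 1 this is |t| / sqrt(n), the mean paired difference in units
    of its SD.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    return abs(t) / math.sqrt(df + 1)


@dataclass
class CauseEffectSummary:
    """Per-symptom cause-vs-effect contrast across participants."""

    symptom_id: int
    mean_causal: float | None  # C, averaged over contributing participants
    mean_effect: float | None  # E
    sd_causal: float | None
    sd_effect: float | None
    n_cause: int  # participants with a defined C
    n_effect: int  # participants with a defined E
    r_ec: float | None  # Pearson r between per-participant C and E
    t_ec: float | None  # paired t on (C - E)
    df_ec: int | None
    p_ec: float | None
    d_ec: float | None
    defined: bool  # False when < 2 participants contribute both C and E
    significant: bool | None = None  # set by the Holm correction across symptoms


def cause_effect_comparison(
    records: Sequence[ParticipantRecord],
    symptom: int,
    catalog: SymptomCatalog,
    scope: str | Iterable[int] | None = None,
) -> CauseEffectSummary:
    """Paired t test of mean causal vs mean effect association for one symptom.

    Available-case: a participant contributes to the contrast only when both
    C and E are defined for them.  Zero variance of (C - E) yields an
    undefined-result marker rather than an infinite t.
    """
    c_all, e_all, paired = [], [], []
    for record in records:
        c = mean_causal_association(record, symptom, catalog, scope)
        e = mean_effect_association(record, symptom, catalog, scope)
        if c is not None:
            c_all.append(c)
        if e is not None:
            e_all.append(e)
        if c is not None and e is not None:
            paired.append((c, e))

    summary = CauseEffectSummary(
        symptom_id=symptom,
        mean_causal=_present_mean(c_all),
        mean_effect=_present_mean(e_all),
        sd_causal=float(np.std(c_all, ddof=1)) if len(c_all) > 1 else None,
        sd_effect=float(np.std(e_all, ddof=1)) if len(e_all) > 1 else None,
        n_cause=len(c_all),
        n_effect=len(e_all),
        r_ec=None,
        t_ec=None,
        df_ec=None,
        p_ec=None,
        d_ec=None,
        defined=False,
    )
    if len(paired) < 2:
        return summary

    c_arr = np.array([p[0] for p in paired])
    e_arr = np.array([p[1] for p in paired])
    diff = c_arr - e_arr
    n = len(diff)
    summary.df_ec = n - 1
    if np.std(c_arr) > 0 and np.std(e_arr) > 0:
        summary.r_ec = float(stats.pearsonr(c_arr, e_arr).statistic)
    if np.std(diff, ddof=1) == 0:
        if np.allclose(diff, 0):  # C == E everywhere: t = 0, p = 1
            summary.t_ec, summary.p_ec, summary.d_ec = 0.0, 1.0, 0.0
            summary.defined = True
        return summary
    t_res = stats.ttest_rel(c_arr, e_arr)
    summary.t_ec = float(t_res.statistic)
    summary.p_ec = float(t_res.pvalue)
    summary.d_ec = cohens_d_from_t(summary.t_ec, summary.df_ec)
    summary.defined = True
    return summary


@dataclass
class HolmResult:
    """Step-down multiple-comparison decisions for one p-value family."""

    reject: list[bool]
    alpha: float
    bonferroni_threshold: float  # plain alpha / m
    obtained_threshold: float | None  # largest p actually rejected by Holm

    @property
    def n_rejected(self) -> int:
        return sum(self.reject)


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Holm-Bonferroni (sequential Bonferroni) step-down correction.

    Also reports the plain Bonferroni threshold alpha/m and the largest
    p-value the step-down procedure rejected (the "obtained threshold").
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    rejected_ps = p[reject]
    return HolmResult(
        reject=[bool(r) for r in reject],
        alpha=alpha,
        bonferroni_threshold=alpha / p.size,
        obtained_threshold=float(rejected_ps.max()) if rejected_ps.size else None,
    )


def cause_effect_table(
    records: Sequence[ParticipantRecord],
    catalog: SymptomCatalog,
    alpha: float = 0.05,
    decimals: int = 2,
) -> pd.DataFrame:
    """Instrument-wide descriptive table: frequency M/SD, C, E, and contrasts.

    One row per item with the paired cause-vs-effect test, Holm-corrected
    significance over the family of defined contrasts, and d reported only for
    significant contrasts (full precision kept in the ``*_raw`` columns).
    """
    rows = []
    for item in catalog.items:
        freqs = [
            r.frequencies[item.id]
            for r in records
            if isinstance(r.frequencies[item.id], int)
        ]
        s = cause_effect_comparison(records, item.id, catalog)
        rows.append(
            {
                "symptom_id": item.id,
                "abbreviation": item.abbreviation,
                "category": item.category,
                "freq_mean": np.mean(freqs) if freqs else np.nan,
                "freq_sd": np.std(freqs, ddof=1) if len(freqs) > 1 else np.nan,
                "C_mean": s.mean_causal,
                "C_sd": s.sd_causal,
                "E_mean": s.mean_effect,
                "E_sd": s.sd_effect,
                "r_EC": s.r_ec,
                "t_EC": s.t_ec,
                "df_EC": s.df_ec,
                "p_EC": s.p_ec,
                "d_EC_raw": s.d_ec,
                "defined": s.defined,
            }
        )
    table = pd.DataFrame(rows).set_index("symptom_id")

    defined = table["defined"] & table["p_EC"].notna()
    table["significant"] = False
    if defined.any():
        holm = holm_bonferroni(table.loc[defined, "p_EC"].tolist(), alpha=alpha)
        table.loc[defined, "significant"] = holm.reject
    # d is reported only where the corrected contrast is significant
    table["d_EC"] = np.where(table["significant"], table["d_EC_raw"], np.nan)
    for col in ("freq_mean", "freq_sd", "C_mean", "C_sd", "E_mean", "E_sd",
                "r_EC", "t_EC", "p_EC", "d_EC"):
        table[col] = pd.to_numeric(table[col]).round(decimals)
    return table
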