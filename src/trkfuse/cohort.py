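"""Cohort statistics over transcribed clinical tables and simulated cohorts.

The packaged fixtures transcribe the source study's printed tables: the
full-cohort marginals (overall / fusion-positive / fusion-negative counts
per tumor type, MSI status, age group, gender, stage, and fibrosarcoma
subtype), the per-fusion table of the 40 fusion-positive patients (41
fusions; one patient carries two), and the 13-patient DNA / RNA / IHC
concordance table. Every printed prevalence, enrichment, and concordance
statistic is recomputed from these fixtures; nothing is hard-coded.

Statistical conventions: Fisher's exact test (two-sided, sum of
probabilities <= the observed table's) for 2x2 associations with a
chi-square fallback on request; Wilcoxon rank-sum with midranks for
continuous group comparisons; percentages and medians rounded half-up to
one decimal; 'Unknown' levels excluded pairwise from tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up

__all__ = [
    "CohortTable",
    "AssociationResult",
    "GroupComparison",
    "load_table1",
    "load_table2",
    "load_table3",
    "prevalence",
    "fusion_pattern_summary",
    "association_test",
    "association_test_counts",
    "group_compare_continuous",
    "concordance_summary",
    "msih_enrichment",
    "cooccurrence_counts",
]

STRATIFIERS = ("tumor_type", "subtype", "age_group", "msi", "gender", "stage", "total")


@dataclass(frozen=True)
class CohortTable:
    """Per-patient records plus (optionally) aggregate negative marginals."""

    patients: pd.DataFrame
    negative_marginals: Optional[pd.DataFrame] = None

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def _fixture(name: str):
    return files("trkfuse.data") / name


def load_table1(path=None) -> pd.DataFrame:
    """Cohort marginals: variable, level, overall, positive, negative."""
    df = pd.read_csv(str(path or _fixture("table1_marginals.tsv")), sep="\t")
    bad = df[df.overall != df.positive + df.negative]
    if len(bad):
        raise ValueError(f"marginals do not reconcile: {bad.level.tolist()}")
    return df


def load_table2(path=None) -> pd.DataFrame:
    """Per-fusion records of the fusion-positive patients (41 rows)."""
    return pd.read_csv(str(path or _fixture("table2_patients.tsv")), sep="\t")


def load_table3(path=None) -> pd.DataFrame:
    """DNA / RNA / IHC concordance records (13 rows)."""
    return pd.read_csv(str(path or _fixture("table3_concordance.tsv")), sep="\t")


# ---------------------------------------------------------------------------
# prevalence and pattern accounting
# ---------------------------------------------------------------------------


def prevalence(stratify_by: str = "tumor_type", table1: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Fusion prevalence per stratum: (stratum, n_positive, n_total, percent).

    Percentages are 100 * positive / total, rounded half-up to one decimal;
    strata with zero totals are omitted.
    """
    if stratify_by not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratify_by!r}; choose from {STRATIFIERS}")
    t1 = table1 if table1 is not None else load_table1()
    sub = t1[(t1.variable == stratify_by) & (t1.overall > 0)]
    out = pd.DataFrame(
        {
            "stratum": sub.level.to_numpy(),
            "n_positive": sub.positive.to_numpy(),
            "n_total": sub.overall.to_numpy(),
        }
    )
    out["percent"] = [
        round_half_up(100.0 * p / t, 1) for p, t in zip(out.n_positive, out.n_total)
    ]
    return out.reset_index(drop=True)


def fusion_pattern_summary(table2: Optional[pd.DataFrame] = None) -> dict:
    """Partner diversity, novelty, and rearrangement-type accounting.

    Per-fusion statistics use the 41-fusion denominator, per-patient
    statistics the 40-patient one (one patient carries two fusions).
    """
    t2 = table2 if table2 is not None else load_table2()
    n_fusions = len(t2)
    n_patients = t2.case.nunique()
    per_gene = {}
    for gene, grp in t2.groupby("ntrk_gene"):
        intra = int((grp.fusion_type == "intrachromosomal").sum())
        inter = int((grp.fusion_type == "interchromosomal").sum())
        per_gene[gene] = {
            "n_fusions": len(grp),
            "n_partners": grp.partner.nunique(),
            "intrachromosomal": intra,
            "interchromosomal": inter,
            "intrachromosomal_pct": round_half_up(100.0 * intra / len(grp), 1),
            "interchromosomal_pct": round_half_up(100.0 * inter / len(grp), 1),
        }
    n_novel = int((t2.novelty == "Novel").sum())
    return {
        "n_patients": n_patients,
        "n_fusions": n_fusions,
        "n_definite": int((t2.classification == "Definite").sum()),
        "n_likely": int((t2.classification == "Likely").sum()),
        "unique_partners": int(t2.partner.nunique()),
        "n_novel": n_novel,
        "novel_pct_per_fusion": round_half_up(100.0 * n_novel / n_fusions, 1),
        "per_gene": per_gene,
    }


# ---------------------------------------------------------------------------
# association and group tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    table: np.ndarray
    odds_ratio: Optional[float]
    p_value: float
    method: str


def association_test_counts(table, method: str = "fisher") -> AssociationResult:
    """Exact (or chi-square, on request) test on a prebuilt contingency table.

    For 2x2 tables the default is Fisher's exact test, two-sided by summing
    hypergeometric probabilities <= the observed table's; larger tables use
    chi-square. A degenerate margin (all-zero row or column) leaves the odds
    ratio undefined.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.min() < 0:
        raise ValueError("negative cell counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin: all-zero row or column")
    if method == "fisher":
        if tab.shape != (2, 2):
            raise ValueError("Fisher test implemented for 2x2 tables")
        odds, p = stats.fisher_exact(tab, alternative="two-sided")
        return AssociationResult(tab, float(odds) if np.isfinite(odds) else None, float(p), "fisher")
    if method == "chi2":
        res = stats.chi2_contingency(tab, correction=False)
        odds = None
        if tab.shape == (2, 2) and tab[0, 1] * tab[1, 0] > 0:
            odds = float(tab[0, 0] * tab[1, 1] / (tab[0, 1] * tab[1, 0]))
        return AssociationResult(tab, odds, float(res.pvalue), "chi2")
    raise ValueError(f"unknown method {method!r}")


def association_test(
    exposure: Sequence, outcome: Sequence, method: str = "fisher"
) -> AssociationResult:
    """Build an r x c table from two categorical vectors and test it.

    Observations with an 'Unknown' level in either variable are excluded
    pairwise before tabulation.
    """
    df = pd.DataFrame({"exposure": list(exposure), "outcome": list(outcome)})
    df = df[(df.exposure != "Unknown") & (df.outcome != "Unknown")]
    tab = pd.crosstab(df.exposure, df.outcome)
    return association_test_counts(tab.to_numpy(), method=method)


@dataclass(frozen=True)
class GroupComparison:
    median_a: float
    range_a: tuple[float, float]
    median_b: float
    range_b: tuple[float, float]
    p_value: float


def group_compare_continuous(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Medians, ranges, and a two-sided Wilcoxon rank-sum p (midrank ties)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one observation")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        median_a=round_half_up(float(np.median(a)), 1),
        range_a=(float(a.min()), float(a.max())),
        median_b=round_half_up(float(np.median(b)), 1),
        range_b=(float(b.min()), float(b.max())),
        p_value=float(res.pvalue),
    )


def msih_enrichment(table1: Optional[pd.DataFrame] = None) -> dict:
    """Fusion rate in MSI-H vs MSS patients with the exact enrichment test.

    'Unknown' MSI patients are excluded pairwise. The 2x2 table rows are
    MSI-H / MSS, columns fusion-positive / fusion-negative.
    """
    t1 = table1 if table1 is not None else load_table1()
    msi = t1[t1.variable == "msi"].set_index("level")
    table = np.array(
        [
            [msi.loc["MSI-H", "positive"], msi.loc["MSI-H", "negative"]],
            [msi.loc["MSS", "positive"], msi.loc["MSS", "negative"]],
        ]
    )
    res = association_test_counts(table, method="fisher")
    n_pos = int(t1.loc[t1.variable == "total", "positive"].iloc[0])
    return {
        "msih_fusion_rate_pct": round_half_up(100.0 * table[0, 0] / table[0].sum(), 1),
        "mss_fusion_rate_pct": round_half_up(100.0 * table[1, 0] / table[1].sum(), 2),
        "msih_among_positives_pct": round_half_up(100.0 * table[0, 0] / n_pos, 1),
        "odds_ratio": res.odds_ratio,
        "p_value": res.p_value,
        "table": table,
    }


# ---------------------------------------------------------------------------
# concordance and co-occurrence
# ---------------------------------------------------------------------------


def concordance_summary(table3: Optional[pd.DataFrame] = None) -> dict:
    """Per-assay detection counts among DNA-fusion-positive patients.

    'NotEvaluated' entries are excluded from that assay's denominator; an
    assay with denominator zero is reported as not assessable (None rate).
    """
    t3 = table3 if table3 is not None else load_table3()
    out = {}
    for assay, col in (("dna_seq", "dna_seq"), ("rna_seq", "rna_seq"), ("ihc", "ihc")):
        vals = t3[col]
        evaluated = vals[vals != "NotEvaluated"]
        pos = int((evaluated == "Positive").sum())
        n = int(len(evaluated))
        out[assay] = {
            "n_positive": pos,
            "n_evaluated": n,
            "percent": round_half_up(100.0 * pos / n, 1) if n else None,
        }
    return out


def cooccurrence_counts(patients: pd.DataFrame, flag_columns: Sequence[str]) -> pd.DataFrame:
    """Pairwise co-occurrence counts over boolean per-patient flags."""
    cols = list(flag_columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            both = int((patients[a] & patients[b]).sum())
            rows.append({"flag_a": a, "flag_b": b, "n_both": both})
    return pd.DataFrame(rows)
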