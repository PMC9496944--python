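"""Single-gene response association, recurrent-mutation exclusivity,
gene-pair features, and survival tests.

Gene selection follows the two-condition rule used throughout the analysis:
a gene is response-associated when the Fisher exact p-value of its
per-sample mutated/wild-type 2x2 table against response is below ``alpha``
and the fold change between mutation frequencies in responders and
non-responders exceeds ``fc_min``.  Fold change is two-sided
(max/min of the two frequencies), so enrichment in either group qualifies.

The Fisher test is computed by exact integer enumeration of the
hypergeometric support (table counts via ``math.comb``), which implements
the textbook two-sided definition — sum the probabilities of all tables
with fixed margins whose probability does not exceed the observed table's —
without floating-point tie ambiguity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .burden import DEFAULT_NONSYNONYMOUS_CLASSES, classify_nonsynonymous
from .exceptions import ConvergenceError, ParameterError, ValidationError
from .io_formats import CohortDataset

__all__ = [
    "fisher_exact_2x2",
    "select_response_genes",
    "recurrent_mutation_exclusivity",
    "gene_pair_indicator",
    "logrank_test",
    "cox_ph",
    "SurvivalTestResult",
]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Margins are held fixed; the p-value sums hypergeometric probabilities of
    every table at least as extreme (probability <= observed).  Comparisons
    are done on exact integer table counts C(r1, x) * C(r2, c1 - x).
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ParameterError(f"cell counts must be non-negative integers, got {v}")
    if a + b + c + d == 0:
        raise ParameterError("all four cells are zero; the test is undefined")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    counts = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    observed = counts[a - lo]
    total = sum(counts)
    tail = sum(k for k in counts if k <= observed)
    return tail / total


# ---------------------------------------------------------------------------
# response-associated gene selection
# ---------------------------------------------------------------------------


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, never used to select)."""
    return stats.false_discovery_control(p, method="bh")


def _mutated_samples_per_gene(
    cohort: CohortDataset, classes: frozenset[str]
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for m in cohort.mutations:
        if classify_nonsynonymous(m.consequence, classes):
            out.setdefault(m.gene, set()).add(m.sample_id)
    return out


def select_response_genes(
    cohort: CohortDataset,
    classes: frozenset[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Per-gene Fisher test and fold change of mutation frequency R vs NR.

    Each sample counts once per gene regardless of how many records it has.
    With ``pseudocount`` a Haldane +0.5 correction on all four cells replaces
    the +inf fold-change convention (useful for ranking).  Returns one row
    per mutated gene with the selection flag ``selected``.
    """
    response = cohort.response_series()
    r_ids = set(response.index[response == "R"])
    nr_ids = set(response.index[response == "NR"])
    n_r, n_nr = len(r_ids), len(nr_ids)
    if n_r == 0 or n_nr == 0:
        raise ValidationError(
            f"cohort {cohort.name}: needs at least one R and one NR sample"
        )
    rows = []
    for gene, carriers in sorted(_mutated_samples_per_gene(cohort, classes).items()):
        a = len(carriers & r_ids)       # mutated R
        b = n_r - a                     # wild-type R
        c = len(carriers & nr_ids)      # mutated NR
        d = n_nr - c                    # wild-type NR
        p = fisher_exact_2x2(a, b, c, d)
        freq_r, freq_nr = a / n_r, c / n_nr
        if pseudocount:
            fr = (a + 0.5) / (n_r + 1.0)
            fnr = (c + 0.5) / (n_nr + 1.0)
            fold = max(fr, fnr) / min(fr, fnr)
        elif freq_r == 0.0 and freq_nr == 0.0:
            fold = 1.0
        elif min(freq_r, freq_nr) == 0.0:
            fold = math.inf
        else:
            fold = max(freq_r, freq_nr) / min(freq_r, freq_nr)
        rows.append(
            {
                "gene": gene,
                "n_mut_R": a,
                "n_R": n_r,
                "n_mut_NR": c,
                "n_NR": n_nr,
                "freq_R": freq_r,
                "freq_NR": freq_nr,
                "fold_change": fold,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_mut_R", "n_R", "n_mut_NR", "n_NR",
            "freq_R", "freq_NR", "fold_change", "p_value",
        ],
    )
    if len(df):
        df["q_value"] = _bh_adjust(df["p_value"].to_numpy())
        df["selected"] = (df["p_value"] < alpha) & (df["fold_change"] > fc_min)
    else:
        df["q_value"] = pd.Series(dtype=float)
        df["selected"] = pd.Series(dtype=bool)
    return df


def recurrent_mutation_exclusivity(
    cohort: CohortDataset,
    classes: frozenset[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
    min_recurrence: int = 2,
) -> pd.DataFrame:
    """Classify recurrent protein changes as R-only, NR-only, or shared.

    Identical (gene, protein_change) events are grouped across samples (one
    count per carrying sample); groups with total recurrence below
    ``min_recurrence`` are dropped.  Records without a protein change are
    skipped (count reported in a warning).
    """
    response = cohort.response_series()
    carriers: dict[tuple[str, str], set[str]] = {}
    skipped = 0
    for m in cohort.mutations:
        if not classify_nonsynonymous(m.consequence, classes):
            continue
        if not m.protein_change:
            skipped += 1
            continue
        carriers.setdefault((m.gene, m.protein_change), set()).add(m.sample_id)
    if skipped:
        warnings.warn(
            f"cohort {cohort.name}: {skipped} nonsynonymous records without "
            "protein_change were skipped",
            stacklevel=2,
        )
    rows = []
    for (gene, pc), samples in sorted(carriers.items()):
        n_r = sum(1 for s in samples if response[s] == "R")
        n_nr = len(samples) - n_r
        if n_r + n_nr < min_recurrence:
            continue
        cls = "shared" if (n_r and n_nr) else ("R-only" if n_r else "NR-only")
        rows.append(
            {"gene": gene, "protein_change": pc, "n_R": n_r, "n_NR": n_nr, "class": cls}
        )
    return pd.DataFrame(
        rows, columns=["gene", "protein_change", "n_R", "n_NR", "class"]
    )


def gene_pair_indicator(
    cohort: CohortDataset,
    gene_a: str,
    gene_b: str,
    classes: frozenset[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
) -> pd.Series:
    """Per-sample 0/1: carries a nonsynonymous mutation in gene_a OR gene_b."""
    carriers: set[str] = set()
    for m in cohort.mutations:
        if m.gene in (gene_a, gene_b) and classify_nonsynonymous(m.consequence, classes):
            carriers.add(m.sample_id)
    return pd.Series(
        [1 if s in carriers else 0 for s in cohort.sample_ids],
        index=cohort.sample_ids,
        name=f"{gene_a}|{gene_b}",
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalTestResult:
    statistic: float
    p_value: float
    n_group1: int
    n_group2: int
    hazard_ratio: float | None = None
    hr_ci_lower: float | None = None
    hr_ci_upper: float | None = None


def logrank_test(times, events, group) -> SurvivalTestResult:
    """Two-group log-rank test, chi-square with 1 df.

    ``group`` is a binary vector (0/1).  The statistic is
    ``(sum(O1 - E1))^2 / sum(V)`` over distinct event times, with the usual
    hypergeometric variance at each time.  If no events are observed at all,
    p = 1 is returned with a warning.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group, dtype=int)
    if not (len(t) == len(e) == len(g)):
        raise ParameterError("times, events, group must have equal length")
    n1 = int((g == 1).sum())
    n0 = int((g == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ParameterError("both groups must be nonempty")
    if e.sum() == 0:
        warnings.warn("no observed events; log-rank p set to 1", stacklevel=2)
        return SurvivalTestResult(0.0, 1.0, n0, n1)
    o_minus_e = 0.0
    var = 0.0
    for tau in np.unique(t[e == 1]):
        at_risk = t >= tau
        n = at_risk.sum()
        n1_risk = (at_risk & (g == 1)).sum()
        d = ((t == tau) & (e == 1)).sum()
        d1 = ((t == tau) & (e == 1) & (g == 1)).sum()
        o_minus_e += d1 - d * n1_risk / n
        if n > 1:
            var += d * (n1_risk / n) * (1 - n1_risk / n) * (n - d) / (n - 1)
    if var == 0.0:
        warnings.warn("zero log-rank variance; p set to 1", stacklevel=2)
        return SurvivalTestResult(0.0, 1.0, n0, n1)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return SurvivalTestResult(float(chi2), max(p, np.finfo(float).tiny), n0, n1)


def cox_ph(times, events, covariates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    ``covariates`` is an n x p DataFrame (e.g. gene-pair indicator, age,
    sex).  Returns one row per covariate with ``coef``, ``hazard_ratio``,
    Wald ``ci_lower``/``ci_upper`` at 1 - alpha, and ``p_value``.  Fitting
    is delegated to lifelines' partial-likelihood maximizer.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as LLConvergenceError

    X = pd.DataFrame(covariates).reset_index(drop=True)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ParameterError(f"constant covariates: {constant}")
    n_events = int(np.asarray(events).sum())
    if n_events < X.shape[1]:
        warnings.warn(
            f"only {n_events} events for {X.shape[1]} covariates; "
            "estimates may be unstable",
            stacklevel=2,
        )
    df = X.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    fitter = CoxPHFitter(alpha=alpha)
    try:
        fitter.fit(df, duration_col="_time", event_col="_event")
    except LLConvergenceError as err:
        raise ConvergenceError(f"Cox fit did not converge: {err}") from err
    summary = fitter.summary
    z = stats.norm.ppf(1 - alpha / 2)
    coef = summary["coef"].to_numpy()
    se = summary["se(coef)"].to_numpy()
    return pd.DataFrame(
        {
            "covariate": list(summary.index),
            "coef": coef,
            "hazard_ratio": np.exp(coef),
            "ci_lower": np.exp(coef - z * se),
            "ci_upper": np.exp(coef + z * se),
            "p_value": summary["p"].to_numpy(),
        }
    )
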