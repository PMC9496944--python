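"""Per-sample pathway enrichment of mutated genes and PP/NP selection.

The per-cohort mutation-frequency matrix ``M`` (samples x mutated genes)
feeds a GSVA-style single-sample enrichment score: each gene's values are
turned into cross-sample cumulative scores through a kernel CDF, genes are
ranked within each sample, and a weighted Kolmogorov-Smirnov random walk
over the ranked list yields one enrichment score (ES) per pathway per
sample.  Scores of responders and non-responders are then compared with a
Mann-Whitney U test per cohort, and pathways consistently enriched in
responders (non-responders) across at least ``min_datasets`` cohorts become
positive (negative) pathways, whose gene unions drive the P-TMB.

Zero-inflated mutation matrices produce massive rank ties; ties are broken
by a single seeded gene shuffle fixed per call, so results are reproducible
and unbiased on average.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .burden import DEFAULT_NONSYNONYMOUS_CLASSES, classify_nonsynonymous
from .exceptions import ConfigurationError, ParameterError, ValidationError
from .io_formats import CohortDataset, PathwayCollection

__all__ = [
    "build_mutation_frequency_matrix",
    "gsva_scores",
    "mann_whitney_u",
    "test_pathway_response",
    "select_pathways",
    "PathwaySelection",
]


def build_mutation_frequency_matrix(
    cohort: CohortDataset,
    classes: frozenset[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
    lengths: pd.Series | None = None,
    mode: str = "per_mb",
) -> pd.DataFrame:
    """Samples x genes matrix of per-sample gene mutation burden.

    Only genes with a nonsynonymous mutation in at least one sample form
    columns.  ``mode``: ``per_mb`` = count / coding_length_bp * 1e6 (needs
    ``lengths``), ``count`` = raw count, ``binary`` = indicator.
    """
    if mode not in ("per_mb", "count", "binary"):
        raise ParameterError(f"unknown matrix mode {mode!r}")
    counts: dict[str, dict[str, int]] = {}
    for m in cohort.mutations:
        if classify_nonsynonymous(m.consequence, classes):
            counts.setdefault(m.gene, {}).setdefault(m.sample_id, 0)
            counts[m.gene][m.sample_id] += 1
    genes = sorted(counts)
    samples = cohort.sample_ids
    X = np.zeros((len(samples), len(genes)))
    sidx = {s: i for i, s in enumerate(samples)}
    for j, g in enumerate(genes):
        for s, k in counts[g].items():
            X[sidx[s], j] = k
    if mode == "per_mb":
        if lengths is None:
            raise ParameterError("per_mb mode requires a gene-length table")
        missing = [g for g in genes if g not in lengths.index]
        if missing:
            raise ConfigurationError(
                f"genes without a coding length: {missing[:10]}"
            )
        X = X / lengths.loc[genes].to_numpy(dtype=float) * 1e6
    elif mode == "binary":
        X = (X > 0).astype(float)
    return pd.DataFrame(X, index=samples, columns=genes)


# ---------------------------------------------------------------------------
# GSVA-style enrichment
# ---------------------------------------------------------------------------


def _kernel_cdf(X: np.ndarray, kcdf: str) -> np.ndarray:
    """Cross-sample cumulative score per gene (column-wise), m x n -> m x n."""
    m, n = X.shape
    Z = np.empty_like(X, dtype=float)
    fallback = 0
    for j in range(n):
        v = X[:, j]
        if kcdf == "ecdf":
            Z[:, j] = stats.rankdata(v, method="max") / m
        elif kcdf == "gaussian":
            h = v.std(ddof=1) / 4.0
            if h == 0.0 or not np.isfinite(h):
                fallback += 1
                Z[:, j] = stats.rankdata(v, method="max") / m
            else:
                Z[:, j] = stats.norm.cdf((v[:, None] - v[None, :]) / h).mean(axis=1)
        elif kcdf == "poisson":
            Z[:, j] = stats.poisson.cdf(v[:, None], v[None, :] + 0.5).mean(axis=1)
        else:
            raise ParameterError(f"unknown kcdf {kcdf!r}")
    if fallback:
        warnings.warn(
            f"{fallback} constant gene rows fell back from gaussian to ecdf",
            stacklevel=3,
        )
    return Z


def gsva_scores(
    M: pd.DataFrame,
    pathways: PathwayCollection,
    kcdf: str = "ecdf",
    tau: float = 1.0,
    es_mode: str = "mx_diff",
    seed: int = 0,
) -> pd.DataFrame:
    """GSVA-style enrichment score per pathway per sample.

    ``M`` is samples x genes.  Per sample, genes are ranked by decreasing
    kernel-CDF score (ties broken by a seeded shuffle fixed for the call);
    the centered rank statistic ``r = |n/2 - rank|`` weights a
    Kolmogorov-Smirnov random walk with gene-set increments
    ``r**tau / sum_set(r**tau)`` and uniform decrements ``1/(n - |set|)``.
    ``es_mode='mx_diff'`` returns max positive + min negative deviation;
    ``'two_sided_max'`` the single largest-magnitude deviation.

    Returns pathways x samples; empty intersections with the matrix genes
    are dropped with a warning; a set covering all matrix genes is an error.
    """
    if es_mode not in ("mx_diff", "two_sided_max"):
        raise ParameterError(f"unknown es_mode {es_mode!r}")
    m, n = M.shape
    if m < 3:
        raise ValidationError(f"need >= 3 samples for enrichment scoring, got {m}")
    gene_index = {g: j for j, g in enumerate(M.columns)}
    memberships: dict[str, np.ndarray] = {}
    dropped = []
    for name, genes in pathways.items():
        idx = np.array(sorted(gene_index[g] for g in genes if g in gene_index), dtype=int)
        if idx.size == 0:
            dropped.append(name)
        elif idx.size == n:
            raise ConfigurationError(
                f"pathway {name!r} covers every matrix gene; the decrement "
                "pool is empty"
            )
        else:
            memberships[name] = idx
    if dropped:
        warnings.warn(
            f"{len(dropped)} pathways share no genes with the matrix and are "
            f"dropped: {dropped[:5]}",
            stacklevel=2,
        )
    if not memberships:
        raise ConfigurationError("no pathway overlaps the matrix genes")

    Z = _kernel_cdf(M.to_numpy(dtype=float), kcdf)
    rng = np.random.default_rng(seed)
    shuffle = rng.permutation(n)  # fixed tie-break order for the whole call

    names = list(memberships)
    B = np.zeros((len(names), n), dtype=bool)
    for i, name in enumerate(names):
        B[i, memberships[name]] = True
    set_sizes = B.sum(axis=1)
    dec = 1.0 / (n - set_sizes)  # per-pathway uniform decrement

    ES = np.empty((len(names), m))
    half = n / 2.0
    for s in range(m):
        z = Z[s]
        # order genes by decreasing z, ties by the seeded shuffle
        order = np.lexsort((shuffle, -z))
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        r = np.abs(half - ranks) ** tau
        r_ord = r[order]
        Bo = B[:, order]
        inc_mass = (Bo * r_ord).sum(axis=1)  # sum of weights inside each set
        # a single-gene set landing exactly at rank n/2 (even n) has zero
        # weight mass; its increments are then zero rather than 0/0
        inc_mass = np.where(inc_mass > 0, inc_mass, 1.0)
        steps = np.where(Bo, r_ord / inc_mass[:, None], -dec[:, None])
        walk = np.cumsum(steps, axis=1)
        if es_mode == "mx_diff":
            ES[:, s] = np.maximum(walk.max(axis=1), 0.0) + np.minimum(
                walk.min(axis=1), 0.0
            )
        else:
            mx, mn = walk.max(axis=1), walk.min(axis=1)
            ES[:, s] = np.where(mx >= -mn, mx, mn)
    return pd.DataFrame(ES, index=names, columns=M.index)


# ---------------------------------------------------------------------------
# response testing and pathway selection
# ---------------------------------------------------------------------------


def mann_whitney_u(x, y, exact_max: int = 8) -> tuple[float, float]:
    """Mann-Whitney U (statistic for ``x``) and two-sided p-value.

    Exact full enumeration of group assignments when both group sizes are
    <= ``exact_max`` (extremeness measured by distance of U from its null
    mean, which handles ties exactly); otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ParameterError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    if n1 <= exact_max and n2 <= exact_max:
        dist = abs(u - mu)
        hits = 0
        total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u_p = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u_p - mu) >= dist - 1e-9:
                hits += 1
        return float(u), hits / total
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(stats.norm.sf(max(z, 0.0))))
    return float(u), p


def test_pathway_response(E: pd.DataFrame, response: pd.Series) -> pd.DataFrame:
    """Mann-Whitney U of enrichment scores, responders vs non-responders.

    ``E`` is pathways x samples; ``response`` maps sample -> R/NR.  Returns
    one row per pathway with ``u``, ``p_value`` and ``direction`` =
    sign(median_R - median_NR).
    """
    response = response.loc[E.columns]
    r_cols = response.index[response == "R"]
    nr_cols = response.index[response == "NR"]
    if len(r_cols) == 0 or len(nr_cols) == 0:
        raise ValidationError("both response groups must be nonempty")
    rows = []
    for pw in E.index:
        xr = E.loc[pw, r_cols].to_numpy(dtype=float)
        xnr = E.loc[pw, nr_cols].to_numpy(dtype=float)
        u, p = mann_whitney_u(xr, xnr)
        rows.append(
            {
                "pathway": pw,
                "u": u,
                "p_value": p,
                "direction": int(np.sign(np.median(xr) - np.median(xnr))),
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "u", "p_value", "direction"])


# the name looks like a pytest test when imported into a test module
test_pathway_response.__test__ = False  # type: ignore[attr-defined]


@dataclass
class PathwaySelection:
    """PP/NP labels per pathway plus the derived gene unions."""

    table: pd.DataFrame  # pathway, n_cohorts_positive, n_cohorts_negative, label
    pp_pathways: list[str]
    np_pathways: list[str]
    pp_genes: set[str] = field(default_factory=set)
    np_genes: set[str] = field(default_factory=set)


def select_pathways(
    tests_by_cohort: Mapping[str, pd.DataFrame],
    pathways: PathwayCollection,
    alpha: float = 0.05,
    min_datasets: int = 4,
) -> PathwaySelection:
    """Label pathways PP/NP from per-cohort Mann-Whitney tables.

    PP: p < alpha with responder-higher direction in >= ``min_datasets``
    cohorts; NP analogous.  A pathway qualifying as both is excluded with a
    warning.  Gene unions over the PP (NP) pathways give ``pp_genes``
    (``np_genes``).
    """
    if len(tests_by_cohort) < min_datasets:
        raise ValidationError(
            f"need >= {min_datasets} cohorts, got {len(tests_by_cohort)}"
        )
    pos: dict[str, int] = {}
    neg: dict[str, int] = {}
    seen: list[str] = []
    for table in tests_by_cohort.values():
        for row in table.itertuples(index=False):
            if row.pathway not in pos:
                pos[row.pathway] = neg[row.pathway] = 0
                seen.append(row.pathway)
            if row.p_value < alpha and row.direction > 0:
                pos[row.pathway] += 1
            elif row.p_value < alpha and row.direction < 0:
                neg[row.pathway] += 1
    rows = []
    pp_names, np_names = [], []
    for pw in seen:
        is_pp = pos[pw] >= min_datasets
        is_np = neg[pw] >= min_datasets
        if is_pp and is_np:
            warnings.warn(
                f"pathway {pw!r} qualifies as both PP and NP; excluded",
                stacklevel=2,
            )
            label = "none"
        elif is_pp:
            label = "PP"
            pp_names.append(pw)
        elif is_np:
            label = "NP"
            np_names.append(pw)
        else:
            label = "none"
        rows.append(
            {
                "pathway": pw,
                "n_cohorts_positive": pos[pw],
                "n_cohorts_negative": neg[pw],
                "label": label,
            }
        )
    table = pd.DataFrame(
        rows, columns=["pathway", "n_cohorts_positive", "n_cohorts_negative", "label"]
    )
    pp_genes: set[str] = set()
    for pw in pp_names:
        pp_genes |= pathways[pw]
    np_genes: set[str] = set()
    for pw in np_names:
        np_genes |= pathways[pw]
    return PathwaySelection(table, pp_names, np_names, pp_genes, np_genes)
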