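"""Nonsynonymous classification, TMB, and the pathway-derived TMB (P-TMB).

TMB is the count of nonsynonymous somatic mutations per megabase of coding
sequence.  P-TMB restricts the burden to two curated gene sets — genes of
response-positive pathways (PP) and response-negative pathways (NP) — and
contrasts them:

    P-TMB = (sum_{g in PP} P_g / sum_{g in PP} L_g
             - sum_{g in NP} N_g / sum_{g in NP} L_g) * 1e6

where ``P_g``/``N_g`` are per-gene nonsynonymous mutation counts in the
sample and ``L_g`` coding lengths in bp.  Both denominators run over *all*
genes of the set, mutated or not, so the score is a difference of two
per-Mb mutation rates and is linear (additive) in the mutation list.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ConfigurationError, ParameterError
from .io_formats import CohortDataset, MutationRecord

__all__ = [
    "DEFAULT_NONSYNONYMOUS_CLASSES",
    "normalize_consequence",
    "classify_nonsynonymous",
    "compute_tmb",
    "compute_ptmb",
    "compute_burden_table",
    "BurdenResult",
]

# The ten consequence classes counted as nonsynonymous (normalized form).
DEFAULT_NONSYNONYMOUS_CLASSES = frozenset(
    {
        "missense mutation",
        "inframe insertion",
        "inframe deletion",
        "frameshift insertion",
        "frameshift deletion",
        "start lost",
        "stop gained",
        "stop lost",
        "splice acceptor variant",
        "splice donor variant",
    }
)

# Synonyms from the VEP consequence ontology and TCGA-MAF Variant_Classification
# vocabularies, mapped onto the canonical class names above (normalized form).
_SYNONYMS = {
    "missense variant": "missense mutation",
    "inframe ins": "inframe insertion",
    "inframe del": "inframe deletion",
    "in frame ins": "inframe insertion",
    "in frame del": "inframe deletion",
    "frame shift ins": "frameshift insertion",
    "frame shift del": "frameshift deletion",
    "nonsense mutation": "stop gained",
    "nonstop mutation": "stop lost",
    "translation start site": "start lost",
    # MAF's Splice_Site does not distinguish acceptor from donor; both are
    # counted, so mapping to either canonical name preserves the decision.
    "splice site": "splice acceptor variant",
}

_WS = re.compile(r"[\s_-]+")


def normalize_consequence(consequence: str) -> str:
    """Lower-case and unify separators; resolve known synonyms."""
    key = _WS.sub(" ", consequence.strip().lower())
    return _SYNONYMS.get(key, key)


def classify_nonsynonymous(
    consequence: str,
    classes: frozenset[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
) -> bool:
    """True if the (possibly compound, ``&``-joined) consequence is counted.

    Matching is case- and separator-insensitive; unknown terms are simply
    not counted.
    """
    return any(
        normalize_consequence(part) in classes
        for part in consequence.split("&")
    )


def _nonsyn_count(
    mutations: Iterable[MutationRecord], classes: frozenset[str]
) -> int:
    return sum(1 for m in mutations if classify_nonsynonymous(m.consequence, classes))


def compute_tmb(
    mutations: Sequence[MutationRecord],
    classes: frozenset[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
    denominator_mb: float = 30.0,
) -> float:
    """Nonsynonymous mutations per megabase for one sample's mutation list."""
    if not denominator_mb > 0:
        raise ParameterError(f"denominator_mb must be > 0, got {denominator_mb}")
    return _nonsyn_count(mutations, classes) / denominator_mb


def _set_length(genes: frozenset[str] | set[str], lengths: pd.Series, label: str) -> int:
    missing = sorted(g for g in genes if g not in lengths.index)
    if missing:
        raise ConfigurationError(
            f"{label} genes missing from the length table: {missing[:10]}"
        )
    return int(lengths.loc[sorted(genes)].sum())


def compute_ptmb(
    mutations: Sequence[MutationRecord],
    pp_genes: Iterable[str],
    np_genes: Iterable[str],
    lengths: pd.Series,
    classes: frozenset[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
    allow_empty_np: bool = False,
    allow_empty_pp: bool = False,
) -> float:
    """Pathway-derived TMB for one sample.

    ``lengths`` must cover every member of both sets; the denominators are
    the summed coding lengths of the full sets, independent of which genes
    happen to be mutated.  Genes in both sets are counted on both sides
    (with a warning).  An empty set is an error unless the corresponding
    ``allow_empty_*`` flag zeroes that term explicitly.
    """
    pp = set(pp_genes)
    np_ = set(np_genes)
    if not pp and not allow_empty_pp:
        raise ConfigurationError("empty PP gene set (pass allow_empty_pp to zero it)")
    if not np_ and not allow_empty_np:
        raise ConfigurationError("empty NP gene set (pass allow_empty_np to zero it)")
    overlap = pp & np_
    if overlap:
        warnings.warn(
            f"{len(overlap)} genes in both PP and NP are counted on both "
            f"sides: {sorted(overlap)[:5]}",
            stacklevel=2,
        )

    def term(genes: set[str], label: str) -> float:
        if not genes:
            return 0.0
        total_bp = _set_length(genes, lengths, label)
        count = sum(
            1
            for m in mutations
            if m.gene in genes and classify_nonsynonymous(m.consequence, classes)
        )
        return count / total_bp

    score = (term(pp, "PP") - term(np_, "NP")) * 1e6
    if not math.isfinite(score):
        raise ConfigurationError("non-finite P-TMB")
    return score


@dataclass(frozen=True)
class BurdenResult:
    """Per-sample burden summary."""

    sample_id: str
    n_nonsyn: int
    tmb: float
    ptmb: float


def compute_burden_table(
    cohort: CohortDataset,
    pp_genes: Iterable[str],
    np_genes: Iterable[str],
    lengths: pd.Series,
    classes: frozenset[str] = DEFAULT_NONSYNONYMOUS_CLASSES,
    denominator_mb: float = 30.0,
    allow_empty_np: bool = False,
    allow_empty_pp: bool = False,
) -> pd.DataFrame:
    """TMB and P-TMB for every sample of a cohort.

    Returns a DataFrame with columns sample_id, n_nonsyn, tmb, ptmb, in the
    clinical table's sample order.
    """
    pp = set(pp_genes)
    np_ = set(np_genes)
    by_sample = cohort.mutations_by_sample()
    rows = []
    with warnings.catch_warnings():
        # the overlap warning is per-cohort, not per-sample
        if pp & np_:
            warnings.warn(
                f"cohort {cohort.name}: {len(pp & np_)} genes in both PP and NP",
                stacklevel=2,
            )
        warnings.simplefilter("ignore")
        for sid in cohort.sample_ids:
            muts = by_sample[sid]
            rows.append(
                BurdenResult(
                    sample_id=sid,
                    n_nonsyn=_nonsyn_count(muts, classes),
                    tmb=compute_tmb(muts, classes, denominator_mb),
                    ptmb=compute_ptmb(
                        muts, pp, np_, lengths, classes,
                        allow_empty_np=allow_empty_np,
                        allow_empty_pp=allow_empty_pp,
                    ),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
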