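"""Multi-cohort synthetic ICB datasets with planted pathway effects.

The generator emulates the statistical structure the analysis assumes:
several independent cohorts of tumor samples with R/NR response labels,
per-gene nonsynonymous mutation counts that are Poisson in the gene's
coding length and a per-Mb rate, a lognormal per-sample rate multiplier
(real per-patient mutation burdens span orders of magnitude), planted
"positive" pathways whose genes mutate faster in responders (and,
optionally, "negative" pathways faster in non-responders), and censored
exponential survival with a reduced hazard for carriers of a designated
gene pair.  A manifest records every planted truth so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import (
    ClinicalRecord,
    CohortDataset,
    MutationRecord,
    PathwayCollection,
    write_clinical,
    write_gene_lengths,
    write_gmt,
    write_mutations,
)

__all__ = ["SimulationConfig", "SimulationResult", "simulate_cohorts",
           "simulate_survival", "write_fixture_bundle"]

# consequence classes drawn for nonsynonymous records, missense-heavy as in
# real exomes
_NONSYN_CLASSES = [
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
    "frameshift_insertion",
    "frameshift_deletion",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "splice_acceptor_variant",
    "splice_donor_variant",
]
_NONSYN_WEIGHTS = np.array(
    [0.60, 0.02, 0.04, 0.03, 0.06, 0.01, 0.14, 0.01, 0.04, 0.05]
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic multi-cohort generator.

    Rates are nonsynonymous mutations per megabase per sample; effects are
    multiplicative (>= 1) and apply to planted-pathway genes in the
    corresponding response group.  Survival times are in months.
    """

    n_cohorts: int = 6
    n_samples: int = 60
    response_rate: float = 0.5
    n_genes: int = 2000
    gene_length_median_bp: float = 1500.0
    gene_length_sigma: float = 0.8
    n_pathways: int = 60
    genes_per_pathway: int = 25
    planted_pp_pathways: int = 10
    planted_np_pathways: int = 0
    background_rate: float = 15.0
    pp_effect: float = 3.0
    np_effect: float = 1.0
    sample_rate_sigma: float = 0.8
    overdispersion: float | None = None  # negative-binomial 1/size; None = Poisson
    synonymous_fraction: float = 0.3
    hotspot_fraction: float = 0.25
    baseline_hazard: float = 0.05
    survival_hazard_ratio: float = 0.5
    censoring_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts < 1 or self.n_samples < 2 or self.n_genes < 2:
            raise ValidationError("n_cohorts, n_samples, n_genes too small")
        if not 0.0 < self.response_rate < 1.0:
            raise ValidationError("response_rate must be in (0, 1)")
        planted = self.planted_pp_pathways + self.planted_np_pathways
        if planted > self.n_pathways:
            raise ValidationError("planted pathway counts exceed n_pathways")
        if planted * self.genes_per_pathway > self.n_genes:
            raise ValidationError("planted pathways need more genes than exist")
        for name in ("background_rate", "gene_length_median_bp", "baseline_hazard",
                     "censoring_rate", "survival_hazard_ratio"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.pp_effect < 1.0 or self.np_effect < 1.0:
            raise ValidationError("effect multipliers must be >= 1")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValidationError("overdispersion must be > 0 when set")


@dataclass
class SimulationResult:
    cohorts: list[CohortDataset]
    lengths: pd.Series
    pathways: PathwayCollection
    manifest: dict = field(default_factory=dict)


def _draw_counts(rng: np.random.Generator, lam: np.ndarray,
                 overdispersion: float | None) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(lam)
    # gamma-Poisson mixture: shape k = 1/overdispersion, mean preserved
    k = 1.0 / overdispersion
    return rng.poisson(rng.gamma(k, lam / k))


def simulate_cohorts(config: SimulationConfig) -> SimulationResult:
    """Generate cohorts, gene lengths, pathways and the ground-truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    width = len(str(config.n_genes))
    genes = np.array([f"GENE{i:0{width}d}" for i in range(1, config.n_genes + 1)])
    lengths_bp = np.maximum(
        rng.lognormal(np.log(config.gene_length_median_bp),
                      config.gene_length_sigma, config.n_genes),
        150.0,
    ).astype(int)
    lengths = pd.Series(lengths_bp, index=genes, name="coding_length_bp")

    # planted pathways draw disjoint genes; null pathways draw from the rest
    n_planted = config.planted_pp_pathways + config.planted_np_pathways
    perm = rng.permutation(config.n_genes)
    planted_gene_idx = perm[: n_planted * config.genes_per_pathway]
    rest_idx = perm[n_planted * config.genes_per_pathway:]
    sets: dict[str, list[str]] = {}
    pw_width = len(str(config.n_pathways))
    planted_pp, planted_np = [], []
    for i in range(config.n_pathways):
        name = f"PW{i + 1:0{pw_width}d}"
        if i < config.planted_pp_pathways:
            block = planted_gene_idx[
                i * config.genes_per_pathway:(i + 1) * config.genes_per_pathway
            ]
            planted_pp.append(name)
        elif i < n_planted:
            block = planted_gene_idx[
                i * config.genes_per_pathway:(i + 1) * config.genes_per_pathway
            ]
            planted_np.append(name)
        else:
            block = rng.choice(rest_idx, size=config.genes_per_pathway, replace=False)
        sets[name] = sorted(genes[block])
    pathways = PathwayCollection(sets)

    pp_gene_mask = np.zeros(config.n_genes, dtype=bool)
    for pw in planted_pp:
        pp_gene_mask[np.isin(genes, list(pathways[pw]))] = True
    np_gene_mask = np.zeros(config.n_genes, dtype=bool)
    for pw in planted_np:
        np_gene_mask[np.isin(genes, list(pathways[pw]))] = True

    # survival gene pair: the two longest genes outside the planted sets, so
    # the carrier frequency is as realistic (high) as the model allows
    free = ~(pp_gene_mask | np_gene_mask)
    free_order = np.argsort(lengths_bp * free)
    pair_idx = free_order[-2:]
    pair_genes = sorted(str(g) for g in genes[pair_idx])

    # fixed per-gene hotspot protein changes for recurrent-mutation realism
    hotspot_pos = rng.integers(1, 800, size=(config.n_genes, 3))
    hotspot_aa = rng.integers(0, len(_AA), size=(config.n_genes, 3, 2))

    n_r = int(round(config.n_samples * config.response_rate))
    n_r = min(max(n_r, 1), config.n_samples - 1)

    cohorts = []
    for c in range(config.n_cohorts):
        cname = f"cohort{c + 1}"
        sample_ids = [f"{cname}_S{j + 1:03d}" for j in range(config.n_samples)]
        is_r = np.zeros(config.n_samples, dtype=bool)
        is_r[rng.choice(config.n_samples, size=n_r, replace=False)] = True

        # per-sample lognormal rate multiplier, normalized to mean 1
        sig = config.sample_rate_sigma
        mult = rng.lognormal(-0.5 * sig**2, sig, config.n_samples)

        base = lengths_bp[:, None] * (config.background_rate / 1e6) * mult[None, :]
        effect = np.ones_like(base)
        effect[np.ix_(pp_gene_mask, is_r)] *= config.pp_effect
        effect[np.ix_(np_gene_mask, ~is_r)] *= config.np_effect
        lam = base * effect
        counts = _draw_counts(rng, lam, config.overdispersion)
        syn_counts = rng.poisson(lam * config.synonymous_fraction)

        mutations: list[MutationRecord] = []
        # iterate samples outer, genes inner for stable record order
        for s_idx in range(config.n_samples):
            nz = np.nonzero(counts[:, s_idx] + syn_counts[:, s_idx])[0]
            for g_idx in nz:
                for _ in range(int(counts[g_idx, s_idx])):
                    cls = _NONSYN_CLASSES[
                        rng.choice(len(_NONSYN_CLASSES), p=_NONSYN_WEIGHTS)
                    ]
                    pc = None
                    if cls == "missense_variant":
                        if rng.random() < config.hotspot_fraction:
                            h = rng.integers(0, 3)
                            pc = (
                                f"{_AA[hotspot_aa[g_idx, h, 0]]}"
                                f"{hotspot_pos[g_idx, h]}"
                                f"{_AA[hotspot_aa[g_idx, h, 1]]}"
                            )
                        else:
                            pc = (
                                f"{_AA[rng.integers(0, len(_AA))]}"
                                f"{rng.integers(1, 800)}"
                                f"{_AA[rng.integers(0, len(_AA))]}"
                            )
                    mutations.append(
                        MutationRecord(
                            sample_id=sample_ids[s_idx],
                            gene=str(genes[g_idx]),
                            consequence=cls,
                            protein_change=pc,
                        )
                    )
                for _ in range(int(syn_counts[g_idx, s_idx])):
                    mutations.append(
                        MutationRecord(
                            sample_id=sample_ids[s_idx],
                            gene=str(genes[g_idx]),
                            consequence="synonymous_variant",
                        )
                    )

        carrier = (counts[pair_idx[0], :] + counts[pair_idx[1], :]) > 0
        hazard = config.baseline_hazard * np.where(
            carrier, config.survival_hazard_ratio, 1.0
        )
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / config.censoring_rate, config.n_samples)
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)

        clinical = [
            ClinicalRecord(
                sample_id=sample_ids[j],
                response="R" if is_r[j] else "NR",
                os_time=round(float(os_time[j]), 4),
                os_event=int(os_event[j]),
            )
            for j in range(config.n_samples)
        ]
        cohorts.append(CohortDataset(cname, mutations, clinical))

    manifest = {
        "planted_pp": planted_pp,
        "planted_np": planted_np,
        "survival_pair": pair_genes,
        "config": asdict(config),
    }
    return SimulationResult(cohorts, lengths, pathways, manifest)


def simulate_survival(
    n: int,
    hazard_ratio: float = 0.5,
    carrier_freq: float = 0.3,
    baseline_hazard: float = 0.05,
    censoring_rate: float = 0.03,
    seed: int = 0,
    covariates: bool = True,
) -> pd.DataFrame:
    """Exponential-baseline survival with a binary carrier indicator.

    Small analytic companion to the cohort generator for parameter-recovery
    tests of the Cox fit: carriers have hazard ``baseline * hazard_ratio``,
    censoring is independent exponential, and optional age/sex covariates
    are generated independent of survival.
    """
    rng = np.random.default_rng(seed)
    carrier = (rng.random(n) < carrier_freq).astype(int)
    hazard = baseline_hazard * np.where(carrier == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / censoring_rate, n)
    df = pd.DataFrame(
        {
            "time": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
            "carrier": carrier,
        }
    )
    if covariates:
        df["age"] = rng.normal(62.0, 10.0, n).round(1)
        df["sex"] = rng.integers(0, 2, n)
    return df


def write_fixture_bundle(result: SimulationResult, directory) -> None:
    """Write cohort TSVs, shared lengths, GMT and a key=value manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cohort in result.cohorts:
        write_mutations(cohort.mutations, directory / f"{cohort.name}_mutations.tsv")
        write_clinical(cohort.clinical, directory / f"{cohort.name}_clinical.tsv")
    write_gene_lengths(result.lengths, directory / "lengths.tsv")
    write_gmt(result.pathways, directory / "pathways.gmt")
    with open(directory / "manifest.txt", "w", encoding="utf-8") as fh:
        fh.write(f"planted_pp={','.join(result.manifest['planted_pp'])}\n")
        fh.write(f"planted_np={','.join(result.manifest['planted_np'])}\n")
        fh.write(f"survival_pair={','.join(result.manifest['survival_pair'])}\n")
        for key, value in result.manifest["config"].items():
            fh.write(f"config.{key}={value}\n")
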