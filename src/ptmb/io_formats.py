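"""On-disk formats and in-memory containers for the P-TMB pipeline.

Somatic mutations arrive as MAF-like tab-separated tables (one call per
row), clinical annotations as per-sample TSV with a RECIST-family response
label, gene coding lengths as a two-column TSV, and pathway gene sets in
Broad GMT format.  Everything is read into light dataclasses (one row, one
record) or plain pandas objects; per-sample/per-gene matrices live in
DataFrames downstream.

Consequence strings are kept verbatim at parse time; vocabulary
normalization (``missense_variant`` vs ``missense mutation``) happens in
:mod:`ptmb.burden` at classification time so that files round-trip
byte-faithfully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError, ParameterError, ValidationError

__all__ = [
    "MutationRecord",
    "ClinicalRecord",
    "CohortDataset",
    "PathwayCollection",
    "read_mutations",
    "write_mutations",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_gene_list",
    "write_table",
]

# Column vocabularies for the two supported MAF dialects.  ``maf_min`` is the
# package's own minimal dialect; ``maf_full`` accepts TCGA/firehose headers.
_DIALECTS = {
    "maf_min": {
        "sample": "sample",
        "gene": "gene",
        "consequence": "consequence",
        "protein_change": "protein_change",
        "chrom": "chrom",
        "pos": "pos",
    },
    "maf_full": {
        "sample": "Tumor_Sample_Barcode",
        "gene": "Hugo_Symbol",
        "consequence": "Variant_Classification",
        "protein_change": "Protein_Change",
        "chrom": "Chromosome",
        "pos": "Start_Position",
    },
}

_RESPONSE_MAP = {
    "r": "R",
    "responder": "R",
    "cr": "R",
    "pr": "R",
    "complete response": "R",
    "partial response": "R",
    "long-term-benefit": "R",
    "long term benefit": "R",
    "longterm benefit": "R",
    "nr": "NR",
    "non-responder": "NR",
    "nonresponder": "NR",
    "sd": "NR",
    "pd": "NR",
    "stable disease": "NR",
    "progressive disease": "NR",
    "minimal-or-no-benefit": "NR",
    "minimal or no benefit": "NR",
    "no benefit": "NR",
}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call (post-annotation), keyed by sample and gene."""

    sample_id: str
    gene: str
    consequence: str
    protein_change: str | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("MutationRecord.sample_id must be non-empty")
        if not self.gene:
            raise ValidationError("MutationRecord.gene must be non-empty")
        if self.pos is not None and self.pos <= 0:
            raise ValidationError(f"MutationRecord.pos must be positive, got {self.pos}")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical annotation: response label and optional survival."""

    sample_id: str
    response: str  # "R" or "NR"
    os_time: float | None = None
    os_event: int | None = None

    def __post_init__(self) -> None:
        if self.response not in ("R", "NR"):
            raise ValidationError(
                f"response must be 'R' or 'NR', got {self.response!r}; "
                "use read_clinical/normalize_response to map RECIST labels"
            )
        if (self.os_time is None) != (self.os_event is None):
            raise ValidationError(
                f"sample {self.sample_id}: os_time and os_event must be "
                "present together"
            )
        if self.os_time is not None and self.os_time < 0:
            raise ValidationError(f"sample {self.sample_id}: negative os_time")
        if self.os_event is not None and self.os_event not in (0, 1):
            raise ValidationError(f"sample {self.sample_id}: os_event must be 0/1")


@dataclass
class CohortDataset:
    """One ICB-treated cohort: mutation calls plus per-sample clinical data."""

    name: str
    mutations: list[MutationRecord]
    clinical: list[ClinicalRecord]

    def __post_init__(self) -> None:
        ids = [c.sample_id for c in self.clinical]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"cohort {self.name}: duplicate sample_ids {dupes}")
        known = set(ids)
        orphans = sorted({m.sample_id for m in self.mutations} - known)
        if orphans:
            raise ValidationError(
                f"cohort {self.name}: mutation sample_ids missing from "
                f"clinical table: {orphans[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.clinical]

    def response_series(self) -> pd.Series:
        return pd.Series(
            {c.sample_id: c.response for c in self.clinical}, name="response"
        ).loc[self.sample_ids]

    def mutations_by_sample(self) -> dict[str, list[MutationRecord]]:
        out: dict[str, list[MutationRecord]] = {s: [] for s in self.sample_ids}
        for m in self.mutations:
            out[m.sample_id].append(m)
        return out


class PathwayCollection:
    """Ordered mapping pathway name -> set of gene symbols."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        self._sets: dict[str, frozenset[str]] = {}
        for name, genes in sets.items():
            gset = frozenset(genes)
            if not gset:
                raise ValidationError(f"pathway {name!r} has an empty gene set")
            if name in self._sets:
                raise ValidationError(f"duplicate pathway name {name!r}")
            self._sets[name] = gset

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __eq__(self, other) -> bool:
        return isinstance(other, PathwayCollection) and self._sets == other._sets

    def items(self):
        return self._sets.items()

    def names(self) -> list[str]:
        return list(self._sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self._sets.values():
            out |= g
        return frozenset(out)

    def subset(self, names: Sequence[str]) -> "PathwayCollection":
        return PathwayCollection({n: self._sets[n] for n in names})


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_mutations(path, dialect: str = "maf_min") -> list[MutationRecord]:
    """Read a MAF-like mutation TSV into records.

    Unknown columns are ignored; consequence strings are preserved verbatim.
    """
    if dialect not in _DIALECTS:
        raise ParameterError(f"unknown MAF dialect {dialect!r}; use maf_min or maf_full")
    cols = _DIALECTS[dialect]
    df = _read_tsv(path)
    for required in ("sample", "gene", "consequence"):
        if cols[required] not in df.columns:
            raise FormatError(
                f"{path}: missing required column {cols[required]!r} "
                f"(dialect {dialect})"
            )
    if df.empty:
        warnings.warn(f"{path}: no mutation rows", stacklevel=2)
        return []
    has_pc = cols["protein_change"] in df.columns
    has_chrom = cols["chrom"] in df.columns
    has_pos = cols["pos"] in df.columns
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        pc = row.get(cols["protein_change"], "") if has_pc else ""
        chrom = row.get(cols["chrom"], "") if has_chrom else ""
        pos = row.get(cols["pos"], "") if has_pos else ""
        records.append(
            MutationRecord(
                sample_id=row[cols["sample"]],
                gene=row[cols["gene"]],
                consequence=row[cols["consequence"]],
                protein_change=pc or None,
                chrom=chrom or None,
                pos=int(pos) if pos else None,
            )
        )
    return records


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column gene/length TSV into a Series (bp, int) indexed by gene."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (gene, length)")
    lengths = {}
    # positional: first column is gene, second is length
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene, raw = row[0], row[1]
        if gene in lengths:
            raise ValidationError(f"{path}: duplicate gene {gene!r} at row {i}")
        try:
            value = int(raw)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: non-integer length {raw!r} for gene {gene!r} at row {i}"
            ) from None
        if value <= 0:
            raise ValidationError(
                f"{path}: non-positive length {value} for gene {gene!r} at row {i}"
            )
        lengths[gene] = value
    return pd.Series(lengths, name="coding_length_bp", dtype=int)


def read_gmt(path) -> PathwayCollection:
    """Read a Broad-format GMT file: name, description, member genes."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway {name!r}")
            sets[name] = set(g for g in fields[2:] if g)
    return PathwayCollection(sets)


def normalize_response(label: str) -> str:
    """Map a RECIST-family response label to R/NR."""
    key = label.strip().lower().replace("_", " ")
    if key in _RESPONSE_MAP:
        return _RESPONSE_MAP[key]
    raise ValidationError(f"unmappable response label {label!r}")


def read_clinical(path) -> list[ClinicalRecord]:
    """Read a clinical TSV: sample_id, response, optional os_time/os_event."""
    df = _read_tsv(path)
    for required in ("sample_id", "response"):
        if required not in df.columns:
            raise FormatError(f"{path}: missing required column {required!r}")
    has_time = "os_time" in df.columns
    has_event = "os_event" in df.columns
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        t = d.get("os_time", "") if has_time else ""
        e = d.get("os_event", "") if has_event else ""
        records.append(
            ClinicalRecord(
                sample_id=d["sample_id"],
                response=normalize_response(d["response"]),
                os_time=float(t) if t else None,
                os_event=int(e) if e else None,
            )
        )
    return records


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list, keeping order, dropping blanks."""
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# writers (round-trip counterparts)
# ---------------------------------------------------------------------------


def _comment_block(params: Mapping[str, object] | None) -> str:
    from . import __version__

    lines = [f"# ptmb {__version__}"]
    for k, v in (params or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, params: Mapping[str, object] | None = None) -> None:
    """Write a result DataFrame as TSV with a ``#`` provenance comment block."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_block(params))
        df.to_csv(fh, sep="\t", index=False)


def write_mutations(records: Sequence[MutationRecord], path, dialect: str = "maf_min") -> None:
    cols = _DIALECTS[dialect]
    df = pd.DataFrame(
        {
            cols["sample"]: [m.sample_id for m in records],
            cols["gene"]: [m.gene for m in records],
            cols["consequence"]: [m.consequence for m in records],
            cols["protein_change"]: [m.protein_change or "" for m in records],
            cols["chrom"]: [m.chrom or "" for m in records],
            cols["pos"]: ["" if m.pos is None else m.pos for m in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_gene_lengths(lengths: pd.Series, path) -> None:
    df = pd.DataFrame({"gene": lengths.index, "coding_length_bp": lengths.values})
    df.to_csv(path, sep="\t", index=False)


def write_gmt(pathways: PathwayCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def write_clinical(records: Sequence[ClinicalRecord], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in records],
            "response": [c.response for c in records],
            "os_time": ["" if c.os_time is None else repr(c.os_time) for c in records],
            "os_event": ["" if c.os_event is None else c.os_event for c in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
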