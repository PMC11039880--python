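"""Core domain types for the ceRNA analysis pipeline.

The experiment is a 2x2 design: Oct4 knockdown (siNT vs siOct4) crossed with
oxidized-phospholipid treatment (DMSO vehicle vs POVPC), assayed on three
molecule classes (lncRNA, mRNA, miRNA) as feature x sample intensity matrices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class Knockdown(str, enum.Enum):
    siNT = "siNT"
    siOct4 = "siOct4"


class Treatment(str, enum.Enum):
    DMSO = "DMSO"
    POVPC = "POVPC"


class MoleculeClass(str, enum.Enum):
    lncRNA = "lncRNA"
    mRNA = "mRNA"
    miRNA = "miRNA"


#: (knockdown, treatment) pair naming one cell of the 2x2 design.
Condition = Tuple[Knockdown, Treatment]


def condition_label(cond: Condition) -> str:
    return f"{cond[0].value}-{cond[1].value}"


@dataclass(frozen=True)
class Sample:
    """One array sample: a replicate of one design cell."""

    sample_id: str
    knockdown: Knockdown
    treatment: Treatment
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def condition(self) -> Condition:
        return (self.knockdown, self.treatment)


class SampleDesign:
    """Ordered collection of samples with unique ids, aligned to matrix columns."""

    def __init__(self, samples: Sequence[Sample]):
        ids = [s.sample_id for s in samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample ids in design: {sorted(dupes)}")
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleDesign) and self.samples == other.samples

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def columns_for(self, cond: Condition) -> list[str]:
        """Sample ids belonging to one design cell, in design order."""
        return [s.sample_id for s in self.samples if s.condition == cond]

    def require_replicates(self, cond: Condition, n: int = 2) -> list[str]:
        cols = self.columns_for(cond)
        if len(cols) < n:
            raise ValueError(
                f"condition {condition_label(cond)} has {len(cols)} replicate(s); "
                f"need >= {n}"
            )
        return cols


@dataclass(frozen=True)
class Comparison:
    """A two-group contrast: test condition over control condition."""

    name: str
    test_group: Condition
    control_group: Condition

    def __post_init__(self) -> None:
        if self.test_group == self.control_group:
            raise ValueError("comparison test and control groups must differ")


def _cmp(test: Condition, control: Condition) -> Comparison:
    return Comparison(
        name=f"{condition_label(test)}_vs_{condition_label(control)}",
        test_group=test,
        control_group=control,
    )


#: The three contrasts of the study: POVPC effect in wild type, Oct4 knockdown
#: effect, and POVPC effect under Oct4 deficiency.
CANONICAL_COMPARISONS: tuple[Comparison, ...] = (
    _cmp((Knockdown.siNT, Treatment.POVPC), (Knockdown.siNT, Treatment.DMSO)),
    _cmp((Knockdown.siOct4, Treatment.DMSO), (Knockdown.siNT, Treatment.DMSO)),
    _cmp((Knockdown.siOct4, Treatment.POVPC), (Knockdown.siOct4, Treatment.DMSO)),
)


def comparison_by_name(name: str) -> Comparison:
    for c in CANONICAL_COMPARISONS:
        if c.name == name:
            return c
    known = ", ".join(c.name for c in CANONICAL_COMPARISONS)
    raise KeyError(f"unknown comparison {name!r}; canonical comparisons: {known}")


class ExpressionMatrix:
    """Feature x sample matrix of nonnegative intensities with its design.

    ``data`` is a pandas DataFrame indexed by feature id with one column per
    sample, column order matching the design.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        design: SampleDesign,
        molecule_class: MoleculeClass,
        normalized: bool = False,
    ):
        if list(data.columns) != design.sample_ids:
            raise ValueError("matrix columns do not match design sample ids/order")
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise ValueError(f"duplicate feature ids: {dupes}")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("matrix contains missing values")
        if (values < 0).any():
            raise ValueError("matrix contains negative intensities")
        self.data = data.astype(float)
        self.design = design
        self.molecule_class = MoleculeClass(molecule_class)
        self.normalized = bool(normalized)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def group_values(self, cond: Condition) -> pd.DataFrame:
        return self.data[self.design.columns_for(cond)]

    def with_data(self, data: pd.DataFrame, normalized: Optional[bool] = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            data,
            self.design,
            self.molecule_class,
            self.normalized if normalized is None else normalized,
        )


class Strand(str, enum.Enum):
    plus = "+"
    minus = "-"


@dataclass
class GenomicFeature:
    """Stranded genomic interval (0-based, half-open) for one annotated feature."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: Strand
    molecule_class: MoleculeClass
    gene_name: Optional[str] = None
    exons: Optional[list[tuple[int, int]]] = None
    annotated_in_reference: bool = True

    def __post_init__(self) -> None:
        self.strand = Strand(self.strand)
        self.molecule_class = MoleculeClass(self.molecule_class)
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"{self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.exons is not None:
            exons = sorted((int(a), int(b)) for a, b in self.exons)
            for (a, b) in exons:
                if a < self.start or b > self.end or a >= b:
                    raise ValueError(f"{self.feature_id}: exon ({a},{b}) outside span")
            for (_, b1), (a2, _) in zip(exons, exons[1:]):
                if a2 < b1:
                    raise ValueError(f"{self.feature_id}: overlapping exons")
            self.exons = exons

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand is Strand.plus else self.end - 1

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Exons when annotated, else the whole span treated as exonic."""
        return self.exons if self.exons else [(self.start, self.end)]


class InteractionKind(str, enum.Enum):
    lnc_mir = "lnc_mir"
    mir_mrna = "mir_mrna"


class Evidence(str, enum.Enum):
    validated = "validated"
    predicted = "predicted"


#: Separator used when one interaction row is attributed to a miRNA family
#: (several co-listed miRNAs sharing a target), as target databases print them.
MIRNA_GROUP_SEP = "|"


@dataclass(frozen=True)
class InteractionRecord:
    """One lncRNA->miRNA binding edge or miRNA->mRNA targeting edge.

    ``source_id`` may name a miRNA family as a ``|``-joined list for mir_mrna
    rows; row multiplicity in input tables is preserved verbatim.
    """

    kind: InteractionKind
    source_id: str
    target_id: str
    binding_sites: Optional[int] = None
    evidence: Evidence = Evidence.validated

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", InteractionKind(self.kind))
        object.__setattr__(self, "evidence", Evidence(self.evidence))
        if self.kind is InteractionKind.lnc_mir:
            if self.binding_sites is None or self.binding_sites < 1:
                raise ValueError(
                    f"lnc_mir edge {self.source_id}->{self.target_id}: "
                    f"binding_sites must be >= 1"
                )

    @property
    def source_members(self) -> tuple[str, ...]:
        return tuple(m for m in self.source_id.split(MIRNA_GROUP_SEP) if m)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} has no members")


@dataclass(frozen=True)
class DiseaseAnnotation:
    lncRNA_id: str
    disease_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lncRNA_id:
            raise ValueError("lncRNA_id must be non-empty")


class DEStatus(str, enum.Enum):
    up = "up"
    down = "down"
    ns = "ns"


@dataclass
class DERecord:
    """Per-feature differential-expression result for one comparison.

    ``fc`` is the linear fold change test/control on group means; downregulation
    is fc < 1. ``raw_intensity`` is the un-normalized test-group mean signal,
    used by the expressed-lncRNA filter (> 100 in raw fluorescence units).
    """

    feature_id: str
    comparison: str
    mean_test: float
    mean_control: float
    fc: float
    log2fc: float
    p: float
    adj_p: float
    raw_intensity: float
    status: DEStatus
    annotated_in_reference: bool = True

    def __post_init__(self) -> None:
        self.status = DEStatus(self.status)
        if self.fc <= 0:
            raise ValueError(f"{self.feature_id}: fold change must be positive")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"{self.feature_id}: p out of [0,1]")
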