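"""Prevalence-weighted summaries of population-sequencing mutation tables.

Each record is one variant in one population with the fraction of reads
carrying it (its prevalence) and an optional protein-class annotation.
Summaries: a prevalence filter (boundary-inclusive: "present at <5%" are
dropped, exactly 5% is kept) and a class histogram where each mutation
contributes its prevalence as weight, so a gene hit twice contributes twice
and unclassified genes form their own bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EmptyTableError, ParameterError

UNCLASSIFIED = "unclassified"
DEFAULT_PREVALENCE_THRESHOLD = 0.05


@dataclass(frozen=True)
class MutationRecord:
    """One variant with its population prevalence and annotation."""

    population: str
    position: int          # 1-based genomic coordinate
    gene: str
    mutation: str          # free-text description (SNP/indel/IS insertion)
    prevalence: float      # fraction of reads in [0, 1]
    protein_class: str = ""  # empty = unclassified

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ParameterError("prevalence must lie in [0, 1]")
        if self.position < 1:
            raise ParameterError("position must be >= 1")

    @property
    def class_label(self) -> str:
        label = self.protein_class.strip() if self.protein_class else ""
        return label if label else UNCLASSIFIED


@dataclass
class ClassHistogram:
    """Prevalence-weighted protein-class histogram."""

    entries: dict[str, float]          # class -> summed prevalence weight
    total_weight: float = field(init=False)
    fractions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.entries.values()):
            raise ParameterError("histogram weights must be non-negative")
        self.total_weight = float(sum(self.entries.values()))
        if self.total_weight > 0:
            self.fractions = {k: w / self.total_weight
                              for k, w in self.entries.items()}
        else:
            self.fractions = {k: 0.0 for k in self.entries}


def filter_prevalence(records: list[MutationRecord],
                      threshold: float = DEFAULT_PREVALENCE_THRESHOLD
                      ) -> list[MutationRecord]:
    """Keep records with prevalence >= threshold, preserving order.

    Boundary-inclusive: a mutation at exactly the threshold is retained
    (only those "present at <threshold" are dropped).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold must lie in [0, 1]")
    return [r for r in records if r.prevalence >= threshold]


def class_histogram(records: list[MutationRecord]) -> ClassHistogram:
    """Per-class summed prevalence weights, normalized to fractions.

    Every mutation contributes its own prevalence to its gene's class;
    records without a class annotation accumulate in the "unclassified" bin.
    """
    if not records:
        raise EmptyTableError("cannot histogram an empty mutation table")
    entries: dict[str, float] = {}
    for r in records:
        entries[r.class_label] = entries.get(r.class_label, 0.0) + r.prevalence
    return ClassHistogram(entries=entries)


def merge_histograms(*hists: ClassHistogram) -> ClassHistogram:
    """Weight-wise sum of histograms (e.g. pooling several populations)."""
    if not hists:
        raise EmptyTableError("nothing to merge")
    entries: dict[str, float] = {}
    for h in hists:
        for k, w in h.entries.items():
            entries[k] = entries.get(k, 0.0) + w
    return ClassHistogram(entries=entries)


def unclassified_fraction(hist: ClassHistogram) -> float:
    """Fraction of total scaled weight in the unclassified bin (0 if absent)."""
    return hist.fractions.get(UNCLASSIFIED, 0.0)


def annotate_classes(records: list[MutationRecord],
                     gene_to_class: dict[str, str]) -> list[MutationRecord]:
    """Attach protein classes from a gene→class mapping.

    A record whose gene is missing from the mapping (or maps to an empty
    string) stays unclassified; existing annotations are overwritten.
    """
    out = []
    for r in records:
        label = gene_to_class.get(r.gene, "")
        out.append(MutationRecord(population=r.population, position=r.position,
                                  gene=r.gene, mutation=r.mutation,
                                  prevalence=r.prevalence,
                                  protein_class=label))
    return out
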