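"""Core domain types for gene-panel variant prioritization.

The pipeline operates on normalized single-alt variant records joined to an
annotation table, pedigrees with affection status, and a panel definition
carrying per-gene inheritance modes. Coordinates are 1-based, fully closed
(VCF convention) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Optional

#: (chrom, pos 1-based, ref, alt) after decomposition and minimal representation.
VariantKey = tuple[str, int, str, str]


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"
    MISSING = "missing"

    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI)


class Consequence(str, Enum):
    """Collapsed functional-consequence vocabulary used by the report tables."""

    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequences expected to truncate or severely deform the protein product.
TRUNCATING_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT_DELETION,
        Consequence.FRAMESHIFT_INSERTION,
        Consequence.SPLICING,
    }
)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class InheritanceModel(str, Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"


#: Iteration order when several models fit a pedigree.
MODEL_PRECEDENCE = (InheritanceModel.AD, InheritanceModel.XL, InheritanceModel.AR)


class ReferenceStatus:
    """Prior-report status of a variant: novel, a dbSNP id, or a citation."""

    __slots__ = ("label",)

    def __init__(self, label: str):
        self.label = label.strip()

    @property
    def is_novel(self) -> bool:
        return self.label.lower() == "novel" or self.label == ""

    @property
    def is_dbsnp(self) -> bool:
        return self.label.lower().startswith("rs") and self.label[2:].isdigit()

    @property
    def is_literature(self) -> bool:
        return not (self.is_novel or self.is_dbsnp)

    @property
    def rsid(self) -> Optional[str]:
        return self.label if self.is_dbsnp else None

    def __eq__(self, other):
        return isinstance(other, ReferenceStatus) and self.label == other.label

    def __hash__(self):
        return hash(self.label)

    def __repr__(self):
        return f"ReferenceStatus({self.label!r})"

    def __str__(self):
        return self.label if self.label else "novel"


@dataclass(frozen=True)
class VariantRecord:
    """One normalized (site, alt) observation with per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: Optional[float]
    genotypes: dict[str, Genotype] = field(default_factory=dict, compare=False)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotationRow:
    """Functional and population annotation for one variant key.

    Missing population frequencies are ``None`` (absent), never 0 — the filter
    layer treats "not reported in this database" as its own state.
    """

    variant_key: VariantKey
    gene: str
    exon: int
    hgvs_c: str
    hgvs_p: str
    consequence: Consequence
    af_evs: Optional[float]
    af_1kg: Optional[float]
    af_inhouse: Optional[float]
    reference_status: ReferenceStatus

    def __post_init__(self):
        for name in ("af_evs", "af_1kg", "af_inhouse"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        ref, alt = self.variant_key[2], self.variant_key[3]
        for allele in (ref, alt):
            if not allele or any(b not in "ACGT" for b in allele):
                raise ValueError(f"allele {allele!r} is not uppercase DNA")

    @property
    def frequencies(self) -> dict[str, Optional[float]]:
        return {"evs": self.af_evs, "1kg": self.af_1kg, "inhouse": self.af_inhouse}


@dataclass(frozen=True)
class KnownPathogenicEntry:
    gene: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    rsid: str = ""
    citation: str = ""

    def __post_init__(self):
        if not (self.hgvs_c or self.hgvs_p or self.rsid):
            raise ValueError("entry needs at least one of hgvs_c/hgvs_p/rsid")


@dataclass(frozen=True)
class PanelGene:
    gene: str
    modes: frozenset[str]  # subset of {"AD", "AR", "XL", "digenic"}
    refseq: str
    cytoband: str
    exon_count: int

    def __post_init__(self):
        if not self.modes:
            raise ValueError(f"panel gene {self.gene} has no inheritance modes")
        bad = self.modes - {"AD", "AR", "XL", "digenic"}
        if bad:
            raise ValueError(f"unknown modes {bad} for {self.gene}")

    @property
    def chrom(self) -> str:
        """Chromosome label parsed from the cytogenetic band."""
        band = self.cytoband
        if band[:1] in ("X", "Y"):
            return band[0]
        i = 0
        while i < len(band) and band[i].isdigit():
            i += 1
        return band[:i]

    def supports(self, model: InheritanceModel) -> bool:
        return model.value in self.modes


@dataclass(frozen=True)
class Individual:
    iid: str
    father: Optional[str]
    mother: Optional[str]
    sex: Sex
    affection: Affection

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Directed family graph; parent links resolved, founders have no parents."""

    family_id: str
    individuals: dict[str, Individual]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.individuals:
            raise PedigreeError(f"pedigree {self.family_id!r} is empty")
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self.individuals:
                    raise PedigreeError(
                        f"{self.family_id}: individual {ind.iid} references "
                        f"absent parent {parent}"
                    )
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"{self.family_id}: individual {ind.iid} has exactly one "
                    "parent; founders must have both parents absent"
                )
        # cycle check by DFS over parent links
        state: dict[str, int] = {}

        def visit(iid: str, stack: tuple[str, ...]) -> None:
            if iid in stack:
                raise PedigreeError(
                    f"{self.family_id}: {iid} is its own ancestor"
                )
            if state.get(iid) == 2:
                return
            ind = self.individuals[iid]
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    visit(parent, stack + (iid,))
            state[iid] = 2

        for iid in self.individuals:
            visit(iid, ())

    # --- structure queries -------------------------------------------------

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_founder]

    def affected(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.affection is Affection.AFFECTED]

    def children_of(self, iid: str) -> list[Individual]:
        return [
            i for i in self.individuals.values() if iid in (i.father, i.mother)
        ]

    def depth(self, iid: str) -> int:
        """Founder depth: founders are 0, a child is 1 + max parent depth."""
        ind = self.individuals[iid]
        if ind.is_founder:
            return 0
        return 1 + max(self.depth(ind.father), self.depth(ind.mother))

    def generation_levels(self) -> dict[int, list[Individual]]:
        levels: dict[int, list[Individual]] = {}
        for ind in self.individuals.values():
            levels.setdefault(self.depth(ind.iid), []).append(ind)
        return levels

    @property
    def n_generations(self) -> int:
        return max(self.depth(i) for i in self.individuals) + 1


class PathogenicityClass(IntEnum):
    """Four-tier pathogenicity scheme.

    I  — previously reported pathogenic;
    II — predicted severe: truncating (stopgain/frameshift/canonical splice)
         or missense supported by the in-silico ensemble;
    III — protein-changing but not ensemble-supported;
    IV — everything else.
    """

    I = 1
    II = 2
    III = 3
    IV = 4

    @property
    def roman(self) -> str:
        return self.name


@dataclass(frozen=True)
class Classification:
    value: PathogenicityClass
    rationale: str

    def __post_init__(self):
        if not self.rationale:
            raise ValueError("rationale must be non-empty")


class PolyPhen2(str, Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    MISSING = "missing"


class Sift(str, Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


@dataclass(frozen=True)
class PredictorOutputs:
    polyphen2: PolyPhen2 = PolyPhen2.MISSING
    sift: Sift = Sift.MISSING
    mutpred: Optional[float] = None

    def __post_init__(self):
        if self.mutpred is not None and not (0.0 <= self.mutpred <= 1.0):
            raise ValueError(f"mutpred={self.mutpred} outside [0, 1]")


class PhaseStatus(str, Enum):
    RESOLVED_TRANS = "resolved_trans"
    RESOLVED_CIS = "resolved_cis"
    ASSUMED_TRANS = "assumed_trans"


@dataclass(frozen=True)
class SegregationViolation:
    individual: str
    expected: tuple[Genotype, ...]
    observed: Genotype


@dataclass(frozen=True)
class SegregationResult:
    model: InheritanceModel
    consistent: bool
    violations: tuple[SegregationViolation, ...] = ()
    untested: tuple[str, ...] = ()

    def __post_init__(self):
        if self.consistent != (len(self.violations) == 0):
            raise ValueError("consistent must mirror empty violations")


class UnitKind(str, Enum):
    FAMILIAL = "familial"
    SIMPLEX = "simplex"


@dataclass(frozen=True)
class CaseUnit:
    unit_id: str
    kind: UnitKind
    pedigree: Pedigree
    proband_id: str


@dataclass(frozen=True)
class CandidateCall:
    """One prioritized finding: a single variant (AD/XL/hom-AR) or an
    in-trans pair (compound-het AR), with per-allele classes attached."""

    unit_id: str
    gene: str
    model: InheritanceModel
    variants: tuple[AnnotationRow, ...]
    member_classes: tuple[Classification, ...]
    genotype_label: str  # "Hetero" | "Hemi" | "Homo" | "Compound hetero"
    phase_status: Optional[PhaseStatus] = None
    segregation: Optional[SegregationResult] = None
    confirmed: bool = False
    primary: bool = True

    def __post_init__(self):
        if len(self.variants) != len(self.member_classes):
            raise ValueError("one class per member variant required")
        if self.model is InheritanceModel.AR:
            if len(self.variants) not in (1, 2):
                raise ValueError("AR call carries one hom-alt variant or a pair")
        elif len(self.variants) != 1:
            raise ValueError(f"{self.model.value} call carries exactly one variant")

    @property
    def call_class(self) -> PathogenicityClass:
        return min(c.value for c in self.member_classes)


@dataclass(frozen=True)
class CarrierFinding:
    """A single qualifying allele in a recessive gene without a qualifying
    counter-allele — reported, never counted as solving the case."""

    unit_id: str
    gene: str
    variant: AnnotationRow
    classification: Classification
    reason: str


def truncate_pct(x: float, digits: int = 1) -> float:
    """Truncate a percentage toward zero at ``digits`` decimals (7/16 -> 43.7)."""
    scale = 10**digits
    return math.floor(x * scale) / scale


@dataclass(frozen=True)
class CohortSummary:
    n_familial: int
    n_simplex: int
    solved_familial: int
    solved_simplex: int
    overall_rate: float  # percent
    novel_fraction: float  # percent over candidate variant occurrences
    per_gene_counts: dict[str, dict[str, float]]  # stratum -> gene -> percent share
    compound_het_count: int
    single_allele_carriers: tuple[CarrierFinding, ...]
    n_candidate_variants: int = 0
    simplex_ar_share: float = 0.0  # % of solved simplex units under AR

    @property
    def familial_rate(self) -> float:
        if self.n_familial == 0:
            return 0.0
        return truncate_pct(100.0 * self.solved_familial / self.n_familial)

    @property
    def simplex_rate(self) -> float:
        if self.n_simplex == 0:
            return 0.0
        return truncate_pct(100.0 * self.solved_simplex / self.n_simplex)


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: trim shared suffix, then shared prefix.

    Keeps at least one base on each side; adjusts pos for prefix trimming.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt
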