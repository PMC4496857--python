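"""Four-tier pathogenicity classification with a 2-of-3 in-silico ensemble.

Class I: previously reported pathogenic (matched against the known-variant
table by gene + HGVS or by dbSNP id). Class II: variants expected to wreck
the protein — stopgain, frameshift, canonical splice — or novel missense
calls supported by at least two of PolyPhen-2, SIFT and MutPred. Class III:
protein-changing but not ensemble-supported. Class IV: everything else.

Vote semantics: PolyPhen-2 counts "probably" and "possibly damaging", SIFT
counts "damaging", MutPred counts a score strictly above 0.5. A missing
predictor contributes no vote (conservative: truncating variants have no
missense scores and must not error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .models import (
    AnnotationRow,
    Classification,
    Consequence,
    KnownPathogenicEntry,
    PathogenicityClass,
    PolyPhen2,
    PredictorOutputs,
    Sift,
    TRUNCATING_CONSEQUENCES,
)


@dataclass(frozen=True)
class ClassifierConfig:
    mutpred_threshold: float = 0.5  # strict: a vote requires score > threshold
    votes_required: int = 2
    polyphen_pathogenic: frozenset[PolyPhen2] = frozenset(
        {PolyPhen2.PROBABLY_DAMAGING, PolyPhen2.POSSIBLY_DAMAGING}
    )
    splice_class2: bool = True  # canonical splice variants are Class II-eligible

    def __post_init__(self):
        if not (1 <= self.votes_required <= 3):
            raise ValueError("votes_required must be in 1..3")


def ensemble_vote(
    pred: PredictorOutputs, config: ClassifierConfig = ClassifierConfig()
) -> tuple[bool, int]:
    """Count damaging votes across the three predictors.

    Returns (pathogenic, votes) where pathogenic means votes >= the
    configured quorum. A MutPred score exactly at the threshold is NOT a
    vote.
    """
    votes = 0
    if pred.polyphen2 in config.polyphen_pathogenic:
        votes += 1
    if pred.sift is Sift.DAMAGING:
        votes += 1
    if pred.mutpred is not None and pred.mutpred > config.mutpred_threshold:
        votes += 1
    return votes >= config.votes_required, votes


def is_known_pathogenic(
    annotation: AnnotationRow, db: list[KnownPathogenicEntry]
) -> Optional[KnownPathogenicEntry]:
    """First database entry matching by gene + HGVS (c. or p.) or by rsid."""
    rsid = annotation.reference_status.rsid
    for entry in db:
        if entry.gene == annotation.gene and (
            (entry.hgvs_c and entry.hgvs_c == annotation.hgvs_c)
            or (entry.hgvs_p and entry.hgvs_p == annotation.hgvs_p)
        ):
            return entry
        if entry.rsid and rsid and entry.rsid == rsid:
            return entry
    return None


def classify(
    annotation: AnnotationRow,
    pred: PredictorOutputs,
    db: list[KnownPathogenicEntry],
    config: ClassifierConfig = ClassifierConfig(),
) -> Classification:
    """Assign one of the four classes to a cascade-filtered variant."""
    entry = is_known_pathogenic(annotation, db)
    if entry is not None:
        who = entry.citation or entry.rsid or "known"
        return Classification(PathogenicityClass.I, f"previously reported ({who})")

    cons = annotation.consequence
    truncating = cons in TRUNCATING_CONSEQUENCES
    if cons is Consequence.SPLICING and not config.splice_class2:
        truncating = False
    if truncating:
        return Classification(PathogenicityClass.II, f"truncating consequence ({cons.value})")

    if cons is Consequence.NONSYNONYMOUS:
        pathogenic, votes = ensemble_vote(pred, config)
        if pathogenic:
            return Classification(
                PathogenicityClass.II,
                f"missense with {votes}/3 damaging predictions",
            )
        return Classification(
            PathogenicityClass.III,
            f"missense with only {votes}/3 damaging predictions",
        )
    return Classification(PathogenicityClass.IV, f"other consequence ({cons.value})")


def classify_members(
    annotations: tuple[AnnotationRow, ...],
    predictors,
    db: list[KnownPathogenicEntry],
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[Classification, ...]:
    """Classify every member allele of a (possibly compound) candidate.

    ``predictors`` maps variant key -> PredictorOutputs (an AnnotationTable
    works). The call-level class is the best (lowest) member class; pairs
    keep both member classes for reporting.
    """
    out = []
    for ann in annotations:
        if hasattr(predictors, "predictors_for"):
            pred = predictors.predictors_for(ann.variant_key)
        else:
            pred = predictors.get(ann.variant_key, PredictorOutputs())
        out.append(classify(ann, pred, db, config))
    return tuple(out)
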