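"""End-to-end prediction from sequences and a scanner domain table.

Glues the stages together the way the workflow runs in practice: delimit
each C/E core's Down-Seq, classify it by signature, classify it by
context, reconcile, rebuild the per-protein token lists with the
reconciled subtypes, segment and concatenate into an assembly, and infer
monomer isomery.
"""

from __future__ import annotations

from dataclasses import dataclass

from .archmodel import (
    Assembly,
    C_TYPES,
    DomainAnnotation,
    DomainToken,
    Organism,
    concat_assembly,
)
from .classify import (
    SubtypeCall,
    classify_by_context,
    classify_by_signature,
    reconcile,
)
from .downseq import SpacerExpectation, delimit_regions
from .isomery import PeptidePrediction, predict_structure
from .logos import SignatureModel


@dataclass
class PipelineResult:
    assembly: Assembly
    calls: list[SubtypeCall]
    prediction: PeptidePrediction


def classify_annotations(
    sequences: dict[str, str],
    annotations: list[DomainAnnotation],
    models: dict[DomainToken, SignatureModel] | None = None,
    expectation: SpacerExpectation = SpacerExpectation(),
    threshold_frac: float = 0.6,
    min_margin: float = 3.0,
) -> list[SubtypeCall]:
    """Reconciled subtype calls for every C/E-superfamily core annotation.

    Signature classification runs only when models are supplied; otherwise
    the context calls stand alone.
    """
    context_calls = {
        (c.protein_id, c.interval): c for c in classify_by_context(annotations)
    }
    calls = []
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)
    for protein_id, rows in by_protein.items():
        rows = sorted(rows, key=lambda r: r.start)
        seq = sequences.get(protein_id)
        for i, ann in enumerate(rows):
            if ann.kind not in C_TYPES:
                continue
            key = (protein_id, (ann.start, ann.end))
            ctx = context_calls[key]
            if models is None or seq is None:
                calls.append(ctx)
                continue
            next_start = rows[i + 1].start if i + 1 < len(rows) else None
            split = delimit_regions(
                (ann.start, ann.end), next_start, len(seq), expectation
            )
            down = seq[split.downseq[0] : split.downseq[1]]
            sig = classify_by_signature(
                down,
                models,
                threshold_frac=threshold_frac,
                min_margin=min_margin,
                protein_id=protein_id,
                interval=(ann.start, ann.end),
            )
            merged = reconcile(ctx, sig)
            merged.flags.extend(split.flags)
            calls.append(merged)
    return calls


def assembly_from_annotations(
    annotations: list[DomainAnnotation],
    calls: list[SubtypeCall] | None = None,
    organism_hint: Organism = Organism.UNKNOWN,
    protein_order: list[str] | None = None,
) -> Assembly:
    """Token lists from an annotation table (plus subtype calls) -> assembly.

    Each C/E core annotation is replaced by its reconciled subtype token
    when a call exists; gene order follows ``protein_order`` or first
    appearance in the table.
    """
    call_map = {}
    for c in calls or []:
        call_map[(c.protein_id, c.interval)] = c
    by_protein: dict[str, list[DomainAnnotation]] = {}
    order: list[str] = []
    for ann in annotations:
        if ann.protein_id not in by_protein:
            order.append(ann.protein_id)
        by_protein.setdefault(ann.protein_id, []).append(ann)
    if protein_order is not None:
        order = list(protein_order)
    synthetases = []
    for pid in order:
        tokens = []
        for ann in sorted(by_protein[pid], key=lambda r: r.start):
            kind = ann.kind
            call = call_map.get((pid, (ann.start, ann.end)))
            if call is not None and call.subtype is not None:
                kind = call.subtype
            tokens.append(kind)
        synthetases.append((pid, tokens))
    return concat_assembly(synthetases, organism_hint)


def predict_from_annotations(
    sequences: dict[str, str],
    annotations: list[DomainAnnotation],
    models: dict[DomainToken, SignatureModel] | None = None,
    organism_hint: Organism = Organism.UNKNOWN,
    monomer_predictions: list[list[str]] | None = None,
    racemase_present: bool = False,
    chromophore_candidates: list[str] | None = None,
    protein_order: list[str] | None = None,
) -> PipelineResult:
    """The full workflow: classify, assemble, and predict the peptide."""
    calls = classify_annotations(sequences, annotations, models)
    assembly = assembly_from_annotations(
        annotations, calls, organism_hint, protein_order
    )
    prediction = predict_structure(
        assembly, monomer_predictions, racemase_present, chromophore_candidates
    )
    prediction.provenance = "+".join(pid for pid, _ in assembly.synthetases)
    return PipelineResult(assembly, calls, prediction)
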